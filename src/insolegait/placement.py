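"""Sensor-reduction study tools: rank sensors per gait event and score subsets.

Given recordings from a dense sensor grid and events detected on the
full-configuration vGRF, each sensor is ranked by *responsivity* (how quickly
it crosses its force threshold after the event) and *amplitude* (its peak
force around the event).  A reduced subset is scored by how synchronously it
detects events compared with the full set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .biomech import GaitSignals, VoltageStream, process_stream
from .events import StrideTable, detect_events
from .layout import InsoleLayout
from .transduction import TactelCalibration, force_from_voltage, system_force_threshold

__all__ = ["SensorScore", "SensorRanking", "rank_sensors", "evaluate_subset", "SubsetEvaluation"]

#: sentinel latency for sensors that never cross threshold in any window
NEVER = math.inf


@dataclass(frozen=True)
class SensorScore:
    sensor_id: int
    latency: float      # s, median crossing latency from the event; inf if never
    amplitude: float    # N, median peak force in the event window


@dataclass(frozen=True)
class SensorRanking:
    """Ordered sensor scores per event type; best sensors first."""

    hs: tuple[SensorScore, ...]
    to: tuple[SensorScore, ...]

    def ids(self, event: str) -> list[int]:
        return [s.sensor_id for s in getattr(self, event)]


def _rank_for_event(
    t: np.ndarray,
    forces: np.ndarray,
    ids: np.ndarray,
    event_times: np.ndarray,
    window: float,
    thresh: float,
    rising: bool,
) -> tuple[SensorScore, ...]:
    n_sensors = forces.shape[1]
    latencies = np.full(n_sensors, NEVER)
    amplitudes = np.zeros(n_sensors)
    for s in range(n_sensors):
        lats, amps = [], []
        for ev in event_times:
            in_amp = (t >= ev - window / 2) & (t <= ev + window / 2)
            if np.any(in_amp):
                amps.append(float(np.max(forces[in_amp, s])))
            in_lat = (t >= ev) & (t <= ev + window)
            seg = forces[in_lat, s]
            hit = seg >= thresh if rising else seg < thresh
            if np.any(hit):
                lats.append(float(t[in_lat][np.argmax(hit)] - ev))
        if lats:
            latencies[s] = float(np.median(lats))
        if amps:
            amplitudes[s] = float(np.median(amps))

    # composite: rank-sum of latency (ascending) and amplitude (descending)
    lat_rank = np.argsort(np.argsort(latencies, kind="stable"), kind="stable")
    amp_rank = np.argsort(np.argsort(-amplitudes, kind="stable"), kind="stable")
    composite = lat_rank + amp_rank
    order = sorted(range(n_sensors), key=lambda s: (composite[s], ids[s]))
    return tuple(
        SensorScore(int(ids[s]), float(latencies[s]), float(amplitudes[s]))
        for s in order
    )


def rank_sensors(
    stream: VoltageStream,
    cal: TactelCalibration,
    layout: InsoleLayout,
    events: StrideTable,
    window: float = 0.15,
) -> SensorRanking:
    """Rank every sensor for HS and TO responsivity and amplitude.

    ``events`` must come from the full-configuration vGRF.  The per-sensor
    force threshold is ``f(v_thresh)``, the single-sensor noise-floor force.
    Latency is the median delay from the event to the sensor's threshold
    crossing (rising for HS, falling for TO) within ``window`` seconds;
    sensors that never cross get an infinite sentinel and rank last.
    """
    if len(events) == 0:
        raise ValueError("no events to rank against")
    forces = force_from_voltage(cal, stream.frames)
    thresh = system_force_threshold(cal, 1)
    t = stream.timestamps
    return SensorRanking(
        hs=_rank_for_event(t, forces, layout.ids, events.hs_times, window, thresh, True),
        to=_rank_for_event(t, forces, layout.ids, events.to_times, window, thresh, False),
    )


@dataclass(frozen=True)
class SubsetEvaluation:
    """Stride-matched event-time differences: subset minus full configuration."""

    hs_diffs: np.ndarray        # s
    to_diffs: np.ndarray        # s
    n_full: int
    n_subset: int

    def fraction_within(self, tol: float) -> dict:
        """Fraction of paired strides whose |difference| <= tol seconds."""
        out = {}
        for name, d in (("hs", self.hs_diffs), ("to", self.to_diffs)):
            out[name] = float(np.mean(np.abs(d) <= tol)) if len(d) else float("nan")
        return out


def evaluate_subset(
    subset_ids,
    stream: VoltageStream,
    cal: TactelCalibration,
    layout: InsoleLayout,
    min_stance: float = 0.1,
    min_swing: float = 0.1,
) -> SubsetEvaluation:
    """Compare event detection on a sensor subset against the full configuration.

    The contact threshold scales with the sensor count (``n * f(v_thresh)``)
    so the comparison is not biased by threshold magnitude.  Strides are
    paired by nearest HS.
    """
    subset_ids = [int(i) for i in subset_ids]
    if not subset_ids:
        raise ValueError("subset must be non-empty")
    sub_layout = layout.subset(subset_ids)
    id_to_col = {int(pid): k for k, pid in enumerate(layout.ids)}
    cols = [id_to_col[i] for i in subset_ids]

    full_sig = process_stream(stream, cal, layout,
                              system_force_threshold(cal, len(layout)))
    sub_stream = VoltageStream(stream.timestamps, stream.frames[:, cols],
                               stream.sample_rate)
    sub_sig = process_stream(sub_stream, cal, sub_layout,
                             system_force_threshold(cal, len(cols)))

    full_ev = detect_events(full_sig, system_force_threshold(cal, len(layout)),
                            min_stance, min_swing)
    sub_ev = detect_events(sub_sig, system_force_threshold(cal, len(cols)),
                           min_stance, min_swing)
    if len(sub_ev) == 0:
        raise ValueError("subset produced no detectable strides")

    from .validation import pair_strides  # local import to avoid a cycle

    pairs = pair_strides(full_ev, sub_ev)
    hs_d = np.array([sub_ev.hs_times[j] - full_ev.hs_times[i] for i, j in pairs])
    to_d = np.array([sub_ev.to_times[j] - full_ev.to_times[i] for i, j in pairs])
    return SubsetEvaluation(hs_d, to_d, n_full=len(full_ev), n_subset=len(sub_ev))
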