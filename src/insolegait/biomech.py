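"""Per-frame conversion of multichannel tactel voltages into vGRF and CoP_AP.

All operations are pointwise in time (output at sample k depends only on
sample k), so batch processing and one-sample-at-a-time streaming give
identical results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layout import InsoleLayout
from .transduction import TactelCalibration, force_from_voltage, system_force_threshold

__all__ = [
    "VoltageStream",
    "GaitSignals",
    "compute_vgrf",
    "compute_cop_ap",
    "estimate_baseline",
    "deoffset",
    "process_stream",
]


@dataclass(frozen=True)
class VoltageStream:
    """Timestamped frames of de-offset tactel voltages (V) at a uniform rate."""

    timestamps: np.ndarray      # (n,) seconds
    frames: np.ndarray          # (n, n_channels) volts
    sample_rate: float = 100.0

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        fr = np.atleast_2d(np.asarray(self.frames, dtype=float))
        if len(t) != fr.shape[0]:
            raise ValueError("timestamps and frames disagree in length")
        if len(t) > 1:
            dt = np.diff(t)
            if not np.allclose(dt, 1.0 / self.sample_rate, atol=1e-6):
                raise ValueError("timestamps are not uniform at the stated sample rate")
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "frames", fr)

    @property
    def n_channels(self) -> int:
        return self.frames.shape[1]

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass(frozen=True)
class GaitSignals:
    """Derived vGRF (N) and CoP_AP (cm) series; CoP is NaN during swing."""

    timestamps: np.ndarray
    vgrf: np.ndarray
    cop_ap: np.ndarray
    sample_rate: float = 100.0

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        v = np.asarray(self.vgrf, dtype=float)
        c = np.asarray(self.cop_ap, dtype=float)
        if not (len(t) == len(v) == len(c)):
            raise ValueError("timestamps, vgrf and cop_ap must have equal length")
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "vgrf", v)
        object.__setattr__(self, "cop_ap", c)

    def __len__(self) -> int:
        return len(self.timestamps)


def compute_vgrf(frame, cal: TactelCalibration) -> float:
    """Total vertical force: sum of per-tactel piecewise forces for one frame."""
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ValueError("invalid frame: non-finite channel value")
    return float(np.sum(force_from_voltage(cal, frame)))


def compute_cop_ap(forces, layout: InsoleLayout, vgrf_thresh: float) -> float:
    """Density-weighted AP centroid of the tactel forces, NaN below threshold.

    CoP_AP = sum(F_i * w_i * AP_i) / sum(F_i * w_i) when the total force
    reaches the contact threshold; undefined (NaN) otherwise.
    """
    forces = np.asarray(forces, dtype=float)
    if np.any(forces < 0):
        raise ValueError("forces must be non-negative")
    if len(forces) != len(layout):
        raise ValueError("force vector length does not match layout")
    if float(np.sum(forces)) < vgrf_thresh:
        return float("nan")
    w = layout.ap_weights
    denom = float(np.sum(forces * w))
    if denom <= 0:
        return float("nan")
    return float(np.sum(forces * w * layout.ap) / denom)


def estimate_baseline(frames, n_samples: int = 50) -> np.ndarray:
    """Per-channel zero-load baseline: median over the first unloaded samples."""
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    if len(frames) == 0:
        raise ValueError("no frames to estimate a baseline from")
    return np.median(frames[:n_samples], axis=0)


def deoffset(frames, baseline) -> np.ndarray:
    """Subtract a per-channel zero-load baseline from voltage frames."""
    return np.atleast_2d(np.asarray(frames, dtype=float)) - np.asarray(baseline, dtype=float)


def process_stream(
    stream: VoltageStream,
    cal: TactelCalibration,
    layout: InsoleLayout,
    vgrf_thresh: float | None = None,
    baseline: np.ndarray | None = None,
) -> GaitSignals:
    """Convert a voltage stream to vGRF and CoP_AP series, frame by frame.

    ``vgrf_thresh`` defaults to ``n_channels * f(v_thresh)``.  An optional
    per-channel ``baseline`` is subtracted first (zero-load de-offset).
    Causal: each output sample depends only on its own input frame.
    """
    if stream.n_channels != len(layout):
        raise ValueError("stream channel count does not match layout")
    if vgrf_thresh is None:
        vgrf_thresh = system_force_threshold(cal, stream.n_channels)
    frames = stream.frames if baseline is None else deoffset(stream.frames, baseline)
    if not np.all(np.isfinite(frames)):
        raise ValueError("invalid frame: non-finite channel value")

    forces = force_from_voltage(cal, frames)          # (n, ch), pointwise
    vgrf = forces.sum(axis=1)
    w = layout.ap_weights
    # row-wise sums (not matmul) so one-sample and batch processing reduce in
    # the same order and are bit-identical
    num = np.sum(forces * (w * layout.ap), axis=1)
    den = np.sum(forces * w, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cop = np.where((vgrf >= vgrf_thresh) & (den > 0), num / np.where(den > 0, den, 1.0), np.nan)
    return GaitSignals(stream.timestamps, vgrf, cop, stream.sample_rate)
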