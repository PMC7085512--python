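"""Validation battery against a reference device (force plate).

Implements temporal alignment/resampling, median-absolute-error of event
times, stance-normalized profile comparison (Pearson correlation, RMSE),
within-device repeatability, and body-mass normalization of vGRF peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .biomech import GaitSignals
from .events import StrideTable, detect_events

__all__ = [
    "ReferenceRecording",
    "ValidationReport",
    "GRAVITY",
    "align_and_resample",
    "pair_strides",
    "event_mae",
    "stance_profiles",
    "profile_agreement",
    "repeatability_rmse",
    "peak_bm_percent",
    "stance_to_stride_percent",
    "percent_ratio",
    "validate",
]

GRAVITY = 9.81  # m/s^2


@dataclass(frozen=True)
class ReferenceRecording:
    """Force-plate style reference: vGRF (N) and CoP_AP (cm) at a uniform rate."""

    timestamps: np.ndarray
    vgrf: np.ndarray
    cop_ap: np.ndarray
    sample_rate: float = 200.0
    event_threshold: float = 20.0

    def __post_init__(self) -> None:
        if self.event_threshold <= 0:
            raise ValueError("event_threshold must be > 0")
        t = np.asarray(self.timestamps, dtype=float)
        v = np.asarray(self.vgrf, dtype=float)
        c = np.asarray(self.cop_ap, dtype=float)
        if not (len(t) == len(v) == len(c)):
            raise ValueError("timestamps, vgrf and cop_ap must have equal length")
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "vgrf", v)
        object.__setattr__(self, "cop_ap", c)

    def as_signals(self) -> GaitSignals:
        return GaitSignals(self.timestamps, self.vgrf, self.cop_ap, self.sample_rate)


def align_and_resample(
    insole: GaitSignals,
    ref: ReferenceRecording,
    trigger_offset: float = 0.0,
) -> tuple[GaitSignals, GaitSignals]:
    """Put the reference on the insole timeline.

    The reference clock is shifted by ``trigger_offset`` (seconds to add to
    reference timestamps to express them in insole time), then linearly
    interpolated at the insole timestamps inside the overlap window.  Returns
    the cropped insole signals and the resampled reference as a pair.
    """
    t_ref = np.asarray(ref.timestamps, dtype=float) + trigger_offset
    t_in = insole.timestamps
    lo, hi = max(t_in[0], t_ref[0]), min(t_in[-1], t_ref[-1])
    if hi <= lo:
        raise ValueError("no temporal overlap between insole and reference")
    m = (t_in >= lo) & (t_in <= hi)
    t_out = t_in[m]
    vgrf = np.interp(t_out, t_ref, ref.vgrf)
    cop = np.interp(t_out, t_ref, ref.cop_ap)
    cropped = GaitSignals(t_out, insole.vgrf[m], insole.cop_ap[m], insole.sample_rate)
    resampled = GaitSignals(t_out, vgrf, cop, insole.sample_rate)
    return cropped, resampled


def pair_strides(
    ref: StrideTable, other: StrideTable, max_sep: float | None = None
) -> list[tuple[int, int]]:
    """Match strides across devices by nearest heel-strike.

    ``max_sep`` defaults to half the median reference stride time; unmatched
    strides are dropped.
    """
    if len(ref) == 0 or len(other) == 0:
        return []
    if max_sep is None:
        stride_times = [s.stride_time for s in ref if s.stride_time is not None]
        max_sep = 0.5 * float(np.median(stride_times)) if stride_times else 0.5
    hs_other = other.hs_times
    pairs = []
    used = set()
    for i, hs in enumerate(ref.hs_times):
        j = int(np.argmin(np.abs(hs_other - hs)))
        if j in used or abs(hs_other[j] - hs) > max_sep:
            continue
        used.add(j)
        pairs.append((i, j))
    return pairs


def event_mae(
    ref_events: StrideTable,
    insole_events: StrideTable,
    max_sep: float | None = None,
) -> dict:
    """Median absolute error of HS, TO and stance duration over paired strides.

    Returned in seconds and as a percentage of each stride's reference stance
    duration (per-stride percentage, then median).
    """
    pairs = pair_strides(ref_events, insole_events, max_sep)
    if not pairs:
        return {"n_pairs": 0}
    rs, is_ = zip(*pairs)
    r_hs, i_hs = ref_events.hs_times[list(rs)], insole_events.hs_times[list(is_)]
    r_to, i_to = ref_events.to_times[list(rs)], insole_events.to_times[list(is_)]
    r_stance = ref_events.stance_durations[list(rs)]
    i_stance = insole_events.stance_durations[list(is_)]

    d_hs = np.abs(r_hs - i_hs)
    d_to = np.abs(r_to - i_to)
    d_stance = np.abs(r_stance - i_stance)
    return {
        "n_pairs": len(pairs),
        "mae_hs_s": float(np.median(d_hs)),
        "mae_to_s": float(np.median(d_to)),
        "mae_stance_s": float(np.median(d_stance)),
        "mae_hs_pct_stance": float(np.median(d_hs / r_stance * 100.0)),
        "mae_to_pct_stance": float(np.median(d_to / r_stance * 100.0)),
        "mae_stance_pct_stance": float(np.median(d_stance / r_stance * 100.0)),
    }


def stance_profiles(
    signals: GaitSignals,
    table: StrideTable,
    signal: str = "vgrf",
    n_points: int = 101,
    lowpass_cutoff: float | None = 20.0,
) -> np.ndarray:
    """Time-normalized per-stride stance profiles, rows = strides.

    Each stance segment (HS up to, excluding, TO) is optionally zero-phase
    low-pass filtered (4th-order Butterworth) and linearly resampled to
    ``n_points`` samples.  Stances shorter than 3 samples are skipped with a
    warning.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    x = signals.vgrf if signal == "vgrf" else signals.cop_ap
    t = signals.timestamps
    fs = signals.sample_rate
    sos = None
    if lowpass_cutoff is not None:
        if lowpass_cutoff >= fs / 2:
            raise ValueError("lowpass_cutoff must be below the Nyquist frequency")
        sos = sp_signal.butter(4, lowpass_cutoff, fs=fs, output="sos")

    rows = []
    for k, s in enumerate(table):
        i0 = int(np.searchsorted(t, s.hs_time - 1e-9))
        i1 = int(np.searchsorted(t, s.to_time - 1e-9))
        seg = x[i0:i1].astype(float)
        if len(seg) < 3 or not np.all(np.isfinite(seg)):
            warnings.warn(f"stride {k}: stance too short or undefined, skipped")
            continue
        if sos is not None:
            padlen = min(len(seg) - 1, 24)
            seg = sp_signal.sosfiltfilt(sos, seg, padlen=padlen)
        tau = np.linspace(0.0, 1.0, len(seg))
        rows.append(np.interp(np.linspace(0.0, 1.0, n_points), tau, seg))
    return np.array(rows) if rows else np.empty((0, n_points))


@dataclass(frozen=True)
class ProfileAgreement:
    rho: float
    rmse: float | None
    zero_variance: bool = False


def profile_agreement(
    profiles_a: np.ndarray, profiles_b: np.ndarray, kind: str = "cop"
) -> ProfileAgreement:
    """Pearson correlation (and, for CoP, RMSE) between per-device average profiles.

    RMSE is reported only for ``kind="cop"``; device amplitudes for vGRF are
    not comparable, so only the correlation is meaningful there.
    """
    a = np.atleast_2d(np.asarray(profiles_a, dtype=float)).mean(axis=0)
    b = np.atleast_2d(np.asarray(profiles_b, dtype=float)).mean(axis=0)
    if len(a) != len(b):
        raise ValueError("profiles must share the same number of points")
    if np.std(a) == 0 or np.std(b) == 0:
        return ProfileAgreement(rho=float("nan"), rmse=None, zero_variance=True)
    rho = float(sp_stats.pearsonr(a, b).statistic)
    rmse = float(np.sqrt(np.mean((a - b) ** 2))) if kind == "cop" else None
    return ProfileAgreement(rho=rho, rmse=rmse)


def repeatability_rmse(
    profiles: np.ndarray,
    mode: str = "cop",
    body_mass: float | None = None,
    g: float = GRAVITY,
) -> float:
    """Within-device stride-to-stride repeatability.

    Per stride, the RMSE against the mean profile; for ``mode="vgrf"``
    profiles are first normalized by body weight and the per-stride RMSE is
    divided by that stride's mean normalized value (result in %).  For
    ``mode="cop"`` the result is in cm.  The recording value is the median
    over strides; NaN if fewer than two strides.
    """
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    if profiles.shape[0] < 2:
        warnings.warn("repeatability undefined for fewer than 2 strides")
        return float("nan")
    if mode == "vgrf":
        if body_mass is None or body_mass <= 0:
            raise ValueError("vgrf mode requires a positive body_mass")
        profiles = profiles / (body_mass * g)
    mean_profile = profiles.mean(axis=0)
    per_stride = np.sqrt(np.mean((profiles - mean_profile) ** 2, axis=1))
    if mode == "vgrf":
        per_stride = per_stride / profiles.mean(axis=1) * 100.0
    return float(np.median(per_stride))


def peak_bm_percent(vgrf_stance, body_mass: float, g: float = GRAVITY) -> float:
    """Peak of a vGRF stance profile as a percentage of body weight."""
    if body_mass <= 0:
        raise ValueError("body_mass must be > 0")
    x = np.asarray(vgrf_stance, dtype=float)
    if x.size == 0:
        raise ValueError("empty profile")
    return float(np.max(x) / (body_mass * g) * 100.0)


def stance_to_stride_percent(pct_of_stance: float, stance_fraction: float = 0.60) -> float:
    """Re-express an event-timing error from % of stance to % of stride period."""
    if not (0 < stance_fraction < 1):
        raise ValueError("stance_fraction must lie in (0, 1)")
    return pct_of_stance * stance_fraction


def percent_ratio(numerator: float, denominator: float) -> float:
    """Ratio of two like quantities expressed as a percentage."""
    if denominator == 0:
        raise ValueError("denominator must be non-zero")
    return numerator / denominator * 100.0


@dataclass(frozen=True)
class ValidationReport:
    """Full comparison of an insole recording against a reference device."""

    n_pairs: int
    mae_hs_s: float | None = None
    mae_to_s: float | None = None
    mae_stance_s: float | None = None
    mae_hs_pct_stance: float | None = None
    mae_to_pct_stance: float | None = None
    mae_stance_pct_stance: float | None = None
    rho_vgrf: float | None = None
    rho_cop: float | None = None
    rmse_cop_cm: float | None = None
    repeatability_vgrf_insole_pct: float | None = None
    repeatability_vgrf_ref_pct: float | None = None
    repeatability_cop_insole_cm: float | None = None
    repeatability_cop_ref_cm: float | None = None
    vgrf_peak_insole_bm_pct: float | None = None
    vgrf_peak_ref_bm_pct: float | None = None
    empty_pairing: bool = False
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "extra"}
        d.update(self.extra)
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=float) + "\n")

    def to_table(self) -> str:
        lines = [f"{k:34s} {v}" for k, v in self.to_dict().items()]
        return "\n".join(lines)


def validate(
    insole: GaitSignals,
    ref: ReferenceRecording,
    body_mass: float,
    insole_threshold: float,
    trigger_offset: float = 0.0,
    n_points: int = 101,
    lowpass_cutoff: float | None = 20.0,
    min_stance: float = 0.1,
    min_swing: float = 0.1,
) -> ValidationReport:
    """Run the full validation battery.

    Events are detected on each device at its own threshold and sampling
    rate; profiles are stance-normalized per device and compared via their
    averages.  Peaks are medians of per-stride maxima in % body weight.
    """
    insole_c, _ = align_and_resample(insole, ref, trigger_offset)
    ins_events = detect_events(insole_c, insole_threshold, min_stance, min_swing)
    ref_events = detect_events(ref.as_signals(), ref.event_threshold, min_stance, min_swing)

    mae = event_mae(ref_events, ins_events)
    if mae["n_pairs"] == 0:
        return ValidationReport(n_pairs=0, empty_pairing=True)

    ins_v = stance_profiles(insole_c, ins_events, "vgrf", n_points, lowpass_cutoff)
    ins_c = stance_profiles(insole_c, ins_events, "cop_ap", n_points, lowpass_cutoff)
    ref_v = stance_profiles(ref.as_signals(), ref_events, "vgrf", n_points, lowpass_cutoff)
    ref_c = stance_profiles(ref.as_signals(), ref_events, "cop_ap", n_points, lowpass_cutoff)

    agr_v = profile_agreement(ins_v, ref_v, kind="vgrf")
    agr_c = profile_agreement(ins_c, ref_c, kind="cop")

    return ValidationReport(
        n_pairs=mae["n_pairs"],
        mae_hs_s=mae["mae_hs_s"],
        mae_to_s=mae["mae_to_s"],
        mae_stance_s=mae["mae_stance_s"],
        mae_hs_pct_stance=mae["mae_hs_pct_stance"],
        mae_to_pct_stance=mae["mae_to_pct_stance"],
        mae_stance_pct_stance=mae["mae_stance_pct_stance"],
        rho_vgrf=agr_v.rho,
        rho_cop=agr_c.rho,
        rmse_cop_cm=agr_c.rmse,
        repeatability_vgrf_insole_pct=repeatability_rmse(ins_v, "vgrf", body_mass),
        repeatability_vgrf_ref_pct=repeatability_rmse(ref_v, "vgrf", body_mass),
        repeatability_cop_insole_cm=repeatability_rmse(ins_c, "cop"),
        repeatability_cop_ref_cm=repeatability_rmse(ref_c, "cop"),
        vgrf_peak_insole_bm_pct=float(np.median([peak_bm_percent(p, body_mass) for p in ins_v]))
        if len(ins_v) else None,
        vgrf_peak_ref_bm_pct=float(np.median([peak_bm_percent(p, body_mass) for p in ref_v]))
        if len(ref_v) else None,
    )
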