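"""Synthetic gait generator emulating both the instrumented insole and a force plate.

Builds a parametric double-bump stance vGRF and a monotone heel-to-toe CoP,
allocates the total force over the tactels with a Gaussian kernel, and
synthesizes insole voltages by inverse transduction with optional first-order
sensor lag and white voltage noise.  The noiseless truth doubles as the
reference-device recording.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from .biomech import VoltageStream
from .events import Stride, StrideTable
from .layout import InsoleLayout, default_layout
from .transduction import DEFAULT_CALIBRATION, TactelCalibration, voltage_from_force
from .validation import GRAVITY, ReferenceRecording

__all__ = [
    "GaitSimConfig",
    "SyntheticTrial",
    "vgrf_template",
    "cop_template",
    "allocate_tactel_forces",
    "simulate_trial",
]


@dataclass(frozen=True)
class GaitSimConfig:
    """Parameters of a synthetic walking trial.

    vGRF amplitudes are fractions of body weight *as seen by the insole*
    (the partial sensorized area reads only ~20% of the physiological load,
    hence the small defaults).  ``edge_bm``/``edge_width`` shape the sharp
    loading/unloading transients at foot contact and lift-off so that the
    force rises through realistic detection thresholds within a few
    milliseconds, as a real heel impact does.
    """

    body_mass: float = 66.2            # kg
    stride_time: float = 1.1           # s
    stance_fraction: float = 0.60
    n_strides: int = 10
    foot_length: float = 26.0          # cm
    peak1_bm: float = 0.20             # first vGRF peak, body-weight fraction
    peak2_bm: float = 0.18             # second vGRF peak
    valley_bm: float = 0.12            # mid-stance valley level
    peak1_pos: float = 0.25            # stance fraction of the first peak
    peak2_pos: float = 0.75
    bump_width: float = 0.25           # raised-cosine half-width (stance fraction)
    edge_bm: float = 0.06              # contact/lift-off transient amplitude
    edge_width: float = 0.02           # transient half-width (stance fraction)
    cop_start_frac: float = 0.10       # CoP at contact, fraction of foot length
    cop_end_frac: float = 0.85
    cop_steepness: float = 8.0         # logistic slope of the heel->toe ramp
    allocation_spread: float = 3.0     # cm, Gaussian kernel sigma
    voltage_noise_sd: float = 0.005    # V
    sensor_lag_tau: float = 0.02       # s, first-order lag time constant
    lag_asymmetry: float = 0.5         # unloading tau = lag_asymmetry * tau
    insole_rate: float = 100.0         # Hz
    ref_rate: float = 200.0            # Hz
    ref_threshold: float = 20.0        # N, reference-device event threshold
    lead_in: float = 0.4               # s of swing before the first contact
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.stance_fraction < 1):
            raise ValueError("stance_fraction must be in (0, 1)")
        if self.voltage_noise_sd < 0:
            raise ValueError("voltage_noise_sd must be >= 0")
        if not (0 < self.peak1_pos < self.peak2_pos < 1):
            raise ValueError("peak positions must satisfy 0 < p1 < p2 < 1")


def _rc(tau, center: float, half_width: float):
    """Raised-cosine bump: 1 at its center, 0 outside |tau - center| >= half_width."""
    tau = np.asarray(tau, dtype=float)
    u = np.abs(tau - center) / half_width
    out = np.where(u < 1.0, 0.5 * (1.0 + np.cos(np.pi * np.minimum(u, 1.0))), 0.0)
    return out


def vgrf_template(tau, cfg: GaitSimConfig):
    """Stance vGRF (N) at normalized stance time ``tau`` in [0, 1].

    Two raised-cosine bumps (the 'M' shape) plus a mid-stance valley bump and
    sharp contact/lift-off transients; exactly zero at tau = 0 and 1.
    """
    tau = np.asarray(tau, dtype=float)
    bw = cfg.body_mass * GRAVITY
    valley_center = 0.5 * (cfg.peak1_pos + cfg.peak2_pos)
    valley_hw = 0.5 * (cfg.peak2_pos - cfg.peak1_pos)
    f = (
        cfg.peak1_bm * _rc(tau, cfg.peak1_pos, cfg.bump_width)
        + cfg.peak2_bm * _rc(tau, cfg.peak2_pos, cfg.bump_width)
        + cfg.valley_bm * _rc(tau, valley_center, valley_hw)
        + cfg.edge_bm * _rc(tau, cfg.edge_width, cfg.edge_width)
        + cfg.edge_bm * _rc(tau, 1.0 - cfg.edge_width, cfg.edge_width)
    ) * bw
    f = np.where((tau < 0) | (tau > 1), 0.0, f)
    return float(f) if f.ndim == 0 else f


def cop_template(tau, cfg: GaitSimConfig):
    """CoP_AP (cm) at normalized stance time: normalized logistic heel->toe ramp.

    Exactly ``cop_start`` at tau = 0 and ``cop_end`` at tau = 1, non-decreasing,
    symmetric about tau = 0.5.
    """
    tau = np.asarray(tau, dtype=float)
    start = cfg.cop_start_frac * cfg.foot_length
    end = cfg.cop_end_frac * cfg.foot_length
    k = cfg.cop_steepness

    def sig(x):
        return 1.0 / (1.0 + np.exp(-x))

    lo, hi = sig(-k / 2), sig(k / 2)
    s = (sig(k * (tau - 0.5)) - lo) / (hi - lo)
    out = start + (end - start) * s
    return float(out) if out.ndim == 0 else out


def allocate_tactel_forces(
    total: float,
    cop: float,
    layout: InsoleLayout,
    spread: float,
    f_cap: float | None = None,
) -> np.ndarray:
    """Distribute a total force over tactels with a Gaussian kernel at the CoP.

    Forces are proportional to ``exp(-(ap - cop)^2 / (2 spread^2))`` and
    rescaled to sum to ``total``.  Per-tactel forces above ``f_cap`` are
    clipped with iterative redistribution of the excess; if every tactel
    saturates a warning is raised and the sum falls short of ``total``.
    """
    if total < 0:
        raise ValueError("total force must be >= 0")
    ap = layout.ap
    if total == 0:
        return np.zeros(len(ap))
    w = np.exp(-((ap - cop) ** 2) / (2.0 * spread**2))
    w = w / w.sum()
    f = total * w
    if f_cap is None:
        return f
    for _ in range(len(ap)):
        over = f > f_cap
        if not np.any(over):
            return f
        excess = float(np.sum(f[over] - f_cap))
        f[over] = f_cap
        free = ~over & (f < f_cap)
        if not np.any(free):
            warnings.warn("all tactels saturated; allocated force falls short of total")
            return f
        wf = w[free] / w[free].sum()
        f[free] = f[free] + excess * wf
    return f


def _allocate_batch(
    totals: np.ndarray, cops: np.ndarray, layout: InsoleLayout,
    spread: float, f_cap: float,
) -> np.ndarray:
    """Vectorized allocation for a whole trial; falls back to the scalar path
    only for the rare saturated samples."""
    ap = layout.ap
    n = len(totals)
    forces = np.zeros((n, len(ap)))
    loaded = totals > 0
    if np.any(loaded):
        d = ap[None, :] - cops[loaded, None]
        w = np.exp(-(d**2) / (2.0 * spread**2))
        w /= w.sum(axis=1, keepdims=True)
        forces[loaded] = totals[loaded, None] * w
    over = np.where((forces > f_cap).any(axis=1))[0]
    for i in over:
        forces[i] = allocate_tactel_forces(
            float(totals[i]), float(cops[i]), layout, spread, f_cap
        )
    return forces


@dataclass(frozen=True)
class SyntheticTrial:
    """A simulated recording: insole stream, reference recording, and the truth."""

    insole: VoltageStream
    reference: ReferenceRecording
    truth: StrideTable
    true_vgrf: np.ndarray       # total force on the insole timeline (N)
    true_cop: np.ndarray        # CoP on the insole timeline (cm, NaN in swing)
    config: GaitSimConfig
    layout: InsoleLayout
    calibration: TactelCalibration


def _truth_series(t: np.ndarray, cfg: GaitSimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless total force and CoP at arbitrary times."""
    rel = t - cfg.lead_in
    stance_dur = cfg.stance_fraction * cfg.stride_time
    k = np.floor(rel / cfg.stride_time)
    tau = (rel - k * cfg.stride_time) / stance_dur
    in_stance = (k >= 0) & (k < cfg.n_strides) & (tau >= 0.0) & (tau <= 1.0)
    force = np.zeros_like(t)
    cop = np.full_like(t, np.nan)
    if np.any(in_stance):
        force[in_stance] = vgrf_template(tau[in_stance], cfg)
        cop[in_stance] = cop_template(tau[in_stance], cfg)
    return force, cop


def _threshold_crossings(cfg: GaitSimConfig, thresh: float) -> tuple[float, float]:
    """First up-crossing and last down-crossing of the template through ``thresh``,
    in normalized stance time, located by bracketing on a dense grid + brentq."""
    grid = np.linspace(0.0, 1.0, 8001)
    f = vgrf_template(grid, cfg) - thresh
    above = f > 0
    if not np.any(above):
        raise ValueError("template never reaches the event threshold")
    i_first = int(np.argmax(above))
    i_last = len(above) - 1 - int(np.argmax(above[::-1]))
    g: Callable[[float], float] = lambda x: float(vgrf_template(x, cfg)) - thresh
    tau_up = brentq(g, grid[i_first - 1], grid[i_first]) if i_first > 0 else 0.0
    tau_dn = brentq(g, grid[i_last], grid[i_last + 1]) if i_last < len(grid) - 1 else 1.0
    return float(tau_up), float(tau_dn)


def _first_order_lag(
    v: np.ndarray, dt: float, tau_load: float, tau_unload: float
) -> np.ndarray:
    """Per-channel first-order lag; loading (voltage going negative) and
    unloading can use different time constants."""
    if tau_load <= 0 and tau_unload <= 0:
        return v.copy()
    a_load = 1.0 - np.exp(-dt / tau_load) if tau_load > 0 else 1.0
    a_unload = 1.0 - np.exp(-dt / tau_unload) if tau_unload > 0 else 1.0
    out = np.empty_like(v)
    out[0] = v[0]
    for i in range(1, len(v)):
        loading = v[i] < out[i - 1]
        alpha = np.where(loading, a_load, a_unload)
        out[i] = out[i - 1] + alpha * (v[i] - out[i - 1])
    return out


def simulate_trial(
    cfg: GaitSimConfig,
    cal: TactelCalibration = DEFAULT_CALIBRATION,
    layout: InsoleLayout | None = None,
) -> SyntheticTrial:
    """Generate a complete synthetic trial.

    The reference recording is the noiseless truth sampled at ``ref_rate``.
    Insole voltages are the inverse transduction of the allocated per-tactel
    forces, passed through a first-order lag and white voltage noise, at
    ``insole_rate``.  The ground-truth stride table is anchored at the
    reference event threshold, computed analytically from the template.
    All randomness derives from ``cfg.seed``.
    """
    if layout is None:
        layout = default_layout(cfg.foot_length)
    rng = np.random.default_rng(cfg.seed)
    stance_dur = cfg.stance_fraction * cfg.stride_time
    total_t = 2 * cfg.lead_in + cfg.n_strides * cfg.stride_time

    t_ref = np.arange(0.0, total_t, 1.0 / cfg.ref_rate)
    t_ins = np.arange(0.0, total_t, 1.0 / cfg.insole_rate)

    ref_force, ref_cop = _truth_series(t_ref, cfg)
    ins_force, ins_cop = _truth_series(t_ins, cfg)

    # ground-truth events at the reference threshold
    strides: list[Stride] = []
    if cfg.n_strides > 0:
        tau_up, tau_dn = _threshold_crossings(cfg, cfg.ref_threshold)
        for k in range(cfg.n_strides):
            hs = cfg.lead_in + k * cfg.stride_time + tau_up * stance_dur
            to = cfg.lead_in + k * cfg.stride_time + tau_dn * stance_dur
            stride_time = cfg.stride_time if k + 1 < cfg.n_strides else None
            strides.append(Stride(hs, to, stride_time))
    truth = StrideTable(tuple(strides))

    forces = _allocate_batch(
        ins_force, ins_cop, layout, cfg.allocation_spread, cal.f_saturation
    )
    volts = voltage_from_force(cal, np.clip(forces, 0.0, cal.f_saturation))
    volts = _first_order_lag(
        volts, 1.0 / cfg.insole_rate,
        cfg.sensor_lag_tau, cfg.sensor_lag_tau * cfg.lag_asymmetry,
    )
    if cfg.voltage_noise_sd > 0:
        volts = volts + rng.normal(0.0, cfg.voltage_noise_sd, volts.shape)

    insole = VoltageStream(t_ins, volts, cfg.insole_rate)
    reference = ReferenceRecording(
        t_ref, ref_force, ref_cop, cfg.ref_rate, cfg.ref_threshold
    )
    return SyntheticTrial(
        insole=insole, reference=reference, truth=truth,
        true_vgrf=ins_force, true_cop=ins_cop,
        config=cfg, layout=layout, calibration=cal,
    )
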