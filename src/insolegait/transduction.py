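"""Tactel force transduction: voltage-to-force model, its inverse, and calibration fitting.

Each tactel (LED/photodiode pair under a silicone frustum) outputs a voltage
that goes *negative* as load increases, once the unloaded baseline has been
subtracted.  A quartic polynomial maps de-offset voltage to force; voltages
above a small noise threshold are treated as zero load.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "TactelCalibration",
    "LoadUnloadCurve",
    "FitStats",
    "DEFAULT_CALIBRATION",
    "force_from_voltage",
    "voltage_from_force",
    "system_force_threshold",
    "fit_calibration",
]


@dataclass(frozen=True)
class FitStats:
    """Goodness-of-fit summary for a calibration polynomial."""

    sse: float
    r_squared: float
    adj_r_squared: float
    rmse: float
    n_points: int


@dataclass(frozen=True)
class TactelCalibration:
    """Quartic voltage-to-force polynomial F = p1*V^4 + p2*V^3 + p3*V^2 + p4*V + p5.

    Parameters
    ----------
    p1..p5
        Polynomial coefficients (N/V^4 ... N/V, N).  ``p5`` is the force at
        0 V and is 0 for a properly de-offset sensor.
    v_thresh
        Noise-floor voltage threshold (V).  Voltages above it read as zero
        force.
    v_saturation
        Voltage at sensor saturation (V); voltages below it are clamped.
    """

    p1: float
    p2: float
    p3: float
    p4: float
    p5: float = 0.0
    v_thresh: float = -0.01
    v_saturation: float = -1.0
    fit: FitStats | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (self.v_saturation < self.v_thresh < 0):
            raise ValueError(
                f"require v_saturation < v_thresh < 0, got "
                f"{self.v_saturation} / {self.v_thresh}"
            )

    @property
    def coeffs(self) -> np.ndarray:
        """Coefficients in :func:`numpy.polyval` order (highest degree first)."""
        return np.array([self.p1, self.p2, self.p3, self.p4, self.p5])

    @property
    def f_saturation(self) -> float:
        """Force (N) at the saturation voltage."""
        return float(np.polyval(self.coeffs, self.v_saturation))

    def polynomial(self, v):
        """Raw polynomial value, without the piecewise zero branch."""
        return np.polyval(self.coeffs, v)

    def to_dict(self) -> dict:
        return {
            "p1": self.p1,
            "p2": self.p2,
            "p3": self.p3,
            "p4": self.p4,
            "p5": self.p5,
            "v_thresh": self.v_thresh,
            "v_saturation": self.v_saturation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TactelCalibration":
        return cls(**{k: float(d[k]) for k in
                      ("p1", "p2", "p3", "p4", "p5", "v_thresh", "v_saturation")})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TactelCalibration":
        return cls.from_dict(json.loads(Path(path).read_text()))


#: Factory calibration of the 16-tactel insole prototype.
DEFAULT_CALIBRATION = TactelCalibration(
    p1=186.1, p2=224.5, p3=64.76, p4=-18.59, p5=0.0,
    v_thresh=-0.01, v_saturation=-1.0,
)


@dataclass(frozen=True)
class LoadUnloadCurve:
    """One quasi-static load-unload cycle of one tactel.

    ``direction`` labels each sample as ``"loading"`` or ``"unloading"``.
    """

    voltage: np.ndarray
    force: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.voltage, dtype=float)
        f = np.asarray(self.force, dtype=float)
        d = np.asarray(self.direction)
        if not (len(v) == len(f) == len(d)):
            raise ValueError("voltage, force and direction must have equal length")
        if np.any(f < 0):
            raise ValueError("forces must be non-negative")
        object.__setattr__(self, "voltage", v)
        object.__setattr__(self, "force", f)
        object.__setattr__(self, "direction", d)

    def branch(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        m = self.direction == which
        return self.voltage[m], self.force[m]


def force_from_voltage(cal: TactelCalibration, v):
    """Convert a de-offset tactel voltage (V) to force (N).

    Piecewise: 0 N above the noise threshold, the calibration polynomial
    below it.  Voltages past saturation are clamped; tiny negative numerical
    residue is clamped to 0.  Accepts scalars or arrays.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite voltage")
    vc = np.clip(v, cal.v_saturation, None)
    f = np.where(vc > cal.v_thresh, 0.0, np.polyval(cal.coeffs, vc))
    f = np.maximum(f, 0.0)
    return float(f) if f.ndim == 0 else f


def voltage_from_force(cal: TactelCalibration, f):
    """Invert the calibration polynomial: force (N) -> voltage (V).

    The polynomial is strictly decreasing on ``[v_saturation, 0]``, so the
    inverse is found on that full interval; ``f = 0`` maps to 0 V exactly.
    Vectorized: interpolation on a fine grid refined by Newton iterations to
    ``|polynomial(v) - f| < 1e-9`` N.

    Raises
    ------
    ValueError
        If any force lies outside ``[0, f_saturation]``.
    """
    f_arr = np.asarray(f, dtype=float)
    fsat = cal.f_saturation
    if np.any(~np.isfinite(f_arr)) or np.any(f_arr < 0) or np.any(f_arr > fsat + 1e-12):
        raise ValueError(f"force out of range [0, {fsat:.4g}] N")
    coeffs = cal.coeffs
    dcoeffs = np.polyder(coeffs)

    # monotone grid -> first guess, then Newton
    vgrid = np.linspace(cal.v_saturation, 0.0, 4097)
    fgrid = np.polyval(coeffs, vgrid)  # decreasing in v: reverse for interp
    v = np.interp(f_arr, fgrid[::-1], vgrid[::-1])
    for _ in range(60):
        resid = np.polyval(coeffs, v) - f_arr
        if np.all(np.abs(resid) < 1e-10):
            break
        deriv = np.polyval(dcoeffs, v)
        step = np.where(np.abs(deriv) > 1e-12, resid / deriv, 0.0)
        v = np.clip(v - step, cal.v_saturation, 0.0)
    return float(v) if v.ndim == 0 else v


def system_force_threshold(cal: TactelCalibration, n_sensors: int = 16) -> float:
    """Foot-contact force threshold: ``n_sensors * f(v_thresh)``.

    Evaluates the polynomial branch at the noise threshold voltage (the force
    each sensor would read at its noise amplitude) and scales by the sensor
    count.  With the factory calibration and 16 sensors this is ~3 N.
    """
    n_sensors = int(n_sensors)
    if n_sensors < 1:
        raise ValueError("n_sensors must be >= 1")
    return n_sensors * float(np.polyval(cal.coeffs, cal.v_thresh))


def _mean_curve(curve: LoadUnloadCurve, vgrid: np.ndarray) -> np.ndarray:
    """Average the loading and unloading branches of one cycle on a voltage grid."""
    branches = []
    for which in ("loading", "unloading"):
        v, f = curve.branch(which)
        if len(v) == 0:
            continue
        order = np.argsort(v)
        branches.append(np.interp(vgrid, v[order], f[order]))
    if not branches:
        raise ValueError("curve has no labelled branches")
    return np.mean(branches, axis=0)


def fit_calibration(
    curves: Sequence[LoadUnloadCurve],
    v_thresh: float = -0.01,
    v_saturation: float = -1.0,
    n_grid: int = 500,
) -> TactelCalibration:
    """Fit the quartic voltage-to-force polynomial to load-unload cycles.

    Load and unload branches are averaged per cycle onto a common voltage
    grid, then averaged across cycles/sensors, and a degree-4 polynomial with
    zero intercept (``p5 = 0``) is least-squares fitted to the mean curve.
    The returned calibration carries a :class:`FitStats` in ``.fit``.
    """
    if len(curves) == 0:
        raise ValueError("need at least one load-unload curve")
    for c in curves:
        if len(c.voltage) < 10:
            raise ValueError("each curve needs >= 10 points")

    # common grid = union of sampled voltages so noiseless curves are fitted
    # exactly (no resampling error); capped at n_grid points
    all_v = np.unique(np.concatenate([c.voltage for c in curves]))
    if len(all_v) < 5:
        raise ValueError("degenerate voltage grid: fewer than 5 distinct voltages")
    vgrid = all_v if len(all_v) <= n_grid else np.linspace(all_v[0], all_v[-1], n_grid)

    mean_f = np.mean([_mean_curve(c, vgrid) for c in curves], axis=0)

    # constrained LS: F = p1 V^4 + p2 V^3 + p3 V^2 + p4 V  (no intercept)
    X = np.column_stack([vgrid**4, vgrid**3, vgrid**2, vgrid])
    beta, *_ = np.linalg.lstsq(X, mean_f, rcond=None)
    pred = X @ beta

    resid = mean_f - pred
    sse = float(np.sum(resid**2))
    sst = float(np.sum((mean_f - mean_f.mean()) ** 2))
    n, k = len(vgrid), 4
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    rmse = float(np.sqrt(sse / max(n - k, 1)))

    return TactelCalibration(
        p1=float(beta[0]), p2=float(beta[1]), p3=float(beta[2]), p4=float(beta[3]),
        p5=0.0, v_thresh=v_thresh, v_saturation=v_saturation,
        fit=FitStats(sse=sse, r_squared=r2, adj_r_squared=adj_r2, rmse=rmse, n_points=n),
    )
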