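"""Threshold-based gait-event detection and stride temporal parameters.

Heel-strike (HS) is the first sample with vGRF at or above the contact
threshold after a swing; toe-off (TO) is the first sample back below it.
Short spurious phases are debounced by merging them into their neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .biomech import GaitSignals

__all__ = ["Stride", "StrideTable", "detect_events", "temporal_parameters"]


@dataclass(frozen=True)
class Stride:
    hs_time: float
    to_time: float
    stride_time: float | None = None   # HS to next HS; None for the last stride

    @property
    def stance_duration(self) -> float:
        return self.to_time - self.hs_time

    @property
    def stance_fraction(self) -> float | None:
        if self.stride_time is None:
            return None
        return self.stance_duration / self.stride_time


@dataclass(frozen=True)
class StrideTable:
    """Chronologically ordered, non-overlapping strides."""

    strides: tuple[Stride, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "strides", tuple(self.strides))
        for s in self.strides:
            if not s.hs_time < s.to_time:
                raise ValueError("each stride requires hs_time < to_time")
        for a, b in zip(self.strides, self.strides[1:]):
            if b.hs_time <= a.to_time:
                raise ValueError("strides must be chronological and non-overlapping")

    def __len__(self) -> int:
        return len(self.strides)

    def __iter__(self):
        return iter(self.strides)

    @property
    def hs_times(self) -> np.ndarray:
        return np.array([s.hs_time for s in self.strides])

    @property
    def to_times(self) -> np.ndarray:
        return np.array([s.to_time for s in self.strides])

    @property
    def stance_durations(self) -> np.ndarray:
        return np.array([s.stance_duration for s in self.strides])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stride_idx": np.arange(len(self.strides)),
                "hs_s": self.hs_times,
                "to_s": self.to_times,
                "stance_s": self.stance_durations,
                "stride_s": [s.stride_time for s in self.strides],
                "stance_frac": [s.stance_fraction for s in self.strides],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "StrideTable":
        strides = []
        for _, row in df.iterrows():
            stride_s = row.get("stride_s")
            if stride_s is not None and not np.isfinite(stride_s):
                stride_s = None
            strides.append(Stride(float(row["hs_s"]), float(row["to_s"]),
                                  None if stride_s is None else float(stride_s)))
        return cls(tuple(strides))


def _runs(mask: np.ndarray) -> list[tuple[int, int, bool]]:
    """Run-length encode a boolean array as (start, stop, value) with stop exclusive."""
    out = []
    n = len(mask)
    i = 0
    while i < n:
        j = i
        while j < n and mask[j] == mask[i]:
            j += 1
        out.append((i, j, bool(mask[i])))
        i = j
    return out


def _debounce(mask: np.ndarray, min_true: int, min_false: int) -> np.ndarray:
    """Merge interior runs shorter than their minimum length into neighbours.

    Two passes: short swing gaps inside a stance are filled first (so chatter
    around the threshold at contact does not split or delay the stance), then
    short stance blips are removed.  Leading/trailing runs are left alone
    (handled by the incomplete-phase dropping downstream).
    """
    mask = mask.copy()
    for target, min_len in ((False, min_false), (True, min_true)):
        while True:
            runs = _runs(mask)
            cands = [
                (stop - start, idx)
                for idx, (start, stop, val) in enumerate(runs)
                if 0 < idx < len(runs) - 1
                and val == target and (stop - start) < min_len
            ]
            if not cands:
                break
            _, idx = min(cands)
            start, stop, _ = runs[idx]
            mask[start:stop] = not target
    return mask


def detect_events(
    signals: GaitSignals,
    vgrf_thresh: float,
    min_stance: float = 0.1,
    min_swing: float = 0.1,
) -> StrideTable:
    """Segment a vGRF series into strides at the given contact threshold.

    Candidate stance/swing phases shorter than ``min_stance``/``min_swing``
    seconds are merged into their neighbours (set both to 0 to disable).
    Stances touching the ends of the record are incomplete and dropped.
    """
    if vgrf_thresh <= 0:
        raise ValueError("vgrf_thresh must be > 0")
    vgrf = np.asarray(signals.vgrf, dtype=float)
    t = np.asarray(signals.timestamps, dtype=float)
    if len(vgrf) == 0:
        return StrideTable()

    fs = signals.sample_rate
    contact = vgrf >= vgrf_thresh
    contact = _debounce(contact, int(round(min_stance * fs)), int(round(min_swing * fs)))

    stances = []
    for start, stop, val in _runs(contact):
        if not val:
            continue
        if start == 0 or stop == len(contact):
            continue  # incomplete leading/trailing stance
        stances.append((start, stop))

    strides = []
    for k, (start, stop) in enumerate(stances):
        hs = t[start]
        to = t[stop]  # first sample below threshold after the stance
        stride_time = t[stances[k + 1][0]] - hs if k + 1 < len(stances) else None
        strides.append(Stride(hs, to, stride_time))
    return StrideTable(tuple(strides))


def temporal_parameters(table: StrideTable) -> dict:
    """Median and interquartile range of stance duration, stride time, stance fraction."""
    if len(table) == 0:
        return {}

    def med_iqr(x):
        x = np.asarray(x, dtype=float)
        if len(x) == 0:
            return {"median": float("nan"), "iqr": float("nan"), "n": 0}
        q25, q75 = np.percentile(x, [25, 75])
        return {"median": float(np.median(x)), "iqr": float(q75 - q25), "n": len(x)}

    stride_times = [s.stride_time for s in table if s.stride_time is not None]
    fractions = [s.stance_fraction for s in table if s.stance_fraction is not None]
    return {
        "stance_duration_s": med_iqr(table.stance_durations),
        "stride_time_s": med_iqr(stride_times),
        "stance_fraction": med_iqr(fractions),
        "n_strides": len(table),
    }


def write_stride_table(table: StrideTable, path: str | Path) -> None:
    df = table.to_dataframe()
    with open(path, "w") as fh:
        fh.write("# insolegait-csv v1 stride_table\n")
        df.to_csv(fh, index=False, float_format="%.6f")


def read_stride_table(path: str | Path) -> StrideTable:
    df = pd.read_csv(path, comment="#")
    return StrideTable.from_dataframe(df)
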