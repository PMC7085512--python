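"""Insole geometry: tactel positions and antero-posterior density weights.

Sensors cluster under the heel and metatarsal heads, so a plain force-weighted
centroid would be biased toward crowded regions.  Each tactel therefore gets a
weight equal to the reciprocal of the number of tactels sharing its
antero-posterior (AP) bin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "TactelPosition",
    "InsoleLayout",
    "compute_ap_weights",
    "scale_layout",
    "default_layout",
]


@dataclass(frozen=True)
class TactelPosition:
    """One tactel: id plus AP (heel=0, toward toe) and optional ML coordinate, in cm."""

    id: int
    ap: float
    ml: float | None = None


def compute_ap_weights(
    positions: Sequence[TactelPosition], bin_width: float = 1.0
) -> np.ndarray:
    """Per-tactel density weights: 1 / (tactels in the same AP bin).

    Bins are fixed-width with edges anchored at the heel (AP = 0), so the
    weighting is deterministic and covariant under uniform scaling when the
    bin width is scaled alongside the coordinates.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if len(positions) == 0:
        raise ValueError("empty position list")
    ap = np.array([p.ap for p in positions], dtype=float)
    bins = np.floor(ap / bin_width).astype(int)
    _, inverse, counts = np.unique(bins, return_inverse=True, return_counts=True)
    return 1.0 / counts[inverse]


@dataclass(frozen=True)
class InsoleLayout:
    """Tactel positions, foot length, and the derived AP density weights."""

    positions: tuple[TactelPosition, ...]
    foot_length: float
    bin_width: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", tuple(self.positions))
        ids = [p.id for p in self.positions]
        if len(set(ids)) != len(ids):
            raise ValueError("tactel ids must be unique")
        for p in self.positions:
            if not (0 <= p.ap <= self.foot_length):
                raise ValueError(f"tactel {p.id}: AP {p.ap} outside [0, {self.foot_length}]")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def ids(self) -> np.ndarray:
        return np.array([p.id for p in self.positions])

    @property
    def ap(self) -> np.ndarray:
        return np.array([p.ap for p in self.positions], dtype=float)

    @property
    def ap_weights(self) -> np.ndarray:
        return compute_ap_weights(self.positions, self.bin_width)

    def subset(self, ids: Sequence[int]) -> "InsoleLayout":
        """Layout restricted to the given tactel ids (weights recomputed)."""
        keep = set(ids)
        missing = keep - set(int(i) for i in self.ids)
        if missing:
            raise ValueError(f"unknown tactel ids: {sorted(missing)}")
        return InsoleLayout(
            tuple(p for p in self.positions if p.id in keep),
            self.foot_length, self.bin_width,
        )

    def to_dict(self) -> dict:
        return {
            "foot_length_cm": self.foot_length,
            "bin_width_cm": self.bin_width,
            "tactels": [
                {"id": p.id, "ap_cm": p.ap, "ml_cm": p.ml} for p in self.positions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InsoleLayout":
        return cls(
            positions=tuple(
                TactelPosition(int(t["id"]), float(t["ap_cm"]),
                               None if t.get("ml_cm") is None else float(t["ml_cm"]))
                for t in d["tactels"]
            ),
            foot_length=float(d["foot_length_cm"]),
            bin_width=float(d.get("bin_width_cm", 1.0)),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "InsoleLayout":
        return cls.from_dict(json.loads(Path(path).read_text()))


def scale_layout(layout: InsoleLayout, new_foot_length: float) -> InsoleLayout:
    """Rescale all coordinates (and the bin width) to a new foot length."""
    if new_foot_length <= 0:
        raise ValueError("new_foot_length must be > 0")
    s = new_foot_length / layout.foot_length
    return InsoleLayout(
        positions=tuple(
            TactelPosition(p.id, p.ap * s, None if p.ml is None else p.ml * s)
            for p in layout.positions
        ),
        foot_length=new_foot_length,
        bin_width=layout.bin_width * s,
    )


def default_layout(foot_length: float = 26.0) -> InsoleLayout:
    """Illustrative 16-tactel layout: heel cluster, midfoot, metatarsal cluster, toe.

    Qualitative stand-in for the prototype PCB; exact sensor coordinates of
    the hardware are not published.
    """
    base = 26.0
    spec = [
        # (id, ap_cm, ml_cm) on a 26 cm foot
        (1, 2.0, -1.5), (2, 2.0, 1.5), (3, 3.5, -2.0), (4, 3.5, 2.0),
        (5, 5.0, 0.0),
        (6, 10.5, 2.5), (7, 12.5, 2.0),
        (8, 17.0, -3.0), (9, 17.0, -1.0), (10, 17.5, 1.0), (11, 18.5, 2.5),
        (12, 18.5, -2.0), (13, 19.5, 0.5),
        (14, 22.5, -2.5), (15, 23.0, 0.0), (16, 24.0, -1.5),
    ]
    s = foot_length / base
    return InsoleLayout(
        positions=tuple(TactelPosition(i, ap * s, ml * s) for i, ap, ml in spec),
        foot_length=foot_length,
        bin_width=1.0 * s,
    )
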