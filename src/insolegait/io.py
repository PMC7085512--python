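"""Delimited-text readers/writers for streams, signals, recordings and reports.

Every CSV starts with a versioned schema comment line, e.g.::

    # insolegait-csv v1 voltage_stream fs=100.0

Timestamps are written with 6 fractional digits (10 us resolution).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .biomech import GaitSignals, VoltageStream
from .events import read_stride_table, write_stride_table
from .validation import ReferenceRecording, ValidationReport

__all__ = [
    "write_voltage_stream", "read_voltage_stream",
    "write_gait_signals", "read_gait_signals",
    "write_reference", "read_reference",
    "write_stride_table", "read_stride_table",
    "write_manifest", "read_manifest",
]

_MAGIC = "# insolegait-csv v1"


class FormatError(ValueError):
    """Raised when a file does not parse as the expected schema."""


def _write_header(fh, kind: str, **meta) -> None:
    extra = " ".join(f"{k}={v}" for k, v in meta.items())
    fh.write(f"{_MAGIC} {kind}{' ' + extra if extra else ''}\n")


def _read_header(path: Path, kind: str) -> dict:
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
    if not first.startswith(_MAGIC):
        raise FormatError(f"{path}: missing '{_MAGIC}' header line")
    parts = first[len(_MAGIC):].split()
    if not parts or parts[0] != kind:
        raise FormatError(f"{path}: expected schema '{kind}', got {parts[:1]}")
    meta = {}
    for tok in parts[1:]:
        k, _, v = tok.partition("=")
        meta[k] = v
    return meta


def _read_csv(path: Path, expected_cols: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: {exc}") from exc
    missing = [c for c in expected_cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


def _require_complete(df: pd.DataFrame, cols, path: Path) -> None:
    """Reject rows with missing values in columns that may not be empty."""
    bad = df[list(cols)].isna().any(axis=1)
    if bad.any():
        raise FormatError(f"{path}: malformed row at line {int(bad.idxmax()) + 3}")


def write_voltage_stream(stream: VoltageStream, path: str | Path) -> None:
    cols = {"time_s": stream.timestamps}
    for i in range(stream.n_channels):
        cols[f"v{i + 1:02d}"] = stream.frames[:, i]
    with open(path, "w") as fh:
        _write_header(fh, "voltage_stream", fs=stream.sample_rate)
        pd.DataFrame(cols).to_csv(fh, index=False, float_format="%.6f")


def read_voltage_stream(path: str | Path) -> VoltageStream:
    path = Path(path)
    meta = _read_header(path, "voltage_stream")
    df = _read_csv(path, ["time_s"])
    vcols = sorted(c for c in df.columns if c.startswith("v"))
    if not vcols:
        raise FormatError(f"{path}: no voltage channel columns")
    _require_complete(df, ["time_s", *vcols], path)
    fs = float(meta.get("fs", 100.0))
    t = df["time_s"].to_numpy(float)
    if len(t) > 1 and not np.allclose(np.diff(t), 1.0 / fs, atol=1e-4):
        raise FormatError(f"{path}: timestamps inconsistent with fs={fs} header")
    return VoltageStream(t, df[vcols].to_numpy(float), fs)


def write_gait_signals(signals: GaitSignals, path: str | Path) -> None:
    df = pd.DataFrame(
        {"time_s": signals.timestamps, "vgrf_N": signals.vgrf,
         "cop_ap_cm": signals.cop_ap}
    )
    with open(path, "w") as fh:
        _write_header(fh, "gait_signals", fs=signals.sample_rate)
        df.to_csv(fh, index=False, float_format="%.6f")


def read_gait_signals(path: str | Path) -> GaitSignals:
    path = Path(path)
    meta = _read_header(path, "gait_signals")
    df = _read_csv(path, ["time_s", "vgrf_N"])
    _require_complete(df, ["time_s", "vgrf_N"], path)  # cop_ap may be empty (swing)
    return GaitSignals(
        df["time_s"].to_numpy(float),
        df["vgrf_N"].to_numpy(float),
        df["cop_ap_cm"].to_numpy(float),
        float(meta.get("fs", 100.0)),
    )


def write_reference(ref: ReferenceRecording, path: str | Path) -> None:
    df = pd.DataFrame(
        {"time_s": ref.timestamps, "vgrf_N": ref.vgrf, "cop_ap_cm": ref.cop_ap}
    )
    with open(path, "w") as fh:
        _write_header(fh, "reference", fs=ref.sample_rate, thresh=ref.event_threshold)
        df.to_csv(fh, index=False, float_format="%.6f")


def read_reference(path: str | Path) -> ReferenceRecording:
    path = Path(path)
    meta = _read_header(path, "reference")
    df = _read_csv(path, ["time_s", "vgrf_N"])
    _require_complete(df, ["time_s", "vgrf_N"], path)
    fs = float(meta.get("fs", 200.0))
    t = df["time_s"].to_numpy(float)
    if len(t) > 1 and not np.allclose(np.diff(t), 1.0 / fs, atol=1e-4):
        raise FormatError(f"{path}: timestamps inconsistent with fs={fs} header")
    return ReferenceRecording(
        t, df["vgrf_N"].to_numpy(float), df["cop_ap_cm"].to_numpy(float),
        fs, float(meta.get("thresh", 20.0)),
    )


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=float) + "\n")


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
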