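"""File formats: trace tables, truth sidecars, localization tables.

Trace files are delimited text with columns ``frame,I_DD,I_DA,I_AA``;
the ground-truth sidecar shares the trace file's basename with a
``.truth.json`` suffix.  Localization tables are delimited text with
columns ``x_nm,y_nm,frame``; Picasso-style headers (``x [nm]``,
``y [nm]``, ``frame``) are accepted on read.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GroundTruth, TraceSet
from .traces import AlexTrace, CorrectionFactors

__all__ = [
    "write_trace",
    "read_trace",
    "write_trace_set",
    "read_trace_set",
    "read_localizations",
    "write_localizations",
]

_LOC_ALIASES = {"x [nm]": "x_nm", "y [nm]": "y_nm", "x": "x_nm", "y": "y_nm"}


def write_trace(trace: AlexTrace, path: Path, truth: GroundTruth | None = None) -> None:
    path = Path(path)
    pd.DataFrame(
        {"frame": trace.frame, "I_DD": trace.I_DD, "I_DA": trace.I_DA, "I_AA": trace.I_AA}
    ).to_csv(path, index=False)
    if truth is not None:
        payload = {
            "true_efficiency": truth.true_efficiency,
            "bleach_frames": truth.bleach_frames,
            "factors": asdict(truth.factors),
            "species": truth.species,
        }
        Path(str(path).removesuffix(".csv") + ".truth.json").write_text(
            json.dumps(payload, indent=1)
        )


def read_trace(path: Path) -> tuple[AlexTrace, GroundTruth | None]:
    path = Path(path)
    df = pd.read_csv(path)
    trace = AlexTrace(
        frame=df["frame"].to_numpy(),
        I_DD=df["I_DD"].to_numpy(float),
        I_DA=df["I_DA"].to_numpy(float),
        I_AA=df["I_AA"].to_numpy(float),
        trace_id=path.stem,
    )
    sidecar = Path(str(path).removesuffix(".csv") + ".truth.json")
    truth = None
    if sidecar.exists():
        d = json.loads(sidecar.read_text())
        truth = GroundTruth(
            true_efficiency=d["true_efficiency"],
            bleach_frames=d["bleach_frames"],
            factors=CorrectionFactors(**d["factors"]),
            species=d.get("species", "fret"),
        )
    return trace, truth


def write_trace_set(ts: TraceSet, out_dir: Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for trace, truth in zip(ts.traces, ts.truths):
        p = out_dir / f"{trace.trace_id or f'trace_{len(paths):05d}'}.csv"
        write_trace(trace, p, truth)
        paths.append(p)
    return paths


def read_trace_set(in_dir: Path) -> TraceSet:
    traces, truths = [], []
    for p in sorted(Path(in_dir).glob("*.csv")):
        tr, gt = read_trace(p)
        traces.append(tr)
        truths.append(gt)
    if any(g is None for g in truths):
        truths = []  # mixed or absent sidecars: treat as unlabelled
        return TraceSet(traces=traces, truths=[])
    return TraceSet(traces=traces, truths=truths)


def read_localizations(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df = df.rename(columns=_LOC_ALIASES)
    missing = {"x_nm", "y_nm", "frame"} - set(df.columns)
    if missing:
        raise ValueError(f"localization table missing columns: {sorted(missing)}")
    if not np.all(np.isfinite(df[["x_nm", "y_nm"]].to_numpy())):
        raise ValueError("non-finite coordinates in localization table")
    return df[["x_nm", "y_nm", "frame"]]


def write_localizations(df: pd.DataFrame, path: Path) -> None:
    df[["x_nm", "y_nm", "frame"]].to_csv(path, index=False)
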