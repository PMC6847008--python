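"""Readers and writers for every artifact format, with strict validation.

Formats:

* trace tables -- CSV/TSV with columns ``molecule_id, frame_index, donor,
  acceptor``; 0-based contiguous frame indices, one file per condition;
* condition manifests -- YAML/JSON describing a condition (name, role,
  ligand, trace file, frame interval);
* ground truth -- JSON, one object per simulated molecule;
* results -- JSON for rate/bootstrap/relative-activity summaries (floats at
  6 significant digits), CSV for per-molecule records and spot counts;
* spot frames -- single-channel 16-bit TIFF stacks, one slice per timepoint.

Times are ``frame_index * frame_interval`` (frame start).  Writers are pure
functions of their inputs: same input, byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .fret import IntensityTrace
from .kinetics import MoleculeEventRecord

__all__ = [
    "TraceTableError",
    "ConditionManifest",
    "read_traces",
    "write_traces",
    "read_manifest",
    "write_manifest",
    "write_ground_truth",
    "read_ground_truth",
    "write_results",
    "write_records_csv",
    "read_spot_counts",
    "write_spot_counts",
    "write_tiff_stack",
    "read_tiff_stack",
]

TRACE_COLUMNS = ["molecule_id", "frame_index", "donor", "acceptor"]


class TraceTableError(ValueError):
    """A trace table or manifest failed validation."""


@dataclass
class ConditionManifest:
    """One measured condition: where its traces live and how to label it."""

    condition_name: str
    role: str
    trace_file: str
    frame_interval: float
    ligand_name: str | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.role not in ("reference", "ligand"):
            raise TraceTableError(
                f"manifest {self.condition_name!r}: role must be 'reference' or "
                f"'ligand', got {self.role!r}"
            )
        if self.role == "ligand" and not self.ligand_name:
            raise TraceTableError(
                f"manifest {self.condition_name!r}: role 'ligand' requires ligand_name"
            )
        if not (math.isfinite(self.frame_interval) and self.frame_interval > 0):
            raise TraceTableError(
                f"manifest {self.condition_name!r}: frame_interval must be > 0"
            )


def read_manifest(path: str | Path) -> ConditionManifest:
    """Load a YAML or JSON condition manifest; the trace file must exist."""
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise TraceTableError(f"{path}: manifest must be a mapping")
    try:
        manifest = ConditionManifest(**data)
    except TypeError as exc:
        raise TraceTableError(f"{path}: {exc}") from exc
    trace_path = Path(manifest.trace_file)
    if not trace_path.is_absolute():
        trace_path = path.parent / trace_path
        manifest.trace_file = str(trace_path)
    if not trace_path.exists():
        raise TraceTableError(f"{path}: trace_file {manifest.trace_file!r} does not exist")
    return manifest


def write_manifest(manifest: ConditionManifest, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(manifest), fh, sort_keys=False)


def read_traces(path: str | Path, frame_interval: float) -> list[IntensityTrace]:
    """Read one condition's trace table into per-molecule traces.

    Frames are sorted by index and must form a gap-free run starting at 0;
    duplicates, gaps, missing columns and non-numeric intensities are
    rejected with the offending molecule/row named.
    """
    if not (math.isfinite(frame_interval) and frame_interval > 0):
        raise TraceTableError(f"frame_interval must be positive, got {frame_interval}")
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype={"molecule_id": str})
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceTableError(f"{path}: missing required columns {missing}")
    for col in ("frame_index", "donor", "acceptor"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int((converted.isna()).idxmax())
            raise TraceTableError(f"{path}: non-numeric {col!r} at row {row}")
        df[col] = converted

    dup = df.duplicated(subset=["molecule_id", "frame_index"])
    if dup.any():
        r = df[dup].iloc[0]
        raise TraceTableError(
            f"{path}: duplicate (molecule_id, frame_index) = "
            f"({r['molecule_id']!r}, {int(r['frame_index'])})"
        )

    traces = []
    for mol_id, grp in df.groupby("molecule_id", sort=True):
        grp = grp.sort_values("frame_index")
        idx = grp["frame_index"].to_numpy()
        expected = np.arange(len(idx))
        if not np.array_equal(idx, expected):
            first_bad = int(expected[idx != expected][0])
            raise TraceTableError(
                f"{path}: molecule {mol_id!r} has a frame_index gap at index {first_bad}"
            )
        traces.append(
            IntensityTrace(
                molecule_id=str(mol_id),
                donor=grp["donor"].to_numpy(dtype=float),
                acceptor=grp["acceptor"].to_numpy(dtype=float),
                frame_interval=frame_interval,
            )
        )
    return traces


def write_traces(traces: Sequence[IntensityTrace], path: str | Path) -> None:
    """Write traces as a long-format table (header always present)."""
    rows = []
    for tr in traces:
        rows.append(
            pd.DataFrame(
                {
                    "molecule_id": tr.molecule_id,
                    "frame_index": np.arange(tr.n_frames),
                    "donor": tr.donor,
                    "acceptor": tr.acceptor,
                }
            )
        )
    df = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=TRACE_COLUMNS)
    )
    sep = "\t" if Path(path).suffix.lower() in (".tsv", ".tab") else ","
    df.to_csv(path, sep=sep, index=False, float_format="%.6g")


def write_ground_truth(truths: Iterable, path: str | Path) -> None:
    """Serialize simulator ground truth to JSON."""
    payload = [
        {
            "molecule_id": t.molecule_id,
            "conformer": t.conformer,
            "events": [_round6(x) for x in t.unfolding_event_times],
            "bleach": {
                "donor": _round6(t.bleach_time_donor),
                "acceptor": _round6(t.bleach_time_acceptor),
            },
            "state_path": [
                [label, _round6(a), _round6(b)] for label, a, b in t.state_path
            ],
        }
        for t in truths
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_ground_truth(path: str | Path) -> list[dict]:
    with open(path) as fh:
        return json.load(fh)


def _round6(x: Any) -> Any:
    """Round floats to 6 significant digits for stable serialization."""
    if isinstance(x, float):
        return float(f"{x:.6g}") if math.isfinite(x) else x
    return x


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return [_to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return _round6(float(obj))
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def write_results(result: Any, path: str | Path) -> None:
    """Write an analysis result (dataclass, dict, or list thereof) to JSON.

    Key order follows field declaration order; floats carry 6 significant
    digits.  Per-molecule record lists are better served by
    :func:`write_records_csv`.
    """
    with open(path, "w") as fh:
        json.dump(_to_jsonable(result), fh, indent=1)
        fh.write("\n")


def write_records_csv(records: Sequence[MoleculeEventRecord], path: str | Path) -> None:
    """Per-molecule event records as CSV (header-only when empty)."""
    df = pd.DataFrame(
        [
            {
                "molecule_id": r.molecule_id,
                "n_events": r.n_events,
                "observation_time_s": r.observation_time,
                "rate_per_s": r.rate,
            }
            for r in records
        ],
        columns=["molecule_id", "n_events", "observation_time_s", "rate_per_s"],
    )
    df.to_csv(path, index=False, float_format="%.6g")


def read_spot_counts(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a (time_s, count) CSV; returns times and counts arrays."""
    df = pd.read_csv(path)
    for col in ("time_s", "count"):
        if col not in df.columns:
            raise TraceTableError(f"{path}: missing column {col!r}")
    return df["time_s"].to_numpy(dtype=float), df["count"].to_numpy(dtype=float)


def write_spot_counts(series, path: str | Path) -> None:
    """Write a spot-count series as (time_s, count, percent_remaining) CSV."""
    pd.DataFrame(
        {
            "time_s": series.times,
            "count": series.counts,
            "percent_remaining": series.percent_remaining,
        }
    ).to_csv(path, index=False, float_format="%.6g")


def write_tiff_stack(frames: Sequence[np.ndarray], path: str | Path) -> None:
    """Write frames as a single-channel 16-bit TIFF stack (clipped to range)."""
    stack = np.stack([np.clip(np.rint(f), 0, 65535).astype(np.uint16) for f in frames])
    tifffile.imwrite(path, stack, photometric="minisblack")


def read_tiff_stack(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    return arr.astype(float)
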