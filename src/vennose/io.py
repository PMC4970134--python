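"""File I/O: recording CSVs, feature tables, predictions, reports, manifests.

Dialects
--------
* Recording CSV: header ``time,<sensor_1>,...,<sensor_n>``; one file
  per sample; times in seconds, strictly increasing and uniform.
* Feature-table CSV: header = feature names plus ``label``; one row
  per sample, index column = sample id.
* Predictions CSV: one row per prediction with the interval, the
  correctness flag and (for Venn methods) the flattened K×K matrix.

All floats are serialised with 17 significant digits so write-then-
read reproduces values exactly.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import Dataset
from .errors import ParseError
from .signal_features import SensorRecording
from .validity import PredictionRecord, ValidityReport

__all__ = [
    "read_recording_csv",
    "write_recording_csv",
    "read_feature_table",
    "write_feature_table",
    "write_predictions",
    "read_predictions",
    "write_validity_report",
    "write_manifest",
    "file_digest",
]

_FLOAT_FMT = "%.17g"


def read_recording_csv(path, label=None, baseline_window=None) -> SensorRecording:
    """Read one recording (``time,<sensor>...`` CSV) into a SensorRecording.

    The time column must be uniform; the sampling rate is derived from
    it.  Malformed files raise :class:`ParseError` naming the problem
    line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] < 2 or df.columns[0] != "time":
        raise ParseError(f"{path}: header must be 'time,<sensor_1>,...' "
                         f"(got {list(df.columns)[:3]})")
    if df.isna().any().any():
        bad = int(df[df.isna().any(axis=1)].index[0]) + 2  # header is line 1
        raise ParseError(f"{path}: missing or non-numeric value at line {bad}")
    t = df["time"].to_numpy(dtype=float)
    if t.size < 2:
        raise ParseError(f"{path}: need at least two time steps")
    dt = np.diff(t)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0)) + 3
        raise ParseError(f"{path}: time column must be strictly increasing "
                         f"(violated at line {bad})")
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        bad = int(np.argmax(~np.isclose(dt, dt[0], rtol=1e-6, atol=1e-9))) + 3
        raise ParseError(f"{path}: time column must be uniform (violated at line {bad})")
    return SensorRecording(
        readings=df.iloc[:, 1:].to_numpy(dtype=float),
        sampling_rate=1.0 / dt[0],
        baseline_window=baseline_window,
        sample_id=path.stem,
        label=label,
        sensor_names=tuple(df.columns[1:]),
    )


def write_recording_csv(recording: SensorRecording, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(recording.readings, columns=list(recording.sensor_names))
    df.insert(0, "time", recording.times())
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_feature_table(path) -> tuple[Dataset, list]:
    """Read a feature table CSV; returns (Dataset, feature_names).

    The first column is the sample id index; a ``label`` column is
    required.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if "label" not in df.columns:
        raise ParseError(f"{path}: feature table is missing the 'label' column")
    names = [c for c in df.columns if c != "label"]
    data = Dataset.from_dataframe(df, label_column="label")
    return data, names


def write_feature_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=True, index_label="sample_id", float_format=_FLOAT_FMT)
    return path


def write_predictions(records, path, matrices=None, labels=None) -> Path:
    """Write prediction records (and, for Venn methods, their matrices).

    Columns: step, sample_id, true_label, predicted_label, p_lower,
    p_upper, correct, then optional row-major ``P_<i>_<j>`` matrix
    entries.
    """
    path = Path(path)
    rows = []
    for idx, r in enumerate(records):
        row = {
            "step": r.step if r.step >= 0 else idx,
            "sample_id": r.sample_id,
            "true_label": r.true_label,
            "predicted_label": r.predicted_label,
            "p_lower": r.p_lower,
            "p_upper": r.p_upper,
            "correct": int(r.correct),
        }
        if matrices is not None:
            P = np.asarray(matrices[idx])
            for i in range(P.shape[0]):
                for j in range(P.shape[1]):
                    row[f"P_{i}_{j}"] = P[i, j]
        rows.append(row)
    df = pd.DataFrame(rows)
    if labels is not None:
        df.attrs["labels"] = list(labels)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_predictions(path) -> list[PredictionRecord]:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    needed = {"p_lower", "p_upper", "correct"}
    if not needed.issubset(df.columns):
        raise ParseError(f"{path}: predictions CSV needs columns {sorted(needed)}")
    records = []
    for _, row in df.iterrows():
        records.append(PredictionRecord(
            p_lower=float(row["p_lower"]), p_upper=float(row["p_upper"]),
            correct=bool(int(row["correct"])),
            sample_id=str(row.get("sample_id", "")),
            true_label=row.get("true_label"),
            predicted_label=row.get("predicted_label"),
            step=int(row.get("step", -1)),
        ))
    return records


def write_validity_report(report: ValidityReport, path) -> Path:
    path = Path(path)
    payload = report.to_dict()
    # JSON has no Infinity literal; use a string sentinel
    if not np.isfinite(payload["d_ln"]):
        payload["d_ln"] = "Infinity"
    path.write_text(json.dumps(payload, indent=2))
    return path


def file_digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path, *, config: dict, seeds: dict, inputs=(),
                   outputs=()) -> Path:
    """Emit a run manifest: config echo, seeds, version, input digests.

    Reruns with an identical manifest (same inputs, seeds and config)
    reproduce the run's outputs.
    """
    from . import __version__

    path = Path(path)
    manifest = {
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": config,
        "seeds": seeds,
        "inputs": {str(p): file_digest(p) for p in inputs},
        "outputs": [str(p) for p in outputs],
    }
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
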