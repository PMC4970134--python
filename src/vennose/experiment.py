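"""Experiment orchestration: run a method (or all six) end to end.

``run_experiment`` ties the feature table, a protocol and a method
together and writes the artifacts of one run — predictions CSV,
validity report JSON, confusion-table CSV and a reproducibility
manifest — into an output directory.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import Dataset
from .errors import InvalidInputError
from .io import write_manifest, write_predictions, write_validity_report
from .protocols import (ExperimentConfig, ProtocolResult, offline_loo,
                        online_run, sensitivity_specificity)

__all__ = ["run_experiment"]


def _write_confusion(result: ProtocolResult, path: Path) -> Path:
    labels = list(result.confusion.labels)
    df = pd.DataFrame(result.confusion.counts, index=labels, columns=labels)
    sens, spec = sensitivity_specificity(result.confusion)
    df["sensitivity"] = sens
    df["specificity"] = spec
    df.to_csv(path, index_label="true\\predicted")
    return path


def run_experiment(data: Dataset, config: ExperimentConfig, out_dir,
                   protocol: str = "offline", input_paths=()) -> ProtocolResult:
    """Run one experiment and write its artifacts under ``out_dir``.

    Parameters
    ----------
    data : feature Dataset (already extracted/assembled).
    config : ExperimentConfig naming the method, mode and seed.
    out_dir : directory for predictions.csv, report.json,
        confusion.csv and manifest.json (created if missing).
    protocol : ``"offline"`` (leave-one-out) or ``"online"``.
    input_paths : source files to digest into the manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if protocol == "offline":
        result = offline_loo(data, config)
    elif protocol == "online":
        result = online_run(data, config)
    else:
        raise InvalidInputError(f"unknown protocol {protocol!r}; "
                                "expected 'offline' or 'online'")
    pred_path = out_dir / "predictions.csv"
    report_path = out_dir / "report.json"
    conf_path = out_dir / "confusion.csv"
    write_predictions(result.records, pred_path, labels=data.labels)
    write_validity_report(result.report, report_path)
    _write_confusion(result, conf_path)
    write_manifest(
        out_dir / "manifest.json",
        config={**asdict(result.config), "protocol": protocol,
                "classification_rate": result.classification_rate,
                "fit_count": result.fit_count,
                "n_samples": data.n, "labels": list(data.labels),
                "test_order": result.test_order},
        seeds={"seed": config.seed},
        inputs=input_paths,
        outputs=[pred_path, report_path, conf_path],
    )
    return result
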