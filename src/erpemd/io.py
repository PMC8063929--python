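"""CSV readers/writers for cohorts, ERPs, feature tables and reports.

Epoched data travels in a flat long format (subject, condition, trial,
channel, sample, value) with a sidecar labels manifest; ERP waveforms are
one channels × samples CSV per subject × condition.  Everything is plain
text so pipelines remain inspectable with standard tools.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortSpec, EpochedRecording
from .erp import ERPWaveform

__all__ = [
    "write_labels",
    "read_labels",
    "write_cohort_long",
    "read_cohort_long",
    "write_erps",
    "read_erps",
    "write_feature_table",
    "read_feature_table",
    "report_to_dict",
    "write_report",
]


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"subject_id": list(labels), "group": list(labels.values())}
    ).to_csv(path, index=False)


def read_labels(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path)
    return dict(zip(df["subject_id"], df["group"]))


def write_cohort_long(cohort: Cohort, out_dir: str | Path) -> None:
    """Write the long-format epochs CSV plus the labels manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    for (sid, cond), rec in cohort.recordings.items():
        n_tr, n_ch, n_s = rec.data.shape
        tr, ch, sm = np.meshgrid(
            np.arange(n_tr), np.arange(n_ch), np.arange(n_s), indexing="ij"
        )
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": sid,
                    "condition": cond,
                    "trial": tr.ravel(),
                    "channel": ch.ravel(),
                    "sample": sm.ravel(),
                    "value": rec.data.ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(out / "epochs.csv", index=False)
    write_labels(cohort.labels, out / "labels.csv")
    meta = dataclasses.asdict(cohort.spec)
    meta["effect"] = "custom"  # effect model is not round-tripped
    with open(out / "cohort.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)


def read_cohort_long(
    in_dir: str | Path, fs: float = 500.0, t0: int = 100
) -> tuple[dict[tuple[str, str], EpochedRecording], dict[str, str]]:
    """Read epochs.csv + labels.csv back into recordings and labels."""
    in_dir = Path(in_dir)
    df = pd.read_csv(in_dir / "epochs.csv")
    meta_path = in_dir / "cohort.json"
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
        fs = float(meta.get("fs", fs))
        lo = float(meta.get("epoch_window_ms", [-200, 800])[0])
        t0 = int(round(-lo * fs / 1000.0))
    recordings: dict[tuple[str, str], EpochedRecording] = {}
    for (sid, cond), g in df.groupby(["subject_id", "condition"], sort=False):
        n_tr = int(g["trial"].max()) + 1
        n_ch = int(g["channel"].max()) + 1
        n_s = int(g["sample"].max()) + 1
        data = np.empty((n_tr, n_ch, n_s))
        data[g["trial"], g["channel"], g["sample"]] = g["value"]
        recordings[(sid, cond)] = EpochedRecording(sid, cond, data, fs, t0)
    labels = read_labels(in_dir / "labels.csv")
    return recordings, labels


def write_erps(
    erps: Mapping[str, Mapping[str, ERPWaveform]], out_dir: str | Path
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sid, per_cond in erps.items():
        for cond, erp in per_cond.items():
            pd.DataFrame(erp.data).to_csv(
                out / f"{sid}_{cond}.csv", index=False, header=False
            )


def read_erps(
    in_dir: str | Path, fs: float = 500.0, t0: int = 100
) -> dict[str, dict[str, ERPWaveform]]:
    erps: dict[str, dict[str, ERPWaveform]] = {}
    for path in sorted(Path(in_dir).glob("*_*.csv")):
        sid, cond = path.stem.split("_", 1)
        data = pd.read_csv(path, header=None).to_numpy(dtype=float)
        erps.setdefault(sid, {})[cond] = ERPWaveform(sid, cond, data, fs, t0)
    return erps


def write_feature_table(
    table: pd.DataFrame, labels: Mapping[str, str], path: str | Path
) -> None:
    """Subjects × features CSV with the group label as the last column."""
    out = table.copy()
    out["group"] = [labels[s] for s in out.index]
    out.to_csv(path, index_label="subject_id")


def read_feature_table(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    df = pd.read_csv(path, index_col="subject_id")
    labels = dict(df["group"])
    return df.drop(columns=["group"]), labels


def report_to_dict(report) -> dict:
    """JSON-safe summary of an EvaluationReport."""
    return {
        "accuracy": report.accuracy,
        "sensitivity": report.sensitivity,
        "specificity": report.specificity,
        "confusion": {
            "tp": report.confusion.tp,
            "tn": report.confusion.tn,
            "fp": report.confusion.fp,
            "fn": report.confusion.fn,
            "positive_class": report.confusion.positive_class,
        },
        "resample_id": report.resample_id,
        "folds": [
            {
                "fold": f.fold,
                "hyperparams": f.hyperparams,
                "selected_columns": [str(c) for c in f.selected_columns],
            }
            for f in report.folds
        ],
    }


def write_report(result, path: str | Path) -> None:
    payload = {
        "problem": result.problem,
        "classifier": result.classifier,
        "variant": result.variant,
        "summary": result.summary,
        "reports": [report_to_dict(r) for r in result.reports],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
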