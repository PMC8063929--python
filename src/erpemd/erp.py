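"""Epochs-to-ERP pipeline: exclusion, re-referencing, baseline, averaging.

The pipeline order is fixed: subjects with too few trials in any condition
are excluded, the remaining epochs are re-referenced to the average of all
electrodes, baseline-corrected over the pre-stimulus window, and averaged
within condition to one ERP waveform per subject × condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .cohort import Cohort, EpochedRecording

__all__ = [
    "ERPWaveform",
    "exclude_low_trial_subjects",
    "filter_known_outcome",
    "rereference_to_average",
    "baseline_correct",
    "average_trials",
    "build_erps",
]


@dataclass
class ERPWaveform:
    """Trial-averaged ERP for one subject in one condition (channels × samples)."""

    subject_id: str
    condition: str
    data: np.ndarray  # (n_channels, n_samples), µV
    fs: float
    t0: int

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def exclude_low_trial_subjects(
    recordings: Mapping[tuple[str, str], EpochedRecording],
    conditions: Iterable[str],
    min_trials: int = 10,
) -> tuple[list[str], pd.DataFrame]:
    """Drop subjects with fewer than ``min_trials`` trials in any condition.

    Returns the retained subject ids (input order) and an exclusion log
    with one row per violating subject × condition.
    """
    conditions = list(conditions)
    subjects: list[str] = []
    for sid, _ in recordings:
        if sid not in subjects:
            subjects.append(sid)
    for sid in subjects:
        for cond in conditions:
            if (sid, cond) not in recordings:
                raise ValueError(
                    f"incomplete cohort: subject {sid!r} has no recording "
                    f"for condition {cond!r}"
                )
    rows = []
    excluded = set()
    for sid in subjects:
        for cond in conditions:
            n = recordings[(sid, cond)].n_trials
            if n < min_trials:
                rows.append({"subject_id": sid, "condition": cond, "n_trials": n})
                excluded.add(sid)
    retained = [s for s in subjects if s not in excluded]
    log = pd.DataFrame(rows, columns=["subject_id", "condition", "n_trials"])
    return retained, log


def filter_known_outcome(labels: Mapping[str, str]) -> list[str]:
    """Subject ids whose diagnostic outcome is ascertained (drops HR-unknown)."""
    return [s for s, g in labels.items() if g != "HR-unknown"]


def rereference_to_average(data: np.ndarray) -> np.ndarray:
    """Re-reference to the instantaneous mean across channels.

    Accepts (..., channels, samples); at every sample the cross-channel
    mean of the output is zero.  Idempotent.
    """
    data = np.asarray(data, dtype=float)
    if data.shape[-2] < 2:
        raise ValueError("average re-referencing requires >= 2 channels")
    return data - data.mean(axis=-2, keepdims=True)


def _window_slice(
    fs: float, t0: int, n_samples: int, window_ms: tuple[float, float]
) -> slice:
    lo_ms, hi_ms = window_ms
    lo = t0 + int(round(lo_ms * fs / 1000.0))
    hi = t0 + int(round(hi_ms * fs / 1000.0))
    if not (0 <= lo < hi <= n_samples):
        raise ValueError(
            f"baseline window {window_ms} ms maps to samples [{lo}, {hi}) "
            f"outside the epoch of {n_samples} samples"
        )
    return slice(lo, hi)


def baseline_correct(
    data: np.ndarray,
    fs: float,
    t0: int,
    window_ms: tuple[float, float] = (-200.0, 0.0),
) -> np.ndarray:
    """Subtract the mean over the (half-open) baseline window per channel.

    Accepts (..., channels, samples); the window defaults to the full
    pre-stimulus interval.
    """
    data = np.asarray(data, dtype=float)
    sl = _window_slice(fs, t0, data.shape[-1], window_ms)
    return data - data[..., sl].mean(axis=-1, keepdims=True)


def average_trials(recording: EpochedRecording) -> ERPWaveform:
    """Pointwise mean across trials."""
    if recording.n_trials < 1:
        raise ValueError("cannot average a recording with zero trials")
    return ERPWaveform(
        subject_id=recording.subject_id,
        condition=recording.condition,
        data=recording.data.mean(axis=0),
        fs=recording.fs,
        t0=recording.t0,
    )


def build_erps(
    cohort: Cohort,
    min_trials: int = 10,
    baseline_window_ms: tuple[float, float] = (-200.0, 0.0),
) -> tuple[dict[str, dict[str, ERPWaveform]], dict[str, str], pd.DataFrame]:
    """Run the full pipeline: exclude → re-reference → baseline → average.

    Returns (erps[subject][condition], retained labels, exclusion log).
    """
    retained, log = exclude_low_trial_subjects(
        cohort.recordings, cohort.spec.conditions, min_trials=min_trials
    )
    erps: dict[str, dict[str, ERPWaveform]] = {}
    for sid in retained:
        per_cond: dict[str, ERPWaveform] = {}
        for cond in cohort.spec.conditions:
            rec = cohort.recordings[(sid, cond)]
            data = rereference_to_average(rec.data)
            data = baseline_correct(data, rec.fs, rec.t0, baseline_window_ms)
            per_cond[cond] = average_trials(
                EpochedRecording(sid, cond, data, rec.fs, rec.t0)
            )
        erps[sid] = per_cond
    labels = {s: cohort.labels[s] for s in retained}
    return erps, labels, log
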