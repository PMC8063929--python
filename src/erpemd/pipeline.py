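"""End-to-end orchestration: cohort → ERPs → IMFs → feature table."""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .cohort import Cohort
from .emd import SiftConfig
from .erp import ERPWaveform, build_erps
from .features import (
    column_label,
    extract_subject_features,
    reduce_max_across_channels,
)

__all__ = ["features_from_erps", "features_from_cohort"]


def features_from_erps(
    erps: Mapping[str, Mapping[str, ERPWaveform]],
    conditions,
    sift_config: SiftConfig = SiftConfig(),
    reduction: str = "signed",
) -> pd.DataFrame:
    """Subjects × 108 reduced feature table from per-subject ERPs."""
    rows = []
    index = []
    cols: Optional[list[str]] = None
    for sid, per_cond in erps.items():
        mat = extract_subject_features(per_cond, sift_config, conditions)
        vec = reduce_max_across_channels(mat, mode=reduction)
        if cols is None:
            cols = [column_label(c) for c in vec.columns]
        rows.append(vec.values)
        index.append(sid)
    return pd.DataFrame(np.asarray(rows), index=index, columns=cols)


def features_from_cohort(
    cohort: Cohort,
    min_trials: int = 10,
    sift_config: SiftConfig = SiftConfig(),
    reduction: str = "signed",
) -> tuple[pd.DataFrame, dict[str, str], pd.DataFrame]:
    """Full pipeline; returns (feature table, retained labels, exclusion log)."""
    erps, labels, log = build_erps(cohort, min_trials=min_trials)
    table = features_from_erps(
        erps, cohort.spec.conditions, sift_config, reduction
    )
    return table, labels, log
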