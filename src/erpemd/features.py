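"""Per-IMF feature battery and the channels × features matrix.

For every stimulus condition, channel and IMF, six scalars are computed:
signal energy, an (unnormalized) Shannon entropy of the squared
amplitudes, and four distribution statistics (mean, standard deviation,
skewness, fourth central moment).  With 6 conditions × 3 IMFs × 6
features a subject yields a channels × 108 matrix, which is reduced to a
single 108-vector by taking, per column, the maximum over channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CONDITIONS
from .emd import SiftConfig, decompose_to_n
from .erp import ERPWaveform

__all__ = [
    "FEATURE_NAMES",
    "FeatureMatrix",
    "FeatureVector",
    "imf_energy",
    "shannon_entropy",
    "statistical_features",
    "feature_columns",
    "column_label",
    "assemble_features",
    "reduce_max_across_channels",
    "extract_subject_features",
    "columns_for_condition",
    "columns_for_imf",
]

#: Fixed feature order within each (condition, IMF) block.
FEATURE_NAMES: tuple[str, ...] = (
    "energy",
    "shannon_entropy",
    "mean",
    "std",
    "skewness",
    "moment",
)


def imf_energy(x: np.ndarray) -> float:
    """Sum of squared amplitudes (µV²)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty waveform")
    return float(np.sum(x * x))


def shannon_entropy(x: np.ndarray) -> float:
    """−Σ x²·ln(x²), with 0·ln 0 := 0.

    Applied verbatim to the squared amplitudes (no normalization to a
    probability distribution); natural logarithm.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty waveform")
    p = x * x
    nz = p > 0
    return float(-np.sum(p[nz] * np.log(p[nz])))


def statistical_features(x: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, sample std, skewness, fourth central moment).

    Std uses the n−1 denominator; skewness is the biased third
    standardized moment, 0 by convention for a zero-variance sample.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples for statistics")
    mean = float(np.mean(x))
    std = float(np.std(x, ddof=1))
    if std == 0.0:
        return mean, 0.0, 0.0, 0.0
    skew = float(stats.skew(x, bias=True))
    m4 = float(stats.moment(x, moment=4))
    return mean, std, skew, m4


def _all_features(x: np.ndarray) -> tuple[float, ...]:
    mean, std, skew, m4 = statistical_features(x)
    return imf_energy(x), shannon_entropy(x), mean, std, skew, m4


# ----------------------------------------------------------------------
# labeled assembly
# ----------------------------------------------------------------------

def feature_columns(
    conditions: Sequence[str] = CONDITIONS, n_imfs: int = 3
) -> list[tuple[str, int, str]]:
    """Ordered (condition, imf_index, feature) triples; condition-major."""
    return [
        (cond, j, feat)
        for cond in conditions
        for j in range(1, n_imfs + 1)
        for feat in FEATURE_NAMES
    ]


def column_label(col: tuple[str, int, str]) -> str:
    cond, j, feat = col
    return f"{cond}|imf{j}|{feat}"


@dataclass
class FeatureMatrix:
    """Channels × (6·3·6 = 108) labeled feature matrix for one subject."""

    subject_id: str
    values: np.ndarray  # (n_channels, n_columns)
    columns: list[tuple[str, int, str]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, columns=[column_label(c) for c in self.columns]
        )


@dataclass
class FeatureVector:
    """Per-column channel maximum of a FeatureMatrix."""

    subject_id: str
    values: np.ndarray  # (n_columns,)
    columns: list[tuple[str, int, str]]
    argmax_channel: np.ndarray  # (n_columns,) int


def assemble_features(
    subject_id: str,
    imfs_by_condition: Mapping[str, Sequence[Sequence[np.ndarray]]],
    conditions: Sequence[str] = CONDITIONS,
    n_imfs: int = 3,
) -> FeatureMatrix:
    """Build the channels × 108 matrix from per-channel IMF waveforms.

    ``imfs_by_condition[cond][channel][imf_index]`` is one IMF waveform.
    Every condition must be present with the same channel count and
    ``n_imfs`` modes per channel; a missing cell is an error naming it.
    """
    n_channels = None
    for cond in conditions:
        if cond not in imfs_by_condition:
            raise ValueError(f"missing decompositions for condition {cond!r}")
        chans = imfs_by_condition[cond]
        if n_channels is None:
            n_channels = len(chans)
        elif len(chans) != n_channels:
            raise ValueError(
                f"condition {cond!r} has {len(chans)} channels, expected {n_channels}"
            )
        for c, modes in enumerate(chans):
            if len(modes) != n_imfs:
                raise ValueError(
                    f"subject {subject_id!r}, condition {cond!r}, channel {c}: "
                    f"expected {n_imfs} IMFs, got {len(modes)}"
                )
    assert n_channels is not None and n_channels >= 1
    cols = feature_columns(conditions, n_imfs)
    values = np.empty((n_channels, len(cols)))
    j = 0
    for cond in conditions:
        chans = imfs_by_condition[cond]
        for imf_idx in range(n_imfs):
            block = np.array(
                [_all_features(chans[c][imf_idx]) for c in range(n_channels)]
            )
            values[:, j : j + len(FEATURE_NAMES)] = block
            j += len(FEATURE_NAMES)
    return FeatureMatrix(subject_id=subject_id, values=values, columns=cols)


def reduce_max_across_channels(
    matrix: FeatureMatrix, mode: str = "signed"
) -> FeatureVector:
    """Per column, the maximum over channels (plus the attaining channel).

    ``mode="signed"`` takes the plain maximum; ``mode="abs"`` takes the
    value of largest magnitude (sign preserved).
    """
    if matrix.values.shape[0] < 1:
        raise ValueError("empty feature matrix")
    if mode == "signed":
        arg = np.argmax(matrix.values, axis=0)
    elif mode == "abs":
        arg = np.argmax(np.abs(matrix.values), axis=0)
    else:
        raise ValueError(f"unknown reduction mode {mode!r}")
    vals = matrix.values[arg, np.arange(matrix.values.shape[1])]
    return FeatureVector(
        subject_id=matrix.subject_id,
        values=vals,
        columns=list(matrix.columns),
        argmax_channel=arg,
    )


# ----------------------------------------------------------------------
# from ERPs
# ----------------------------------------------------------------------

def extract_subject_features(
    erps_by_condition: Mapping[str, ERPWaveform],
    sift_config: SiftConfig = SiftConfig(),
    conditions: Sequence[str] = CONDITIONS,
) -> FeatureMatrix:
    """Decompose every channel of every condition ERP and assemble features."""
    imfs_by_condition = {}
    sid = None
    for cond in conditions:
        if cond not in erps_by_condition:
            raise ValueError(f"missing ERP for condition {cond!r}")
        erp = erps_by_condition[cond]
        sid = erp.subject_id
        imfs_by_condition[cond] = [
            decompose_to_n(erp.data[c], sift_config)
            for c in range(erp.n_channels)
        ]
    assert sid is not None
    return assemble_features(sid, imfs_by_condition, conditions, sift_config.n_imfs)


# ----------------------------------------------------------------------
# ablation column subsets
# ----------------------------------------------------------------------

def columns_for_condition(
    columns: Sequence[tuple[str, int, str]], condition: str
) -> list[int]:
    """Column indices for one stimulus condition (3 IMFs × 6 features = 18)."""
    idx = [i for i, (cond, _, _) in enumerate(columns) if cond == condition]
    if not idx:
        raise ValueError(f"unknown condition {condition!r}")
    return idx


def columns_for_imf(
    columns: Sequence[tuple[str, int, str]], imf_index: int
) -> list[int]:
    """Column indices for one IMF (6 conditions × 6 features = 36)."""
    idx = [i for i, (_, j, _) in enumerate(columns) if j == imf_index]
    if not idx:
        raise ValueError(f"unknown IMF index {imf_index!r}")
    return idx
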