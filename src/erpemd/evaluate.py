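"""Nested cross-validated k-NN / SVM evaluation with in-fold selection.

The outer stratified k-fold loop estimates generalization; within each
outer training fold an inner stratified k-fold grid search picks the
hyperparameters, and feature standardization plus correlation-weight
selection are refit on training rows only, so no test information leaks
into model choice.  Confusion counts are pooled over the outer test
folds.  For the imbalanced diagnostic-outcome problem, the majority class
is repeatedly subsampled (without replacement) to the minority size and
the whole nested CV is run per balanced resample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .cohort import GROUP_CONTROL, GROUP_HR_ASD, GROUP_HR_NOASD, HR_FAMILY_GROUPS
from .selection import rank_and_select

__all__ = [
    "CVConfig",
    "ConfusionCounts",
    "EvaluationReport",
    "ExperimentResult",
    "DEFAULT_KNN_GRID",
    "DEFAULT_SVM_GRID",
    "SVM_KERNELS",
    "knn_classify",
    "svm_classify",
    "nested_cv",
    "balanced_resample",
    "compute_metrics",
    "risk_labels",
    "run_experiment",
]

#: Scanned neighbor counts (odd, so binary votes cannot tie on count).
DEFAULT_KNN_GRID: tuple[int, ...] = tuple(range(1, 22, 2))

#: Kernel families compared for the SVM: linear, quadratic and cubic
#: polynomials, and Gaussian at three width presets.
SVM_KERNELS: tuple[str, ...] = (
    "linear",
    "quadratic",
    "cubic",
    "gaussian_fine",
    "gaussian_medium",
    "gaussian_coarse",
)

DEFAULT_SVM_C: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)

#: (kernel, C) grid ordered simplest-kernel-first, then smallest C, so the
#: first grid point among inner-accuracy ties is the simplest model.
DEFAULT_SVM_GRID: tuple[tuple[str, float], ...] = tuple(
    (kern, C) for kern in SVM_KERNELS for C in DEFAULT_SVM_C
)


@dataclass(frozen=True)
class CVConfig:
    """Nested-CV layout and hyperparameter grids."""

    outer_folds: int = 10
    inner_folds: int = 9
    stratified: bool = True
    seed: int = 0
    knn_grid: tuple[int, ...] = DEFAULT_KNN_GRID
    svm_grid: tuple[tuple[str, float], ...] = DEFAULT_SVM_GRID
    selection_k: int = 30

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("outer_folds and inner_folds must be >= 2")
        if not self.knn_grid or not self.svm_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        if self.selection_k < 1:
            raise ValueError("selection_k must be >= 1")


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int
    positive_class: str

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class FoldResult:
    fold: int
    hyperparams: dict
    selected_columns: list
    test_index: np.ndarray
    predictions: np.ndarray
    truth: np.ndarray


@dataclass
class EvaluationReport:
    folds: list[FoldResult]
    confusion: ConfusionCounts
    accuracy: float
    sensitivity: float
    specificity: float
    resample_id: Optional[int] = None


@dataclass
class ExperimentResult:
    """One classification experiment: reports plus summary means."""

    problem: str
    classifier: str
    variant: str
    reports: list[EvaluationReport]
    summary: dict = field(default_factory=dict)


# ----------------------------------------------------------------------
# classifiers
# ----------------------------------------------------------------------

def knn_classify(
    train: np.ndarray,
    train_labels: Sequence,
    test: np.ndarray,
    k: int,
) -> np.ndarray:
    """k-nearest-neighbor prediction with Euclidean distances.

    Majority vote among the k nearest training rows; a tied vote goes to
    the tied class with the single nearest member.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    Xtr = np.asarray(train, dtype=float)
    Xte = np.asarray(test, dtype=float)
    ytr = np.asarray(train_labels)
    if k > Xtr.shape[0]:
        raise ValueError(f"k={k} exceeds {Xtr.shape[0]} training rows")
    D = cdist(Xte, Xtr, metric="euclidean")
    # argsort is deterministic (stable ties by training index)
    nearest = np.argsort(D, axis=1, kind="stable")[:, :k]
    preds = []
    for row in nearest:
        neigh_labels = ytr[row]
        classes, counts = np.unique(neigh_labels, return_counts=True)
        top = counts.max()
        tied = classes[counts == top]
        if tied.size == 1:
            preds.append(tied[0])
        else:
            # nearest member of the tied classes wins
            for idx in row:
                if ytr[idx] in tied:
                    preds.append(ytr[idx])
                    break
    return np.asarray(preds)


def _svm_gamma(kernel: str, n_features: int) -> Optional[float]:
    # Gaussian width presets: kernel scale sigma = sqrt(p)/4, sqrt(p),
    # 4*sqrt(p) for fine/medium/coarse; K = exp(-||u-v||^2 / sigma^2).
    root_p = float(np.sqrt(n_features))
    sigma = {
        "gaussian_fine": root_p / 4.0,
        "gaussian_medium": root_p,
        "gaussian_coarse": 4.0 * root_p,
    }.get(kernel)
    return None if sigma is None else 1.0 / (sigma * sigma)


def _make_svc(kernel: str, C: float, n_features: int) -> SVC:
    if kernel == "linear":
        return SVC(kernel="linear", C=C)
    if kernel == "quadratic":
        return SVC(kernel="poly", degree=2, coef0=1.0, gamma="scale", C=C)
    if kernel == "cubic":
        return SVC(kernel="poly", degree=3, coef0=1.0, gamma="scale", C=C)
    gamma = _svm_gamma(kernel, n_features)
    if gamma is None:
        raise ValueError(f"unknown SVM kernel {kernel!r}")
    return SVC(kernel="rbf", gamma=gamma, C=C)


def svm_classify(
    train: np.ndarray,
    train_labels: Sequence,
    test: np.ndarray,
    kernel: str = "linear",
    C: float = 1.0,
) -> np.ndarray:
    """Margin-based binary prediction with the named kernel preset."""
    Xtr = np.asarray(train, dtype=float)
    ytr = np.asarray(train_labels)
    if np.unique(ytr).size < 2:
        raise ValueError("SVM training requires two classes")
    clf = _make_svc(kernel, C, Xtr.shape[1])
    clf.fit(Xtr, ytr)
    return clf.predict(np.asarray(test, dtype=float))


def _predict(
    classifier: str,
    params: dict,
    Xtr: np.ndarray,
    ytr: np.ndarray,
    Xte: np.ndarray,
) -> np.ndarray:
    if classifier == "knn":
        return knn_classify(Xtr, ytr, Xte, params["k"])
    if classifier == "svm":
        return svm_classify(Xtr, ytr, Xte, params["kernel"], params["C"])
    raise ValueError(f"unknown classifier {classifier!r}")


# ----------------------------------------------------------------------
# metrics
# ----------------------------------------------------------------------

def compute_metrics(confusion: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); NaN where a denominator is 0."""
    c = confusion
    acc = (c.tp + c.tn) / c.total if c.total > 0 else float("nan")
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else float("nan")
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else float("nan")
    return acc, sens, spec


def _pool_confusion(
    truth: np.ndarray, preds: np.ndarray, positive_class: str
) -> ConfusionCounts:
    pos_t = truth == positive_class
    pos_p = preds == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        positive_class=positive_class,
    )


# ----------------------------------------------------------------------
# standardization helper (training statistics only)
# ----------------------------------------------------------------------

def _fit_zscore(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mu, sd


# ----------------------------------------------------------------------
# nested CV
# ----------------------------------------------------------------------

def nested_cv(
    table: np.ndarray | pd.DataFrame,
    labels: Sequence,
    classifier: str,
    config: CVConfig,
    positive_class: str,
    columns: Optional[Sequence] = None,
) -> EvaluationReport:
    """Stratified nested cross-validation with in-fold selection.

    Per outer fold, z-scoring statistics, the correlation-weight ranking
    and the hyperparameter choice are all fit on the outer-training rows;
    the inner loop refits scaling and selection per inner split and picks
    the grid point with the best mean inner accuracy (ties go to the
    earlier — simpler/smaller — grid entry).  Metrics are pooled over the
    outer test predictions.
    """
    if isinstance(table, pd.DataFrame):
        if columns is None:
            columns = list(table.columns)
        X = table.to_numpy(dtype=float)
    else:
        X = np.asarray(table, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] != y.size:
        raise ValueError("feature table and labels disagree on sample count")
    k_sel = min(config.selection_k, X.shape[1])
    grid: list[dict]
    if classifier == "knn":
        grid = [{"k": k} for k in config.knn_grid]
    elif classifier == "svm":
        grid = [{"kernel": kern, "C": C} for kern, C in config.svm_grid]
    else:
        raise ValueError(f"unknown classifier {classifier!r}")

    outer = StratifiedKFold(
        n_splits=config.outer_folds, shuffle=True, random_state=config.seed % (2**31)
    )
    folds: list[FoldResult] = []
    all_truth: list[np.ndarray] = []
    all_preds: list[np.ndarray] = []
    for fold_id, (tr_idx, te_idx) in enumerate(outer.split(X, y)):
        Xtr_raw, ytr = X[tr_idx], y[tr_idx]
        Xte_raw, yte = X[te_idx], y[te_idx]

        # inner grid search on the outer-training rows only
        inner = StratifiedKFold(
            n_splits=config.inner_folds,
            shuffle=True,
            random_state=(config.seed * 1000 + fold_id + 1) % (2**31),
        )
        scores = np.zeros(len(grid))
        for itr, ite in inner.split(Xtr_raw, ytr):
            Xi, yi = Xtr_raw[itr], ytr[itr]
            Xv, yv = Xtr_raw[ite], ytr[ite]
            mu, sd = _fit_zscore(Xi)
            Xi_z, Xv_z = (Xi - mu) / sd, (Xv - mu) / sd
            rank = rank_and_select(Xi_z, yi, k_sel)
            cols = rank.selected
            for g, params in enumerate(grid):
                if classifier == "knn" and params["k"] > Xi.shape[0]:
                    scores[g] -= 1.0  # infeasible on this split
                    continue
                pred = _predict(classifier, params, Xi_z[:, cols], yi, Xv_z[:, cols])
                scores[g] += float(np.mean(pred == yv))
        best = int(np.argmax(scores))  # first max wins ties (simplest model)
        params = grid[best]

        # refit on the full outer-training fold
        mu, sd = _fit_zscore(Xtr_raw)
        Xtr_z, Xte_z = (Xtr_raw - mu) / sd, (Xte_raw - mu) / sd
        rank = rank_and_select(Xtr_z, ytr, k_sel, columns=columns)
        cols = rank.selected
        preds = _predict(classifier, params, Xtr_z[:, cols], ytr, Xte_z[:, cols])
        folds.append(
            FoldResult(
                fold=fold_id,
                hyperparams=dict(params),
                selected_columns=(
                    rank.selected_labels
                    if rank.selected_labels is not None
                    else list(map(int, cols))
                ),
                test_index=te_idx,
                predictions=preds,
                truth=yte,
            )
        )
        all_truth.append(yte)
        all_preds.append(preds)

    truth = np.concatenate(all_truth)
    preds = np.concatenate(all_preds)
    confusion = _pool_confusion(truth, preds, positive_class)
    acc, sens, spec = compute_metrics(confusion)
    return EvaluationReport(
        folds=folds,
        confusion=confusion,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
    )


# ----------------------------------------------------------------------
# balanced resampling
# ----------------------------------------------------------------------

def balanced_resample(
    minority_ids: Sequence,
    majority_ids: Sequence,
    repeats: int = 5,
    seed: int = 0,
) -> list[list]:
    """Per repeat: all minority ids + an equal-size majority subsample.

    Majority ids are drawn without replacement within a repeat; draws are
    independent across repeats and deterministic for a given seed.
    """
    minority = list(minority_ids)
    majority = list(majority_ids)
    if len(minority) > len(majority):
        raise ValueError("minority class is larger than majority class")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(repeats):
        picked = rng.choice(len(majority), size=len(minority), replace=False)
        out.append(minority + [majority[i] for i in sorted(picked)])
    return out


# ----------------------------------------------------------------------
# experiments
# ----------------------------------------------------------------------

def risk_labels(groups: Sequence[str]) -> np.ndarray:
    """Collapse three-group labels to the familial-risk dichotomy."""
    return np.asarray(
        ["HR" if g in HR_FAMILY_GROUPS else GROUP_CONTROL for g in groups]
    )


def _variant_columns(columns: Sequence, variant: str) -> list[int]:
    from .features import columns_for_condition, columns_for_imf

    if variant == "all":
        return list(range(len(columns)))
    if variant.startswith("imf"):
        return columns_for_imf(_as_triples(columns), int(variant[3:]))
    return columns_for_condition(_as_triples(columns), variant)


def _as_triples(columns: Sequence) -> list[tuple[str, int, str]]:
    out = []
    for col in columns:
        if isinstance(col, tuple):
            out.append(col)
        else:
            cond, imf, feat = str(col).split("|")
            out.append((cond, int(imf.removeprefix("imf")), feat))
    return out


def run_experiment(
    table: pd.DataFrame,
    groups: Sequence[str],
    problem: str,
    classifier: str = "knn",
    config: Optional[CVConfig] = None,
    variant: str = "all",
    resamples: int = 5,
) -> ExperimentResult:
    """Run one classification problem end to end.

    ``problem="risk"`` classifies control vs high-risk with a single
    nested CV (defaults: 10 outer × 9 inner folds; positive class HR).
    ``problem="outcome"`` classifies HR-ASD vs HR-noASD over ``resamples``
    balanced majority subsamples (defaults: 5 outer × 4 inner folds per
    resample; positive class HR-ASD), reporting per-resample metrics and
    their unweighted mean.  ``variant`` restricts the feature columns: a
    condition name (18 columns) or ``"imf1"``/``"imf2"``/``"imf3"`` (36
    columns).
    """
    groups = np.asarray(groups)
    if problem == "risk":
        cfg = config or CVConfig(outer_folds=10, inner_folds=9, selection_k=30)
        y = risk_labels(groups)
        keep_cols = _variant_columns(list(table.columns), variant)
        sub = table.iloc[:, keep_cols]
        report = nested_cv(sub, y, classifier, cfg, positive_class="HR")
        result = ExperimentResult(
            problem=problem,
            classifier=classifier,
            variant=variant,
            reports=[report],
        )
    elif problem == "outcome":
        cfg = config or CVConfig(outer_folds=5, inner_folds=4, selection_k=11)
        mask_asd = groups == GROUP_HR_ASD
        mask_no = groups == GROUP_HR_NOASD
        ids = np.asarray(table.index)
        sets = balanced_resample(
            list(ids[mask_asd]), list(ids[mask_no]),
            repeats=resamples, seed=cfg.seed,
        )
        keep_cols = _variant_columns(list(table.columns), variant)
        reports = []
        for r, subject_set in enumerate(sets):
            sub = table.loc[subject_set].iloc[:, keep_cols]
            y = np.asarray(
                [GROUP_HR_ASD if s in set(ids[mask_asd]) else GROUP_HR_NOASD
                 for s in subject_set]
            )
            rcfg = CVConfig(
                outer_folds=cfg.outer_folds,
                inner_folds=cfg.inner_folds,
                stratified=cfg.stratified,
                seed=cfg.seed + 17 * (r + 1),
                knn_grid=cfg.knn_grid,
                svm_grid=cfg.svm_grid,
                selection_k=cfg.selection_k,
            )
            rep = nested_cv(sub, y, classifier, rcfg, positive_class=GROUP_HR_ASD)
            rep.resample_id = r
            reports.append(rep)
        result = ExperimentResult(
            problem=problem,
            classifier=classifier,
            variant=variant,
            reports=reports,
        )
    else:
        raise ValueError(f"unknown problem {problem!r}")

    accs = [r.accuracy for r in result.reports]
    sens = [r.sensitivity for r in result.reports]
    spec = [r.specificity for r in result.reports]
    result.summary = {
        "accuracy": float(np.mean(accs)),
        "sensitivity": float(np.nanmean(sens)),
        "specificity": float(np.nanmean(spec)),
        "n_reports": len(result.reports),
    }
    return result


def observation_count(n_subjects: int, n_conditions: int = 6) -> int:
    """Condition-level observations feeding assembly (one ERP per condition)."""
    return n_subjects * n_conditions
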