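"""Fused linear-SVM classification of multilevel connectivity features.

One linear SVM is trained per feature type — static network edges, low-order
dynamic-network central moments, high-order dynamic-network central moments —
after two-stage feature selection, and the three decision scores are fused by
a tuned weighted average.  Performance is estimated with stratified outer
k-fold cross-validation repeated several times, with a nested inner CV on the
training portion tuning, per feature type, the t-test threshold p, the LASSO
penalty lambda, and the SVM trade-off C, plus the fusion weights alpha, by
maximizing inner mean accuracy (ties break toward the first grid point in
enumeration order).

All preprocessing (z-scoring), selection and tuning are computed strictly on
training subjects; feature extraction itself is per-subject and leakage-free,
so feature tables are precomputed once per cohort.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import DimensionError, MetricsWarning, SelectionFallbackWarning
from .io import Cohort, make_pair_index
from .moments import moment_matrix, vectorize
from .networks import build_cfcn, build_ho_dfcn, build_lo_dfcn
from .selection import apply_two_stage, feature_pvalues

__all__ = [
    "FEATURE_TYPES",
    "HyperGrid",
    "Metrics",
    "compute_metrics",
    "fuse_scores",
    "train_linear_svm",
    "extract_feature_tables",
    "MultiLevelFCClassifier",
    "FoldResult",
    "CVResult",
    "nested_cv",
    "selection_frequency",
    "sweep_params",
]

#: feature-type keys, in fusion order (c = 0, 1, 2)
FEATURE_TYPES = ("static", "lo", "ho")


@dataclass
class HyperGrid:
    """Hyperparameter search grids for the nested inner CV.

    Defaults are the full published grids; :meth:`desk` returns the reduced
    desk-scale grid used by the bundled tests and the acceptance script.
    """

    p_thresholds: Sequence[float] = tuple(np.round(np.arange(0.01, 0.101, 0.01), 2))
    lambdas: Sequence[float] = tuple(np.round(np.arange(0.1, 0.71, 0.1), 1))
    svm_tradeoffs: Sequence[float] = tuple(2.0 ** np.arange(-5, 6))
    fusion_weights: Sequence[float] = tuple(np.round(np.arange(0.1, 0.91, 0.1), 1))
    T_grid: Sequence[int] = tuple(range(40, 91, 10))
    S_grid: Sequence[int] = tuple(range(2, 13, 2))
    d_grid: Sequence[int] = tuple(range(1, 8))

    def __post_init__(self) -> None:
        for name in ("p_thresholds", "lambdas", "svm_tradeoffs", "fusion_weights"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"grid {name} must be non-empty")

    @classmethod
    def desk(cls) -> "HyperGrid":
        """Reduced grids sized for a single-CPU desk run."""
        return cls(
            p_thresholds=(0.01, 0.05, 0.1),
            lambdas=(0.1, 0.3, 0.5, 0.7),
            svm_tradeoffs=(0.125, 0.5, 2.0, 8.0),
        )


# ---------------------------------------------------------------------------
# metrics


@dataclass
class Metrics:
    """Confusion counts and the six derived evaluation measures."""

    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    tpr: float
    tnr: float
    ppv: float
    npv: float
    f1: float

    def to_dict(self) -> Dict[str, float]:
        return {
            "ACC": self.acc,
            "TPR": self.tpr,
            "TNR": self.tnr,
            "PPV": self.ppv,
            "NPV": self.npv,
            "F1": self.f1,
            "TP": self.tp,
            "TN": self.tn,
            "FP": self.fp,
            "FN": self.fn,
        }


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator)", MetricsWarning, stacklevel=3)
        return float("nan")
    return num / den


def compute_metrics(predicted, true) -> Metrics:
    """Standard confusion metrics with the patient class (+1) as positive.

    PPV is TP/(TP+FP) and F1 = 2TP/(2TP+FN+FP); ratios with a zero
    denominator are reported as NaN with a warning.
    """
    predicted = np.asarray(predicted).ravel()
    true = np.asarray(true).ravel()
    if predicted.shape != true.shape:
        raise DimensionError("predicted and true label vectors differ in length")
    if predicted.size < 1:
        raise DimensionError("need at least one prediction")
    for v in (predicted, true):
        if not set(np.unique(v)) <= {-1, 1}:
            raise ValueError("labels must be +1/-1")
    tp = int(((predicted == 1) & (true == 1)).sum())
    tn = int(((predicted == -1) & (true == -1)).sum())
    fp = int(((predicted == 1) & (true == -1)).sum())
    fn = int(((predicted == -1) & (true == 1)).sum())
    return Metrics(
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        acc=(tp + tn) / (tp + tn + fp + fn),
        tpr=_ratio(tp, tp + fn, "TPR"),
        tnr=_ratio(tn, fp + tn, "TNR"),
        ppv=_ratio(tp, tp + fp, "PPV"),
        npv=_ratio(tn, fn + tn, "NPV"),
        f1=_ratio(2 * tp, 2 * tp + fn + fp, "F1"),
    )


def fuse_scores(scores, alphas) -> float:
    """Weighted average of per-classifier decision scores.

    The predicted label is +1 if the fused score is strictly positive,
    -1 otherwise (an exact tie predicts the control class).
    """
    scores = np.asarray(scores, dtype=float).ravel()
    alphas = np.asarray(alphas, dtype=float).ravel()
    if scores.shape != alphas.shape:
        raise DimensionError("scores and alphas differ in length")
    if (alphas < 0).any():
        raise ValueError("fusion weights must be nonnegative")
    total = alphas.sum()
    if total == 0:
        raise ValueError("fusion weights must not all be zero")
    return float((alphas @ scores) / total)


def train_linear_svm(
    x: np.ndarray, y: np.ndarray, tradeoff: float = 1.0, tol: float = 1e-3
) -> SVC:
    """Soft-margin linear SVM; ``tradeoff`` is the regularization constant C."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to train an SVM")
    return SVC(kernel="linear", C=tradeoff, tol=tol).fit(x, y)


# ---------------------------------------------------------------------------
# feature extraction


def _as_series_list(x) -> List[np.ndarray]:
    if isinstance(x, Cohort):
        return x.data_list()
    if isinstance(x, np.ndarray) and x.ndim == 3:
        return [x[i] for i in range(x.shape[0])]
    out = [np.asarray(s, dtype=float) for s in x]
    if not out:
        raise DimensionError("empty list of time series")
    n = out[0].shape[1]
    for s in out:
        if s.ndim != 2 or s.shape[1] != n:
            raise DimensionError("all subjects must share the same ROI count")
    return out


def _subject_features(
    data: np.ndarray,
    feature_type: str,
    *,
    lo_window: int,
    lo_step: int,
    lo_order: int,
    ho_window: int,
    ho_step: int,
    ho_order: int,
    normalization: str,
    ho_trim: str,
) -> np.ndarray:
    if feature_type == "static":
        return vectorize(build_cfcn(data)).values
    if feature_type == "lo":
        dyn = build_lo_dfcn(data, lo_window, lo_step)
        return vectorize(moment_matrix(dyn, lo_order, normalization)).values
    if feature_type == "ho":
        lo = build_lo_dfcn(data, ho_window, ho_step)
        dyn = build_ho_dfcn(lo, trim=ho_trim)
        return vectorize(moment_matrix(dyn, ho_order, normalization)).values
    raise ValueError(f"unknown feature type {feature_type!r}")


def extract_feature_tables(
    x,
    *,
    lo_window: int = 60,
    lo_step: int = 2,
    lo_order: int = 4,
    ho_window: int = 40,
    ho_step: int = 12,
    ho_order: int = 2,
    normalization: str = "paper",
    ho_trim: str = "pair_excluded",
    feature_types: Sequence[str] = FEATURE_TYPES,
) -> Dict[str, np.ndarray]:
    """Per-type (n_subjects x N(N-1)/2) feature tables for a cohort.

    Feature extraction uses only one subject's own data, so tables may be
    precomputed once and sliced by cross-validation folds without leakage.
    """
    series = _as_series_list(x)
    kw = dict(
        lo_window=lo_window,
        lo_step=lo_step,
        lo_order=lo_order,
        ho_window=ho_window,
        ho_step=ho_step,
        ho_order=ho_order,
        normalization=normalization,
        ho_trim=ho_trim,
    )
    return {
        t: np.stack([_subject_features(s, t, **kw) for s in series])
        for t in feature_types
    }


# ---------------------------------------------------------------------------
# inner-CV tuning and fitting on feature tables


@dataclass
class _TypeModel:
    scaler: StandardScaler
    selection: object  # SelectionResult
    svm: SVC
    params: Tuple[float, float, float]  # (p_threshold, lam, svm_c)

    def decision_scores(self, table: np.ndarray) -> np.ndarray:
        x = self.scaler.transform(table)[:, self.selection.stage2_mask]
        return self.svm.decision_function(x)


def _fit_tables(
    tables: Dict[str, np.ndarray],
    y: np.ndarray,
    params: Dict[str, Tuple[float, float, float]],
) -> Dict[str, _TypeModel]:
    models: Dict[str, _TypeModel] = {}
    for t, table in tables.items():
        p_thr, lam, svm_c = params[t]
        scaler = StandardScaler().fit(table)
        pv = feature_pvalues(table, y)
        sel = apply_two_stage(scaler.transform(table), y, pv, p_thr, lam)
        svm = SVC(kernel="linear", C=svm_c).fit(
            scaler.transform(table)[:, sel.stage2_mask], y
        )
        models[t] = _TypeModel(scaler=scaler, selection=sel, svm=svm, params=(p_thr, lam, svm_c))
    return models


def _fused_predict(
    models: Dict[str, _TypeModel], tables: Dict[str, np.ndarray], alphas: Dict[str, float]
) -> Tuple[np.ndarray, np.ndarray]:
    keys = list(models)
    a = np.array([alphas[t] for t in keys])
    score_mat = np.stack([models[t].decision_scores(tables[t]) for t in keys])
    fused = (a @ score_mat) / a.sum()
    return np.where(fused > 0, 1, -1), fused


def _tune(
    tables: Dict[str, np.ndarray],
    y: np.ndarray,
    grid: HyperGrid,
    inner_folds: int,
    seed: int,
) -> Tuple[Dict[str, Tuple[float, float, float]], Dict[str, float], float]:
    """Inner-CV grid search; returns per-type params, fusion alphas, inner ACC.

    For each feature type the (p, lambda, C) triple maximizing the inner mean
    single-SVM accuracy is picked (first grid point on ties, in enumeration
    order p -> lambda -> C); the fusion weights are then tuned on the stored
    inner validation scores of the per-type winners.
    """
    types = list(tables)
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed % 2**31)
    splits = list(skf.split(np.zeros(len(y)), y))
    combos = list(itertools.product(grid.p_thresholds, grid.lambdas, grid.svm_tradeoffs))
    best_params: Dict[str, Tuple[float, float, float]] = {}
    best_scores: Dict[str, List[np.ndarray]] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SelectionFallbackWarning)
        for t in types:
            x = tables[t]
            folds = []
            for tr, va in splits:
                scaler = StandardScaler().fit(x[tr])
                folds.append(
                    (tr, va, feature_pvalues(x[tr], y[tr]), scaler.transform(x[tr]), scaler.transform(x[va]))
                )
            accs = np.empty(len(combos))
            cache: List[List[np.ndarray]] = []
            ci = 0
            for p_thr in grid.p_thresholds:
                for lam in grid.lambdas:
                    masks = []
                    for tr, va, pv, xtr, xva in folds:
                        sel = apply_two_stage(xtr, y[tr], pv, p_thr, lam)
                        masks.append(sel.stage2_mask)
                    for svm_c in grid.svm_tradeoffs:
                        fold_scores = []
                        fold_accs = []
                        for (tr, va, pv, xtr, xva), mask in zip(folds, masks):
                            svm = SVC(kernel="linear", C=svm_c).fit(xtr[:, mask], y[tr])
                            sc = svm.decision_function(xva[:, mask])
                            fold_scores.append(sc)
                            fold_accs.append(
                                float((np.where(sc > 0, 1, -1) == y[va]).mean())
                            )
                        accs[ci] = float(np.mean(fold_accs))
                        cache.append(fold_scores)
                        ci += 1
            idx = int(np.argmax(accs))  # first maximum in enumeration order
            best_params[t] = combos[idx]
            best_scores[t] = cache[idx]
    # fusion weights on the stored validation scores of the per-type winners
    if len(types) == 1:
        return best_params, {types[0]: 1.0}, float(np.max(accs))
    alpha_combos = list(itertools.product(grid.fusion_weights, repeat=len(types)))
    y_val = [y[va] for _, va in splits]
    best_alpha, best_acc = None, -1.0
    for alphas in alpha_combos:
        a = np.asarray(alphas, dtype=float)
        fold_accs = []
        for f in range(len(splits)):
            score_mat = np.stack([best_scores[t][f] for t in types])
            fused = (a @ score_mat) / a.sum()
            fold_accs.append(float((np.where(fused > 0, 1, -1) == y_val[f]).mean()))
        acc = float(np.mean(fold_accs))
        if acc > best_acc:  # strict: ties keep the earlier combo
            best_acc, best_alpha = acc, a
    norm = best_alpha / best_alpha.sum()
    return best_params, dict(zip(types, norm.tolist())), best_acc


# ---------------------------------------------------------------------------
# the estimator


class MultiLevelFCClassifier(ClassifierMixin, BaseEstimator):
    """Fused ensemble of linear SVMs over multilevel connectivity features.

    The estimator consumes raw ROI time series (a list of (M, N) arrays or an
    (n_subjects, M, N) array) and internally builds the static network, the
    low-order dynamic network summarized by its order-``lo_order`` central
    moments, and the high-order ("correlation's correlation") dynamic network
    summarized by its order-``ho_order`` moments; each feature block is
    z-scored, filtered by t-test + LASSO, classified by a linear SVM, and the
    decision scores are fused by a weighted average.

    Parameters
    ----------
    lo_window, lo_step, lo_order : sliding-window length/step (volumes) and
        moment order for the low-order dynamic network (defaults 60, 2, 4).
    ho_window, ho_step, ho_order : same for the high-order network
        (defaults 40, 12, 2).
    normalization : {"paper", "standard"}
        Central-moment divisor, K^d or K.
    ho_trim : {"pair_excluded", "full_profile"}
        Whether FC profiles drop the pair's own positions before correlating.
    p_threshold, lam, svm_c : fixed hyperparameters used when ``tune=False``
        (applied to every feature type).
    alphas : fusion weights used when ``tune=False``, one per feature type.
    tune : bool
        If True, tune (p, lambda, C) per type and the fusion weights by an
        inner stratified ``inner_folds``-fold CV over ``grid``.
    grid : HyperGrid or None (defaults to the full published grids).
    random_state : seed for the inner CV shuffling.

    Attributes
    ----------
    classes_ : array([-1, 1])
    models_ : per-type fitted scaler/selection/SVM bundles
    alphas_ : per-type fusion weights (normalized to sum 1)
    tuned_params_ : per-type (p_threshold, lambda, C) actually used
    inner_acc_ : inner-CV fused accuracy of the winning configuration
        (only when ``tune=True``)
    """

    def __init__(
        self,
        lo_window: int = 60,
        lo_step: int = 2,
        lo_order: int = 4,
        ho_window: int = 40,
        ho_step: int = 12,
        ho_order: int = 2,
        normalization: str = "paper",
        ho_trim: str = "pair_excluded",
        p_threshold: float = 0.05,
        lam: float = 0.3,
        svm_c: float = 1.0,
        alphas: Tuple[float, float, float] = (1.0, 1.0, 1.0),
        tune: bool = False,
        grid: HyperGrid | None = None,
        inner_folds: int = 5,
        random_state: int = 0,
    ):
        self.lo_window = lo_window
        self.lo_step = lo_step
        self.lo_order = lo_order
        self.ho_window = ho_window
        self.ho_step = ho_step
        self.ho_order = ho_order
        self.normalization = normalization
        self.ho_trim = ho_trim
        self.p_threshold = p_threshold
        self.lam = lam
        self.svm_c = svm_c
        self.alphas = alphas
        self.tune = tune
        self.grid = grid
        self.inner_folds = inner_folds
        self.random_state = random_state

    def _extract(self, x) -> Dict[str, np.ndarray]:
        return extract_feature_tables(
            x,
            lo_window=self.lo_window,
            lo_step=self.lo_step,
            lo_order=self.lo_order,
            ho_window=self.ho_window,
            ho_step=self.ho_step,
            ho_order=self.ho_order,
            normalization=self.normalization,
            ho_trim=self.ho_trim,
        )

    def fit(self, X, y):
        series = _as_series_list(X)
        y = np.asarray(y).ravel()
        if y.shape[0] != len(series):
            raise DimensionError("labels length does not match number of subjects")
        if not set(np.unique(y)) <= {-1, 1} or len(np.unique(y)) < 2:
            raise ValueError("labels must be +1/-1 with both classes present")
        self.n_roi_ = series[0].shape[1]
        tables = self._extract(series)
        if self.tune:
            grid = self.grid if self.grid is not None else HyperGrid()
            params, alphas, inner_acc = _tune(
                tables, y, grid, self.inner_folds, self.random_state
            )
            self.inner_acc_ = inner_acc
        else:
            params = {t: (self.p_threshold, self.lam, self.svm_c) for t in FEATURE_TYPES}
            a = np.asarray(self.alphas, dtype=float)
            if (a < 0).any() or a.sum() == 0:
                raise ValueError("alphas must be nonnegative and not all zero")
            alphas = dict(zip(FEATURE_TYPES, (a / a.sum()).tolist()))
        self.tuned_params_ = params
        self.alphas_ = alphas
        self.models_ = _fit_tables(tables, y, params)
        self.classes_ = np.array([-1, 1])
        return self

    def decision_function(self, X) -> np.ndarray:
        tables = self._extract(X)
        _, fused = _fused_predict(self.models_, tables, self.alphas_)
        return fused

    def predict(self, X) -> np.ndarray:
        return np.where(self.decision_function(X) > 0, 1, -1)


# ---------------------------------------------------------------------------
# nested cross-validation


@dataclass
class FoldResult:
    repetition: int
    fold: int
    test_indices: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    fused_scores: np.ndarray
    tuned_params: Dict[str, Tuple[float, float, float]]
    alphas: Dict[str, float]
    selected: Dict[str, np.ndarray]  # per-type selected feature indices


@dataclass
class CVResult:
    """Everything produced by one repeated nested-CV run."""

    folds: List[FoldResult]
    metrics_per_rep: List[Metrics]
    aggregate: Dict[str, Dict[str, float]]
    n_roi: int
    outer_folds: int
    inner_folds: int
    repetitions: int
    seed: int
    subject_ids: List[str] | None = None
    config: Dict[str, object] = field(default_factory=dict)

    def to_dict(self) -> Dict[str, object]:
        return {
            "aggregate": self.aggregate,
            "metrics_per_rep": [m.to_dict() for m in self.metrics_per_rep],
            "n_roi": self.n_roi,
            "outer_folds": self.outer_folds,
            "inner_folds": self.inner_folds,
            "repetitions": self.repetitions,
            "seed": self.seed,
            "subject_ids": self.subject_ids,
            "config": self.config,
            "folds": [
                {
                    "repetition": f.repetition,
                    "fold": f.fold,
                    "test_indices": f.test_indices.tolist(),
                    "y_true": f.y_true.tolist(),
                    "y_pred": f.y_pred.tolist(),
                    "fused_scores": f.fused_scores.tolist(),
                    "tuned_params": {t: list(v) for t, v in f.tuned_params.items()},
                    "alphas": f.alphas,
                    "selected": {t: v.tolist() for t, v in f.selected.items()},
                }
                for f in self.folds
            ],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


def _aggregate(metrics_per_rep: List[Metrics]) -> Dict[str, Dict[str, float]]:
    keys = ("ACC", "TPR", "TNR", "PPV", "NPV", "F1")
    table = {k: np.array([m.to_dict()[k] for m in metrics_per_rep]) for k in keys}
    return {
        k: {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=0))}
        for k, v in table.items()
    }


def nested_cv(
    X,
    y=None,
    *,
    grid: HyperGrid | None = None,
    outer_folds: int = 6,
    inner_folds: int = 5,
    repetitions: int = 10,
    seed: int = 0,
    lo_window: int = 60,
    lo_step: int = 2,
    lo_order: int = 4,
    ho_window: int = 40,
    ho_step: int = 12,
    ho_order: int = 2,
    normalization: str = "paper",
    ho_trim: str = "pair_excluded",
    feature_types: Sequence[str] = FEATURE_TYPES,
) -> CVResult:
    """Repeated stratified outer CV with nested inner-CV hyperparameter tuning.

    ``X`` may be a :class:`~dynconn.io.Cohort` (labels taken from it) or a
    list/array of time series with ``y`` given separately.  Repetition ``r``
    uses outer-split seed ``seed + r``; everything downstream is a pure
    function of the inputs and ``seed``.
    """
    subject_ids = None
    if isinstance(X, Cohort):
        subject_ids = [s.subject_id for s in X.subjects]
        y = X.labels()
        series = X.data_list()
    else:
        series = _as_series_list(X)
        if y is None:
            raise ValueError("y is required when X is not a Cohort")
        y = np.asarray(y).ravel()
    n_pos, n_neg = int((y == 1).sum()), int((y == -1).sum())
    if min(n_pos, n_neg) < outer_folds:
        raise ValueError(
            f"stratified {outer_folds}-fold CV needs >= {outer_folds} subjects per "
            f"class, got {n_pos} patients / {n_neg} controls"
        )
    grid = grid if grid is not None else HyperGrid()
    tables = extract_feature_tables(
        series,
        lo_window=lo_window,
        lo_step=lo_step,
        lo_order=lo_order,
        ho_window=ho_window,
        ho_step=ho_step,
        ho_order=ho_order,
        normalization=normalization,
        ho_trim=ho_trim,
        feature_types=feature_types,
    )
    folds: List[FoldResult] = []
    metrics_per_rep: List[Metrics] = []
    for rep in range(repetitions):
        skf = StratifiedKFold(
            n_splits=outer_folds, shuffle=True, random_state=(seed + rep) % 2**31
        )
        rep_true, rep_pred = [], []
        for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
            train_tables = {t: v[tr] for t, v in tables.items()}
            params, alphas, _ = _tune(
                train_tables, y[tr], grid, inner_folds, seed=seed + rep
            )
            models = _fit_tables(train_tables, y[tr], params)
            test_tables = {t: v[te] for t, v in tables.items()}
            pred, fused = _fused_predict(models, test_tables, alphas)
            folds.append(
                FoldResult(
                    repetition=rep,
                    fold=fold,
                    test_indices=te,
                    y_true=y[te],
                    y_pred=pred,
                    fused_scores=fused,
                    tuned_params=params,
                    alphas=alphas,
                    selected={
                        t: m.selection.selected_indices() for t, m in models.items()
                    },
                )
            )
            rep_true.append(y[te])
            rep_pred.append(pred)
        metrics_per_rep.append(
            compute_metrics(np.concatenate(rep_pred), np.concatenate(rep_true))
        )
    return CVResult(
        folds=folds,
        metrics_per_rep=metrics_per_rep,
        aggregate=_aggregate(metrics_per_rep),
        n_roi=series[0].shape[1],
        outer_folds=outer_folds,
        inner_folds=inner_folds,
        repetitions=repetitions,
        seed=seed,
        subject_ids=subject_ids,
        config={
            "lo_window": lo_window,
            "lo_step": lo_step,
            "lo_order": lo_order,
            "ho_window": ho_window,
            "ho_step": ho_step,
            "ho_order": ho_order,
            "normalization": normalization,
            "ho_trim": ho_trim,
            "feature_types": list(feature_types),
        },
    )


def selection_frequency(result: CVResult) -> pd.DataFrame:
    """Per feature type, how often each ROI pair was selected across all
    folds x repetitions (counts bounded by outer_folds x repetitions).

    ROI indices in the report are 1-based; rows are sorted by descending
    count (ties by feature index) and never include never-selected pairs.
    """
    pair_map = make_pair_index(result.n_roi)
    rows = []
    for t in sorted({t for f in result.folds for t in f.selected}):
        counts: Dict[int, int] = {}
        for f in result.folds:
            for idx in f.selected.get(t, ()):
                counts[int(idx)] = counts.get(int(idx), 0) + 1
        for idx, cnt in counts.items():
            i, j = pair_map.pairs[idx]
            rows.append(
                {
                    "feature_type": t,
                    "feature_index": idx,
                    "roi_i": i + 1,
                    "roi_j": j + 1,
                    "count": cnt,
                }
            )
    df = pd.DataFrame(rows, columns=["feature_type", "feature_index", "roi_i", "roi_j", "count"])
    return df.sort_values(
        ["feature_type", "count", "feature_index"], ascending=[True, False, True]
    ).reset_index(drop=True)


def sweep_params(
    X,
    y=None,
    *,
    level: str = "lo",
    T_grid: Sequence[int] | None = None,
    S_grid: Sequence[int] | None = None,
    d_grid: Sequence[int] | None = None,
    grid: HyperGrid | None = None,
    outer_folds: int = 6,
    inner_folds: int = 5,
    repetitions: int = 1,
    seed: int = 0,
    normalization: str = "paper",
    ho_trim: str = "pair_excluded",
) -> pd.DataFrame:
    """Mean nested-CV accuracy of a single network level over a (T, S, d) grid.

    Runs one single-type nested CV per parameter combination; combinations
    whose window length exceeds a subject's series length are skipped.
    """
    if level not in ("lo", "ho"):
        raise ValueError("level must be 'lo' or 'ho'")
    grid = grid if grid is not None else HyperGrid()
    T_grid = T_grid if T_grid is not None else grid.T_grid
    S_grid = S_grid if S_grid is not None else grid.S_grid
    d_grid = d_grid if d_grid is not None else grid.d_grid
    if isinstance(X, Cohort):
        y = X.labels()
        series = X.data_list()
    else:
        series = _as_series_list(X)
        y = np.asarray(y).ravel()
    m_min = min(s.shape[0] for s in series)
    rows = []
    for t_len, step, order in itertools.product(T_grid, S_grid, d_grid):
        if t_len > m_min:
            continue
        kw = dict(lo_window=t_len, lo_step=step, lo_order=order)
        if level == "ho":
            kw = dict(ho_window=t_len, ho_step=step, ho_order=order)
        res = nested_cv(
            series,
            y,
            grid=grid,
            outer_folds=outer_folds,
            inner_folds=inner_folds,
            repetitions=repetitions,
            seed=seed,
            normalization=normalization,
            ho_trim=ho_trim,
            feature_types=(level,),
            **kw,
        )
        rows.append(
            {
                "level": level,
                "T": t_len,
                "S": step,
                "d": order,
                "acc_mean": res.aggregate["ACC"]["mean"],
                "acc_sd": res.aggregate["ACC"]["sd"],
            }
        )
    return pd.DataFrame(rows, columns=["level", "T", "S", "d", "acc_mean", "acc_sd"])
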