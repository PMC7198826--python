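"""Two-stage discriminative feature selection: t-test filter, then LASSO.

Stage 1 keeps every feature whose two-sided pooled-variance two-sample
t-test between the two diagnostic groups has p below a threshold.  Stage 2
fits a LASSO regression of the +/-1 labels on the z-scored surviving
features,

    min_w  (1/2L) * sum_l (I(l) - <y(l), w>)^2  +  lambda * ||w||_1,

and keeps the features with nonzero coefficients (|w| > 1e-8).  The t-test
screens features marginally; the LASSO then prunes jointly, discounting
correlated survivors.  Both stages are fitted strictly on training subjects.

Degenerate paths are kept total so nested cross-validation never aborts: an
empty stage 1 falls back to the 10 smallest-p features, and an all-zero
LASSO falls back to the 10 smallest-p stage-1 features; both emit a
:class:`~dynconn.errors.SelectionFallbackWarning`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import Lasso, LinearRegression
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted, validate_data

from .errors import DimensionError, SelectionFallbackWarning

__all__ = [
    "SelectionResult",
    "feature_pvalues",
    "ttest_filter",
    "lasso_select",
    "two_stage_select",
    "TwoStageSelector",
]

NONZERO_TOL = 1e-8
FALLBACK_K = 10


@dataclass
class SelectionResult:
    """Masks and weights produced by the two-stage selection."""

    stage1_mask: np.ndarray
    stage2_mask: np.ndarray
    weights: np.ndarray  # full length P; zero outside stage 1
    pvalues: np.ndarray
    p_threshold: float
    lam: float

    @property
    def n_selected(self) -> int:
        return int(self.stage2_mask.sum())

    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.stage2_mask)


def _check_xy(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y).ravel()
    if x.ndim != 2:
        raise DimensionError("feature table must be 2-D (subjects x features)")
    if y.shape[0] != x.shape[0]:
        raise DimensionError("labels length does not match feature table")
    if not set(np.unique(y)) <= {-1, 1}:
        raise ValueError("labels must be +1/-1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if (y == 1).sum() < 2 or (y == -1).sum() < 2:
        raise ValueError("each class needs at least 2 subjects for the t-test")
    return x, y


def feature_pvalues(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided pooled-variance two-sample t-test p-value per feature.

    Features with zero variance in both groups give NaN (never selected).
    """
    x, y = _check_xy(x, y)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant features legitimately yield NaN here; silence scipy's
        # catastrophic-cancellation notice for them
        warnings.filterwarnings("ignore", message=".*catastrophic cancellation.*")
        res = stats.ttest_ind(x[y == 1], x[y == -1], axis=0, equal_var=True)
    return np.asarray(res.pvalue, dtype=float)


def ttest_filter(x: np.ndarray, y: np.ndarray, p_threshold: float) -> np.ndarray:
    """Stage-1 mask: p < p_threshold (NaN p-values are always excluded)."""
    pv = feature_pvalues(x, y)
    with np.errstate(invalid="ignore"):
        return pv < p_threshold


def lasso_select(
    x1: np.ndarray, y: np.ndarray, lam: float
) -> tuple[np.ndarray, np.ndarray]:
    """LASSO coefficients and nonzero mask on (z-scored) stage-1 features.

    ``lam`` is on the per-subject scale: the objective is
    (1/2L)||I - X w||^2 + lam ||w||_1 with an unpenalized intercept, so all
    weights vanish for lam >= max_j |<x_j, I - mean(I)>| / L.  ``lam=0`` is
    the ordinary least-squares limit.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    x1 = np.asarray(x1, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if lam == 0:
        coef = LinearRegression().fit(x1, y).coef_
    else:
        model = Lasso(alpha=lam, fit_intercept=True, tol=1e-6, max_iter=10_000)
        model.fit(x1, y)
        coef = model.coef_
    coef = np.asarray(coef, dtype=float)
    return coef, np.abs(coef) > NONZERO_TOL


def _fallback_smallest_p(pvalues: np.ndarray, within: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of the k smallest-p features among ``within`` (NaN last)."""
    idx = np.flatnonzero(within)
    order = idx[np.argsort(pvalues[idx], kind="stable")]  # NaN sorts last
    mask = np.zeros(pvalues.size, dtype=bool)
    mask[order[: min(k, order.size)]] = True
    return mask


def apply_two_stage(
    x_scaled: np.ndarray,
    y: np.ndarray,
    pvalues: np.ndarray,
    p_threshold: float,
    lam: float,
) -> SelectionResult:
    """Run both stages given precomputed p-values and z-scored features.

    Shared by :class:`TwoStageSelector` and the nested-CV tuner so that the
    tuner's grid search and the final refit select identically.
    """
    with np.errstate(invalid="ignore"):
        stage1 = pvalues < p_threshold
    if not stage1.any():
        warnings.warn(
            f"no feature passed the t-test at p<{p_threshold}; "
            f"falling back to the {FALLBACK_K} smallest p-values",
            SelectionFallbackWarning,
            stacklevel=2,
        )
        stage1 = _fallback_smallest_p(pvalues, np.ones_like(stage1), FALLBACK_K)
    coef, nz = lasso_select(x_scaled[:, stage1], y, lam)
    weights = np.zeros(x_scaled.shape[1])
    weights[stage1] = coef
    stage2 = np.zeros_like(stage1)
    stage2[np.flatnonzero(stage1)[nz]] = True
    if not stage2.any():
        warnings.warn(
            "LASSO zeroed every stage-1 feature; "
            f"falling back to the {FALLBACK_K} smallest p-values within stage 1",
            SelectionFallbackWarning,
            stacklevel=2,
        )
        stage2 = _fallback_smallest_p(pvalues, stage1, FALLBACK_K)
    return SelectionResult(
        stage1_mask=stage1,
        stage2_mask=stage2,
        weights=weights,
        pvalues=pvalues,
        p_threshold=p_threshold,
        lam=lam,
    )


def two_stage_select(
    x: np.ndarray, y: np.ndarray, p_threshold: float, lam: float
) -> SelectionResult:
    """t-test filter then LASSO on a raw feature table (z-scored internally)."""
    x, y = _check_xy(x, y)
    pv = feature_pvalues(x, y)
    x_scaled = StandardScaler().fit_transform(x)
    return apply_two_stage(x_scaled, y, pv, p_threshold, lam)


class TwoStageSelector(SelectorMixin, BaseEstimator):
    """scikit-learn transformer wrapping the two-stage selection.

    Parameters
    ----------
    p_threshold : float, default 0.05
        Stage-1 two-sample t-test p-value cutoff.
    lam : float, default 0.3
        Stage-2 LASSO penalty (per-subject scale; larger is sparser).

    The t-test is scale-invariant and the LASSO stage standardizes features
    internally with training statistics, so the selector may be fed raw or
    pre-scaled features; ``transform`` returns the original columns.
    """

    def __init__(self, p_threshold: float = 0.05, lam: float = 0.3):
        self.p_threshold = p_threshold
        self.lam = lam

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        X, y = _check_xy(X, y)
        pv = feature_pvalues(X, y)
        x_scaled = StandardScaler().fit_transform(X)
        result = apply_two_stage(x_scaled, y, pv, self.p_threshold, self.lam)
        self.result_ = result
        self.pvalues_ = result.pvalues
        self.stage1_mask_ = result.stage1_mask
        self.stage2_mask_ = result.stage2_mask
        self.weights_ = result.weights
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "stage2_mask_")
        return self.stage2_mask_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags
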