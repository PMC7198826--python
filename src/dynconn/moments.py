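"""Temporal-order-invariant central-moment summaries of dynamic networks.

A dynamic network gives, for each ROI pair (i, j), a length-K series of
windowed connectivity values.  Because resting-state windows carry no
temporal correspondence across subjects, the series is summarized by its
central moments, which depend only on the multiset of values:

    m_ij(d) = sum_k (rho_ij(k) - mean)^d / K^d     ("paper" normalization)
    m_ij(d) = sum_k (rho_ij(k) - mean)^d / K       ("standard" normalization)

with the order-1 moment replaced by the arithmetic mean (the raw first
central moment is identically zero).  The ``paper`` divisor K^d is the
default; ``standard`` is the conventional d-th central moment.

Implementation note: each pair series is sorted before accumulation, so the
computed moment is *bitwise* identical under any permutation or reversal of
the windows, not merely equal in exact arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, SymmetryError
from .io import PairIndexMap, make_pair_index
from .networks import ConnMatrix, DynNet

__all__ = [
    "MomentMatrix",
    "FeatureVector",
    "pair_series",
    "central_moment",
    "moment_matrix",
    "vectorize",
    "devectorize",
]

NORMALIZATIONS = ("paper", "standard")


@dataclass
class MomentMatrix:
    """NxN symmetric matrix of per-pair central moments of order ``order``."""

    values: np.ndarray
    order: int
    source_kind: str
    normalization: str

    @property
    def n_roi(self) -> int:
        return self.values.shape[0]


@dataclass
class FeatureVector:
    """Lower-triangle vectorization of a symmetric matrix, with provenance."""

    values: np.ndarray
    pair_map: PairIndexMap
    provenance: tuple

    def __len__(self) -> int:
        return len(self.values)


def pair_series(dyn: DynNet, i: int, j: int) -> np.ndarray:
    """The (i, j) entry of every window matrix, in window order."""
    if i == j:
        raise ValueError("pair series is defined for distinct ROIs only")
    return dyn.windows[:, i, j].copy()


def _check_norm(normalization: str) -> None:
    if normalization not in NORMALIZATIONS:
        raise ValueError(f"normalization must be one of {NORMALIZATIONS}")


def central_moment(seq, d: int, normalization: str = "paper") -> float:
    """d-th central moment of a sequence; d=1 returns the plain mean."""
    _check_norm(normalization)
    seq = np.asarray(seq, dtype=float).ravel()
    if seq.size == 0:
        raise DimensionError("central_moment of an empty sequence")
    if d < 1:
        raise ValueError("moment order d must be >= 1")
    s = np.sort(seq)  # order-invariant accumulation
    k = s.size
    mean = float(s.mean())
    if d == 1:
        return mean
    total = float(((s - mean) ** d).sum())
    divisor = float(k) ** d if normalization == "paper" else float(k)
    return total / divisor


def moment_matrix(dyn: DynNet, d: int, normalization: str = "paper") -> MomentMatrix:
    """Central-moment matrix of a dynamic network (entrywise over ROI pairs).

    The diagonal (constant unit series) comes out as 1 for d=1 and 0 for
    d>=2; it never enters the feature vector, which excludes the diagonal.
    """
    _check_norm(normalization)
    if d < 1:
        raise ValueError("moment order d must be >= 1")
    w = np.sort(dyn.windows, axis=0)  # same order-invariant trick, vectorized
    k = w.shape[0]
    mean = w.mean(axis=0)
    if d == 1:
        vals = mean
    else:
        divisor = float(k) ** d if normalization == "paper" else float(k)
        vals = ((w - mean) ** d).sum(axis=0) / divisor
    return MomentMatrix(
        values=vals, order=d, source_kind=dyn.kind, normalization=normalization
    )


def _matrix_values(m) -> np.ndarray:
    return np.asarray(getattr(m, "values", m), dtype=float)


def vectorize(m, pair_map: PairIndexMap | None = None) -> FeatureVector:
    """Vectorize the strictly lower triangle of a symmetric matrix.

    The order follows :func:`dynconn.io.make_pair_index`; length N(N-1)/2.
    """
    vals = _matrix_values(m)
    if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
        raise DimensionError("vectorize expects a square matrix")
    if not np.allclose(vals, vals.T, atol=1e-10, rtol=0):
        raise SymmetryError("vectorize expects a symmetric matrix")
    n = vals.shape[0]
    if pair_map is None:
        pair_map = make_pair_index(n)
    elif pair_map.n_roi != n:
        raise DimensionError("pair map does not match matrix size")
    rows, cols = np.tril_indices(n, k=-1)
    provenance = (
        getattr(m, "source_kind", getattr(m, "kind", "matrix")),
        getattr(m, "order", None),
    )
    return FeatureVector(values=vals[rows, cols], pair_map=pair_map, provenance=provenance)


def devectorize(vec, n_roi: int, diagonal: float = 1.0) -> np.ndarray:
    """Inverse of :func:`vectorize` up to the (excluded) diagonal."""
    values = np.asarray(getattr(vec, "values", vec), dtype=float).ravel()
    expected = n_roi * (n_roi - 1) // 2
    if values.size != expected:
        raise DimensionError(
            f"vector length {values.size} does not match N(N-1)/2 = {expected}"
        )
    out = np.full((n_roi, n_roi), diagonal, dtype=float)
    rows, cols = np.tril_indices(n_roi, k=-1)
    out[rows, cols] = values
    out[cols, rows] = values
    return out
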