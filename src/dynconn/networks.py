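"""Construction of the three functional-connectivity network levels.

* static C-FCN: full-scan Pearson correlation between each ROI pair;
* low-order dynamic FCN (Lo-D-FCN): the ordered series of windowed
  correlation matrices from a sliding window of length T and step S;
* high-order dynamic FCN (Ho-D-FCN): per window, the "correlation's
  correlation" — the Pearson correlation between two ROIs' short-time FC
  profiles (their rows of the windowed correlation matrix).

Windows are rectangular (no taper, no within-window detrending) and the
trailing volumes not covered by a full window are discarded, so the window
count is K = floor((M - T)/S) + 1.  No Fisher z-transform is applied at any
level.  Zero-variance signals yield correlation 0 with a
:class:`~dynconn.errors.DegenerateCorrelationWarning` instead of NaN, which
keeps every matrix total for the moment summaries downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateCorrelationWarning, DimensionError
from .io import SubjectTimeSeries

__all__ = [
    "ConnMatrix",
    "DynNet",
    "pearson",
    "build_cfcn",
    "sliding_windows",
    "build_lo_dfcn",
    "build_ho_dfcn",
]


@dataclass
class ConnMatrix:
    """An NxN symmetric connectivity matrix with unit diagonal."""

    values: np.ndarray
    kind: str = "static"  # static | lo_window | ho_window
    window_index: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise DimensionError("connectivity matrix must be square")

    @property
    def n_roi(self) -> int:
        return self.values.shape[0]


@dataclass
class DynNet:
    """An ordered series of K connectivity matrices sharing ROI indexing.

    ``windows`` is a (K, N, N) array; ``window_length``/``step``/``n_volumes``
    record the sliding-window specification that produced it.
    """

    windows: np.ndarray
    kind: str  # lo_window | ho_window
    window_length: int
    step: int
    n_volumes: int

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        if self.windows.ndim != 3 or self.windows.shape[1] != self.windows.shape[2]:
            raise DimensionError("DynNet windows must be a (K, N, N) array")
        expected = (self.n_volumes - self.window_length) // self.step + 1
        if self.windows.shape[0] != expected:
            raise DimensionError(
                f"window count {self.windows.shape[0]} violates "
                f"K = floor((M-T)/S)+1 = {expected}"
            )

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_roi(self) -> int:
        return self.windows.shape[1]

    def __len__(self) -> int:
        return self.n_windows

    def __getitem__(self, k: int) -> ConnMatrix:
        return ConnMatrix(self.windows[k], kind=self.kind, window_index=k)


def pearson(x, y) -> float:
    """Sample Pearson correlation of two equal-length sequences.

    If either sequence has zero variance the correlation is undefined; this
    returns 0.0 and warns rather than propagating NaN.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise DimensionError("pearson: length mismatch")
    if x.size < 2:
        raise DimensionError("pearson: need at least 2 samples")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = float(np.sqrt(xd @ xd))
    sy = float(np.sqrt(yd @ yd))
    if sx == 0.0 or sy == 0.0:
        warnings.warn(
            "zero-variance input to pearson; returning 0",
            DegenerateCorrelationWarning,
            stacklevel=2,
        )
        return 0.0
    return float(np.clip((xd @ yd) / (sx * sy), -1.0, 1.0))


def _corr_columns(data: np.ndarray) -> np.ndarray:
    """Column-wise correlation matrix with the degenerate-to-zero rule."""
    data = np.asarray(data, dtype=float)
    m = data.shape[0]
    if m < 2:
        raise DimensionError("need at least 2 time points for correlation")
    centered = data - data.mean(axis=0)
    norms = np.sqrt(np.einsum("ij,ij->j", centered, centered))
    degenerate = norms == 0.0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance signal(s); correlations set to 0",
            DegenerateCorrelationWarning,
            stacklevel=3,
        )
    safe = np.where(degenerate, 1.0, norms)
    z = centered / safe
    corr = np.clip(z.T @ z, -1.0, 1.0)
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return corr


def _as_data(ts) -> np.ndarray:
    if isinstance(ts, SubjectTimeSeries):
        return ts.data
    return np.asarray(ts, dtype=float)


def build_cfcn(ts) -> ConnMatrix:
    """Static C-FCN: full-length Pearson correlation between all ROI pairs."""
    data = _as_data(ts)
    if data.ndim != 2:
        raise DimensionError("time series must be a 2-D matrix")
    return ConnMatrix(_corr_columns(data), kind="static")


def sliding_windows(m: int, t: int, s: int) -> list[tuple[int, int]]:
    """Half-open volume ranges [kS, kS+T) for k = 0..K-1, K = floor((M-T)/S)+1."""
    if t < 2:
        raise DimensionError("window length T must be >= 2")
    if t > m:
        raise DimensionError(f"window length T={t} exceeds series length M={m}")
    if s < 1:
        raise DimensionError("step S must be >= 1")
    k = (m - t) // s + 1
    return [(i * s, i * s + t) for i in range(k)]


def build_lo_dfcn(ts, window_length: int, step: int) -> DynNet:
    """Lo-D-FCN: windowed correlation matrices over the sliding-window grid."""
    data = _as_data(ts)
    m = data.shape[0]
    spans = sliding_windows(m, window_length, step)
    windows = np.stack([_corr_columns(data[a:b]) for a, b in spans])
    return DynNet(
        windows, kind="lo_window", window_length=window_length, step=step, n_volumes=m
    )


def _ho_window(c: np.ndarray, trim: str) -> np.ndarray:
    n = c.shape[0]
    if trim == "full_profile":
        return _corr_columns(c.T)  # rows of c as variables
    out = np.eye(n)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        for j in range(i):
            keep[i] = keep[j] = False
            out[i, j] = out[j, i] = pearson(c[i, keep], c[j, keep])
            keep[i] = keep[j] = True
    return out


def build_ho_dfcn(lo: DynNet, trim: str = "pair_excluded") -> DynNet:
    """Ho-D-FCN from a Lo-D-FCN via the correlation's-correlation principle.

    For window k and ROI pair (i, j), the entry is the Pearson correlation of
    the two short-time FC profiles (rows i and j of the windowed correlation
    matrix).  With ``trim="pair_excluded"`` (default) positions i and j are
    removed from both profiles before correlating, since the untrimmed
    profiles contain the unit self-correlations and the duplicated (i, j)
    entry, which mechanically inflate the correlation.  ``trim="full_profile"``
    keeps the complete rows.
    """
    if trim not in ("pair_excluded", "full_profile"):
        raise ValueError(f"unknown trim mode {trim!r}")
    if lo.kind != "lo_window":
        raise ValueError("build_ho_dfcn expects a lo_window DynNet")
    n = lo.n_roi
    if n < 3:
        raise DimensionError("high-order construction needs at least 3 ROIs")
    if trim == "pair_excluded" and n < 4:
        raise DimensionError(
            "pair-excluded profiles need at least 4 ROIs (trimmed length >= 2)"
        )
    windows = np.stack([_ho_window(lo.windows[k], trim) for k in range(lo.n_windows)])
    return DynNet(
        windows,
        kind="ho_window",
        window_length=lo.window_length,
        step=lo.step,
        n_volumes=lo.n_volumes,
    )
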