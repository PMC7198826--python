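"""Synthetic cohorts with group-dependent dynamic connectivity.

The generator is a Markov state-switching multivariate normal: each subject
carries a hidden connectivity-state sequence drawn from a per-group Markov
chain, and each time volume is a zero-mean Gaussian draw with the active
state's covariance plus isotropic observation noise.  This is the simplest
process with separately controllable

* static connectivity means (through the state covariances and the group's
  stationary state occupancy),
* dynamic-connectivity fluctuation variance (through dwell times / switching
  rates), and
* fluctuation asymmetry (through asymmetric state occupancy: a group that
  mostly sits in one state with brief excursions has a skewed windowed-
  correlation distribution).

Default study conditions: 45 patients vs 47 controls, N=16 ROIs, M=170
volumes, two block-structured connectivity states differing by a single-ROI
block swap, controls dwelling mostly in state 0 (stationary occupancy 5/6)
while patients alternate evenly between states.  The pairs whose state
correlation changes across states are the injected "effect" pairs; they
differ between groups in windowed-correlation mean, variance and skewness.

Everything is a pure function of :class:`SimParams` including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .io import Cohort, SubjectTimeSeries

__all__ = [
    "SimParams",
    "SimTruth",
    "make_block_states",
    "default_transitions",
    "null_transitions",
    "stationary_distribution",
    "simulate_subject",
    "generate_cohort",
    "mixture_correlation",
]

PATIENT, CONTROL = 1, -1


def make_block_states(
    n_roi: int,
    n_states: int,
    within_r: float,
    seed: int,
    jitter: float = 0.02,
) -> List[np.ndarray]:
    """Block-structured SPD correlation matrices, one per hidden state.

    State 0 splits the ROIs into two equal blocks with correlation
    ``within_r`` inside a block and 0 across blocks (unit variances).  Each
    subsequent state swaps a small set of ROIs between the blocks, so a
    handful of pairs change correlation between states while the rest stay
    put.  A small symmetric jitter is added and the result is projected back
    to the nearest positive-definite matrix with unit diagonal.
    """
    if n_roi < 3:
        raise ValueError("need at least 3 ROIs")
    if n_states < 1:
        raise ValueError("need at least 1 state")
    if not (0.0 <= within_r < 1.0):
        raise ValueError("within_r must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    half = n_roi // 2
    n_swap = max(1, n_roi // 16)
    states: List[np.ndarray] = []
    for s in range(n_states):
        block = np.zeros(n_roi, dtype=int)
        block[half:] = 1
        if s > 0:
            lo = np.arange((s - 1) * n_swap, s * n_swap) % half
            hi = half + lo
            block[lo], block[hi] = block[hi].copy(), block[lo].copy()
        cov = np.where(block[:, None] == block[None, :], within_r, 0.0)
        np.fill_diagonal(cov, 1.0)
        noise = rng.normal(0.0, jitter, size=(n_roi, n_roi))
        noise = (noise + noise.T) / 2.0
        np.fill_diagonal(noise, 0.0)
        states.append(_nearest_spd_correlation(cov + noise))
    return states


def _nearest_spd_correlation(a: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Clip eigenvalues at ``floor`` and rescale to unit diagonal."""
    vals, vecs = np.linalg.eigh((a + a.T) / 2.0)
    spd = (vecs * np.maximum(vals, floor)) @ vecs.T
    d = np.sqrt(np.diag(spd))
    spd = spd / np.outer(d, d)
    return (spd + spd.T) / 2.0


def default_transitions(n_states: int) -> Dict[int, np.ndarray]:
    """Per-group Markov chains of the default study conditions.

    Controls dwell in state 0 (stay 0.97; from any excursion state, return
    with 0.15 per step), giving stationary occupancy 5/6 in state 0 for two
    states.  Patients switch symmetrically (stay 0.88), giving uniform
    occupancy and roughly twice the switching rate.
    """
    if n_states == 1:
        one = np.ones((1, 1))
        return {PATIENT: one, CONTROL: one.copy()}
    k = n_states
    ctrl = np.zeros((k, k))
    ctrl[0, 0] = 0.97
    ctrl[0, 1:] = 0.03 / (k - 1)
    for s in range(1, k):
        ctrl[s, 0] = 0.15
        ctrl[s, s] = 0.85
    pat = np.full((k, k), 0.12 / (k - 1))
    np.fill_diagonal(pat, 0.88)
    return {PATIENT: pat, CONTROL: ctrl}


def null_transitions(n_states: int) -> Dict[int, np.ndarray]:
    """Identical chains for both groups: no injected group difference."""
    base = default_transitions(n_states)[CONTROL]
    return {PATIENT: base.copy(), CONTROL: base.copy()}


@dataclass
class SimParams:
    """Generator parameters; the defaults are the package's study conditions."""

    n_patients: int = 45
    n_controls: int = 47
    n_roi: int = 16
    n_volumes: int = 170
    n_states: int = 2
    within_r: float = 0.6
    state_cov: List[np.ndarray] | None = None
    transitions: Dict[int, np.ndarray] | None = None
    noise_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.state_cov is None:
            self.state_cov = make_block_states(
                self.n_roi, self.n_states, self.within_r, seed=self.seed
            )
        if self.transitions is None:
            self.transitions = default_transitions(self.n_states)
        if len(self.state_cov) != self.n_states:
            raise ValueError("state_cov length must equal n_states")
        for cov in self.state_cov:
            cov = np.asarray(cov, dtype=float)
            if cov.shape != (self.n_roi, self.n_roi):
                raise ValueError("state covariance has wrong shape")
            if not np.allclose(cov, cov.T, atol=1e-12):
                raise ValueError("state covariance must be symmetric")
            try:
                np.linalg.cholesky(cov)
            except np.linalg.LinAlgError as exc:
                raise ValueError("state covariance must be positive definite") from exc
        for group in (PATIENT, CONTROL):
            p = np.asarray(self.transitions[group], dtype=float)
            if p.shape != (self.n_states, self.n_states):
                raise ValueError("transition matrix has wrong shape")
            if (p < 0).any() or not np.allclose(p.sum(axis=1), 1.0, atol=1e-12):
                raise ValueError("transition rows must be nonnegative and sum to 1")


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort.

    ``effect_pairs`` are the ROI pairs whose state correlation differs across
    hidden states (hence across groups, through occupancy);
    ``expected_static_corr`` maps each group label to the exact population
    full-scan correlation matrix under stationarity (mixture covariance plus
    observation noise), an oracle for the static network of a long scan.
    """

    state_sequences: Dict[str, np.ndarray] = field(default_factory=dict)
    effect_pairs: List[Tuple[int, int]] = field(default_factory=list)
    expected_static_corr: Dict[int, np.ndarray] = field(default_factory=dict)
    occupancy: Dict[int, np.ndarray] = field(default_factory=dict)


def stationary_distribution(p: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix."""
    p = np.asarray(p, dtype=float)
    vals, vecs = np.linalg.eig(p.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def mixture_correlation(params: SimParams, group: int) -> np.ndarray:
    """Population correlation of the stationary state mixture plus noise."""
    pi = stationary_distribution(params.transitions[group])
    cov = sum(w * np.asarray(c) for w, c in zip(pi, params.state_cov))
    cov = cov + params.noise_sd**2 * np.eye(params.n_roi)
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def _effect_pairs(state_cov: List[np.ndarray], min_delta: float = 0.3):
    n = state_cov[0].shape[0]
    stack = np.stack(state_cov)
    delta = stack.max(axis=0) - stack.min(axis=0)
    pairs = [(i, j) for i in range(n) for j in range(i) if delta[i, j] > min_delta]
    return pairs


def simulate_subject(
    params: SimParams, group: int, rng: np.random.Generator, subject_id: str = "sub"
) -> Tuple[SubjectTimeSeries, np.ndarray]:
    """Draw one subject: hidden Markov states, then per-volume Gaussian data.

    Returns the subject and its hidden state sequence (length M).
    """
    if group not in (PATIENT, CONTROL):
        raise ValueError("group must be +1 (patient) or -1 (control)")
    p = np.asarray(params.transitions[group], dtype=float)
    pi = stationary_distribution(p)
    m, n, k = params.n_volumes, params.n_roi, params.n_states
    states = np.empty(m, dtype=int)
    states[0] = rng.choice(k, p=pi)
    for t in range(1, m):
        states[t] = rng.choice(k, p=p[states[t - 1]])
    chols = [np.linalg.cholesky(np.asarray(c)) for c in params.state_cov]
    z = rng.standard_normal(size=(m, n))
    data = np.empty((m, n))
    for s in range(k):
        mask = states == s
        if mask.any():
            data[mask] = z[mask] @ chols[s].T
    if params.noise_sd > 0:
        data = data + params.noise_sd * rng.standard_normal(size=(m, n))
    return SubjectTimeSeries(subject_id=subject_id, data=data, label=group), states


def generate_cohort(params: SimParams) -> Tuple[Cohort, SimTruth]:
    """Generate the full labeled cohort (patients first, then controls).

    Per-subject RNG streams are spawned from the master seed, so cohorts are
    bit-reproducible and subjects are independent.
    """
    n_total = params.n_patients + params.n_controls
    streams = np.random.SeedSequence(params.seed).spawn(n_total)
    truth = SimTruth(
        effect_pairs=_effect_pairs(params.state_cov),
        expected_static_corr={
            g: mixture_correlation(params, g) for g in (PATIENT, CONTROL)
        },
        occupancy={
            g: stationary_distribution(params.transitions[g])
            for g in (PATIENT, CONTROL)
        },
    )
    subjects = []
    width = len(str(n_total))
    for idx in range(n_total):
        group = PATIENT if idx < params.n_patients else CONTROL
        sid = f"sub-{idx + 1:0{width}d}"
        ts, states = simulate_subject(
            params, group, np.random.default_rng(streams[idx]), subject_id=sid
        )
        truth.state_sequences[sid] = states
        subjects.append(ts)
    return Cohort(subjects=subjects), truth
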