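"""Structure-level Markov state model utilities.

A Markov state model (MSM) is a row-stochastic transition matrix T_ij over
conformational states together with its stationary (equilibrium)
distribution p.  This module provides chain simulation, transition counting,
marginalization of a (structure, orientation) state-level matrix down to
structures, a detailed-balance (reversibility) projection by flux
symmetrization, and the relative entropy

    D(T || T_est) = Σ_i Σ_j p(i) T_ij log( T_ij / (T_ij_est + eps) )

used to score reconstructed models against a ground truth, with a small
uniform floor eps = 1e-10 on the estimate to avoid division by zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

__all__ = [
    "MarkovStateModel",
    "equilibrium_distribution",
    "simulate_chain",
    "estimate_from_sequences",
    "marginalize_to_structures",
    "enforce_detailed_balance",
    "relative_entropy",
]

logger = logging.getLogger(__name__)


def _check_row_stochastic(T: np.ndarray) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(T < 0):
        raise ValueError("transition probabilities must be non-negative")
    if np.max(np.abs(T.sum(axis=1) - 1.0)) > 1e-8:
        raise ValueError("transition matrix rows must sum to 1")
    return T


def _strong_components(T: np.ndarray):
    n, labels = connected_components(csr_matrix(T > 0), directed=True,
                                     connection="strong")
    return n, labels


def equilibrium_distribution(T: np.ndarray) -> np.ndarray:
    """Stationary left eigenvector of an irreducible row-stochastic matrix.

    Solves p T = p, Σp = 1 as a linear system; raises on reducible input
    (e.g. the identity matrix), naming the disconnected blocks.
    """
    T = _check_row_stochastic(T)
    n_comp, labels = _strong_components(T)
    if n_comp > 1:
        blocks = [list(np.flatnonzero(labels == k)) for k in range(n_comp)]
        raise ValueError(f"transition matrix is reducible; strongly connected "
                         f"blocks: {blocks}")
    n = T.shape[0]
    a = T.T - np.eye(n)
    a[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    p = np.linalg.solve(a, b)
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    return p


@dataclass(frozen=True)
class MarkovStateModel:
    """Row-stochastic transition matrix with its equilibrium distribution."""

    transition: np.ndarray
    equilibrium: np.ndarray | None = None

    def __post_init__(self):
        T = _check_row_stochastic(self.transition)
        p = self.equilibrium
        if p is None:
            p = equilibrium_distribution(T)
        else:
            p = np.asarray(p, dtype=float)
            if p.shape != (T.shape[0],):
                raise ValueError("equilibrium length must match matrix size")
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
                raise ValueError("equilibrium must be a probability vector")
            if np.max(np.abs(p @ T - p)) > 1e-6:
                raise ValueError("equilibrium is not stationary for the matrix")
        object.__setattr__(self, "transition", T)
        object.__setattr__(self, "equilibrium", p)

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]


def simulate_chain(msm: MarkovStateModel, n_steps: int, seed) -> np.ndarray:
    """Sample a state sequence: s₁ ~ p (equilibrium), s_{t+1} ~ T[s_t, ·]."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    n = msm.n_states
    seq = np.empty(n_steps, dtype=int)
    seq[0] = rng.choice(n, p=msm.equilibrium)
    cum = np.cumsum(msm.transition, axis=1)
    draws = rng.random(n_steps - 1)
    for t in range(1, n_steps):
        seq[t] = int(np.searchsorted(cum[seq[t - 1]], draws[t - 1], side="right"))
    return seq


def estimate_from_sequences(sequences, n_states: int) -> MarkovStateModel:
    """Row-normalized transition counts from one or more state sequences.

    States never left (no outgoing transitions observed) get a self-loop row
    with a logged warning; the equilibrium is the stationary vector obtained
    by power iteration (well defined even if the count matrix is reducible).
    """
    if np.ndim(sequences[0]) == 0:
        sequences = [sequences]
    counts = np.zeros((n_states, n_states))
    for seq in sequences:
        seq = np.asarray(seq, dtype=int)
        if np.any(seq < 0) or np.any(seq >= n_states):
            raise ValueError("state label out of range")
        np.add.at(counts, (seq[:-1], seq[1:]), 1.0)
    rowsum = counts.sum(axis=1)
    empty = rowsum == 0
    if empty.any():
        logger.warning("state(s) %s have no observed outgoing transitions; "
                       "rows left as self-loops", list(np.flatnonzero(empty)))
        counts[empty, np.flatnonzero(empty)] = 1.0
        rowsum = counts.sum(axis=1)
    T = counts / rowsum[:, None]
    from .hmm_fit import stationary_distribution

    return MarkovStateModel(T, stationary_distribution(T))


def marginalize_to_structures(T_states: np.ndarray, p_states: np.ndarray,
                              states: np.ndarray, n_structures: int | None = None,
                              weighting: str = "stationary") -> MarkovStateModel:
    """Reduce a (structure, orientation) state-level matrix to structures.

    With the default stationary weighting,

        T_struct(i, j) = Σ_{s∈i} Σ_{s'∈j} p(s) T(s, s') / Σ_{s∈i} p(s),

    which preserves equilibrium structure populations; ``weighting="uniform"``
    weights the member states of each structure equally instead.  A structure
    group with zero total weight is an error.
    """
    T_states = _check_row_stochastic(T_states)
    states = np.asarray(states, dtype=int)
    m = states[:, 0]
    if n_structures is None:
        n_structures = int(m.max()) + 1
    if weighting == "stationary":
        w = np.asarray(p_states, dtype=float)
    elif weighting == "uniform":
        w = np.full(len(states), 1.0 / len(states))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    member = np.zeros((n_structures, len(states)))
    member[m, np.arange(len(states))] = 1.0
    group_w = member @ w
    if np.any(group_w <= 0):
        raise ValueError(
            f"structure group(s) {list(np.flatnonzero(group_w <= 0))} have zero "
            "total weight"
        )
    flux = (member * w[None, :]) @ T_states @ member.T  # (n_struct, n_struct)
    T_struct = flux / group_w[:, None]
    T_struct /= T_struct.sum(axis=1, keepdims=True)
    from .hmm_fit import stationary_distribution

    return MarkovStateModel(T_struct, stationary_distribution(T_struct))


def _flux_symmetrize(T: np.ndarray, p: np.ndarray):
    flux = (p[:, None] * T + (p[:, None] * T).T) / 2.0
    rowsum = flux.sum(axis=1)
    T_rev = flux / rowsum[:, None]
    p_rev = rowsum / rowsum.sum()
    return T_rev, p_rev


def enforce_detailed_balance(msm: MarkovStateModel) -> MarkovStateModel:
    """Project a model onto detailed balance by flux symmetrization.

    F_ij = (p_i T_ij + p_j T_ji)/2, T'_ij = F_ij / Σ_j F_ij.  The output is
    reversible (p'_i T'_ij = p'_j T'_ji) and an already-reversible model is a
    fixed point.  Requires an irreducible input.
    """
    n_comp, labels = _strong_components(msm.transition)
    if n_comp > 1:
        blocks = [list(np.flatnonzero(labels == k)) for k in range(n_comp)]
        raise ValueError(f"cannot enforce detailed balance on a reducible "
                         f"matrix; strongly connected blocks: {blocks}")
    T_rev, p_rev = _flux_symmetrize(msm.transition, msm.equilibrium)
    return MarkovStateModel(T_rev, p_rev)


def relative_entropy(truth: MarkovStateModel, estimate: MarkovStateModel,
                     eps: float = 1e-10) -> float:
    """D(T || T_est) in nats, weighted by the ground-truth equilibrium.

    A uniform floor ``eps`` is added to the estimate only; terms with
    T_ij = 0 contribute zero by continuity.  Zero iff the models agree
    (up to the eps floor).
    """
    if truth.n_states != estimate.n_states:
        raise ValueError("models must have the same number of states")
    T = truth.transition
    E = estimate.transition + eps
    p = truth.equilibrium
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(T > 0, p[:, None] * T * np.log(np.where(T > 0, T, 1.0) / E),
                         0.0)
    return float(terms.sum())
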