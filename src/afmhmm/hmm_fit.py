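"""Hidden Markov extension of rigid-body fitting.

The hidden state s is the pair (candidate structure m, orientation φ); the
translation (dx, dy) is not part of the state because lateral position does
not influence conformational dynamics.  Emissions are fixed to the per-frame
marginalized likelihoods from the rigid fit; only the transition matrix is
estimated (Baum-Welch), with the initial distribution p(s₁) tied to the
stationary distribution of the current transition matrix.

Topological (rotational) constraints are imposed through the zero pattern of
the initial transition matrix: an entry initialized to zero stays zero under
Baum-Welch re-estimation, so forbidding transitions between states whose
quaternion distance exceeds a threshold (default 0.1) encodes the prior that
a stage-bound molecule does not rotate far between adjacent frames.

All recursions run with per-frame scaling of the exponentiated emission
rows (equivalent to log space); the marginalized log-likelihoods at
N_pixel = 4800 are far outside the floating-point exponent range if
exponentiated directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rigid_fit import EmissionTable

__all__ = [
    "StateSpace",
    "HMMModel",
    "HMMResult",
    "build_state_mask",
    "stationary_distribution",
    "initialize_transitions",
    "log_forward_backward",
    "baum_welch",
    "viterbi",
    "prune_states",
    "prune_union",
    "constrained_max_likelihood_per_orientation",
]


@dataclass(frozen=True)
class StateSpace:
    """Ordered list of (structure index, orientation index) states."""

    states: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.states, dtype=int).reshape(-1, 2)
        if len(np.unique(s, axis=0)) != len(s):
            raise ValueError("duplicate states in state space")
        object.__setattr__(self, "states", s)

    def __len__(self) -> int:
        return len(self.states)

    def index(self, m: int, o: int) -> int:
        hit = np.flatnonzero((self.states[:, 0] == m) & (self.states[:, 1] == o))
        if len(hit) == 0:
            raise KeyError(f"state (m={m}, o={o}) not in state space")
        return int(hit[0])

    def orientation_members(self, o: int) -> np.ndarray:
        return np.flatnonzero(self.states[:, 1] == o)


@dataclass(frozen=True)
class HMMModel:
    """Row-stochastic transition matrix, initial distribution and constraint mask."""

    transition: np.ndarray
    initial: np.ndarray
    mask: np.ndarray | None = None
    threshold: float | None = None

    def __post_init__(self):
        T = np.asarray(self.transition, dtype=float)
        p = np.asarray(self.initial, dtype=float)
        if T.ndim != 2 or T.shape[0] != T.shape[1]:
            raise ValueError("transition matrix must be square")
        if p.shape != (T.shape[0],):
            raise ValueError("initial distribution length must match matrix size")
        if np.any(T < 0) or np.any(p < 0):
            raise ValueError("probabilities must be non-negative")
        if np.max(np.abs(T.sum(axis=1) - 1.0)) > 1e-8:
            raise ValueError("transition matrix rows must sum to 1")
        if abs(p.sum() - 1.0) > 1e-8:
            raise ValueError("initial distribution must sum to 1")
        mask = self.mask
        if mask is not None:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != T.shape:
                raise ValueError("mask shape must match transition matrix")
            if np.any(T[~mask] != 0.0):
                raise ValueError("transition matrix has nonzero forbidden entries")
        object.__setattr__(self, "transition", T)
        object.__setattr__(self, "initial", p)
        object.__setattr__(self, "mask", mask)

    @property
    def n_states(self) -> int:
        return len(self.initial)


@dataclass(frozen=True)
class HMMResult:
    """Baum-Welch output: estimated model, evidence trace, optional decoding."""

    model: HMMModel
    evidence_trace: np.ndarray
    path: np.ndarray | None = None
    path_loglik: float | None = None


def build_state_mask(states: np.ndarray, orientation_mask: np.ndarray) -> np.ndarray:
    """Lift an orientation-pair constraint mask to the (m, φ) state space.

    Structure changes are unconstrained; a state pair is allowed iff its
    orientation pair is allowed.
    """
    o = np.asarray(states, dtype=int)[:, 1]
    return orientation_mask[np.ix_(o, o)]


def stationary_distribution(T: np.ndarray, tol: float = 1e-12,
                            max_iter: int = 100000) -> np.ndarray:
    """Stationary distribution by power iteration from the uniform vector.

    For a reducible chain this converges to a valid stationary vector (a
    block mixture determined by the uniform start), which is what the
    equilibrium-weighted marginalizations need.
    """
    T = np.asarray(T, dtype=float)
    p = np.full(T.shape[0], 1.0 / T.shape[0])
    for _ in range(max_iter):
        nxt = p @ T
        total = nxt.sum()
        if total <= 0:
            raise ValueError("transition matrix has a zero column sum structure")
        nxt /= total
        if np.abs(nxt - p).max() < tol:
            return nxt
        p = nxt
    return p


def initialize_transitions(states: np.ndarray, mask: np.ndarray, seed) -> HMMModel:
    """Random row-stochastic transition matrix honouring a constraint mask.

    Allowed entries are drawn uniform-positive and row-normalized; forbidden
    entries are exactly zero.  p(s₁) is the stationary distribution of the
    initialized matrix.  Identical seeds give bit-identical models.
    """
    states = np.asarray(states, dtype=int)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (len(states), len(states)):
        raise ValueError("mask shape must be (M, M)")
    if not np.all(mask.diagonal()):
        raise ValueError("constraint mask must allow self-transitions")
    if np.any(~mask.any(axis=1)):
        raise ValueError("constraint mask has a row with no allowed transitions")
    rng = np.random.default_rng(seed)
    T = np.where(mask, rng.uniform(0.1, 1.0, size=mask.shape), 0.0)
    T /= T.sum(axis=1, keepdims=True)
    return HMMModel(T, stationary_distribution(T), mask=mask)


def _emission_array(emissions) -> np.ndarray:
    if isinstance(emissions, EmissionTable):
        return emissions.loglik
    return np.asarray(emissions, dtype=float)


def log_forward_backward(emissions, model: HMMModel):
    """Forward-Backward recursion, entirely in log space.

    Returns ``(log_evidence, gamma, xi)`` where gamma is the (T, M) matrix of
    per-frame state posteriors (rows sum to 1) and xi the (T−1, M, M) array
    of pairwise posteriors.  The evidence equals the time-series likelihood
    marginalized over all state paths.

    Log space (rather than per-frame rescaling of exponentiated emissions)
    matters here: rotation-constrained transition matrices combined with
    near-deterministic emissions produce feasible paths whose relative
    weights underflow any linear-space representation, yet still carry all
    of the evidence.
    """
    from scipy.special import logsumexp

    ll = _emission_array(emissions)
    if ll.ndim != 2 or ll.shape[0] < 1:
        raise ValueError("emissions must be a (T, M) array with T >= 1")
    if np.any(np.all(np.isneginf(ll), axis=1)):
        raise ValueError("a frame has all -inf emissions (zero evidence)")
    with np.errstate(divide="ignore"):
        log_T = np.log(model.transition)
        log_pi = np.log(model.initial)
    n_t, n_s = ll.shape

    alpha = np.empty((n_t, n_s))
    alpha[0] = log_pi + ll[0]
    with np.errstate(invalid="ignore"):
        for t in range(1, n_t):
            alpha[t] = logsumexp(alpha[t - 1][:, None] + log_T, axis=0) + ll[t]
        log_evidence = float(logsumexp(alpha[-1]))
        if not log_evidence > -np.inf:
            raise ValueError("zero evidence: no feasible state path")

        beta = np.empty((n_t, n_s))
        beta[-1] = 0.0
        for t in range(n_t - 2, -1, -1):
            beta[t] = logsumexp(log_T + (ll[t + 1] + beta[t + 1])[None, :], axis=1)

        log_gamma = alpha + beta
        gamma = np.exp(log_gamma - logsumexp(log_gamma, axis=1, keepdims=True))

        xi = np.empty((n_t - 1, n_s, n_s))
        for t in range(n_t - 1):
            lx = alpha[t][:, None] + log_T + (ll[t + 1] + beta[t + 1])[None, :]
            xi[t] = np.exp(lx - logsumexp(lx))
    return log_evidence, gamma, xi


def baum_welch(emissions, model: HMMModel, tol: float = 1e-6,
               max_iter: int = 200) -> HMMResult:
    """Estimate transition probabilities by expectation-maximization.

    ``emissions`` may be a single (T, M) table or a list of tables from
    independent movies sharing one transition matrix (sufficient statistics
    are summed over movies).  Emissions are fixed; entries of the transition
    matrix initialized to zero remain zero.  After each update p(s₁) is
    refreshed to the stationary distribution of the current matrix.  Stops
    when the evidence gain drops below ``tol`` (nats) or at ``max_iter``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    tables = emissions if isinstance(emissions, (list, tuple)) else [emissions]
    arrays = [_emission_array(e) for e in tables]
    current = model
    previous = model
    trace = []
    for iteration in range(max_iter):
        total_ev = 0.0
        xi_sum = np.zeros_like(current.transition)
        for arr in arrays:
            ev, _, xi = log_forward_backward(arr, current)
            total_ev += ev
            xi_sum += xi.sum(axis=0)
        if not np.isfinite(total_ev):
            raise FloatingPointError(
                f"non-finite evidence at Baum-Welch iteration {iteration}"
            )
        if trace and total_ev < trace[-1]:
            # Tying p(s1) to the stationary distribution of the transition
            # matrix couples the E and M steps, so an update can (very close
            # to convergence) lower the evidence slightly; reject it and
            # return the previous model, keeping the trace non-decreasing.
            current = previous
            break
        trace.append(total_ev)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            break
        rowsum = xi_sum.sum(axis=1, keepdims=True)
        new_T = np.where(rowsum > 0, xi_sum / np.where(rowsum > 0, rowsum, 1.0),
                         current.transition)
        new_T /= new_T.sum(axis=1, keepdims=True)
        previous = current
        current = HMMModel(new_T, stationary_distribution(new_T), mask=current.mask,
                           threshold=current.threshold)
    return HMMResult(current, np.asarray(trace))


def viterbi(emissions, model: HMMModel):
    """Maximum-likelihood state path (ties -> lowest state index).

    Returns ``(path, path_log_likelihood)``.
    """
    ll = _emission_array(emissions)
    with np.errstate(divide="ignore"):
        log_T = np.log(model.transition)
        log_pi = np.log(model.initial)
    n_t, n_s = ll.shape
    delta = log_pi + ll[0]
    back = np.zeros((n_t, n_s), dtype=int)
    for t in range(1, n_t):
        scores = delta[:, None] + log_T
        back[t] = np.argmax(scores, axis=0)  # first max = lowest predecessor index
        delta = scores[back[t], np.arange(n_s)] + ll[t]
    path = np.empty(n_t, dtype=int)
    path[-1] = int(np.argmax(delta))
    score = float(delta[path[-1]])
    for t in range(n_t - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path, score


def prune_states(emissions: EmissionTable, delta: float):
    """Drop states never within ``delta`` nats of a frame's maximum likelihood.

    A state survives if its log-likelihood is within ``delta`` of the frame
    maximum in at least one frame (each frame's argmax always survives).
    Returns ``(kept_indices, reduced_table)``.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    ll = emissions.loglik
    frame_max = ll.max(axis=1, keepdims=True)
    keep = np.flatnonzero((ll >= frame_max - delta).any(axis=0))
    reduced = EmissionTable(ll[:, keep], emissions.dx[:, keep], emissions.dy[:, keep],
                            emissions.states[keep], tip_radius=emissions.tip_radius,
                            log_offset=emissions.log_offset)
    return keep, reduced


def prune_union(tables, delta: float):
    """Joint pruning for several movies sharing one state space.

    Keeps the union of the per-movie survivors so that a single transition
    matrix can be estimated across movies.  Returns
    ``(kept_indices, [reduced_tables...])``.
    """
    keeps = [prune_states(t, delta)[0] for t in tables]
    keep = np.unique(np.concatenate(keeps))
    reduced = [
        EmissionTable(t.loglik[:, keep], t.dx[:, keep], t.dy[:, keep],
                      t.states[keep], tip_radius=t.tip_radius, log_offset=t.log_offset)
        for t in tables
    ]
    return keep, reduced


def constrained_max_likelihood_per_orientation(emissions, model: HMMModel,
                                               space: StateSpace,
                                               orientation: int) -> float:
    """Viterbi score restricted to states with a given orientation.

    The structure may still vary frame to frame; transition and initial
    probabilities keep their unrestricted values so scores are comparable
    across orientations (and their maximum relates to the unconstrained
    Viterbi score).
    """
    idx = space.orientation_members(orientation)
    if len(idx) == 0:
        raise ValueError(f"no states with orientation index {orientation}")
    ll = _emission_array(emissions)[:, idx]
    sub_T = model.transition[np.ix_(idx, idx)]
    sub_pi = model.initial[idx]
    with np.errstate(divide="ignore"):
        log_T = np.log(sub_T)
        log_pi = np.log(sub_pi)
    delta = log_pi + ll[0]
    for t in range(1, ll.shape[0]):
        delta = np.max(delta[:, None] + log_T, axis=0) + ll[t]
    return float(np.max(delta))
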