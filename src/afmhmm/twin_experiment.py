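"""Twin-experiment framework: synthetic ground truth, data generation, scoring.

A twin experiment validates the estimators against known ground truth: a
structure-level Markov chain drives conformer switching, one orientation
(drawn from the orientation grid) is held fixed per movie, the molecule
drifts laterally as a Gaussian random walk, frames are rendered by tip
collision detection, and i.i.d. Gaussian pixel noise is added.  The fitted
(structure, orientation) sequences are then scored against the generating
truth by unaligned RMSD — computed without superposition, so a 180-degree
orientation flip registers as a large error rather than zero.

The synthetic conformer ensemble is a pseudo-symmetric two-lobed bead model:
two unequal lobes placed along the y axis, so that flipping the molecule
through 180 degrees swaps the lobes and produces a subtly different height
profile — distinguishable at the correct tip radius, but increasingly
confusable as the fitting tip radius departs from the radius that generated
the data.  Conformers differ in lobe separation and a hinge rotation of the
smaller lobe, giving mean pairwise unaligned RMSDs on the ~1 nm scale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import orientations
from .afm_imaging import (AFMImage, ImageGrid, ImageSeries, Structure, TipModel,
                          synthesize_image)
from .hmm_fit import (HMMModel, build_state_mask, baum_welch, initialize_transitions,
                      prune_union, stationary_distribution, viterbi)
from .msm_tools import MarkovStateModel, relative_entropy, _flux_symmetrize
from .rigid_fit import EmissionTable, compute_emissions
from .orientations import quat_distance, rotation_constraint_mask

__all__ = [
    "TwinConfig",
    "GroundTruthRecord",
    "make_ground_truth_msm",
    "make_synthetic_ensemble",
    "generate_afm_series",
    "unaligned_rmsd",
    "run_twin_experiment",
    "bootstrap_transition_ci",
    "write_report",
]

logger = logging.getLogger(__name__)

ALL_METHODS = ("frame_by_frame", "hmm_truthT", "hmm_baumwelch", "hmm_randomT")


@dataclass(frozen=True)
class TwinConfig:
    """Study conditions of the twin experiment.

    Defaults reproduce the reference protocol: 50 sets of 100-frame movies on
    an 80x60 grid at 0.625 nm/pixel, pixel noise std 0.3 nm, lateral drift
    std 0.1 nm/step per axis, tip apex radius 2.5 nm with 10-degree half
    angle, and a 576-point orientation grid.
    """

    n_sets: int = 50
    n_frames: int = 100
    n_structures: int = 50
    n_orientations: int = 576
    noise_sigma: float = 0.3
    drift_sigma: float = 0.1
    tip_radius: float = 2.5
    half_angle_deg: float = 10.0
    pixel_size: float = 0.625
    nx: int = 80
    ny: int = 60
    constraint_threshold: float = 0.1
    prune_delta: float = 20.0
    bw_tol: float = 1e-6
    bw_max_iter: int = 200
    seed: int = 0

    def __post_init__(self):
        for name in ("n_sets", "n_frames", "n_structures", "n_orientations",
                     "noise_sigma", "drift_sigma", "tip_radius", "half_angle_deg",
                     "pixel_size", "nx", "ny", "constraint_threshold",
                     "prune_delta", "bw_tol", "bw_max_iter"):
            if getattr(self, name) < 0 or (name not in ("noise_sigma", "drift_sigma")
                                           and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")

    @property
    def image_grid(self) -> ImageGrid:
        return ImageGrid(self.pixel_size, self.nx, self.ny)

    @property
    def tip(self) -> TipModel:
        return TipModel(self.tip_radius, self.half_angle_deg)


@dataclass(frozen=True)
class GroundTruthRecord:
    """Generating truth of one movie: fixed orientation, per-frame structure
    index, the continuous drift random walk and the pixel-aligned offsets
    actually applied at the imaging step (all in nm)."""

    orientation_index: int
    quaternion: np.ndarray
    states: np.ndarray
    drift: np.ndarray
    drift_applied: np.ndarray


def make_ground_truth_msm(n_states: int, seed, isolated_state: int = 0,
                          isolation: float = 0.1,
                          self_weight: float = 2.0) -> MarkovStateModel:
    """Random reversible metastable MSM with one kinetically isolated state.

    Built from a symmetric positive weight matrix (hence reversible by
    construction) with boosted diagonal for metastability; the couplings of
    ``isolated_state`` are scaled down by ``isolation`` so transitions into
    and out of it are rare, mimicking a kinetically isolated conformation.
    """
    rng = np.random.default_rng(seed)
    w = rng.uniform(0.2, 1.0, size=(n_states, n_states))
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, self_weight)
    w[isolated_state, :] *= isolation
    w[:, isolated_state] *= isolation
    w[isolated_state, isolated_state] = self_weight
    T = w / w.sum(axis=1, keepdims=True)
    p = w.sum(axis=1) / w.sum()
    return MarkovStateModel(T, p)


def _ball_points(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """n points uniform in a ball of the given radius."""
    directions = rng.normal(size=(n, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    return directions * radius * rng.random(n)[:, None] ** (1.0 / 3.0)


def make_synthetic_ensemble(n_structures: int, seed, bead_radius: float = 0.4):
    """Deterministic pseudo-symmetric two-lobed conformer ensemble.

    All conformers share the bead layout of two unequal lobes on the y axis
    (large lobe at -y, small lobe at +y); conformers differ in the lobe
    separation and in a pitch rotation of the small lobe about the x axis
    through the origin — an out-of-plane domain motion that changes the
    height profile, so conformers stay distinguishable under lateral drift —
    plus a small jitter that breaks exact degeneracies.  Identical seeds
    give bit-identical ensembles; all pairwise unaligned RMSDs are strictly
    positive.
    """
    if n_structures < 2:
        raise ValueError("need at least 2 structures")
    rng = np.random.default_rng(seed)
    lobe_large = _ball_points(rng, 60, 1.8) * np.array([1.0, 1.0, 1.25])
    lobe_small = _ball_points(rng, 45, 1.2)
    # varied bead radii give the lobes a rugged, protein-like surface
    radii = np.concatenate([
        rng.uniform(0.5 * bead_radius, 1.4 * bead_radius, len(lobe_large)),
        rng.uniform(0.5 * bead_radius, 1.4 * bead_radius, len(lobe_small)),
    ])
    # conformers lie on an out-of-plane opening coordinate: the small lobe
    # swings about the x axis while the large lobe rolls about y, changing
    # the height profile rather than the lateral footprint
    pitches = np.linspace(-0.8, 0.8, n_structures)
    rolls = np.linspace(-0.5, 0.5, n_structures)

    structures = []
    for i in range(n_structures):
        c, s = np.cos(pitches[i]), np.sin(pitches[i])
        rot_x = np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])
        c2, s2 = np.cos(rolls[i]), np.sin(rolls[i])
        rot_y = np.array([[c2, 0.0, s2], [0.0, 1.0, 0.0], [-s2, 0.0, c2]])
        small = (lobe_small + np.array([0.0, 3.0, 0.0])) @ rot_x.T
        large = lobe_large @ rot_y.T + np.array([0.0, -2.2, 0.0])
        coords = np.vstack([large, small])
        coords = coords + rng.normal(0.0, 0.05, size=coords.shape)
        coords -= coords.mean(axis=0)
        structures.append(Structure(coords, radii))
    return structures


def generate_afm_series(msm: MarkovStateModel, ensemble, grid_q: np.ndarray,
                        config: TwinConfig, set_index: int):
    """Generate one movie plus its ground truth.

    The structure sequence is simulated from the MSM; one orientation is
    drawn uniformly from the grid and held fixed for all frames; the lateral
    position follows a cumulative Gaussian random walk (frame 0 at the
    origin), rounded to the pixel lattice at the imaging step — consistent
    with the integer-slice translation search of the fitting stage, which
    carries no sub-pixel registration; pixel noise is i.i.d. Gaussian.  All
    randomness derives from (config.seed, set_index).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1000 + set_index]))
    from .msm_tools import simulate_chain

    states = simulate_chain(msm, config.n_frames, rng)
    orient_idx = int(rng.integers(len(grid_q)))
    steps = rng.normal(0.0, config.drift_sigma, size=(config.n_frames, 2))
    drift = np.vstack([np.zeros(2), np.cumsum(steps[:-1], axis=0)])
    applied = np.round(drift / config.pixel_size) * config.pixel_size

    grid = config.image_grid
    frames = np.empty((config.n_frames,) + grid.shape)
    for t in range(config.n_frames):
        img = synthesize_image(ensemble[states[t]], grid_q[orient_idx],
                               applied[t, 0], applied[t, 1], config.tip, grid)
        frames[t] = img.heights
    if config.noise_sigma > 0:
        frames = frames + rng.normal(0.0, config.noise_sigma, size=frames.shape)
    truth = GroundTruthRecord(orient_idx, grid_q[orient_idx].copy(), states, drift,
                              applied)
    return ImageSeries(frames, grid), truth


def unaligned_rmsd(state_a, state_b, ensemble, grid_q: np.ndarray) -> float:
    """RMSD between two posed states without structural alignment (nm).

    Each structure is centred at its centroid and rotated by its orientation
    quaternion; the RMSD is taken over corresponding beads with no
    superposition.  Translations are excluded: lateral position is not part
    of the state.  Symmetric; zero iff the states share (m, φ).
    """
    (ma, oa), (mb, ob) = state_a, state_b
    sa, sb = ensemble[ma], ensemble[mb]
    if len(sa) != len(sb):
        raise ValueError("structures must have equal bead counts")
    pa = (sa.coords - sa.coords.mean(axis=0)) @ orientations.quat_to_matrix(grid_q[oa]).T
    pb = (sb.coords - sb.coords.mean(axis=0)) @ orientations.quat_to_matrix(grid_q[ob]).T
    return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))


def _truth_state_model(msm: MarkovStateModel, n_orient: int) -> HMMModel:
    """Ground-truth state-level HMM: structure MSM x orientation-preserving."""
    T = np.kron(msm.transition, np.eye(n_orient))
    p = np.kron(msm.equilibrium, np.full(n_orient, 1.0 / n_orient))
    return HMMModel(T, p)


def _random_model(n_states: int, seed) -> HMMModel:
    rng = np.random.default_rng(seed)
    T = rng.uniform(0.1, 1.0, size=(n_states, n_states))
    T /= T.sum(axis=1, keepdims=True)
    return HMMModel(T, stationary_distribution(T))


def _structure_msm_from_state_model(T_states: np.ndarray, p_states: np.ndarray,
                                    states: np.ndarray,
                                    n_structures: int) -> MarkovStateModel:
    """Marginalize a state-level matrix to structures and project onto
    detailed balance.

    Structures with zero stationary weight (e.g. pruned away entirely) keep a
    self-loop row with a logged warning so the matrix stays comparable to the
    ground truth.
    """
    m = np.asarray(states, dtype=int)[:, 0]
    w = np.asarray(p_states, dtype=float)
    group_w = np.bincount(m, weights=w, minlength=n_structures)
    member = np.zeros((n_structures, len(m)))
    member[m, np.arange(len(m))] = 1.0
    T_struct = np.eye(n_structures)
    present = group_w > 0
    if not present.all():
        logger.warning("structure(s) %s absent from the estimated state space; "
                       "rows left as self-loops", list(np.flatnonzero(~present)))
    flux = (member * w[None, :]) @ T_states @ member.T
    rows = np.flatnonzero(present)
    T_struct[rows] = flux[rows] / group_w[rows, None]
    T_struct[rows] /= T_struct[rows].sum(axis=1, keepdims=True)
    p_struct = stationary_distribution(T_struct)
    T_rev, p_rev = _flux_symmetrize(T_struct, p_struct)
    return MarkovStateModel(T_rev, p_rev)


def run_twin_experiment(config: TwinConfig, radii=None, methods=ALL_METHODS) -> dict:
    """Generate twin data once, then fit it with each method at each radius.

    Per (method, radius) the report holds the estimated (m, φ) per frame,
    the per-frame unaligned RMSD against truth, the zero-RMSD fraction and
    the fraction of flipped-orientation frames (quaternion distance of the
    estimated orientation from truth above 0.5, i.e. rotated by more than 90
    degrees).  For the Baum-Welch method the structure-level MSM is
    reconstructed (orientation marginalization + detailed-balance
    projection) and scored by relative entropy against the generating MSM.
    Fully reproducible from ``config.seed``.
    """
    radii = [float(config.tip_radius)] if radii is None else [float(r) for r in radii]
    methods = tuple(methods)
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")

    msm = make_ground_truth_msm(config.n_structures,
                                np.random.SeedSequence([config.seed, 11]))
    ensemble = make_synthetic_ensemble(config.n_structures,
                                       np.random.SeedSequence([config.seed, 22]))
    grid_q = orientations.generate_grid(config.n_orientations)
    n_orient = len(grid_q)

    movies, truths = [], []
    for k in range(config.n_sets):
        series, truth = generate_afm_series(msm, ensemble, grid_q, config, k)
        movies.append(series)
        truths.append(truth)

    orient_mask = rotation_constraint_mask(grid_q, config.constraint_threshold)
    rmsd_cache: dict = {}

    def _rmsd(sa, sb):
        key = (sa, sb)
        if key not in rmsd_cache:
            rmsd_cache[key] = unaligned_rmsd(sa, sb, ensemble, grid_q)
        return rmsd_cache[key]

    report = {
        "config": asdict(config),
        "radii": radii,
        "truth_transition": msm.transition.tolist(),
        "truth_equilibrium": msm.equilibrium.tolist(),
        "methods": {m: {} for m in methods},
        "relative_entropy": {},
        "bw_evidence_trace": {},
    }

    for radius in radii:
        tip = TipModel(radius, config.half_angle_deg)
        tables = [compute_emissions(s, ensemble, grid_q, tip) for s in movies]
        est: dict = {}

        if "frame_by_frame" in methods:
            est["frame_by_frame"] = [t.states[t.argmax_states()] for t in tables]
        if "hmm_truthT" in methods:
            truth_model = _truth_state_model(msm, n_orient)
            est["hmm_truthT"] = [t.states[viterbi(t, truth_model)[0]] for t in tables]
        if "hmm_randomT" in methods:
            rand_model = _random_model(config.n_structures * n_orient,
                                       np.random.SeedSequence([config.seed, 33]))
            est["hmm_randomT"] = [t.states[viterbi(t, rand_model)[0]] for t in tables]
        if "hmm_baumwelch" in methods:
            kept, reduced = prune_union(tables, config.prune_delta)
            states_kept = reduced[0].states
            mask = build_state_mask(states_kept, orient_mask)
            init = initialize_transitions(states_kept, mask,
                                          np.random.SeedSequence([config.seed, 44]))
            bw = baum_welch(reduced, init, tol=config.bw_tol,
                            max_iter=config.bw_max_iter)
            est["hmm_baumwelch"] = [r.states[viterbi(r, bw.model)[0]] for r in reduced]
            report["bw_evidence_trace"][radius] = [float(v) for v in bw.evidence_trace]
            est_msm = _structure_msm_from_state_model(
                bw.model.transition, bw.model.initial, states_kept,
                config.n_structures)
            report["relative_entropy"][radius] = relative_entropy(msm, est_msm)
            report.setdefault("reconstructed_msm", {})[radius] = \
                est_msm.transition.tolist()

        for method, per_set in est.items():
            rmsd = np.empty((config.n_sets, config.n_frames))
            flips = np.zeros((config.n_sets, config.n_frames), dtype=bool)
            for k, states_est in enumerate(per_set):
                truth = truths[k]
                for t in range(config.n_frames):
                    s_est = (int(states_est[t, 0]), int(states_est[t, 1]))
                    s_true = (int(truth.states[t]), truth.orientation_index)
                    rmsd[k, t] = _rmsd(s_est, s_true)
                    flips[k, t] = quat_distance(grid_q[s_est[1]],
                                                truth.quaternion) > 0.5
            report["methods"][method][radius] = {
                "states": [s.tolist() for s in per_set],
                "rmsd": rmsd.tolist(),
                "zero_rmsd_fraction": float(np.mean(rmsd < 1e-9)),
                "flip_fraction": float(np.mean(flips)),
                "mean_rmsd": float(np.mean(rmsd)),
            }
    return report


def bootstrap_transition_ci(tables, orient_mask: np.ndarray, n_structures: int,
                            n_boot: int = 25, seed: int = 0, tol: float = 1e-4,
                            max_iter: int = 100) -> dict:
    """Bootstrap spread of structure-level transition probabilities.

    ``tables`` are per-movie emission tables sharing one state space (the
    bootstrap unit is the whole movie, preserving within-movie correlation).
    Each replicate resamples movies with replacement and re-runs Baum-Welch;
    matrices are marginalized to structures with detailed-balance projection.
    Returns the full-data point estimate, the replicate samples and their
    per-entry min/max spread.  Fixed seeds give identical replicate
    assignments.
    """
    if len(tables) < 2:
        raise ValueError("bootstrap needs at least 2 movie sets")
    states = tables[0].states
    mask = build_state_mask(states, orient_mask)
    root = np.random.SeedSequence([seed, 4242])
    init_seed, resample_seed = root.spawn(2)

    def _estimate(subset, child_seed):
        init = initialize_transitions(states, mask, child_seed)
        bw = baum_welch(list(subset), init, tol=tol, max_iter=max_iter)
        return _structure_msm_from_state_model(
            bw.model.transition, bw.model.initial, states, n_structures).transition

    point = _estimate(tables, init_seed)
    rng = np.random.default_rng(resample_seed)
    replicate_idx = rng.integers(0, len(tables), size=(n_boot, len(tables)))
    samples = np.empty((n_boot, n_structures, n_structures))
    for b in range(n_boot):
        samples[b] = _estimate([tables[i] for i in replicate_idx[b]], init_seed)
    return {
        "point": point,
        "samples": samples,
        "low": samples.min(axis=0),
        "high": samples.max(axis=0),
        "replicate_indices": replicate_idx,
    }


def write_report(report: dict, outdir) -> None:
    """Write a twin-experiment report: JSON summary plus per-frame RMSD TSVs."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = {
        "config": report["config"],
        "radii": report["radii"],
        "relative_entropy": {str(k): v for k, v in report["relative_entropy"].items()},
        "metrics": {
            method: {
                str(radius): {k: v for k, v in entry.items()
                              if k in ("zero_rmsd_fraction", "flip_fraction",
                                       "mean_rmsd")}
                for radius, entry in per_radius.items()
            }
            for method, per_radius in report["methods"].items()
        },
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    for method, per_radius in report["methods"].items():
        for radius, entry in per_radius.items():
            frame = pd.DataFrame(np.asarray(entry["rmsd"]))
            frame.index.name = "set"
            frame.to_csv(outdir / f"rmsd_{method}_r{radius:g}.tsv", sep="\t")
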