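import numpy as np
import pytest
from scipy.special import logsumexp

from afmhmm import reference
from afmhmm.hmm_fit import (HMMModel, StateSpace, baum_welch, build_state_mask,
                            constrained_max_likelihood_per_orientation,
                            initialize_transitions, log_forward_backward,
                            prune_states, stationary_distribution, viterbi)
from afmhmm.rigid_fit import EmissionTable, make_state_space


def random_model(rng, n, masked=False):
    T = rng.uniform(0.05, 1.0, (n, n))
    mask = None
    if masked:
        mask = rng.random((n, n)) < 0.6
        np.fill_diagonal(mask, True)
        T = np.where(mask, T, 0.0)
    T /= T.sum(axis=1, keepdims=True)
    pi = rng.uniform(0.05, 1.0, n)
    return HMMModel(T, pi / pi.sum(), mask=mask)


def full_mask(n):
    return np.ones((n, n), dtype=bool)


class TestInitialize:
    def test_rows_stochastic_and_mask_respected(self, rng):
        states = make_state_space(2, 4)
        mask = rng.random((8, 8)) < 0.5
        np.fill_diagonal(mask, True)
        model = initialize_transitions(states, mask, seed=3)
        np.testing.assert_allclose(model.transition.sum(axis=1), 1.0, atol=1e-12)
        assert (model.transition[~mask] == 0.0).all()
        assert (model.transition[mask] > 0.0).all()

    def test_initial_distribution_is_stationary(self):
        states = make_state_space(2, 3)
        model = initialize_transitions(states, full_mask(6), seed=0)
        np.testing.assert_allclose(model.initial @ model.transition, model.initial,
                                   atol=1e-10)

    def test_deterministic_per_seed(self):
        states = make_state_space(1, 5)
        a = initialize_transitions(states, full_mask(5), seed=7)
        b = initialize_transitions(states, full_mask(5), seed=7)
        np.testing.assert_array_equal(a.transition, b.transition)

    def test_diagonal_must_be_allowed(self):
        states = make_state_space(1, 3)
        mask = full_mask(3)
        mask[1, 1] = False
        with pytest.raises(ValueError):
            initialize_transitions(states, mask, seed=0)


class TestForwardBackward:
    def test_single_frame_reduces_to_logsumexp(self, rng):
        model = random_model(rng, 4)
        ll = rng.normal(0, 3, (1, 4))
        ev, gamma, xi = log_forward_backward(ll, model)
        assert ev == pytest.approx(logsumexp(np.log(model.initial) + ll[0]))
        assert xi.shape == (0, 4, 4)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0)

    def test_matches_path_enumeration(self, rng):
        """Evidence equals explicit summation over all M^T paths for 100
        random instances with M <= 4, T <= 5 (masked and unmasked)."""
        for trial in range(100):
            n = int(rng.integers(2, 5))
            t = int(rng.integers(2, 6))
            model = random_model(rng, n, masked=trial % 2 == 0)
            ll = rng.normal(0, 2, (t, n))
            ev, gamma, _ = log_forward_backward(ll, model)
            assert ev == pytest.approx(reference.evidence_enumerate(ll, model),
                                       abs=1e-10)
            np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-12)

    def test_uniform_transitions_factorize_over_frames(self, rng):
        n, t = 5, 6
        model = HMMModel(np.full((n, n), 1.0 / n), np.full(n, 1.0 / n))
        ll = rng.normal(0, 3, (t, n))
        ev, _, _ = log_forward_backward(ll, model)
        expected = logsumexp(ll, axis=1).sum() - t * np.log(n)
        assert ev == pytest.approx(expected, abs=1e-10)

    def test_all_neginf_frame_is_zero_evidence_error(self, rng):
        model = random_model(rng, 3)
        ll = np.zeros((2, 3))
        ll[1] = -np.inf
        with pytest.raises(ValueError, match="evidence"):
            log_forward_backward(ll, model)


class TestBaumWelch:
    def test_zero_entries_stay_zero(self, rng):
        model = random_model(rng, 5, masked=True)
        ll = rng.normal(0, 2, (30, 5))
        result = baum_welch(ll, model, tol=1e-8, max_iter=50)
        assert (result.model.transition[~model.mask] == 0.0).all()
        np.testing.assert_allclose(result.model.transition.sum(axis=1), 1.0,
                                   atol=1e-10)

    def test_evidence_is_monotone(self, rng):
        model = random_model(rng, 4)
        ll = rng.normal(0, 2, (60, 4))
        result = baum_welch(ll, model, tol=1e-10, max_iter=80)
        assert np.all(np.diff(result.evidence_trace) >= -1e-8)

    def test_recovers_two_state_chain(self):
        """Well-separated emissions, T = 10000: transition probabilities
        recovered within +-0.02 of the generating values."""
        from afmhmm.msm_tools import MarkovStateModel, simulate_chain

        truth = np.array([[0.9, 0.1], [0.2, 0.8]])
        seq = simulate_chain(MarkovStateModel(truth), 10000, seed=5)
        ll = np.where(np.arange(2)[None, :] == seq[:, None], 0.0, -8.0)
        init = initialize_transitions(make_state_space(2, 1), full_mask(2), seed=1)
        result = baum_welch(ll, init, tol=1e-8, max_iter=300)
        np.testing.assert_allclose(result.model.transition, truth, atol=0.02)

    def test_multiple_sequences_share_one_matrix(self, rng):
        model = random_model(rng, 3)
        seqs = [rng.normal(0, 2, (20, 3)) for _ in range(3)]
        result = baum_welch(seqs, model, tol=1e-8, max_iter=40)
        single = baum_welch(np.concatenate(seqs), model, tol=1e-8, max_iter=40)
        # pooled sequences are a different model (no reset between movies),
        # but both must improve their own evidence monotonically
        assert np.all(np.diff(result.evidence_trace) >= -1e-8)
        assert np.all(np.diff(single.evidence_trace) >= -1e-8)


class TestViterbi:
    def test_single_state_path_is_constant(self, rng):
        model = HMMModel(np.ones((1, 1)), np.ones(1))
        path, _ = viterbi(rng.normal(size=(7, 1)), model)
        assert (path == 0).all()

    def test_matches_path_enumeration(self, rng):
        for trial in range(100):
            n = int(rng.integers(2, 5))
            t = int(rng.integers(2, 6))
            model = random_model(rng, n, masked=trial % 2 == 0)
            ll = rng.normal(0, 2, (t, n))
            path, score = viterbi(ll, model)
            ref_path, ref_score = reference.viterbi_enumerate(ll, model)
            assert score == pytest.approx(ref_score, abs=1e-10)
            np.testing.assert_array_equal(path, ref_path)

    def test_uniform_transitions_reduce_to_framewise_argmax(self, rng):
        n = 6
        model = HMMModel(np.full((n, n), 1.0 / n), np.full(n, 1.0 / n))
        ll = rng.normal(0, 3, (15, n))
        path, _ = viterbi(ll, model)
        np.testing.assert_array_equal(path, np.argmax(ll, axis=1))


class TestPruning:
    def _table(self, rng, t=4, m=6):
        ll = rng.normal(0, 5, (t, m))
        return EmissionTable(ll, np.zeros((t, m)), np.zeros((t, m)),
                             make_state_space(2, 3))

    def test_infinite_delta_keeps_everything(self, rng):
        table = self._table(rng)
        kept, reduced = prune_states(table, np.inf)
        assert len(kept) == table.n_states
        np.testing.assert_array_equal(reduced.loglik, table.loglik)

    def test_frame_argmax_always_survives(self, rng):
        table = self._table(rng)
        kept, _ = prune_states(table, 0.5)
        for t in range(table.n_frames):
            assert np.argmax(table.loglik[t]) in kept

    def test_viterbi_unchanged_for_generous_delta(self, rng):
        table = self._table(rng)
        model = random_model(rng, table.n_states)
        kept, reduced = prune_states(table, 1000.0)
        full_path, full_score = viterbi(table.loglik, model)
        sub_model = HMMModel(
            model.transition[np.ix_(kept, kept)]
            / model.transition[np.ix_(kept, kept)].sum(axis=1, keepdims=True),
            model.initial[kept] / model.initial[kept].sum())
        assert len(kept) == table.n_states  # generous delta prunes nothing
        path, score = viterbi(reduced.loglik, sub_model)
        np.testing.assert_array_equal(kept[path], full_path)


class TestConstrainedOrientation:
    def test_single_orientation_equals_unconstrained(self, rng):
        states = make_state_space(3, 1)
        model = random_model(rng, 3)
        ll = rng.normal(0, 2, (5, 3))
        space = StateSpace(states)
        constrained = constrained_max_likelihood_per_orientation(ll, model, space, 0)
        _, score = viterbi(ll, model)
        assert constrained == pytest.approx(score, abs=1e-10)

    def test_max_over_orientations_bounds_viterbi(self, rng):
        n_struct, n_orient = 2, 3
        states = make_state_space(n_struct, n_orient)
        space = StateSpace(states)
        model = random_model(rng, n_struct * n_orient)
        # emissions favouring a single orientation so the optimum stays there
        ll = rng.normal(0, 1, (6, n_struct * n_orient))
        ll[:, states[:, 1] == 1] += 50.0
        scores = [constrained_max_likelihood_per_orientation(ll, model, space, o)
                  for o in range(n_orient)]
        _, best = viterbi(ll, model)
        assert max(scores) == pytest.approx(best, abs=1e-10)
        assert int(np.argmax(scores)) == 1

    def test_margin_grows_with_frames_on_self_consistent_data(self, rng):
        """With emissions consistently favouring one orientation, its
        constrained path score pulls ahead of the runner-up as frames
        accumulate."""
        n_struct, n_orient, t = 2, 4, 30
        states = make_state_space(n_struct, n_orient)
        space = StateSpace(states)
        model = random_model(rng, n_struct * n_orient)
        ll = rng.normal(0, 0.5, (t, n_struct * n_orient))
        ll[:, states[:, 1] == 2] += 3.0
        margins = []
        for t_used in (5, 15, 30):
            scores = [constrained_max_likelihood_per_orientation(
                ll[:t_used], model, space, o) for o in range(n_orient)]
            ranked = sorted(scores)
            margins.append(ranked[-1] - ranked[-2])
        assert margins[0] < margins[1] < margins[2]

    def test_missing_orientation_rejected(self, rng):
        space = StateSpace(make_state_space(2, 2))
        model = random_model(rng, 4)
        with pytest.raises(ValueError):
            constrained_max_likelihood_per_orientation(
                rng.normal(size=(3, 4)), model, space, orientation=5)


class TestStateMask:
    def test_lifts_orientation_mask_to_states(self):
        states = make_state_space(2, 3)
        omask = np.eye(3, dtype=bool)
        omask[0, 1] = omask[1, 0] = True
        smask = build_state_mask(states, omask)
        s = StateSpace(states)
        for i, (mi, oi) in enumerate(states):
            for j, (mj, oj) in enumerate(states):
                assert smask[i, j] == omask[oi, oj]

    def test_stationary_distribution_fixed_point(self, rng):
        model = random_model(rng, 6)
        p = stationary_distribution(model.transition)
        np.testing.assert_allclose(p @ model.transition, p, atol=1e-10)
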