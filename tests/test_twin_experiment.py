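import numpy as np
import pytest

from afmhmm import orientations as ori
from afmhmm.afm_imaging import TipModel, synthesize_image
from afmhmm.orientations import rotation_constraint_mask
from afmhmm.rigid_fit import compute_emissions
from afmhmm.twin_experiment import (TwinConfig, bootstrap_transition_ci,
                                    generate_afm_series, make_ground_truth_msm,
                                    make_synthetic_ensemble, run_twin_experiment,
                                    unaligned_rmsd, write_report)

CFG = TwinConfig(n_sets=2, n_frames=6, n_structures=4, n_orientations=12, seed=7)


@pytest.fixture(scope="module")
def grid_q():
    return ori.generate_grid(CFG.n_orientations)


@pytest.fixture(scope="module")
def msm():
    return make_ground_truth_msm(CFG.n_structures, 3)


@pytest.fixture(scope="module")
def ensemble():
    return make_synthetic_ensemble(CFG.n_structures, 3)


class TestEnsemble:
    def test_size_and_determinism(self):
        a = make_synthetic_ensemble(6, 11)
        b = make_synthetic_ensemble(6, 11)
        assert len(a) == 6
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1.coords, s2.coords)

    def test_needs_at_least_two_conformers(self):
        with pytest.raises(ValueError):
            make_synthetic_ensemble(1, 0)

    def test_no_duplicate_conformers(self, grid_q):
        ens = make_synthetic_ensemble(6, 11)
        for i in range(6):
            for j in range(i + 1, 6):
                assert unaligned_rmsd((i, 0), (j, 0), ens, grid_q) > 0.0

    def test_pairwise_rmsd_on_nanometre_scale(self, grid_q):
        ens = make_synthetic_ensemble(10, 11)
        vals = [unaligned_rmsd((i, 0), (j, 0), ens, grid_q)
                for i in range(10) for j in range(i + 1, 10)]
        assert 0.5 < np.mean(vals) < 2.5


class TestGroundTruthMsm:
    def test_reversible_and_metastable(self):
        msm = make_ground_truth_msm(10, 5)
        flux = msm.equilibrium[:, None] * msm.transition
        assert np.abs(flux - flux.T).max() < 1e-12
        assert (np.diag(msm.transition) > msm.transition.max(axis=1) / 2).all()

    def test_isolated_state_has_rare_transitions(self):
        msm = make_ground_truth_msm(10, 5, isolated_state=0)
        off = msm.transition[0, 1:].sum()
        others = np.array([msm.transition[i, np.arange(10) != i].sum()
                           for i in range(1, 10)])
        assert off < others.min() / 2


class TestGenerate:
    def test_noiseless_driftless_frames_match_synthesis(self, msm, ensemble, grid_q):
        cfg = TwinConfig(n_sets=1, n_frames=4, n_structures=4, n_orientations=12,
                         noise_sigma=1e-300, drift_sigma=1e-300, seed=7)
        series, truth = generate_afm_series(msm, ensemble, grid_q, cfg, 0)
        for t in range(4):
            expected = synthesize_image(ensemble[truth.states[t]],
                                        grid_q[truth.orientation_index],
                                        tip=cfg.tip, grid=cfg.image_grid)
            np.testing.assert_allclose(series.frames[t], expected.heights, atol=1e-9)

    def test_orientation_fixed_within_a_set(self, msm, ensemble, grid_q):
        series, truth = generate_afm_series(msm, ensemble, grid_q, CFG, 1)
        assert truth.quaternion.shape == (4,)
        np.testing.assert_array_equal(truth.quaternion,
                                      grid_q[truth.orientation_index])

    def test_drift_steps_have_configured_std(self, msm, ensemble, grid_q):
        cfg = TwinConfig(n_sets=1, n_frames=1000, n_structures=4,
                         n_orientations=12, seed=7)
        _, truth = generate_afm_series(msm, ensemble, grid_q, cfg, 0)
        steps = np.diff(truth.drift, axis=0)
        for axis in range(2):
            assert steps[:, axis].std() == pytest.approx(0.1, rel=0.10)

    def test_applied_drift_is_pixel_aligned(self, msm, ensemble, grid_q):
        _, truth = generate_afm_series(msm, ensemble, grid_q, CFG, 0)
        ratio = truth.drift_applied / CFG.pixel_size
        np.testing.assert_allclose(ratio, np.round(ratio), atol=1e-12)

    def test_reproducible_per_seed_and_set(self, msm, ensemble, grid_q):
        s1, t1 = generate_afm_series(msm, ensemble, grid_q, CFG, 0)
        s2, t2 = generate_afm_series(msm, ensemble, grid_q, CFG, 0)
        np.testing.assert_array_equal(s1.frames, s2.frames)
        np.testing.assert_array_equal(t1.states, t2.states)


class TestUnalignedRmsd:
    def test_identical_states_give_zero(self, ensemble, grid_q):
        assert unaligned_rmsd((1, 3), (1, 3), ensemble, grid_q) == 0.0

    def test_half_turn_of_a_rod(self):
        from afmhmm.afm_imaging import Structure

        rod = Structure([[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0]], [0.3, 0.3])
        grid = np.array([[1.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 1.0]])  # identity, z180
        assert unaligned_rmsd((0, 0), (0, 1), [rod], grid) == pytest.approx(2.0)

    def test_symmetric(self, ensemble, grid_q):
        a, b = (0, 2), (3, 7)
        assert unaligned_rmsd(a, b, ensemble, grid_q) == pytest.approx(
            unaligned_rmsd(b, a, ensemble, grid_q))


@pytest.fixture(scope="module")
def tiny_report():
    return run_twin_experiment(CFG, radii=[2.5])


@pytest.fixture(scope="module")
def bootstrap_tables(msm, ensemble, grid_q):
    out = []
    for k in range(4):
        series, _ = generate_afm_series(msm, ensemble, grid_q, CFG, k)
        out.append(compute_emissions(series, ensemble, grid_q, CFG.tip))
    return out


class TestRunTwin:
    def test_report_is_deterministic(self, tiny_report):
        again = run_twin_experiment(CFG, radii=[2.5])
        assert tiny_report["methods"]["frame_by_frame"][2.5]["rmsd"] == \
            again["methods"]["frame_by_frame"][2.5]["rmsd"]
        assert tiny_report["relative_entropy"] == again["relative_entropy"]

    def test_all_methods_reported_with_consistent_shapes(self, tiny_report):
        for method, per_radius in tiny_report["methods"].items():
            entry = per_radius[2.5]
            rmsd = np.asarray(entry["rmsd"])
            assert rmsd.shape == (CFG.n_sets, CFG.n_frames)
            assert 0.0 <= entry["zero_rmsd_fraction"] <= 1.0

    def test_write_report(self, tiny_report, tmp_path):
        write_report(tiny_report, tmp_path)
        assert (tmp_path / "summary.json").exists()
        assert (tmp_path / "rmsd_frame_by_frame_r2.5.tsv").exists()

    def test_matched_radius_robust_to_doubled_noise(self):
        """Doubling the pixel noise to 0.6 nm does not catastrophically
        degrade matched-radius recovery."""
        cfg = TwinConfig(n_sets=3, n_frames=10, n_structures=10,
                         n_orientations=60, noise_sigma=0.6, seed=1)
        rep = run_twin_experiment(cfg, radii=[2.5], methods=("frame_by_frame",))
        assert rep["methods"]["frame_by_frame"][2.5]["zero_rmsd_fraction"] >= 0.9


class TestBootstrap:
    def test_requires_two_sets(self, bootstrap_tables, grid_q):
        mask = rotation_constraint_mask(grid_q, 0.1)
        with pytest.raises(ValueError):
            bootstrap_transition_ci(bootstrap_tables[:1], mask, CFG.n_structures)

    def test_deterministic_and_contains_point_estimate(self, bootstrap_tables,
                                                       grid_q):
        mask = rotation_constraint_mask(grid_q, 0.1)
        ci1 = bootstrap_transition_ci(bootstrap_tables, mask, CFG.n_structures,
                                      n_boot=6, seed=3)
        ci2 = bootstrap_transition_ci(bootstrap_tables, mask, CFG.n_structures,
                                      n_boot=6, seed=3)
        np.testing.assert_array_equal(ci1["replicate_indices"],
                                      ci2["replicate_indices"])
        np.testing.assert_array_equal(ci1["samples"], ci2["samples"])
        inside = (ci1["low"] <= ci1["point"] + 1e-9) & \
                 (ci1["point"] <= ci1["high"] + 1e-9)
        assert inside.mean() > 0.9
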