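import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ctpnet import networks, preprocess as pp
from ctpnet.base import BoldRun, MaskVolume
from ctpnet.hrf import canonical_hrf
from ctpnet.synthetic import (SyntheticSceneConfig, default_beta_truth,
                              generate_task_run)


def _solid_mask(shape):
    return MaskVolume(np.ones(shape, bool))


class TestBuildCubeParcellation:
    @pytest.mark.parametrize("shape,expected", [((6, 6, 6), 8),
                                                ((7, 6, 6), 8),
                                                ((9, 6, 6), 12)])
    def test_tiling_counts(self, shape, expected):
        parc = networks.build_cube_parcellation(_solid_mask(shape))
        assert parc.n_cubes == expected
        # cubes are disjoint and fully in-mask
        all_ids = parc.voxel_ids.ravel()
        assert len(all_ids) == len(set(all_ids))

    def test_mask_smaller_than_cube_rejected(self):
        with pytest.raises(ValueError):
            networks.build_cube_parcellation(_solid_mask((2, 2, 2)))

    def test_partial_blocks_discarded(self):
        mask = np.ones((6, 6, 6), bool)
        mask[0, 0, 0] = False  # breaks one cube
        parc = networks.build_cube_parcellation(MaskVolume(mask))
        assert parc.n_cubes == 7

    def test_dominant_parcel_label(self):
        labels = np.zeros((6, 6, 6), int)
        labels[:3] = 4
        labels[3:] = 9
        parc = networks.build_cube_parcellation(_solid_mask((6, 6, 6)),
                                                parcellation=labels)
        assert set(parc.labels) == {4, 9}


def _net_from_patterns(patterns, shape=(6, 6, 6)):
    """Place explicit per-cube 27-vectors into a volume and build the net."""
    parc = networks.build_cube_parcellation(_solid_mask(shape))
    vol = np.zeros(shape)
    flat = vol.ravel()
    for i, pat in enumerate(patterns):
        flat[parc.voxel_ids[i]] = pat
    return networks.cube_similarity_network(flat.reshape(shape), parc), parc


class TestCubeSimilarityNetwork:
    def test_identical_patterns_edge_weight_one(self, rng):
        pat = rng.standard_normal(27)
        net, _ = _net_from_patterns([pat, pat] + [rng.standard_normal(27)
                                                  for _ in range(6)])
        assert net.weights[0, 1] == pytest.approx(1.0)

    def test_negated_pattern_edge_absent(self, rng):
        pat = rng.standard_normal(27)
        net, _ = _net_from_patterns([pat, -pat] + [rng.standard_normal(27)
                                                   for _ in range(6)])
        assert net.weights[0, 1] == 0.0

    def test_matches_bruteforce_pearson(self, rng):
        parc = networks.build_cube_parcellation(_solid_mask((12, 12, 9)))
        assert parc.n_cubes == 48
        vol = rng.standard_normal((12, 12, 9))
        net = networks.cube_similarity_network(vol, parc)
        pats = vol.ravel()[parc.voxel_ids]
        for i in range(0, 48, 7):
            for j in range(i + 1, 48, 5):
                r = stats.pearsonr(pats[i], pats[j])[0]
                expected = r if r > 0 else 0.0
                assert net.weights[i, j] == pytest.approx(expected, abs=1e-12)

    def test_affine_rescaling_invariance(self, rng):
        parc = networks.build_cube_parcellation(_solid_mask((6, 6, 6)))
        vol = rng.standard_normal((6, 6, 6))
        a = networks.cube_similarity_network(vol, parc)
        b = networks.cube_similarity_network(3.7 * vol + 11.0, parc)
        np.testing.assert_allclose(a.weights, b.weights, atol=1e-12)

    def test_zero_variance_cube_excluded(self, rng):
        pats = [np.full(27, 5.0)] + [rng.standard_normal(27) for _ in range(7)]
        net, _ = _net_from_patterns(pats)
        assert 0 in net.excluded_nodes
        assert np.all(net.weights[0] == 0)

    def test_all_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            _net_from_patterns([np.zeros(27)] * 8)

    def test_common_voxel_reordering_leaves_edges_unchanged(self, rng):
        parc = networks.build_cube_parcellation(_solid_mask((6, 6, 6)))
        vol = rng.standard_normal((6, 6, 6))
        base = networks.cube_similarity_network(vol, parc)
        perm = rng.permutation(27)
        parc.voxel_ids = parc.voxel_ids[:, perm]
        permuted = networks.cube_similarity_network(vol, parc)
        np.testing.assert_allclose(base.weights, permuted.weights, atol=1e-12)


class TestAverageConditionNetwork:
    def _random_net(self, rng, n=8, excluded=()):
        w = rng.random((n, n))
        w = np.triu(w, 1)
        w = w + w.T
        w[list(excluded), :] = 0
        w[:, list(excluded)] = 0
        return networks.SimilarityNetwork(weights=w,
                                          excluded_nodes=np.asarray(excluded,
                                                                    dtype=int))

    def test_single_network_identity(self, rng):
        net = self._random_net(rng)
        avg = networks.average_condition_network([net], "ctp")
        np.testing.assert_allclose(avg.weights, net.weights)

    def test_two_network_mean(self):
        w1 = np.array([[0, 0.2], [0.2, 0]])
        w2 = np.array([[0, 0.6], [0.6, 0]])
        nets = [networks.SimilarityNetwork(w, np.array([], int))
                for w in (w1, w2)]
        avg = networks.average_condition_network(nets, "ctp")
        assert avg.weights[0, 1] == pytest.approx(0.4)

    def test_union_of_exclusions(self, rng):
        nets = [self._random_net(rng, excluded=(1,)),
                self._random_net(rng, excluded=(3, 4))]
        avg = networks.average_condition_network(nets, "rtp")
        assert set(avg.excluded_nodes) == {1, 3, 4}
        assert np.all(avg.weights[[1, 3, 4]] == 0)

    def test_order_invariance(self, rng):
        nets = [self._random_net(rng) for _ in range(4)]
        a = networks.average_condition_network(nets, "ctp")
        b = networks.average_condition_network(nets[::-1], "ctp")
        np.testing.assert_allclose(a.weights, b.weights)

    def test_weights_in_unit_interval(self, rng):
        nets = [self._random_net(rng) for _ in range(3)]
        avg = networks.average_condition_network(nets, "ctp")
        off = avg.weights[np.triu_indices(8, 1)]
        assert np.all(off >= 0) and np.all(off <= 1)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            networks.average_condition_network([], "ctp")


@pytest.fixture(scope="module")
def noiseless_task():
    cfg = SyntheticSceneConfig(grid_shape=(12, 14, 12), roi_n_voxels=60,
                               noise_sd=0.0, drift_slope=0.0,
                               motion_coupling=0.0, seed=3)
    rng = np.random.default_rng(42)
    truth = default_beta_truth(cfg, rng)
    ds = generate_task_run(cfg, beta_truth=truth)
    return cfg, truth, ds


class TestGlmBetaSeries:
    def test_noiseless_recovery_to_numerical_precision(self, noiseless_task):
        cfg, truth, ds = noiseless_task
        run = pp.discard_initial_volumes(ds.bold, 5)
        betas = networks.glm_beta_series(run, ds.events)
        assert betas.trial_betas.shape[0] == 18
        for cond in ("creative", "control"):
            np.testing.assert_allclose(betas.condition_means[cond],
                                       truth[cond], atol=1e-8)

    def test_zero_run_zero_betas(self, noiseless_task):
        _, _, ds = noiseless_task
        run = BoldRun(np.zeros((4, 4, 4, 380)), 2.0, provenance="task",
                      n_discarded=5)
        betas = networks.glm_beta_series(run, ds.events)
        np.testing.assert_allclose(betas.trial_betas, 0.0, atol=1e-12)

    def test_trial_order_permutation_invariance(self, noiseless_task, rng):
        _, _, ds = noiseless_task
        run = pp.discard_initial_volumes(ds.bold, 5)
        base = networks.glm_beta_series(run, ds.events)
        shuffled = ds.events.sample(frac=1.0, random_state=1).reset_index(drop=True)
        perm = networks.glm_beta_series(run, shuffled)
        np.testing.assert_allclose(base.trial_betas, perm.trial_betas,
                                   atol=1e-10)

    def test_overlapping_trials_rejected(self, noiseless_task):
        _, _, ds = noiseless_task
        run = pp.discard_initial_volumes(ds.bold, 5)
        events = ds.events.copy()
        events.loc[1, "onset_s"] = events.loc[0, "onset_s"] + 5.0
        with pytest.raises(ValueError, match="overlap"):
            networks.glm_beta_series(run, events)


class TestTaskConditionNetwork:
    def test_equal_beta_maps_identical_networks(self, rng):
        parc = networks.build_cube_parcellation(_solid_mask((6, 6, 6)))
        vol = rng.standard_normal((6, 6, 6))
        betas = networks.BetaImageSet(
            trial_betas=np.stack([vol, vol]), conditions=["creative", "control"],
            condition_means={"creative": vol, "control": vol})
        a, b = networks.task_condition_network(betas, parc)
        np.testing.assert_allclose(a.weights, b.weights)
        assert a.condition == "creative" and b.condition == "control"

    def test_zero_variance_exclusion_mirrored(self, rng):
        parc = networks.build_cube_parcellation(_solid_mask((6, 6, 6)))
        v1 = rng.standard_normal((6, 6, 6))
        v2 = rng.standard_normal((6, 6, 6))
        v1.ravel()[parc.voxel_ids[2]] = 7.0  # constant cube in creative only
        betas = networks.BetaImageSet(
            trial_betas=np.stack([v1, v2]), conditions=["creative", "control"],
            condition_means={"creative": v1, "control": v2})
        a, b = networks.task_condition_network(betas, parc)
        assert 2 in a.excluded_nodes and 2 in b.excluded_nodes
        assert np.all(b.weights[2] == 0)

    def test_condition_specific_structure_strengthens_edges(self, rng):
        # planted covariance between two cube patterns in one condition only
        parc = networks.build_cube_parcellation(_solid_mask((6, 6, 6)))
        shared = rng.standard_normal(27)
        v_struct = rng.standard_normal((6, 6, 6))
        v_struct.ravel()[parc.voxel_ids[0]] = shared + 0.1 * rng.standard_normal(27)
        v_struct.ravel()[parc.voxel_ids[1]] = shared + 0.1 * rng.standard_normal(27)
        v_plain = rng.standard_normal((6, 6, 6))
        betas = networks.BetaImageSet(
            trial_betas=np.stack([v_struct, v_plain]),
            conditions=["creative", "control"],
            condition_means={"creative": v_struct, "control": v_plain})
        a, b = networks.task_condition_network(betas, parc)
        assert a.weights[0, 1] > b.weights[0, 1] + 0.5


def test_canonical_hrf_matches_nilearn_reference():
    """Double-gamma HRF agrees with nilearn's SPM HRF up to normalisation."""
    nilearn_hrf = pytest.importorskip(
        "nilearn.glm.first_level.hemodynamic_models")
    theirs = nilearn_hrf.spm_hrf(1.0, oversampling=100, time_length=32.0)
    t_theirs = np.linspace(0.0, 32.0, len(theirs))
    theirs = theirs / theirs.max()
    ours = canonical_hrf(0.01)
    ours_interp = np.interp(t_theirs, np.arange(len(ours)) * 0.01, ours)
    np.testing.assert_allclose(ours_interp, theirs, atol=5e-3)
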