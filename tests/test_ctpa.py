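from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from ctpnet import ctpa, preprocess as pp
from ctpnet.base import BoldRun, MaskVolume
from ctpnet.synthetic import SyntheticSceneConfig, generate_resting_run


class TestSelectSampledTimepoints:
    def test_reference_sampling(self):
        idx = ctpa.select_sampled_timepoints(170, 5)
        assert len(idx) == 34
        assert idx[0] == 1 and idx[-1] == 166
        assert np.all(np.diff(idx) == 5)

    @pytest.mark.parametrize("n,stride,expected", [(1, 5, [1]),
                                                   (12, 5, [1, 6, 11]),
                                                   (10, 1, list(range(1, 11)))])
    def test_small_enumerations(self, n, stride, expected):
        np.testing.assert_array_equal(
            ctpa.select_sampled_timepoints(n, stride), expected)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            ctpa.select_sampled_timepoints(0, 5)


def _roi_run(ts, tr=2.0):
    """Build a run + mask whose ROI voxels carry the given (V, T) series."""
    V, T = ts.shape
    data = np.zeros((V, 1, 1, T))
    data[:, 0, 0, :] = ts
    mask = np.ones((V, 1, 1), bool)
    return BoldRun(data, tr), MaskVolume(mask)


class TestZscoreRoi:
    def test_closed_form_standardization(self):
        run, roi = _roi_run(np.array([[1.0, 2.0, 3.0]]))
        z = ctpa.zscore_roi(run, roi, np.array([1, 2, 3]))
        np.testing.assert_allclose(z.z[0], [-1.0, 0.0, 1.0])

    def test_constant_voxel_excluded(self):
        ts = np.vstack([np.arange(10.0), np.full(10, 4.0)])
        run, roi = _roi_run(ts)
        z = ctpa.zscore_roi(run, roi, np.arange(1, 11))
        assert z.roi_n_voxels == 1
        assert z.n_excluded_voxels == 1

    def test_gaussian_exceedance_rate(self, rng):
        # Monte-Carlo against 1 - Phi(2) = 0.02275
        ts = rng.standard_normal((700, 170))
        run, roi = _roi_run(ts)
        z = ctpa.zscore_roi(run, roi, np.arange(1, 171))
        frac = (z.z > 2).mean()
        assert abs(frac - 0.02275) < 0.002

    def test_sampled_index_out_of_range(self):
        run, roi = _roi_run(np.random.default_rng(0).standard_normal((3, 10)))
        with pytest.raises(ValueError):
            ctpa.zscore_roi(run, roi, np.array([11]))


def _zseries(supra_sets, roi_n, n_pts=None, sampled=None):
    """Build a ZScoreSeries whose suprathreshold sets are exactly as given."""
    n_pts = n_pts or len(supra_sets)
    z = np.zeros((roi_n, n_pts))
    for j, s in enumerate(supra_sets):
        for v in s:
            z[v, j] = 3.0
    sampled = sampled if sampled is not None else np.arange(1, n_pts + 1)
    return ctpa.ZScoreSeries(z=z, sampled_indices=np.asarray(sampled),
                             roi_n_voxels=roi_n, voxel_ids=np.arange(roi_n))


class TestClassifyTimepoints:
    def test_hand_traced_example(self):
        # ROI of 200 voxels -> count bound 5. A:10, B:8 disjoint, C:6 with
        # 2/6 = 33% shared with A|B, D:6 with 1/6 = 16.7% shared, E:4.
        A = set(range(0, 10))
        B = set(range(10, 18))
        C = {0, 10, 30, 31, 32, 33}          # 2 of 6 in A|B
        D = {1, 40, 41, 42, 43, 44}          # 1 of 6 in the accepted union
        E = {50, 51, 52, 53}
        cls = ctpa.classify_timepoints(_zseries([A, B, C, D, E], roi_n=200))
        assert set(cls.ctp_indices) == {1, 2, 3}
        assert set(cls.rtp_indices) == {4, 5}

    def test_all_counts_below_bound(self):
        sets = [{0}, {1}, {2, 3}]
        cls = ctpa.classify_timepoints(_zseries(sets, roi_n=200))
        assert cls.n_ctp == 0
        assert cls.top2_failed
        assert set(cls.rtp_indices) == {1, 2, 3}

    def test_top2_rule_requires_both(self):
        # one large point alone is not enough to seed the CTP set
        sets = [set(range(30)), {40}, {41}]
        cls = ctpa.classify_timepoints(_zseries(sets, roi_n=200))
        assert cls.n_ctp == 0 and cls.top2_failed

    def test_order_invariance(self, rng):
        sets = [set(rng.choice(100, size=rng.integers(0, 15), replace=False))
                for _ in range(12)]
        base = ctpa.classify_timepoints(_zseries(sets, roi_n=100))
        perm = rng.permutation(12)
        shuffled = ctpa.classify_timepoints(
            _zseries([sets[j] for j in perm], roi_n=100,
                     sampled=np.arange(1, 13)[perm]))
        assert set(base.ctp_indices) == set(shuffled.ctp_indices)

    def test_empty_roi_rejected(self):
        z = _zseries([{0}], roi_n=1)
        z.roi_n_voxels = 0
        with pytest.raises(ValueError):
            ctpa.classify_timepoints(z)


def _oracle_classify(sets, counts, roi_n, sampled, frac=0.025, overlap=0.30):
    """Independent set-logic re-implementation of the CTP acceptance rules."""
    n = len(sets)
    order = sorted(range(n), key=lambda j: (-counts[j], sampled[j]))
    bound = frac * roi_n
    if n < 2 or counts[order[0]] <= bound or counts[order[1]] <= bound:
        return set()
    ctps = {order[0], order[1]}
    union = sets[order[0]] | sets[order[1]]
    for j in order[2:]:
        if counts[j] > bound and sets[j] and \
                len(sets[j] & union) / len(sets[j]) > overlap:
            ctps.add(j)
            union = union | sets[j]
    return {sampled[j] for j in ctps}


def test_classifier_matches_bruteforce_oracle_on_random_instances(rng):
    """Production classifier == independent set-logic oracle, 1000 instances."""
    for _ in range(1000):
        roi_n = int(rng.integers(20, 60))
        n_pts = int(rng.integers(2, 14))
        sets = [set(rng.choice(roi_n, size=rng.integers(0, roi_n // 2),
                               replace=False)) for _ in range(n_pts)]
        sampled = np.arange(1, n_pts + 1)
        cls = ctpa.classify_timepoints(_zseries(sets, roi_n=roi_n))
        expected = _oracle_classify(sets, [len(s) for s in sets], roi_n, sampled)
        assert set(cls.ctp_indices) == expected


class TestPlantedEventRecovery:
    EVENTS = (16, 41, 66, 91, 116, 141)

    @staticmethod
    def _detect(seed, amplitude):
        cfg = SyntheticSceneConfig(event_times=TestPlantedEventRecovery.EVENTS,
                                   event_amplitude=amplitude,
                                   event_extent_frac=0.10, noise_sd=1.0,
                                   seed=seed)
        ds = generate_resting_run(cfg)
        # temporal chain only: the generator's noise field is already
        # spatially smooth, so no additional spatial smoothing is applied
        run = pp.discard_initial_volumes(ds.bold, 10)
        run = pp.detrend_bandpass(run)
        sampled = ctpa.select_sampled_timepoints(run.n_volumes, 5)
        cls = ctpa.classify_timepoints(ctpa.zscore_roi(run, ds.roi_mask, sampled))
        return set(cls.ctp_indices)

    def test_recovery_sensitivity_at_amplitude_four(self):
        """>= 90% of planted event indices recovered as CTPs over 50 seeds."""
        hits = total = 0
        for seed in range(50):
            detected = self._detect(seed, 4.0)
            hits += len(detected & set(self.EVENTS))
            total += len(self.EVENTS)
        assert hits / total >= 0.9

    def test_detection_monotone_in_amplitude(self):
        """Raising the event amplitude never lowers mean detected CTP count."""
        means = []
        for amp in (0.0, 2.0, 4.0):
            means.append(np.mean([len(self._detect(seed, amp))
                                  for seed in range(8)]))
        assert means[0] <= means[1] + 0.5 and means[1] <= means[2] + 0.5


class TestSubjectContrastMap:
    def _cls(self, ctp, rtp, n_total):
        sampled = np.arange(1, n_total + 1)
        return ctpa.TimePointClassification(
            ctp_indices=np.asarray(ctp), rtp_indices=np.asarray(rtp),
            sampled_indices=sampled, counts=np.zeros(n_total, int),
            supra_sets=[frozenset()] * n_total, roi_n_voxels=10)

    def test_identical_groups_zero_map(self, rng):
        vol = rng.standard_normal((3, 3, 3))
        data = np.repeat(vol[..., None], 8, axis=3)
        res = ctpa.subject_contrast_map(BoldRun(data, 2.0),
                                        self._cls([1, 2, 3, 4], [5, 6, 7, 8], 8))
        np.testing.assert_allclose(res.t_map, 0.0)
        np.testing.assert_allclose(res.mean_diff_map, 0.0)

    def test_separated_groups_large_positive_statistic(self, rng):
        data = np.ones((2, 2, 2, 6))
        data[..., :3] = 3.0
        data += rng.standard_normal(data.shape) * 1e-3
        res = ctpa.subject_contrast_map(BoldRun(data, 2.0),
                                        self._cls([1, 2, 3], [4, 5, 6], 6))
        assert np.all(res.t_map > 100)
        np.testing.assert_allclose(res.mean_diff_map, 2.0, atol=0.01)

    def test_statistic_follows_t_distribution(self, rng):
        # distributional oracle: equal-variance normal volumes, Welch t ~ t(df)
        n1, n2 = 10, 10
        data = rng.standard_normal((22, 22, 22, n1 + n2))
        res = ctpa.subject_contrast_map(
            BoldRun(data, 2.0),
            self._cls(list(range(1, n1 + 1)),
                      list(range(n1 + 1, n1 + n2 + 1)), n1 + n2))
        tvals = res.t_map.ravel()
        ks = stats.kstest(tvals, "t", args=(n1 + n2 - 2,)).statistic
        assert ks < 0.02

    def test_too_few_points_rejected(self, rng):
        data = rng.standard_normal((2, 2, 2, 5))
        with pytest.raises(ctpa.SubjectExcludedError):
            ctpa.subject_contrast_map(BoldRun(data, 2.0),
                                      self._cls([1], [2, 3, 4, 5], 5))


class TestGroupCtpMap:
    def test_single_subject_rejected(self, rng):
        with pytest.raises(ValueError):
            ctpa.group_ctp_map([rng.standard_normal((4, 4, 4))])

    def test_null_contrasts_rarely_yield_clusters(self, rng):
        # null calibration: 16 Gaussian contrast maps, expect no surviving
        # clusters in nearly every replicate
        n_with_cluster = 0
        for _ in range(100):
            contrasts = [rng.standard_normal((12, 12, 12)) for _ in range(16)]
            gmap = ctpa.group_ctp_map(contrasts)
            n_with_cluster += bool(gmap.surviving_clusters)
        assert n_with_cluster <= 5

    @staticmethod
    def _planted(rng, n_voxels_effect):
        effect = np.zeros((14, 14, 14), bool)
        coords = np.argwhere(np.ones((14, 14, 14)))
        center = np.array([7, 7, 7])
        d = ((coords - center) ** 2).sum(axis=1)
        chosen = coords[np.argsort(d)[:n_voxels_effect]]
        effect[tuple(chosen.T)] = True
        contrasts = []
        for _ in range(16):
            c = rng.standard_normal((14, 14, 14))
            c[effect] += 2.0  # Cohen's d = 2
            contrasts.append(c)
        return effect, contrasts

    def test_sixty_voxel_effect_recovered(self, rng):
        effect, contrasts = self._planted(rng, 60)
        gmap = ctpa.group_ctp_map(contrasts)
        assert gmap.surviving_clusters
        coords, _, peak_t = gmap.surviving_clusters[0]
        found = np.zeros_like(effect)
        found[tuple(coords.T)] = True
        assert (found & effect).sum() >= 0.8 * effect.sum()
        assert peak_t > 0

    def test_forty_voxel_effect_removed_by_extent_rule(self, rng):
        effect, contrasts = self._planted(rng, 40)
        gmap = ctpa.group_ctp_map(contrasts)
        # voxelwise the effect is overwhelmingly significant, but the
        # component has <= 50 voxels, so the extent rule removes it
        assert np.abs(gmap.stat_volume[effect]).min() > 4
        assert not gmap.surviving_clusters

    def test_all_zero_contrasts_empty_map(self):
        gmap = ctpa.group_ctp_map([np.zeros((6, 6, 6)) for _ in range(4)])
        assert not gmap.surviving_clusters
        np.testing.assert_allclose(gmap.stat_volume, 0.0)
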