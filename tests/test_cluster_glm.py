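"""Timepoint GLM, cluster permutation machinery and the conflict contrast."""

import numpy as np
import pytest

from stnseq import (
    AccumulatorParams,
    AgentSpec,
    NeuralSimSpec,
    build_design,
    contrast_cluster_test,
    continuous_band_power,
    epoch_power,
    glm_cluster_test,
    group_cluster_test,
    highpass_power,
    regressor_table,
    same_different_contrast,
    simulate_behavior,
    simulate_recording,
    timepoint_glm,
)


class TestTimepointGLM:
    def test_exact_fit_caps_t(self, rng):
        X = rng.standard_normal((40, 3))
        X = (X - X.mean(0)) / X.std(0)
        Y = np.outer(X[:, 0], np.ones(5))  # power identically regressor 0
        res = timepoint_glm(Y, X)
        assert np.all(res.t[0] >= 1e6)
        assert np.all(np.abs(res.coef[1:]) < 1e-10)  # other regressors ~0

    def test_injected_weights_recovered_in_sign(self, rng):
        n, T = 300, 10
        X = rng.standard_normal((n, 4))
        X = np.linalg.qr(X)[0] * np.sqrt(n)  # orthonormal columns, unit SD
        w = np.array([1.0, 0.0, 0.5, -0.5])
        Y = X @ np.outer(w, np.ones(T)) + 0.5 * rng.standard_normal((n, T))
        res = timepoint_glm(Y, X)
        assert np.all(res.coef[0] > 0)
        assert np.all(res.coef[2] > 0)
        assert np.all(res.coef[3] < 0)
        assert np.all(np.abs(res.coef[1]) < np.abs(res.coef[2]))

    def test_invariant_to_constant_offset(self, rng):
        X = rng.standard_normal((60, 2))
        Y = rng.standard_normal((60, 8))
        a = timepoint_glm(Y, X)
        b = timepoint_glm(Y + 7.5, X)
        np.testing.assert_allclose(a.coef, b.coef, atol=1e-10)

    def test_rank_deficiency_reported(self, rng):
        X = rng.standard_normal((50, 2))
        X = np.column_stack([X, X[:, 0]])  # duplicate column
        with pytest.raises(ValueError, match="collinear"):
            timepoint_glm(rng.standard_normal((50, 4)), X, names=["a", "b", "a_copy"])

    def test_minimum_epochs_enforced(self, rng):
        with pytest.raises(ValueError):
            timepoint_glm(rng.standard_normal((12, 4)), rng.standard_normal((12, 4)))


class TestContrastClusterTest:
    def test_pvalue_bounds(self, rng):
        n = 80
        labels = np.zeros(n, bool)
        labels[:40] = True
        # huge effect: observed mass above every permuted maximum
        Y = rng.standard_normal((n, 20))
        Y[labels, 5:15] += 5.0
        res = contrast_cluster_test(Y, labels, n_perm=200, rng=rng)
        assert res.clusters[0].p_fwe == pytest.approx(1.0 / 201.0)
        # no effect at all: any incidental cluster has large p
        Y0 = rng.standard_normal((n, 20))
        res0 = contrast_cluster_test(Y0, labels, n_perm=200, rng=rng)
        for c in res0.clusters:
            assert c.p_fwe > 0.05

    def test_degenerate_constant_series(self, rng):
        labels = np.zeros(40, bool)
        labels[:20] = True
        res = contrast_cluster_test(np.ones((40, 10)), labels, n_perm=100, rng=rng)
        assert res.clusters == []

    def test_low_permutation_count_warns(self, rng):
        labels = np.zeros(40, bool)
        labels[:20] = True
        with pytest.warns(UserWarning):
            contrast_cluster_test(np.random.default_rng(0).standard_normal((40, 5)),
                                  labels, n_perm=50, rng=rng)

    def test_mass_sign_flips_with_data(self, rng):
        labels = np.zeros(60, bool)
        labels[:30] = True
        Y = rng.standard_normal((60, 15))
        Y[labels, 4:9] += 1.5
        a = contrast_cluster_test(Y, labels, n_perm=300, rng=np.random.default_rng(3))
        b = contrast_cluster_test(-Y, labels, n_perm=300, rng=np.random.default_rng(3))
        assert a.clusters[0].mass == pytest.approx(-b.clusters[0].mass, rel=1e-9)
        assert a.clusters[0].sign == -b.clusters[0].sign

    def test_fwe_calibration_quick(self):
        """Type-I error of the max-mass correction on independent epochs."""
        rng = np.random.default_rng(7)
        labels = np.zeros(60, bool)
        labels[:30] = True
        hits = 0
        n_sim = 150
        for _ in range(n_sim):
            Y = rng.standard_normal((60, 27))
            hits += contrast_cluster_test(Y, labels, n_perm=500, rng=rng).any_significant(0.05)
        assert 0.005 <= hits / n_sim <= 0.105

    def test_matches_mne_reference_clusters(self):
        """Observed clusters and masses agree with the mne implementation."""
        mne = pytest.importorskip("mne")
        from mne.stats import permutation_cluster_test, ttest_ind_no_p

        rng = np.random.default_rng(12)
        a = rng.standard_normal((35, 30))
        b = rng.standard_normal((33, 30))
        a[:, 8:16] += 0.9
        labels = np.r_[np.ones(35, bool), np.zeros(33, bool)]
        Y = np.vstack([a, b])
        ours = contrast_cluster_test(Y, labels, n_perm=1000, rng=1)

        def stat_fun(x, y):
            return ttest_ind_no_p(x, y)

        t_obs, clusters, pvals, _ = permutation_cluster_test(
            [a, b], threshold=ours.threshold, n_permutations=1000,
            stat_fun=stat_fun, tail=0, seed=5, verbose=False, out_type="mask",
        )
        np.testing.assert_allclose(ours.stat, t_obs, atol=1e-8)
        ours_masses = sorted(round(abs(c.mass), 4) for c in ours.clusters)
        mne_masses = sorted(round(abs(t_obs[m].sum()), 4) for m in clusters)
        assert ours_masses == mne_masses
        p_ours = min(c.p_fwe for c in ours.clusters)
        assert abs(p_ours - pvals.min()) < 0.05


class TestGLMClusterTest:
    def _data(self, effect, rng, n=250, T=27):
        X = rng.standard_normal((n, 4))
        X = (X - X.mean(0)) / X.std(0)
        Y = rng.standard_normal((n, T))
        if effect:
            Y[:, 8:14] += 0.6 * X[:, [1]]
        return Y, X

    def test_detects_injected_regressor_effect(self, rng):
        Y, X = self._data(True, rng)
        res = glm_cluster_test(Y, X, 1, n_perm=400, rng=3)
        sig = res.significant(0.05)
        assert sig and any(c.mask[8:14].any() for c in sig)
        assert res.significant(0.05)[0].cohen_d != 0

    def test_null_regressor_clean(self, rng):
        Y, X = self._data(False, rng)
        res = glm_cluster_test(Y, X, 2, n_perm=400, rng=4)
        assert not res.any_significant(0.01)

    def test_freedman_lane_agrees_with_row_shuffle(self, rng):
        Y, X = self._data(True, rng)
        a = glm_cluster_test(Y, X, 1, n_perm=300, rng=5, scheme="row_shuffle")
        b = glm_cluster_test(Y, X, 1, n_perm=300, rng=5, scheme="freedman_lane")
        np.testing.assert_allclose(a.stat, b.stat, atol=1e-10)  # same observed t
        assert a.clusters[0].p_fwe < 0.05 and b.clusters[0].p_fwe < 0.05


def test_group_sign_flip_detects_and_controls(rng):
    effect = 0.8 + 0.3 * rng.standard_normal((12, 27))
    res = group_cluster_test(effect, n_perm=500, rng=2)
    assert res.any_significant(0.05)
    null = rng.standard_normal((12, 27))
    res0 = group_cluster_test(null, n_perm=500, rng=2)
    for c in res0.clusters:
        assert c.p_fwe > 0.01


@pytest.fixture(scope="module")
def pipeline_run(task_cfg):
    def run(seed, null):
        trials = simulate_behavior(task_cfg, AgentSpec(), 48, seed)
        reg = regressor_table(trials, AccumulatorParams("M1"), task_cfg.validity)
        spec = NeuralSimSpec(
            b_same_diff=0.0 if null else 0.6,
            b_absev=0.0 if null else 0.3,
            b_cuenum=0.0 if null else -0.3,
            coupling="none",
        )
        rec = simulate_recording(trials, reg, spec, seed + 1000)
        pts = highpass_power(continuous_band_power(rec, "beta"))
        ep = epoch_power(pts, rec.markers, channel="stn")
        return same_different_contrast(ep, reg, n_perm=800, rng=seed + 2000), reg

    return run


class TestSameDifferentContrast:
    def test_dip_then_rise_recovered(self, pipeline_run):
        res, _ = pipeline_run(3, null=False)
        sig = res.cluster.significant(0.05)
        assert sig
        early = (res.times >= 0.10) & (res.times <= 0.45)
        late = (res.times >= 0.60) & (res.times <= 1.50)
        assert res.difference[early].mean() < 0
        assert res.difference[late].mean() > 0
        assert any(c.sign < 0 and c.mask[early].any() for c in sig)
        assert any(c.sign > 0 and c.mask[late].any() for c in sig)

    def test_null_generator_typically_clean(self, pipeline_run):
        hits = sum(
            pipeline_run(seed, null=True)[0].cluster.any_significant(0.05)
            for seed in range(5)
        )
        assert hits <= 1

    def test_design_matrix_standardized(self, demo_beta_epochs, demo_regressors):
        Y, X, names = build_design(demo_beta_epochs, demo_regressors)
        assert names == ["cue_identity", "bayes_norm", "abs_evidence", "cue_number"]
        np.testing.assert_allclose(X.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(X.std(axis=0), 1.0, atol=1e-9)
        assert Y.shape[0] == X.shape[0]

    def test_condition_minimum_enforced(self, demo_beta_epochs, demo_regressors):
        with pytest.raises(ValueError):
            same_different_contrast(
                demo_beta_epochs, demo_regressors, min_epochs=10**6, n_perm=100
            )
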