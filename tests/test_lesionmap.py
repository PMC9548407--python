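"""Lesion mapping: masks, Fisher tests, VBCM, residualization, RVR."""

import numpy as np
import pytest
from scipy import stats

from battkit import lesionmap as lm
from battkit import synthgen as sg


def blob_volumes(n, shape=(8, 8, 8), seed=0):
    rng = np.random.default_rng(seed)
    latent = sg.LatentProfile(rng.standard_normal((n, 2)), ["a", "b"])
    atlas = sg.default_atlas(shape, 2)
    vols, _ = sg.simulate_abnormality(latent, atlas, seed=seed + 1)
    return vols


class TestBuildMask:
    def test_boundary_inclusive(self):
        base = np.zeros((2, 2, 2))
        vols = []
        for i in range(40):
            v = base.copy()
            if i < 4:
                v[0, 0, 0] = 0.9  # abnormal in exactly 4/40 = 10%
            if i < 3:
                v[1, 0, 0] = 0.9  # 3/40 = 7.5%
            v[1, 1, 1] = 0.9      # everyone
            vols.append(v)
        mask = lm.build_mask(vols, threshold=0.10, binarize_at=0.5)
        assert mask.mask[0, 0, 0]          # exactly at threshold → included
        assert not mask.mask[1, 0, 0]      # below threshold → excluded
        assert mask.mask[1, 1, 1]

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            lm.build_mask([np.zeros((3, 3, 3))] * 4, binarize_at=0.5)


class TestFisherVoxelCompare:
    def test_identical_proportions_p_one(self):
        v_damaged = np.ones((2, 2, 2))
        v_intact = np.zeros((2, 2, 2))
        group = [v_damaged] * 5 + [v_intact] * 5
        mask = lm.build_mask(group, threshold=0.1, binarize_at=0.5)
        p = lm.fisher_voxel_compare(group, list(group), mask)
        np.testing.assert_allclose(p[mask.mask], 1.0)

    def test_matches_hypergeometric_enumeration(self):
        """p for a (10/20 vs 0/20) table equals exhaustive enumeration."""
        v1, v0 = np.ones((1, 1, 1)), np.zeros((1, 1, 1))
        a = [v1] * 10 + [v0] * 10
        b = [v0] * 20
        mask = lm.AnalysisMask(np.ones((1, 1, 1), bool), 0.1, 0.5)
        p = lm.fisher_voxel_compare(a, b, mask)[0, 0, 0]
        # enumeration: sum of hypergeometric point masses no larger than observed
        N, K, n = 40, 10, 20
        obs = stats.hypergeom.pmf(10, N, K, n)
        p_enum = sum(stats.hypergeom.pmf(x, N, K, n)
                     for x in range(0, min(K, n) + 1)
                     if stats.hypergeom.pmf(x, N, K, n) <= obs + 1e-12)
        assert p == pytest.approx(p_enum, abs=1e-10)

    def test_group_swap_symmetry(self):
        vols = blob_volumes(20)
        binv = [(v >= 0.3).astype(float) for v in vols]
        mask = lm.build_mask(vols)
        a, b = binv[:12], binv[12:]
        p1 = lm.fisher_voxel_compare(a, b, mask)
        p2 = lm.fisher_voxel_compare(b, a, mask)
        np.testing.assert_allclose(p1[mask.mask], p2[mask.mask])


class TestVBCM:
    def test_single_voxel_t_matches_closed_form(self):
        rng = np.random.default_rng(0)
        n = 25
        score = rng.standard_normal(n)
        y = 0.5 - 0.3 * score + 0.1 * rng.standard_normal(n)
        y = np.clip(y, 0, 1)
        vols = [np.full((1, 1, 1), yi) for yi in y]
        mask = lm.AnalysisMask(np.ones((1, 1, 1), bool), 0.1, 0.5)
        maps = lm.vbcm(vols, score[:, None], n_perm=10, seed=0, mask=mask)
        t_got = maps["C1"].t_map[0, 0, 0]
        res = stats.linregress(score, y)
        t_expected = res.slope / res.stderr
        assert t_got == pytest.approx(t_expected, rel=1e-10)

    def test_t_invariant_to_covariate_rescaling(self):
        rng = np.random.default_rng(1)
        n = 30
        vols = blob_volumes(n, seed=2)
        mask = lm.build_mask(vols)
        score = rng.standard_normal((n, 1))
        cov = rng.standard_normal(n)
        m1 = lm.vbcm(vols, score, covariates=cov, n_perm=5, seed=0, mask=mask)
        m2 = lm.vbcm(vols, score, covariates=100 * cov + 7, n_perm=5, seed=0, mask=mask)
        np.testing.assert_allclose(m1["C1"].t_map[mask.mask],
                                   m2["C1"].t_map[mask.mask], atol=1e-8)

    def test_permutation_seed_determinism(self):
        n = 30
        vols = blob_volumes(n, seed=3)
        mask = lm.build_mask(vols)
        rng = np.random.default_rng(4)
        score = rng.standard_normal((n, 1))
        m1 = lm.vbcm(vols, score, n_perm=50, seed=9, mask=mask)
        m2 = lm.vbcm(vols, score, n_perm=50, seed=9, mask=mask)
        assert [c["fwe_p"] for c in m1["C1"].clusters] == \
               [c["fwe_p"] for c in m2["C1"].clusters]

    def test_rank_deficient_design_errors(self):
        vols = blob_volumes(20, seed=5)
        score = np.ones((20, 2))  # collinear with intercept and each other
        with pytest.raises(ValueError, match="collinear|rank"):
            lm.vbcm(vols, score, n_perm=5, seed=0)


class TestNiftiIO:
    def test_volume_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        vol = rng.uniform(0, 1, (6, 6, 6)).astype(np.float32)
        path = tmp_path / "vol.nii"
        lm.save_volume(vol, path)
        back = lm.load_volume(path)
        np.testing.assert_allclose(back, vol, atol=1e-7)


class TestResidualize:
    def test_projection_properties(self):
        rng = np.random.default_rng(0)
        cov = rng.standard_normal((50, 2))
        y = rng.standard_normal(50)
        res = lm.residualize(y, cov)
        assert np.abs(res @ cov).max() < 1e-8
        np.testing.assert_allclose(lm.residualize(res, cov), res, atol=1e-10)
        np.testing.assert_allclose(lm.residualize(cov[:, 0], cov), 0, atol=1e-10)


class TestRVR:
    def test_perfect_signal(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 5))
        y = X[:, 0].copy()
        fit = lm.rvr_predict_loocv(X, y, n_perm=50, seed=1)
        assert fit.cv_r > 0.99
        assert fit.permutation_p == pytest.approx(1 / 51)  # minimum attainable

    def test_posterior_mean_equals_ridge_closed_form(self):
        rng = np.random.default_rng(1)
        Phi = np.column_stack([np.ones(30), rng.standard_normal((30, 5))])
        y = rng.standard_normal(30)
        alpha = np.array([0.5, 1, 2, 3, 4, 5.0])
        beta = 2.0
        mu = lm.rvr_posterior_mean(Phi, y, alpha, beta)
        ridge = np.linalg.solve(beta * Phi.T @ Phi + np.diag(alpha),
                                beta * Phi.T @ y)
        np.testing.assert_allclose(mu, ridge, atol=1e-10)

    def test_agrees_with_ard_crosscheck(self):
        """Independent sparse-Bayes implementation finds the same signal."""
        from sklearn.linear_model import ARDRegression
        rng = np.random.default_rng(2)
        X = rng.standard_normal((60, 6))
        y = X @ np.array([1.5, 0, 0, -2.0, 0, 0]) + 0.05 * rng.standard_normal(60)
        ard = ARDRegression(fit_intercept=True).fit(X, y)
        w, _, _, _ = lm._rvr_core(np.column_stack([np.ones(60), X]), y)
        np.testing.assert_allclose(w[1:], ard.coef_, atol=0.05)

    def test_constant_target_errors(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            lm.rvr_predict_loocv(rng.standard_normal((12, 4)), np.ones(12),
                                 n_perm=0, seed=0)

    def test_pruned_weights_exactly_zero(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((40, 4))
        y = X[:, 0] + 0.1 * rng.standard_normal(40)
        fit = lm.rvr_fit(X, y)
        pruned = fit.alpha >= 1e9
        assert np.all(fit.weights[pruned] == 0.0)

    def test_signal_beats_shuffled_target(self, cohort, fitted_model):
        """cv_r on a signal-bearing cohort exceeds cv_r after shuffling."""
        latent, _, _ = cohort
        _, _, comp = fitted_model
        atlas = sg.default_atlas((12, 12, 12), 4)
        vols, _ = sg.simulate_abnormality(latent, atlas, seed=8)
        mask = lm.build_mask(vols)
        feats = lm.volumes_to_matrix(vols, mask.mask)
        y = comp.values[:, 0]
        fit = lm.rvr_predict_loocv(feats, y, n_perm=0, seed=0)
        rng = np.random.default_rng(0)
        fit_null = lm.rvr_predict_loocv(feats, y[rng.permutation(y.size)],
                                        n_perm=0, seed=0)
        assert fit.cv_r > fit_null.cv_r
        assert fit.cv_r > 0.5
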