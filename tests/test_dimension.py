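"""PCA machinery: standardisation, CV dimensionality, varimax, scores, LOO."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from battkit import dimension as dim
from battkit import synthgen as sg

from conftest import make_noiseless_scores


def toy_scores(values, names=None):
    values = np.asarray(values, dtype=float)
    return dim.ScoreMatrix(values, [f"P{i}" for i in range(values.shape[0])],
                           names or [f"T{j}" for j in range(values.shape[1])])


class TestStandardize:
    def test_symmetric_column_n_minus_1(self):
        z = dim.standardize(toy_scores([[50, 50], [70, 60], [90, 70]]))
        np.testing.assert_allclose(z.values[:, 0], [-1, 0, 1])  # sd = 20 (n−1)

    def test_zero_variance_error_names_test(self):
        with pytest.raises(ValueError, match="Tbad"):
            dim.standardize(toy_scores([[50, 10], [50, 20]], names=["Tbad", "T1"]))

    def test_self_reference_centres_columns(self):
        rng = np.random.default_rng(0)
        z = dim.standardize(toy_scores(rng.uniform(20, 90, (40, 6))))
        np.testing.assert_allclose(z.values.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(z.values.std(axis=0, ddof=1), 1, atol=1e-10)

    def test_external_reference_used(self):
        sm = toy_scores([[50.0], [70.0]])
        z = dim.standardize(sm, reference=(np.array([60.0]), np.array([10.0])))
        np.testing.assert_allclose(z.values[:, 0], [-1, 1])


class TestCrossvalComponentCount:
    def test_noiseless_rank2_exact(self):
        rng = np.random.default_rng(1)
        L = rng.uniform(0.4, 0.9, size=(6, 2))
        scores = make_noiseless_scores(20, L, seed=2)
        curve = dim.crossval_component_count(scores, folds=5, seed=0)
        assert curve.rmse_by_k[2] < 1e-6
        assert curve.k_selected == 2

    def test_fold_partition(self):
        rng = np.random.default_rng(3)
        folds = dim._fold_indices(10, 5, rng)
        allidx = np.concatenate(folds)
        assert sorted(allidx) == list(range(10))
        assert all(len(f) == 2 for f in folds)

    def test_modal_selection_recovers_four_factors(self, extensive_spec):
        ks = []
        for seed in range(10):
            _, scores, _ = sg.simulate_cohort(extensive_spec, 75, 4, seed=seed)
            ks.append(dim.crossval_component_count(scores, seed=seed).k_selected)
        assert np.bincount(ks).argmax() == 4

    def test_rejects_bad_args(self):
        scores = toy_scores(np.random.default_rng(0).uniform(10, 90, (6, 4)))
        with pytest.raises(ValueError):
            dim.crossval_component_count(scores, folds=7)
        with pytest.raises(ValueError):
            dim.crossval_component_count(scores, k_max=0)


class TestVarimax:
    def test_single_component_rotation_is_identity(self):
        rng = np.random.default_rng(0)
        scores = toy_scores(rng.uniform(10, 90, (30, 5)))
        z = dim.standardize(scores)
        model = dim.fit_rotated_pca(z, 1)
        np.testing.assert_allclose(np.abs(model.rotation), [[1.0]])
        unrotated = dim._pca_loadings(z.values, 1)
        np.testing.assert_allclose(np.abs(model.loadings), np.abs(unrotated),
                                   atol=1e-10)

    def test_matches_exhaustive_angle_oracle(self):
        """2-component toy: rotated loadings equal the grid-search optimum."""
        L0 = np.zeros((6, 2))
        L0[:3, 0] = 0.9
        L0[3:, 1] = 0.9
        theta0 = 0.3781  # on the 1e-4 grid
        c, s = np.cos(theta0), np.sin(theta0)
        mixed = L0 @ np.array([[c, -s], [s, c]])

        best_v, best_L = -np.inf, None
        for theta in np.arange(-0.5, 0.5, 1e-4):  # grid contains −theta0 exactly
            c, s = np.cos(theta), np.sin(theta)
            cand = mixed @ np.array([[c, -s], [s, c]])
            v = dim.varimax_criterion(cand)
            if v > best_v:
                best_v, best_L = v, cand

        rotated, R = dim.varimax(mixed)
        assert dim.varimax_criterion(rotated) >= best_v - 1e-10
        # align sign/permutation before comparing
        perm = np.argmax(np.abs(best_L.T @ rotated), axis=1)
        aligned = rotated[:, perm] * np.sign(np.sum(best_L * rotated[:, perm], axis=0))
        np.testing.assert_allclose(aligned, best_L, atol=1e-6)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_communalities_invariant(self, seed):
        rng = np.random.default_rng(seed)
        scores = toy_scores(rng.uniform(10, 90, (25, 8)))
        z = dim.standardize(scores)
        x = z.values
        L0 = dim._pca_loadings(x, 3)
        model = dim.fit_rotated_pca(z, 3)
        np.testing.assert_allclose(np.sum(L0**2, axis=1),
                                   model.communalities(), atol=1e-8)
        np.testing.assert_allclose(model.rotation.T @ model.rotation,
                                   np.eye(3), atol=1e-8)

    def test_k_exceeding_rank_errors(self):
        rng = np.random.default_rng(0)
        col = rng.uniform(20, 80, 10)
        vals = np.column_stack([col, col + 1, col + 2, rng.uniform(20, 80, 10)])
        with pytest.raises(ValueError, match="rank"):
            dim.fit_rotated_pca(dim.standardize(toy_scores(vals)), 4)


class TestComponentScores:
    def test_mean_patient_scores_zero(self, fitted_model):
        z, model, comp = fitted_model
        np.testing.assert_allclose(comp.values.mean(axis=0), 0, atol=1e-8)
        mean_row = dim.ZMatrix(np.zeros((1, z.values.shape[1])), ["m"],
                               z.test_names, z.reference_means, z.reference_sds)
        np.testing.assert_allclose(
            dim.component_scores(model, mean_row).values, 0, atol=1e-12)

    def test_noiseless_scores_recover_latents(self):
        L = np.zeros((8, 2))
        L[:4, 0] = [0.9, 0.8, 0.85, 0.7]
        L[4:, 1] = [0.9, 0.8, 0.85, 0.7]
        rng = np.random.default_rng(5)
        latent = rng.standard_normal((60, 2))
        latent -= latent.mean(axis=0)
        q, _ = np.linalg.qr(latent)          # exactly uncorrelated in-sample
        latent = q / q.std(axis=0, ddof=1)
        vals = np.clip(50 + 5 * latent @ L.T, 0, 100)
        scores = toy_scores(vals)
        z = dim.standardize(scores)
        model = dim.fit_rotated_pca(z, 2)
        comp = dim.component_scores(model, z)
        cors = np.abs(np.corrcoef(latent.T, comp.values.T)[:2, 2:])
        matched = cors.max(axis=1)
        np.testing.assert_allclose(matched, 1.0, atol=1e-6)

    def test_mismatched_tests_error(self, fitted_model):
        z, model, _ = fitted_model
        bad = dim.ZMatrix(z.values, z.patient_ids, list(reversed(z.test_names)),
                          z.reference_means, z.reference_sds)
        with pytest.raises(ValueError):
            dim.component_scores(model, bad)

    def test_invariant_to_test_column_order(self, cohort):
        """Scores are unchanged (up to sign/order) by shuffling test columns."""
        _, scores, _ = cohort
        rng = np.random.default_rng(11)
        perm = rng.permutation(scores.n_tests)
        shuffled = dim.ScoreMatrix(scores.values[:, perm], scores.patient_ids,
                                   [scores.test_names[j] for j in perm])
        c1 = dim.component_scores(*(lambda z: (dim.fit_rotated_pca(z, 4), z))(
            dim.standardize(scores)))
        c2 = dim.component_scores(*(lambda z: (dim.fit_rotated_pca(z, 4), z))(
            dim.standardize(shuffled)))
        cors = np.abs(np.corrcoef(c1.values.T, c2.values.T)[:4, 4:])
        assert np.all(cors.max(axis=1) > 1 - 1e-8)


class TestLooGeneralizability:
    def test_noiseless_near_perfect(self):
        rng = np.random.default_rng(2)
        L = rng.uniform(0.4, 0.9, size=(6, 2))
        scores = make_noiseless_scores(20, L, seed=4)
        assert dim.loo_generalizability(scores, 2) >= 0.999

    def test_pure_noise_near_zero(self):
        """No latent structure: LOO r hovers near 0 (mildly negative bias)."""
        rs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            scores = toy_scores(np.clip(rng.normal(60, 10, (200, 20)), 0, 100))
            rs.append(dim.loo_generalizability(scores, 1))
        assert abs(np.mean(rs)) < 0.1
        assert all(abs(r) < 0.3 for r in rs)


class TestMatchComponents:
    def test_self_match_is_identity(self, fitted_model):
        _, _, comp = fitted_model
        matching, cm = dim.match_components(comp, comp)
        assert {(a, b) for a, b, _ in matching} == {(n, n) for n in comp.component_names}
        np.testing.assert_allclose(np.diag(cm.to_numpy()), 1.0)

    def test_recovers_permutation_and_sign(self, fitted_model):
        _, _, comp = fitted_model
        perm = [2, 0, 3, 1]
        signs = np.array([1, -1, 1, -1.0])
        b = dim.ComponentScores(comp.values[:, perm] * signs, comp.patient_ids,
                                [f"B{i}" for i in range(4)])
        matching, _ = dim.match_components(comp, b)
        for a_name, b_name, r in matching:
            assert abs(abs(r) - 1.0) < 1e-12
            assert perm[int(b_name[1:])] == int(a_name[1:]) - 1

    def test_no_common_patients_errors(self, fitted_model):
        _, _, comp = fitted_model
        b = dim.ComponentScores(comp.values, [f"X{i}" for i in range(comp.values.shape[0])],
                                comp.component_names)
        with pytest.raises(ValueError):
            dim.match_components(comp, b)
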