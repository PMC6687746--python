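import numpy as np
import pytest
from oracles import (
    best_random_correlation,
    covariance_eig_fractions,
    gev_canonical_correlations,
)

from neurocca import (
    DataMatrix,
    SyntheticConfig,
    fit_cca,
    fix_mode_signs,
    generate,
    pca_reduce,
    project,
    standardize,
    variable_loadings,
)
from neurocca.cca_core import canonical_correlations
from neurocca.synthetic import _strength_for_rho


def dm(values, prefix="v"):
    values = np.asarray(values, dtype=float)
    return DataMatrix(
        values,
        [f"s{i+1}" for i in range(values.shape[0])],
        [f"{prefix}{j+1}" for j in range(values.shape[1])],
    )


class TestPca:
    def test_fractions_match_eigendecomposition_oracle(self, rng):
        view = dm(rng.standard_normal((20, 10)))
        model = pca_reduce(view, 10)
        assert np.allclose(
            model.explained_variance_fractions,
            covariance_eig_fractions(view.values)[:10],
            atol=1e-10,
        )

    def test_full_rank_reduction_explains_everything(self, rng):
        view = dm(rng.standard_normal((12, 8)))
        model = pca_reduce(view, 8)
        assert model.explained_variance_fractions.sum() == pytest.approx(1.0)

    def test_rank_one_signal_dominates(self, rng):
        z = rng.standard_normal(60)
        w = rng.standard_normal(15)
        view = dm(np.outer(z, w) + 1e-6 * rng.standard_normal((60, 15)))
        model = pca_reduce(view, 3)
        assert model.explained_variance_fractions[0] > 0.999

    def test_basis_orthonormal_and_fractions_sorted(self, rng):
        model = pca_reduce(dm(rng.standard_normal((30, 12))), 6)
        assert np.allclose(model.basis.T @ model.basis, np.eye(6), atol=1e-10)
        f = model.explained_variance_fractions
        assert (np.diff(f) <= 1e-12).all() and (f >= 0).all() and f.sum() <= 1 + 1e-12

    def test_sign_convention_deterministic(self, rng):
        view = dm(rng.standard_normal((25, 7)))
        m1, m2 = pca_reduce(view, 4), pca_reduce(view, 4)
        assert np.array_equal(m1.basis, m2.basis)
        top = np.abs(m1.basis).argmax(axis=0)
        assert (m1.basis[top, np.arange(4)] > 0).all()

    def test_d_out_of_range(self, rng):
        view = dm(rng.standard_normal((10, 5)))
        for bad in (0, 6, 10):
            with pytest.raises(ValueError):
                pca_reduce(view, bad)


class TestFitCca:
    def test_identical_views_fully_correlated(self, rng):
        xd = rng.standard_normal((40, 3))
        model = fit_cca(xd, xd.copy())
        assert np.allclose(model.correlations, 1.0, atol=1e-8)

    def test_single_dimension_reduces_to_pearson(self, rng):
        x = rng.standard_normal((50, 1))
        y = 0.5 * x + rng.standard_normal((50, 1))
        model = fit_cca(x, y)
        expected = abs(np.corrcoef(x[:, 0], y[:, 0])[0, 1])
        assert model.correlations[0] == pytest.approx(expected, abs=1e-10)

    def test_matches_generalized_eigenvalue_oracle(self, rng):
        xd = rng.standard_normal((50, 3))
        yd = rng.standard_normal((50, 3))
        model = fit_cca(xd, yd)
        assert np.allclose(model.correlations, gev_canonical_correlations(xd, yd),
                           atol=1e-8)

    def test_variate_normalization_and_structure(self, rng):
        xd = rng.standard_normal((60, 4))
        yd = rng.standard_normal((60, 4)) + 0.5 * xd
        m = fit_cca(xd, yd)
        for v in (m.variates_x, m.variates_y):
            assert np.allclose(v.std(axis=0, ddof=1), 1.0, atol=1e-8)
            c = np.corrcoef(v, rowvar=False)
            assert np.allclose(c - np.diag(np.diag(c)), 0.0, atol=1e-8)
        for k in range(4):
            r = np.corrcoef(m.variates_x[:, k], m.variates_y[:, k])[0, 1]
            assert r == pytest.approx(m.correlations[k], abs=1e-8)

    def test_correlations_sorted_in_unit_interval(self, rng):
        m = fit_cca(rng.standard_normal((30, 5)), rng.standard_normal((30, 5)))
        q = m.correlations
        assert (np.diff(q) <= 1e-12).all() and q.min() >= 0 and q.max() <= 1

    def test_invariant_under_invertible_transforms(self, rng):
        xd = rng.standard_normal((45, 3))
        yd = rng.standard_normal((45, 3))
        a = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        b = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        q1 = fit_cca(xd, yd).correlations
        q2 = fit_cca(xd @ a, yd @ b).correlations
        assert np.allclose(q1, q2, atol=1e-8)

    def test_beats_random_search(self, rng):
        xd = rng.standard_normal((40, 2))
        yd = rng.standard_normal((40, 2)) + 0.3 * xd
        first = fit_cca(xd, yd).correlations[0]
        assert best_random_correlation(xd, yd, 2000, rng) <= first + 1e-9

    def test_rank_deficiency_rejected(self, rng):
        xd = rng.standard_normal((30, 3))
        xd[:, 2] = xd[:, 0] + xd[:, 1]
        with pytest.raises(ValueError, match="rank deficient"):
            fit_cca(xd, rng.standard_normal((30, 3)))

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError, match="n > d"):
            fit_cca(rng.standard_normal((3, 3)), rng.standard_normal((3, 3)))

    def test_fast_path_agrees_with_full_fit(self, rng):
        xd = rng.standard_normal((35, 4))
        yd = rng.standard_normal((35, 4))
        assert np.allclose(
            canonical_correlations(xd, yd), fit_cca(xd, yd).correlations, atol=1e-10
        )


class TestProject:
    def test_training_data_reproduces_variates(self, rng):
        brain = dm(rng.standard_normal((40, 10)), "e")
        behav = dm(rng.standard_normal((40, 8)), "i")
        px_m, py_m = pca_reduce(brain, 4), pca_reduce(behav, 4)
        model = fit_cca(px_m.component_scores, py_m.component_scores)
        vx, vy = project(model, px_m, py_m, brain, behav)
        assert np.allclose(vx, model.variates_x, atol=1e-10)
        assert np.allclose(vy, model.variates_y, atol=1e-10)

    def test_row_permutation_permutes_variates(self, rng):
        brain = dm(rng.standard_normal((30, 6)), "e")
        behav = dm(rng.standard_normal((30, 5)), "i")
        px_m, py_m = pca_reduce(brain, 3), pca_reduce(behav, 3)
        model = fit_cca(px_m.component_scores, py_m.component_scores)
        perm = rng.permutation(30)
        ids = [brain.subject_ids[i] for i in perm]
        vx, vy = project(
            model, px_m, py_m, brain.subset_subjects(ids), behav.subset_subjects(ids)
        )
        assert np.allclose(vx, model.variates_x[perm], atol=1e-10)
        assert np.allclose(vy, model.variates_y[perm], atol=1e-10)

    def test_out_of_sample_correlation_near_population(self):
        a = _strength_for_rho(0.8)
        cfg = SyntheticConfig(
            n_subjects=4000, p_brain=20, q_behaviour=20, k_modes=1,
            a_x=(a,), a_y=(a,), site_effect=0, motion_effect=0,
            missing_rate=0, n_near_constant=0, seed=5,
        )
        bundle, truth = generate(cfg)
        half = bundle.n_subjects // 2
        train = bundle.subset_subjects(bundle.subject_ids[:half])
        test = bundle.subset_subjects(bundle.subject_ids[half:])
        xb, yb = standardize(train.brain), standardize(train.behaviour)
        px_m, py_m = pca_reduce(xb, 5), pca_reduce(yb, 5)
        model = fit_cca(px_m.component_scores, py_m.component_scores)
        # apply training standardization to test subjects
        from neurocca.preprocess import Standardizer

        sx = Standardizer.fit(train.brain)
        sy = Standardizer.fit(train.behaviour)
        vx, vy = project(model, px_m, py_m, sx.transform(test.brain),
                         sy.transform(test.behaviour))
        r = np.corrcoef(vx[:, 0], vy[:, 0])[0, 1]
        assert r == pytest.approx(truth.population_correlations[0], abs=0.05)

    def test_variable_mismatch_rejected(self, rng):
        brain = dm(rng.standard_normal((20, 5)), "e")
        other = dm(rng.standard_normal((20, 5)), "x")
        px_m = pca_reduce(brain, 2)
        with pytest.raises(ValueError, match="variables differ"):
            px_m.project(other)


class TestLoadings:
    def test_proportional_variable_loads_fully(self, rng):
        variate = rng.standard_normal((50, 1))
        view = dm(np.column_stack([3.0 * variate[:, 0], rng.standard_normal(50)]))
        table = variable_loadings(view, variate)
        assert table.loc["v1", "mode1"] == pytest.approx(1.0)
        assert abs(table.loc["v2", "mode1"]) < 0.5

    def test_independent_variable_loads_nothing(self, rng):
        n = 20000
        variate = rng.standard_normal((n, 1))
        view = dm(rng.standard_normal((n, 1)))
        table = variable_loadings(view, variate)
        assert abs(table.loc["v1", "mode1"]) < 0.03

    def test_matches_pearson_oracle(self, rng):
        from scipy import stats

        view = dm(rng.standard_normal((40, 6)))
        variates = rng.standard_normal((40, 2))
        table = variable_loadings(view, variates)
        for j, vid in enumerate(view.variable_ids):
            for k in range(2):
                expected = stats.pearsonr(view.values[:, j], variates[:, k]).statistic
                assert table.loc[vid, f"mode{k+1}"] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_variable_rejected(self, rng):
        view = dm(np.column_stack([np.full(20, 2.0), rng.standard_normal(20)]))
        with pytest.raises(ValueError, match="zero-variance"):
            variable_loadings(view, rng.standard_normal((20, 1)))

    def test_sign_fix_makes_top_behaviour_loading_positive(self, rng):
        behav = dm(rng.standard_normal((60, 6)), "i")
        brain = dm(rng.standard_normal((60, 8)) + 0.3, "e")
        px_m, py_m = pca_reduce(brain, 3), pca_reduce(behav, 3)
        model = fit_cca(px_m.component_scores, py_m.component_scores)
        fixed, signs = fix_mode_signs(model, behav)
        table = variable_loadings(behav, fixed.variates_y)
        for col in table.columns:
            assert table[col].iloc[table[col].abs().argmax()] > 0
        # u/P_X flipped jointly with v/P_Y: correlations unchanged
        assert np.allclose(fixed.correlations, model.correlations)
        for k in range(3):
            r = np.corrcoef(fixed.variates_x[:, k], fixed.variates_y[:, k])[0, 1]
            assert r == pytest.approx(model.correlations[k], abs=1e-8)
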