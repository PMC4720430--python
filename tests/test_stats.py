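"""Mixed-model REML, shrinkage Fs permutation test, q-values, ANOVA parts."""

import numpy as np
import pytest

from confounderscan.core_io import (
    Dose,
    ExpressionMatrix,
    SampleRecord,
    SampleTable,
    Series,
    ValidationError,
)
from confounderscan.mixedstats import (
    anova_decomposition,
    estimate_qvalues,
    fit_mixed_model,
    fit_mixed_model_matrix,
    fs_permutation_test,
    shrink_variances,
)
from confounderscan.screens import relabel_biopsy_order
from confounderscan.synthetic import SimulationConfig, build_design, simulate_experiment

from conftest import make_table, matrix_from


def oneway_table(n_ind=4, n_rep=5):
    times = [0, 1, 2, 3, 4, 5][:n_rep]
    return make_table([(f"m{i}", Series.EARLY, times, Dose.NONE, False)
                       for i in range(n_ind)])


class TestMixedModelReml:
    def test_balanced_oneway_matches_anova_closed_form(self):
        rng = np.random.default_rng(0)
        tbl = oneway_table(4, 5)
        u = rng.normal(0, 0.5, 4)
        y = 5 + u[np.repeat(np.arange(4), 5)] + rng.normal(0, 0.2, 20)
        fit = fit_mixed_model(y, tbl, fixed="intercept", random_individual=True)
        gm = y.reshape(4, 5).mean(axis=1)
        msb = 5 * np.sum((gm - y.mean()) ** 2) / 3
        msw = np.sum((y.reshape(4, 5) - gm[:, None]) ** 2) / 16
        assert fit.sigma_u2 == pytest.approx(max(0.0, (msb - msw) / 5), abs=1e-8)
        assert fit.sigma_e2 == pytest.approx(msw, abs=1e-8)

    def test_matches_lme4_reference_fit(self):
        """Frozen oracle: lmer(y ~ 0 + t + (1|ind), REML) on this fixture."""
        rng = np.random.default_rng(42)
        tbl = make_table([(f"M{i}", Series.EARLY, (0, 1, 2, 3, 4, 5),
                           Dose.NONE, False) for i in range(4)])
        u = rng.normal(0, 0.6, 4)
        eff = {0: 0.0, 1: 0.5, 2: 1.0, 3: 0.2, 4: -0.3, 5: 0.1}
        y = (5 + np.array([eff[int(r.recovery_time_h)] for r in tbl])
             + u[np.repeat(np.arange(4), 6)]
             + rng.normal(0, 0.3, 24))
        fit = fit_mixed_model(y, tbl, fixed="dose_time", random_individual=True)
        np.testing.assert_allclose(
            fit.coefficients,
            [5.182336451, 5.520527359, 6.191661851,
             5.374032769, 4.903223958, 5.091275693], atol=2e-6)
        assert fit.sigma_u2 == pytest.approx(0.24247739338, abs=2e-6)
        assert fit.sigma_e2 == pytest.approx(0.04872416124, abs=2e-6)
        np.testing.assert_allclose(
            fit.individual_coefs,
            [-0.1547369760, -0.6078748328, 0.2822710018, 0.4803408071],
            atol=2e-6)

    def test_zero_signal_truncates_variance_at_zero(self):
        rng = np.random.default_rng(1)
        tbl = oneway_table(4, 6)
        found = []
        for _ in range(20):
            y = rng.normal(0, 0.3, 24)
            fit = fit_mixed_model(y, tbl, fixed="intercept")
            assert fit.sigma_u2 >= 0.0
            found.append(fit.sigma_u2 == 0.0)
        assert any(found)  # truncation actually engages under the null

    def test_without_random_term_reduces_to_ols(self):
        rng = np.random.default_rng(2)
        tbl = oneway_table(3, 4)
        y = rng.normal(size=12)
        fit = fit_mixed_model(y, tbl, fixed="dose_time", random_individual=False)
        # group-means OLS = per-level means
        labels = [f"early|U|t{r.recovery_time_h:g}" for r in tbl]
        for lvl, coef in zip(fit.level_names, fit.coefficients):
            mask = [l == lvl for l in labels]
            assert coef == pytest.approx(np.mean(y[np.array(mask)]), abs=1e-10)
        assert np.all(fit.individual_coefs == 0.0)

    def test_blups_sum_to_zero_on_balanced_design(self):
        rng = np.random.default_rng(3)
        tbl = oneway_table(4, 6)
        y = rng.normal(size=24) + np.repeat(rng.normal(0, 1, 4), 6)
        fit = fit_mixed_model(y, tbl, fixed="intercept")
        assert abs(np.sum(fit.individual_coefs)) < 1e-8

    def test_variance_component_recovery_median_within_20pct(self):
        """500 simulated genes on the default-size design (16 individuals)."""
        rng = np.random.default_rng(4)
        tbl = oneway_table(16, 6)
        G = 500
        u = rng.normal(0, 0.5, (G, 16))
        Y = u[:, np.repeat(np.arange(16), 6)] + rng.normal(0, 0.2, (G, 96))
        m = ExpressionMatrix([f"g{i}" for i in range(G)], tbl.sample_ids, Y)
        coll = fit_mixed_model_matrix(m, tbl, fixed="intercept")
        assert abs(np.median(coll.sigma_u2) / 0.25 - 1) < 0.2
        assert abs(np.median(coll.sigma_e2) / 0.04 - 1) < 0.2


class TestShrinkage:
    def test_equal_variances_unchanged(self):
        s = np.full(50, 0.3)
        np.testing.assert_allclose(shrink_variances(s, df=10), s, rtol=1e-12)

    def test_shrinks_toward_center(self):
        rng = np.random.default_rng(5)
        s = np.exp(rng.normal(0, 1, 200))
        out = np.log(shrink_variances(s, df=8))
        x = np.log(s)
        # distances to the mean shrink, order preserved
        assert np.all(np.abs(out - x.mean()) <= np.abs(x - x.mean()) + 1e-12)
        assert np.all(np.diff(out[np.argsort(x)]) >= -1e-12)


class TestFsPermutationTest:
    @staticmethod
    def _null_setup(G=120, seed=0):
        cfg = SimulationConfig(n_genes=G, n_individuals=8, rng_seed=seed)
        design = build_design(cfg)
        matrix, _ = simulate_experiment(cfg, design)
        rel = relabel_biopsy_order(design.filter(treated=False))
        return matrix, rel

    def test_determinism_same_seed(self):
        matrix, rel = self._null_setup()
        r1 = fs_permutation_test(matrix, rel, ("b1", "b2"), 100, seed=9)
        r2 = fs_permutation_test(matrix, rel, ("b1", "b2"), 100, seed=9)
        np.testing.assert_array_equal(r1.pvalues, r2.pvalues)
        r3 = fs_permutation_test(matrix, rel, ("b1", "b2"), 100, seed=10)
        assert not np.array_equal(r1.pvalues, r3.pvalues)

    def test_invariant_to_per_individual_constants(self):
        matrix, rel = self._null_setup()
        offsets = {ind: k * 3.0 for k, ind in enumerate(rel.individual_ids)}
        shifted = matrix.values.copy()
        col_of = {s: j for j, s in enumerate(matrix.sample_ids)}
        for r in rel:
            shifted[:, col_of[r.sample_id]] += offsets[r.individual_id]
        m2 = ExpressionMatrix(matrix.gene_ids, matrix.sample_ids, shifted)
        r1 = fs_permutation_test(matrix, rel, ("b1", "b2"), 100, seed=4,
                                 random_individual=True)
        r2 = fs_permutation_test(m2, rel, ("b1", "b2"), 100, seed=4,
                                 random_individual=True)
        np.testing.assert_allclose(r1.fs, r2.fs, rtol=1e-6)
        np.testing.assert_array_equal(r1.pvalues, r2.pvalues)

    def test_planted_contrast_effect_detected(self):
        matrix, rel = self._null_setup(G=80, seed=3)
        vals = matrix.values.copy()
        col_of = {s: j for j, s in enumerate(matrix.sample_ids)}
        for r in rel:   # strong b2 shift for the first 5 genes
            if r.biopsy_order == 2:
                vals[:5, col_of[r.sample_id]] += 2.0
        m2 = ExpressionMatrix(matrix.gene_ids, matrix.sample_ids, vals)
        res = fs_permutation_test(m2, rel, ("b1", "b2"), 100, seed=1)
        assert res.pvalues[:5].max() < 0.01
        assert np.median(res.pvalues[5:]) > 0.2

    def test_individual_missing_contrast_level_excluded(self):
        matrix, rel = self._null_setup()
        res = fs_permutation_test(matrix, rel, ("b1", "b5"), 100, seed=2)
        # only early mice carry b5; result is still well-formed
        assert np.all(res.pvalues > 0) and np.all(res.pvalues <= 1)

    def test_too_few_permutations_rejected(self):
        matrix, rel = self._null_setup()
        with pytest.raises(ValidationError):
            fs_permutation_test(matrix, rel, ("b1", "b2"), 50, seed=0)


class TestQValues:
    def test_bh_equivalence_with_pi0_fixed(self):
        res = estimate_qvalues(np.array([0.01, 0.02, 0.03, 0.5]), pi0=1.0)
        np.testing.assert_allclose(res.qvalues, [0.04, 0.04, 0.04, 0.5])

    def test_all_ones_degenerate(self):
        res = estimate_qvalues(np.ones(10))
        assert res.pi0 == 1.0
        np.testing.assert_array_equal(res.qvalues, np.ones(10))

    def test_pi0_near_one_on_uniform(self):
        rng = np.random.default_rng(6)
        res = estimate_qvalues(rng.uniform(size=10000))
        assert 0.9 <= res.pi0 <= 1.0

    def test_qvalues_monotone_in_p(self):
        rng = np.random.default_rng(7)
        p = np.concatenate([rng.uniform(0, 0.01, 50), rng.uniform(size=500)])
        res = estimate_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(res.qvalues[order]) >= -1e-12)
        assert np.all(res.qvalues <= 1.0)

    def test_invalid_input_rejected(self):
        with pytest.raises(ValidationError):
            estimate_qvalues(np.array([]))
        with pytest.raises(ValidationError):
            estimate_qvalues(np.array([0.0, 0.5]))


class TestAnovaDecomposition:
    @staticmethod
    def _crossed_table():
        # 4 individuals fully crossed with the early grid (one series, no nesting)
        return make_table([(f"m{i}", Series.EARLY, (0, 1, 2, 3, 4, 5),
                            Dose.NONE, False) for i in range(4)])

    def test_exact_recovery_of_planted_structure(self):
        tbl = self._crossed_table()
        rng = np.random.default_rng(8)
        alpha = rng.normal(size=(3, 4)); alpha -= alpha.mean(axis=1, keepdims=True)
        gamma = rng.normal(size=(3, 6)); gamma -= gamma.mean(axis=1, keepdims=True)
        iof = np.repeat(np.arange(4), 6)
        cof = np.tile(np.arange(6), 4)
        Y = 2.0 + alpha[:, iof] + gamma[:, cof]
        m = ExpressionMatrix(["g1", "g2", "g3"], tbl.sample_ids, Y)
        dec = anova_decomposition(m, tbl)
        np.testing.assert_allclose(dec.mu, [2.0] * 3, atol=1e-9)
        np.testing.assert_allclose(dec.individual_effects, alpha, atol=1e-9)
        np.testing.assert_allclose(dec.cell_effects, gamma, atol=1e-9)
        np.testing.assert_allclose(dec.residuals, 0.0, atol=1e-9)

    def test_conservation_and_sum_to_zero_on_full_design(self):
        cfg = SimulationConfig(n_genes=20, n_individuals=8, n_individual=5,
                               n_treatment=5, rng_seed=9)
        design = build_design(cfg)
        matrix, _ = simulate_experiment(cfg, design)
        dec = anova_decomposition(matrix, design)
        np.testing.assert_allclose(dec.fitted() + dec.residuals,
                                   matrix.sample_cols(design.sample_ids),
                                   atol=1e-9)
        np.testing.assert_allclose(dec.individual_effects.sum(axis=1), 0.0,
                                   atol=1e-9)
        np.testing.assert_allclose(dec.cell_effects.sum(axis=1), 0.0, atol=1e-9)

    def test_too_small_design_rejected(self):
        tbl = make_table([("m1", Series.EARLY, (0, 1), Dose.NONE, False)])
        m = matrix_from(["g"], tbl.sample_ids, [[1.0, 2.0]])
        with pytest.raises(ValidationError):
            anova_decomposition(m, tbl)
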