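import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dranet import regression, simulate
from dranet.exceptions import ConfigError, InputError, ValidationError
from dranet.regression import (DRAScan, adjust_bh, fit_gene_model,
                               permutation_null, run_dra_scan, subsample_power)

from conftest import make_sample_table


def ols_oracle(y, X):
    """Normal-equations + t-distribution reference for the coefficient tests."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), dof)
    return beta, p


class TestAdjustBH:
    def test_definition_oracle(self):
        out = adjust_bh([0.01, 0.02, 0.03, 0.5])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.5])

    def test_identities(self):
        assert np.allclose(adjust_bh([1.0, 1.0, 1.0]), 1.0)
        assert adjust_bh([0.3])[0] == pytest.approx(0.3)

    def test_monotone_and_capped_on_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.random(rng.integers(1, 30))
            adj = adjust_bh(p)
            assert (adj <= 1).all() and (adj >= p - 1e-12).all()
            order = np.argsort(p)
            assert (np.diff(adj[order]) >= -1e-12).all()

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(20):
            p = rng.random(50)
            assert np.allclose(adjust_bh(p),
                               multipletests(p, method="fdr_bh")[1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            adjust_bh([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    @settings(deadline=None, derandomize=True)
    def test_step_up_properties_hold_for_any_p_vector(self, p):
        adj = adjust_bh(p)
        p = np.asarray(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0 + 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        # the smallest adjusted value is min over i of p_(i) * m / i
        m = len(p)
        expected_min = min(ps * m / (i + 1) for i, ps in enumerate(np.sort(p)))
        assert adj.min() == pytest.approx(min(expected_min, 1.0), abs=1e-12)


class TestFitGeneModel:
    def test_noiseless_line_recovers_slope_with_degeneracy_flag(self):
        sens = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        fit = fit_gene_model(2.0 * sens + 3.0, sens)
        assert fit.gamma_hat == pytest.approx(2.0, abs=1e-10)
        assert fit.p_value == 0.0
        assert fit.flag == regression.FLAG_DEGENERATE

    def test_matches_normal_equations_with_factor_covariate(self, rng):
        n = 8
        sens = rng.standard_normal(n)
        batch = np.array(["a", "a", "b", "b", "a", "b", "a", "b"])
        y = rng.standard_normal(n)
        fit = fit_gene_model(y, sens, pd.DataFrame({"batch": batch}))
        X = np.column_stack([np.ones(n), sens, (batch == "b").astype(float)])
        beta, p = ols_oracle(y, X)
        assert fit.gamma_hat == pytest.approx(beta[1], abs=1e-10)
        assert fit.p_value == pytest.approx(p[1], abs=1e-10)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(12)
        n = 100
        sens = rng.standard_normal(n)
        pvals = [fit_gene_model(rng.standard_normal(n), sens).p_value
                 for _ in range(1000)]
        assert np.mean(np.array(pvals) < 0.05) == pytest.approx(0.05, abs=0.02)

    def test_aliased_design_flagged_not_crashed(self):
        sens = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        cov = pd.DataFrame({"pc1": sens})  # perfectly aliased with sensitivity
        fit = fit_gene_model(np.arange(6.0), sens, cov)
        assert fit.flag == regression.FLAG_RANK_DEFICIENT
        assert np.isnan(fit.p_value)


class TestRunDRAScan:
    def test_planted_genes_recovered(self, small_panel):
        expr, samples, truth = small_panel
        res = run_dra_scan(expr, samples, "drugA", alpha=0.1)
        planted = set(truth.dra_genes)
        found = set(res.significant_genes)
        assert len(planted & found) / len(planted) >= 0.8

    def test_sign_classes_partition_totals(self, small_panel):
        expr, samples, _ = small_panel
        res = run_dra_scan(expr, samples, "drugA")
        assert res.n_positive + res.n_negative == res.n_significant
        pos = res.table[res.table["sign_class"] == "positive"]
        assert (pos["gamma_hat"] > 0).all() and (pos["fdr"] <= 0.1).all()

    def test_location_invariance(self, small_panel):
        expr, samples, _ = small_panel
        res1 = run_dra_scan(expr, samples, "drugA")
        res2 = run_dra_scan(expr + 5.0, samples, "drugA")
        assert np.allclose(res1.table["gamma_hat"], res2.table["gamma_hat"],
                           atol=1e-10)
        assert np.allclose(res1.table["p_value"], res2.table["p_value"],
                           atol=1e-10)

    def test_gene_order_invariance(self, small_panel):
        expr, samples, _ = small_panel
        res1 = run_dra_scan(expr, samples, "drugA")
        shuffled = expr.sample(frac=1, random_state=1)
        res2 = run_dra_scan(shuffled, samples, "drugA")
        pd.testing.assert_frame_equal(
            res1.table.sort_index(), res2.table.sort_index())

    def test_zero_variance_gene_flagged(self, small_panel):
        expr, samples, _ = small_panel
        expr = expr.copy()
        expr.iloc[0] = 3.14
        res = run_dra_scan(expr, samples, "drugA")
        assert res.table.iloc[0]["flag"] == regression.FLAG_ZERO_VARIANCE
        assert res.table.iloc[0]["sign_class"] == "nonsignificant"

    def test_no_overlapping_samples_rejected(self, small_panel):
        expr, samples, _ = small_panel
        renamed = expr.rename(columns=lambda c: "X" + c)
        with pytest.raises(InputError):
            run_dra_scan(renamed, samples, "drugA")

    def test_confounder_adjustment_removes_batch_artifact(self):
        # 50 genes driven purely by batch; sensitivity also tracks batch, so
        # the unadjusted fit sees a spurious association in every gene while
        # the adjusted p-values fall back to uniform (mean ~ 0.5)
        rng = np.random.default_rng(4)
        n = 120
        batch = np.repeat(["b0", "b1"], n // 2)
        sens = np.where(batch == "b1", 5.0, 2.0) + rng.normal(0, 0.5, n)
        naked_p, adjusted_p = [], []
        for _ in range(50):
            y = np.where(batch == "b1", 1.0, 0.0) + rng.normal(0, 0.3, n)
            naked_p.append(fit_gene_model(y, sens).p_value)
            adjusted_p.append(
                fit_gene_model(y, sens, pd.DataFrame({"batch": batch})).p_value)
        assert max(naked_p) < 1e-6
        assert np.mean(adjusted_p) > 0.3
        assert (adjust_bh(adjusted_p) > 0.1).all()


class TestPermutationNull:
    def test_all_null_frequency_saturates(self):
        cfg = simulate.SimulationConfig(n_samples=100, n_genes=100, n_dra=0, seed=8)
        expr, samples, _ = simulate.simulate_panel(cfg)
        res = permutation_null(expr, samples, "drugA", n_perm=30, seed=1)
        assert res.observed_count == 0
        assert res.frequency == 30  # ties count under the >= convention

    def test_planted_signal_never_beaten(self, small_panel):
        expr, samples, _ = small_panel
        res = permutation_null(expr, samples, "drugA", n_perm=50, seed=2)
        assert res.observed_count >= 15
        assert res.frequency == 0
        assert res.average_count < 2

    def test_deterministic_given_seed(self, small_panel):
        expr, samples, _ = small_panel
        r1 = permutation_null(expr, samples, "drugA", n_perm=10, seed=3)
        r2 = permutation_null(expr, samples, "drugA", n_perm=10, seed=3)
        assert r1 == r2

    def test_invalid_n_perm_rejected(self, small_panel):
        expr, samples, _ = small_panel
        with pytest.raises(ConfigError):
            permutation_null(expr, samples, "drugA", n_perm=0)


class TestSubsamplePower:
    def test_full_size_single_rep_equals_full_scan(self, small_panel):
        expr, samples, truth = small_panel
        full = run_dra_scan(expr, samples, "drugA").n_significant
        table = subsample_power(expr, samples, "drugA", sizes=[150], reps=1, seed=0)
        assert table["mean_significant"].iloc[0] == full

    def test_power_nondecreasing_in_sample_size(self, small_panel):
        expr, samples, _ = small_panel
        rhos = []
        for seed in range(10):
            table = subsample_power(expr, samples, "drugA",
                                    sizes=[50, 75, 100, 125, 150],
                                    reps=10, seed=seed)
            rho = stats.spearmanr(table["size"], table["mean_significant"]).statistic
            rhos.append(rho)
        assert np.mean(rhos) > 0.9

    def test_oversized_subsample_rejected(self, small_panel):
        expr, samples, _ = small_panel
        with pytest.raises(ConfigError):
            subsample_power(expr, samples, "drugA", sizes=[1000], reps=1)
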