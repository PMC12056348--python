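import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ectogradient.stats import (
    StatsError,
    design_matrix,
    diagnostics,
    fit_formula,
    fit_ols,
    parse_formula,
    select_model,
    tukey_pairwise,
)


def _toy_table(n=24, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "elevation": rng.uniform(200, 1300, n),
            "species": rng.choice(["A", "B"], n),
            "occurrence": rng.choice(["g1", "g2", "g3"], n),
        }
    )
    df["y"] = 1.0 + 0.002 * df["elevation"] + rng.normal(0, 0.5, n)
    return df


class TestDesignMatrix:
    def test_continuous_plus_three_level_factor(self):
        df = _toy_table()
        X, names = design_matrix(df, [("elevation",), ("occurrence",)])
        assert X.shape[1] == 4  # intercept + slope + 2 dummies
        assert names[0] == "Intercept"
        assert names[2:] == ["occurrence[T.g2]", "occurrence[T.g3]"]

    def test_full_three_way_interaction_column_count(self):
        df = _toy_table(60, seed=1)
        _, terms = parse_formula("y ~ elevation * species * occurrence")
        X, names = design_matrix(df, terms)
        # 1 + [1 + 1 + 2] + [1 + 2 + 2] + [2] + intercept-is-first
        assert X.shape[1] == 12

    def test_unknown_term_rejected(self):
        with pytest.raises(StatsError, match="unknown term"):
            design_matrix(_toy_table(), [("altitude",)])

    def test_constant_factor_names_offender(self):
        df = _toy_table()
        df["species"] = "A"
        with pytest.raises(StatsError, match="species"):
            design_matrix(df, [("species",)])

    def test_reference_levels_are_first_sorted(self):
        df = pd.DataFrame(
            {
                "occurrence": ["syntopy", "allotopy_muralis", "allotopy_horvathi"] * 4,
                "y": np.arange(12.0),
            }
        )
        _, names = design_matrix(df, [("occurrence",)])
        # allotopy_horvathi sorts first -> reference; no dummy carries it
        assert "occurrence[T.allotopy_horvathi]" not in names
        assert "occurrence[T.syntopy]" in names


class TestFitOLS:
    def test_exact_interpolation_of_linear_data(self):
        x = np.arange(10.0)
        X = np.column_stack([np.ones(10), x])
        y = 2.0 + 3.0 * x
        fit = fit_ols(y, X, ["Intercept", "x"])
        assert fit.rss == pytest.approx(0.0, abs=1e-18)
        assert fit.beta == pytest.approx([2.0, 3.0])

    def test_three_point_line(self):
        X = np.column_stack([np.ones(3), [0.0, 1.0, 2.0]])
        fit = fit_ols(np.array([0.0, 1.0, 2.0]), X)
        assert fit.beta[1] == pytest.approx(1.0)
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_statsmodels_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(40), rng.normal(size=(40, 2))])
        y = X @ [1.0, -2.0, 0.5] + rng.normal(0, 0.3, 40)
        ours = fit_ols(y, X)
        ref = sm.OLS(y, X).fit()
        np.testing.assert_allclose(ours.beta, ref.params, rtol=1e-10)
        np.testing.assert_allclose(ours.se, ref.bse, rtol=1e-10)
        np.testing.assert_allclose(ours.p, ref.pvalues, rtol=1e-8)

    def test_aicc_formula_and_error_variance_convention(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        y = rng.normal(size=20)
        fit = fit_ols(y, X)
        n, k = 20, 3  # 2 coefficients + error variance
        expect = n * np.log(fit.rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        assert fit.k == k
        assert fit.aicc == pytest.approx(expect, rel=1e-12)

    def test_underdetermined_rejected(self):
        with pytest.raises(StatsError):
            fit_ols(np.zeros(2), np.ones((2, 3)))

    def test_singular_design_rejected(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(StatsError):
            fit_ols(np.zeros(10), X)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_ols_equals_normal_equations_oracle(seed):
    rng = np.random.default_rng(seed)
    n, k = 15, 3
    X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
    y = rng.normal(size=n)
    fit = fit_ols(y, X)
    beta_oracle = np.linalg.inv(X.T @ X) @ X.T @ y
    np.testing.assert_allclose(fit.beta, beta_oracle, atol=1e-10)


class TestSelectModel:
    def _fits(self, gap):
        """Two nested fits whose AICc difference is controlled via rss."""
        rng = np.random.default_rng(0)
        n = 30
        X_red = np.column_stack([np.ones(n), rng.normal(size=n)])
        X_full = np.column_stack([X_red, rng.normal(size=n)])
        y = rng.normal(size=n)
        red = fit_ols(y, X_red, formula="reduced")
        full = fit_ols(y, X_full, formula="full")
        full.aicc = red.aicc - gap  # controlled ΔAICc
        return full, red

    def test_large_improvement_keeps_full(self):
        full, red = self._fits(5.0)
        chosen, info = select_model(full, red)
        assert chosen is full
        assert info["delta_aicc"] == pytest.approx(5.0)

    def test_marginal_improvement_keeps_reduced(self):
        full, red = self._fits(1.9)
        chosen, _ = select_model(full, red)
        assert chosen is red

    def test_tie_goes_to_simpler_model(self):
        full, red = self._fits(0.0)
        chosen, _ = select_model(full, red)
        assert chosen is red

    def test_argument_order_invariance(self):
        full, red = self._fits(5.0)
        assert select_model(full, red)[0] is select_model(red, full)[0]

    def test_mismatched_n_rejected(self):
        full, red = self._fits(0.0)
        red.n = 29
        with pytest.raises(StatsError):
            select_model(full, red)


class TestTukey:
    def _balanced_groups(self, means, n=8, sd=0.4, seed=3):
        rng = np.random.default_rng(seed)
        rows = []
        for g, m in means.items():
            for _ in range(n):
                rows.append({"occurrence": g, "y": m + sd * rng.normal()})
        return pd.DataFrame(rows)

    def test_two_level_factor_adjusted_equals_unadjusted(self):
        df = self._balanced_groups({"g1": 0.0, "g2": 1.0})
        fit = fit_formula(df, "y ~ occurrence")
        contrasts = tukey_pairwise(fit, "occurrence", df)
        assert len(contrasts) == 1
        p_t = fit.p[fit.terms.index("occurrence[T.g2]")]
        assert contrasts[0].adjusted_p == pytest.approx(p_t, rel=1e-6)

    def test_identical_groups_zero_estimates(self):
        df = self._balanced_groups({"g1": 2.0, "g2": 2.0, "g3": 2.0}, sd=0.0)
        df["y"] += 0.001 * np.arange(len(df))  # break exact singularity
        fit = fit_formula(df, "y ~ occurrence")
        for c in tukey_pairwise(fit, "occurrence", df):
            assert abs(c.estimate) < 0.05

    def test_q_statistic_matches_studentized_range_oracle(self):
        """Balanced one-way case: q = |diff| / sqrt(MSE/n)."""
        n = 8
        df = self._balanced_groups({"g1": 0.0, "g2": 0.8, "g3": 2.0}, n=n)
        fit = fit_formula(df, "y ~ occurrence")
        contrasts = tukey_pairwise(fit, "occurrence", df)
        assert len(contrasts) == 3
        mse = fit.rss / fit.df_resid
        groups = df.groupby("occurrence")["y"].mean()
        for c in contrasts:
            diff = abs(groups[c.pair[1]] - groups[c.pair[0]])
            q = diff / np.sqrt(mse / n)
            p_oracle = sps.studentized_range.sf(q, 3, fit.df_resid)
            assert c.adjusted_p == pytest.approx(p_oracle, rel=1e-6, abs=1e-12)

    def test_all_unordered_pairs_present_once(self):
        df = self._balanced_groups({"g1": 0.0, "g2": 1.0, "g3": 2.0})
        fit = fit_formula(df, "y ~ occurrence")
        pairs = {tuple(sorted(c.pair)) for c in tukey_pairwise(fit, "occurrence", df)}
        assert pairs == {("g1", "g2"), ("g1", "g3"), ("g2", "g3")}

    def test_factor_absent_from_model_rejected(self):
        df = self._balanced_groups({"g1": 0.0, "g2": 1.0})
        df["elevation"] = np.arange(len(df), dtype=float)
        fit = fit_formula(df, "y ~ elevation")
        with pytest.raises(StatsError):
            tukey_pairwise(fit, "occurrence", df)


class TestDiagnostics:
    def test_normal_residuals_rarely_flagged(self):
        """Calibration: Shapiro p > 0.01 for >= 95 of 100 normal draws."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = np.column_stack([np.ones(200), rng.normal(size=200)])
            y = X @ [1.0, 2.0] + rng.normal(size=200)
            rep = diagnostics(fit_ols(y, X))
            if rep["shapiro_p"] > 0.01:
                hits += 1
        assert hits >= 95

    def test_constructed_heteroscedasticity_is_flagged(self):
        rng = np.random.default_rng(7)
        x = np.linspace(1.0, 10.0, 200)
        X = np.column_stack([np.ones(200), x])
        y = 2.0 + x + rng.normal(size=200) * x ** 2 * 0.2
        rep = diagnostics(fit_ols(y, X), X=X)
        assert rep["breusch_pagan_p"] < 0.05

    def test_qq_coordinates_sorted_ascending(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(50), rng.normal(size=50)])
        rep = diagnostics(fit_ols(rng.normal(size=50), X))
        assert np.all(np.diff(rep["qq_theoretical"]) > 0)
        assert np.all(np.diff(rep["qq_sample"]) >= 0)

    def test_small_samples_skipped_with_reason(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        rep = diagnostics(fit_ols(np.arange(5.0) + 0.1 * np.random.default_rng(0).normal(size=5), X))
        assert rep["skipped"]


class TestFormulaPipeline:
    def test_fit_formula_with_interactions_runs(self):
        df = _toy_table(48, seed=9)
        fit = fit_formula(df, "y ~ elevation + species + occurrence + elevation:species")
        assert "elevation:species[T.B]" in fit.terms
        assert fit.n == 48

    def test_na_rows_dropped_listwise(self):
        df = _toy_table(30, seed=4)
        df.loc[:4, "y"] = np.nan
        fit = fit_formula(df, "y ~ elevation")
        assert fit.n == 25
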