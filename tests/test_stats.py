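"""Statistical battery: ANOVA, ANCOVA, Bonferroni, and exact Fisher tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from choromorph import stats


def anova_oracle(arrays):
    """From-scratch one-way ANOVA via explicit sums of squares."""
    all_values = np.concatenate(arrays)
    grand = all_values.mean()
    ss_between = sum(len(a) * (np.mean(a) - grand) ** 2 for a in arrays)
    ss_within = sum(((a - np.mean(a)) ** 2).sum() for a in arrays)
    df_b = len(arrays) - 1
    df_w = len(all_values) - len(arrays)
    f = (ss_between / df_b) / (ss_within / df_w)
    p = sps.f.sf(f, df_b, df_w)
    return f, p


class TestAnova:
    def test_identical_groups_give_f_zero_p_one(self):
        values = [5.0, 5.0, 5.0, 5.0]
        groups = ["a", "a", "b", "b"]
        comp = stats.anova_oneway(values, groups)
        assert comp.statistic == 0.0
        assert comp.p_value == 1.0

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 6)
        comp = stats.anova_oneway(
            np.concatenate([a, b]), ["a"] * 8 + ["b"] * 6
        )
        t, _ = sps.ttest_ind(a, b, equal_var=True)
        assert comp.statistic == pytest.approx(t**2, rel=1e-12)

    def test_matches_sum_of_squares_oracle(self):
        arrays = [
            np.array([3.1, 2.9, 3.4, 3.0]),
            np.array([4.2, 4.5, 3.9]),
            np.array([2.0, 2.2, 1.8, 2.4, 2.1]),
        ]
        values = np.concatenate(arrays)
        groups = ["a"] * 4 + ["b"] * 3 + ["c"] * 5
        comp = stats.anova_oneway(values, groups)
        f, p = anova_oracle(arrays)
        assert comp.statistic == pytest.approx(f, abs=1e-10)
        assert comp.p_value == pytest.approx(p, abs=1e-10)
        assert len(comp.pairwise) == 3  # omnibus significant here

    def test_degenerate_group_errors(self):
        with pytest.raises(ValueError, match="fewer than two"):
            stats.anova_oneway([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestAncova:
    def test_no_covariates_reduces_to_anova(self):
        rng = np.random.default_rng(2)
        values = rng.normal(0, 1, 20)
        groups = np.repeat(["a", "b", "c", "d"], 5)
        anova = stats.anova_oneway(values, groups)
        ancova = stats.ancova(values, groups, covariates=None)
        assert ancova.statistic == pytest.approx(anova.statistic, abs=1e-10)
        assert ancova.p_value == pytest.approx(anova.p_value, abs=1e-10)

    def test_matches_normal_equations_on_six_rows(self):
        """Two groups, one covariate, n = 6: solved by hand via X'X b = X'y."""
        y = np.array([2.0, 3.0, 4.0, 7.0, 8.0, 10.0])
        g = np.array(["a", "a", "a", "b", "b", "b"])
        z = np.array([1.0, 2.0, 3.0, 1.5, 2.5, 4.0])
        X_full = np.column_stack([np.ones(6), (g == "b").astype(float), z])
        beta = np.linalg.solve(X_full.T @ X_full, X_full.T @ y)
        resid_full = y - X_full @ beta
        sse_full = resid_full @ resid_full
        X_red = np.column_stack([np.ones(6), z])
        beta_red = np.linalg.solve(X_red.T @ X_red, X_red.T @ y)
        sse_red = (y - X_red @ beta_red) @ (y - X_red @ beta_red)
        f_oracle = (sse_red - sse_full) / (sse_full / 3)
        zbar = z.mean()
        adj_a = beta[0] + beta[2] * zbar
        adj_b = beta[0] + beta[1] + beta[2] * zbar

        comp = stats.ancova(y, g, covariates=pd.DataFrame({"z": z}))
        assert comp.statistic == pytest.approx(f_oracle, abs=1e-10)
        assert comp.adjusted_means["a"][0] == pytest.approx(adj_a, abs=1e-10)
        assert comp.adjusted_means["b"][0] == pytest.approx(adj_b, abs=1e-10)
        assert comp.df == (1.0, 3.0)

    def test_uncorrelated_covariate_leaves_means_near_raw(self):
        rng = np.random.default_rng(3)
        groups = np.repeat(["a", "b"], 50)
        effects = np.where(groups == "a", 0.0, 1.0)
        values = effects + rng.normal(0, 0.3, 100)
        noise_cov = rng.normal(0, 1, 100)  # independent of group and outcome
        comp = stats.ancova(values, groups, pd.DataFrame({"z": noise_cov}))
        for g in ("a", "b"):
            raw = values[groups == g].mean()
            assert comp.adjusted_means[g][0] == pytest.approx(raw, abs=0.05)

    def test_recovers_group_effect_under_age_confounding(self):
        """A known additive group effect confounded with age is recovered by
        the age-adjusted model."""
        rng = np.random.default_rng(4)
        n = 120
        groups = np.repeat(["a", "b"], n // 2)
        age = np.where(groups == "a", 60, 80) + rng.normal(0, 5, n)
        true_effect = 5.0
        values = 0.5 * age + np.where(groups == "b", true_effect, 0.0) + rng.normal(0, 1.0, n)
        comp = stats.ancova(values, groups, pd.DataFrame({"age": age}))
        recovered = comp.adjusted_means["b"][0] - comp.adjusted_means["a"][0]
        se = np.hypot(comp.adjusted_means["a"][1], comp.adjusted_means["b"][1])
        assert recovered == pytest.approx(true_effect, abs=4 * se + 0.2)

    def test_gender_enters_as_indicator(self):
        rng = np.random.default_rng(5)
        n = 40
        groups = np.repeat(["a", "b"], n // 2)
        gender = rng.choice(["F", "M"], n)
        values = rng.normal(0, 1, n) + (gender == "M") * 2.0
        comp = stats.ancova(
            values, groups,
            pd.DataFrame({"age": rng.normal(70, 8, n), "gender": gender}),
            model="age_gender",
        )
        assert 0.0 <= comp.p_value <= 1.0

    def test_rank_deficient_design_names_columns(self):
        values = np.arange(8.0)
        groups = np.repeat(["a", "b"], 4)
        dup = np.repeat([0.0, 1.0], 4)  # identical to the group indicator
        with pytest.raises(ValueError, match="collinear.*z"):
            stats.ancova(values, groups, pd.DataFrame({"z": dup}))

    def test_missing_covariate_rejected(self):
        with pytest.raises(ValueError, match="complete"):
            stats.ancova(
                [1.0, 2.0, 3.0, 4.0], ["a", "a", "b", "b"],
                pd.DataFrame({"z": [1.0, np.nan, 2.0, 3.0]}),
            )


class TestBonferroni:
    def test_multiplies_and_caps(self):
        assert stats.bonferroni_pairwise([0.01], n_pairs=6) == [0.06]
        assert stats.bonferroni_pairwise([0.5], n_pairs=3) == [1.0]

    def test_four_groups_enumerate_six_pairs(self):
        rng = np.random.default_rng(6)
        values = np.concatenate([rng.normal(m, 0.2, 6) for m in (0, 2, 4, 6)])
        groups = np.repeat(["a", "b", "c", "d"], 6)
        comp = stats.anova_oneway(values, groups)
        assert comp.p_value < 0.05
        assert len(comp.pairwise) == 6


class TestFisher:
    @staticmethod
    def hypergeom_2x2_oracle(table):
        """Closed-form two-sided Fisher p for a 2x2 table via the
        hypergeometric pmf with probability ordering."""
        (a, b), (c, d) = table
        n1, n = a + b, a + b + c + d
        k = a + c
        support = np.arange(max(0, k - (n - n1)), min(k, n1) + 1)
        pmf = sps.hypergeom.pmf(support, n, n1, k)
        p_obs = sps.hypergeom.pmf(a, n, n1, k)
        return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())

    @pytest.mark.parametrize(
        "table",
        [
            [[3, 7], [5, 2]],
            [[10, 2], [4, 9]],
            [[1, 11], [9, 3]],
            [[14, 0], [5, 6]],
            [[6, 6], [6, 6]],
        ],
    )
    def test_matches_2x2_hypergeometric_closed_form(self, table):
        p = stats.fisher_exact_rxc(table)
        assert p == pytest.approx(self.hypergeom_2x2_oracle(table), abs=1e-12)

    def test_identical_rows_give_p_one(self):
        assert stats.fisher_exact_rxc([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_zero_margin_flagged(self):
        with pytest.warns(UserWarning, match="zero margin"):
            assert stats.fisher_exact_rxc([[0, 0], [3, 4]]) == 1.0

    def test_enumeration_probabilities_sum_to_one(self):
        table = np.array([[4, 2], [1, 5], [3, 3]])
        rows, cols = table.sum(axis=1), table.sum(axis=0)
        total = table.sum()
        log_ps = [
            stats._log_table_probability(t, rows, cols, total)
            for t in stats.enumerate_margin_tables(rows, cols)
        ]
        assert np.exp(log_ps).sum() == pytest.approx(1.0, abs=1e-12)

    def test_visibility_counts_highly_significant(self):
        """Choriocapillaris visible in 14/14 controls, 5/11 early AMD, 0/33
        reticular eyes: the exact test is significant far below 0.001."""
        p = stats.fisher_exact_rxc([[14, 0], [5, 6], [0, 33]])
        assert 0.0 < p < 0.001


def test_anova_type1_rate_is_calibrated_quickly():
    rate = stats.anova_type1_rate(n_per_group=(14, 11, 23, 10),
                                  n_reps=200, seed=12)
    assert 0.01 <= rate <= 0.10
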