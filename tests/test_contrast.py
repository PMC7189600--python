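"""Donor ratios, one-sample t-test vs 1, Grubbs, KS normality, PCA, and the
PrimingContrast model surface.

Independent oracles: the t-test p-value is recomputed from the regularized
incomplete beta function; the Grubbs critical value from the published
t-quantile formula; PCA scores from an eigendecomposition of the Gram
matrix.
"""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from secretomics.contrast import (
    PrimingContrast,
    donor_ratios,
    grubbs_critical_value,
    grubbs_outlier,
    ks_normality,
    one_sample_t_vs_1,
    pca_row_centered,
    significance_call,
)


def t_cdf_p_two_sided(t_stat: float, df: int) -> float:
    """Two-sided t p-value via the regularized incomplete beta function."""
    return float(special.betainc(df / 2.0, 0.5, df / (df + t_stat * t_stat)))


class TestDonorRatios:
    def test_identical_conditions_give_unit_ratios(self):
        x = pd.Series([3.0, 5.0, 7.0], index=["D1", "D2", "D3"])
        ratios = donor_ratios(x, x)
        assert list(ratios) == [1.0, 1.0, 1.0]
        assert ratios.std(ddof=1) == 0.0

    def test_forced_arithmetic(self):
        resting = pd.Series([1.0, 2.0], index=["D1", "D2"])
        primed = pd.Series([2.0, 4.0], index=["D1", "D2"])
        ratios = donor_ratios(resting, primed)
        assert list(ratios) == [2.0, 2.0]
        assert ratios.mean() == 2.0

    def test_unpaired_donor_is_error(self):
        with pytest.raises(ValueError, match="unpaired"):
            donor_ratios(pd.Series([1.0], index=["D1"]),
                         pd.Series([1.0], index=["D2"]))

    def test_zero_resting_excluded_with_warning(self):
        resting = pd.Series([0.0, 2.0], index=["D1", "D2"])
        primed = pd.Series([1.0, 4.0], index=["D1", "D2"])
        with pytest.warns(UserWarning, match="excluded"):
            ratios = donor_ratios(resting, primed)
        assert list(ratios.index) == ["D2"]

    def test_generator_fold_recovery(self):
        """Injected fold 3.71 at small noise, 4 donors: the mean recovered
        ratio over replicates approaches the truth."""
        from secretomics.elisa import amount_table
        from secretomics.simulate import SyntheticConfig, generate_elisa_panel

        means = []
        for rep in range(200):
            cfg = SyntheticConfig(seed=1000 + rep, n_factors=12,
                                  n_detect_factors=10, n_lost_factors=0,
                                  n_gained_factors=0, factor_cv=0.15,
                                  factor_fold={"F001": 3.71})
            panel, _ = generate_elisa_panel(cfg)
            table = amount_table(panel)
            model = PrimingContrast.from_amounts(table)
            ratios = donor_ratios(model.resting.loc["F001"],
                                  model.primed.loc["F001"])
            means.append(ratios.mean())
        assert np.mean(means) == pytest.approx(3.71, rel=0.05)


class TestOneSampleT:
    def test_all_ones_convention(self):
        assert one_sample_t_vs_1([1.0, 1.0, 1.0, 1.0]) == 1.0

    def test_sd_zero_mean_off_convention(self):
        assert one_sample_t_vs_1([2.0, 2.0, 2.0]) == 0.0

    def test_matches_incomplete_beta_oracle(self):
        x = np.array([2.0, 2.2, 1.8, 2.1])
        t_stat = (x.mean() - 1.0) / (x.std(ddof=1) / math.sqrt(len(x)))
        expected = t_cdf_p_two_sided(t_stat, len(x) - 1)
        assert one_sample_t_vs_1(x) == pytest.approx(expected, rel=1e-12)

    def test_arithmetic_mean_contract(self):
        """Ratios symmetric on the log scale still test the arithmetic mean:
        (0.5, 2.0) has mean 1.25 != 1, so p < 1."""
        p = one_sample_t_vs_1([0.5, 2.0])
        x = np.array([0.5, 2.0])
        t_stat = (x.mean() - 1.0) / (x.std(ddof=1) / math.sqrt(2))
        assert p == pytest.approx(t_cdf_p_two_sided(t_stat, 1), rel=1e-12)

    def test_type_i_error_at_n4(self):
        """Under a log-normal null around 1 with n = 4 donors the rejection
        rate at alpha = 0.05 sits near, but not exactly at, the nominal
        level (arithmetic-scale test on skewed ratios)."""
        rng = np.random.default_rng(42)
        sigma = math.sqrt(math.log(1 + 0.2 ** 2))
        x = np.exp(rng.standard_normal((10_000, 4)) * sigma - sigma ** 2 / 2)
        t_stat = (x.mean(axis=1) - 1.0) / (x.std(axis=1, ddof=1) / 2.0)
        p = 2 * stats.t.sf(np.abs(t_stat), df=3)
        rate = float(np.mean(p < 0.05))
        assert 0.03 <= rate <= 0.08


class TestSignificanceCall:
    @pytest.mark.parametrize(
        "mean_ratio, p, expected",
        [
            (3.71, 0.02, "up"),
            (4.22, 0.07, "trend"),
            (1.5, 0.001, "unchanged"),    # fold criterion unmet
            (0.3, 0.01, "down"),
            (0.4, 0.09, "trend"),
            (2.5, 0.2, "unchanged"),
        ],
    )
    def test_call_rules(self, mean_ratio, p, expected):
        assert significance_call(mean_ratio, p) == expected

    def test_detection_flags_override(self):
        assert significance_call(np.nan, np.nan, detected_resting=False,
                                 detected_primed=True) == "gained"
        assert significance_call(np.nan, np.nan, detected_resting=True,
                                 detected_primed=False) == "lost"

    def test_monotone_in_log_mean_ratio(self):
        """At fixed p, moving the mean ratio further from 1 never weakens
        the call."""
        strength = {"unchanged": 0, "trend": 1, "up": 2, "down": 2}
        for p in (0.01, 0.07, 0.5):
            calls = [significance_call(r, p) for r in
                     (1.1, 1.5, 2.01, 3.0, 10.0)]
            ranks = [strength[c] for c in calls]
            assert ranks == sorted(ranks)

    def test_power_of_recovery_simulation(self):
        """Injected 4-fold effect, CV 20%, n = 4: called 'up' in >= 80% of
        simulations."""
        rng = np.random.default_rng(7)
        sigma = math.sqrt(math.log(1 + 0.2 ** 2))
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            noise = np.exp(rng.standard_normal((2, 4)) * sigma - sigma ** 2 / 2)
            ratios = 4.0 * noise[0] / noise[1]
            call = significance_call(ratios.mean(), one_sample_t_vs_1(ratios))
            hits += call == "up"
        assert hits / n_sim >= 0.80


class TestGrubbs:
    def test_flags_extreme_point(self):
        assert grubbs_outlier([1.0, 1.1, 0.9, 10.0]) == 3

    def test_constant_values_flag_nothing(self):
        assert grubbs_outlier([1.0, 1.0, 1.0]) is None

    def test_symmetric_data_without_extreme(self):
        x = [0.9, 1.0, 1.1, 1.0, 0.95, 1.05]
        g = max(abs(v - np.mean(x)) for v in x) / np.std(x, ddof=1)
        assert g <= grubbs_critical_value(len(x))
        assert grubbs_outlier(x) is None

    def test_critical_value_matches_published_formula(self):
        for n, alpha in [(4, 0.05), (6, 0.05), (10, 0.01)]:
            t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
            expected = (n - 1) / math.sqrt(n) * math.sqrt(t ** 2 / (n - 2 + t ** 2))
            assert grubbs_critical_value(n, alpha) == pytest.approx(expected)

    def test_small_n_is_domain_error(self):
        with pytest.raises(ValueError):
            grubbs_outlier([1.0, 2.0])


class TestKSNormality:
    def test_normal_draws_rarely_rejected(self):
        rng = np.random.default_rng(0)
        p_values = [ks_normality(rng.standard_normal(100), n_mc=400, seed=9)
                    for _ in range(200)]
        assert np.mean(np.array(p_values) > 0.05) >= 0.95

    def test_exponential_draws_mostly_rejected(self):
        rng = np.random.default_rng(0)
        p_values = [ks_normality(rng.exponential(size=100), n_mc=400, seed=9)
                    for _ in range(200)]
        assert np.mean(np.array(p_values) < 0.05) > 0.5

    def test_constant_values_error(self):
        with pytest.raises(ValueError):
            ks_normality([1.0, 1.0, 1.0])

    def test_statistic_agrees_with_statsmodels_lilliefors(self):
        from statsmodels.stats.diagnostic import lilliefors

        rng = np.random.default_rng(3)
        x = rng.standard_normal(50)
        p_sm = lilliefors(x, dist="norm")[1]
        p_ours = ks_normality(x, n_mc=4000, seed=1)
        # same statistic, independent null calibrations (MC vs table)
        assert (p_ours > 0.05) == (p_sm > 0.05)
        assert p_ours == pytest.approx(p_sm, abs=0.15)


class TestPCA:
    def test_identical_samples_give_equal_scores(self):
        mat = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [1.0, 2.0, 3.0]})
        scores, evr = pca_row_centered(mat)
        assert scores["PC1"].nunique() == 1

    def test_rank_one_matrix_pc1_explains_all(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=5)
        v = rng.normal(size=4)
        mat = pd.DataFrame(np.outer(u, v), columns=list("abcd"))
        _, evr = pca_row_centered(mat)
        assert evr[0] == pytest.approx(1.0)

    def test_matches_gram_eigendecomposition(self):
        """Scores match an independent eigendecomposition of the centered
        Gram matrix, up to component sign."""
        rng = np.random.default_rng(2)
        mat = pd.DataFrame(rng.normal(size=(8, 5)), columns=list("abcde"))
        scores, evr = pca_row_centered(mat)
        centered = (mat.sub(mat.mean(axis=1), axis=0)).to_numpy()
        gram = centered.T @ centered
        w, v = np.linalg.eigh(gram)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        for k in range(3):
            expected = v[:, k] * math.sqrt(w[k])
            got = scores.iloc[:, k].to_numpy()
            assert np.allclose(np.abs(got), np.abs(expected))
        assert np.allclose(evr[:3], w[:3] / w.sum())

    def test_too_few_complete_rows_error(self):
        mat = pd.DataFrame({"s1": [1.0, np.nan], "s2": [2.0, 1.0]})
        with pytest.raises(ValueError, match="complete rows"):
            pca_row_centered(mat)


class TestPrimingContrastModel:
    def test_fit_recovers_injected_effects(self):
        from secretomics.elisa import amount_table
        from secretomics.simulate import SyntheticConfig, generate_elisa_panel

        cfg = SyntheticConfig(seed=3, factor_fold={"F001": 8.0, "F002": 0.1})
        panel, truth = generate_elisa_panel(cfg)
        results = PrimingContrast.from_amounts(amount_table(panel)).fit()
        assert results.table.at["F001", "call"] == "up"
        assert results.table.at["F002", "call"] == "down"
        assert set(results.of("gained")) == set(
            truth.factor_detected.index[
                truth.factor_detected["primed"]
                & ~truth.factor_detected["resting"]])
        assert set(results.of("lost")) == set(
            truth.factor_detected.index[
                truth.factor_detected["resting"]
                & ~truth.factor_detected["primed"]])

    def test_grubbs_removal_recorded_and_n_drops(self):
        resting = pd.DataFrame([[1.0, 1.0, 1.0, 1.0]], index=["A1"],
                               columns=["D1", "D2", "D3", "D4"])
        primed = pd.DataFrame([[1.02, 0.98, 1.01, 30.0]], index=["A1"],
                              columns=["D1", "D2", "D3", "D4"])
        res = PrimingContrast(resting, primed).fit()
        assert res.table.at["A1", "outlier_donor"] == "D4"
        assert res.table.at["A1", "n"] == 3

    def test_summary_mentions_calls(self):
        resting = pd.DataFrame([[1.0, 1.0, 1.0, 1.0]], index=["A1"],
                               columns=list("abcd"))
        primed = resting * 4.0
        res = PrimingContrast(resting, primed.astype(float)).fit(grubbs=False)
        text = res.summary()
        assert "Priming contrast" in text
        assert "fold threshold" in text
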