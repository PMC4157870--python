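import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import subjects_from_counts
from dualsite.association import (
    GenotypeCounts,
    SeparationError,
    chi2_independence,
    crude_odds_ratios,
    demographics_compare,
    fit_logistic,
    genotype_distribution_test,
    hwe_test,
    model_recode,
    odds_ratio_2x2,
    power_two_group,
    tabulate_genotypes,
    welch_t_from_summary,
)


class TestTabulateGenotypes:
    def test_reconstructs_female_stratum_cells(self, table2):
        df = subjects_from_counts(table2["female"], "female")
        counts = tabulate_genotypes(df, "female")
        assert counts.case_counts == (51, 103, 61)
        assert counts.control_counts == (133, 183, 80)

    def test_missing_genotypes_excluded(self, table2):
        df = subjects_from_counts(table2["female"], "female")
        df.loc[df.index[:10], "genotype"] = "missing"
        counts = tabulate_genotypes(df, "female")
        assert counts.n_cases + counts.n_controls == len(df) - 10

    def test_all_missing_is_error(self):
        df = pd.DataFrame(
            {"status": ["case"], "sex": ["male"], "genotype": ["missing"]}
        )
        with pytest.raises(ValueError):
            tabulate_genotypes(df, "male")

    def test_random_subjects_match_hand_count(self, rng):
        df = pd.DataFrame(
            {
                "status": rng.choice(["case", "control"], 300),
                "sex": rng.choice(["male", "female"], 300),
                "genotype": rng.choice(["CC", "CG", "GG", "missing"], 300),
            }
        )
        counts = tabulate_genotypes(df, "male")
        sub = df[(df.sex == "male") & (df.genotype != "missing")]
        for status, triple in (("case", counts.case_counts), ("control", counts.control_counts)):
            for g, n in zip(("CC", "CG", "GG"), triple):
                assert n == ((sub.status == status) & (sub.genotype == g)).sum()


class TestHwe:
    def test_study_controls_p_value(self):
        res = hwe_test((538, 998, 461))
        assert res.p_value == pytest.approx(0.965, abs=5e-4)
        assert res.chi2 == pytest.approx(0.0019, abs=1e-4)
        assert sum(res.expected_counts) == pytest.approx(1997)

    def test_exact_equilibrium_counts(self):
        res = hwe_test((25, 50, 25))
        assert res.chi2 == 0.0
        assert res.p_value == 1.0

    def test_monomorphic_degenerate(self):
        res = hwe_test((100, 0, 0))
        assert (res.chi2, res.p_value) == (0.0, 1.0)

    def test_random_triples_match_direct_formula(self, rng):
        for _ in range(50):
            obs = rng.integers(1, 200, 3)
            n = obs.sum()
            p = (2 * obs[0] + obs[1]) / (2 * n)
            exp = n * np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
            chi2 = ((obs - exp) ** 2 / exp).sum()
            res = hwe_test(tuple(int(x) for x in obs))
            assert res.chi2 == pytest.approx(chi2)
            assert res.p_value == pytest.approx(stats.chi2.sf(chi2, 1))

    def test_null_rejection_rate_near_alpha(self, rng):
        # 2,000 HWE-true tables; rejection within Monte-Carlo error of 5%
        tables = rng.multinomial(400, [0.36, 0.48, 0.16], size=2000)
        rate = np.mean([hwe_test(tuple(t)).p_value < 0.05 for t in tables])
        assert 0.03 <= rate <= 0.07


class TestOddsRatio2x2:
    def test_female_hom_alt_contrast_from_study_counts(self):
        res = odds_ratio_2x2(61, 51, 80, 133)
        assert res.value == pytest.approx(1.99, abs=5e-3)
        assert res.ci_low == pytest.approx(1.25, abs=5e-3)
        assert res.ci_high == pytest.approx(3.16, abs=5e-3)

    def test_null_table_symmetric(self):
        res = odds_ratio_2x2(10, 10, 10, 10)
        assert res.value == pytest.approx(1.0)
        assert res.ci_low * res.ci_high == pytest.approx(1.0)

    def test_exposure_flip_inverts_exactly(self, rng):
        for _ in range(20):
            a, b, c, d = rng.integers(1, 100, 4)
            assert odds_ratio_2x2(a, b, c, d).value * odds_ratio_2x2(b, a, d, c).value == pytest.approx(1.0)

    def test_zero_cell_triggers_haldane_correction(self):
        res = odds_ratio_2x2(0, 10, 5, 10)
        assert res.corrected
        assert math.isfinite(res.value) and res.value > 0


class TestModelRecode:
    def test_female_dominant_cells(self, table2):
        assert model_recode(table2["female"], "dominant") == (164, 51, 263, 133)

    def test_male_recessive_cells(self, table2):
        assert model_recode(table2["male"], "recessive") == (180, 677, 381, 1220)

    def test_dominant_and_recessive_recompose_genotypes(self, table2):
        c = table2["overall"]
        a_d, b_d, c_d, d_d = model_recode(c, "dominant")
        a_r, b_r, c_r, d_r = model_recode(c, "recessive")
        assert (b_d, d_d) == (c.case_counts[0], c.control_counts[0])
        assert (a_r, c_r) == (c.case_counts[2], c.control_counts[2])
        assert a_d + b_d == b_r + a_r == sum(c.case_counts)

    def test_unknown_model_rejected(self, table2):
        with pytest.raises(ValueError):
            model_recode(table2["overall"], "codominant")


class TestFitLogistic:
    def test_single_binary_predictor_equals_closed_form(self):
        a, b, c, d = 61, 51, 80, 133  # exposed/unexposed cases, controls
        y = np.r_[np.ones(a + b), np.zeros(c + d)]
        x = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        closed = odds_ratio_2x2(a, b, c, d)
        assert fit.loc["x", "or"] == pytest.approx(closed.value, abs=1e-6)
        assert fit.loc["x", "ci_low"] == pytest.approx(closed.ci_low, abs=1e-6)
        assert fit.loc["x", "ci_high"] == pytest.approx(closed.ci_high, abs=1e-6)

    def test_female_additive_per_allele_or(self, table2):
        (contrast, cells, res), = crude_odds_ratios(table2["female"], "additive")
        assert contrast == "per-allele"
        assert res.value == pytest.approx(1.41, abs=5e-3)
        assert res.ci_low == pytest.approx(1.12, abs=5e-3)
        assert res.ci_high == pytest.approx(1.78, abs=5e-3)

    def test_covariate_recovery_on_simulated_data(self, rng):
        n = 20000
        x = rng.normal(size=n)
        z = rng.binomial(1, 0.4, n).astype(float)
        eta = -0.5 + 0.5 * x + 0.8 * z
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        fit = fit_logistic(y.astype(float), pd.DataFrame({"x": x, "z": z}))
        for name, beta in (("x", 0.5), ("z", 0.8)):
            assert abs(fit.loc[name, "coef"] - beta) < 3 * fit.loc[name, "se"]

    def test_complete_separation_raises(self):
        y = np.r_[np.ones(20), np.zeros(20)]
        x = y.copy()
        with pytest.raises((SeparationError, RuntimeError)):
            fit_logistic(y, pd.DataFrame({"x": x}))

    def test_genotype_distribution_p_smoke(self, table2):
        p = genotype_distribution_test(table2["overall"])
        assert 0.0 <= p <= 1.0


class TestDemographics:
    def test_study_smoking_and_drinking_chi2(self):
        chi2, p = chi2_independence([[647, 419], [982, 1011]])
        assert p == pytest.approx(1.611e-9, abs=2e-12)
        chi2, p = chi2_independence([[572, 486], [898, 1092]])
        assert p == pytest.approx(2.583e-6, abs=2e-9)

    def test_study_age_from_summary_statistics(self):
        t, p = welch_t_from_summary(54.96, 11.37, 1081, 55.56, 10.28, 2008)
        assert p == pytest.approx(0.149, abs=1e-3)
        t2, p2 = welch_t_from_summary(54.96, 11.37, 1081, 55.56, 10.28, 2008, equal_var=True)
        assert 0.0 < p2 < 1.0  # pooled variant available but lands at ~0.136

    def test_identical_groups_give_p_one(self):
        df = pd.DataFrame(
            {
                "status": ["case"] * 20 + ["control"] * 20,
                "sex": ["male", "female"] * 20,
                "age": list(np.linspace(40, 70, 20)) * 2,
                "smoking": ["never", "ever"] * 20,
                "drinking": ["never", "ever"] * 20,
            }
        )
        out = demographics_compare(df).set_index("variable")
        assert out.loc["sex", "p_value"] == pytest.approx(1.0)
        assert out.loc["age", "p_value"] == pytest.approx(1.0)

    def test_zero_variance_age_rejected(self):
        df = pd.DataFrame(
            {"status": ["case"] * 3 + ["control"] * 3, "age": [50.0] * 6,
             "sex": ["male"] * 6, "smoking": ["never"] * 6, "drinking": ["never"] * 6}
        )
        with pytest.raises(ValueError):
            demographics_compare(df)


class TestPower:
    def test_null_or_gives_alpha(self):
        assert power_two_group(1000, 2000, 1.0, 0.3) == pytest.approx(0.05, abs=1e-6)

    def test_monotone_in_n_and_effect(self):
        base = power_two_group(500, 500, 1.3, 0.4)
        assert power_two_group(2000, 2000, 1.3, 0.4) > base
        assert power_two_group(500, 500, 1.6, 0.4) > base
        assert power_two_group(500, 500, 1 / 1.6, 0.4) > base  # magnitude matters

    def test_matches_monte_carlo_oracle(self, rng):
        # simulate 20,000 studies at the study's scale: exposure 0.48 in
        # controls, OR 1.30, Wald test on the 2x2
        n1, n0, or_, p0 = 1081, 2008, 1.30, 0.48
        odds1 = or_ * p0 / (1 - p0)
        p1 = odds1 / (1 + odds1)
        a = rng.binomial(n1, p1, 20000)
        c = rng.binomial(n0, p0, 20000)
        b, d = n1 - a, n0 - c
        log_or = np.log(a * d / (b * c))
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        mc = np.mean(np.abs(log_or / se) > stats.norm.ppf(0.975))
        approx = power_two_group(n1, n0, or_, p0)
        assert approx == pytest.approx(mc, abs=0.01)
        assert approx == pytest.approx(0.94, abs=0.02)  # study-reported cross-check
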