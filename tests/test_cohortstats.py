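"""Statistical engine: reference limits, rank tests, ANCOVA, normative models.

Wrapped library routines are cross-checked against independent oracles:
brute-force enumeration (Mann-Whitney), the rank-difference closed form
(Spearman), the rank-sum definition (Kruskal-Wallis), and Monte-Carlo
calibration under the null.
"""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import marrowmap.cohortstats as cs
import marrowmap as mm


def brute_force_mw_p(x, y):
    """Two-sided exact Mann-Whitney p by enumerating all rank assignments."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    center = n * m / 2
    us = []
    for idx in combinations(range(n + m), n):
        u = ranks[list(idx)].sum() - n * (n + 1) / 2
        us.append(u)
    us = np.array(us)
    return float(np.mean(np.abs(us - center) >= abs(u_obs - center) - 1e-12))


class TestReferenceLimits:
    def test_normal_sample_uses_mean_2sd(self):
        rng = np.random.default_rng(0)
        x = rng.normal(65.6, 7.2, 100)
        rl = cs.reference_limits(x, "ff")
        assert rl.method == "mean_2sd"
        assert rl.lower == pytest.approx(x.mean() - 2 * x.std(ddof=1))
        assert rl.upper == pytest.approx(x.mean() + 2 * x.std(ddof=1))
        assert rl.lower < rl.upper

    def test_summary_arithmetic(self):
        assert cs.mean_2sd_limits(65.6, 7.2) == pytest.approx((51.2, 80.0))

    def test_lognormal_uses_percentiles(self):
        rng = np.random.default_rng(1)
        x = np.exp(rng.normal(0, 1, 200))
        rl = cs.reference_limits(x, "skewed")
        assert rl.method == "percentile_5_95"
        assert rl.lower == pytest.approx(np.percentile(x, 5))
        assert rl.upper == pytest.approx(np.percentile(x, 95))

    def test_method_flips_with_increasing_skew(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 1, 150)
        methods = []
        for lam in (0.05, 0.4, 1.2, 2.5):
            methods.append(cs.reference_limits(np.exp(lam * base), "x").method)
        assert methods[0] == "mean_2sd" and methods[-1] == "percentile_5_95"

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            cs.reference_limits([5.0] * 20)

    def test_too_small(self):
        with pytest.raises(ValueError):
            cs.reference_limits([1.0, 2.0])


class TestMannWhitney:
    def test_small_exact_example(self):
        r = cs.mann_whitney([1, 2], [3, 4])
        assert r.statistic == 0
        assert r.p_value == pytest.approx(1 / 3)

    def test_identical_samples(self):
        x = np.arange(10.0)
        r = cs.mann_whitney(x, x)
        assert r.p_value == pytest.approx(1.0, abs=0.01)

    def test_exact_matches_enumeration(self):
        rng = np.random.default_rng(7)
        for n in (2, 3, 5):
            for m_ in (2, 4, 6):
                vals = rng.permutation(np.arange(1.0, n + m_ + 1))
                x, y = vals[:n], vals[n:]
                r = cs.mann_whitney(x, y)
                assert r.extra["method"] == "exact"
                assert r.p_value == pytest.approx(brute_force_mw_p(x, y))

    def test_power_at_two_sd_shift(self):
        # Monte-Carlo oracle: rejection rate > 0.9 for a 2 SD shift, n=30/30
        rng = np.random.default_rng(11)
        rejections = 0
        for _ in range(500):
            x = rng.normal(0, 1, 30)
            y = rng.normal(2, 1, 30)
            if cs.mann_whitney(x, y).p_value < 0.05:
                rejections += 1
        assert rejections / 500 > 0.9

    def test_empty_group(self):
        with pytest.raises(ValueError):
            cs.mann_whitney([], [1.0])


class TestKruskalWallis:
    def test_identical_constants_h_zero(self):
        r = cs.kruskal_wallis([[3.0, 3.0], [3.0], [3.0, 3.0, 3.0]])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_matches_rank_formula(self):
        groups = [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]
        # Oracle: H = 12/(N(N+1)) * sum n_i (rbar_i - rbar)^2, no ties.
        pooled = np.concatenate(groups)
        ranks = stats.rankdata(pooled)
        n_tot = pooled.size
        h = 0.0
        start = 0
        for g in groups:
            r_i = ranks[start:start + len(g)]
            h += len(g) * (r_i.mean() - (n_tot + 1) / 2) ** 2
            start += len(g)
        h *= 12 / (n_tot * (n_tot + 1))
        assert cs.kruskal_wallis(groups).statistic == pytest.approx(h)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            cs.kruskal_wallis([[1.0, 2.0]])


class TestSpearman:
    def test_monotone_is_one(self):
        r = cs.spearman([1, 2, 3, 4], [10, 20, 21, 40])
        assert r.statistic == pytest.approx(1.0)

    def test_rank_difference_closed_form(self):
        r = cs.spearman([1, 2, 3], [3, 1, 2])
        assert r.statistic == pytest.approx(-0.5)

    def test_closed_form_on_random_permutations(self):
        rng = np.random.default_rng(4)
        for n in (5, 8, 13):
            x = np.arange(1.0, n + 1)
            y = rng.permutation(x)
            d2 = np.sum((x - y) ** 2)   # ranks equal values here
            expected = 1 - 6 * d2 / (n * (n ** 2 - 1))
            assert cs.spearman(x, y).statistic == pytest.approx(expected)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert cs.spearman(x, y).statistic == pytest.approx(
            cs.spearman(y, x).statistic)

    def test_zero_variance_flagged(self):
        r = cs.spearman([1, 1, 1], [1, 2, 3])
        assert np.isnan(r.statistic) and r.extra.get("undefined")


def _truth_table(n_per_cell, seed, zero_sex_effect=False, noiseless=False):
    """Cohort table of generator ground truth (no imaging), for model tests."""
    cfg = mm.GeneratorConfig()
    metas = mm.sample_cohort(n_per_cell, seed, cfg)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    rows = []
    for m in metas:
        t = mm.marrow_truth(m, cfg, rng=None if noiseless else rng)
        adc = t.true_adc
        if zero_sex_effect and m.sex == "F":
            adc -= 53.0
        rows.append(dict(subject_id=m.subject_id, sex=m.sex, age=m.age,
                         age_group=m.age_group, bmi=m.bmi,
                         median_ff=t.true_ff, median_adc=adc,
                         median_nsi_b50=1.5, median_nsi_b900=3.0))
    return pd.DataFrame(rows)


class TestAncova:
    def test_exact_linear_response_recovered(self):
        df = _truth_table(3, 1, noiseless=True)
        df["resp"] = 10.0 - 0.25 * df.age
        fit = cs.ancova(df, "resp")
        assert fit.coefficients["age"]["estimate"] == pytest.approx(-0.25, abs=1e-9)
        assert fit.adjusted_r2 == pytest.approx(1.0)

    def test_interaction_term_present(self):
        df = _truth_table(5, 2)
        fit = cs.ancova(df, "median_adc", interaction=True)
        assert "sex_code:age" in fit.coefficients
        assert "sex_code:age" in fit.anova

    def test_null_sex_pvalues_uniform(self):
        # KS check over 200 seeds on a response with no sex effect.
        rng = np.random.default_rng(8)
        ages = np.tile(np.repeat([35, 45, 55, 65, 75], 4), 2)
        sexes = np.repeat(["M", "F"], 20)
        pvals = []
        for _ in range(200):
            df = pd.DataFrame({"sex": sexes, "age": ages,
                               "resp": rng.normal(0, 1, 40)})
            pvals.append(cs.ancova(df, "resp").anova["sex_code"]["p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestNormativeModels:
    def test_exact_tables_recover_coefficients(self):
        df = _truth_table(2, 3, noiseless=True)
        models = cs.fit_normative(df)
        ff, adc = models["ff_model"], models["adc_model"]
        assert ff.coef("age") == pytest.approx(0.3, abs=1e-9)
        assert ff.coef("Intercept") == pytest.approx(49.0, abs=1e-7)
        assert adc.coef("sex_code") == pytest.approx(53.0, abs=1e-8)
        assert adc.coef("age") == pytest.approx(-1.0, abs=1e-9)

    def test_single_sex_rejected(self):
        df = _truth_table(2, 3)
        with pytest.raises(ValueError):
            cs.fit_normative(df[df.sex == "M"])

    def test_recovery_across_seeds(self):
        # Mean fitted slope over 100 seeds stays near truth (generator-level).
        ff_slopes, sex_coefs = [], []
        for seed in range(100):
            df = _truth_table(10, seed)
            models = cs.fit_normative(df)
            ff_slopes.append(models["ff_model"].coef("age"))
            sex_coefs.append(models["adc_model"].coef("sex_code"))
        assert abs(np.mean(ff_slopes) - 0.3) < 0.03
        assert abs(np.mean(sex_coefs) - 53.0) < 5.0


class TestPredict:
    @pytest.mark.parametrize("age,expected", [(30, 58.0), (80, 73.0)])
    def test_ff_predictions(self, age, expected):
        assert cs.predict("ff", age) == pytest.approx(expected)

    @pytest.mark.parametrize("sex,age,expected", [("M", 30, 450.0),
                                                  ("F", 30, 503.0),
                                                  ("F", 85, 448.0)])
    def test_adc_predictions(self, sex, age, expected):
        assert cs.predict("adc", age, sex=sex) == pytest.approx(expected)

    def test_adc_requires_sex(self):
        with pytest.raises(ValueError):
            cs.predict("adc", 40)

    def test_age_range_enforced(self):
        with pytest.raises(ValueError):
            cs.predict("ff", 20)


class TestGroupCompare:
    def test_structure_and_single_band_error(self):
        df = _truth_table(4, 6)
        results = cs.group_compare(df, "median_adc")
        mw = [r for r in results if r.test == "mann_whitney"]
        kw = [r for r in results if r.test == "kruskal_wallis"]
        assert len(mw) == 5 and len(kw) == 2
        with pytest.raises(ValueError):
            cs.group_compare(df[df.age_group == "30-39"], "median_adc")

    def test_null_false_positive_rate(self):
        rng = np.random.default_rng(9)
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            if cs.mann_whitney(rng.normal(0, 1, 10), rng.normal(0, 1, 10)).p_value < 0.05:
                hits += 1
        assert 0.02 < hits / n_rep < 0.09
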