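"""Cohort-level statistics: reference limits, nonparametric comparisons,
ANCOVA and the normative sex/age models.

The battery mirrors standard normative-imaging practice: Shapiro-Wilk-gated
reference limits (mean +/- 2SD if normal, else empirical 5th/95th
percentiles), Mann-Whitney U between sexes, Kruskal-Wallis across 10-year age
bands within sex, Spearman rank correlation with age, ANCOVA (Type II sums of
squares) for sex/age effects, and OLS normative models

    %FF  ~ age                  (published coefficients: 0.3 * Age + 49)
    ADC  ~ sex + age            (published: 480 + 53 * Sex - Age,
                                 Sex = 0 for men, 1 for women)

No multiplicity adjustment is applied (matching the reporting convention the
package reproduces: p < 0.05 significant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

#: Sex coding used by every model in this module (single source of truth).
SEX_CODE = {"M": 0, "F": 1}

#: Published normative coefficients (reporting units: % and um^2/s).
NORMATIVE_FF = {"intercept": 49.0, "age": 0.3}
NORMATIVE_ADC = {"intercept": 480.0, "sex": 53.0, "age": -1.0}

PARAMETERS = ("median_ff", "median_nsi_b50", "median_nsi_b900", "median_adc")


@dataclass
class ReferenceLimits:
    parameter: str
    mean: float
    sd: float
    lower: float
    upper: float
    method: str          # "mean_2sd" | "percentile_5_95"
    shapiro_p: float
    n: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    group_sizes: tuple
    label: str = ""
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    def as_dict(self) -> dict:
        d = dict(test=self.test, statistic=self.statistic, p_value=self.p_value,
                 group_sizes=list(self.group_sizes), label=self.label)
        d.update(self.extra)
        return d


@dataclass
class ModelFit:
    formula: str
    coefficients: dict       # name -> {estimate, se, p}
    adjusted_r2: float
    f_statistic: float
    df: tuple                # (df_model, df_resid)
    n: int
    anova: dict = field(default_factory=dict)   # term -> {F, p} (Type II)

    def coef(self, name: str) -> float:
        return self.coefficients[name]["estimate"]

    def se(self, name: str) -> float:
        return self.coefficients[name]["se"]

    def as_dict(self) -> dict:
        return dict(formula=self.formula, coefficients=self.coefficients,
                    adjusted_r2=self.adjusted_r2, f_statistic=self.f_statistic,
                    df=list(self.df), n=self.n, anova=self.anova)


def mean_2sd_limits(mean: float, sd: float) -> tuple[float, float]:
    """Normal-range bounds under normality: mean -/+ 2 SD."""
    return mean - 2.0 * sd, mean + 2.0 * sd


def reference_limits(values, parameter: str = "", alpha: float = 0.05) -> ReferenceLimits:
    """Shapiro-Wilk-gated reference limits.

    Normal (p >= alpha): mean +/- 2 * sample SD (n-1 denominator); otherwise
    empirical 5th/95th percentiles (linear interpolation between order
    statistics).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("reference limits require n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) sample: Shapiro-Wilk undefined")
    w, p = stats.shapiro(x)
    mean, sd = float(np.mean(x)), float(np.std(x, ddof=1))
    if p >= alpha:
        lower, upper = mean_2sd_limits(mean, sd)
        method = "mean_2sd"
    else:
        lower, upper = np.percentile(x, [5, 95], method="linear")
        method = "percentile_5_95"
    return ReferenceLimits(parameter=parameter, mean=mean, sd=sd,
                           lower=float(lower), upper=float(upper),
                           method=method, shapiro_p=float(p), n=int(x.size))


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U: exact for small tie-free samples
    (min n <= 8), normal approximation with tie correction otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and min(x.size, y.size) <= 8) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(test="mann_whitney", statistic=float(res.statistic),
                      p_value=float(res.pvalue), group_sizes=(x.size, y.size),
                      extra={"method": method})


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H with tie correction; p from chi-square (k-1 df)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis requires >= 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:       # identical constants: H = 0 by definition
        return TestResult(test="kruskal_wallis", statistic=0.0, p_value=1.0,
                          group_sizes=tuple(g.size for g in groups))
    h, p = stats.kruskal(*groups)
    return TestResult(test="kruskal_wallis", statistic=float(h), p_value=float(p),
                      group_sizes=tuple(g.size for g in groups))


def spearman(x, y) -> TestResult:
    """Spearman rank correlation (tie-aware mid-ranks), p via t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman requires two equal-length samples, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult(test="spearman", statistic=float("nan"),
                          p_value=float("nan"), group_sizes=(x.size,),
                          extra={"undefined": True})
    r, p = stats.spearmanr(x, y)
    return TestResult(test="spearman", statistic=float(r), p_value=float(p),
                      group_sizes=(x.size,))


# ---------------------------------------------------------------------------
# Models

def _with_sex_code(table: pd.DataFrame) -> pd.DataFrame:
    df = table.copy()
    if "sex_code" not in df:
        df["sex_code"] = df["sex"].map(SEX_CODE)
        if df["sex_code"].isna().any():
            raise ValueError("sex column must contain only 'M'/'F'")
    return df


def _model_fit(fit, formula: str, anova: dict | None = None) -> ModelFit:
    coefs = {name: {"estimate": float(fit.params[name]),
                    "se": float(fit.bse[name]),
                    "p": float(fit.pvalues[name])}
             for name in fit.params.index}
    return ModelFit(formula=formula, coefficients=coefs,
                    adjusted_r2=float(fit.rsquared_adj),
                    f_statistic=float(fit.fvalue),
                    df=(int(fit.df_model), int(fit.df_resid)),
                    n=int(fit.nobs), anova=anova or {})


def ancova(table: pd.DataFrame, response: str,
           interaction: bool = False) -> ModelFit:
    """OLS of ``response ~ sex + age`` (optionally + sex:age) with Type II
    partial F tests per term."""
    df = _with_sex_code(table).dropna(subset=[response])
    formula = f"{response} ~ sex_code + age"
    if interaction:
        formula += " + sex_code:age"
    fit = smf.ols(formula, data=df).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValueError("rank-deficient design matrix")
    aov = sm.stats.anova_lm(fit, typ=2)
    anova = {term: {"F": float(row["F"]), "p": float(row["PR(>F)"]),
                    "df": float(row["df"])}
             for term, row in aov.iterrows() if term != "Residual"}
    return _model_fit(fit, formula, anova)


def fit_normative(table: pd.DataFrame) -> dict:
    """Fit the two normative models on a cohort table.

    Returns {"ff_model": %FF ~ age, "adc_model": ADC ~ sex + age}.
    """
    df = _with_sex_code(table)
    if len(df) < 10:
        raise ValueError("normative fits require >= 10 subjects")
    if df["sex_code"].nunique() < 2:
        raise ValueError("ADC model requires both sexes in the table")
    ff_fit = smf.ols("median_ff ~ age", data=df).fit()
    adc_fit = smf.ols("median_adc ~ sex_code + age", data=df).fit()
    return {"ff_model": _model_fit(ff_fit, "median_ff ~ age"),
            "adc_model": _model_fit(adc_fit, "median_adc ~ sex_code + age")}


def predict(model: str, age: float, sex: str | None = None,
            fit: ModelFit | None = None) -> float:
    """Evaluate a normative model at (sex, age).

    Uses the published default coefficients unless a fitted ModelFit is
    given. ``sex`` is required for the ADC model.
    """
    if not (30 <= age <= 85):
        raise ValueError("age must be within 30-85 years")
    if model == "ff":
        if fit is not None:
            return fit.coef("Intercept") + fit.coef("age") * age
        return NORMATIVE_FF["intercept"] + NORMATIVE_FF["age"] * age
    if model == "adc":
        if sex not in SEX_CODE:
            raise ValueError("ADC prediction requires sex 'M' or 'F'")
        s = SEX_CODE[sex]
        if fit is not None:
            return (fit.coef("Intercept") + fit.coef("sex_code") * s
                    + fit.coef("age") * age)
        return (NORMATIVE_ADC["intercept"] + NORMATIVE_ADC["sex"] * s
                + NORMATIVE_ADC["age"] * age)
    raise ValueError(f"unknown model {model!r}; expected 'ff' or 'adc'")


def group_compare(table: pd.DataFrame, parameter: str) -> list[TestResult]:
    """Per-age-band Mann-Whitney (M vs F) and per-sex Kruskal-Wallis across
    bands, alpha = 0.05, no multiplicity adjustment."""
    df = _with_sex_code(table).dropna(subset=[parameter])
    results = []
    for band, sub in df.groupby("age_group", sort=True):
        x = sub.loc[sub.sex == "M", parameter].to_numpy()
        y = sub.loc[sub.sex == "F", parameter].to_numpy()
        if x.size and y.size:
            r = mann_whitney(x, y)
            r.label = f"{parameter} M-vs-F {band}"
            results.append(r)
    for sex, sub in df.groupby("sex"):
        groups = [g[parameter].to_numpy() for _, g in sub.groupby("age_group")]
        r = kruskal_wallis(groups)
        r.label = f"{parameter} across-bands {sex}"
        results.append(r)
    return results
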