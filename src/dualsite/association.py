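"""Case-control association statistics for a single biallelic variant.

Covers the classic single-SNP toolkit: Hardy-Weinberg goodness of fit in
controls, demographics comparison (Welch/pooled t, Pearson chi-square),
crude odds ratios with Woolf confidence intervals under four genetic models
(genotype, additive, dominant, recessive), covariate-adjusted odds ratios by
maximum-likelihood logistic regression, sex-stratified analyses, and a
normal-approximation power computation.

Genotypes are coded hom-ref / het / hom-alt (default labels CC / CG / GG for
a C/G variant); the alt allele is the risk allele whose dosage enters the
additive model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger(__name__)

GENOTYPE_LABELS = ("CC", "CG", "GG")  # hom-ref, het, hom-alt
MODELS = ("genotype", "additive", "dominant", "recessive")
STRATA = ("overall", "male", "female")
Z95 = stats.norm.ppf(0.975)


class SeparationError(RuntimeError):
    """Complete/quasi-complete separation: the MLE does not exist."""


@dataclass(frozen=True)
class GenotypeCounts:
    """3x2 genotype-by-status table (hom-ref, het, hom-alt)."""

    case_counts: tuple[int, int, int]
    control_counts: tuple[int, int, int]
    stratum: str = "overall"

    @property
    def n_cases(self) -> int:
        return sum(self.case_counts)

    @property
    def n_controls(self) -> int:
        return sum(self.control_counts)


@dataclass(frozen=True)
class HweResult:
    chi2: float
    df: int
    p_value: float
    expected_counts: tuple[float, float, float]


@dataclass(frozen=True)
class OddsRatio:
    value: float
    ci_low: float
    ci_high: float
    p_value: float
    corrected: bool = False  # Haldane-Anscombe 0.5 applied to a zero cell


@dataclass(frozen=True)
class AssociationResult:
    model: str
    contrast: str  # e.g. "CG vs CC", "per-allele", "CG+GG vs CC"
    stratum: str
    counts: str  # "cases/controls" exposed cells, Table-2 style
    or_crude: OddsRatio
    or_adjusted: OddsRatio | None = None


def tabulate_genotypes(
    subjects: pd.DataFrame,
    stratum: str = "overall",
    labels: tuple[str, str, str] = GENOTYPE_LABELS,
) -> GenotypeCounts:
    """Genotype counts per status within a stratum; missing genotypes dropped."""
    df = subjects
    if stratum != "overall":
        df = df[df["sex"] == stratum]
    if df.empty:
        raise ValueError(f"stratum {stratum!r} contains no subjects")
    genotyped = df[df["genotype"].isin(labels)]
    n_missing = len(df) - len(genotyped)
    if genotyped.empty:
        raise ValueError(f"stratum {stratum!r} has no genotyped subjects")
    if n_missing:
        log.info("stratum %s: excluded %d subjects without genotype", stratum, n_missing)

    def triple(status: str) -> tuple[int, int, int]:
        sub = genotyped[genotyped["status"] == status]
        return tuple(int((sub["genotype"] == g).sum()) for g in labels)

    return GenotypeCounts(triple("case"), triple("control"), stratum=stratum)


def hwe_test(control_counts: tuple[int, int, int]) -> HweResult:
    """Goodness-of-fit chi-square against Hardy-Weinberg proportions.

    Allele frequency is estimated from the counts themselves; the test has
    one degree of freedom. Monomorphic input returns chi2 = 0, p = 1.
    """
    obs = np.asarray(control_counts, dtype=float)
    n = obs.sum()
    if n <= 0:
        raise ValueError("control genotype counts sum to zero")
    p = (2 * obs[0] + obs[1]) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        log.warning("monomorphic genotype counts; HWE test degenerate")
        return HweResult(0.0, 1, 1.0, tuple(obs))
    exp = n * np.array([p * p, 2 * p * q, q * q])
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return HweResult(chi2, 1, float(stats.chi2.sf(chi2, 1)), tuple(exp))


def odds_ratio_2x2(a: float, b: float, c: float, d: float) -> OddsRatio:
    """Cross-product odds ratio with Woolf 95% CI and Wald p-value.

    ``a``/``b`` are exposed/unexposed cases, ``c``/``d`` exposed/unexposed
    controls. Any zero cell triggers the Haldane-Anscombe 0.5 correction and
    flags the result.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any():
        raise ValueError("cell counts must be non-negative")
    corrected = bool((cells == 0).any())
    if corrected:
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    log_or = math.log(a_ * d_ / (b_ * c_))
    se = math.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    z = log_or / se
    return OddsRatio(
        math.exp(log_or),
        math.exp(log_or - Z95 * se),
        math.exp(log_or + Z95 * se),
        float(2 * stats.norm.sf(abs(z))),
        corrected,
    )


def model_recode(counts: GenotypeCounts, model: str):
    """Recode a genotype table under a genetic model.

    genotype  -> two (a, b, c, d) tables: het vs hom-ref, hom-alt vs hom-ref
    dominant  -> (het + hom-alt) vs hom-ref
    recessive -> hom-alt vs (hom-ref + het)
    additive  -> (dosage values, case counts, control counts) for 0/1/2
    """
    (r0, r1, r2) = counts.case_counts
    (s0, s1, s2) = counts.control_counts
    if model == "genotype":
        return [(r1, r0, s1, s0), (r2, r0, s2, s0)]
    if model == "dominant":
        return (r1 + r2, r0, s1 + s2, s0)
    if model == "recessive":
        return (r2, r0 + r1, s2, s0 + s1)
    if model == "additive":
        return (np.array([0, 1, 2]), np.array([r0, r1, r2]), np.array([s0, s1, s2]))
    raise ValueError(f"unknown genetic model {model!r}; use one of {MODELS}")


def _expand_dosage(counts: GenotypeCounts) -> tuple[np.ndarray, np.ndarray]:
    dose, cases, ctrls = model_recode(counts, "additive")
    y = np.r_[np.ones(cases.sum()), np.zeros(ctrls.sum())]
    x = np.r_[np.repeat(dose, cases), np.repeat(dose, ctrls)].astype(float)
    return y, x


def fit_logistic(outcome: np.ndarray, design: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """ML logistic fit (IRLS); returns per-coefficient OR, Wald 95% CI and p.

    The design matrix should NOT include an intercept; one is added. Raises
    :class:`SeparationError` on perfect prediction and ``RuntimeError`` on
    non-convergence.
    """
    X = sm.add_constant(pd.DataFrame(design), has_constant="add")
    y = np.asarray(outcome, dtype=float)
    if len(y) <= X.shape[1]:
        raise ValueError("more parameters than observations")
    model = sm.Logit(y, X.astype(float))
    try:
        res = model.fit(disp=0, maxiter=100)
    except np.linalg.LinAlgError as exc:
        raise SeparationError(f"singular information matrix: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError(f"logistic fit did not converge: {res.mle_retvals}")
    fitted = res.predict(X)
    if np.all((fitted > 1 - 1e-10) == (y == 1)) and len(np.unique(y)) == 2 and (
        np.abs(fitted - y) < 1e-10
    ).all():
        raise SeparationError("complete separation: fitted probabilities are 0/1")
    ci = res.conf_int()
    out = pd.DataFrame(
        {
            "coef": res.params,
            "se": res.bse,
            "or": np.exp(res.params),
            "ci_low": np.exp(ci[0]),
            "ci_high": np.exp(ci[1]),
            "p_value": res.pvalues,
        }
    )
    return out


def crude_odds_ratios(counts: GenotypeCounts, model: str) -> list[tuple[str, str, OddsRatio]]:
    """Crude OR(s) for one genetic model from the genotype table alone.

    Returns ``(contrast, "a/c" exposed counts, OddsRatio)`` tuples. The
    additive model fits a single-predictor dosage logistic regression; the
    other models use the closed-form 2x2 computation.
    """
    g = GENOTYPE_LABELS
    if model == "genotype":
        tables = model_recode(counts, model)
        out = []
        for label, (a, b, c, d) in zip((f"{g[1]} vs {g[0]}", f"{g[2]} vs {g[0]}"), tables):
            out.append((label, f"{a}/{c}", odds_ratio_2x2(a, b, c, d)))
        return out
    if model == "additive":
        y, x = _expand_dosage(counts)
        fit = fit_logistic(y, pd.DataFrame({"dosage": x}))
        row = fit.loc["dosage"]
        het = counts.case_counts[1], counts.control_counts[1]
        return [
            (
                "per-allele",
                f"{het[0]}/{het[1]}",
                OddsRatio(row["or"], row["ci_low"], row["ci_high"], row["p_value"]),
            )
        ]
    a, b, c, d = model_recode(counts, model)
    contrast = f"{g[1]}+{g[2]} vs {g[0]}" if model == "dominant" else f"{g[2]} vs {g[0]}+{g[1]}"
    return [(contrast, f"{a}/{c}", odds_ratio_2x2(a, b, c, d))]


def genotype_distribution_test(counts: GenotypeCounts) -> float:
    """Pearson chi-square p for the 3x2 genotype-by-status distribution."""
    table = np.array([counts.case_counts, counts.control_counts], dtype=float)
    table = table[:, table.sum(axis=0) > 0]
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


# ---------------------------------------------------------------------------
# subject-level analyses
# ---------------------------------------------------------------------------


def _genetic_design(genotype: pd.Series, model: str) -> pd.DataFrame:
    g0, g1, g2 = GENOTYPE_LABELS
    if model == "genotype":
        return pd.DataFrame(
            {g1: (genotype == g1).astype(float), g2: (genotype == g2).astype(float)}
        )
    if model == "additive":
        return pd.DataFrame({"dosage": genotype.map({g0: 0.0, g1: 1.0, g2: 2.0})})
    if model == "dominant":
        return pd.DataFrame({"carrier": genotype.isin([g1, g2]).astype(float)})
    if model == "recessive":
        return pd.DataFrame({"hom_alt": (genotype == g2).astype(float)})
    raise ValueError(f"unknown genetic model {model!r}")


def _covariate_design(df: pd.DataFrame, adjust: list[str], unknown: str) -> pd.DataFrame:
    cols = {}
    for cov in adjust:
        if cov == "age":
            cols["age"] = df["age"].astype(float)
        elif cov in ("smoking", "drinking"):
            cols[f"{cov}_ever"] = (df[cov] == "ever").astype(float)
            if unknown == "level":
                cols[f"{cov}_unknown"] = (df[cov] == "unknown").astype(float)
        elif cov in ("gender", "sex"):
            cols["male"] = (df["sex"] == "male").astype(float)
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    return pd.DataFrame(cols, index=df.index)


def associate(
    subjects: pd.DataFrame,
    models: tuple[str, ...] = MODELS,
    strata: tuple[str, ...] = STRATA,
    adjust: list[str] | None = None,
    unknown: str = "level",
) -> list[AssociationResult]:
    """Crude and (optionally) adjusted ORs per genetic model and stratum.

    ``adjust`` lists covariates for the multivariable logistic model; in
    sex-specific strata a requested gender covariate is dropped. ``unknown``
    controls smoking/drinking "unknown" handling in adjusted fits: keep as an
    indicator level (default, preserves n) or exclude those subjects.
    """
    if unknown not in ("level", "exclude"):
        raise ValueError("unknown= must be 'level' or 'exclude'")
    results: list[AssociationResult] = []
    for stratum in strata:
        counts = tabulate_genotypes(subjects, stratum)
        df = subjects if stratum == "overall" else subjects[subjects["sex"] == stratum]
        df = df[df["genotype"].isin(GENOTYPE_LABELS)].copy()
        for model in models:
            crude = crude_odds_ratios(counts, model)
            adjusted: list[OddsRatio | None] = [None] * len(crude)
            if adjust:
                cov = [c for c in adjust if stratum == "overall" or c not in ("gender", "sex")]
                sub = df
                if unknown == "exclude":
                    sub = sub[
                        (sub.get("smoking", "never") != "unknown")
                        & (sub.get("drinking", "never") != "unknown")
                    ]
                design = pd.concat(
                    [
                        _genetic_design(sub["genotype"], model),
                        _covariate_design(sub, cov, unknown),
                    ],
                    axis=1,
                )
                fit = fit_logistic((sub["status"] == "case").to_numpy(float), design)
                gene_cols = _genetic_design(sub["genotype"], model).columns
                adjusted = [
                    OddsRatio(
                        fit.loc[c, "or"], fit.loc[c, "ci_low"],
                        fit.loc[c, "ci_high"], fit.loc[c, "p_value"],
                    )
                    for c in gene_cols
                ]
            for (contrast, cells, or_crude), or_adj in zip(crude, adjusted):
                results.append(
                    AssociationResult(model, contrast, stratum, cells, or_crude, or_adj)
                )
    return results


def association_table(results: list[AssociationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "model": r.model, "contrast": r.contrast, "stratum": r.stratum,
            "cases/controls": r.counts,
            "or_crude": r.or_crude.value, "crude_ci_low": r.or_crude.ci_low,
            "crude_ci_high": r.or_crude.ci_high, "p_crude": r.or_crude.p_value,
        }
        if r.or_adjusted is not None:
            row.update(
                or_adjusted=r.or_adjusted.value,
                adj_ci_low=r.or_adjusted.ci_low,
                adj_ci_high=r.or_adjusted.ci_high,
                p_adjusted=r.or_adjusted.p_value,
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# demographics
# ---------------------------------------------------------------------------


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-sample t test from summary statistics (Welch by default)."""
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var)
    return float(t), float(p)


def chi2_independence(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square of independence without continuity correction."""
    chi2, p, _, _ = stats.chi2_contingency(np.asarray(table, float), correction=False)
    return float(chi2), float(p)


def demographics_compare(subjects: pd.DataFrame, equal_var: bool = False) -> pd.DataFrame:
    """Case-control comparison of age (t test) and categorical covariates (chi2).

    Smoking/drinking "unknown" subjects are excluded from those chi-square
    tests; sex uses the full 2x2.
    """
    cases = subjects[subjects["status"] == "case"]
    ctrls = subjects[subjects["status"] == "control"]
    if len(cases) < 2 or len(ctrls) < 2:
        raise ValueError("need >= 2 subjects per group")
    rows = []
    age_case, age_ctrl = cases["age"].dropna(), ctrls["age"].dropna()
    if age_case.std(ddof=1) == 0 and age_ctrl.std(ddof=1) == 0:
        raise ValueError("zero age variance in both groups")
    t, p = stats.ttest_ind(age_case, age_ctrl, equal_var=equal_var)
    rows.append({"variable": "age", "test": "welch_t" if not equal_var else "pooled_t",
                 "statistic": float(t), "p_value": float(p)})
    for var, levels in (
        ("sex", ("male", "female")),
        ("smoking", ("never", "ever")),
        ("drinking", ("never", "ever")),
    ):
        if var not in subjects.columns:
            continue
        table = np.array(
            [[(grp[var] == lv).sum() for lv in levels] for grp in (cases, ctrls)],
            dtype=float,
        )
        if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
            continue
        chi2, p = chi2_independence(table)
        rows.append({"variable": var, "test": "pearson_chi2",
                     "statistic": chi2, "p_value": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------


def power_two_group(
    n_case: int,
    n_control: int,
    detectable_or: float,
    control_freq: float,
    alpha: float = 0.05,
) -> float:
    """Normal-approximation power of the two-sided log-OR Wald test.

    ``control_freq`` is the exposure frequency among controls; case exposure
    frequency follows from the odds ratio. The SE uses expected cell counts.
    """
    if min(n_case, n_control, detectable_or) <= 0 or not 0 < control_freq < 1:
        raise ValueError("sample sizes, OR and control_freq must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    p0 = control_freq
    odds1 = detectable_or * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    se = math.sqrt(
        1 / (n_case * p1) + 1 / (n_case * (1 - p1))
        + 1 / (n_control * p0) + 1 / (n_control * (1 - p0))
    )
    z = stats.norm.ppf(1 - alpha / 2)
    shift = abs(math.log(detectable_or)) / se
    return float(stats.norm.cdf(shift - z) + stats.norm.cdf(-shift - z))
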