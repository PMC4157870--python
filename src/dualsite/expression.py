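"""Genotype-stratified relative expression from qPCR cycle thresholds.

Relative expression uses the 2^-dCt method with a reference gene:
dCt = mean Ct_target - mean Ct_reference per sample (technical replicates
averaged), rel = 2^-dCt. Samples whose replicate Ct coefficient of variation
exceeds 5% on either gene are flagged for re-analysis. Group differences are
tested non-parametrically (Kruskal-Wallis across genotypes, pairwise
Mann-Whitney).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

CV_THRESHOLD = 0.05  # duplicate QC: re-analyze samples with CV > 5%
EXACT_MW_MAX_N = 20  # combined sample size up to which the exact MW null is used


@dataclass(frozen=True)
class RelativeExpression:
    sample_id: str
    genotype: str
    delta_ct: float
    rel_expr: float
    qc_flag: str  # "pass" | "high_cv"


def _cv(values: np.ndarray) -> float:
    """Coefficient of variation (sample SD / mean); 0 for a single replicate."""
    if len(values) < 2:
        return 0.0
    m = values.mean()
    if m == 0:
        return np.inf
    return float(values.std(ddof=1) / abs(m))


def relative_expression(
    records: pd.DataFrame,
    cv_threshold: float = CV_THRESHOLD,
    cv_on: str = "ct",
) -> list[RelativeExpression]:
    """Per-sample 2^-dCt from a Ct table.

    ``records`` needs columns sample_id, genotype, ct_target, ct_reference
    (one row per technical replicate). ``cv_on`` selects whether the QC CV is
    computed on raw Ct replicates (default) or on linearized 2^-Ct values.
    """
    required = {"sample_id", "genotype", "ct_target", "ct_reference"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
    if cv_on not in ("ct", "linear"):
        raise ValueError("cv_on must be 'ct' or 'linear'")
    bad_ct = records[["ct_target", "ct_reference"]].isna()
    if bad_ct.to_numpy().any():
        bad = records.loc[bad_ct.any(axis=1), "sample_id"].unique()
        raise ValueError(f"missing Ct values for samples: {list(bad)}")

    out: list[RelativeExpression] = []
    for sample_id, grp in records.groupby("sample_id", sort=True):
        tgt = grp["ct_target"].to_numpy(float)
        ref = grp["ct_reference"].to_numpy(float)
        if not ((0 < tgt) & (tgt <= 45)).all() or not ((0 < ref) & (ref <= 45)).all():
            raise ValueError(f"sample {sample_id}: Ct outside plausible (0, 45]")
        if cv_on == "ct":
            cvs = (_cv(tgt), _cv(ref))
        else:
            cvs = (_cv(2.0 ** -tgt), _cv(2.0 ** -ref))
        delta = float(tgt.mean() - ref.mean())
        out.append(
            RelativeExpression(
                sample_id=str(sample_id),
                genotype=str(grp["genotype"].iloc[0]),
                delta_ct=delta,
                rel_expr=float(2.0 ** -delta),
                qc_flag="high_cv" if max(cvs) > cv_threshold else "pass",
            )
        )
    return out


def expression_frame(values: list[RelativeExpression]) -> pd.DataFrame:
    return pd.DataFrame([v.__dict__ for v in values])


def mann_whitney(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney p; exact null for small untied samples,
    otherwise normal approximation with tie and continuity correction."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.r_[x, y]
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= EXACT_MW_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def group_compare(
    values: list[RelativeExpression] | pd.DataFrame,
    group_col: str = "genotype",
    value_col: str = "rel_expr",
    min_group: int = 2,
) -> dict:
    """Kruskal-Wallis across groups plus pairwise two-sided Mann-Whitney.

    Groups with fewer than ``min_group`` observations are skipped (warned).
    All-tied data yields kw_p = 1 with a degenerate-data warning.
    """
    df = values if isinstance(values, pd.DataFrame) else expression_frame(values)
    groups = {
        str(g): sub[value_col].to_numpy(float)
        for g, sub in df.groupby(group_col, sort=True)
    }
    usable = {}
    for g, v in groups.items():
        if len(v) < min_group:
            log.warning("group %s has %d < %d samples; skipped", g, len(v), min_group)
        else:
            usable[g] = v
    if len(usable) < 2:
        raise ValueError("need >= 2 groups with enough samples")
    pooled = np.concatenate(list(usable.values()))
    if np.all(pooled == pooled[0]):
        log.warning("all values identical; group test degenerate")
        kw_p = 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kw_p = float(stats.kruskal(*usable.values()).pvalue)
    pairwise = {
        f"{g1} vs {g2}": mann_whitney(usable[g1], usable[g2])
        for g1, g2 in itertools.combinations(sorted(usable), 2)
    }
    return {"kw_p": kw_p, "pairwise_mw_p": pairwise, "group_sizes": {g: len(v) for g, v in usable.items()}}


def plot_expression(values: list[RelativeExpression], path: str) -> None:
    """Vertical scatter of relative expression per genotype with median lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = expression_frame(values)
    genotypes = sorted(df["genotype"].unique())
    fig, ax = plt.subplots(figsize=(4, 4))
    rng = np.random.default_rng(0)
    for i, g in enumerate(genotypes):
        y = df.loc[df["genotype"] == g, "rel_expr"]
        x = i + rng.uniform(-0.12, 0.12, len(y))
        ax.plot(x, y, "o", ms=4, alpha=0.7)
        ax.hlines(y.median(), i - 0.25, i + 0.25, color="black")
    ax.set_xticks(range(len(genotypes)), genotypes)
    ax.set_ylabel("relative expression (2^-dCt)")
    ax.set_xlabel("genotype")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
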