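"""Phenotype-function association statistics over a two-group cohort.

Spearman rank correlations between cellular phenotype variables and the
functional outcomes (Rmax obstruction, PD200 ratio, change in baseline Bi),
with exact permutation p-values at the study's small group sizes; unpaired
and paired t-tests for group comparisons; and repeated-measures ANOVA with
Dunnett-style contrasts against the baseline level for the challenge
series. No multiple-testing correction is applied to the primary p-values
(a Benjamini-Hochberg column is reported alongside for transparency).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssociationResult",
    "spearman",
    "correlation_report",
    "group_tests",
    "rm_anova_dunnett",
    "DEFAULT_PAIRS",
]

#: largest sample size for which the permutation p-value is exact
EXACT_PERMUTATION_N = 9

OUTCOMES = ("rmax", "pd200_ratio", "dbaseline_bi")

#: variable pairs of the standard correlation report
DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (
    ("pd200_ratio", "rmax"),
    ("rmax", "dbaseline_bi"),
    ("pd200_ratio", "dbaseline_bi"),
    ("gsh", "pd200_ratio"),
    ("gsh", "rmax"),
    ("gsh", "dbaseline_bi"),
    ("gsh", "pct_tgfb1"),
    ("pct_tgfb1", "rmax"),
    ("pct_tgfb1", "pd200_ratio"),
    ("pct_tgfb1", "dbaseline_bi"),
    ("pct_il13", "rmax"),
    ("pct_il13", "pd200_ratio"),
    ("pct_il13", "dbaseline_bi"),
    ("pct_serca2b", "rmax"),
    ("pct_serca2b", "pd200_ratio"),
    ("pct_serca2b", "dbaseline_bi"),
    ("pct_serca2b", "pct_il13"),
)


@dataclass(frozen=True)
class AssociationResult:
    var_x: str
    var_y: str
    r: float
    p: float
    n: int
    method: str  # "exact-permutation" | "asymptotic"
    flag: str | None = None  # e.g. "constant-input"


@lru_cache(maxsize=4)
def _permutation_matrix(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def spearman(x, y, var_x: str = "x", var_y: str = "y") -> AssociationResult:
    """Spearman rank correlation with average ranks for ties.

    Missing values are removed pairwise (at least 4 complete pairs
    required). The two-tailed p-value is exact — computed by full
    enumeration of rank permutations — for n <= 9 (the study's group
    sizes), and the large-sample t approximation otherwise. Constant input
    leaves r undefined and flags the result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return AssociationResult(var_x, var_y, np.nan, np.nan, n, "none", flag="constant-input")
    rho, p_asym = stats.spearmanr(x, y)
    if n <= EXACT_PERMUTATION_N:
        rx = stats.rankdata(x) - (n + 1) / 2
        ry = stats.rankdata(y) - (n + 1) / 2
        perms = _permutation_matrix(n)
        stat_null = ry[perms] @ rx  # proportional to rho under permutation
        stat_obs = float(ry @ rx)
        p = float(np.mean(np.abs(stat_null) >= abs(stat_obs) - 1e-9))
        return AssociationResult(var_x, var_y, float(rho), p, n, "exact-permutation")
    return AssociationResult(var_x, var_y, float(rho), float(p_asym), n, "asymptotic")


def correlation_report(cohort: pd.DataFrame, pairs=DEFAULT_PAIRS) -> pd.DataFrame:
    """Tidy table of Spearman correlations over the configured pairs.

    Missing values are excluded pairwise and the n actually used is
    reported per row; a Benjamini-Hochberg adjusted column accompanies the
    unadjusted p-values.
    """
    rows = []
    for a, b in pairs:
        res = spearman(cohort[a], cohort[b], a, b)
        rows.append(
            {"var_x": a, "var_y": b, "r": res.r, "p": res.p, "n": res.n,
             "method": res.method, "flag": res.flag}
        )
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["p_bh"] = np.nan
    if ok.any():
        out.loc[ok, "p_bh"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


def group_tests(
    cohort: pd.DataFrame,
    variables=None,
    group_col: str = "group",
    paired_pairs=(("pd200_pre", "pd200_post"),),
) -> pd.DataFrame:
    """Two-group comparison table: unpaired t per variable, paired t for
    within-animal pre/post pairs. Two-tailed p-values; alpha = 0.05 by the
    study's convention, but no thresholding is applied here."""
    groups = cohort[group_col].unique()
    if len(groups) != 2:
        raise ValueError("need exactly two groups")
    g1 = cohort[cohort[group_col] == groups[0]]
    g2 = cohort[cohort[group_col] == groups[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need at least 2 animals per group")
    if variables is None:
        variables = [
            c for c in cohort.columns
            if c not in (group_col, "animal_id") and pd.api.types.is_numeric_dtype(cohort[c])
        ]
    rows = []
    for var in variables:
        a = g1[var].dropna()
        b = g2[var].dropna()
        t, p = stats.ttest_ind(a, b)
        rows.append({"variable": var, "test": "unpaired_t", "stat": float(t),
                     "p": float(p), "n1": len(a), "n2": len(b)})
    for pre, post in paired_pairs:
        if pre not in cohort or post not in cohort:
            continue
        for label, g in ((groups[0], g1), (groups[1], g2)):
            sub = g[[pre, post]].dropna()
            t, p = stats.ttest_rel(sub[pre], sub[post])
            rows.append({"variable": f"{pre}-vs-{post} [{label}]", "test": "paired_t",
                         "stat": float(t), "p": float(p), "n1": len(sub), "n2": len(sub)})
    return pd.DataFrame(rows)


def rm_anova_dunnett(values: pd.DataFrame, baseline_col: str) -> dict:
    """Repeated-measures ANOVA over within-animal levels plus contrasts of
    each level against the baseline level.

    ``values`` is wide: one row per animal, one column per level (the
    baseline period and each challenge). The omnibus test is a one-way
    repeated-measures ANOVA; the per-level comparisons against baseline use
    Dunnett's many-to-one procedure on the level samples.
    """
    if baseline_col not in values.columns:
        raise ValueError("baseline column missing")
    if len(values) < 2:
        raise ValueError("need at least 2 subjects")
    long = values.reset_index(drop=True).reset_index(names="subject").melt(
        id_vars="subject", var_name="level", value_name="value"
    )
    aov = AnovaRM(long, depvar="value", subject="subject", within=["level"]).fit()
    f = float(aov.anova_table["F Value"].iloc[0])
    p = float(aov.anova_table["Pr > F"].iloc[0])
    others = [c for c in values.columns if c != baseline_col]
    dun = stats.dunnett(*[values[c].to_numpy() for c in others], control=values[baseline_col].to_numpy())
    contrasts = {c: float(pv) for c, pv in zip(others, np.atleast_1d(dun.pvalue))}
    return {"F": f, "p": p, "contrast_p": contrasts}
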