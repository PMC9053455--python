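"""Socioeconomic characterization of the clusters.

For each regional indicator the battery computes per-cluster means (with
largest / smallest flags), screens univariate normality (Shapiro-Wilk within
each cluster), tests variance homogeneity (Levene, group-mean centering),
then runs either the classical one-way ANOVA (homoscedastic case) or the
Brown-Forsythe robust test of equal means (F* with Satterthwaite denominator
degrees of freedom), and finishes with pairwise post hoc comparisons:
Bonferroni-adjusted pooled-variance t tests when variances are homogeneous,
Tamhane's T2 (pairwise Welch tests with a Sidak-type conservative
adjustment) when they are not.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import COVARIATE_NAMES
from .taxonomy import ClusterSolution

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# descriptive cluster means
# ---------------------------------------------------------------------------

def cluster_means_table(
    covariates: pd.DataFrame,
    solution: ClusterSolution,
    indicators: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Arithmetic mean of each indicator per cluster, with min/max flags.

    Rows are indicators; columns are cluster names (label when available,
    else ``C<i>``) plus ``largest`` / ``smallest`` flag columns naming the
    extreme-holding clusters.
    """
    indicators = list(indicators) if indicators is not None else list(COVARIATE_NAMES)
    cov = covariates.set_index("region_id")
    missing = [r for r in solution.assignments if r not in cov.index]
    if missing:
        raise ValueError(f"regions in solution missing covariates: {sorted(missing)}")
    cluster_of = pd.Series(
        {rid: _cluster_name(solution, ci) for rid, ci in solution.assignments.items()}
    )
    grouped = cov.loc[cluster_of.index, indicators].groupby(cluster_of.values)
    means = grouped.mean().T  # indicators x clusters
    means["largest"] = means.idxmax(axis=1)
    means["smallest"] = means[[c for c in means.columns if c != "largest"]].idxmin(axis=1)
    means.index.name = "indicator"
    return means


def _cluster_name(solution: ClusterSolution, ci: int) -> str:
    if solution.labels is not None:
        return solution.labels[ci]
    return f"C{ci + 1}"


def _groups_for(
    covariates: pd.DataFrame, solution: ClusterSolution, indicator: str
) -> Dict[str, np.ndarray]:
    cov = covariates.set_index("region_id")
    out: Dict[str, List[float]] = {}
    for rid, ci in solution.assignments.items():
        out.setdefault(_cluster_name(solution, ci), []).append(float(cov.at[rid, indicator]))
    return {k: np.asarray(v) for k, v in sorted(out.items())}


# ---------------------------------------------------------------------------
# assumption screening
# ---------------------------------------------------------------------------

def normality_screen(
    covariates: pd.DataFrame,
    solution: ClusterSolution,
    alpha: float = 0.05,
    indicators: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Shapiro-Wilk within each cluster; an indicator is excluded from the
    ANOVA battery if normality is rejected at ``alpha`` in *any* cluster.

    Clusters of size < 3 (or with zero spread) are untestable: the indicator
    stays included, flagged with a warning reason.
    """
    indicators = list(indicators) if indicators is not None else list(COVARIATE_NAMES)
    rows = []
    for ind in indicators:
        groups = _groups_for(covariates, solution, ind)
        reasons = []
        included = True
        untestable = False
        for cname, vals in groups.items():
            if len(vals) < 3 or np.ptp(vals) == 0:
                untestable = True
                reasons.append(f"{cname}: untestable (n={len(vals)} or constant)")
                continue
            p = float(stats.shapiro(vals).pvalue)
            if p < alpha:
                included = False
                reasons.append(f"{cname}: normality rejected (p={p:.4f})")
        if untestable and included:
            logger.warning("normality screen for %s partially untestable", ind)
        rows.append(
            {
                "indicator": ind,
                "included": included,
                "untestable": untestable,
                "reason": "; ".join(reasons),
            }
        )
    return pd.DataFrame(rows)


def levene_test(groups: Sequence[np.ndarray]) -> Tuple[float, float]:
    """Levene's homogeneity-of-variance test with group-mean centering."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("every group needs at least two observations")
    # degenerate case: identical absolute deviations in every group (e.g.
    # two-point symmetric groups) make the ANOVA-on-deviations 0/0
    absdev = np.concatenate([np.abs(g - g.mean()) for g in groups])
    if np.ptp(absdev) == 0.0:
        return 0.0, 1.0
    stat, p = stats.levene(*groups, center="mean")
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# mean-equality tests
# ---------------------------------------------------------------------------

def oneway_anova(groups: Sequence[np.ndarray]) -> Tuple[float, int, int, float]:
    """Classical one-way ANOVA; returns (F, df1, df2, p).

    Zero within-group variance is handled explicitly: equal group means give
    F = 0 (p = 1), unequal means give F = inf (p = 0).
    """
    _check_groups(groups)
    k = len(groups)
    n = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = k - 1, n - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, df1, df2, 1.0
        return float("inf"), df1, df2, 0.0
    f = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), df1, df2, p


def brown_forsythe_robust(groups: Sequence[np.ndarray]) -> Tuple[float, int, float, float]:
    """Brown-Forsythe robust test of *equal means* (the F* statistic).

    F* = sum n_i (xbar_i - xbar)^2 / sum (1 - n_i/N) s_i^2 with a
    Satterthwaite-type denominator degrees of freedom; for two groups it
    coincides with Welch's t test (F* = t^2, same df).
    Returns (F*, df1, df2, p); df2 is real-valued.
    """
    _check_groups(groups)
    k = len(groups)
    ns = np.array([len(g) for g in groups], dtype=float)
    n = ns.sum()
    means = np.array([g.mean() for g in groups])
    variances = np.array([g.var(ddof=1) for g in groups])
    grand = np.concatenate(groups).mean()
    numer = float(np.sum(ns * (means - grand) ** 2))
    weights = (1.0 - ns / n) * variances
    denom = float(weights.sum())
    df1 = k - 1
    if denom == 0.0:
        if numer == 0.0:
            return 0.0, df1, float(n - k), 1.0
        return float("inf"), df1, float(n - k), 0.0
    c = weights / denom
    df2 = float(1.0 / np.sum(c**2 / (ns - 1.0)))
    f = numer / denom
    p = float(stats.f.sf(f, df1, df2))
    return float(f), df1, df2, p


def _check_groups(groups: Sequence[np.ndarray]) -> None:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("every group needs at least two observations")


# ---------------------------------------------------------------------------
# post hoc pairwise comparisons
# ---------------------------------------------------------------------------

@dataclass
class PairwiseComparison:
    pair: Tuple[str, str]
    mean_difference: float
    raw_p: float
    adjusted_p: float
    significant: bool
    procedure: str


def bonferroni_adjust(p_raw: float, m: int) -> float:
    return min(1.0, m * p_raw)


def sidak_adjust(p_raw: float, m: int) -> float:
    return min(1.0, 1.0 - (1.0 - p_raw) ** m)


def posthoc_pairwise(
    groups: Dict[str, np.ndarray],
    homoscedastic: bool,
    alpha: float = 0.05,
) -> List[PairwiseComparison]:
    """All pairwise mean comparisons with multiplicity adjustment.

    Homoscedastic: t tests on the pooled within-group variance with
    Bonferroni adjustment (p * m, capped at 1).  Heteroscedastic: Tamhane's
    T2, i.e. pairwise Welch t statistics with the Sidak-type conservative
    adjustment 1 - (1 - p)^m.
    """
    names = sorted(groups)
    _check_groups([groups[n] for n in names])
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    n_total = sum(len(groups[n]) for n in names)
    k = len(names)
    # pooled within-group variance and its df (homoscedastic route)
    ss_within = sum(((groups[n] - groups[n].mean()) ** 2).sum() for n in names)
    df_pool = n_total - k
    s2_pool = ss_within / df_pool if df_pool > 0 else 0.0

    out = []
    for a, b in pairs:
        ga, gb = groups[a], groups[b]
        diff = float(ga.mean() - gb.mean())
        if homoscedastic:
            se = np.sqrt(s2_pool * (1.0 / len(ga) + 1.0 / len(gb)))
            if se == 0.0:
                raw = 1.0 if diff == 0.0 else 0.0
            else:
                t = diff / se
                raw = float(2.0 * stats.t.sf(abs(t), df_pool))
            adj = bonferroni_adjust(raw, m)
            proc = "bonferroni"
        else:
            va, vb = ga.var(ddof=1) / len(ga), gb.var(ddof=1) / len(gb)
            se2 = va + vb
            if se2 == 0.0:
                raw = 1.0 if diff == 0.0 else 0.0
            else:
                t = diff / np.sqrt(se2)
                df_w = se2**2 / (va**2 / (len(ga) - 1) + vb**2 / (len(gb) - 1))
                raw = float(2.0 * stats.t.sf(abs(t), df_w))
            adj = sidak_adjust(raw, m)
            proc = "tamhane_t2"
        out.append(
            PairwiseComparison(
                pair=(a, b),
                mean_difference=diff,
                raw_p=raw,
                adjusted_p=adj,
                significant=adj < alpha,
                procedure=proc,
            )
        )
    return out


# ---------------------------------------------------------------------------
# full battery
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    indicator: str
    included: bool
    exclusion_reason: str
    f_stat: float = np.nan
    df: Tuple[float, float] = (np.nan, np.nan)
    p_value: float = np.nan
    robust_used: bool = False
    levene_stat: float = np.nan
    levene_p: float = np.nan
    pairwise: List[PairwiseComparison] = field(default_factory=list)

    def posthoc_summary(self, alpha: float = 0.05) -> str:
        """Compact 'A != {B, C}' rendering of the significant pairs."""
        sig: Dict[str, List[str]] = {}
        for c in self.pairwise:
            if c.significant:
                sig.setdefault(c.pair[0], []).append(c.pair[1])
        if not sig:
            return "-"
        parts = []
        for a in sorted(sig):
            others = ", ".join(sorted(sig[a]))
            parts.append(f"{a} != {{{others}}}" if len(sig[a]) > 1 else f"{a} != {sig[a][0]}")
        return "; ".join(parts)


def anova_battery(
    covariates: pd.DataFrame,
    solution: ClusterSolution,
    alpha: float = 0.05,
    indicators: Optional[Sequence[str]] = None,
) -> List[AnovaResult]:
    """Run the full per-indicator battery over all clusters."""
    indicators = list(indicators) if indicators is not None else list(COVARIATE_NAMES)
    screen = normality_screen(covariates, solution, alpha, indicators).set_index("indicator")
    results = []
    for ind in indicators:
        included = bool(screen.at[ind, "included"])
        reason = str(screen.at[ind, "reason"])
        res = AnovaResult(indicator=ind, included=included, exclusion_reason=reason)
        if not included:
            results.append(res)
            continue
        groups = _groups_for(covariates, solution, ind)
        glist = [groups[n] for n in sorted(groups)]
        res.levene_stat, res.levene_p = levene_test(glist)
        homoscedastic = res.levene_p >= alpha
        if homoscedastic:
            res.f_stat, df1, df2, res.p_value = oneway_anova(glist)
            res.df = (float(df1), float(df2))
            res.robust_used = False
        else:
            res.f_stat, df1, df2, res.p_value = brown_forsythe_robust(glist)
            res.df = (float(df1), df2)
            res.robust_used = True
        res.pairwise = posthoc_pairwise(groups, homoscedastic, alpha)
        results.append(res)
    return results


def anova_table(results: List[AnovaResult], alpha: float = 0.05) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "indicator": r.indicator,
                "included": r.included,
                "F": r.f_stat,
                "df1": r.df[0],
                "df2": r.df[1],
                "p_value": r.p_value,
                "robust_used": r.robust_used,
                "levene_p": r.levene_p,
                "posthoc": r.posthoc_summary(alpha) if r.included else "",
                "exclusion_reason": "" if r.included else r.exclusion_reason,
            }
        )
    return pd.DataFrame(rows)


def standardized_means_matrix(
    covariates: pd.DataFrame, solution: ClusterSolution
) -> pd.DataFrame:
    """Cluster means of z-scored indicators (display companion to the raw
    means table; standardization is across regions, not within clusters)."""
    cov = covariates.set_index("region_id")[list(COVARIATE_NAMES)]
    z = (cov - cov.mean()) / cov.std(ddof=1)
    cluster_of = pd.Series(
        {rid: _cluster_name(solution, ci) for rid, ci in solution.assignments.items()}
    )
    return z.loc[cluster_of.index].groupby(cluster_of.values).mean().T
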