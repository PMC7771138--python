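"""Inferential wrappers applied to effect sizes and trait dispersions.

Three classical nonparametric/robust procedures:

* Wilcoxon signed-ranks test of whether a vector of effect sizes departs
  from zero overall (trait convergence or divergence across plots),
* Spearman rank correlation of effect sizes or trait values against an
  environmental gradient,
* Levene's test for heterogeneity of unweighted trait dispersion between
  topographic groups (classic mean-centered form by default; median
  centering gives the Brown-Forsythe variant).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError

_EXACT_WILCOXON_MAX_N = 25


@dataclass(frozen=True)
class DepartureTest:
    """Wilcoxon signed-ranks departure of effect sizes from zero."""

    statistic: float
    p_value: float
    n: int
    direction: str  # convergent | divergent | none
    sufficient: bool = True


@dataclass(frozen=True)
class GradientCorrelation:
    """Spearman rank correlation along an environmental variable."""

    rho: float
    p_value: float
    n: int
    variable: str
    undefined: bool = False


@dataclass(frozen=True)
class LeveneResult:
    """One-way Levene test of dispersion differences among groups."""

    F: float
    df_between: int
    df_within: int
    p_value: float
    factor: str
    degenerate: bool = False


def wilcoxon_departure(es_values, alpha: float = 0.05) -> DepartureTest:
    """Two-tailed Wilcoxon signed-ranks test of ES against zero.

    Zeros are dropped (signed-rank convention); the exact null
    distribution is used up to n = 25 and the normal approximation with
    continuity correction beyond.  The direction label reads the sign of
    the ES median when the test is significant at ``alpha``.
    """
    es = np.asarray(es_values, dtype=float)
    es = es[~np.isnan(es)]
    nonzero = es[es != 0.0]
    if es.size and nonzero.size == 0:
        return DepartureTest(statistic=0.0, p_value=1.0, n=0, direction="none")
    if nonzero.size == 0:
        return DepartureTest(statistic=math.nan, p_value=math.nan, n=0,
                             direction="none", sufficient=False)
    if nonzero.size == 1:
        # a single pair has no two-sided signed-rank resolution
        return DepartureTest(statistic=math.nan, p_value=math.nan, n=1,
                             direction="none", sufficient=False)
    method = "exact" if nonzero.size <= _EXACT_WILCOXON_MAX_N else "approx"
    res = stats.wilcoxon(nonzero, alternative="two-sided", method=method,
                         correction=(method == "approx"))
    p = float(res.pvalue)
    sufficient = nonzero.size >= 5
    if sufficient and p < alpha:
        direction = "convergent" if np.median(nonzero) < 0 else "divergent"
    else:
        direction = "none"
    return DepartureTest(statistic=float(res.statistic), p_value=p,
                         n=int(nonzero.size), direction=direction,
                         sufficient=sufficient)


def gradient_correlation(values, env, variable: str = "") -> GradientCorrelation:
    """Spearman rho (average-rank ties, two-sided t-approximation p)."""
    v = np.asarray(values, dtype=float)
    e = np.asarray(env, dtype=float)
    ok = ~(np.isnan(v) | np.isnan(e))
    v, e = v[ok], e[ok]
    if v.size < 4:
        raise InsufficientDataError("gradient correlation needs >=4 paired values")
    if np.ptp(v) == 0.0 or np.ptp(e) == 0.0:
        return GradientCorrelation(rho=math.nan, p_value=math.nan, n=int(v.size),
                                   variable=variable, undefined=True)
    res = stats.spearmanr(v, e)
    return GradientCorrelation(rho=float(res.statistic), p_value=float(res.pvalue),
                               n=int(v.size), variable=variable)


def levene_test(values, groups, center: str = "mean",
                factor: str = "") -> LeveneResult:
    """One-way ANOVA F on absolute deviations from the group center."""
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    ok = ~np.isnan(v)
    v, g = v[ok], g[ok]
    levels = sorted(set(g.tolist()))
    if len(levels) < 2:
        raise InsufficientDataError("Levene's test needs >=2 groups")
    samples = [v[g == lev] for lev in levels]
    for lev, s in zip(levels, samples):
        if s.size < 2:
            raise InsufficientDataError(
                f"group {lev!r} has {s.size} observation(s); need >=2")
    centers = [np.mean(s) if center == "mean" else np.median(s) for s in samples]
    devs = [np.abs(s - c) for s, c in zip(samples, centers)]
    df_between = len(levels) - 1
    df_within = int(sum(s.size for s in samples)) - len(levels)
    if all(np.all(d == 0.0) for d in devs):
        return LeveneResult(F=math.nan, df_between=df_between,
                            df_within=df_within, p_value=math.nan,
                            factor=factor, degenerate=True)
    # Guard the 0/0 corners of the deviation ANOVA before calling scipy:
    # identical per-group spreads mean no between-group signal (F = 0),
    # zero within-group spread with differing group spreads means F -> inf.
    all_dev = np.concatenate(devs)
    grand = all_dev.mean()
    ssb = sum(d.size * (d.mean() - grand) ** 2 for d in devs)
    ssw = sum(((d - d.mean()) ** 2).sum() for d in devs)
    if ssb == 0.0:
        return LeveneResult(F=0.0, df_between=df_between, df_within=df_within,
                            p_value=1.0, factor=factor)
    if ssw == 0.0:
        return LeveneResult(F=math.inf, df_between=df_between,
                            df_within=df_within, p_value=0.0, factor=factor)
    res = stats.levene(*samples, center=center)
    return LeveneResult(F=float(res.statistic), df_between=df_between,
                        df_within=df_within, p_value=float(res.pvalue),
                        factor=factor)
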