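"""Community-level trait statistics and the variance decomposition.

For a plot *j* with species relative covers :math:`p_{ij}` and plot-level
species trait means :math:`x_{ij}`:

* unweighted community average — the arithmetic mean of the
  :math:`x_{ij}` over the species present (a presence/absence view),
* community-weighted mean — :math:`\\mathrm{CWM}_j = \\sum_i p_{ij} x_{ij}`,
* community-weighted variance —
  :math:`\\mathrm{CWV}_j = \\sum_i p_{ij} (x_{ij} - \\mathrm{CWM}_j)^2`
  (an abundance-weighted population variance),
* unweighted dispersion — the n−1 sample variance of the :math:`x_{ij}`.

The decomposition splits among-plot variation in the community average
into interspecific (species turnover; computed by substituting species
grand means, the "fixed" averages, for the plot-specific means) and
intraspecific (the specific-minus-fixed remainder) components plus a
covariation cross-term, so that
``SS_total = SS_inter + SS_intra + 2*SS_cov`` exactly.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import AnalysisConfig, CommunityMatrix, TraitTable
from .errors import InsufficientDataError, ValidationError

_WEIGHT_TOL = 1e-9

WEIGHTINGS = ("weighted", "unweighted")


def _check_weighting(weighting: str) -> None:
    if weighting not in WEIGHTINGS:
        raise ValueError(f"weighting must be one of {WEIGHTINGS}")


def _align(covers: pd.Series | np.ndarray | None, values: pd.Series | np.ndarray):
    """Align a cover vector with a trait-value vector on species labels."""
    if covers is None:
        v = np.asarray(values, dtype=float)
        return None, v
    if isinstance(covers, pd.Series) and isinstance(values, pd.Series):
        common = covers.index.intersection(values.index)
        return covers.loc[common].to_numpy(float), values.loc[common].to_numpy(float)
    p = np.asarray(covers, dtype=float)
    v = np.asarray(values, dtype=float)
    if p.shape != v.shape:
        raise ValidationError("cover and trait vectors differ in length")
    return p, v


def community_average(covers, values, weighting: str = "weighted",
                      *, renormalize: bool = False) -> float:
    """Community trait average for one plot.

    ``weighting='unweighted'`` returns the arithmetic mean of the species
    values; ``'weighted'`` returns sum(p_i * x_i) and requires the covers
    to sum to 1 unless ``renormalize`` is set (used when a species lacks
    this particular trait and the remaining weights must be rescaled).

    Returns NaN when no species carries a value.
    """
    _check_weighting(weighting)
    p, v = _align(covers if weighting == "weighted" else None, values)
    if v.size == 0:
        return math.nan
    if weighting == "unweighted":
        return float(np.mean(v))
    s = p.sum()
    if renormalize:
        if s <= 0:
            return math.nan
        p = p / s
    elif abs(s - 1.0) > _WEIGHT_TOL:
        raise ValidationError(f"relative covers sum to {s!r}, not 1")
    return float(p @ v)


def community_weighted_variance(covers, values, *, renormalize: bool = False) -> float:
    """CWV = sum(p_i * (x_i - CWM)^2); 0 for a single-species plot."""
    p, v = _align(covers, values)
    if v.size == 0:
        return math.nan
    s = p.sum()
    if renormalize:
        if s <= 0:
            return math.nan
        p = p / s
    elif abs(s - 1.0) > _WEIGHT_TOL:
        raise ValidationError(f"relative covers sum to {s!r}, not 1")
    cwm = p @ v
    return float(p @ (v - cwm) ** 2)


def unweighted_dispersion(values) -> float:
    """Sample variance (n-1 denominator) of species plot means; NaN if n<2."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return math.nan
    return float(np.var(v, ddof=1))


def community_trait_summary(m: CommunityMatrix, traits: TraitTable,
                            cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Per-plot, per-trait summary of means, variances and richness.

    Weighted statistics are NaN for plots flagged incomplete during
    normalization; weights are renormalized per trait over the species
    that carry that trait.
    """
    cfg = cfg or AnalysisConfig()
    traits = traits.transformed(cfg.log_transform)
    rows = []
    for plot in m.plots:
        weights = m.plot_weights(plot) if m.normalized else None
        complete = plot not in m.incomplete_plots
        for trait in cfg.trait_list:
            x = traits.plot_values(plot, trait)
            if weights is not None:
                x = x.loc[x.index.intersection(weights.index)]
            n = len(x)
            uw_mean = float(x.mean()) if n else math.nan
            uw_var = unweighted_dispersion(x.to_numpy()) if n else math.nan
            if weights is not None and complete and n:
                w_mean = community_average(weights, x, "weighted", renormalize=True)
                w_var = community_weighted_variance(weights, x, renormalize=True)
            else:
                w_mean = w_var = math.nan
            rows.append({
                "plot_id": plot, "trait_name": trait,
                "unweighted_mean": uw_mean, "weighted_mean": w_mean,
                "unweighted_variance": uw_var, "weighted_variance": w_var,
                "species_count": n,
                "degenerate": n < 2,
            })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DecompositionResult:
    """Among-plot variance split for one trait and weighting.

    ``per_plot`` holds the three per-plot averages (total, interspecific,
    intraspecific); the SS fields are among-plot sums of squared deviations
    from the respective grand means, with ``ss_cov`` the cross-product
    term, so ``ss_total = ss_inter + ss_intra + 2*ss_cov``.  Relative
    contributions are fractions of ``ss_total`` (the covariation share is
    signed and may be negative); NaN when ``ss_total`` is zero.
    """

    trait_name: str
    weighting: str
    per_plot: pd.DataFrame = field(repr=False)
    ss_total: float
    ss_inter: float
    ss_intra: float
    ss_cov: float

    @property
    def n_plots(self) -> int:
        return len(self.per_plot)

    @property
    def frac_inter(self) -> float:
        return self.ss_inter / self.ss_total if self.ss_total > 0 else math.nan

    @property
    def frac_intra(self) -> float:
        return self.ss_intra / self.ss_total if self.ss_total > 0 else math.nan

    @property
    def frac_cov(self) -> float:
        return 2.0 * self.ss_cov / self.ss_total if self.ss_total > 0 else math.nan


def decompose_trait_variance(m: CommunityMatrix, traits: TraitTable,
                             trait_name: str, weighting: str = "weighted",
                             cfg: AnalysisConfig | None = None) -> DecompositionResult:
    """Partition among-plot variation of the community trait average.

    Per plot, the total average uses the plot-specific species means, the
    interspecific average substitutes species grand means under the same
    weights, and the intraspecific average is their difference.
    """
    _check_weighting(weighting)
    cfg = cfg or AnalysisConfig()
    traits = traits.transformed(cfg.log_transform)
    gm = traits.grand_means(trait_name)
    rows = []
    for plot in m.plots:
        if weighting == "weighted" and plot in m.incomplete_plots:
            continue
        x = traits.plot_values(plot, trait_name)
        if m.normalized and weighting == "weighted":
            w = m.plot_weights(plot)
            x = x.loc[x.index.intersection(w.index)]
            if len(x) == 0:
                continue
            total = community_average(w, x, "weighted", renormalize=True)
            inter = community_average(w, gm.loc[x.index], "weighted", renormalize=True)
        else:
            if len(x) == 0:
                continue
            total = community_average(None, x, "unweighted")
            inter = community_average(None, gm.loc[x.index], "unweighted")
        rows.append({"plot_id": plot, "total_average": total,
                     "interspecific_average": inter,
                     "intraspecific_average": total - inter})
    if len(rows) < 2:
        raise InsufficientDataError(
            f"decomposition of {trait_name} needs >=2 valid plots, got {len(rows)}")
    per_plot = pd.DataFrame(rows)
    tot = per_plot["total_average"].to_numpy()
    inter = per_plot["interspecific_average"].to_numpy()
    intra = per_plot["intraspecific_average"].to_numpy()
    d_tot = tot - tot.mean()
    d_inter = inter - inter.mean()
    d_intra = intra - intra.mean()
    return DecompositionResult(
        trait_name=trait_name, weighting=weighting, per_plot=per_plot,
        ss_total=float(d_tot @ d_tot), ss_inter=float(d_inter @ d_inter),
        ss_intra=float(d_intra @ d_intra), ss_cov=float(d_inter @ d_intra),
    )


@dataclass(frozen=True)
class ContributionComparison:
    """Paired t comparison of relative contributions between weightings."""

    statistic: float
    p_value: float
    n_pairs: int
    mean_difference: float
    degenerate: bool = False


def compare_contributions(d_weighted: list[DecompositionResult],
                          d_unweighted: list[DecompositionResult],
                          component: str = "intraspecific") -> ContributionComparison:
    """Paired t test on per-trait relative contributions, weighted vs not.

    ``component`` selects which share is compared: ``interspecific``,
    ``intraspecific`` or ``covariation``. Pairs are matched by trait name.
    A zero-spread difference vector is degenerate: the t statistic is
    undefined, and p is reported as 1 by convention.
    """
    attr = {"interspecific": "frac_inter", "intraspecific": "frac_intra",
            "covariation": "frac_cov"}[component]
    dw = {d.trait_name: getattr(d, attr) for d in d_weighted}
    du = {d.trait_name: getattr(d, attr) for d in d_unweighted}
    common = sorted(set(dw) & set(du))
    diffs = np.array([dw[t] - du[t] for t in common], dtype=float)
    diffs = diffs[~np.isnan(diffs)]
    if diffs.size < 2:
        raise InsufficientDataError("paired t test needs >=2 trait pairs")
    if np.ptp(diffs) == 0.0:
        t = 0.0 if diffs[0] == 0.0 else math.inf * np.sign(diffs[0])
        return ContributionComparison(statistic=float(t), p_value=1.0,
                                      n_pairs=diffs.size,
                                      mean_difference=float(diffs.mean()),
                                      degenerate=True)
    t, p = stats.ttest_rel(diffs, np.zeros_like(diffs))
    return ContributionComparison(statistic=float(t), p_value=float(p),
                                  n_pairs=diffs.size,
                                  mean_difference=float(diffs.mean()))
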