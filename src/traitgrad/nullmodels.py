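"""Randomization machinery: abundance-shuffling null model and the
modified permutation test for trait covariation.

The null model for the community-weighted variance permutes a plot's
relative-cover vector among its own species, which breaks any
trait-abundance association while preserving the species list, richness
and the exact multiset of abundances (hence evenness).  The observed CWV
is located within the null distribution as a quantile ``q`` (ties get
half weight) and rescaled to an effect size ``ES = 2q - 1`` in [-1, 1]:
negative values mean lower dispersion than expected (trait convergence),
positive values divergence.

The covariation test asks whether two community-level trait averages
covary across plots more than expected when one trait's species-level
values are shuffled among species — the construction that protects the
test from the inflated Type I error rate of naive correlations between
community-weighted means.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import AnalysisConfig, CommunityMatrix, TraitTable
from .errors import ConfigError, InsufficientDataError
from .community import community_average, community_weighted_variance

_TIE_RTOL = 1e-9
_TIE_ATOL = 1e-12


def shuffle_abundances(covers, rng: np.random.Generator):
    """Permute a plot's relative-cover vector among its species.

    Returns the permuted vector (same dtype family, same multiset of
    values).  With fewer than two species there is nothing to shuffle and
    the input is returned unchanged.
    """
    p = np.asarray(covers, dtype=float)
    if p.size < 2:
        return p.copy()
    return p[rng.permutation(p.size)]


def _null_cwv(p: np.ndarray, x: np.ndarray, n_perm: int,
              rng: np.random.Generator) -> np.ndarray:
    """CWV under ``n_perm`` random assignments of covers to species.

    Uses the raw-moment identity CWV = sum(p x^2) - (sum(p x))^2, valid
    because each permuted cover vector still sums to 1.
    """
    idx = np.argsort(rng.random((n_perm, p.size)), axis=1)
    P = p[idx]
    m1 = P @ x
    m2 = P @ (x * x)
    return m2 - m1 * m1


@dataclass(frozen=True)
class EffectSizeResult:
    """Null-model effect size of the CWV for one plot and trait."""

    plot_id: object
    trait_name: str
    observed_cwv: float
    null_quantile: float
    effect_size: float
    n_permutations: int
    seed: int
    degenerate: bool = False


def cwv_effect_size(covers, values, trait_name: str = "",
                    cfg: AnalysisConfig | None = None,
                    rng: np.random.Generator | None = None,
                    plot_id=None, seed: int = -1) -> EffectSizeResult:
    """Effect size of observed CWV against the abundance-shuffling null.

    ``q = (#{null < obs} + 0.5 * #{null = obs}) / n_permutations`` and
    ``ES = 2q - 1``.  Equality is judged at a relative tolerance so that
    an exactly flat trait vector (every shuffle reproducing the observed
    CWV) yields q = 0.5, ES = 0.  Plots with fewer than two retained
    species are degenerate: CWV is 0 by construction and no ES is
    defined.
    """
    cfg = cfg or AnalysisConfig()
    if cfg.n_permutations < 1:
        raise ConfigError("n_permutations must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    p = np.asarray(covers, dtype=float)
    x = np.asarray(values, dtype=float)
    if p.size < 2:
        return EffectSizeResult(plot_id, trait_name, 0.0, math.nan, math.nan,
                                cfg.n_permutations, seed, degenerate=True)
    s = p.sum()
    if s <= 0:
        raise ConfigError("cover vector sums to zero")
    p = p / s
    # Observed CWV computed with the same raw-moment formula as the null
    # values so that exact ties are detected reliably.
    obs = float(p @ (x * x) - (p @ x) ** 2)
    null = _null_cwv(p, x, cfg.n_permutations, rng)
    tied = np.isclose(null, obs, rtol=_TIE_RTOL, atol=_TIE_ATOL)
    lower = (null < obs) & ~tied
    q = (lower.sum() + 0.5 * tied.sum()) / cfg.n_permutations
    return EffectSizeResult(
        plot_id=plot_id, trait_name=trait_name,
        observed_cwv=float(community_weighted_variance(p, x)),
        null_quantile=float(q), effect_size=float(2.0 * q - 1.0),
        n_permutations=cfg.n_permutations, seed=seed,
    )


def effect_sizes_table(m: CommunityMatrix, traits: TraitTable,
                       cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Per-plot, per-trait effect sizes as a tidy DataFrame.

    A master seed streams one deterministic sub-seed per (plot, trait)
    via ``numpy.random.SeedSequence`` spawning in sorted plot/trait
    order; each row records the sub-seed it used.
    """
    cfg = cfg or AnalysisConfig()
    traits = traits.transformed(cfg.log_transform)
    ss = np.random.SeedSequence(cfg.seed)
    rows = []
    plots = m.plots
    children = ss.spawn(len(plots) * len(cfg.trait_list))
    k = 0
    for plot in plots:
        weights = m.plot_weights(plot)
        complete = plot not in m.incomplete_plots
        for trait in cfg.trait_list:
            child = children[k]
            k += 1
            sub_seed = int(child.generate_state(1, np.uint32)[0])
            x = traits.plot_values(plot, trait)
            common = x.index.intersection(weights.index)
            x = x.loc[common]
            p = weights.loc[common]
            if not complete or len(x) < 2:
                res = EffectSizeResult(plot, trait, 0.0 if len(x) else math.nan,
                                       math.nan, math.nan, cfg.n_permutations,
                                       sub_seed, degenerate=True)
            else:
                res = cwv_effect_size(p.to_numpy(), x.to_numpy(), trait, cfg,
                                      np.random.default_rng(sub_seed),
                                      plot_id=plot, seed=sub_seed)
            rows.append(res)
    return pd.DataFrame([{
        "plot_id": r.plot_id, "trait_name": r.trait_name,
        "observed_cwv": r.observed_cwv, "null_quantile": r.null_quantile,
        "effect_size": r.effect_size, "n_permutations": r.n_permutations,
        "seed": r.seed, "degenerate": r.degenerate,
    } for r in rows])


@dataclass(frozen=True)
class CovariationTestResult:
    """Permutation test of covariation between two community averages."""

    trait_pair: tuple[str, str]
    weighting: str
    group: str
    observed_rho: float
    p_value: float
    n_plots: int
    n_permutations: int
    seed: int
    undefined: bool = False


def _value_matrix(m: CommunityMatrix, traits: TraitTable, trait: str,
                  plots: list) -> tuple[np.ndarray, np.ndarray, list]:
    """Species x plot value matrix with grand-mean fallback, plus weights.

    Rows are the species carrying the trait that occur in any of the
    plots; ``V[s, j]`` is the species' plot-specific mean where measured
    and its grand mean elsewhere (the fallback only matters for species
    present in a plot without a local measurement).  ``W[j, s]`` holds
    renormalized relative covers over the species present in plot j (zero
    for absent species).
    """
    gm = traits.grand_means(trait)
    present: dict = {}
    for j, plot in enumerate(plots):
        w = m.plot_weights(plot)
        present[plot] = w[w.index.isin(gm.index)]
    species = sorted(set().union(*[set(w.index) for w in present.values()]))
    if not species:
        raise InsufficientDataError(f"no species with trait {trait} in group")
    s_index = {s: i for i, s in enumerate(species)}
    V = np.tile(gm.loc[species].to_numpy(float)[:, None], (1, len(plots)))
    W = np.zeros((len(plots), len(species)))
    for j, plot in enumerate(plots):
        x = traits.plot_values(plot, trait)
        for s, val in x.items():
            if s in s_index:
                V[s_index[s], j] = val
        w = present[plot]
        tot = w.sum()
        for s, wv in w.items():
            W[j, s_index[s]] = wv / tot
    return V, W, species


def modified_permutation_covariation(
    m: CommunityMatrix, traits: TraitTable, trait_a: str, trait_b: str,
    weighting: str = "weighted", group_plots: list | None = None,
    cfg: AnalysisConfig | None = None,
    rng: np.random.Generator | None = None,
    group: str = "all", seed: int = -1,
) -> CovariationTestResult:
    """Spearman correlation of two community averages against a null in
    which one trait's species-level values are permuted among species.

    The observed statistic is Spearman's rho between the per-plot
    community averages of ``trait_a`` and ``trait_b`` over the group's
    plots.  Each permutation reassigns the whole trait-a value profile of
    one species (its plot-level means and grand mean together) to another
    species, recomputes the trait-a averages with the original weights,
    and recomputes rho; the two-sided p-value is
    ``(1 + #{|rho_null| >= |rho_obs|}) / (n_permutations + 1)``.

    With ``cfg.covariation_permute == 'plot'`` the per-plot trait-a
    averages themselves are permuted among plots instead.
    """
    cfg = cfg or AnalysisConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if group_plots is None:
        group_plots = m.plots
    group_plots = [p for p in group_plots
                   if not (weighting == "weighted" and p in m.incomplete_plots)]
    if len(group_plots) < 4:
        raise InsufficientDataError(
            f"covariation test needs >=4 plots, got {len(group_plots)}")

    V_a, W, _ = _value_matrix(m, traits, trait_a, group_plots)
    V_b, W_b, _ = _value_matrix(m, traits, trait_b, group_plots)
    nplots = len(group_plots)
    if weighting == "unweighted":
        W = (W > 0) / np.maximum((W > 0).sum(axis=1, keepdims=True), 1)
        W_b = (W_b > 0) / np.maximum((W_b > 0).sum(axis=1, keepdims=True), 1)

    avg_a = np.einsum("js,sj->j", W, V_a)
    avg_b = np.einsum("js,sj->j", W_b, V_b)
    if np.ptp(avg_a) == 0.0 or np.ptp(avg_b) == 0.0:
        return CovariationTestResult((trait_a, trait_b), weighting, group,
                                     math.nan, math.nan, nplots,
                                     cfg.n_permutations, seed, undefined=True)
    rho_obs = float(stats.spearmanr(avg_a, avg_b).statistic)

    n_perm = cfg.n_permutations
    rank_b = stats.rankdata(avg_b)
    rho_null = np.empty(n_perm)
    if cfg.covariation_permute == "plot":
        perms = np.argsort(rng.random((n_perm, nplots)), axis=1)
        null_avgs = avg_a[perms]
    else:
        S = V_a.shape[0]
        perms = np.argsort(rng.random((n_perm, S)), axis=1)
        null_avgs = np.empty((n_perm, nplots))
        chunk = max(1, int(2_000_000 // max(S * nplots, 1)))
        for start in range(0, n_perm, chunk):
            sl = perms[start:start + chunk]
            null_avgs[start:start + chunk] = np.einsum(
                "js,psj->pj", W, V_a[sl])
    rank_null = stats.rankdata(null_avgs, axis=1)
    rb = rank_b - rank_b.mean()
    rn = rank_null - rank_null.mean(axis=1, keepdims=True)
    denom = np.sqrt((rn * rn).sum(axis=1) * (rb * rb).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho_null = (rn @ rb) / denom
    exceed = np.abs(rho_null) >= np.abs(rho_obs) - _TIE_ATOL
    exceed = exceed & np.isfinite(rho_null)
    p = (1.0 + exceed.sum()) / (n_perm + 1.0)
    return CovariationTestResult(
        trait_pair=(trait_a, trait_b), weighting=weighting, group=group,
        observed_rho=rho_obs, p_value=float(p), n_plots=nplots,
        n_permutations=n_perm, seed=seed,
    )
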