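"""Abundance-shuffling null model and covariation permutation test."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import traitgrad as tg
from traitgrad.nullmodels import (
    cwv_effect_size,
    modified_permutation_covariation,
    shuffle_abundances,
)
from traitgrad.community import community_weighted_variance
from traitgrad.errors import InsufficientDataError


def exact_null_quantile(p, x):
    """Oracle: place observed CWV within all len(p)! cover assignments."""
    p, x = np.asarray(p, float), np.asarray(x, float)
    p = p / p.sum()
    obs = p @ (x * x) - (p @ x) ** 2
    nulls = []
    for perm in itertools.permutations(range(len(p))):
        q = p[list(perm)]
        nulls.append(q @ (x * x) - (q @ x) ** 2)
    nulls = np.asarray(nulls)
    tied = np.isclose(nulls, obs, rtol=1e-9, atol=1e-12)
    lower = (nulls < obs) & ~tied
    return (lower.sum() + 0.5 * tied.sum()) / len(nulls)


class TestShuffle:
    def test_two_species_both_orders_equally_likely(self, rng):
        counts = {(0.7, 0.3): 0, (0.3, 0.7): 0}
        for _ in range(2000):
            out = tuple(shuffle_abundances([0.7, 0.3], rng))
            counts[out] += 1
        # binomial(2000, 0.5): 5 sigma band
        assert abs(counts[(0.7, 0.3)] - 1000) < 5 * math.sqrt(2000 * 0.25)

    def test_multiset_of_abundances_conserved(self, rng):
        p = rng.dirichlet(np.ones(7))
        out = shuffle_abundances(p, rng)
        assert np.allclose(np.sort(out), np.sort(p))

    def test_three_species_uniform_over_permutations(self, rng):
        p = np.array([0.5, 0.3, 0.2])
        counts = {}
        for _ in range(6000):
            key = tuple(shuffle_abundances(p, rng))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 6
        chi2 = sum((c - 1000) ** 2 / 1000 for c in counts.values())
        # chi-square with 5 df: reject only far out in the tail
        assert chi2 < stats.chi2.ppf(0.999, df=5)

    def test_single_species_returned_unchanged(self, rng):
        assert shuffle_abundances([1.0], rng).tolist() == [1.0]


class TestEffectSize:
    def test_flat_trait_vector_gives_zero_effect_size(self, rng):
        res = cwv_effect_size([0.6, 0.3, 0.1], [4.0, 4.0, 4.0], rng=rng)
        assert res.null_quantile == pytest.approx(0.5)
        assert res.effect_size == pytest.approx(0.0)

    def test_degenerate_single_species_plot(self, rng):
        res = cwv_effect_size([1.0], [5.0], rng=rng)
        assert res.degenerate
        assert math.isnan(res.effect_size)

    def test_matches_exhaustive_enumeration(self, rng):
        p = [0.5, 0.3, 0.2]
        x = [1.0, 2.0, 3.0]
        q_exact = exact_null_quantile(p, x)
        cfg = tg.AnalysisConfig(n_permutations=9999)
        res = cwv_effect_size(p, x, cfg=cfg, rng=rng)
        se = math.sqrt(q_exact * (1 - q_exact) / 9999)
        assert abs(res.null_quantile - q_exact) <= 3 * se + 0.5 / 9999
        assert res.observed_cwv == pytest.approx(0.61)

    def test_es_bounds_and_minimum_case(self, rng):
        # dominant cover on the central trait value: observed CWV near the
        # bottom of the null, ES close to -1
        p = [0.96, 0.02, 0.02]
        x = [5.0, 0.0, 10.0]
        res = cwv_effect_size(p, x, cfg=tg.AnalysisConfig(n_permutations=999),
                              rng=rng)
        assert -1.0 <= res.effect_size <= 1.0
        q_exact = exact_null_quantile(p, x)
        assert res.null_quantile == pytest.approx(q_exact, abs=0.05)

    def test_affine_trait_transform_preserves_effect_size(self):
        p = np.array([0.4, 0.3, 0.2, 0.1])
        x = np.array([2.0, 9.0, 4.0, 7.0])
        cfg = tg.AnalysisConfig(n_permutations=499)
        r1 = cwv_effect_size(p, x, cfg=cfg, rng=np.random.default_rng(7))
        r2 = cwv_effect_size(p, 3.5 * x - 20.0, cfg=cfg,
                             rng=np.random.default_rng(7))
        assert r1.effect_size == pytest.approx(r2.effect_size, abs=1e-12)

    def test_table_is_deterministic_under_master_seed(self, small_study):
        _, cover, traits = small_study
        cfg = tg.AnalysisConfig(n_permutations=99, seed=11,
                                trait_list=("SLA", "LN"))
        a = tg.effect_sizes_table(cover, traits, cfg)
        b = tg.effect_sizes_table(cover, traits, cfg)
        pd.testing.assert_frame_equal(a, b)


def _covariation_fixture(values_a: dict, values_b: dict, n_plots=6, roll=True):
    """All species present in all plots with fixed unequal covers."""
    species = sorted(values_a)
    base_w = np.linspace(1.0, 2.0, len(species))
    cov_rows, trait_rows = [], []
    for j in range(n_plots):
        w = np.roll(base_w, j) if roll else base_w.copy()
        w = w / w.sum()
        for k, sp in enumerate(species):
            cov_rows.append({"site": "A", "plot_id": f"p{j}", "species_id": sp,
                             "raw_percent_cover": 100.0 * w[k]})
            for trait, vals in (("SLA", values_a), ("LN", values_b)):
                # mild plot-level wiggle so plot means differ across plots
                trait_rows.append({
                    "plot_id": f"p{j}", "species_id": sp, "trait_name": trait,
                    "plot_mean_value": vals[sp] * (1 + 0.03 * j),
                    "n_individuals": 3})
    traits = pd.DataFrame(trait_rows)
    traits["species_grand_mean"] = traits.groupby(
        ["species_id", "trait_name"])["plot_mean_value"].transform("mean")
    t = tg.TraitTable.from_frame(traits)
    m = tg.CommunityMatrix.from_frame(pd.DataFrame(cov_rows))
    return tg.normalize_relative_cover(m, t), t


class TestCovariation:
    def test_monotone_transform_gives_perfect_rho(self):
        # with community composition held fixed across plots, plot averages
        # of a trait and of its monotone transform rank identically
        va = {"a": 10.0, "b": 20.0, "c": 30.0, "d": 40.0}
        vb = {s: v**2 for s, v in va.items()}  # monotone transform
        m, t = _covariation_fixture(va, vb, roll=False)
        res = modified_permutation_covariation(
            m, t, "SLA", "LN", "weighted", None,
            tg.AnalysisConfig(n_permutations=99), np.random.default_rng(0))
        assert res.observed_rho == pytest.approx(1.0)

    def test_constant_trait_undefined(self):
        va = {"a": 10.0, "b": 10.0, "c": 10.0, "d": 10.0}
        vb = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}
        cov_rows, trait_rows = [], []
        for j in range(5):
            for sp in va:
                cov_rows.append({"site": "A", "plot_id": f"p{j}",
                                 "species_id": sp, "raw_percent_cover": 25.0})
                for trait, vals in (("SLA", va), ("LN", vb)):
                    trait_rows.append({
                        "plot_id": f"p{j}", "species_id": sp,
                        "trait_name": trait, "plot_mean_value": vals[sp],
                        "n_individuals": 3})
        traits = pd.DataFrame(trait_rows)
        traits["species_grand_mean"] = traits.groupby(
            ["species_id", "trait_name"])["plot_mean_value"].transform("mean")
        t = tg.TraitTable.from_frame(traits)
        m = tg.normalize_relative_cover(
            tg.CommunityMatrix.from_frame(pd.DataFrame(cov_rows)), t)
        res = modified_permutation_covariation(
            m, t, "SLA", "LN", "weighted", None,
            tg.AnalysisConfig(n_permutations=99), np.random.default_rng(0))
        assert res.undefined

    def test_group_too_small(self, small_study):
        _, cover, traits = small_study
        with pytest.raises(InsufficientDataError):
            modified_permutation_covariation(
                cover, traits, "SLA", "LN", "weighted", cover.plots[:3],
                tg.AnalysisConfig(n_permutations=9))

    def test_monte_carlo_p_matches_exhaustive_species_permutation(self):
        """4 species, 6 plots: the 24-assignment exhaustive null."""
        va = {"a": 12.0, "b": 25.0, "c": 18.0, "d": 31.0}
        vb = {"a": 30.0, "b": 14.0, "c": 22.0, "d": 11.0}
        m, t = _covariation_fixture(va, vb)
        plots = m.plots
        cfg = tg.AnalysisConfig(n_permutations=9999)
        res = modified_permutation_covariation(
            m, t, "SLA", "LN", "weighted", plots, cfg,
            np.random.default_rng(123))

        # oracle: enumerate all 4! species relabelings of trait a
        species = sorted(va)
        weights = {p: m.plot_weights(p) for p in plots}
        vals_a = {p: t.plot_values(p, "SLA") for p in plots}
        vals_b = {p: t.plot_values(p, "LN") for p in plots}
        avg_b = np.array([float((weights[p] * vals_b[p]).sum()) for p in plots])
        rhos = []
        for perm in itertools.permutations(species):
            mapping = dict(zip(species, perm))
            avg_a = []
            for p in plots:
                v = np.array([vals_a[p].loc[mapping[s]] for s in species])
                w = np.array([weights[p].loc[s] for s in species])
                avg_a.append(float(w @ v))
            rhos.append(stats.spearmanr(avg_a, avg_b).statistic)
        rhos = np.array(rhos)
        rho_obs = rhos[0]  # identity permutation comes first
        assert res.observed_rho == pytest.approx(rho_obs, rel=1e-9)
        frac = np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12)
        se = math.sqrt(frac * (1 - frac) / 9999)
        assert abs(res.p_value - frac) <= 3 * se + 2.0 / 9999

    def test_plot_level_permutation_option(self):
        va = {"a": 12.0, "b": 25.0, "c": 18.0, "d": 31.0}
        vb = {"a": 30.0, "b": 14.0, "c": 22.0, "d": 11.0}
        m, t = _covariation_fixture(va, vb)
        cfg = tg.AnalysisConfig(n_permutations=999, covariation_permute="plot")
        res = modified_permutation_covariation(
            m, t, "SLA", "LN", "weighted", None, cfg, np.random.default_rng(5))
        assert 0.0 < res.p_value <= 1.0
        assert abs(res.observed_rho) <= 1.0
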