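"""Community averages, weighted variance, and the variance decomposition."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import traitgrad as tg
from traitgrad.community import (
    community_average,
    community_weighted_variance,
    compare_contributions,
    decompose_trait_variance,
    unweighted_dispersion,
)
from traitgrad.errors import InsufficientDataError, ValidationError


class TestAverages:
    def test_weighted_average(self):
        assert community_average([0.5, 0.3, 0.2], [1, 2, 3]) == pytest.approx(1.7)

    def test_unweighted_average(self):
        assert community_average(None, [1, 2, 3], "unweighted") == pytest.approx(2.0)

    def test_equal_covers_reduce_to_unweighted(self):
        w = community_average([0.5, 0.5], [3.1, 7.7])
        u = community_average(None, [3.1, 7.7], "unweighted")
        assert w == pytest.approx(u, abs=1e-12)

    def test_unnormalized_weights_rejected(self):
        with pytest.raises(ValidationError):
            community_average([0.5, 0.3], [1, 2])

    def test_empty_returns_undefined_marker(self):
        assert math.isnan(community_average([], [], "weighted", renormalize=True))

    @given(st.floats(-5, 5), st.floats(0.1, 4))
    @settings(max_examples=30, deadline=None)
    def test_cwm_is_affine_equivariant(self, b, a):
        p = np.array([0.5, 0.3, 0.2])
        x = np.array([1.0, 2.0, 3.0])
        lhs = community_average(p, a * x + b)
        rhs = a * community_average(p, x) + b
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)


class TestWeightedVariance:
    def test_hand_computed_cwv(self):
        assert community_weighted_variance([0.5, 0.3, 0.2], [1, 2, 3]) == \
            pytest.approx(0.61)

    def test_single_species_gives_zero(self):
        assert community_weighted_variance([1.0], [5.0]) == 0.0

    def test_symmetric_two_point(self):
        assert community_weighted_variance([0.5, 0.5], [0, 2]) == pytest.approx(1.0)

    def test_raw_moment_identity_on_random_plots(self, rng):
        for _ in range(1000):
            n = rng.integers(2, 12)
            p = rng.dirichlet(np.ones(n))
            x = rng.normal(0, 10, n)
            cwv = community_weighted_variance(p, x)
            cwm = community_average(p, x)
            assert abs(cwv - (p @ (x * x) - cwm**2)) < 1e-9

    def test_uniform_weights_give_population_variance(self, rng):
        x = rng.normal(5, 2, 8)
        p = np.full(8, 1 / 8)
        assert community_weighted_variance(p, x) == \
            pytest.approx(np.var(x), rel=1e-12)

    def test_invariant_under_species_relabeling(self, rng):
        p = rng.dirichlet(np.ones(6))
        x = rng.normal(0, 3, 6)
        perm = rng.permutation(6)
        assert community_weighted_variance(p[perm], x[perm]) == \
            pytest.approx(community_weighted_variance(p, x), rel=1e-12)


class TestUnweightedDispersion:
    def test_sample_variance(self):
        assert unweighted_dispersion([1, 2, 3]) == pytest.approx(1.0)

    def test_identical_values(self):
        assert unweighted_dispersion([4, 4, 4]) == 0.0

    def test_single_species_undefined(self):
        assert math.isnan(unweighted_dispersion([4.0]))


def _community(plot_values: dict, covers: dict | None = None):
    """Build a tiny normalized study from {plot: {species: value}} H data."""
    cov_rows, trait_rows = [], []
    for plot, spvals in plot_values.items():
        w = covers[plot] if covers else {s: 1.0 for s in spvals}
        for sp, val in spvals.items():
            cov_rows.append({"site": "A", "plot_id": plot, "species_id": sp,
                             "raw_percent_cover": 100.0 * w[sp]})
            trait_rows.append({"plot_id": plot, "species_id": sp,
                               "trait_name": "H", "plot_mean_value": val,
                               "n_individuals": 1})
    traits = pd.DataFrame(trait_rows)
    traits["species_grand_mean"] = traits.groupby("species_id")[
        "plot_mean_value"].transform("mean")
    t = tg.TraitTable.from_frame(traits)
    m = tg.CommunityMatrix.from_frame(pd.DataFrame(cov_rows))
    return tg.normalize_relative_cover(m, t), t


class TestDecomposition:
    def test_single_species_turnover_free_variation_is_intraspecific(self):
        m, t = _community({"p1": {"a": 10.0}, "p2": {"a": 12.0}})
        d = decompose_trait_variance(m, t, "H", "unweighted")
        assert d.ss_inter == pytest.approx(0.0, abs=1e-12)
        assert d.ss_cov == pytest.approx(0.0, abs=1e-12)
        assert d.ss_total == pytest.approx(d.ss_intra, rel=1e-12)
        assert d.ss_total == pytest.approx(2.0)  # deviations +/-1 around 11

    def test_no_itv_means_all_interspecific(self):
        # plot values equal species grand means everywhere
        m, t = _community({"p1": {"a": 10.0, "b": 20.0},
                           "p2": {"a": 10.0, "b": 20.0},
                           "p3": {"b": 20.0, "c": 5.0}})
        d = decompose_trait_variance(m, t, "H", "unweighted")
        assert d.ss_intra == pytest.approx(0.0, abs=1e-12)
        assert d.ss_total == pytest.approx(d.ss_inter, rel=1e-12)

    def test_additivity_against_independent_oracle(self, rng):
        # random 5-plot x 4-species instance; recompute both sides from
        # independently coded per-plot averages
        plots = {}
        covers = {}
        for j in range(5):
            vals, w = {}, {}
            for s in "abcd":
                vals[s] = float(rng.uniform(5, 30))
                w[s] = float(rng.uniform(0.1, 1.0))
            tot = sum(w.values())
            covers[f"p{j}"] = {s: v / tot for s, v in w.items()}
            plots[f"p{j}"] = vals
        m, t = _community(plots, covers)
        for weighting in ("weighted", "unweighted"):
            d = decompose_trait_variance(m, t, "H", weighting)
            assert d.ss_total == pytest.approx(
                d.ss_inter + d.ss_intra + 2 * d.ss_cov, rel=1e-9, abs=1e-9)
            # oracle: recompute total averages directly
            gm = {s: np.mean([plots[p][s] for p in plots]) for s in "abcd"}
            for _, row in d.per_plot.iterrows():
                p = row["plot_id"]
                if weighting == "weighted":
                    tot_avg = sum(covers[p][s] * plots[p][s] for s in "abcd")
                    int_avg = sum(covers[p][s] * gm[s] for s in "abcd")
                else:
                    tot_avg = np.mean([plots[p][s] for s in "abcd"])
                    int_avg = np.mean([gm[s] for s in "abcd"])
                assert row["total_average"] == pytest.approx(tot_avg, rel=1e-9)
                assert row["interspecific_average"] == pytest.approx(int_avg, rel=1e-9)
                assert row["intraspecific_average"] == pytest.approx(
                    tot_avg - int_avg, rel=1e-9, abs=1e-12)

    def test_needs_two_plots(self):
        m, t = _community({"p1": {"a": 10.0, "b": 20.0}})
        with pytest.raises(InsufficientDataError):
            decompose_trait_variance(m, t, "H", "unweighted")


class TestCompareContributions:
    def _dec(self, trait, frac_intra):
        # minimal DecompositionResult with a chosen intraspecific share
        per_plot = pd.DataFrame({"plot_id": ["p1", "p2"]})
        ss_total = 1.0
        return tg.DecompositionResult(
            trait_name=trait, weighting="weighted", per_plot=per_plot,
            ss_total=ss_total, ss_inter=1 - frac_intra, ss_intra=frac_intra,
            ss_cov=0.0)

    def test_identical_contributions_give_null_result(self):
        dw = [self._dec(t, 0.3) for t in ("H", "LA", "SLA")]
        du = [self._dec(t, 0.3) for t in ("H", "LA", "SLA")]
        c = compare_contributions(dw, du)
        assert c.statistic == 0.0
        assert c.p_value == 1.0

    def test_constant_nonzero_differences_flagged_degenerate(self):
        dw = [self._dec(t, 0.4) for t in ("H", "LA", "SLA")]
        du = [self._dec(t, 0.3) for t in ("H", "LA", "SLA")]
        c = compare_contributions(dw, du)
        assert c.degenerate
        assert c.mean_difference == pytest.approx(0.1)

    def test_matches_closed_form_paired_t(self):
        from scipy import stats as ss
        diffs = np.array([0.2, -0.1, 0.15, 0.05, -0.02, 0.3])
        traits = ("H", "LA", "SLA", "LDMC", "LN", "d13C")
        dw = [self._dec(t, 0.3 + d) for t, d in zip(traits, diffs)]
        du = [self._dec(t, 0.3) for t in traits]
        c = compare_contributions(dw, du)
        n = diffs.size
        t_exp = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(n))
        p_exp = 2 * ss.t.sf(abs(t_exp), df=n - 1)
        assert c.statistic == pytest.approx(t_exp, rel=1e-9)
        assert c.p_value == pytest.approx(p_exp, rel=1e-9)
        assert c.n_pairs == 6
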