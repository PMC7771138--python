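"""Effect sizes of community-weighted variance against the shuffling null.

For each plot, species covers are shuffled among the plot's species 999
times; the observed CWV's quantile q in that null distribution is
rescaled to ES = 2q - 1. Negative ES = abundant species more similar than
chance (convergence); positive = divergence. A Wilcoxon signed-ranks test
asks whether the community as a whole departs from ES = 0.
"""
import traitgrad as tg

ds = tg.generate_dataset(tg.SyntheticConfig(seed=1, gamma_abund=2.0,
                                            gamma_presence=0.0,
                                            trait_cover_fraction=1.0))
traits = tg.trait_table_from_frame(ds.individuals)
cover = tg.normalize_relative_cover(ds.cover, traits)

cfg = tg.AnalysisConfig(n_permutations=999, seed=1, trait_list=("SLA",))
es = tg.effect_sizes_table(cover, traits, cfg)
ok = es[~es["degenerate"]]
print(ok[["plot_id", "observed_cwv", "null_quantile", "effect_size"]]
      .head(8).to_string(index=False))

dep = tg.wilcoxon_departure(ok["effect_size"].to_numpy())
print(f"\nmean ES = {ok['effect_size'].mean():+.3f} over {dep.n} plots; "
      f"Wilcoxon W = {dep.statistic:.1f}, p = {dep.p_value:.4f} "
      f"({dep.direction})")
print("With the abundance filter on, the mean ES drifts negative: abundant "
      "species converge on locally favourable SLA values. One 40-plot study "
      "has limited power; scripts/acceptance.py repeats this over 50 "
      "replicates per filter strength.")
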