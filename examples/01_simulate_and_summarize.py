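"""Simulate a 40-plot understory study and summarize community traits.

Generates the default synthetic design (2 sites x 4 topographic positions
x 5 plots, ~100-species pool, 15 individuals per species per plot), then
prints weighted and unweighted community averages for SLA. The weighted
mean (CWM) weights each species by its relative cover; the unweighted
mean treats every present species equally.
"""
import traitgrad as tg

ds = tg.generate_dataset(tg.SyntheticConfig(seed=1))
traits = tg.trait_table_from_frame(ds.individuals)
cover = tg.normalize_relative_cover(ds.cover, traits)

summary = tg.community_trait_summary(cover, traits,
                                     tg.AnalysisConfig(trait_list=("SLA",)))
print(summary[["plot_id", "unweighted_mean", "weighted_mean",
               "weighted_variance", "species_count"]].head(8).to_string(index=False))
print(f"\n{len(summary)} plots; SLA in mm^2/mg. Where the weighted mean "
      "diverges from the unweighted one, abundant species differ from the "
      "average present species - the signature of abundance-level filtering.")
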