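"""End-to-end orchestration: simulate and analyse, with deterministic
seeding and tidy CSV outputs.

``run_analysis`` executes load -> normalize -> community statistics ->
variance decomposition -> environment PCA -> CWV null-model effect
sizes -> departure / gradient-correlation / Levene tests -> covariation
permutation tests per topographic position, and writes one tidy CSV per
stage plus ``sem_input.csv`` (plot-level averages joined with the
environment) for external mixed-model or SEM fitting.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .association import gradient_correlation, levene_test, wilcoxon_departure
from .community import (
    community_trait_summary,
    compare_contributions,
    decompose_trait_variance,
)
from .datamodel import (
    AnalysisConfig,
    CommunityMatrix,
    EnvironmentTable,
    TraitTable,
    normalize_relative_cover,
)
from .errors import InsufficientDataError, TraitgradError
from .gradient import environment_pca
from .nullmodels import effect_sizes_table, modified_permutation_covariation
from .synthetic import SyntheticConfig, generate_dataset

log = logging.getLogger("traitgrad")

#: Environmental variables used for ES gradient correlations by default.
DEFAULT_GRADIENT_VARS = ("avg_temp", "soil_moisture", "soil_N")


@dataclass
class PipelineReport:
    """What a run produced: file registry, config echo, seeds, warnings."""

    outputs: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "outputs": {k: str(v) for k, v in self.outputs.items()},
            "config": self.config, "seeds": self.seeds,
            "warnings": self.warnings, "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=str))


def _jsonable(v):
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, dict):
        return {("-".join(k) if isinstance(k, tuple) else str(k)): _jsonable(x)
                for k, x in v.items()}
    if isinstance(v, tuple):
        return list(v)
    return v


def _config_dict(cfg) -> dict:
    return {k: _jsonable(v) for k, v in dataclasses.asdict(cfg).items()}


def run_simulation(cfg: SyntheticConfig | None = None,
                   out_dir: str | os.PathLike = ".") -> PipelineReport:
    """Generate a synthetic dataset and write cover/traits/env CSVs."""
    cfg = cfg or SyntheticConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = generate_dataset(cfg)
    report = PipelineReport(config=_config_dict(cfg),
                            seeds={"master": cfg.seed},
                            metadata={"n_plots": cfg.n_plots,
                                      "n_species_pool": cfg.n_species_pool})
    io.write_cover_table(ds.cover, out / "cover.csv")
    io.write_individual_traits(ds.individuals, out / "traits.csv")
    io.write_environment_table(ds.env, out / "env.csv")
    report.outputs = {"cover": out / "cover.csv", "traits": out / "traits.csv",
                      "env": out / "env.csv"}
    manifest = out / "manifest.json"
    report.to_json(manifest)
    report.outputs["manifest"] = manifest
    return report


def load_tables(cover_path, traits_path, env_path
                ) -> tuple[CommunityMatrix, TraitTable, EnvironmentTable]:
    return (io.read_cover_table(cover_path), io.read_trait_table(traits_path),
            io.read_environment_table(env_path))


def run_analysis(cover_path, traits_path, env_path,
                 cfg: AnalysisConfig | None = None,
                 out_dir: str | os.PathLike = ".") -> PipelineReport:
    """Execute every analysis stage and write its output tables."""
    cfg = cfg or AnalysisConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(config=_config_dict(cfg),
                            seeds={"master": cfg.seed})

    stage = "load"
    try:
        cover, traits, env = load_tables(cover_path, traits_path, env_path)

        common = sorted(set(cover.plots) & set(env.plots))
        for p in sorted(set(env.plots) - set(cover.plots)):
            report.warnings.append(f"plot {p!r} in env but not in cover; dropped")
        for p in sorted(set(cover.plots) - set(env.plots)):
            report.warnings.append(f"plot {p!r} in cover but not in env; dropped")
        cover = CommunityMatrix.from_frame(
            cover.data[cover.data["plot_id"].isin(common)])
        env = EnvironmentTable.from_frame(
            env.data[env.data["plot_id"].isin(common)])

        stage = "normalize"
        cover = normalize_relative_cover(cover, traits, cfg)
        for p in sorted(cover.incomplete_plots):
            report.warnings.append(
                f"plot {p!r}: trait-measured species cover below "
                f"{cfg.cover_threshold:.0%}; excluded from weighted statistics")

        stage = "community_stats"
        summary = community_trait_summary(cover, traits, cfg)
        _write(report, out, "summary", summary)

        stage = "decomposition"
        decomp_rows, dec_w, dec_u = [], [], []
        for weighting, sink in (("weighted", dec_w), ("unweighted", dec_u)):
            for trait in cfg.trait_list:
                try:
                    d = decompose_trait_variance(cover, traits, trait,
                                                 weighting, cfg)
                except InsufficientDataError as e:
                    report.warnings.append(f"decomposition {trait}: {e}")
                    continue
                sink.append(d)
                decomp_rows.append({
                    "trait_name": trait, "weighting": weighting,
                    "n_plots": d.n_plots, "ss_total": d.ss_total,
                    "ss_inter": d.ss_inter, "ss_intra": d.ss_intra,
                    "ss_cov": d.ss_cov, "frac_inter": d.frac_inter,
                    "frac_intra": d.frac_intra, "frac_cov": d.frac_cov,
                })
        _write(report, out, "decomposition", pd.DataFrame(decomp_rows))
        comp_rows = []
        for component in ("interspecific", "intraspecific"):
            try:
                c = compare_contributions(dec_w, dec_u, component)
                comp_rows.append({"component": component, "t": c.statistic,
                                  "p_value": c.p_value, "n_pairs": c.n_pairs,
                                  "mean_difference": c.mean_difference,
                                  "degenerate": c.degenerate})
            except InsufficientDataError as e:
                report.warnings.append(f"contribution comparison: {e}")
        _write(report, out, "contribution_comparison", pd.DataFrame(comp_rows))

        stage = "pca"
        axes = environment_pca(env)
        _write(report, out, "pca_loadings",
               axes.loadings.rename_axis("variable").reset_index())
        _write(report, out, "pca_scores",
               axes.scores.rename_axis("plot").reset_index())
        _write(report, out, "pca_summary", pd.DataFrame({
            "axis": axes.loadings.columns,
            "eigenvalue": axes.eigenvalues,
            "variance_explained": axes.variance_explained,
            "retained": axes.eigenvalues > 1.0,
        }))

        stage = "effect_sizes"
        es = effect_sizes_table(cover, traits, cfg)
        _write(report, out, "effect_sizes", es)

        stage = "departure_tests"
        positions = env.positions()
        dep_rows = []
        groups = {"all": set(cover.plots)}
        for pos in sorted(positions.unique()):
            groups[pos] = set(positions.index[positions == pos])
        for trait in cfg.trait_list:
            es_t = es[(es["trait_name"] == trait) & ~es["degenerate"]]
            for gname, plots in groups.items():
                vals = es_t.loc[es_t["plot_id"].isin(plots), "effect_size"]
                d = wilcoxon_departure(vals.to_numpy())
                dep_rows.append({"trait_name": trait, "grouping": gname,
                                 "W": d.statistic, "n": d.n, "p_value": d.p_value,
                                 "direction": d.direction,
                                 "sufficient": d.sufficient})
        _write(report, out, "departure_tests", pd.DataFrame(dep_rows))

        stage = "gradient_correlations"
        envmat = env.matrix()
        pc1 = axes.scores["PC1"]
        corr_rows = []
        for trait in cfg.trait_list:
            es_t = es[(es["trait_name"] == trait) & ~es["degenerate"]]
            es_t = es_t.set_index("plot_id")["effect_size"]
            covariates = {v: envmat[v] for v in DEFAULT_GRADIENT_VARS}
            covariates["PC1"] = pc1
            for vname, series in covariates.items():
                joined = pd.concat([es_t, series], axis=1, join="inner").dropna()
                if len(joined) < 4:
                    continue
                g = gradient_correlation(joined.iloc[:, 0], joined.iloc[:, 1],
                                         vname)
                corr_rows.append({"trait_name": trait, "variable": vname,
                                  "rho": g.rho, "p_value": g.p_value, "n": g.n,
                                  "undefined": g.undefined})
        _write(report, out, "gradient_correlations", pd.DataFrame(corr_rows))

        stage = "dispersion_tests"
        lev_rows = []
        tdata = traits.transformed(cfg.log_transform).data
        env_idx = env.data.set_index("plot_id")
        for trait in cfg.trait_list:
            sl = tdata[tdata["trait_name"] == trait]
            if cfg.levene_unit == "species":
                values = sl["plot_mean_value"].to_numpy()
                plot_ids = sl["plot_id"]
            else:
                per_plot = sl.groupby("plot_id")["plot_mean_value"].mean()
                values = per_plot.to_numpy()
                plot_ids = per_plot.index.to_series()
            for factor, col in (("aspect", "aspect_class"),
                                ("elevation", "elevation_class")):
                labels = env_idx.loc[plot_ids, col].to_numpy()
                try:
                    r = levene_test(values, labels, cfg.levene_center, factor)
                except InsufficientDataError as e:
                    report.warnings.append(f"Levene {trait}/{factor}: {e}")
                    continue
                lev_rows.append({"trait_name": trait, "factor": factor,
                                 "F": r.F, "df_between": r.df_between,
                                 "df_within": r.df_within, "p_value": r.p_value,
                                 "degenerate": r.degenerate})
        _write(report, out, "dispersion_tests", pd.DataFrame(lev_rows))

        stage = "covariation_tests"
        cov_rows = []
        pairs = [(a, b) for i, a in enumerate(cfg.trait_list)
                 for b in cfg.trait_list[i + 1:]]
        ss = np.random.SeedSequence((cfg.seed, 2026))
        children = iter(ss.spawn(len(pairs) * 2 * len(groups)))
        for a, b in pairs:
            for weighting in ("weighted", "unweighted"):
                for gname, plots in groups.items():
                    child = next(children)
                    sub_seed = int(child.generate_state(1, np.uint32)[0])
                    try:
                        r = modified_permutation_covariation(
                            cover, traits, a, b, weighting, sorted(plots),
                            cfg, np.random.default_rng(sub_seed),
                            group=gname, seed=sub_seed)
                    except InsufficientDataError as e:
                        report.warnings.append(
                            f"covariation {a}-{b}/{weighting}/{gname}: {e}")
                        continue
                    cov_rows.append({
                        "trait_a": a, "trait_b": b, "weighting": weighting,
                        "group": gname, "rho": r.observed_rho,
                        "p_value": r.p_value, "n_plots": r.n_plots,
                        "n_permutations": r.n_permutations, "seed": r.seed,
                        "undefined": r.undefined})
                    report.seeds[f"covariation:{a}-{b}:{weighting}:{gname}"] = sub_seed
        _write(report, out, "covariation", pd.DataFrame(cov_rows))

        stage = "sem_input"
        wide_w = summary.pivot(index="plot_id", columns="trait_name",
                               values="weighted_mean").add_suffix("_weighted")
        wide_u = summary.pivot(index="plot_id", columns="trait_name",
                               values="unweighted_mean").add_suffix("_unweighted")
        sem = env.data.set_index("plot_id").join([wide_w, wide_u, pc1])
        _write(report, out, "sem_input", sem.rename_axis("plot").reset_index())
    except TraitgradError as e:
        raise TraitgradError(f"stage {stage!r} failed: {e}") from e

    report.metadata.update({
        "n_plots": len(cover.plots),
        "n_species": len(cover.species),
        "incomplete_plots": sorted(map(str, cover.incomplete_plots)),
    })
    report.to_json(out / "report.json")
    report.outputs["report"] = out / "report.json"
    missing = [str(p) for p in report.outputs.values() if not Path(p).exists()]
    if missing:
        raise TraitgradError(f"outputs missing on completion: {missing}")
    return report


def _write(report: PipelineReport, out: Path, name: str, df: pd.DataFrame) -> None:
    path = out / f"{name}.csv"
    df.to_csv(path, index=False)
    report.outputs[name] = path
    log.info("wrote %s (%d rows)", path, len(df))
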