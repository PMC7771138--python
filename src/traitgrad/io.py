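"""CSV readers and writers for the three input tables.

Formats (comma-separated, UTF-8, ``.`` decimal, header row mandatory):

* ``cover.csv`` — ``site, plot, species, percent_cover`` with an optional
  ``subplot`` column; subplot covers are averaged by species over the
  subplots of each plot before any analysis (absent subplots count as zero
  cover is *not* assumed — the mean runs over the rows present, so a
  survey recording explicit zeros should include them).
* ``traits.csv`` — either individual-level
  (``site, plot, species, individual, H, LA, SLA, LDMC, LN, d13C``) or
  plot-mean level (same minus ``individual``, plus ``n_individuals``).
* ``env.csv`` — ``plot`` plus the ten environmental variables plus
  ``site, elevation_class, aspect_class``.
"""
from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .datamodel import (
    ENV_VARS,
    POSITIVE_TRAITS,
    TRAITS,
    CommunityMatrix,
    EnvironmentTable,
    TraitTable,
)
from .errors import SchemaError, ValidationError

_COVER_REQUIRED = ("site", "plot", "species", "percent_cover")


def read_cover_table(path: str | os.PathLike) -> CommunityMatrix:
    """Load a percent-cover CSV into a (not yet normalized) CommunityMatrix."""
    df = pd.read_csv(path)
    missing = [c for c in _COVER_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"cover table is missing column(s): {missing}")
    neg = df.index[df["percent_cover"] < 0]
    if len(neg):
        raise ValidationError(f"negative percent_cover at row {neg[0]}")
    if "subplot" in df.columns:
        if df.duplicated(subset=["plot", "species", "subplot"]).any():
            raise ValidationError("duplicate (plot, species, subplot) row")
        df = (
            df.groupby(["site", "plot", "species"], as_index=False)["percent_cover"]
            .mean()
        )
    else:
        if df.duplicated(subset=["plot", "species"]).any():
            raise ValidationError("duplicate (plot, species) row")
    out = df.rename(columns={
        "plot": "plot_id", "species": "species_id",
        "percent_cover": "raw_percent_cover",
    })
    return CommunityMatrix.from_frame(out)


def read_trait_table(path: str | os.PathLike) -> TraitTable:
    """Load a trait CSV (individual- or plot-mean level) into a TraitTable.

    Individual rows are aggregated to plot means; the species grand mean is
    the unweighted mean of plot means across the plots where the species
    was measured. A missing (NaN) value for one trait leaves the species in
    play for its other traits.
    """
    return trait_table_from_frame(pd.read_csv(path))


def trait_table_from_frame(df: pd.DataFrame) -> TraitTable:
    """Aggregate a raw (individual- or plot-mean level) frame to a TraitTable."""
    for col in ("site", "plot", "species"):
        if col not in df.columns:
            raise SchemaError(f"trait table is missing column(s): ['{col}']")
    id_cols = {"site", "plot", "species", "individual", "n_individuals"}
    trait_cols = [c for c in df.columns if c not in id_cols]
    unknown = set(trait_cols) - set(TRAITS)
    if unknown:
        raise SchemaError(f"unknown trait column(s): {sorted(unknown)}")
    if not trait_cols:
        raise SchemaError("trait table has no trait columns")
    for t in trait_cols:
        if t in POSITIVE_TRAITS and (df[t].dropna() <= 0).any():
            bad = df.loc[df[t] <= 0].iloc[0]
            raise ValidationError(
                f"nonpositive {t} value for species {bad['species']!r} "
                f"in plot {bad['plot']!r}"
            )

    individual_level = "individual" in df.columns
    long = df.melt(
        id_vars=[c for c in df.columns if c in id_cols],
        value_vars=trait_cols, var_name="trait_name", value_name="value",
    ).dropna(subset=["value"])

    if individual_level:
        agg = (
            long.groupby(["plot", "species", "trait_name"], as_index=False)
            .agg(plot_mean_value=("value", "mean"), n_individuals=("value", "size"))
        )
    else:
        if "n_individuals" not in df.columns:
            raise SchemaError(
                "plot-mean trait table is missing column(s): ['n_individuals']"
            )
        agg = long.rename(columns={"value": "plot_mean_value"})[
            ["plot", "species", "trait_name", "plot_mean_value", "n_individuals"]
        ]
        if agg.duplicated(subset=["plot", "species", "trait_name"]).any():
            raise ValidationError("duplicate (plot, species, trait) row")

    agg["species_grand_mean"] = agg.groupby(["species", "trait_name"])[
        "plot_mean_value"].transform("mean")
    agg = agg.rename(columns={"plot": "plot_id", "species": "species_id"})
    return TraitTable.from_frame(agg)


def read_environment_table(path: str | os.PathLike) -> EnvironmentTable:
    """Load the plot x environment CSV."""
    df = pd.read_csv(path)
    df = df.rename(columns={"plot": "plot_id"})
    return EnvironmentTable.from_frame(df)


def write_cover_table(m: CommunityMatrix, path: str | os.PathLike) -> None:
    out = m.data.rename(columns={
        "plot_id": "plot", "species_id": "species",
        "raw_percent_cover": "percent_cover",
    })[["site", "plot", "species", "percent_cover"]]
    out.to_csv(path, index=False)


def write_trait_table(t: TraitTable, path: str | os.PathLike,
                      site_of_plot: dict | None = None) -> None:
    """Write plot-mean-level traits.csv (wide, one column per trait)."""
    df = t.data
    n_ind = df.groupby(["plot_id", "species_id"])["n_individuals"].first()
    wide = df.pivot_table(index=["plot_id", "species_id"], columns="trait_name",
                          values="plot_mean_value", aggfunc="first")
    wide = wide.reindex(columns=[c for c in TRAITS if c in wide.columns])
    wide.columns.name = None
    wide = wide.join(n_ind).reset_index().rename(
        columns={"plot_id": "plot", "species_id": "species"})
    site_of_plot = site_of_plot or {}
    wide.insert(0, "site", wide["plot"].map(lambda p: site_of_plot.get(p, "site")))
    wide.to_csv(path, index=False)


def write_environment_table(e: EnvironmentTable, path: str | os.PathLike) -> None:
    out = e.data.rename(columns={"plot_id": "plot"})
    cols = ["plot", *ENV_VARS, "site", "elevation_class", "aspect_class"]
    out[cols].to_csv(path, index=False)


def write_individual_traits(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write an individual-level trait table as produced by the simulator."""
    cols = ["site", "plot", "species", "individual",
            *[t for t in TRAITS if t in df.columns]]
    df[cols].to_csv(path, index=False)
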