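"""Core tables of the pipeline and their invariants.

Three tidy tables drive every analysis stage:

* :class:`CommunityMatrix` — plot x species percent cover, and after
  :func:`normalize_relative_cover` the relative covers ``p_ij`` used as
  abundance weights.
* :class:`TraitTable` — per-plot per-species trait means ``x_ij`` (the
  "specific" averages) together with species grand means (the "fixed"
  averages used for the interspecific component of the variance
  decomposition).
* :class:`EnvironmentTable` — one row per plot with the ten environmental
  variables plus the design factors (site, elevation class, aspect class).

All three wrap a validated :class:`pandas.DataFrame`; construction goes
through ``from_frame`` so that every instance in circulation satisfies the
documented invariants.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, SchemaError, ValidationError

#: The six functional traits, in canonical order.
TRAITS: tuple[str, ...] = ("H", "LA", "SLA", "LDMC", "LN", "d13C")

#: Traits that must be strictly positive (leaf carbon isotope ratio may be
#: negative and typically is, around -30 permil).
POSITIVE_TRAITS: frozenset[str] = frozenset({"H", "LA", "SLA", "LDMC", "LN"})

#: Trait units, for documentation and output metadata.
TRAIT_UNITS: dict[str, str] = {
    "H": "cm",
    "LA": "mm^2",
    "SLA": "mm^2/mg",
    "LDMC": "mg/g",
    "LN": "mg/g",
    "d13C": "permil",
}

#: The ten environmental variables measured per plot.
ENV_VARS: tuple[str, ...] = (
    "avg_temp",
    "max_temp",
    "min_temp",
    "soil_moisture",
    "pH",
    "NO3_N",
    "NH4_N",
    "PO4",
    "soil_N",
    "PAR",
)

ELEVATION_LEVELS = ("high", "low")
ASPECT_LEVELS = ("north", "south")

_COVER_SUM_TOL = 1e-9


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the statistical pipeline.

    Parameters
    ----------
    n_permutations
        Number of null-model randomizations for effect sizes and the
        covariation permutation test (default 9999).
    seed
        Master seed; per-plot and per-trait sub-seeds are spawned from it
        deterministically.
    trait_list
        Subset of the six traits to analyse.
    cover_threshold
        Minimum fraction of a plot's cumulative raw cover that must be
        represented by trait-measured species (default 0.80); plots below
        it are flagged incomplete and excluded from weighted statistics.
    es_tail
        Tail convention for effect-size significance (only ``two_sided``).
    levene_center
        ``mean`` for classic Levene, ``median`` for Brown-Forsythe.
    log_transform
        Traits to log-transform before all statistics (off by default).
    covariation_permute
        Exchangeable unit of the covariation permutation test:
        ``species`` (default) permutes species-level trait identities,
        ``plot`` permutes plot-level community averages directly.
    levene_unit
        ``species`` (default) pools species-level plot means across plots;
        ``plot`` uses plot-level unweighted averages.
    """

    n_permutations: int = 9999
    seed: int = 0
    trait_list: tuple[str, ...] = TRAITS
    cover_threshold: float = 0.80
    es_tail: str = "two_sided"
    levene_center: str = "mean"
    log_transform: tuple[str, ...] = ()
    covariation_permute: str = "species"
    levene_unit: str = "species"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if not (0.0 < self.cover_threshold <= 1.0):
            raise ConfigError("cover_threshold must be in (0, 1]")
        unknown = set(self.trait_list) - set(TRAITS)
        if unknown:
            raise ConfigError(f"unknown traits in trait_list: {sorted(unknown)}")
        if self.es_tail != "two_sided":
            raise ConfigError("es_tail must be 'two_sided'")
        if self.levene_center not in ("mean", "median"):
            raise ConfigError("levene_center must be 'mean' or 'median'")
        if self.covariation_permute not in ("species", "plot"):
            raise ConfigError("covariation_permute must be 'species' or 'plot'")
        if self.levene_unit not in ("species", "plot"):
            raise ConfigError("levene_unit must be 'species' or 'plot'")
        unknown = set(self.log_transform) - set(TRAITS)
        if unknown:
            raise ConfigError(f"unknown traits in log_transform: {sorted(unknown)}")


def _require_columns(df: pd.DataFrame, cols: Iterable[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} is missing column(s): {missing}")


@dataclass(frozen=True)
class CommunityMatrix:
    """Plot x species cover records.

    ``data`` columns: ``site``, ``plot_id``, ``species_id``,
    ``raw_percent_cover`` and, once normalized, ``relative_cover``
    (NaN before normalization).  ``incomplete_plots`` lists plots whose
    trait-measured species fall below the cover threshold; they are kept
    in the table but excluded from weighted statistics downstream.
    """

    data: pd.DataFrame
    normalized: bool = False
    incomplete_plots: frozenset = field(default_factory=frozenset)

    _COLUMNS = ("site", "plot_id", "species_id", "raw_percent_cover", "relative_cover")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, *, normalized: bool = False,
                   incomplete_plots: Iterable = ()) -> "CommunityMatrix":
        df = df.copy()
        if "relative_cover" not in df.columns:
            df["relative_cover"] = np.nan
        if "site" not in df.columns:
            df["site"] = "site"
        _require_columns(df, cls._COLUMNS, "cover table")
        df = df.loc[:, list(cls._COLUMNS)].reset_index(drop=True)

        neg = df.index[df["raw_percent_cover"] < 0]
        if len(neg):
            raise ValidationError(
                f"negative raw_percent_cover at row index {neg[0]}"
            )
        dup = df.duplicated(subset=["plot_id", "species_id"])
        if dup.any():
            pair = df.loc[dup.idxmax(), ["plot_id", "species_id"]].tolist()
            raise ValidationError(f"duplicate (plot, species) pair: {pair}")
        if normalized:
            rel = df["relative_cover"]
            if (rel.dropna() < 0).any():
                raise ValidationError("negative relative_cover")
            incomplete = set(incomplete_plots)
            sums = df.dropna(subset=["relative_cover"]).groupby("plot_id")[
                "relative_cover"].sum()
            bad = sums[(sums - 1.0).abs() > _COVER_SUM_TOL]
            bad = bad[~bad.index.isin(incomplete)]
            if len(bad):
                raise ValidationError(
                    f"relative covers in plot {bad.index[0]!r} sum to "
                    f"{bad.iloc[0]:.12f}, not 1"
                )
        return cls(data=df, normalized=normalized,
                   incomplete_plots=frozenset(incomplete_plots))

    @property
    def plots(self) -> list:
        return sorted(self.data["plot_id"].unique())

    @property
    def species(self) -> list:
        return sorted(self.data["species_id"].unique())

    def plot_slice(self, plot_id) -> pd.DataFrame:
        """Rows for one plot, indexed by species."""
        sl = self.data[self.data["plot_id"] == plot_id]
        return sl.set_index("species_id")

    def plot_weights(self, plot_id) -> pd.Series:
        """Relative covers p_ij of one plot as a species-indexed Series."""
        if not self.normalized:
            raise ValidationError("relative covers unset; normalize first")
        sl = self.plot_slice(plot_id)["relative_cover"].dropna()
        return sl


@dataclass(frozen=True)
class TraitTable:
    """Per-plot per-species trait means with species grand means.

    ``data`` columns: ``plot_id``, ``species_id``, ``trait_name``,
    ``plot_mean_value``, ``n_individuals``, ``species_grand_mean``.
    The grand mean (the "fixed" or interspecific value) is the unweighted
    mean of a species' plot-level means across all plots where it was
    measured, and is constant across that species' rows for a trait.
    """

    data: pd.DataFrame

    _COLUMNS = ("plot_id", "species_id", "trait_name", "plot_mean_value",
                "n_individuals", "species_grand_mean")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TraitTable":
        df = df.copy()
        _require_columns(df, cls._COLUMNS, "trait table")
        df = df.loc[:, list(cls._COLUMNS)].reset_index(drop=True)
        unknown = set(df["trait_name"].unique()) - set(TRAITS)
        if unknown:
            raise SchemaError(f"unknown trait name(s): {sorted(unknown)}")
        pos = df["trait_name"].isin(POSITIVE_TRAITS)
        bad = df.loc[pos & (df["plot_mean_value"] <= 0)]
        if len(bad):
            r = bad.iloc[0]
            raise ValidationError(
                f"nonpositive {r['trait_name']} value {r['plot_mean_value']} "
                f"for species {r['species_id']!r} in plot {r['plot_id']!r}"
            )
        if (df["n_individuals"] < 1).any():
            raise ValidationError("n_individuals must be >= 1 where a plot mean is present")
        gm = df.groupby(["species_id", "trait_name"])["species_grand_mean"].nunique()
        if (gm > 1).any():
            sp, tr = gm[gm > 1].index[0]
            raise ValidationError(
                f"species_grand_mean for species {sp!r}, trait {tr} differs across plots"
            )
        dup = df.duplicated(subset=["plot_id", "species_id", "trait_name"])
        if dup.any():
            raise ValidationError("duplicate (plot, species, trait) row")
        return cls(data=df)

    def traits_present(self) -> list[str]:
        present = set(self.data["trait_name"].unique())
        return [t for t in TRAITS if t in present]

    def species_with_trait(self, trait: str) -> set:
        return set(self.data.loc[self.data["trait_name"] == trait, "species_id"])

    def measured_species(self) -> set:
        """Species with at least one measured trait."""
        return set(self.data["species_id"].unique())

    def plot_values(self, plot_id, trait: str) -> pd.Series:
        """Plot-specific species means x_ij for one plot and trait."""
        sl = self.data[(self.data["plot_id"] == plot_id)
                       & (self.data["trait_name"] == trait)]
        return sl.set_index("species_id")["plot_mean_value"]

    def grand_means(self, trait: str) -> pd.Series:
        """Species grand means (fixed averages) for one trait."""
        sl = self.data[self.data["trait_name"] == trait]
        return sl.groupby("species_id")["species_grand_mean"].first()

    def transformed(self, log_traits: Sequence[str]) -> "TraitTable":
        """Return a copy with the given traits natural-log transformed.

        Both the plot means and the grand means are transformed; grand
        means are recomputed as the mean of the transformed plot means so
        the fixed-average convention is preserved on the log scale.
        """
        if not log_traits:
            return self
        bad = set(log_traits) - POSITIVE_TRAITS
        if bad:
            raise ConfigError(f"cannot log-transform sign-ambiguous trait(s): {sorted(bad)}")
        df = self.data.copy()
        mask = df["trait_name"].isin(log_traits)
        df.loc[mask, "plot_mean_value"] = np.log(df.loc[mask, "plot_mean_value"])
        new_gm = df.groupby(["species_id", "trait_name"])["plot_mean_value"].transform("mean")
        df.loc[mask, "species_grand_mean"] = new_gm[mask]
        return TraitTable(data=df)


@dataclass(frozen=True)
class EnvironmentTable:
    """One row per plot: ten environmental variables plus design factors."""

    data: pd.DataFrame

    _COLUMNS = ("plot_id", *ENV_VARS, "site", "elevation_class", "aspect_class")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EnvironmentTable":
        df = df.copy()
        _require_columns(df, cls._COLUMNS, "environment table")
        df = df.loc[:, list(cls._COLUMNS)].reset_index(drop=True)
        if df["plot_id"].duplicated().any():
            dup = df.loc[df["plot_id"].duplicated(), "plot_id"].iloc[0]
            raise ValidationError(f"duplicate plot {dup!r} in environment table")
        for var in ENV_VARS:
            if df[var].isna().any():
                raise ValidationError(f"missing value in environment variable {var}")
        bad = set(df["elevation_class"]) - set(ELEVATION_LEVELS)
        if bad:
            raise ValidationError(f"unknown elevation_class level(s): {sorted(bad)}")
        bad = set(df["aspect_class"]) - set(ASPECT_LEVELS)
        if bad:
            raise ValidationError(f"unknown aspect_class level(s): {sorted(bad)}")
        return cls(data=df)

    @property
    def plots(self) -> list:
        return sorted(self.data["plot_id"].unique())

    def matrix(self) -> pd.DataFrame:
        """Plot-indexed numeric matrix of the ten environmental variables."""
        return self.data.set_index("plot_id")[list(ENV_VARS)].astype(float)

    def positions(self) -> pd.Series:
        """Topographic position (elevation x aspect) per plot, e.g. 'high-north'."""
        d = self.data.set_index("plot_id")
        return d["elevation_class"].str.cat(d["aspect_class"], sep="-")


def normalize_relative_cover(m: CommunityMatrix, traits: TraitTable,
                             cfg: AnalysisConfig | None = None) -> CommunityMatrix:
    """Restrict each plot to trait-measured species and renormalize p_ij.

    Species without any trait measurement are dropped from the weights;
    their share of the plot's cumulative raw cover is checked against
    ``cfg.cover_threshold``.  A plot whose measured species represent less
    than the threshold is flagged incomplete (kept, excluded from weighted
    statistics) rather than rejected, mirroring a sampling protocol that
    measures traits only on species covering at least that fraction.
    """
    cfg = cfg or AnalysisConfig()
    measured = traits.measured_species()
    df = m.data.copy()
    incomplete: set = set()
    keep_rows = []
    for plot, grp in df.groupby("plot_id", sort=False):
        total = grp["raw_percent_cover"].sum()
        if total <= 0:
            raise ValidationError(f"plot {plot!r} has zero cumulative cover")
        sub = grp[grp["species_id"].isin(measured)]
        covered = sub["raw_percent_cover"].sum() / total
        if covered + _COVER_SUM_TOL < cfg.cover_threshold:
            incomplete.add(plot)
        if len(sub) == 0:
            incomplete.add(plot)
            continue
        keep_rows.append(sub.index)
    if not keep_rows:
        raise ValidationError("no plot retains any trait-measured species")
    kept = df.loc[np.concatenate([idx.values for idx in keep_rows])].copy()
    sums = kept.groupby("plot_id")["raw_percent_cover"].transform("sum")
    kept["relative_cover"] = kept["raw_percent_cover"] / sums
    return CommunityMatrix.from_frame(kept, normalized=True,
                                      incomplete_plots=incomplete)
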