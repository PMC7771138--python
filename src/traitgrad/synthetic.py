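"""Synthetic forest-understory communities along a resource gradient.

The generator emulates the data structure the pipeline analyses: two
sites, four topographic positions (high/low elevation x north/south
aspect), five plots per position per site, a ~100-species pool, percent
cover per plot, fifteen measured individuals per species per plot for
six functional traits, and ten plot-level environmental variables.

Mechanistically, a single latent *resource score* per plot (high = cool,
moist, nitrogen-rich) drives everything:

* the ten environmental variables are noisy linear readouts of the score
  around position-specific profiles calibrated to growing-season field
  ranges, so a correlation-matrix PCA recovers a dominant axis;
* each species has a resource optimum correlated with its leaf-economics
  position (high-SLA species favour resource-rich plots);
* presence filtering: occurrence probability decays with the squared
  optimum-score mismatch at rate ``gamma_presence``;
* abundance filtering: conditional on presence, cover is lognormal with
  log-mean depressed by a saturating function of the squared mismatch at
  rate ``gamma_abund`` (the penalty levels off at large niche distance,
  preventing single-species collapse), amplified in resource-poor plots
  (``stress_amplification``), so abundant species converge on locally
  favourable trait values;
* intraspecific variation: individual trait values scatter around the
  species grand mean with standard deviation ``sigma_intra`` and a
  directional component (``plasticity``) tracking the resource score.

With ``gamma_presence = gamma_abund = 0`` and ``sigma_intra = 0`` the
traits carry no signal of the environment, which is the null condition
used to calibrate the effect-size machinery.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import ENV_VARS, TRAITS, CommunityMatrix, EnvironmentTable
from .errors import ConfigError, ValidationError

POSITIONS: tuple[tuple[str, str], ...] = (
    ("high", "north"), ("high", "south"), ("low", "north"), ("low", "south"),
)

#: Latent resource score of each position (high-north richest).
POSITION_RESOURCE: dict[tuple[str, str], float] = {
    ("high", "north"): 1.0,
    ("high", "south"): 1.0 / 3.0,
    ("low", "north"): -1.0 / 3.0,
    ("low", "south"): -1.0,
}

# Position profiles (mean, sd) for the ten variables, calibrated to
# growing-season conditions of southern Appalachian understory plots
# (temperatures degC, moisture %, nutrient fluxes ug/cm^2/day, soil N %,
# PAR % of open sky). SDs are per-plot spreads within a position.
ENV_PROFILE: dict[str, dict[tuple[str, str], tuple[float, float]]] = {
    "avg_temp": {("high", "north"): (18.3, 2.1), ("high", "south"): (18.7, 2.1),
                 ("low", "north"): (19.0, 2.1), ("low", "south"): (20.3, 2.2)},
    "max_temp": {("high", "north"): (19.6, 0.36), ("high", "south"): (20.4, 0.42),
                 ("low", "north"): (20.3, 0.42), ("low", "south"): (22.1, 0.49)},
    "min_temp": {("high", "north"): (16.1, 5.4), ("high", "south"): (16.8, 5.4),
                 ("low", "north"): (17.0, 5.4), ("low", "south"): (18.0, 5.4)},
    "soil_moisture": {("high", "north"): (15.1, 1.25), ("high", "south"): (13.4, 1.45),
                      ("low", "north"): (14.1, 1.41), ("low", "south"): (12.7, 1.63)},
    "pH": {("high", "north"): (5.03, 0.29), ("high", "south"): (4.90, 0.31),
           ("low", "north"): (5.25, 0.31), ("low", "south"): (5.12, 0.34)},
    "NO3_N": {("high", "north"): (0.45, 0.18), ("high", "south"): (0.09, 0.18),
              ("low", "north"): (0.11, 0.18), ("low", "south"): (0.05, 0.20)},
    "NH4_N": {("high", "north"): (0.46, 0.20), ("high", "south"): (0.40, 0.22),
              ("low", "north"): (0.27, 0.22), ("low", "south"): (0.10, 0.25)},
    "PO4": {("high", "north"): (0.26, 0.29), ("high", "south"): (0.30, 0.29),
            ("low", "north"): (0.15, 0.29), ("low", "south"): (0.21, 0.31)},
    "soil_N": {("high", "north"): (0.47, 0.07), ("high", "south"): (0.36, 0.07),
               ("low", "north"): (0.19, 0.07), ("low", "south"): (0.14, 0.09)},
    "PAR": {("high", "north"): (1.86, 0.49), ("high", "south"): (1.42, 0.58),
            ("low", "north"): (0.85, 0.56), ("low", "south"): (1.30, 0.65)},
}

#: Correlation of each variable with the within-position resource residual.
ENV_RESOURCE_CORR: dict[str, float] = {
    "avg_temp": -0.5, "max_temp": -0.5, "min_temp": -0.3,
    "soil_moisture": 0.6, "pH": 0.1, "NO3_N": 0.4, "NH4_N": 0.4,
    "PO4": 0.1, "soil_N": 0.6, "PAR": 0.2,
}

_NONNEGATIVE_VARS = ("soil_moisture", "NO3_N", "NH4_N", "PO4", "soil_N", "PAR")

#: Trait means on the simulation (transformed) scale: natural log for the
#: positive-only traits, natural scale for d13C.
DEFAULT_TRAIT_MEANS: dict[str, float] = {
    "H": np.log(20.0), "LA": np.log(1500.0), "SLA": np.log(30.0),
    "LDMC": np.log(250.0), "LN": np.log(25.0), "d13C": -30.0,
}

DEFAULT_TRAIT_SDS: dict[str, float] = {
    "H": 0.5, "LA": 0.8, "SLA": 0.3, "LDMC": 0.25, "LN": 0.25, "d13C": 1.5,
}

#: Leaf-economics-spectrum correlation structure of species grand means.
DEFAULT_TRAIT_CORR = np.array([
    # H     LA    SLA   LDMC  LN    d13C
    [1.0, 0.4, 0.0, 0.0, 0.0, 0.0],
    [0.4, 1.0, 0.2, 0.0, 0.1, 0.0],
    [0.0, 0.2, 1.0, -0.6, 0.6, -0.3],
    [0.0, 0.0, -0.6, 1.0, -0.4, 0.2],
    [0.0, 0.1, 0.6, -0.4, 1.0, -0.2],
    [0.0, 0.0, -0.3, 0.2, -0.2, 1.0],
])


def default_trait_covariance() -> np.ndarray:
    sd = np.array([DEFAULT_TRAIT_SDS[t] for t in TRAITS])
    return DEFAULT_TRAIT_CORR * np.outer(sd, sd)


def _default_sigma_intra() -> dict[str, float]:
    # One third of the interspecific sd per trait, on the transformed scale.
    return {t: DEFAULT_TRAIT_SDS[t] / 3.0 for t in TRAITS}


@dataclass(frozen=True)
class SyntheticConfig:
    """All dials of the generator; defaults are the study-design conditions."""

    n_sites: int = 2
    plots_per_position: int = 5
    n_species_pool: int = 100
    n_individuals: int = 15
    trait_covariance: np.ndarray = field(default_factory=default_trait_covariance)
    trait_means: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_MEANS))
    gamma_presence: float = 0.5
    gamma_abund: float = 1.5
    sigma_intra: dict = field(default_factory=_default_sigma_intra)
    plasticity: float = 0.5
    stress_amplification: float = 1.0
    opt_link: float = 0.7
    opt_sd: float = 0.8
    resource_sd: float = 0.3
    base_presence: float = 0.18
    abund_sigma: float = 1.0
    cover_round: float = 0.1
    cover_floor: float = 0.1
    trait_cover_fraction: float = 0.85
    env_profile: dict = field(default_factory=lambda: {
        var: dict(prof) for var, prof in ENV_PROFILE.items()})
    env_resource_corr: dict = field(default_factory=lambda: dict(ENV_RESOURCE_CORR))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.plots_per_position < 1:
            raise ConfigError("n_sites and plots_per_position must be >= 1")
        if self.n_species_pool < 1:
            raise ConfigError("n_species_pool must be >= 1")
        if self.n_individuals < 1:
            raise ConfigError("n_individuals must be >= 1")
        cov = np.asarray(self.trait_covariance, dtype=float)
        if cov.shape != (len(TRAITS), len(TRAITS)):
            raise ConfigError("trait_covariance must be 6x6")
        if not np.allclose(cov, cov.T):
            raise ConfigError("trait_covariance must be symmetric")
        if np.linalg.eigvalsh(cov).min() < -1e-10:
            raise ConfigError("trait_covariance must be positive semidefinite")
        for name in ("gamma_presence", "gamma_abund", "plasticity",
                     "stress_amplification", "abund_sigma", "opt_sd",
                     "resource_sd", "stress_amplification"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if any(v < 0 for v in self.sigma_intra.values()):
            raise ConfigError("sigma_intra entries must be >= 0")
        if not (0.0 < self.base_presence < 1.0):
            raise ConfigError("base_presence must be in (0, 1)")
        if not (0.0 < self.trait_cover_fraction <= 1.0):
            raise ConfigError("trait_cover_fraction must be in (0, 1]")
        for var in ENV_VARS:
            if var not in self.env_profile:
                raise ConfigError(f"env_profile missing variable {var!r}")
            for pos, (mean, sd) in self.env_profile[var].items():
                if sd < 0:
                    raise ConfigError(
                        f"negative sd for {var!r} at position {pos}")
            if abs(self.env_resource_corr.get(var, 0.0)) > 1.0:
                raise ConfigError(f"env_resource_corr[{var!r}] outside [-1, 1]")

    @property
    def n_plots(self) -> int:
        return self.n_sites * len(POSITIONS) * self.plots_per_position


@dataclass(frozen=True)
class SpeciesPool:
    """Species grand means (transformed scale) and resource optima."""

    species_ids: tuple
    grand_means: pd.DataFrame = field(repr=False)  # species x trait, transformed
    optima: pd.Series = field(repr=False)


def _plot_layout(cfg: SyntheticConfig) -> pd.DataFrame:
    rows = []
    for s in range(cfg.n_sites):
        site = f"S{s + 1}"
        for elev, aspect in POSITIONS:
            for k in range(cfg.plots_per_position):
                rows.append({
                    "plot_id": f"{site}-{elev[0]}{aspect[0]}-{k + 1:02d}",
                    "site": site, "elevation_class": elev,
                    "aspect_class": aspect,
                })
    return pd.DataFrame(rows)


def generate_environment(cfg: SyntheticConfig, rng: np.random.Generator
                         ) -> tuple[EnvironmentTable, pd.Series]:
    """Draw the plot x environment table and the latent resource scores.

    Returns the table together with a plot-indexed Series of resource
    scores (not part of the observable table; the environmental variables
    are its noisy readouts).
    """
    layout = _plot_layout(cfg)
    n = len(layout)
    pos = list(zip(layout["elevation_class"], layout["aspect_class"]))
    base = np.array([POSITION_RESOURCE[p] for p in pos])
    z = rng.standard_normal(n)
    resource = base + cfg.resource_sd * z
    data = {"plot_id": layout["plot_id"]}
    for var in ENV_VARS:
        mean = np.array([cfg.env_profile[var][p][0] for p in pos])
        sd = np.array([cfg.env_profile[var][p][1] for p in pos])
        c = cfg.env_resource_corr.get(var, 0.0)
        eps = rng.standard_normal(n)
        val = mean + sd * (c * z + np.sqrt(1.0 - c * c) * eps)
        if var in _NONNEGATIVE_VARS:
            val = np.maximum(val, 0.01)
        data[var] = val
    data["site"] = layout["site"]
    data["elevation_class"] = layout["elevation_class"]
    data["aspect_class"] = layout["aspect_class"]
    table = EnvironmentTable.from_frame(pd.DataFrame(data))
    scores = pd.Series(resource, index=layout["plot_id"].to_numpy(),
                       name="resource_score")
    return table, scores


def generate_species_pool(cfg: SyntheticConfig, rng: np.random.Generator
                          ) -> SpeciesPool:
    """Draw species grand-mean trait vectors and linked resource optima."""
    cov = np.asarray(cfg.trait_covariance, dtype=float)
    mean = np.array([cfg.trait_means[t] for t in TRAITS])
    G = rng.multivariate_normal(mean, cov, size=cfg.n_species_pool,
                                method="cholesky" if _is_pd(cov) else "svd")
    ids = tuple(f"sp{i + 1:03d}" for i in range(cfg.n_species_pool))
    gm = pd.DataFrame(G, index=list(ids), columns=list(TRAITS))
    sla_sd = np.sqrt(cov[TRAITS.index("SLA"), TRAITS.index("SLA")])
    if sla_sd > 0:
        z_sla = (gm["SLA"] - cfg.trait_means["SLA"]) / sla_sd
    else:
        z_sla = pd.Series(0.0, index=gm.index)
    noise = rng.standard_normal(cfg.n_species_pool)
    opt = cfg.opt_sd * (cfg.opt_link * z_sla.to_numpy()
                        + np.sqrt(max(0.0, 1.0 - cfg.opt_link ** 2)) * noise)
    return SpeciesPool(species_ids=ids, grand_means=gm,
                       optima=pd.Series(opt, index=gm.index, name="optimum"))


def _is_pd(cov: np.ndarray) -> bool:
    return np.linalg.eigvalsh(cov).min() > 1e-10


_EMPTY_PLOT_RETRIES = 20


def generate_communities(cfg: SyntheticConfig, env: EnvironmentTable,
                         resource: pd.Series, pool: SpeciesPool,
                         rng: np.random.Generator
                         ) -> tuple[CommunityMatrix, pd.DataFrame]:
    """Draw covers and individual trait measurements for every plot.

    Returns the (unnormalized) cover matrix and an individual-level trait
    table (columns site, plot, species, individual, H..d13C) covering the
    most abundant species up to ``trait_cover_fraction`` of each plot's
    cumulative cover, with ``n_individuals`` rows per measured species.
    """
    S = cfg.n_species_pool
    opt = pool.optima.to_numpy()
    gm = pool.grand_means
    alpha = float(np.log(cfg.base_presence / (1.0 - cfg.base_presence)))
    site_of = env.data.set_index("plot_id")["site"].to_dict()
    sigma = np.array([cfg.sigma_intra.get(t, 0.0) for t in TRAITS])

    cover_rows, indiv_rows = [], []
    for plot in env.plots:
        r = float(resource.loc[plot])
        mism2 = (opt - r) ** 2
        # stress in [0, 1]: 0 at the resource-rich end of the design range
        stress = float(np.clip((1.0 - r) / 2.0, 0.0, 1.0))
        g_eff = cfg.gamma_abund * (1.0 + cfg.stress_amplification * stress)
        prob = 1.0 / (1.0 + np.exp(-(alpha - cfg.gamma_presence * mism2)))
        # Saturating niche penalty: performance differences level off with
        # squared mismatch, so the filter steers relative abundance without
        # collapsing every plot onto a single dominant.
        penalty = mism2 / (1.0 + mism2)
        percent = None
        for _ in range(_EMPTY_PLOT_RETRIES):
            present = rng.random(S) < prob
            if not present.any():
                continue
            logw = (-g_eff * penalty[present]
                    + cfg.abund_sigma * rng.standard_normal(present.sum()))
            w = np.exp(logw - logw.max())
            pct = 100.0 * w / w.sum()
            if cfg.cover_round > 0:
                pct = np.round(pct / cfg.cover_round) * cfg.cover_round
            if cfg.cover_floor > 0:
                # Trace species are recorded at the minimum resolvable
                # cover, not dropped: the species list is a field
                # observation and the null model conditions on it.
                pct = np.maximum(pct, cfg.cover_floor)
            keep = pct > 0
            if keep.any():
                percent = pct[keep]
                kept_species = np.array(pool.species_ids)[present][keep]
                break
        if percent is None:
            raise ValidationError(
                f"plot {plot!r} drew no species in {_EMPTY_PLOT_RETRIES} attempts; "
                "raise base_presence or lower gamma_presence")

        order = np.argsort(percent)[::-1]
        cum = np.cumsum(percent[order]) / percent.sum()
        n_measured = int(np.searchsorted(cum, cfg.trait_cover_fraction) + 1)
        measured = set(kept_species[order][:n_measured])

        for sp, pct_i in zip(kept_species, percent):
            cover_rows.append({"site": site_of[plot], "plot_id": plot,
                               "species_id": sp, "raw_percent_cover": float(pct_i)})
        for sp in kept_species:
            if sp not in measured:
                continue
            base_t = gm.loc[sp].to_numpy()
            shift = sigma * cfg.plasticity * r
            draws = (base_t + shift
                     + sigma * rng.standard_normal((cfg.n_individuals, len(TRAITS))))
            for t_idx, t in enumerate(TRAITS):
                if t != "d13C":
                    draws[:, t_idx] = np.exp(draws[:, t_idx])
            for i in range(cfg.n_individuals):
                row = {"site": site_of[plot], "plot": plot, "species": sp,
                       "individual": i + 1}
                row.update({t: float(draws[i, k]) for k, t in enumerate(TRAITS)})
                indiv_rows.append(row)

    cover = CommunityMatrix.from_frame(pd.DataFrame(cover_rows))
    individuals = pd.DataFrame(indiv_rows)
    return cover, individuals


@dataclass(frozen=True)
class SyntheticDataset:
    """One simulated study: cover, individual traits, environment, latents."""

    cover: CommunityMatrix
    individuals: pd.DataFrame = field(repr=False)
    env: EnvironmentTable
    resource: pd.Series = field(repr=False)
    pool: SpeciesPool


def generate_dataset(cfg: SyntheticConfig | None = None,
                     seed: int | None = None) -> SyntheticDataset:
    """Run the three generators in order under one deterministic stream."""
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    env, resource = generate_environment(cfg, rng)
    pool = generate_species_pool(cfg, rng)
    cover, individuals = generate_communities(cfg, env, resource, pool, rng)
    return SyntheticDataset(cover=cover, individuals=individuals, env=env,
                            resource=resource, pool=pool)
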