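"""Shared fixtures: small hand-built tables and a reduced simulated study."""
import numpy as np
import pandas as pd
import pytest

import traitgrad as tg
from traitgrad.synthetic import SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def toy_cover(tmp_path):
    """One site, two plots, hand-chosen covers."""
    df = pd.DataFrame({
        "site": ["A"] * 5,
        "plot": ["p1", "p1", "p1", "p2", "p2"],
        "species": ["sp1", "sp2", "sp3", "sp1", "sp2"],
        "percent_cover": [60.0, 30.0, 10.0, 50.0, 50.0],
    })
    path = tmp_path / "cover.csv"
    df.to_csv(path, index=False)
    return path


@pytest.fixture
def toy_traits(tmp_path):
    """Plot-mean trait table for sp1/sp2 only (sp3 unmeasured)."""
    df = pd.DataFrame({
        "site": ["A"] * 4,
        "plot": ["p1", "p1", "p2", "p2"],
        "species": ["sp1", "sp2", "sp1", "sp2"],
        "n_individuals": [15, 15, 15, 15],
        "H": [12.0, 20.0, 16.0, 22.0],
        "SLA": [25.0, 35.0, 27.0, 33.0],
    })
    path = tmp_path / "traits.csv"
    df.to_csv(path, index=False)
    return path


def make_env_frame(n_plots=8, seed=0):
    rng = np.random.default_rng(seed)
    plots = [f"p{i}" for i in range(n_plots)]
    data = {"plot_id": plots}
    for var in tg.ENV_VARS:
        data[var] = rng.normal(10, 2, n_plots)
    data["site"] = ["A"] * n_plots
    data["elevation_class"] = [("high", "low")[i % 2] for i in range(n_plots)]
    data["aspect_class"] = ["north" if i < n_plots // 2 else "south"
                            for i in range(n_plots)]
    return pd.DataFrame(data)


@pytest.fixture
def env_frame():
    return make_env_frame()


@pytest.fixture(scope="session")
def small_study():
    """A reduced simulated study shared by pipeline-level tests."""
    cfg = SyntheticConfig(seed=42, plots_per_position=2, n_species_pool=40)
    ds = tg.generate_dataset(cfg)
    traits = tg.trait_table_from_frame(ds.individuals)
    cover = tg.normalize_relative_cover(ds.cover, traits)
    return ds, cover, traits
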