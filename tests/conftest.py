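import numpy as np
import pandas as pd
import pytest

from nsink.synthetic import (
    Relation,
    SiteGeneratorConfig,
    WorldGeneratorConfig,
    make_site_table,
    make_world,
)


@pytest.fixture(scope="session")
def site_table() -> pd.DataFrame:
    """Default 13-site synthetic table, seed 1."""
    return make_site_table(SiteGeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def noiseless_site_table() -> pd.DataFrame:
    """Site table with all relation noise switched off."""
    cfg = SiteGeneratorConfig(seed=1)
    cfg.relations = {
        name: Relation(rel.predictor, rel.intercept, rel.slope, 0.0)
        for name, rel in cfg.relations.items()
    }
    return make_site_table(cfg)


@pytest.fixture(scope="session")
def world():
    """Small synthetic raster world, seed 1."""
    return make_world(WorldGeneratorConfig(nx=24, ny=12, seed=1))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
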