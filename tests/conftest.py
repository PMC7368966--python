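import numpy as np
import pytest
from hypothesis import settings

import nirband as nb

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def fixtures():
    """Named synthetic datasets shared across the suite (seed 0)."""
    return nb.standard_fixtures(seed=0)


@pytest.fixture(scope="session")
def planted(fixtures):
    return fixtures["planted_band"]


@pytest.fixture(scope="session")
def tiny(fixtures):
    return fixtures["tiny"]


@pytest.fixture(scope="session")
def rank1(fixtures):
    return fixtures["rank1"]


@pytest.fixture(scope="session")
def planted_split(planted):
    """SNV-pretreated calibration/validation/testing parts of the planted set."""
    ds, _ = planted
    split = nb.split_dataset(ds, 90, 50, 54, seed=0)
    snv = nb.snv_transform(ds)
    return (snv.subset(split.calibration), snv.subset(split.validation),
            snv.subset(split.testing), split)


@pytest.fixture(scope="session")
def tiny_split(tiny):
    ds, _ = tiny
    split = nb.split_dataset(ds, 14, 8, 8, seed=0)
    snv = nb.snv_transform(ds)
    return (snv.subset(split.calibration), snv.subset(split.validation),
            snv.subset(split.testing), split)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
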