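import numpy as np
import pytest

from ptmrot.config import RunConfig
from ptmrot.library_build import RotamerLibraryModel
from ptmrot.synthetic_fixtures import (
    default_spec,
    gen_torsion_dataset,
    two_region_spec,
)


@pytest.fixture(scope="session")
def sep_records():
    """2000 phosphoserine torsion records from the default mixture."""
    return gen_torsion_dataset(default_spec("SEP"), 2000, seed=1)


@pytest.fixture(scope="session")
def sep_model(sep_records):
    return RotamerLibraryModel(sep_records)


@pytest.fixture(scope="session")
def sep_bi(sep_model):
    return sep_model.fit(backbone_dependent=False)


@pytest.fixture(scope="session")
def sep_bd_coupled():
    """Backbone-coupled dataset, fitted model and BD library."""
    spec = two_region_spec("SEP")
    records = gen_torsion_dataset(spec, 3000, seed=7)
    model = RotamerLibraryModel(records)
    return spec, records, model, model.fit()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def config():
    return RunConfig()
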