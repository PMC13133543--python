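import numpy as np
import pytest

from miaqsar.chem_model import load_template_library
from miaqsar.datasets import load_compound_table, load_proposals, specs_from_table
from miaqsar.mia_encoder import build_descriptor_matrix, default_canvas


@pytest.fixture(scope="session")
def library():
    return load_template_library()


@pytest.fixture(scope="session")
def canvas(library):
    return default_canvas(library)


@pytest.fixture(scope="session")
def series_df():
    return load_compound_table()


@pytest.fixture(scope="session")
def series_specs(series_df):
    return specs_from_table(series_df)


@pytest.fixture(scope="session")
def proposal_specs():
    return load_proposals()


@pytest.fixture(scope="session")
def y33(series_df):
    return series_df["pic50"].to_numpy(dtype=float)


@pytest.fixture(scope="session")
def dm_vdw(series_specs, canvas, library):
    """vdW-radius descriptor matrix of the 33-compound series (shared)."""
    return build_descriptor_matrix(series_specs, "vdw_radius", canvas, library)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
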