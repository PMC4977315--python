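import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from isotrace import TaxonTable
from isotrace.simulate import generate_fixture_bundle


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """A complete two-scenario synthetic bundle on disk (written once per session)."""
    out = tmp_path_factory.mktemp("bundle")
    truth = generate_fixture_bundle(out, seed=7, noise_delta_sd=0.5, noise_rate_cv=0.05)
    return out, truth


@pytest.fixture()
def toy_distance():
    """Two perfectly separated groups of three points on a line."""
    x = np.array([0.0, 0.0, 0.0, 10.0, 10.0, 10.0])[:, None]
    return squareform(pdist(x)), ["A", "A", "A", "B", "B", "B"]


@pytest.fixture()
def small_taxa():
    data = pd.DataFrame(
        {
            "s1": [30.0, 50.0, 18.0, 1.5, 0.5],
            "s2": [25.0, 55.0, 16.0, 2.5, 1.0],
        },
        index=[
            "Bacteria;Actinobacteria",
            "Bacteria;Proteobacteria",
            "Bacteria;Firmicutes",
            "Fungi;Ascomycota",
            "Archaea;Euryarchaeota",
        ],
    )
    return TaxonTable(data)
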