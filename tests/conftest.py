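import numpy as np
import pytest

from ltpdigest import datasets
from ltpdigest.proteins import ProteinRecord


@pytest.fixture(scope="session")
def wheat():
    return datasets.wheat_ltp1()


@pytest.fixture(scope="session")
def wheat_reduced():
    return datasets.wheat_ltp1(cys_state="reduced")


@pytest.fixture
def toy_protein():
    # small sequence with one tryptic (K4) and one chymotryptic (Y7) site
    return ProteinRecord(id="toy", sequence="GASKAGYTR")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
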