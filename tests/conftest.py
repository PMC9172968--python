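import numpy as np
import pandas as pd
import pytest

from seizmap.studydata import selected_compound_scores, top_regulated_genes


@pytest.fixture(scope="session")
def top_genes() -> pd.DataFrame:
    """Curated top-10 up/down DE rows of the sv2a knockout contrast."""
    return top_regulated_genes()


@pytest.fixture(scope="session")
def compound_scores() -> pd.DataFrame:
    """Connectivity scores of the six compounds picked for follow-up."""
    return selected_compound_scores()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
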