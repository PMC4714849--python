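import numpy as np
import pytest

from lncforge import lncrna_identification as ident
from lncforge.pipeline import train_default_scorer
from lncforge.synthetic_data import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def dataset():
    """The default synthetic study at seed 1 (shared; treat as read-only)."""
    return generate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def scorer():
    """Coding-potential scorer trained on the default corpora at seed 1."""
    return train_default_scorer(seed=1)


@pytest.fixture(scope="session")
def cascade_result(dataset, scorer):
    """(records, report) of the full cascade on the default dataset."""
    return ident.apply_filter_cascade(
        dataset.candidates, dataset.reference, dataset.genome,
        ident.FilterConfig(), scorer=scorer,
        homology_hits=dataset.homology_hits, scaffolds=dataset.scaffolds,
        expression=dataset.fpkm.values,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
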