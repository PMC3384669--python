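import numpy as np
import pytest

from rootid import (
    PairwiseScorer,
    SimParams,
    TaxonRecord,
    Taxonomy,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def scorer():
    return PairwiseScorer()


@pytest.fixture(scope="session")
def toy_taxonomy():
    """Two families, three genera, with one region-absent species."""
    return Taxonomy(
        [
            TaxonRecord("Alpha prima", "Alpha", "Alphaceae", "eudicot"),
            TaxonRecord("Alpha secunda", "Alpha", "Alphaceae", "eudicot"),
            TaxonRecord(
                "Alpha tertia", "Alpha", "Alphaceae", "eudicot", occurs_in_region=False
            ),
            TaxonRecord("Beta prima", "Beta", "Alphaceae", "eudicot"),
            TaxonRecord("Gamma prima", "Gamma", "Gammaceae", "monocot"),
            TaxonRecord("Gamma secunda", "Gamma", "Gammaceae", "monocot"),
        ]
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A small clean simulated study shared across test modules."""
    return simulate_dataset(
        SimParams(
            seed=11,
            n_families=3,
            genera_per_family=2,
            species_per_genus=2,
            n_queries=12,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
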