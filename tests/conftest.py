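import numpy as np
import pytest

from homeosort import SimScenario, simulate_dataset
from homeosort.distances import DistanceMatrix
from homeosort.io import SampleConfig, SamplesTable


@pytest.fixture(scope="session")
def default_dataset():
    """100 loci at the default generating conditions (shared, read-only)."""
    return simulate_dataset(SimScenario(n_loci=100, seed=11))


@pytest.fixture
def samples_table():
    return SamplesTable(
        [
            SampleConfig("M1", "M1", 2, "reference_taxon_member"),
            SampleConfig("M2", "M2", 2, "diploid"),
            SampleConfig("P1", "P1", 2, "diploid"),
            SampleConfig("P2", "P2", 2, "diploid"),
            SampleConfig("OUT", "OUT", 2, "outgroup"),
            SampleConfig("T1", "TET", 4, "tetraploid"),
        ]
    )


def matrix_from_pairs(labels, dist):
    """Build a DistanceMatrix from a frozenset-pair -> distance mapping."""
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = dist[frozenset({labels[i], labels[j]})]
            values[i, j] = values[j, i] = d
    return DistanceMatrix(tuple(str(l) for l in labels), values)


@pytest.fixture
def make_matrix():
    return matrix_from_pairs
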