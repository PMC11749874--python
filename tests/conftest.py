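import numpy as np
import pandas as pd
import pytest

from ovodiverge import synthetic_data as synth
from ovodiverge.core_io import CellMetadata, CountMatrix, PipelineConfig


@pytest.fixture(scope="session")
def species_tree():
    return synth.SpeciesTree()


@pytest.fixture(scope="session")
def truth():
    return synth.SimulationTruth(rng_seed=4)


@pytest.fixture(scope="session")
def annotations(truth, species_tree):
    return synth.simulate_genomes_and_peaks(truth, species_tree,
                                            n_peaks=600, seed=4)


@pytest.fixture(scope="session")
def read_sim(truth, annotations):
    return synth.simulate_reads_and_fragments(truth, annotations,
                                              n_reads=20_000, seed=4)


@pytest.fixture(scope="session")
def expression_cohort(truth, species_tree):
    return synth.simulate_expression(species_tree, truth, n_genes=600,
                                     cells_per_type=60, seed=4)


@pytest.fixture(scope="session")
def link_cohort():
    t = synth.SimulationTruth(rng_seed=5)
    return synth.simulate_link_cohort(t, seed=5)


@pytest.fixture()
def config():
    return PipelineConfig()


def toy_counts(values: np.ndarray, prefix: str = "g", species: str = "s1",
               cell_type: str = "TC") -> tuple[CountMatrix, CellMetadata]:
    """Dense matrix + metadata helper for hand-built examples."""
    values = np.asarray(values)
    features = [f"{prefix}{i}" for i in range(values.shape[0])]
    cells = [f"{species}_c{i}" for i in range(values.shape[1])]
    meta = CellMetadata(pd.DataFrame({
        "cell_id": cells, "species": species, "cell_type": cell_type,
        "library_id": "lib",
    }))
    return CountMatrix(features, cells, values), meta
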