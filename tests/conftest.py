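import numpy as np
import pytest

from microbiability import (
    OtuTable,
    SimulationConfig,
    build_relationship_matrix,
    filter_otus,
    simulate_dataset,
    to_model_matrix,
)


@pytest.fixture(scope="session")
def small_dataset():
    """An 80-animal synthetic dataset with a clear microbial signal."""
    cfg = SimulationConfig(
        n_animals_per_line=(40, 40),
        n_otus=60,
        library_size=3000,
        sigma2_m=0.3,
        sigma2_e_by_line={"HFP": 0.7, "LFP": 0.4},
        seed=7,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_mrm(small_dataset):
    return build_relationship_matrix(
        to_model_matrix(filter_otus(small_dataset.otu_table))
    )


@pytest.fixture
def toy_table():
    """4 OTUs x 3 samples with unequal totals and a constant-zero OTU."""
    counts = np.array(
        [
            [10.0, 20.0, 5.0],
            [0.0, 4.0, 1.0],
            [5.0, 5.0, 5.0],
            [0.0, 0.0, 0.0],
        ]
    )
    return OtuTable(counts, ["a", "b", "c", "d"], ["s1", "s2", "s3"])
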