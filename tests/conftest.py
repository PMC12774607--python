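import numpy as np
import pytest

import gammaxo as gx


@pytest.fixture
def toy_map():
    return gx.GeneticMapTable(
        {("1", "F"): 90.0, ("1", "M"): 80.0, ("2", "F"): 70.0, ("2", "M"): 60.0}
    )


@pytest.fixture
def toy_dataset(toy_map):
    """2 meioses x 2 chromosomes with a mix of 0/1/2-crossover records."""
    recs = [
        gx.TransmittedChromosome("f1", "F", "1", 90.0, np.array([10.0, 55.0])),
        gx.TransmittedChromosome("f1", "F", "2", 70.0, np.array([30.0])),
        gx.TransmittedChromosome("m1", "M", "1", 80.0, np.array([])),
        gx.TransmittedChromosome("m1", "M", "2", 60.0, np.array([12.5])),
    ]
    return gx.CrossoverDataset(recs, toy_map)


@pytest.fixture(scope="session")
def cc_dataset():
    """A full synthetic Collaborative-Cross-scale dataset at the published
    genome-wide parameters: 474 meioses per sex x 19 autosomes."""
    return gx.simulate_dataset(gx.SimSpec(seed=20260930))


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated dataset (30 meioses/sex) for fit smoke tests."""
    return gx.simulate_dataset(gx.SimSpec(seed=7, n_meioses_per_sex=30))
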