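import numpy as np
import pytest

from finesgs import (GenotypeTable, SimulationConfig, SpatialFrame, simulate)


@pytest.fixture(scope="session")
def sim_small():
    """One low-dispersal simulated dataset shared by read-only tests."""
    cfg = SimulationConfig(n_per_cohort=40, burn_in_generations=6, rng_seed=11)
    return simulate(cfg)


@pytest.fixture(scope="session")
def sim_cohort_frames(sim_small):
    """Per-cohort SpatialFrame views of the shared simulation."""
    frames = {}
    for label in sim_small.genotypes.cohort_labels:
        idx = np.where(sim_small.genotypes.cohorts.astype(str) == label)[0]
        frames[label] = SpatialFrame(
            [sim_small.frame.ids[i] for i in idx],
            sim_small.frame.x[idx], sim_small.frame.y[idx],
            sim_small.frame.plot_bounds)
    return frames


@pytest.fixture
def toy_table():
    """5 diploid individuals, 2 loci, one missing call, haplotypes."""
    calls = np.array([
        [[1, 1], [2, 3]],
        [[1, 2], [3, 3]],
        [[2, 2], [2, 2]],
        [[1, 2], [-1, -1]],
        [[2, 2], [2, 3]],
    ])
    return GenotypeTable(
        ids=[f"i{k}" for k in range(5)],
        cohorts=np.array(["a", "a", "a", "b", "b"], dtype=object),
        loci=["L1", "L2"],
        calls=calls,
        haplotypes=np.array([1, 1, 2, 3, 2]),
    )
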