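import numpy as np
import pytest

from chalkmir.synthetic import SimDesign, make_genome, plant_mirna_loci, simulate_libraries


@pytest.fixture(scope="session")
def small_design() -> SimDesign:
    return SimDesign(
        genotypes=["Cyp", "Lagr"],
        replicates_per_cell=3,
        n_true_loci=6,
        n_background_clusters=3,
        dicing_precision=0.95,
        mean_locus_count=150,
        dispersion=0.1,
        fold_changes={"locus001": 4.0, "locus002": 0.25},
        seed=42,
    )


@pytest.fixture(scope="session")
def small_world(small_design):
    """(genome, truth, libraries) for a compact simulated experiment."""
    genome = make_genome(1, 40_000, 0.43, small_design.seed)
    genome, truth = plant_mirna_loci(genome, small_design)
    libraries = simulate_libraries(truth, small_design, genome)
    return genome, truth, libraries


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
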