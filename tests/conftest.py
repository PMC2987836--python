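import numpy as np
import pytest

from sitesleuth.simulate import (
    MotifSpec,
    generate_genome,
    make_training_sets,
    plant_motifs,
    random_coding_intervals,
)
from sitesleuth.tables import synthesize_feature_tables


@pytest.fixture(scope="session")
def bundle():
    """One synthetic feature-table bundle shared across tests."""
    return synthesize_feature_tables(1)


@pytest.fixture(scope="session")
def small_scenario():
    """A 20 kb genome with 12 almost-exact planted 8-mers and training sets."""
    length = 20_000
    genome = generate_genome(length, gc_fraction=0.5, seed=11)
    coding = random_coding_intervals(length, fraction=0.5, seed=11)
    pg = plant_motifs(genome, coding, MotifSpec("TGACGTCA", theta=0.02),
                      n_sites=12, seed=11)
    sets = make_training_sets(pg, n_negatives=1500, seed=11)
    return {"pg": pg, **sets}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
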