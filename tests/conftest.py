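import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rponseq as r

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

PLANTED_SMALL = {
    "sigma54_activator_dependent": 2,
    "sigma54_bypass": 2,
    "sigma70_constitutive": 2,
    "sigma70_repressed_by_sigma54": 4,
}


@pytest.fixture(scope="session")
def small_genome():
    """40-gene genome with two promoters of each type and one repressed
    exemplar per positional class (classes cycle I..IV)."""
    return r.build_genome(40, PLANTED_SMALL, seed=1)


@pytest.fixture(scope="session")
def small_counts(small_genome):
    return r.simulate_counts(small_genome, depth=500_000, n_replicates=3,
                             dispersion=10.0, seed=2)


@pytest.fixture(scope="session")
def small_expr(small_genome, small_counts):
    lengths = {g.gene_id: g.length_bp for g in small_genome.genes}
    return r.build_expression_table(small_counts, lengths)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
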