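import random

import pytest

from spanprime.pipeline import design_markers
from spanprime.simulate import SimParams, simulate_ortholog_pair

# The planted-design study conditions: a 4-exon (3-intron) ortholog pair at
# 0.97 exon / 0.60 intron identity, fixed seed.
PLANTED_PARAMS = SimParams(seed=7, n_exons=(4, 4))


@pytest.fixture(scope="session")
def sim_pair():
    return simulate_ortholog_pair(PLANTED_PARAMS)


@pytest.fixture(scope="session")
def design_result(sim_pair):
    return design_markers(sim_pair.species_a.gene, sim_pair.species_b.gene)


@pytest.fixture()
def rnd():
    return random.Random(20240915)


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))
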