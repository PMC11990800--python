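import numpy as np
import pytest

from karyosim.events import EventProbabilities, divide
from karyosim.genome import toy_genome
from karyosim.genotype import CloneGenotype, diploid_genotype, ploidy


@pytest.fixture(scope="session")
def genome():
    return toy_genome()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_genotype_walk(genome, rng, n_steps=5, max_homologs=14):
    """A bounded random genotype: a few random division events from diploid.

    Resets to diploid whenever the walk dies out or homolog counts explode,
    so returned genotypes stay in a biologically plausible range.
    """
    probs = EventProbabilities(
        p_misseg=0.3, p_arm_misseg=0.3, p_wgd=0.05,
        p_focal_amp=0.15, p_focal_del=0.15,
    )
    g = diploid_genotype(genome)
    for _ in range(n_steps):
        a, b, _, _ = divide(g, probs, genome, rng)
        g = a if rng.random() < 0.5 else b
        if ploidy(g, genome) == 0 or g.total_homologs > max_homologs:
            g = diploid_genotype(genome)
    return g


@pytest.fixture()
def random_genotype(genome, rng):
    def make(steps=5):
        return random_genotype_walk(genome, rng, steps)

    return make
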