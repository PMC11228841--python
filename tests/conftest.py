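import numpy as np
import pytest

from xrfrag import (
    DamageModel,
    Feature,
    FeatureSet,
    Genome,
    make_random_genome,
    simulate_fragments,
)


@pytest.fixture
def tiny_circular():
    return Genome("chrM", "TTAT", topology="circular", compartment="mito")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def mito_genome():
    """A small AT-rich circular mitochondrial genome."""
    return make_random_genome(
        8000, 0.7, "circular", seed=11, genome_id="mito", compartment="mito"
    )


@pytest.fixture(scope="session")
def mito_features(mito_genome):
    """An annotation partition over the session mito genome."""
    return FeatureSet(
        [
            Feature("mito", 500, 2000, "+", "CDS"),
            Feature("mito", 2100, 2600, "-", "tRNA"),
            Feature("mito", 3000, 4500, "-", "rRNA"),
            Feature("mito", 5000, 5400, "+", "intron"),
            Feature("mito", 5400, 6800, "+", "CDS"),
        ]
    )


@pytest.fixture(scope="session")
def trimmed_library(mito_genome):
    """A five_prime_trim library over {26,24,22,20}, equal weights."""
    model = DamageModel(
        mechanism="five_prime_trim",
        primary_length=26,
        trim_step=2,
        trim_max_steps=3,
        dimer_offset_3p=19,
    )
    reads, truth = simulate_fragments(mito_genome, model, 4000, seed=5)
    return model, reads, truth


def random_dna(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))
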