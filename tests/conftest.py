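import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from mitocomp.synthetic import EvolutionSpec, GenomeSpec, evolve, simulate_genome


@pytest.fixture(scope="session")
def default_genome():
    """One default synthetic mitogenome with its truth table."""
    return simulate_genome(GenomeSpec(seed=1))


@pytest.fixture(scope="session")
def clade(default_genome):
    """Three descendants of the default genome under default evolution."""
    genome, _ = default_genome
    return evolve(genome, EvolutionSpec(seed=2))


@pytest.fixture(scope="session")
def shallow_clade(default_genome):
    """A low-divergence clade where multiple hits are rare: the regime in
    which observed site differences track realized substitution events."""
    genome, _ = default_genome
    espec = EvolutionSpec(
        branch_lengths={"AB": 0.004, "A": 0.01, "B": 0.01, "C": 0.012},
        seed=3,
    )
    return evolve(genome, espec)
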