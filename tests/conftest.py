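import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from mitoreorg.simulate import SimSpec, generate_genome


@pytest.fixture(scope="session")
def ago_genome():
    """One synthetic genome with the vertebrate ancestral gene order."""
    genome, ledger = generate_genome(SimSpec(seed=7), 0)
    return genome, ledger


@pytest.fixture(scope="session")
def ltpf_genome():
    """One synthetic genome with the neobatrachian LTPF arrangement and a
    pseudogenized trnS(AGY) (62 bp relic), Glandirana-style."""
    spec = SimSpec(seed=8, order="neobatrachian_LTPF",
                   pseudogenize=("trnS(AGY)",))
    genome, ledger = generate_genome(spec, 0)
    return genome, ledger
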