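import pytest
from hypothesis import HealthCheck, settings

from alnkit.pairwise import GapModel, ScoringScheme
from alnkit.seqio import DNA, load_preset_matrix

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def linear_scheme() -> ScoringScheme:
    """match +1 / mismatch −1 / linear gap −2 over DNA."""
    return ScoringScheme(load_preset_matrix("simple-dna"), GapModel("linear", -2), DNA)


@pytest.fixture(scope="session")
def affine_scheme() -> ScoringScheme:
    """match +1 / mismatch −1 / affine open −3 extend −1 over DNA."""
    return ScoringScheme(
        load_preset_matrix("simple-dna"), GapModel("affine", -3, -1), DNA
    )
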