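import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import syntasi as st

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

_BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


@pytest.fixture
def trigger() -> st.MiRNATrigger:
    return st.validate_trigger("AtmiR173a_TS", st.ATMIR173A_TS)


@pytest.fixture
def make_guides():
    """Factory for n distinct random 21-mers (seeded)."""

    def _make(n: int, seed: int = 0) -> list[str]:
        rng = np.random.default_rng(seed)
        guides: set[str] = set()
        while len(guides) < n:
            guides.add(random_seq(rng, 21))
        return sorted(guides)

    return _make


@pytest.fixture
def design1(trigger, make_guides) -> st.PrecursorDesign:
    return st.assemble_minimal(trigger, st.ATTAS1C_SPACER, make_guides(1),
                               name="min_1g")


@pytest.fixture
def design4(trigger, make_guides) -> st.PrecursorDesign:
    return st.assemble_minimal(trigger, st.ATTAS1C_SPACER, make_guides(4),
                               name="min_4g")
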