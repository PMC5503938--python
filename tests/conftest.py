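import random

import pytest
from hypothesis import HealthCheck, settings

from snofrag.sequence_io import SnoRNARecord, SmallRNARead

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240901)


@pytest.fixture
def small_catalog(rng) -> list[SnoRNARecord]:
    """Three random references (80-150 nt) with distinct sequences."""
    return [
        SnoRNARecord(id=f"sno{i}", sequence=random_dna(rng, 80 + 35 * i))
        for i in range(3)
    ]


def make_read(seq: str, read_id: str = "r1") -> SmallRNARead:
    return SmallRNARead(id=read_id, sequence=seq)
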