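import random

import pytest
from hypothesis import settings

from virome_triage.io_formats import NucleotideSequence

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return random.Random(20240917)


@pytest.fixture
def random_sequences(rng):
    """Seeded random DNA sequences of assorted lengths."""

    def make(n, min_len=60, max_len=2000):
        return [
            NucleotideSequence(
                id=f"seq{i}",
                residues="".join(
                    rng.choice("ACGT") for _ in range(rng.randint(min_len, max_len))
                ),
            )
            for i in range(n)
        ]

    return make
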