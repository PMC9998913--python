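"""Shared fixtures: small deterministic genomes and read sets.

Everything is generated programmatically; no stored data files.
"""

from __future__ import annotations

import random

import pytest

from sagcycle.formats import Read
from sagcycle.simulate import (
    make_bias_profile,
    sample_long_reads,
    simulate_genome,
)


@pytest.fixture(scope="session")
def genome20k():
    return simulate_genome(20000, 0.5, seed=3, circular=True)


@pytest.fixture(scope="session")
def genome50k():
    return simulate_genome(50000, 0.37, seed=101, circular=True)


@pytest.fixture(scope="session")
def uniform_profile20k(genome20k):
    return make_bias_profile(genome20k, target_breadth=1.0, skew=0.0, seed=1)


@pytest.fixture(scope="session")
def clean_reads20k(genome20k, uniform_profile20k):
    """Error-free 20x reads over the 20 kb circular genome."""
    return sample_long_reads(
        genome20k, uniform_profile20k, mean_depth=20,
        read_len_mean=3000, read_len_sd=500,
        error_rate=0.0, chimera_rate=0.0, seed=7,
    )


def random_seq(n: int, seed: int) -> str:
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture
def make_read():
    def _make(rid: str, seq: str, q: int = 30) -> Read:
        return Read(id=rid, seq=seq, quals=(q,) * len(seq))

    return _make
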