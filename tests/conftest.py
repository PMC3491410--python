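"""Shared fixtures: small seeded genomes and reference sets."""

import pytest

from methmap import build_reference_set, simulate_genome
from methmap.reference_prep import ConvertedReference, FULL, PLUS


@pytest.fixture(scope="session")
def small_genome():
    return simulate_genome(20000, gc=0.4, seed=7)


@pytest.fixture(scope="session")
def base_refset(small_genome):
    return build_reference_set(small_genome, "base")


@pytest.fixture(scope="session")
def color_refset(small_genome):
    return build_reference_set(small_genome, "color")


def make_text_ref(text: str, space: str = "base", seed_q: int = 4) -> ConvertedReference:
    """A bare reference over an explicit text, for search-engine tests."""
    return ConvertedReference(FULL, PLUS, space, {"c": text}, seed_q)


@pytest.fixture
def text_ref():
    return make_text_ref
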