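import random

import pytest

from mixtar.debruijn import build_graph
from mixtar.io import Read, ReadSet

BASES = "ACGT"


def tiling_graph(sequences, k, delta=1.0):
    """Graph of delta=1 'tiling reads' (each sequence given once, forward
    strand only) — the controlled single-strand construction used by the
    worked examples."""
    rs = ReadSet(
        [Read(f"t{i}", s) for i, s in enumerate(sequences)],
        coverage_depth=delta,
    )
    return build_graph(rs, k, require_augmented=False)


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(BASES) for _ in range(n))


@pytest.fixture
def rng():
    return random.Random(20250927)


@pytest.fixture
def attgcg_repeat():
    """The 18-bp exact tandem repeat with pattern ATTGCG and 3 copies."""
    return "ATTGCG" * 3
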