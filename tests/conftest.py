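from __future__ import annotations

import numpy as np
import pytest

from seqcurate import AlignScoring, ReferenceLocus
from seqcurate._scoring import PairwiseEngine

BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in np.flatnonzero(rng.random(len(seq)) < rate):
        out[i] = BASES[(BASES.index(out[i]) + rng.integers(1, 4)) % 4]
    return "".join(out)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240117)


@pytest.fixture(scope="session")
def reference() -> ReferenceLocus:
    r = np.random.default_rng(99)
    return ReferenceLocus(accession="TESTREF", seq=random_dna(r, 1140))


@pytest.fixture(scope="session")
def engine() -> PairwiseEngine:
    return PairwiseEngine(AlignScoring())
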