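import math

import numpy as np
import pytest

from entroread.corpus_io import FrequencyTable


@pytest.fixture
def dyadic_table():
    """probs (0.5, 0.25, 0.25): closed-form Shannon entropy 1.5 bits."""
    return FrequencyTable({"a": 2, "b": 1, "c": 1})


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def random_table(rng: np.random.Generator, max_vocab: int = 1000) -> FrequencyTable:
    """A random frequency table with vocab <= max_vocab, heavy-tailed counts."""
    v = int(rng.integers(1, max_vocab + 1))
    counts = rng.geometric(p=rng.uniform(0.01, 0.9), size=v)
    return FrequencyTable({f"w{i}": int(c) for i, c in enumerate(counts)})


def oracle_spectrum(table: FrequencyTable, alphas) -> list[float]:
    """Naive high-precision summation oracle for the entropy family.

    Plain per-term evaluation with math.fsum; independent of the package's
    vectorized implementation.
    """
    n = sum(table.counts.values())
    probs = [c / n for c in table.counts.values()]
    out = []
    for a in alphas:
        if a == 0:
            out.append(math.log2(len(probs)))
        elif a == 1:
            out.append(-math.fsum(p * math.log2(p) for p in probs))
        elif math.isinf(a):
            out.append(-math.log2(max(probs)))
        else:
            out.append(math.log2(math.fsum(p**a for p in probs)) / (1.0 - a))
    return out
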