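import numpy as np
import pytest

from willham.pedigree import UNKNOWN, Pedigree, validate_pedigree


def random_pedigree(rng: np.random.Generator, n_max: int = 50) -> Pedigree:
    """A random acyclic pedigree: parents drawn among earlier animals or unknown."""
    n = int(rng.integers(1, n_max + 1))
    rows = []
    for i in range(n):
        aid = f"A{i}"
        if i == 0 or rng.random() < 0.25:
            rows.append((aid, UNKNOWN, UNKNOWN))
            continue
        s = f"A{rng.integers(0, i)}" if rng.random() < 0.85 else UNKNOWN
        d = f"A{rng.integers(0, i)}" if rng.random() < 0.85 else UNKNOWN
        rows.append((aid, s, d))
    return validate_pedigree(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
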