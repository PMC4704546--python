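import numpy as np
import pytest

import barcodeval as bv


@pytest.fixture
def toy_alignment() -> bv.MarkerAlignment:
    """Two species x two specimens, one clean diagnostic difference."""
    return bv.MarkerAlignment(
        marker="toy",
        ids=["x1", "x2", "y1", "y2"],
        species=["Aus alba", "Aus alba", "Aus bella", "Aus bella"],
        seqs=["AAAACCCC", "AAAACCCC", "AAAATTTT", "AAAATTTT"],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)


def random_alignment(rng, n_rows=None, n_cols=None, missing_frac=0.15):
    """Random small alignment over {A,C,G,T,N,-,?} with species labels."""
    n_rows = n_rows or int(rng.integers(2, 9))
    n_cols = n_cols or int(rng.integers(1, 21))
    bases = np.array(list("ACGT"))
    miss = np.array(list("N-?"))
    rows = []
    for _ in range(n_rows):
        chars = bases[rng.integers(0, 4, n_cols)]
        mask = rng.random(n_cols) < missing_frac
        chars[mask] = miss[rng.integers(0, 3, int(mask.sum()))]
        rows.append("".join(chars))
    ids = [f"sp{i}" for i in range(n_rows)]
    species = [f"Species {i // 2}" for i in range(n_rows)]
    return bv.MarkerAlignment(marker="rand", ids=ids, species=species, seqs=rows)
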