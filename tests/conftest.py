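import numpy as np
import pytest

from alidrift.msa_io import Alignment


@pytest.fixture
def random_pair_alignment():
    """Factory: 2-taxon alignment of iid uniform nucleotides."""

    def make(n_sites=200, seed=0, taxa=("X", "Y"), n_taxa=2):
        rng = np.random.default_rng(seed)
        grid = rng.choice(list("ACGT"), size=(n_taxa, n_sites))
        labels = list(taxa) if n_taxa == len(taxa) else [f"T{i}" for i in range(n_taxa)]
        return Alignment(labels, grid)

    return make


@pytest.fixture
def small_alignment():
    return Alignment(
        ["A", "B", "C", "D"],
        np.array([list("ACGTACGTAC"),
                  list("ACGTACGTAC"),
                  list("TGCATGCATG"),
                  list("ACGAACGAAC")]),
    )
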