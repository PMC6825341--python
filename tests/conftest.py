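import numpy as np
import pytest

from contactfold.contact_consensus import build_consensus
from contactfold.msa_stats import AlignedSequenceSet
from contactfold.toygen import (CorruptionSpec, ToySpec, corrupt_contacts,
                                make_fragment_library, make_toy_structure,
                                true_contacts)

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_msa(rng, n_rows, width, gap_prob=0.15):
    """Random gapped alignment; the query (first row) is kept gap-light so
    the match-column count stays positive."""
    rows = []
    for k in range(n_rows):
        chars = []
        for _ in range(width):
            if k > 0 and rng.random() < gap_prob:
                chars.append("-")
            else:
                chars.append(AA[rng.integers(len(AA))])
        rows.append((f"seq{k}", "".join(chars)))
    return AlignedSequenceSet(rows[0][0], tuple(rows))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def hairpin40():
    return make_toy_structure(ToySpec("beta_hairpin", 40, seed=11))


@pytest.fixture(scope="session")
def bundle60():
    return make_toy_structure(ToySpec("helix_bundle", 60, seed=7))


@pytest.fixture(scope="session")
def hairpin40_contacts(hairpin40):
    return true_contacts(hairpin40)


@pytest.fixture(scope="session")
def hairpin40_consensus(hairpin40, hairpin40_contacts):
    preds = [
        corrupt_contacts(hairpin40_contacts,
                         CorruptionSpec(0.8, "very_high", 0.02, s), 40)
        for s in (1, 2, 3)
    ]
    return build_consensus(preds, 40, nf=100.0)


@pytest.fixture(scope="session")
def hairpin40_frags(hairpin40):
    return make_fragment_library(hairpin40, lengths=tuple(range(3, 10)),
                                 per_position=6, jitter=0.05, seed=5)
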