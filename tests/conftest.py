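import numpy as np
import pytest

from ticlust.seqsim import AnnotatedSequence
from ticlust.simdata import SimParams, make_benchmark
from ticlust.taxonomy import TaxonomicPath

BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, length))


def with_substitutions(seq: str, n_subs: int, offset: int = 0, stride: int = 4) -> str:
    """Substitute ``n_subs`` distinct positions at ``offset, offset+stride,
    ...``; each base is rotated by a varying amount so the change is
    guaranteed.  Spacing the substitutions keeps the optimal global
    alignment gapless, so pairwise identities are exactly the substitution
    counts; calls with disjoint position ranges are additive."""
    out = list(seq)
    for j in range(n_subs):
        i = offset + stride * j
        out[i] = BASES[(BASES.index(out[i]) + 1 + (j % 3)) % 4]
    return "".join(out)


def make_seq(sid, seq, size=1, **ranks) -> AnnotatedSequence:
    return AnnotatedSequence(
        id=sid, seq=seq, taxonomy=TaxonomicPath.from_names(**ranks), size=size
    )


FULL_LINEAGE = dict(
    domain="Bacteria",
    phylum="Phylum_1",
    **{"class": "Class_1"},
    order="Order_1",
    family="Family_001",
)


@pytest.fixture()
def rng():
    # function-scoped so every test sees the same stream regardless of
    # which other tests ran before it
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def mini_params():
    return SimParams(
        n_families=3,
        genera_per_family=3,
        species_per_genus=3,
        zotus_per_species=2,
        n_samples=3,
        seed=7,
    )


@pytest.fixture(scope="session")
def mini_benchmark(mini_params):
    """54-sequence community with full observed taxonomy (no pruning)."""
    return make_benchmark(mini_params)
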