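"""Shared fixtures: the synthetic study conditions used across the suite.

Parent genomes are 1 Mb i.i.d. sequences differing in GC content (0.30 /
0.50 / 0.65); pools carry 5 fragments of 5 kb per parent. These are the
standard conditions of the binning experiments; individual tests that need
lighter inputs build their own smaller records.
"""

import pytest

from spectrabin import FragmentSpec, GenomeSpec, make_pool, synth_genome

GENOME_LENGTH = 1_000_000
FRAG_LENGTH = 5_000
FRAGS_PER_PARENT = 5
TWO_PARENT_GC = (0.30, 0.65)
THREE_PARENT_GC = (0.30, 0.50, 0.65)
STUDY_SEED = 1


def build_pool(gcs, seed, genome_length=GENOME_LENGTH,
               frag_length=FRAG_LENGTH, n=FRAGS_PER_PARENT):
    specs = [
        GenomeSpec(length=genome_length, gc_content=gc, seed=seed + i,
                   id=f"parent{i + 1}_gc{gc:.2f}")
        for i, gc in enumerate(gcs)
    ]
    return make_pool(specs, FragmentSpec(n=n, length=frag_length, seed=seed))


@pytest.fixture(scope="session")
def two_parent_pool():
    """AT-rich vs GC-rich parents (GC 0.30 / 0.65) with a 10-fragment pool."""
    return build_pool(TWO_PARENT_GC, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def three_parent_pool():
    """Three parents (GC 0.30 / 0.50 / 0.65) with a 15-fragment pool."""
    return build_pool(THREE_PARENT_GC, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def small_parents():
    """200 kb AT-rich / GC-rich parents for cheaper set-selection tests."""
    return [
        synth_genome(GenomeSpec(length=200_000, gc_content=gc, seed=50 + i,
                                id=f"small{i + 1}_gc{gc:.2f}"))
        for i, gc in enumerate(TWO_PARENT_GC)
    ]
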