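"""Shared fixtures: a small part library, joint tag sets, and a pooled
96-colony read simulation reused by the demultiplexing and genotyping
tests (session-scoped; simulating and calling reads is the slow part)."""

import numpy as np
import pytest

from partchar import (ReadSimConfig, build_references, design_tags,
                      enumerate_pairs, random_part_library,
                      simulate_tagged_reads)
from partchar.pipeline import DEFAULT_FLANK3, DEFAULT_FLANK5

FLANKS = [DEFAULT_FLANK5, DEFAULT_FLANK3]


@pytest.fixture(scope="session")
def part_library():
    return random_part_library(n_promoters=4, n_rbs=5, seed=3)


@pytest.fixture(scope="session")
def refs(part_library):
    return build_references(part_library, DEFAULT_FLANK5, DEFAULT_FLANK3)


@pytest.fixture(scope="session")
def fwd_tags():
    return design_tags(8, seed=0, avoid_context=FLANKS)


@pytest.fixture(scope="session")
def rev_tags(fwd_tags):
    return design_tags(12, seed=1, orientation="reverse",
                       existing=[t.sequence for t in fwd_tags],
                       avoid_context=FLANKS)


@pytest.fixture(scope="session")
def pairs96(fwd_tags, rev_tags):
    return enumerate_pairs(fwd_tags, rev_tags)


@pytest.fixture(scope="session")
def colony_specs(part_library, pairs96):
    """96 colonies with known genotypes, one per tag pair."""
    combos = part_library.combinations()
    rng = np.random.default_rng(0)
    return [(i, combos[rng.integers(len(combos))], pairs96[i]) for i in range(96)]


@pytest.fixture(scope="session")
def noisy_pool(colony_specs, refs):
    """30 reads/colony at 5% substitution + 3% indel — the pipeline's
    nominal nanopore operating point."""
    config = ReadSimConfig(substitution_rate=0.05, insertion_rate=0.015,
                           deletion_rate=0.015, reads_per_colony=30, seed=7)
    return simulate_tagged_reads(colony_specs, refs, config)


@pytest.fixture(scope="session")
def clean_pool(colony_specs, refs):
    """Error-free reads for identity checks."""
    config = ReadSimConfig(substitution_rate=0.0, insertion_rate=0.0,
                           deletion_rate=0.0, reads_per_colony=5, seed=11)
    return simulate_tagged_reads(colony_specs, refs, config)
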