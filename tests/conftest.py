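"""Shared fixtures: a small synthetic plastome with ground truth, and a
four-taxon genome family evolved from it."""

from __future__ import annotations

import pytest

from plastokit.synth import PlastomeSpec, make_plastome, evolve_genomes

FAMILY_TREE = "((caroliniana_1:0.0001,caroliniana_2:0.0001):0.004,outgroup_1:0.01,outgroup_2:0.006);"


@pytest.fixture(scope="session")
def small_plastome():
    """(AnnotatedGenome, QuadripartitePartition) at the fast test scale."""
    return make_plastome(PlastomeSpec.small(seed=11))


@pytest.fixture(scope="session")
def genome_family(small_plastome):
    """Four descendant genomes plus the realized pairwise-difference table."""
    genome, partition = small_plastome
    genomes, diffs = evolve_genomes(
        genome, FAMILY_TREE, seed=12, partition=partition
    )
    return genomes, diffs, partition
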