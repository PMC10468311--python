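"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import pytest

from trapmap import synth
from trapmap.seqio import TEConsensus
from trapmap.split_align import find_split_alignments
from trapmap.te_mapper import call_insertions, cluster_junctions


@pytest.fixture(scope="session")
def small_genome():
    """A 5 kb single-contig random genome (deterministic)."""
    return synth.make_genome(7, {"chr1": 5000})


@pytest.fixture(scope="session")
def small_te():
    """A 300 bp TE consensus for constructed-read tests."""
    return synth.make_te_consensus(11, "tx", 300)


@pytest.fixture(scope="session")
def study():
    """The standard planted-insertion study: 100 kb contig, five insertions
    with TSD lengths {8, 8, 8, 5, 0} in mixed orientations."""
    return synth.insertion_study(1)


@pytest.fixture(scope="session")
def study_reads(study):
    """Error-free 2x100 nt reads at 20x coverage over the sample genome."""
    return synth.simulate_reads(study.genome_post, read_len=100, coverage=20.0,
                                error_rate=0.0, seed=2)


@pytest.fixture(scope="session")
def study_calls(study, study_reads):
    """Split -> cluster -> call pipeline output for the standard study."""
    splits = find_split_alignments(study_reads, study.genome_pre,
                                   study.te_library)
    clusters = cluster_junctions(splits, cluster_tol=3)
    return call_insertions(clusters, study.genome_pre)


def pelement_truths(study):
    return [t for t in study.truths if t.te_name == "SXP"]
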