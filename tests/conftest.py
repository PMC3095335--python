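"""Shared fixtures: tiny alignments, trees, and cluster assignments."""

import numpy as np
import pytest

from seldiv.phylo import read_newick
from seldiv.seqio import (
    CodonAlignment,
    GroupAssignment,
    ProteinAlignment,
    SequenceRecord,
)


@pytest.fixture
def toy_protein_alignment() -> ProteinAlignment:
    return ProteinAlignment(
        [
            SequenceRecord("a", "MKV-A"),
            SequenceRecord("b", "MQVLA"),
            SequenceRecord("c", "MQVLA"),
            SequenceRecord("d", "MKVLA"),
        ]
    )


@pytest.fixture
def toy_codon_pair() -> CodonAlignment:
    # 4 fourfold-box codons; third positions differ by one transition (T->C)
    # and one transversion (A->T)
    return CodonAlignment(
        [
            SequenceRecord("p1", "GCTGGACCAGTA"),
            SequenceRecord("p2", "GCCGGACCTGTA"),
        ]
    )


@pytest.fixture
def quartet_tree():
    return read_newick("((a1:1,a2:1):1,(b1:1,b2:1):1);")


@pytest.fixture
def two_cluster_groups() -> GroupAssignment:
    return GroupAssignment(
        {"a1": "monocot", "a2": "monocot", "b1": "dicot", "b2": "dicot"}
    )


@pytest.fixture
def equal_codon_freqs() -> np.ndarray:
    return np.full(61, 1.0 / 61)
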