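"""Shared fixtures and generators for the test suite."""

from __future__ import annotations

import random

import numpy as np
import pytest

from matrisome.genetic_code import SENSE_CODONS
from matrisome.io import SequenceRecord, read_newick


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def random_codon_seq(rng, n_codons: int) -> str:
    return "".join(SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=n_codons))


def random_records(rng, n: int, alphabet: str = "nucleotide"):
    """Random sequence records with ids, descriptions, and varied lengths."""
    out = []
    for i in range(n):
        length = int(rng.integers(1, 120))
        if alphabet == "nucleotide":
            residues = "".join("ACGTN-"[j] for j in rng.integers(6, size=length))
        else:
            residues = "".join(
                "ACDEFGHIKLMNPQRSTVWYX-"[j] for j in rng.integers(22, size=length)
            )
        desc = "" if i % 3 == 0 else f"desc {i}"
        out.append(SequenceRecord(f"seq{i:03d}", desc, residues, alphabet))
    return out


def random_tree_newick(rand: random.Random, leaves: list[str], lengths: bool = True) -> str:
    """Random rooted binary tree over the given leaf labels."""
    items = [
        f"{l}:{rand.randint(1, 9)}" if lengths else l for l in leaves
    ]
    while len(items) > 1:
        i = rand.randrange(len(items))
        a = items.pop(i)
        j = rand.randrange(len(items))
        b = items.pop(j)
        blen = f":{rand.randint(1, 9)}" if lengths else ""
        items.append(f"({a},{b}){blen}")
    return items[0] + ";"


def topology_signature(tree):
    """Hashable topology+length signature: leafsets under each node."""
    sig = []
    for node in tree.postorder_node_iter():
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        length = None if node.edge.length is None else round(node.edge.length, 9)
        sig.append((leaves, length, node.label))
    return frozenset(sig)


@pytest.fixture
def species_tree_4():
    return read_newick("((A:1,B:1):1,(C:1,D:1):1);")
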