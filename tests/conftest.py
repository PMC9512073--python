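"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the code paths they check:

* ``brute_force_matches`` decides pattern placement by a forward set-based
  reachability sweep over positions (the implementation backtracks over
  elements);
* ``brute_force_parsimony`` enumerates every ancestral 0/1 assignment and
  counts edge changes (the implementation is a dynamic programme);
* ``tripeptide_motif_ids`` checks PTS1 membership class-by-class on the
  terminal tripeptide (the scanner matches anchored patterns on the full
  sequence).
"""

from __future__ import annotations

import itertools
import random

import numpy as np
import pytest

from ptschrono.chronology import ensure_node_names
from ptschrono.io import load_fixture_tree
from ptschrono.patterns import (
    STANDARD_AMINO_ACIDS,
    MotifElement,
    MotifPattern,
)
from ptschrono.scanner import MotifSet

ALPHABET = "".join(sorted(STANDARD_AMINO_ACIDS))


@pytest.fixture(scope="session")
def motifs() -> MotifSet:
    return MotifSet.default()


@pytest.fixture()
def fixture_tree():
    tree = load_fixture_tree()
    ensure_node_names(tree)
    return tree


# ---------------------------------------------------------------- oracles


def brute_force_matches(pattern: MotifPattern, sequence: str) -> set[tuple[int, int]]:
    """All (start, end) placements, by set-based position reachability."""
    seq = sequence.upper()
    spans: set[tuple[int, int]] = set()
    starts = [0] if pattern.n_anchor else range(len(seq) + 1)
    for start in starts:
        reach = {start}
        for el in pattern.elements:
            nxt: set[int] = set()
            for pos in reach:
                if el.kind == "residue_class":
                    if pos < len(seq) and seq[pos] in el.residues:
                        nxt.add(pos + 1)
                else:
                    for gap in range(el.min_repeat, el.max_repeat + 1):
                        if pos + gap <= len(seq):
                            nxt.add(pos + gap)
            reach = nxt
        for end in reach:
            if end <= start:
                continue
            if pattern.c_anchor and end != len(seq):
                continue
            spans.add((start, end))
    return spans


def random_pattern(rng: random.Random, allow_anchors: bool = True) -> MotifPattern:
    """Random dialect pattern: classes of 1-10 residues, wildcards with
    bounds <= 5, 1-6 elements."""
    elements = []
    for _ in range(rng.randint(1, 6)):
        if rng.random() < 0.35:
            lo = rng.randint(0, 5)
            hi = rng.randint(lo, 5)
            elements.append(MotifElement("wildcard", min_repeat=lo, max_repeat=hi))
        else:
            size = rng.randint(1, 10)
            residues = tuple(rng.sample(ALPHABET, size))
            elements.append(MotifElement("residue_class", residues))
    return MotifPattern(
        motif_id="rnd",
        elements=tuple(elements),
        n_anchor=allow_anchors and rng.random() < 0.25,
        c_anchor=allow_anchors and rng.random() < 0.25,
    )


def random_sequence(rng: random.Random, max_len: int = 60) -> str:
    return "".join(rng.choice(ALPHABET) for _ in range(rng.randint(0, max_len)))


def tripeptide_motif_ids(tripeptide: str, motifs: MotifSet) -> set[str]:
    """PTS1 motifs matching a tripeptide, by direct class membership."""
    assert len(tripeptide) == 3
    hits = set()
    for p in motifs.pts1:
        if len(p.elements) != 3:
            continue
        if all(aa in el.residues for el, aa in zip(p.elements, tripeptide)):
            hits.add(p.motif_id)
    return hits


def enumerate_matching_tripeptides(pattern: MotifPattern) -> set[str]:
    """All tripeptides matched, by exhausting the 20**3 possibilities with
    direct membership checks."""
    out = set()
    for tri in itertools.product(ALPHABET, repeat=3):
        if len(pattern.elements) == 3 and all(
            el.kind == "wildcard" or aa in el.residues
            for el, aa in zip(pattern.elements, tri)
        ):
            out.add("".join(tri))
    return out


def brute_force_parsimony(tree, leaf_states: dict[str, int]) -> int:
    """Minimum change count by enumerating all internal 0/1 assignments."""
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    best = None
    for bits in itertools.product((0, 1), repeat=len(internal)):
        assign = dict(zip(internal, bits))
        for leaf in tree.leaf_node_iter():
            assign[leaf] = leaf_states[leaf.taxon.label]
        changes = sum(
            1
            for node in tree.preorder_node_iter()
            if node.parent_node is not None
            and assign[node] != assign[node.parent_node]
        )
        best = changes if best is None else min(best, changes)
    return best


def random_newick(rng: random.Random, n_leaves: int) -> str:
    """Random rooted topology by repeated joining; may include polytomies."""
    nodes = [f"L{i}" for i in range(n_leaves)]
    while len(nodes) > 1:
        k = min(len(nodes), rng.choice([2, 2, 2, 3]))
        picked = [nodes.pop(rng.randrange(len(nodes))) for _ in range(k)]
        nodes.append("(" + ",".join(picked) + ")")
    return nodes[0] + ";"


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
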