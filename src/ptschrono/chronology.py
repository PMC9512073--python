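"""When did each glycosomal character arise?  Parsimony on the species tree.

A binary character (a PTS-bearing orthogroup, from ``binarize``) is mapped
onto the rooted species tree two ways:

* :func:`fitch_parsimony` — the minimum number of 0↔1 changes under
  unordered small parsimony (unit-cost dynamic programming, exact on
  multifurcating trees), with one most-parsimonious ancestral assignment.
* :func:`dollo_gain` — the Dollo scenario: a single gain at the MRCA of all
  character-bearing leaves, plus the minimal set of loss edges explaining
  every absence inside the gained clade.

Gains are then placed into one of four evolutionary epochs relative to the
Discoba root, the Kinetoplastea+Diplonemea ancestor (where peroxisomes
became glycosomes) and the Kinetoplastea ancestor:

``ancestral_peroxisomal``
    the character predates the glycosome — its gain maps above the
    Kinetoplastea+Diplonemea ancestor (equivalently, it also occurs in
    *Naegleria* or euglenids);
``glycosome_origin``
    gained at the Kinetoplastea+Diplonemea ancestor, i.e. during or shortly
    after the origin of glycosomes from peroxisomes;
``kinetoplastid_early``
    gained at the Kinetoplastea ancestor;
``late_taxon_specific``
    gained later, in a subset of taxa.

The root state is assumed 0 for glycosomal characters (polarisation by the
peroxisome-bearing *Naegleria* outgroup); leaves scored ``?`` (incomplete
genome/transcriptome data) constrain neither the MRCA nor the loss edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy
import pandas as pd

from .io import DIPLONEMEA, KINETOPLASTEA

__all__ = [
    "EPOCHS",
    "MISSING",
    "CharacterHistory",
    "ensure_node_names",
    "reference_nodes",
    "fitch_parsimony",
    "dollo_gain",
    "assign_epoch",
    "chronology_table",
]

MISSING = "?"

ANCESTRAL = "ancestral_peroxisomal"
ORIGIN = "glycosome_origin"
KINETOPLASTID_EARLY = "kinetoplastid_early"
LATE = "late_taxon_specific"
ABSENT = "absent"

EPOCHS = (ANCESTRAL, ORIGIN, KINETOPLASTID_EARLY, LATE)

_INF = float("inf")


def ensure_node_names(tree: dendropy.Tree) -> dendropy.Tree:
    """Give every node a stable name: leaves keep their taxon label,
    unnamed internal nodes get ``n<preorder index>``."""
    for i, node in enumerate(tree.preorder_node_iter()):
        if node.is_leaf():
            node.label = node.taxon.label
        elif not node.label:
            node.label = f"n{i}"
    return tree


def _leaf_labels(node: dendropy.Node) -> set[str]:
    return {leaf.taxon.label for leaf in node.leaf_iter()}


def _mrca(tree: dendropy.Tree, labels: set[str]) -> dendropy.Node:
    if not labels:
        raise ValueError("cannot take MRCA of an empty leaf set")
    node = tree.mrca(taxon_labels=list(labels))
    if node is None:
        raise ValueError(f"labels not all present in tree: {sorted(labels)[:5]}")
    return node


def reference_nodes(tree: dendropy.Tree) -> dict[str, dendropy.Node]:
    """The three reference nodes of the epoch classification, located by the
    taxa present in the tree (works on the fixture tree and on subtrees)."""
    present = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    kine = set(KINETOPLASTEA) & present
    diplo = set(DIPLONEMEA) & present
    if not kine or not diplo:
        raise ValueError(
            "tree must contain kinetoplastid and diplonemid taxa to define "
            "the epoch reference nodes"
        )
    return {
        "discoba_root": tree.seed_node,
        "kinetoplastea_diplonemea": _mrca(tree, kine | diplo),
        "kinetoplastea": _mrca(tree, kine),
    }


def _validated_states(
    tree: dendropy.Tree, leaf_states: Mapping[str, object], allow_missing: bool = True
) -> dict[str, int | str]:
    out: dict[str, int | str] = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        if label not in leaf_states:
            raise ValueError(f"missing state for leaf {label!r}")
        s = leaf_states[label]
        if s == MISSING:
            if not allow_missing:
                raise ValueError(f"missing data ({label!r}) not allowed here")
            out[label] = MISSING
        elif s in (0, 1, "0", "1"):
            out[label] = int(s)
        else:
            raise ValueError(f"leaf state for {label!r} must be 0, 1 or '?': {s!r}")
    return out


def fitch_parsimony(
    tree: dendropy.Tree, leaf_states: Mapping[str, object]
) -> tuple[int, dict[str, int]]:
    """Minimum-change count and one most-parsimonious ancestral assignment.

    Unit-cost dynamic programming over states {0,1}; exact on polytomies.
    Ties are broken toward state 0 (the character delayed rather than
    anticipated).  Leaves scored ``?`` contribute no cost in either state.

    Returns ``(score, states)`` where ``states`` maps every node name
    (see :func:`ensure_node_names`) to its assigned state.
    """
    ensure_node_names(tree)
    states = _validated_states(tree, leaf_states)
    cost: dict[dendropy.Node, tuple[float, float]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = states[node.taxon.label]
            if s == MISSING:
                cost[node] = (0.0, 0.0)
            else:
                cost[node] = (0.0 if s == 0 else _INF, 0.0 if s == 1 else _INF)
        else:
            c0 = c1 = 0.0
            for child in node.child_nodes():
                k0, k1 = cost[child]
                c0 += min(k0, k1 + 1)
                c1 += min(k0 + 1, k1)
            cost[node] = (c0, c1)
    root = tree.seed_node
    score = int(min(cost[root]))
    assignment: dict[str, int] = {}
    chosen: dict[dendropy.Node, int] = {}
    for node in tree.preorder_node_iter():
        c0, c1 = cost[node]
        if node is root:
            s = 0 if c0 <= c1 else 1
        else:
            p = chosen[node.parent_node]
            t0 = c0 + (1 if p != 0 else 0)
            t1 = c1 + (1 if p != 1 else 0)
            s = 0 if t0 <= t1 else 1
        chosen[node] = s
        assignment[node.label] = s
    return score, assignment


@dataclass
class CharacterHistory:
    """One character's inferred gain/loss scenario on the species tree."""

    orthogroup_id: str
    gain_node: str | None            # node name, or None for an all-zero character
    loss_edges: tuple[str, ...]      # each edge named by its child node
    fitch_score: int
    ancestral_states: dict[str, int] = field(default_factory=dict, repr=False)
    lgt_suspect: bool = False

    @property
    def n_losses(self) -> int:
        return len(self.loss_edges)

    @property
    def dollo_events(self) -> int:
        return (1 if self.gain_node is not None else 0) + self.n_losses


def dollo_gain(
    tree: dendropy.Tree,
    leaf_states: Mapping[str, object],
    orthogroup_id: str = "",
    lgt_loss_threshold: int | None = None,
) -> CharacterHistory:
    """Single-gain/multiple-loss scenario for a binary character.

    The gain is placed at the MRCA of all leaves scoring 1; the losses are
    the minimal edge set explaining every 0-leaf inside the gained clade —
    one loss per maximal subtree containing no 1-leaf (subtrees holding only
    ``?`` leaves need no loss).  ``ancestral_states`` reports the implied
    node states: 1 on the gained clade minus the lost subtrees.

    When ``lgt_loss_threshold`` is given, a character whose loss count
    exceeds it is flagged ``lgt_suspect``: repeated implied losses may
    actually reflect lateral acquisition rather than vertical descent.
    """
    ensure_node_names(tree)
    states = _validated_states(tree, leaf_states)
    fitch_score, _ = fitch_parsimony(tree, leaf_states)
    ones = {label for label, s in states.items() if s == 1}
    if not ones:
        return CharacterHistory(
            orthogroup_id=orthogroup_id,
            gain_node=None,
            loss_edges=(),
            fitch_score=fitch_score,
            ancestral_states={n.label: 0 for n in tree.preorder_node_iter()},
        )
    gain = _mrca(tree, ones)
    # has_one[node]: a definite 1-leaf below; all ?/0 subtrees need one loss
    has_one: dict[dendropy.Node, bool] = {}
    has_zero: dict[dendropy.Node, bool] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = states[node.taxon.label]
            has_one[node] = s == 1
            has_zero[node] = s == 0
        else:
            has_one[node] = any(has_one[c] for c in node.child_nodes())
            has_zero[node] = any(has_zero[c] for c in node.child_nodes())
    loss_edges: list[str] = []
    lost_roots: list[dendropy.Node] = []

    def walk(node: dendropy.Node) -> None:
        for child in node.child_nodes():
            if not has_one[child]:
                if has_zero[child]:  # all-? subtrees are unconstrained
                    loss_edges.append(child.label)
                    lost_roots.append(child)
            else:
                walk(child)

    walk(gain)
    lost = set()
    for r in lost_roots:
        lost.add(r)
        lost.update(r.preorder_iter())
    in_gain = {gain} | set(gain.preorder_iter())
    ancestral = {
        n.label: (1 if (n in in_gain and n not in lost) else 0)
        for n in tree.preorder_node_iter()
    }
    history = CharacterHistory(
        orthogroup_id=orthogroup_id,
        gain_node=gain.label,
        loss_edges=tuple(sorted(loss_edges)),
        fitch_score=fitch_score,
        ancestral_states=ancestral,
    )
    if lgt_loss_threshold is not None and history.n_losses > lgt_loss_threshold:
        history.lgt_suspect = True
    return history


def assign_epoch(
    history: CharacterHistory,
    tree: dendropy.Tree,
    refs: dict[str, dendropy.Node] | None = None,
) -> str:
    """Epoch label for a character's inferred gain node (see module docs)."""
    if history.gain_node is None:
        return ABSENT
    refs = refs or reference_nodes(tree)
    ensure_node_names(tree)
    by_name = {n.label: n for n in tree.preorder_node_iter()}
    try:
        gain = by_name[history.gain_node]
    except KeyError:
        raise ValueError(f"gain node {history.gain_node!r} not in tree") from None
    kd = refs["kinetoplastea_diplonemea"]
    kine = refs["kinetoplastea"]
    if gain is kd:
        return ORIGIN
    if gain is kine:
        return KINETOPLASTID_EARLY
    # strict ancestors of the glycosome origin: the character was already
    # peroxisomal before glycosomes existed
    ancestor = kd.parent_node
    while ancestor is not None:
        if gain is ancestor:
            return ANCESTRAL
        ancestor = ancestor.parent_node
    return LATE


def chronology_table(
    tree: dendropy.Tree,
    binary_matrix: pd.DataFrame,
    lgt_loss_threshold: int | None = None,
) -> pd.DataFrame:
    """Run Dollo inference and epoch assignment for every orthogroup row of a
    binarized presence matrix; returns a tidy results table."""
    refs = reference_nodes(tree)
    rows = []
    for og, row in binary_matrix.iterrows():
        history = dollo_gain(
            tree, row.to_dict(), orthogroup_id=str(og),
            lgt_loss_threshold=lgt_loss_threshold,
        )
        rows.append(
            {
                "orthogroup_id": og,
                "gain_node": history.gain_node or "",
                "n_losses": history.n_losses,
                "loss_edges": ",".join(history.loss_edges),
                "fitch_score": history.fitch_score,
                "epoch": assign_epoch(history, tree, refs),
                "lgt_suspect": history.lgt_suspect,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "orthogroup_id", "gain_node", "n_losses", "loss_edges",
            "fitch_score", "epoch", "lgt_suspect",
        ],
    )
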