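"""Collapse per-protein PTS calls into an orthogroup × taxon state matrix.

Each cell records what the scanned proteomes say about one orthogroup in one
taxon: no orthologue at all (``absent``), orthologue(s) present but none with
a detected targeting signal (``present_no_PTS``), or present with PTS1, PTS2
or both.  An orthologue without a detectable PTS is deliberately kept
distinct from absence — an extra-organellar localisation cannot be excluded
for such proteins, and only :func:`binarize` collapses the distinction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .io import OrthoMap
from .scanner import PTSCall

__all__ = ["STATES", "PresenceMatrix", "build_matrix", "binarize", "BINARIZE_RULES"]

ABSENT = "absent"
PRESENT_NO_PTS = "present_no_PTS"
PRESENT_PTS1 = "present_PTS1"
PRESENT_PTS2 = "present_PTS2"
PRESENT_BOTH = "present_both"

#: Cell states, ordered by increasing targeting evidence.
STATES = (ABSENT, PRESENT_NO_PTS, PRESENT_PTS1, PRESENT_PTS2, PRESENT_BOTH)

BINARIZE_RULES = ("any_pts", "pts1_only", "pts2_only", "present_at_all")


@dataclass
class PresenceMatrix:
    """Orthogroup × taxon grid of PTS presence states with provenance."""

    states: pd.DataFrame  # index: orthogroup_id, columns: taxon_id, cells: STATES
    provenance: dict[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)

    @property
    def orthogroups(self) -> list[str]:
        return list(self.states.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.states.columns)

    def to_tsv(self, path) -> None:
        self.states.rename_axis("orthogroup_id").to_csv(path, sep="\t")

    def to_long_tsv(self, path) -> None:
        """Long format with the contributing protein ids per cell."""
        rows = [
            {
                "orthogroup_id": og,
                "taxon_id": tax,
                "state": self.states.at[og, tax],
                "protein_ids": ",".join(self.provenance.get((og, tax), ())),
            }
            for og in self.states.index
            for tax in self.states.columns
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _join_state(has_pts1: bool, has_pts2: bool) -> str:
    if has_pts1 and has_pts2:
        return PRESENT_BOTH
    if has_pts1:
        return PRESENT_PTS1
    if has_pts2:
        return PRESENT_PTS2
    return PRESENT_NO_PTS


def build_matrix(
    calls: Iterable[PTSCall],
    orthomap: OrthoMap,
    taxa: Sequence[str],
) -> PresenceMatrix:
    """Aggregate protein-level calls to orthogroup × taxon states.

    The cell state is the join over all mapped proteins of that cell: any
    paralogue with a PTS1 plus any with a PTS2 gives ``present_both``, any
    PTS1 gives ``present_PTS1``, any PTS2 ``present_PTS2``, otherwise
    ``present_no_PTS``; cells with no mapped protein are ``absent``.  A
    protein mapped to several orthogroups contributes to each.  Calls for
    proteins not in the orthomap are ignored with a warning; the result does
    not depend on call order.
    """
    logger = logging.getLogger(__name__)
    if not taxa:
        raise ValueError("taxa list must not be empty")
    membership = orthomap.frame.groupby("protein_id")[["orthogroup_id", "taxon_id"]]
    by_protein = {
        pid: list(zip(g["orthogroup_id"], g["taxon_id"]))
        for pid, g in membership
    }
    orthogroups = orthomap.orthogroups
    agg: dict[tuple[str, str], dict[str, object]] = {}
    for call in sorted(calls, key=lambda c: c.protein_id):
        if call.protein_id not in by_protein:
            logger.warning(
                "protein %s not in orthomap; ignored", call.protein_id
            )
            continue
        for og, tax in by_protein[call.protein_id]:
            cell = agg.setdefault(
                (og, tax), {"pts1": False, "pts2": False, "proteins": []}
            )
            cell["pts1"] = cell["pts1"] or call.has_pts1
            cell["pts2"] = cell["pts2"] or call.has_pts2
            cell["proteins"].append(call.protein_id)
    states = pd.DataFrame(ABSENT, index=orthogroups, columns=list(taxa))
    provenance: dict[tuple[str, str], tuple[str, ...]] = {}
    for (og, tax), cell in agg.items():
        if tax not in states.columns:
            raise ValueError(f"orthomap taxon {tax!r} not in taxa list")
        states.at[og, tax] = _join_state(cell["pts1"], cell["pts2"])
        provenance[(og, tax)] = tuple(sorted(cell["proteins"]))
    return PresenceMatrix(states=states, provenance=provenance)


_RULE_POSITIVE = {
    "any_pts": {PRESENT_PTS1, PRESENT_PTS2, PRESENT_BOTH},
    "pts1_only": {PRESENT_PTS1, PRESENT_BOTH},
    "pts2_only": {PRESENT_PTS2, PRESENT_BOTH},
    "present_at_all": {PRESENT_NO_PTS, PRESENT_PTS1, PRESENT_PTS2, PRESENT_BOTH},
}


def binarize(matrix: PresenceMatrix, rule: str = "any_pts") -> pd.DataFrame:
    """Collapse the five-state matrix to 0/1 under ``rule``.

    ``any_pts`` is the localisation criterion used for the chronology: an
    orthologue counts as glycosomal evidence only when it carries a PTS.
    ``present_at_all`` instead scores bare presence of the orthologue.
    """
    if rule not in _RULE_POSITIVE:
        raise ValueError(f"unknown binarize rule {rule!r}; use one of {BINARIZE_RULES}")
    positive = _RULE_POSITIVE[rule]
    return matrix.states.isin(positive).astype(int)
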