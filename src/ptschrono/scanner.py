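"""PTS1/PTS2 scanning of protein sequences.

A PTS1 is a C-terminal tripeptide signal; a PTS2 is a nonapeptide signal
near the N-terminus.  The default :class:`MotifSet` holds the nine consensus
patterns used throughout this package: four C-anchored tripeptide patterns
(A-D) for PTS1 and five nonapeptide patterns (E-I) for PTS2, of which F is
N-anchored (it begins at the initiator methionine).

``scan_pts1`` evaluates the PTS1 patterns against the C-terminus only;
``scan_pts2`` searches a configurable N-terminal window (default 40
residues), wide enough to accommodate reported PTS2 instances that overlap
an N-terminal mitochondrial targeting signal.  The initiator methionine is
never stripped (pattern F explicitly requires it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .patterns import MatchSpan, MotifPattern, find_matches, parse_pattern

__all__ = [
    "DEFAULT_PTS1_PATTERNS",
    "DEFAULT_PTS2_PATTERNS",
    "DEFAULT_PTS2_WINDOW",
    "MotifSet",
    "ProteinRecord",
    "PTSCall",
    "scan_pts1",
    "scan_pts2",
    "scan_proteome",
]

logger = logging.getLogger(__name__)

#: Consensus PTS1 tripeptide patterns (C-anchored).
DEFAULT_PTS1_PATTERNS: dict[str, str] = {
    "A": "[ASCGPNYTV]-[KNRHQDS]-[LMVAIF]>",
    "B": "[STAGCN]-[RKH]-[LIVMAFY]>",
    "C": "S-S-[LIF]>",
    "D": "[ACGHNPT]-[HMNQRS]-[IMY]>",
}

#: Consensus PTS2 nonapeptide patterns; F is anchored at the initiator Met.
DEFAULT_PTS2_PATTERNS: dict[str, str] = {
    "E": "[RKHQ]-[VLIWFY]-X(5)-[HKQR]-[ILVYAF]",
    "F": "<M-X(0,20)-[RK]-[LVI]-X(5)-[HQ]-[ILAF]",
    "G": "R-[LVIQ]-X(2)-[LVIH]-[LSGA]-X-[HQ]-[LA]",
    "H": "[RK]-[LVIQ]-X(2)-[LVIHQ]-[LSGAK]-X-[HQ]-[LAF]",
    "I": "R-[LI]-X(2)-[LI]-X(2)-[HQ]-L",
}

#: Default N-terminal window (residues) searched for a PTS2.
DEFAULT_PTS2_WINDOW = 40


@dataclass(frozen=True)
class MotifSet:
    """The motif patterns applied by the scanner, split by signal type."""

    pts1: tuple[MotifPattern, ...]
    pts2: tuple[MotifPattern, ...]

    def __post_init__(self) -> None:
        ids = [p.motif_id for p in self.pts1 + self.pts2]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate motif_ids in MotifSet")

    @classmethod
    def default(cls) -> "MotifSet":
        """The nine consensus patterns A-I."""
        return cls(
            pts1=tuple(
                parse_pattern(t, mid) for mid, t in DEFAULT_PTS1_PATTERNS.items()
            ),
            pts2=tuple(
                parse_pattern(t, mid) for mid, t in DEFAULT_PTS2_PATTERNS.items()
            ),
        )

    @classmethod
    def from_patterns(
        cls, pts1: dict[str, str], pts2: dict[str, str]
    ) -> "MotifSet":
        return cls(
            pts1=tuple(parse_pattern(t, mid) for mid, t in pts1.items()),
            pts2=tuple(parse_pattern(t, mid) for mid, t in pts2.items()),
        )


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence from a taxon's predicted proteome."""

    protein_id: str
    taxon_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for protein {self.protein_id!r}")


@dataclass(frozen=True)
class PTSCall:
    """Per-protein scan result."""

    protein_id: str
    pts1_hits: frozenset[str]
    pts2_hits: tuple[tuple[str, MatchSpan], ...]
    taxon_id: str = ""

    @property
    def has_pts1(self) -> bool:
        return bool(self.pts1_hits)

    @property
    def has_pts2(self) -> bool:
        return bool(self.pts2_hits)


def _c_anchored(pattern: MotifPattern) -> MotifPattern:
    # PTS1 patterns are evaluated C-anchored even if supplied without ">".
    if pattern.c_anchor:
        return pattern
    return MotifPattern(
        motif_id=pattern.motif_id,
        elements=pattern.elements,
        n_anchor=pattern.n_anchor,
        c_anchor=True,
        source_text=pattern.source_text + ">",
    )


def scan_pts1(protein: ProteinRecord, motifs: MotifSet | None = None) -> frozenset[str]:
    """Motif ids of the PTS1 patterns matching the protein's C-terminus.

    A sequence shorter than 3 residues cannot carry a tripeptide signal and
    yields an empty set with a logged warning.
    """
    motifs = motifs or MotifSet.default()
    seq = protein.sequence.upper()
    if len(seq) < 3:
        logger.warning(
            "protein %s shorter than 3 residues; no PTS1 possible",
            protein.protein_id,
        )
        return frozenset()
    hits = {
        p.motif_id
        for p in (_c_anchored(q) for q in motifs.pts1)
        if find_matches(p, seq)
    }
    return frozenset(hits)


def scan_pts2(
    protein: ProteinRecord,
    motifs: MotifSet | None = None,
    window: int = DEFAULT_PTS2_WINDOW,
) -> list[tuple[str, MatchSpan]]:
    """PTS2 hits within the protein's N-terminal window.

    Unanchored patterns are searched in ``sequence[0:window]``; N-anchored
    patterns (F) only from position 0.  A hit is reported when its span
    starts within the window.
    """
    if window < 9:
        raise ValueError("PTS2 window must be at least 9 residues")
    motifs = motifs or MotifSet.default()
    seq = protein.sequence.upper()
    prefix = seq[:window]
    hits: list[tuple[str, MatchSpan]] = []
    for p in motifs.pts2:
        # anchored patterns start at 0 and may extend past the window edge;
        # unanchored ones must fit inside the window
        target = seq if p.n_anchor else prefix
        for span in find_matches(p, target):
            if span.start >= window:
                continue
            hits.append((p.motif_id, span))
    hits.sort(key=lambda h: (h[1].start, h[1].end, h[0]))
    return hits


def scan_proteome(
    proteome: list[ProteinRecord],
    motifs: MotifSet | None = None,
    window: int = DEFAULT_PTS2_WINDOW,
) -> list[PTSCall]:
    """Scan every protein for PTS1 and PTS2; one call per input, in order.

    Raises
    ------
    ValueError
        On duplicate protein ids.
    """
    motifs = motifs or MotifSet.default()
    seen: set[str] = set()
    calls: list[PTSCall] = []
    for rec in proteome:
        if rec.protein_id in seen:
            raise ValueError(f"duplicate protein_id {rec.protein_id!r}")
        seen.add(rec.protein_id)
        calls.append(
            PTSCall(
                protein_id=rec.protein_id,
                taxon_id=rec.taxon_id,
                pts1_hits=scan_pts1(rec, motifs),
                pts2_hits=tuple(scan_pts2(rec, motifs, window)),
            )
        )
    n1 = sum(c.has_pts1 for c in calls)
    n2 = sum(c.has_pts2 for c in calls)
    logger.info(
        "scanned %d proteins: %d with PTS1, %d with PTS2", len(calls), n1, n2
    )
    return calls
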