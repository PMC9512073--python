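"""Restricted PROSITE-dialect motif patterns for targeting-signal scanning.

The peroxisomal targeting signals handled by this package are written in a
small subset of PROSITE pattern notation:

* a literal residue (``S``) or a residue class in brackets (``[LIF]``);
* the wildcard ``X`` matching any residue, optionally with a repeat count
  ``X(5)`` or a repeat range ``X(0,20)``;
* elements joined by ``-``;
* optional terminal anchors ``<`` (pattern must start at the N-terminus)
  and ``>`` (pattern must end at the C-terminus).

Negated classes ``{...}`` and repeats of non-wildcard elements are not part
of the dialect and are rejected with a :class:`PatternSyntaxError`.

Matching semantics: every distinct placement ``(start, end)`` satisfying all
elements and anchors is reported.  Residue classes match only the 20 standard
amino acids; ambiguity codes (B, J, O, U, X, Z) in a *sequence* are matched by
wildcard positions only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "STANDARD_AMINO_ACIDS",
    "MotifElement",
    "MotifPattern",
    "MatchSpan",
    "PatternSyntaxError",
    "SequenceAlphabetError",
    "parse_pattern",
    "find_matches",
    "count_matching_kmers",
]

#: The 20 standard one-letter amino-acid codes.
STANDARD_AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Maximum repeat bound accepted for a wildcard element.
MAX_WILDCARD_REPEAT = 50


class PatternSyntaxError(ValueError):
    """Raised for malformed pattern text; carries the offending position."""

    def __init__(self, message: str, text: str, pos: int):
        self.text = text
        self.pos = pos
        super().__init__(f"{message} (at position {pos} in {text!r})")


class SequenceAlphabetError(ValueError):
    """Raised when a scanned sequence contains non-letter characters."""


@dataclass(frozen=True)
class MotifElement:
    """One element of a motif: a residue class or a wildcard run.

    A residue class always spans exactly one position (``min_repeat ==
    max_repeat == 1``); a wildcard spans any number of positions in
    ``[min_repeat, max_repeat]``.
    """

    kind: str  # "residue_class" | "wildcard"
    residues: tuple[str, ...] = ()  # source order preserved, no duplicates
    min_repeat: int = 1
    max_repeat: int = 1

    def __post_init__(self) -> None:
        if self.kind == "residue_class":
            # normalise any iterable of residues to an order-preserving,
            # duplicate-free tuple (frozen dataclass: go through __setattr__)
            object.__setattr__(
                self, "residues", tuple(dict.fromkeys(self.residues))
            )
            if not self.residues:
                raise ValueError("residue_class element with empty residue set")
            if not set(self.residues) <= STANDARD_AMINO_ACIDS:
                bad = "".join(sorted(set(self.residues) - STANDARD_AMINO_ACIDS))
                raise ValueError(f"non-standard residues in class: {bad}")
            if (self.min_repeat, self.max_repeat) != (1, 1):
                raise ValueError("residue_class elements have min=max=1")
        elif self.kind == "wildcard":
            if not 0 <= self.min_repeat <= self.max_repeat <= MAX_WILDCARD_REPEAT:
                raise ValueError(
                    f"wildcard repeat bounds out of range: "
                    f"({self.min_repeat},{self.max_repeat})"
                )
        else:
            raise ValueError(f"unknown element kind: {self.kind!r}")

    @property
    def is_fixed_length(self) -> bool:
        return self.min_repeat == self.max_repeat

    def render(self) -> str:
        """Canonical PROSITE-dialect text for this element."""
        if self.kind == "residue_class":
            if len(self.residues) == 1:
                return self.residues[0]
            return "[" + "".join(self.residues) + "]"
        if (self.min_repeat, self.max_repeat) == (1, 1):
            return "X"
        if self.min_repeat == self.max_repeat:
            return f"X({self.min_repeat})"
        return f"X({self.min_repeat},{self.max_repeat})"


@dataclass(frozen=True)
class MotifPattern:
    """A parsed motif: ordered elements plus optional terminal anchors."""

    motif_id: str
    elements: tuple[MotifElement, ...]
    n_anchor: bool = False
    c_anchor: bool = False
    source_text: str = ""

    def render(self) -> str:
        """Rebuild the pattern string (equals ``source_text`` up to
        whitespace and class-residue ordering)."""
        body = "-".join(e.render() for e in self.elements)
        return ("<" if self.n_anchor else "") + body + (">" if self.c_anchor else "")

    @property
    def min_length(self) -> int:
        return sum(e.min_repeat for e in self.elements)

    @property
    def max_length(self) -> int:
        return sum(e.max_repeat for e in self.elements)

    @property
    def is_fixed_length(self) -> bool:
        return self.min_length == self.max_length


@dataclass(frozen=True, order=True)
class MatchSpan:
    """Half-open, 0-based placement of a motif on a sequence."""

    start: int
    end: int
    motif_id: str = field(compare=False, default="")

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid span ({self.start},{self.end})")


_WILDCARD_RE = re.compile(r"X(?:\((\d+)(?:,(\d+))?\))?$")


def _parse_element(token: str, text: str, pos: int) -> MotifElement:
    if token.startswith("["):
        if not token.endswith("]"):
            raise PatternSyntaxError(f"unclosed class {token!r}", text, pos)
        inner = token[1:-1]
        if not inner:
            raise PatternSyntaxError("empty residue class", text, pos)
        bad = set(inner) - STANDARD_AMINO_ACIDS
        if bad:
            raise PatternSyntaxError(
                f"non-amino-acid letter {''.join(sorted(bad))!r} in class {token!r}",
                text, pos,
            )
        return MotifElement("residue_class", tuple(inner))
    if "]" in token or "[" in token:
        raise PatternSyntaxError(f"stray bracket in token {token!r}", text, pos)
    m = _WILDCARD_RE.match(token)
    if token.startswith("X"):
        if m is None:
            raise PatternSyntaxError(f"malformed wildcard {token!r}", text, pos)
        if m.group(1) is None:
            lo = hi = 1  # bare X: exactly one arbitrary residue
        elif m.group(2) is None:
            lo = hi = int(m.group(1))
        else:
            lo, hi = int(m.group(1)), int(m.group(2))
        if not 0 <= lo <= hi <= MAX_WILDCARD_REPEAT:
            raise PatternSyntaxError(
                f"wildcard bounds ({lo},{hi}) out of range", text, pos
            )
        return MotifElement("wildcard", min_repeat=lo, max_repeat=hi)
    if len(token) == 1 and token in STANDARD_AMINO_ACIDS:
        return MotifElement("residue_class", (token,))
    if "{" in token or "}" in token:
        raise PatternSyntaxError(
            f"negated classes {token!r} are not supported by this dialect",
            text, pos,
        )
    raise PatternSyntaxError(f"unrecognised token {token!r}", text, pos)


def parse_pattern(text: str, motif_id: str = "") -> MotifPattern:
    """Parse PROSITE-dialect pattern ``text`` into a :class:`MotifPattern`.

    Whitespace inside the pattern (as in the printed motif ``X (5)``) is
    ignored.  A trailing PROSITE full stop is accepted and stripped.

    Raises
    ------
    PatternSyntaxError
        On malformed brackets or parentheses, empty classes, letters outside
        the 20-residue alphabet, interior anchors, or negated classes.
    """
    if not isinstance(text, str) or not text.strip():
        raise PatternSyntaxError("empty pattern", text or "", 0)
    compact = re.sub(r"\s+", "", text).rstrip(".")
    work = compact
    n_anchor = c_anchor = False
    if work.startswith("<"):
        n_anchor = True
        work = work[1:]
    if work.endswith(">"):
        c_anchor = True
        work = work[:-1]
    if "<" in work or ">" in work:
        raise PatternSyntaxError(
            "anchor in pattern interior", compact,
            max(work.find("<"), work.find(">")) + (1 if n_anchor else 0),
        )
    if not work:
        raise PatternSyntaxError("pattern has anchors but no elements", compact, 0)
    elements: list[MotifElement] = []
    pos = 1 if n_anchor else 0
    for token in work.split("-"):
        if not token:
            raise PatternSyntaxError("empty element between separators", compact, pos)
        elements.append(_parse_element(token, compact, pos))
        pos += len(token) + 1
    return MotifPattern(
        motif_id=motif_id or compact,
        elements=tuple(elements),
        n_anchor=n_anchor,
        c_anchor=c_anchor,
        source_text=text,
    )


def _check_sequence(sequence: str) -> str:
    seq = sequence.upper()
    if not seq.isalpha() and seq != "":
        bad = next(c for c in seq if not c.isalpha())
        raise SequenceAlphabetError(
            f"sequence contains non-letter character {bad!r}"
        )
    return seq


def _match_from(
    elements: tuple[MotifElement, ...],
    seq: str,
    start: int,
    must_end: int | None,
) -> Iterator[int]:
    """Yield every end index of a placement of ``elements`` beginning at
    ``start``.  Shortest wildcard gaps are tried first; callers re-sort."""
    if not elements:
        if must_end is None or start == must_end:
            yield start
        return
    head, rest = elements[0], elements[1:]
    if head.kind == "residue_class":
        if start < len(seq) and seq[start] in head.residues:
            yield from _match_from(rest, seq, start + 1, must_end)
        return
    rest_min = sum(e.min_repeat for e in rest)
    limit = (must_end if must_end is not None else len(seq)) - rest_min
    for gap in range(head.min_repeat, head.max_repeat + 1):
        if start + gap > limit:
            break
        yield from _match_from(rest, seq, start + gap, must_end)


def find_matches(pattern: MotifPattern, sequence: str) -> list[MatchSpan]:
    """Return every distinct placement of ``pattern`` on ``sequence``.

    The sequence is folded to uppercase.  An ``n_anchor`` forces
    ``start == 0``; a ``c_anchor`` forces ``end == len(sequence)``.  Variable
    wildcards enumerate every gap length, so overlapping and nested
    placements are all reported.  Results are sorted by ``(start, end)``.
    """
    seq = _check_sequence(sequence)
    if not seq:
        return []
    if pattern.n_anchor:
        starts: Iterable[int] = [0]
    elif pattern.c_anchor and pattern.is_fixed_length:
        # only one feasible placement for an end-anchored fixed-length motif
        starts = [len(seq) - pattern.min_length] if len(seq) >= pattern.min_length else []
    else:
        starts = range(len(seq) - pattern.min_length + 1)
    must_end = len(seq) if pattern.c_anchor else None
    spans = {
        (s, e)
        for s in starts
        for e in _match_from(pattern.elements, seq, s, must_end)
        if e > s
    }
    return [MatchSpan(s, e, pattern.motif_id) for s, e in sorted(spans)]


def count_matching_kmers(pattern: MotifPattern, k: int) -> int:
    """Exact number of length-``k`` strings over the 20-residue alphabet
    matched by ``pattern`` (anchors at both ends are implied by fixing the
    length).

    Counted by dynamic programming over (element, consumed-length); for a
    fixed-length class-only pattern this reduces to the product of the class
    sizes.

    Raises
    ------
    ValueError
        If ``k`` lies outside the pattern's achievable length bounds.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if k == 0:
        return 1 if pattern.min_length == 0 else 0
    if not pattern.min_length <= k <= pattern.max_length:
        raise ValueError(
            f"k={k} incompatible with pattern length bounds "
            f"[{pattern.min_length},{pattern.max_length}]"
        )
    # ways[j] = number of strings of length j matched by the elements so far
    ways = {0: 1}
    for el in pattern.elements:
        nxt: dict[int, int] = {}
        for j, w in ways.items():
            if el.kind == "residue_class":
                if j + 1 <= k:
                    nxt[j + 1] = nxt.get(j + 1, 0) + w * len(el.residues)
            else:
                for gap in range(el.min_repeat, el.max_repeat + 1):
                    if j + gap <= k:
                        nxt[j + gap] = nxt.get(j + gap, 0) + w * 20 ** gap
        ways = nxt
    return ways.get(k, 0)
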