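"""Tree-aware synthetic proteomes with planted targeting signals.

The generator emulates the statistical structure of the study inputs so the
whole pipeline is testable without database access:

* each orthogroup is a binary "glycosomal" character that evolves on the
  species tree by a single gain at a chosen node followed by independent
  per-edge losses (:func:`simulate_character`);
* taxa carrying the character receive orthologue sequences with a targeting
  signal planted at the right place (:func:`plant_motif`) — detection by the
  scanner is then guaranteed by construction;
* taxa without the character either lack the orthologue or (mimicking
  ambiguous orthologues) carry a copy scrubbed of any PTS by rejection
  sampling.

Background sequences are i.i.d. residues, uniform over the 20 standard
amino acids by default.  This is deliberately unrealistic: under a uniform
background the false-positive rate of the PTS1 scan has the exact closed
form ``N_union / 8000`` (the number of tripeptides matched by any PTS1
pattern over all 20**3), which makes the generator's output an analytic test
oracle.  Losses are modelled per edge, not per unit branch length — the
fixture tree carries no meaningful branch lengths.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .chronology import ensure_node_names
from .io import OrthoMap, write_fasta
from .patterns import STANDARD_AMINO_ACIDS, MotifPattern
from .scanner import (
    DEFAULT_PTS2_WINDOW,
    MotifSet,
    ProteinRecord,
    scan_pts1,
    scan_pts2,
)

__all__ = [
    "SimulationConfig",
    "StudyData",
    "simulate_character",
    "sample_motif_instance",
    "plant_motif",
    "random_protein",
    "scrub_pts",
    "generate_study",
    "write_study",
    "pts1_matching_tripeptides",
]

ALPHABET = "".join(sorted(STANDARD_AMINO_ACIDS))

SIGNAL_KINDS = ("A", "B", "C", "D", "E", "F", "G", "H", "I", "none")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_character(
    tree: dendropy.Tree,
    gain_node: str,
    loss_probability: float,
    seed,
) -> dict[str, int]:
    """Evolve one binary character: state 1 appears at ``gain_node`` and is
    inherited down the tree, flipping to 0 independently on each descendant
    edge with ``loss_probability`` (once lost, never regained).

    Returns the leaf states keyed by taxon label.
    """
    if not 0.0 <= loss_probability <= 1.0:
        raise ValueError("loss_probability must be in [0,1]")
    rng = _as_rng(seed)
    ensure_node_names(tree)
    by_name = {n.label: n for n in tree.preorder_node_iter()}
    if gain_node not in by_name:
        raise ValueError(f"gain node {gain_node!r} not in tree")
    gain = by_name[gain_node]
    state: dict[dendropy.Node, int] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if node is gain:
            state[node] = 1
        elif parent is None or state.get(parent, 0) == 0:
            state[node] = 0
        else:
            state[node] = 0 if rng.random() < loss_probability else 1
    return {
        leaf.taxon.label: state[leaf] for leaf in tree.leaf_node_iter()
    }


def sample_motif_instance(pattern: MotifPattern, seed) -> str:
    """Draw one concrete peptide matched by ``pattern``: classes sample a
    member residue, wildcards sample a length then arbitrary residues."""
    rng = _as_rng(seed)
    out: list[str] = []
    for el in pattern.elements:
        if el.kind == "residue_class":
            out.append(rng.choice(sorted(el.residues)))
        else:
            gap = int(rng.integers(el.min_repeat, el.max_repeat + 1))
            out.extend(rng.choice(list(ALPHABET), size=gap))
    return "".join(out)


def plant_motif(
    sequence: str,
    pattern: MotifPattern,
    where: str = "c_terminal",
    offset: int = 0,
    seed=None,
) -> str:
    """Overwrite part of ``sequence`` with a sampled instance of ``pattern``.

    ``where='c_terminal'`` replaces the final residues (PTS1 planting);
    ``where='n_terminal_offset'`` replaces residues starting at ``offset``
    (PTS2 planting; N-anchored patterns require ``offset == 0``).  The
    result is guaranteed to be detected by the corresponding scanner call.
    """
    instance = sample_motif_instance(pattern, seed)
    if len(instance) > len(sequence):
        raise ValueError("sequence too short to plant motif instance")
    if where == "c_terminal":
        return sequence[: len(sequence) - len(instance)] + instance
    if where == "n_terminal_offset":
        if pattern.n_anchor and offset != 0:
            raise ValueError("N-anchored patterns must be planted at offset 0")
        if offset + len(instance) > len(sequence):
            raise ValueError("motif instance does not fit at requested offset")
        return sequence[:offset] + instance + sequence[offset + len(instance):]
    raise ValueError(f"unknown placement {where!r}")


def random_protein(
    rng: np.random.Generator,
    length: int,
    frequencies: Sequence[float] | None = None,
) -> str:
    """An i.i.d. random sequence over the 20 standard residues (uniform by
    default; ``frequencies`` follows alphabetical residue order)."""
    if frequencies is not None:
        frequencies = np.asarray(frequencies, dtype=float)
        if len(frequencies) != 20 or not np.isclose(frequencies.sum(), 1.0):
            raise ValueError("frequencies must be 20 values summing to 1")
    return "".join(rng.choice(list(ALPHABET), size=length, p=frequencies))


def pts1_matching_tripeptides(motifs: MotifSet | None = None) -> set[str]:
    """All tripeptides matched by at least one (C-anchored) PTS1 pattern,
    by exhaustive enumeration of the 20**3 = 8000 possibilities."""
    motifs = motifs or MotifSet.default()
    matched: set[str] = set()
    for tri in itertools.product(ALPHABET, repeat=3):
        tripeptide = "".join(tri)
        for p in motifs.pts1:
            if all(
                el.kind == "wildcard" or aa in el.residues
                for el, aa in zip(p.elements, tripeptide)
            ) and len(p.elements) == 3:
                matched.add(tripeptide)
                break
    return matched


def scrub_pts(
    sequence: str,
    motifs: MotifSet,
    rng: np.random.Generator,
    window: int = DEFAULT_PTS2_WINDOW,
    max_tries: int = 1000,
) -> str:
    """Rejection-sample until the sequence carries neither PTS1 nor PTS2.

    The C-terminal tripeptide and the N-terminal window are resampled
    (uniform residues) until the scanner reports nothing.
    """
    seq = sequence
    for _ in range(max_tries):
        rec = ProteinRecord("tmp", "", seq)
        has1 = bool(scan_pts1(rec, motifs)) if len(seq) >= 3 else False
        has2 = bool(scan_pts2(rec, motifs, window))
        if not has1 and not has2:
            return seq
        if has1:
            seq = seq[:-3] + random_protein(rng, 3)
        if has2:
            n = min(window, len(seq))
            seq = random_protein(rng, n) + seq[n:]
    raise RuntimeError("failed to scrub targeting signals (pathological input)")


@dataclass
class SimulationConfig:
    """Study-shaped simulation settings.

    ``gain_nodes`` may name one node (every character gains there), list one
    node per character, or be ``"random"`` (each character gains at a
    uniformly drawn internal node).  ``signal_kinds`` follows the same
    per-character convention over {A..I, none, random}; planted PTS1 kinds
    are A-D, PTS2 kinds E-I, and ``none`` yields orthologues carrying no
    signal at all.
    """

    tree: dendropy.Tree
    n_orthogroups: int = 20
    gain_nodes: str | Sequence[str] = "random"
    loss_probability: float = 0.05
    proteins_per_cell: int = 1
    length_range: tuple[int, int] = (80, 300)
    background_frequencies: Sequence[float] | None = None
    signal_kinds: str | Sequence[str] = "random"
    no_pts_presence_prob: float = 0.3
    window: int = DEFAULT_PTS2_WINDOW
    seed: int = 0
    motifs: MotifSet = dataclass_field(default_factory=MotifSet.default)

    def __post_init__(self) -> None:
        if self.n_orthogroups < 0:
            raise ValueError("n_orthogroups must be >= 0")
        if self.proteins_per_cell < 1:
            raise ValueError("proteins_per_cell must be >= 1")
        lo, hi = self.length_range
        if lo < 10 or hi < lo:
            raise ValueError("sequence lengths must satisfy 10 <= min <= max")
        if not 0.0 <= self.loss_probability <= 1.0:
            raise ValueError("loss_probability must be in [0,1]")
        if not 0.0 <= self.no_pts_presence_prob <= 1.0:
            raise ValueError("no_pts_presence_prob must be in [0,1]")


@dataclass
class StudyData:
    """Generated study inputs plus the ground truth for recovery scoring."""

    proteomes: dict[str, list[ProteinRecord]]
    orthomap: OrthoMap
    truth: pd.DataFrame  # orthogroup_id, gain_node, signal_kind + one column per taxon


def _pick_per_character(spec, n: int, choices: Sequence[str], rng) -> list[str]:
    if isinstance(spec, str):
        if spec == "random":
            return [str(rng.choice(list(choices))) for _ in range(n)]
        return [spec] * n
    spec = list(spec)
    if len(spec) != n:
        raise ValueError(f"need one entry per orthogroup ({n}), got {len(spec)}")
    return [str(s) for s in spec]


def generate_study(config: SimulationConfig) -> StudyData:
    """Generate per-taxon proteomes, an orthogroup map and a truth table.

    Outputs are valid pipeline inputs; the truth table holds each
    character's gain node, planted signal kind and per-taxon 0/1 states, so
    downstream inferences can be scored against the simulation.
    Deterministic per ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    tree = ensure_node_names(config.tree)
    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    internal = [n.label for n in tree.preorder_node_iter() if not n.is_leaf()]
    n = config.n_orthogroups
    gains = _pick_per_character(config.gain_nodes, n, internal, rng)
    pattern_by_id = {
        p.motif_id: p for p in config.motifs.pts1 + config.motifs.pts2
    }
    signal_choices = list(pattern_by_id) + ["none"]
    kinds = _pick_per_character(config.signal_kinds, n, signal_choices, rng)
    pts1_ids = {p.motif_id for p in config.motifs.pts1}

    proteomes: dict[str, list[ProteinRecord]] = {t: [] for t in taxa}
    ortho_rows: list[dict[str, str]] = []
    truth_rows: list[dict[str, object]] = []
    lo, hi = config.length_range
    for i in range(n):
        og = f"OG{i + 1:04d}"
        states = simulate_character(
            tree, gains[i], config.loss_probability, rng
        )
        kind = kinds[i]
        for taxon in taxa:
            present = states[taxon] == 1
            if not present and rng.random() >= config.no_pts_presence_prob:
                continue  # orthologue absent from this taxon
            for j in range(config.proteins_per_cell):
                length = int(rng.integers(lo, hi + 1))
                seq = random_protein(rng, length, config.background_frequencies)
                if present and kind != "none":
                    pattern = pattern_by_id[kind]
                    if kind in pts1_ids:
                        seq = plant_motif(seq, pattern, "c_terminal", seed=rng)
                    else:
                        offset = 0 if pattern.n_anchor else int(
                            rng.integers(1, config.window - pattern.max_length)
                        )
                        seq = plant_motif(
                            seq, pattern, "n_terminal_offset", offset, seed=rng
                        )
                else:
                    seq = scrub_pts(seq, config.motifs, rng, config.window)
                pid = f"{taxon}.{og}.p{j + 1}"
                proteomes[taxon].append(ProteinRecord(pid, taxon, seq))
                ortho_rows.append(
                    {
                        "protein_id": pid,
                        "taxon_id": taxon,
                        "orthogroup_id": og,
                        "enzyme_label": f"enzyme_{i + 1}",
                    }
                )
        truth_rows.append(
            {"orthogroup_id": og, "gain_node": gains[i], "signal_kind": kind,
             **{t: states[t] for t in taxa}}
        )
    ortho_frame = pd.DataFrame(
        ortho_rows,
        columns=["protein_id", "taxon_id", "orthogroup_id", "enzyme_label"],
    )
    truth = pd.DataFrame(
        truth_rows, columns=["orthogroup_id", "gain_node", "signal_kind", *taxa]
    )
    return StudyData(
        proteomes=proteomes,
        orthomap=OrthoMap(ortho_frame, taxa=taxa),
        truth=truth,
    )


def write_study(study: StudyData, outdir: str | Path) -> None:
    """Write one FASTA per taxon, the orthomap TSV and the truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for taxon, records in study.proteomes.items():
        write_fasta(records, outdir / f"{taxon}.fasta")
    study.orthomap.frame.to_csv(outdir / "orthomap.tsv", sep="\t", index=False)
    taxa = [c for c in study.truth.columns
            if c not in ("orthogroup_id", "gain_node", "signal_kind")]
    payload = {
        row["orthogroup_id"]: {
            "gain_node": row["gain_node"],
            "signal_kind": row["signal_kind"],
            "states": {t: int(row[t]) for t in taxa},
        }
        for _, row in study.truth.iterrows()
    }
    (outdir / "truth.json").write_text(json.dumps(payload, indent=1) + "\n")
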