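"""Readers and writers: FASTA proteomes, orthogroup tables, Newick trees.

Conventions (applied everywhere in this package):

* coordinates are 0-based, half-open;
* taxon ids are underscored binomials, matched case-sensitively across files;
* readers reject malformed input rather than silently repairing it.

The study taxon set — 24 euglenozoans plus three *Naegleria* outgroup
species — and a rooted species tree encoding their relationships are shipped
as package data (:data:`STUDY_TAXA`, :func:`load_fixture_tree`).
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .scanner import ProteinRecord, PTSCall

__all__ = [
    "KINETOPLASTEA",
    "DIPLONEMEA",
    "EUGLENIDA",
    "HETEROLOBOSEA",
    "STUDY_TAXA",
    "OrthoMap",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "load_fixture_tree",
    "read_orthomap",
    "write_calls_tsv",
    "write_calls_json",
    "read_motif_table",
]

# The analysed lineages.  Kinetoplastea, Diplonemea and Euglenida are the
# three major euglenozoan classes; Naegleria (Heterolobosea) is the
# peroxisome-bearing outgroup used to polarise gains.
KINETOPLASTEA: tuple[str, ...] = (
    "Trypanosoma_brucei",
    "Trypanosoma_vivax",
    "Trypanosoma_cruzi",
    "Leishmania_major",
    "Endotrypanum_monterogeii",
    "Leishmania_tarentolae",
    "Crithidia_fasciculata",
    "Blechomonas_ayalai",
    "Leptomonas_pyrrhocoris",
    "Leptomonas_seymouri",
    "Paratrypanosoma_confusum",
    "Angomonas_deanei",
    "Strigomonas_culicis",
    "Phytomonas_sp",
    "Perkinsela_sp",
    "Trypanoplasma_borreli",
    "Bodo_saltans",
)

DIPLONEMEA: tuple[str, ...] = (
    "Diplonema_papillatum",
    "Diplonema_japonicum",
    "Diplonema_ambulator",
    "Hemistasia_phaeocysticola",
)

EUGLENIDA: tuple[str, ...] = (
    "Euglena_gracilis",
    "Euglena_longa",
    "Rhabdomonas_costata",
)

HETEROLOBOSEA: tuple[str, ...] = (
    "Naegleria_gruberi",
    "Naegleria_fowleri",
    "Naegleria_lovaniensis",
)

#: All 27 taxa of the comparative analysis.
STUDY_TAXA: tuple[str, ...] = (
    KINETOPLASTEA + DIPLONEMEA + EUGLENIDA + HETEROLOBOSEA
)

ORTHOMAP_COLUMNS = ["protein_id", "taxon_id", "orthogroup_id", "enzyme_label"]


class OrthoMap:
    """Validated protein → orthogroup → taxon mapping.

    Wraps a DataFrame with columns ``protein_id, taxon_id, orthogroup_id,
    enzyme_label``.  A protein may belong to several orthogroups (one row
    per membership); ``(protein_id, taxon_id, orthogroup_id)`` triples are
    unique and every ``(protein_id, taxon_id)`` pair maps consistently.
    """

    def __init__(self, frame: pd.DataFrame, taxa: Sequence[str] | None = None):
        missing = [c for c in ORTHOMAP_COLUMNS[:3] if c not in frame.columns]
        if missing:
            raise ValueError(f"orthomap missing columns: {missing}")
        frame = frame.copy()
        if "enzyme_label" not in frame.columns:
            frame["enzyme_label"] = ""
        frame = frame[ORTHOMAP_COLUMNS + [
            c for c in frame.columns if c not in ORTHOMAP_COLUMNS
        ]]
        dup = frame.duplicated(["protein_id", "taxon_id", "orthogroup_id"])
        if dup.any():
            first = frame[dup].iloc[0]
            raise ValueError(
                "duplicate orthomap row for protein "
                f"{first.protein_id!r} / taxon {first.taxon_id!r}"
            )
        # one protein id must not appear under two taxa
        per_protein = frame.groupby("protein_id")["taxon_id"].nunique()
        clashed = per_protein[per_protein > 1]
        if len(clashed):
            raise ValueError(
                f"protein id(s) mapped to multiple taxa: {list(clashed.index)[:5]}"
            )
        if taxa is not None:
            unknown = set(frame["taxon_id"]) - set(taxa)
            if unknown:
                raise ValueError(f"unknown taxon id(s): {sorted(unknown)[:5]}")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def orthogroups(self) -> list[str]:
        return sorted(self.frame["orthogroup_id"].unique())

    def groups_of(self, protein_id: str) -> list[str]:
        rows = self.frame[self.frame["protein_id"] == protein_id]
        return sorted(rows["orthogroup_id"].unique())


def _parse_description(description: str, default_taxon: str) -> tuple[str, str]:
    parts = description.split()
    protein_id = parts[0]
    taxon = default_taxon
    for tok in parts[1:]:
        if tok.startswith("taxon="):
            taxon = tok[len("taxon="):]
    return protein_id, taxon


def read_fasta(
    path: str | Path | TextIO, default_taxon: str = ""
) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    The description line is parsed as ``protein_id taxon=<taxon_id>``; when
    no ``taxon=`` field is present, ``default_taxon`` is used.  A trailing
    ``*`` stop symbol is stripped.  Empty records and duplicate ids are
    rejected.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        protein_id, taxon = _parse_description(rec.description, default_taxon)
        seq = str(rec.seq).upper().rstrip("*")
        if not seq:
            raise ValueError(f"empty sequence for record {protein_id!r}")
        if protein_id in seen:
            raise ValueError(f"duplicate record id {protein_id!r}")
        seen.add(protein_id)
        records.append(ProteinRecord(protein_id, taxon, seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path | TextIO) -> None:
    """Write records with ``taxon=`` annotations readable by :func:`read_fasta`."""
    seq_records = [
        SeqRecord(
            Seq(r.sequence),
            id=r.protein_id,
            description=f"taxon={r.taxon_id}" if r.taxon_id else "",
        )
        for r in records
    ]
    SeqIO.write(seq_records, path, "fasta")


def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a single rooted Newick tree with uniquely labelled leaves.

    Underscores in labels are preserved literally; branch lengths are parsed
    but ignored by all downstream parsimony computations.
    """
    return read_newick_string(Path(source).read_text())


def load_fixture_tree() -> dendropy.Tree:
    """The shipped 27-taxon Discoba species tree (outgroup-rooted)."""
    ref = resources.files("ptschrono.data").joinpath("discoba_fig1.nwk")
    tree = read_newick_string(ref.read_text())
    return tree


def read_newick_string(newick: str) -> dendropy.Tree:
    """Parse a literal Newick string (same validation as :func:`read_newick`)."""
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as e:
        raise ValueError(f"duplicate leaf labels in newick: {e}") from e
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) < 2:
        raise ValueError("tree must have at least 2 leaves")
    if len(labels) != len(set(labels)):
        dups = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate leaf labels: {dups}")
    return tree


def read_orthomap(
    path: str | Path | TextIO, taxa: Sequence[str] | None = STUDY_TAXA
) -> OrthoMap:
    """Read the TSV orthogroup mapping; validates taxa against ``taxa``
    (pass ``None`` to skip the taxon check)."""
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return OrthoMap(frame, taxa=taxa)


def write_orthomap(orthomap: OrthoMap, path: str | Path | TextIO) -> None:
    orthomap.frame.to_csv(path, sep="\t", index=False)


def _fmt_hits(call: PTSCall) -> tuple[str, str]:
    pts1 = ",".join(sorted(call.pts1_hits))
    pts2 = ",".join(
        f"{mid}:{span.start}-{span.end}" for mid, span in call.pts2_hits
    )
    return pts1, pts2


def write_calls_tsv(calls: Iterable[PTSCall], path: str | Path | TextIO) -> None:
    """Scan results as TSV; pts2 spans are 0-based half-open ``start-end``."""
    rows = []
    for c in calls:
        pts1, pts2 = _fmt_hits(c)
        rows.append(
            {
                "protein_id": c.protein_id,
                "taxon_id": c.taxon_id,
                "pts1_hits": pts1,
                "pts2_hits_0based_halfopen": pts2,
                "has_pts1": int(c.has_pts1),
                "has_pts2": int(c.has_pts2),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "protein_id", "taxon_id", "pts1_hits",
            "pts2_hits_0based_halfopen", "has_pts1", "has_pts2",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_calls_json(calls: Iterable[PTSCall], path: str | Path) -> None:
    """Scan results with explicit spans, as JSON."""
    payload = [
        {
            "protein_id": c.protein_id,
            "taxon_id": c.taxon_id,
            "pts1_hits": sorted(c.pts1_hits),
            "pts2_hits": [
                {"motif_id": mid, "start": span.start, "end": span.end}
                for mid, span in c.pts2_hits
            ],
            "has_pts1": c.has_pts1,
            "has_pts2": c.has_pts2,
        }
        for c in calls
    ]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_motif_table(path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    """Read a custom motif file, one motif per line.

    Accepted forms: ``id<TAB>pattern`` (signal type inferred: C-anchored
    patterns are PTS1, the rest PTS2) or the explicit
    ``id<TAB>pts1|pts2<TAB>pattern``.  Returns ``(pts1_patterns,
    pts2_patterns)`` dicts of pattern strings.
    """
    pts1: dict[str, str] = {}
    pts2: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) == 2:
            mid, pattern = fields
            kind = "pts1" if pattern.rstrip().endswith(">") else "pts2"
        elif len(fields) == 3 and fields[1] in ("pts1", "pts2"):
            mid, kind, pattern = fields
        else:
            raise ValueError(
                f"{path}:{i}: expected 'id<TAB>pattern' or "
                "'id<TAB>pts1|pts2<TAB>pattern'"
            )
        if mid in pts1 or mid in pts2:
            raise ValueError(f"{path}:{i}: duplicate motif id {mid!r}")
        (pts1 if kind == "pts1" else pts2)[mid] = pattern
    return pts1, pts2
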