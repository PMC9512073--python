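# ptschrono

Peroxisomal targeting-signal scanning and a parsimony chronology of
glycosome evolution across Discoba.

Glycosomes are the peroxisome-derived organelles of kinetoplastid and
diplonemid protists (the lineage containing *Trypanosoma*, *Leishmania*,
*Bodo* and *Diplonema*), unique for sequestering glycolysis and much of its
extended metabolism. Most matrix proteins enter peroxisomes and glycosomes
post-translationally via one of two targeting signals: **PTS1**, a
C-terminal tripeptide (canonically ‑SKL), or **PTS2**, a nonapeptide near
the N-terminus. Because the signal is encoded in the protein sequence
itself, the organellar proteome of a taxon can be predicted from its
predicted proteome alone — and comparing those predictions across a species
tree dates when each enzyme was first sequestered in the organelle.

`ptschrono` is for comparative genomicists who want that inference as a
reproducible pipeline rather than a manual database survey:

1. **pattern engine** — a restricted PROSITE-dialect matcher
   (`[ASCGPNYTV]-[KNRHQDS]-[LMVAIF]>`, `X(0,20)`, `<`/`>` anchors) with an
   exact k-mer census (`count_matching_kmers`) for analytic false-positive
   rates;
2. **scanner** — nine consensus motifs: four C-anchored PTS1 tripeptide
   patterns (A–D) applied to the C-terminus, five PTS2 nonapeptide patterns
   (E–I) searched in a 40-residue N-terminal window;
3. **presence matrix** — per-protein calls collapsed to orthogroup × taxon
   states in {absent, present_no_PTS, present_PTS1, present_PTS2,
   present_both}, then binarised;
4. **chronology** — Fitch small parsimony (unit-cost DP, exact on
   polytomies) and a Dollo single-gain/multiple-loss reconstruction on a
   shipped 27-taxon species tree (24 euglenozoans + 3 *Naegleria*
   outgroups), assigning each character to one of four epochs:
   `ancestral_peroxisomal`, `glycosome_origin`, `kinetoplastid_early`,
   `late_taxon_specific`;
5. **simulator** — tree-aware synthetic proteomes with planted signals and
   known gain nodes, so every stage is testable offline.

## Worked example

```python
from ptschrono import (
    MotifSet, ProteinRecord, scan_pts1, load_fixture_tree, dollo_gain,
    assign_epoch,
)
from ptschrono.chronology import ensure_node_names
from ptschrono.io import KINETOPLASTEA, DIPLONEMEA, EUGLENIDA, HETEROLOBOSEA

motifs = MotifSet.default()
for tri in ("SKL", "PKL", "SQA", "SKS"):
    print(tri, sorted(scan_pts1(ProteinRecord("p", "t", "MEVKAL" + tri), motifs)))

tree = ensure_node_names(load_fixture_tree())
states = {t: 1 for t in KINETOPLASTEA + DIPLONEMEA}
states |= {t: 0 for t in EUGLENIDA + HETEROLOBOSEA}
h = dollo_gain(tree, states, "GAPDH")
print(h.gain_node, h.n_losses, assign_epoch(h, tree))
```

prints

```
SKL ['A', 'B']
PKL ['A']
SQA ['A']
SKS []
Kinetoplastea_Diplonemea 0 glycosome_origin
```

-SKL satisfies both broad PTS1 consensus patterns, ‑PKL and ‑SQA only the
most permissive one, and ‑SKS — a known non-canonical signal — none, so it
is (correctly) not called by consensus scanning. The binary character
"PTS-bearing GAPDH", present in every kinetoplastid and diplonemid but in
no euglenid or *Naegleria*, maps its single gain to their common ancestor:
the enzyme was sequestered during or shortly after the origin of glycosomes
from peroxisomes.

The same pipeline runs from the shell:

```sh
ptschrono simulate --n-orthogroups 20 --loss-probability 0.05 --seed 1 --out study/
ptschrono chronology --fasta study/*.fasta --orthomap study/orthomap.tsv --out chronology.tsv
```

All coordinates in outputs are 0-based, half-open; taxon ids are
underscored binomials matched case-sensitively.

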