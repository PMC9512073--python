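# Methods

## The inference problem

Peroxisomal/glycosomal matrix proteins carry their address in their own
sequence: a C-terminal tripeptide (PTS1) or an N-terminal nonapeptide
(PTS2). Given predicted proteomes for a set of taxa, an orthogroup table,
and a rooted species tree, the pipeline asks, for each orthogroup: *in
which taxa does at least one member carry a targeting signal, and where on
the tree was that state gained?* The answer places each glycosomal enzyme
into an evolutionary epoch of organelle remodelling.

## Motif model

Signals are modelled as deterministic consensus patterns in a restricted
PROSITE dialect: ordered elements that are either residue classes
(`[STAGCN]`, matching exactly one of the listed residues) or wildcard runs
(`X`, `X(5)`, `X(0,20)`), with optional terminal anchors `<` (match must
start at residue 0) and `>` (match must end at the sequence end). Negated
classes and repeats of non-wildcard elements are outside the dialect and
rejected at parse time. The default set contains four PTS1 tripeptide
patterns (A–D, all C-anchored) and five PTS2 nonapeptide patterns (E–I, of
which F is anchored at the initiator methionine with up to 20 arbitrary
residues before the nonapeptide core).

Matching reports *every* placement, not a best hit: the downstream quantity
is presence/absence, so overlap resolution would add policy without
information. Matching is by backtracking over elements with variable
wildcards enumerated shortest-first; results are canonically re-sorted by
(start, end), so enumeration order is unobservable. Sequences are folded to
uppercase. Ambiguity codes (B, J, O, U, X, Z) satisfy wildcard positions
only, never a residue class — a deliberately conservative rule that cannot
create a PTS call out of an ambiguous residue. For end-anchored
fixed-length patterns the matcher evaluates only the single feasible
placement, making C-terminal scans O(1) per pattern.

`count_matching_kmers` counts, by dynamic programming over (element,
consumed length), exactly how many length-k strings over the 20-residue
alphabet a pattern matches; for class-only patterns this is the product of
class sizes (motif A: 9·7·6 = 378). Together with a uniform-background
simulator this yields closed-form false-positive rates used as test
oracles: the union of motifs A–D covers 452 of the 8000 tripeptides, so a
random protein has PTS1 probability 452/8000 = 5.65%.

## Scanning conventions

* PTS1: patterns are evaluated against the full sequence but, being
  C-anchored, can only match the terminal tripeptide. Patterns supplied
  without the `>` anchor are normalised to C-anchored form — a PTS1 is by
  definition terminal. Sequences shorter than three residues yield an empty
  call with a warning rather than an error.
* PTS2: unanchored patterns are searched within the first `window` residues
  (default 40); N-anchored patterns are evaluated from position 0 on the
  full sequence. The window default is a documented choice: "near the
  N-terminus" must at least accommodate the known PTS2 that overlaps a
  mitochondrial targeting signal, and 40 residues covers the longest
  anchored pattern (1 + 20 + 9 = 30) with margin. It is configurable
  everywhere (`--window`).
* The initiator methionine is never stripped — pattern F requires it.
* A protein may carry both signal types; both are reported.

## Presence matrix

Cell states live on a small lattice: `absent` (no mapped protein),
`present_no_PTS`, `present_PTS1`, `present_PTS2`, `present_both`. The cell
state is the join over all paralogues mapped to that (orthogroup, taxon):
any paralogue's PTS1 plus any other's PTS2 gives `present_both`. An
orthologue without a detectable PTS is *not* absence — it may still be
organellar via a non-canonical signal or piggyback import — so the
five-state matrix preserves the distinction and only `binarize` collapses
it (rules: `any_pts`, `pts1_only`, `pts2_only`, `present_at_all`). The
chronology uses `any_pts`. Aggregation is order-invariant; a protein listed
in several orthogroups contributes to each.

## Chronology

Two reconstructions are computed per binary character:

* **Small parsimony** (`fitch_parsimony`): unit-cost dynamic programming
  over states {0,1} — cost of a subtree given its root state is the sum over
  children of min(child cost, other-state child cost + 1). This is exact on
  multifurcating trees (where the classic union/intersection formulation is
  not) and reduces to Fitch on binary trees. Backtracking ties prefer state
  0: when the data do not force an early gain, the character is assumed
  absent — the conservative, delayed-gain reading.
* **Dollo** (`dollo_gain`): a glycosomal character is gained once and lost
  freely. The gain is the MRCA of all 1-leaves; the losses are one edge per
  maximal subtree below the gain containing no 1-leaf. This loss set is
  minimal and the implied node states reproduce every observed leaf state.
  Leaves scored `?` (taxa with incomplete assemblies or transcriptomes)
  constrain nothing: they are excluded from the MRCA, and subtrees holding
  only `?` leaves require no loss. The root state is implicitly 0 — gains
  are polarised by the peroxisome-bearing *Naegleria* outgroup.

`fitch_score <= dollo_events` always; equality holds when a single-gain
scenario is most parsimonious. A character whose Dollo loss count exceeds a
user threshold can be flagged `lgt_suspect`: repeated implied losses are
the parsimony signature of lateral acquisition, for which no formal
criterion is imposed beyond the flag.

Epochs are assigned from the gain node's position relative to three
reference nodes, located by taxon content (so subtrees and custom trees
work): the Discoba root, the Kinetoplastea+Diplonemea MRCA (where
peroxisomes became glycosomes) and the Kinetoplastea MRCA. Gain strictly
above the Kinetoplastea+Diplonemea MRCA →
`ancestral_peroxisomal` (under Dollo this is equivalent to the character
also occurring in euglenids or *Naegleria*, since any such presence pulls
the MRCA above the glycosome origin); gain exactly at that MRCA →
`glycosome_origin`; at the Kinetoplastea MRCA → `kinetoplastid_early`; any
lower gain → `late_taxon_specific`; an all-zero character has no epoch.

## Fixture tree

The shipped tree has 27 leaves: 17 Kinetoplastea (including *Perkinsela*
as the earliest-branching kinetoplastid, then *Trypanoplasma*, *Bodo*, and
the trypanosomatids with *Paratrypanosoma* basal), 4 Diplonemea, 3
Euglenida, and 3 *Naegleria* species as the heterolobosean outgroup.
Euglenida branch first within Euglenozoa; Diplonemea and Kinetoplastea are
sisters. Internal nodes carry stable labels (`Kinetoplastea`,
`Kinetoplastea_Diplonemea`, `African_trypanosomes`, …); unlabelled internal
nodes of user trees are auto-named `n<preorder index>`. Branch lengths are
parsed and ignored — all inference here is topological.

## Synthetic data

The generator produces study-shaped inputs with known truth. A character
starts at its gain node with state 1 and is inherited downward, flipping to
0 independently on each descendant edge with probability `loss_probability`
(default 0.05) — loss is per edge, not per unit branch length, because the
fixture tree has no meaningful lengths. Leaf presence therefore has the
closed form ∏(1−p) over the gain-to-leaf path, which the tests check.

Character-positive taxa receive `proteins_per_cell` sequences (default 1)
of i.i.d. uniform residues, length uniform on 80–300, with an instance of
the character's signal planted: PTS1 kinds overwrite the terminal
tripeptide, PTS2 kinds overwrite a window-interior stretch (anchored F at
position 0). Instances are sampled uniformly per element, so detection by
the scanner is guaranteed by construction (sensitivity 1). Character-
negative taxa carry the orthologue with probability 0.3 (exercising the
`present_no_PTS` state); such sequences, and positives of kind `none`, are
rejection-sampled until the scanner reports nothing, so false positives
cannot leak into the truth comparison. The uniform background is
deliberately unrealistic — no composition bias, no homology, no indels, no
paralogue birth/death — which is exactly what makes analytic rates exact
test oracles. Passing tests therefore demonstrate correctness of the
machinery, not robustness to real proteome composition; on real data the
false-positive rate depends on residue usage and the PTS2 window choice.

## Verification and problem sizes

All oracles are independent of the paths they check: a set-reachability
placement enumerator for the matcher; exhaustive enumeration over all 20³
tripeptides for the census; brute force over all ancestral assignments for
parsimony (trees of ≤ 8 leaves, all 2⁸ leaf vectors); closed-form survival
for the character simulator. The acceptance script measures the empirical
PTS1 false-positive rate at n = 10⁵ proteins, matcher agreement at 1200
random pattern/sequence pairs, and recovery at 100 loss-free characters
(full pipeline) plus 1000 lossy characters (Dollo only).

One recovery limit is structural, not a defect: with per-edge loss p, a
loss on either edge leaving the gain node erases the character from a whole
descendant lineage, making the data indistinguishable from a later gain.
The recoverable fraction is P(survivors span the gain node) ≈ 1−(1−(1−p)²)
≈ 0.90 at p = 0.05 for a bifurcating gain node, and the MRCA estimator
attains exactly this ceiling (the suite asserts recovery ⇔ spanning).
Loss-free recovery is 100% by construction.

## Known limitations

* Consensus patterns are binary: no position weights, no context scoring of
  residues flanking the tripeptide, so known non-canonical signals (e.g.
  ‑SKS) are not called — by design, since the motif set defines the method.
* Orthology is consumed, not inferred; errors in the orthogroup table
  propagate directly to the matrix.
* Dollo cannot see gains above the MRCA of surviving bearers (see ceiling
  above) and mislabels laterally transferred characters as multi-loss
  verticals unless flagged.
* Experimental localisation evidence can override a missing PTS in reality;
  the matrix keeps `present_no_PTS` distinct precisely so users can apply
  such overrides downstream, but no systematic rule is built in.
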