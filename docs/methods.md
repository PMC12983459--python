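# Methods

## Coordinate conventions

All residue positions are **mature-protein coordinates**: the catalytic
threonine (Thr1, the first T of the conserved TTTL cleavage motif) is
position 1. The mature start is located as the first TTTL occurrence within
the first 90 precursor residues — proteasome β-subunit propeptides are short,
and the window keeps spurious internal TTTL matches from shifting the frame;
the window is configurable. Contig coordinates are 0-based, half-open on the
forward strand; minus-strand ORFs report forward coordinates while their
`nt_seq` runs in reading direction. Only the standard genetic code is
supported (the relevant taxa are vertebrates).

## Screening model

The transcriptome screen emulates a reference-guided BLAST search without
BLAST's e-value machinery: every ORF of at least 50 codons is locally aligned
(Smith–Waterman, BLOSUM62, gap open −11 / extend −1 — the canonical protein
BLAST parameters) against a panel containing PSMB8 exemplars of both lineages
and PSMB5 decoys, and retained when the best hit reaches score ≥ 100 **and**
identity ≥ 0.40. An e-value would require a database-size model that adds
nothing here, since candidate confirmation happens downstream anyway; both
thresholds are exposed in the configuration. Candidates whose best reference
is PSMB5 are retained but flagged and excluded from typing — silently
absorbing the constitutive paralog would be the worst failure mode of this
screen.

QC applies, in a fixed order so each rejection carries one deterministic
primary reason: `decoy_family`, `no_TTTL`, `truncated_before_31`,
`undefined_31`, `duplicate` (identical mature protein within one species
tag; first id kept). The decoy check runs first because PSMB5 paralogs also
lack the TTTL motif and the decoy label is the informative one.

**Residue 31 through alignment, not position.** An indel near the S1 pocket
shifts naive positional indexing onto the wrong residue. The pipeline
therefore maps reference mature position 31 through a global alignment with
an A-lineage reference; if the query carries a gap in that column, residue 31
is *undefined* and the sequence is excluded with reason `undefined_31`
(detail `gap_mapped`) — the behavior known from denticle herring PSMB8, where
indels leave the type unresolvable.

## Typing and lineage

Residue-31 → type: A31/V31 → A, F31/Y31 → F, S31/T31 → S (threonine is
structurally equivalent: a small linear hydroxyl side group), K31 → K. Any
other residue yields an explicit `other(<residue>)` label rather than being
collapsed — novel types are discovered exactly by such fall-throughs.

The diagnostic-residue classifier counts matches against the A-lineage
reference profile (I, S, M, E, G, C, K, E) and the F-lineage profile
(M, T, L, P, A, S, Q, D) at mature positions 13/99/147/150/156/188/189/194.
Undefined residues match neither side; equal counts give `ambiguous` rather
than a forced call, because phylogenetic placement is the better arbiter when
residues disagree. The second classifier assigns lineage by clade membership:
walking from the query tip rootward, the first ancestor containing reference
tips decides (uniform label → that lineage, mixed → `unresolved`). The
pipeline always reports both calls plus an agreement flag; clade membership
is the recommended call on disagreement since individual diagnostic residues
can be homoplasious.

S1-pocket profiling reports residues at mature positions 20, 31, 35, 45, 49,
53 plus Thr1, annotated by side-chain class (positive K/R/H, negative D/E,
polar-hydroxyl S/T, aromatic F/Y/W, small-nonpolar A/G/V/L/I/M/P/C). This is
sequence-level profiling only; no structural modeling is attempted.

## Alignment engine

Pairwise alignment is a three-state Gotoh dynamic program (global and local
modes) in which the first residue of a gap costs `gap_open` and each further
residue `gap_extend`; with `gap_open == gap_extend` it reduces exactly to
linear-gap Needleman–Wunsch, which the tests exploit as an independent
oracle (alongside a cross-check against Biopython's `PairwiseAligner`).
Traceback ties break deterministically: substitution, then gap-in-query,
then gap-in-subject. The DP is NumPy-vectorized row-wise; the
within-row horizontal gap state is computed by a running-maximum
transformation, keeping the Python loop to one pass over rows.

The multiple aligner is progressive: 3-mer count distances, a UPGMA guide
tree with lexicographic-by-id tie-breaking (determinism independent of input
order), and profile–profile global alignment under sum-of-pairs column
scoring with gap-vs-residue scored as `gap_extend`. Profile-level gap
penalties are scaled by the product of the two profile depths: sum-of-pairs
column scores grow as `n_a · n_b`, and unscaled gap penalties would become
asymptotically free in deep profiles (this showed up in development as
spurious gap columns in an alignment of equal-length sequences). Two-sequence
inputs reduce exactly to the pairwise aligner. No iterative refinement is
attempted.

## Phylogenetics

Distances are p-distances over columns where both rows are non-gap,
optionally Poisson-corrected (−ln(1−p); saturation p → 1 is an error, not an
infinite branch). Trees are built with Saitou–Nei neighbor joining: Q-matrix
ties break on the lowest index pair, and negative branch-length estimates are
clamped to zero with the deficit transferred to the sister branch so path
lengths are preserved. NJ is exact on additive matrices — the tests verify
topology recovery on all random 4- and 5-taxon additive matrices against a
brute-force least-squares search over every topology.

Node support is a standard nonparametric bootstrap: alignment columns
resampled with replacement, NJ rebuilt per replicate, support = percentage of
replicates containing each internal bipartition of the point tree. Rows are
canonically sorted by id before resampling so supports do not depend on input
order. A replicate in which some pair loses all shared columns is skipped
(counting it as absence of every bipartition). Rooting places the root at the
midpoint of the branch separating a monophyletic outgroup (the PSMB5
references) from the ingroup; internal-node labels are remapped by
bipartition after rerooting, because rerooting changes which side of each
bipartition a node subtends — supports belong to edges, not nodes.

A distance/NJ engine was chosen deliberately over maximum-likelihood
inference: the questions asked of the tree (lineage monophyly and clade
assignment) are driven by large between-lineage distances, NJ is exact in
the additive regime and fast enough to bootstrap at scale, and it keeps the
package dependency-light and fully deterministic. Model selection,
ultrafast-bootstrap approximations, and divergence-time estimation are out
of scope.

## Synthetic data

The generator emulates the *structure* of holostean immune-tissue
transcriptome assemblies, not any real sequence: all templates are pinned
synthetic constants with PSMB8's architecture — a 20-residue propeptide
(Met start), TTTL at the cleavage site, a 204-residue mature protein
carrying the lineage-diagnostic residues (A or F profile) and the S1-pocket
positions, and a PSMB5-like decoy at roughly 55% identity to both lineage
templates with no TTTL. The A and F templates differ at 15% of mature
positions (identity 0.853), consistent with between-lineage divergence being
several-fold the within-cohort haplotype spread. The decoy is built from an
A/F-balanced hybrid before randomization so the outgroup sits approximately
equidistant from both lineages; an outgroup biased toward one lineage
attaches inside that clade's radiation and breaks its monophyly, which is a
generator artifact rather than a property of the method.

Per sequence: the focal codon 31 is set per specification (e.g. TCT for
bowfin-S, ACC for gar-T, AAG for gar-K); nucleotide substitutions are applied
at rate μ per unconstrained site with a 2:1 third-codon-position bias
(yielding a realistic synonymous/nonsynonymous mixture without a full codon
model); draws creating stop codons are rejected; diagnostic, pocket, TTTL,
start and stop codons are never mutated, so the truth labels remain
well-defined at every μ. With probability `indel_prob` the six nucleotides of
mature codons 30–31 are deleted (frame-preserving), producing the
undefined-31 case. Contigs gain random UTRs (default 80 nt) scrubbed of ATG
so no upstream in-frame start can displace the true ORF start. Within a
cohort, mature-protein haplotypes are kept distinct (regenerating on
collision, μ > 0), matching the upstream deduplication the screen assumes.
The default study-mirroring specification reproduces the published cohort
structure — 35 gar A-lineage sequences (8 A / 24 S(T31) / 3 K) and 22 bowfin
F-lineage sequences (6 F / 16 S) — plus 3 PSMB5 decoys and 3 random contigs,
with μ = 0.02.

What the simulations do **not** contain: read-level noise, assembly
artifacts (chimeras, fragmentation), expression variation, intron-derived
sequence, alternative paralogs beyond the single decoy family, and real
hierarchical population structure within cohorts (haplotypes radiate from
the lineage template). Passing recovery tests therefore demonstrates
correctness of the screening/typing/phylogeny logic under the stated noise
model, not robustness to assembly pathology.

## Problem sizes and numeric choices

The shipped tests and the acceptance script run the full pipeline on ~63
contig transcriptomes (57 PSMB8), with 200 bootstrap replicates for the
monophyly analyses and single-replicate trees inside the 20-seed recovery
loops (bootstrap resampling does not influence type, codon or lineage
calls); the aligner oracle checks are exhaustive over all sequence pairs of
length ≤ 3 over a 4-letter alphabet plus a seeded sample up to length 6.
Alignment scores are integer-valued and exact in float64, so traceback
equality comparisons are safe. Newick output carries branch lengths at 6
decimals and supports as internal node labels; tips are quoted only when
they contain whitespace. Default bootstrap: 200 replicates, seed 42; all
pipeline randomness flows from the single configured seed.
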