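# psmb8kit

Typing and lineage analysis of **PSMB8**, the inducible catalytic β5i subunit
of the vertebrate immunoproteasome, from assembled transcript contigs.

PSMB8 is unusual among immune genes: it persists as two ancient allelic
clades — the **A lineage** and the **F lineage** — maintained by trans-species
polymorphism since early vertebrate evolution. The residue at position 31 of
the mature protein sits in the substrate-binding S1 pocket and defines the
functional *type*: A-type (A31/V31, small side chains), F-type (F31/Y31,
aromatic), plus the more recently described S-type (S31, or the structurally
equivalent T31) and K-type (K31, uniquely charged) found in holostean fishes
(gars and bowfins). Type and lineage are distinct axes — a type can re-arise
by point mutation inside the other lineage — so lineage must be diagnosed
either from eight diagnostic residues (mature positions 13, 99, 147, 150,
156, 188, 189, 194) or from phylogenetic clade membership. This package
implements the whole workflow and a synthetic-transcriptome generator so
every stage is testable without sequence downloads.

## What it does

1. **Screen** (`psmb8kit.screen`): six-frame ORF enumeration over contigs,
   local alignment (BLOSUM62, affine gaps) against a bundled reference panel
   of PSMB8 exemplars and PSMB5 decoys, score/identity thresholds, detection
   of the mature-protein start at the conserved TTTL cleavage motif
   (Thr1 = mature position 1), and QC filters: PSMB5 paralogs flagged,
   no-TTTL, truncation before residue 31, undefined residue 31 (including
   indel-caused gap mapping through a reference alignment), and per-species
   deduplication of identical mature proteins.
2. **Typing** (`psmb8kit.typing`): residue-31 type call, codon usage at the
   focal codon, S1-pocket residue profile (positions 20, 31, 35, 45, 49, 53
   plus the catalytic Thr1) with biochemical annotations, diagnostic-residue
   lineage classification against the A and F reference profiles, and
   per-group conservation summaries.
3. **Phylogeny** (`psmb8kit.phylo`): progressive protein MSA, p- or
   Poisson-corrected distances, neighbor joining, nonparametric bootstrap,
   PSMB5 outgroup rooting, and lineage assignment by clade membership.
4. **Pipeline + CLI** (`psmb8kit.pipeline`, `psmb8kit` command): orchestrates
   screen → typing → codon analysis → phylogeny and writes TSV/Newick/JSON
   reports. Both lineage classifiers always run; disagreements are surfaced,
   with clade membership as the recommended call.
5. **Simulation** (`psmb8kit.synthetic_data`): mock transcriptomes with
   per-contig truth tables — configurable residue-31 identity and codon,
   lineage-diagnostic profiles, substitution rate, deletions spanning
   codon 31, UTRs, PSMB5-like decoys and random contigs.

## Worked example

Simulate a transcriptome with the study-like cohort structure (35 gar
A-lineage sequences split 8 A-type / 24 S-type(T31) / 3 K-type; 22 bowfin
F-lineage sequences split 6 F-type / 16 S-type), then run the pipeline:

```sh
psmb8kit simulate --seed 7 --outdir demo
psmb8kit run --contigs demo/contigs.fasta --outdir demo/report --seed 42
psmb8kit summarize --report-dir demo/report
```

prints

```
wrote 63 contigs to demo/contigs.fasta
counts: {'contigs_in': 63, 'candidates': 60, 'kept': 57, 'rejected': 3}
 group lineage type_label  count
Amical       F          F      6
Amical       F          S     16
Leposs       A          A      8
Leposs       A          K      3
Leposs       A          S     24
```

Of 63 contigs, 60 hit the reference panel, the 3 PSMB5 decoys are flagged and
excluded, and all 57 PSMB8 sequences are recovered with their simulated type
and lineage. The typing table carries one row per kept sequence:

```
seq_id       group   residue31  type_label  codon31  matches_A  matches_F  lineage_diagnostic  s1_pocket                      lineage_clade  lineage_agreement
Amical_0008  Amical  S          S           TCT      0          8          F                   20:S 31:S 35:M 45:A 49:Q 53:G  F              True
```

and the codon-usage table shows the focal-codon conservation pattern — a
single codon per (group, type): TCT for bowfin serines, ACC for gar
threonines, AAG for gar lysines:

```
group   type_label  codon31  count  conserved
Amical  F           TTC      6      True
Amical  S           TCT      16     True
Leposs  A           GCC      8      True
Leposs  K           AAG      3      True
Leposs  S           ACC      24     True
```

`demo/report/tree.nwk` holds the bootstrap-annotated, PSMB5-rooted NJ tree in
which the A- and F-lineage clades are each monophyletic.

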