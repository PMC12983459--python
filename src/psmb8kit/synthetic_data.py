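"""Synthetic transcriptome generator with per-contig truth tables.

Emulates the structure of holostean immune-tissue transcriptome assemblies as
the screening pipeline sees them: contigs carrying a PSMB8 ORF (signal/pro-
peptide, the TTTL mature start, a configurable residue-31 type and codon, and
lineage-diagnostic residues), PSMB5-like decoy paralogs, and random
background contigs — flanked by UTRs and optionally hit by a deletion
spanning codon 31.

All template sequences are synthetic, pinned constants: they reproduce the
*architecture* of PSMB8 (motifs, diagnostic positions, paralog distance),
not any real species' sequence. Diagnostic and S1-pocket codons are excluded
from mutation so the truth labels stay well-defined at every substitution
rate.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Dict, List, Tuple

import pandas as pd

from .screen import TTTL
from .seqio import SeqRecord, translate
from .typing import (
    A_LINEAGE_REFERENCE,
    DIAGNOSTIC_POSITIONS,
    F_LINEAGE_REFERENCE,
    S1_POCKET_POSITIONS,
)

__all__ = [
    "GroupSpec",
    "SimSpec",
    "TruthRecord",
    "make_templates",
    "simulate_sequence",
    "simulate_transcriptome",
    "study_mirror_spec",
    "PROPEPTIDE",
    "A_MATURE",
    "F_MATURE",
    "DECOY_PRECURSOR",
]

# --- pinned synthetic templates (architecture-faithful, not real sequences) ---

PROPEPTIDE = "MDAPVIKLGEQYIKVDGANM"  # 20 residues; Met start
A_MATURE = (
    "TTTLLSERDFAEIQPYIVQSSNHTYPVKGTAGNYMDVAQPIIMAAEGAQEAMGYLSRLHVTHVDFSESQSLPD"
    "QRQLCTPFKLTYPMRPQWRDENPEASFGSEQVNSAKPLEALILRKRVLCFEQISINEFSGEVMLDFEVVGYQN"
    "MGSESVIGKGAQRRRYADGRGAISISEPTVTGFMLGTVLYWCKDYETEHQRDGGGHRG"
)
F_MATURE = (
    "TTTLLSERDFAEMQPYIVQSTNHGYPVKGTFYNYMDVAQPIIMAAEGAQEAMGYLSRLNVTHVDFSESQSLPD"
    "IIQLCTPFKLTYPMRPQWRQENPEATFGSEQVNSAKPLEALILRKRHPCFEQISDNEFSGEVMLDFEVCGYQN"
    "LGSPSVIGDAAQRDRYARFRGWIMGSDPTVTGFMQGTVLYWSQDYATDHQRDGGGHRG"
)
DECOY_PRECURSOR = (
    "MDYGNIKLGVESIKDQWANMTTTQLEGRYFAEVCPYSVDVQPDGYPVKGSAYTQMDVAQPRIMWLEQRQEQAG"
    "YLGQLHVILVVPWDSQSLPDIVQVYTPIWCTKPVESQWRQENPAGSCGSEQGESYKLLKDLILIKRHLCFEQI"
    "FDNDISKEDMLVFCVSLYNRLCSETVHGDGATRDRYADFPGAWMCSDPTQLWFMLGTVLYWSKDYATSHQRDG"
    "GAHVG"
)

#: fixed codon choice per amino acid used to reverse-translate templates
PREFERRED_CODON = {
    "A": "GCC", "R": "AGA", "N": "AAC", "D": "GAC", "C": "TGC", "Q": "CAG",
    "E": "GAG", "G": "GGA", "H": "CAC", "I": "ATC", "L": "CTG", "K": "AAG",
    "M": "ATG", "F": "TTC", "P": "CCA", "S": "AGC", "T": "ACA", "W": "TGG",
    "Y": "TAC", "V": "GTG",
}

_TYPE_RESIDUES = {"A": "AV", "F": "FY", "S": "ST", "K": "K"}
_STOPS = ("TAA", "TAG", "TGA")
PROPEPTIDE_LEN = len(PROPEPTIDE)


@dataclass(frozen=True)
class GroupSpec:
    """One simulated cohort: a species/population tag with a fixed truth label."""

    group: str
    n: int
    lineage: str  # A or F
    type_label: str  # A, F, S, K or other
    codon31: str
    mu: float = 0.02
    indel_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.lineage not in ("A", "F"):
            raise ValueError(f"lineage must be A or F, got {self.lineage!r}")
        if not (0.0 <= self.mu <= 0.3):
            raise ValueError("mu must be within [0, 0.3]")
        aa = translate(self.codon31)
        expected = _TYPE_RESIDUES.get(self.type_label)
        if expected is not None and aa not in expected:
            raise ValueError(
                f"codon31 {self.codon31} encodes {aa}, inconsistent with "
                f"type {self.type_label}"
            )


@dataclass(frozen=True)
class SimSpec:
    groups: Tuple[GroupSpec, ...]
    decoys: int = 3
    random_contigs: int = 3
    utr_len: int = 80
    seed: int = 0


@dataclass(frozen=True)
class TruthRecord:
    contig_id: str
    group: str
    orf_start: int
    orf_end: int
    strand: str
    mature_start: int  # 0-based index of Thr1 within the precursor protein
    lineage: str
    type_label: str
    residue31: str
    codon31: str
    diagnostic: str  # residues at the 8 diagnostic positions, joined
    is_decoy: bool
    has_indel: bool = False


def _to_cdna(protein: str) -> str:
    return "".join(PREFERRED_CODON[a] for a in protein) + "TAA"


def make_templates() -> Dict[str, Dict[str, str]]:
    """The pinned A-lineage, F-lineage and PSMB5-like decoy templates.

    Returns per-template the precursor protein and its cDNA. The A template
    carries the A-lineage diagnostic residues, the F template the F-lineage
    ones; the decoy sits at roughly 55% identity to both and has no TTTL.
    """
    a_precursor = PROPEPTIDE + A_MATURE
    f_precursor = PROPEPTIDE + F_MATURE
    for precursor, ref in (
        (a_precursor, A_LINEAGE_REFERENCE),
        (f_precursor, F_LINEAGE_REFERENCE),
    ):
        assert precursor.index(TTTL) == PROPEPTIDE_LEN
        for pos, res in ref.items():
            assert precursor[PROPEPTIDE_LEN + pos - 1] == res
    assert TTTL not in DECOY_PRECURSOR
    return {
        "A": {"precursor": a_precursor, "cdna": _to_cdna(a_precursor)},
        "F": {"precursor": f_precursor, "cdna": _to_cdna(f_precursor)},
        "decoy": {"precursor": DECOY_PRECURSOR, "cdna": _to_cdna(DECOY_PRECURSOR)},
    }


def _protected_codons(n_codons: int) -> set[int]:
    """Codon indices (0-based, over the precursor) excluded from mutation."""
    protected = {0, n_codons - 1}  # Met start and stop codon
    protected |= {PROPEPTIDE_LEN + p - 1 for p in range(1, 5)}  # TTTL
    protected |= {PROPEPTIDE_LEN + p - 1 for p in DIAGNOSTIC_POSITIONS}
    protected |= {PROPEPTIDE_LEN + p - 1 for p in S1_POCKET_POSITIONS}
    return protected


def _random_utr(rng: random.Random, length: int) -> str:
    """Random UTR, scrubbed of ATG so it cannot introduce upstream starts."""
    utr = "".join(rng.choice("ACGT") for _ in range(length))
    while "ATG" in utr:
        i = utr.index("ATG")
        utr = utr[: i + 2] + "C" + utr[i + 3 :]
    return utr


def simulate_sequence(
    entry: GroupSpec, index: int, rng: random.Random, utr_len: int = 80
) -> Tuple[SeqRecord, TruthRecord]:
    """One PSMB8-bearing contig plus its truth row.

    Substitutions are nucleotide-level at rate ``mu`` per unconstrained site
    with a 2:1 third-codon-position bias (more synonymous than nonsynonymous
    changes without a full codon model); draws creating a stop codon are
    rejected and redrawn. With probability ``indel_prob`` the six nucleotides
    of mature codons 30–31 are deleted, removing residue 31 while preserving
    frame — the situation that leaves the type undefined.
    """
    templates = make_templates()
    cdna = templates[entry.lineage]["cdna"]
    codons = [cdna[i : i + 3] for i in range(0, len(cdna), 3)]
    codon31_idx = PROPEPTIDE_LEN + 30
    codons[codon31_idx] = entry.codon31.upper()

    protected = _protected_codons(len(codons))
    # per-site substitution probabilities: (p1+p2+p3)/3 = mu with p3 = 2 p1
    p12 = min(1.0, 0.75 * entry.mu)
    p3 = min(1.0, 1.5 * entry.mu)
    for ci in range(len(codons)):
        if ci in protected:
            continue
        codon = list(codons[ci])
        for pos, p in ((0, p12), (1, p12), (2, p3)):
            if rng.random() < p:
                choices = [b for b in "ACGT" if b != codon[pos]]
                for base in rng.sample(choices, len(choices)):
                    trial = codon.copy()
                    trial[pos] = base
                    if "".join(trial) not in _STOPS:
                        codon[pos] = base
                        break
        codons[ci] = "".join(codon)

    has_indel = rng.random() < entry.indel_prob
    if has_indel:
        del codons[codon31_idx - 1 : codon31_idx + 1]  # mature codons 30 and 31

    cds = "".join(codons)
    precursor = translate(cds)[:-1]
    # a substitution may have forged an earlier TTTL, invalidating the truth
    # coordinates; scrub it back to the template residue
    while precursor.find(TTTL) != PROPEPTIDE_LEN:
        i = precursor.find(TTTL)
        template_codon = _to_cdna(templates[entry.lineage]["precursor"])[
            3 * i : 3 * i + 3
        ]
        codons[i] = template_codon
        cds = "".join(codons)
        precursor = translate(cds)[:-1]

    utr5 = _random_utr(rng, utr_len)
    utr3 = _random_utr(rng, utr_len)
    contig_seq = utr5 + cds + utr3
    contig_id = f"{entry.group}_{index:04d}"
    record = SeqRecord(
        id=contig_id, seq=contig_seq, moltype="nucleotide", group=entry.group
    )
    mature = precursor[PROPEPTIDE_LEN:]
    truth = TruthRecord(
        contig_id=contig_id,
        group=entry.group,
        orf_start=len(utr5),
        orf_end=len(utr5) + len(cds),
        strand="+",
        mature_start=PROPEPTIDE_LEN,
        lineage=entry.lineage,
        type_label="undefined" if has_indel else entry.type_label,
        residue31="" if has_indel else mature[30],
        codon31="" if has_indel else entry.codon31.upper(),
        diagnostic="".join(
            mature[p - 1] if p <= len(mature) else "-" for p in DIAGNOSTIC_POSITIONS
        ),
        is_decoy=False,
        has_indel=has_indel,
    )
    return record, truth


def _simulate_decoy(
    index: int, rng: random.Random, utr_len: int
) -> Tuple[SeqRecord, TruthRecord]:
    cdna = make_templates()["decoy"]["cdna"]
    utr5, utr3 = _random_utr(rng, utr_len), _random_utr(rng, utr_len)
    contig_id = f"decoy_{index:04d}"
    rec = SeqRecord(
        id=contig_id, seq=utr5 + cdna + utr3, moltype="nucleotide", group="decoy"
    )
    truth = TruthRecord(
        contig_id=contig_id,
        group="decoy",
        orf_start=len(utr5),
        orf_end=len(utr5) + len(cdna),
        strand="+",
        mature_start=-1,
        lineage="",
        type_label="",
        residue31="",
        codon31="",
        diagnostic="",
        is_decoy=True,
    )
    return rec, truth


def simulate_transcriptome(
    spec: SimSpec,
) -> Tuple[List[SeqRecord], pd.DataFrame]:
    """All group contigs, decoys and random contigs, deterministically shuffled.

    Returns the contig records and a truth table with one row per contig
    (random contigs appear with empty labels and ``is_decoy`` False).
    """
    rng = random.Random(spec.seed)
    contigs: List[SeqRecord] = []
    truths: List[TruthRecord] = []
    counters: Dict[str, int] = {}
    seen_matures: Dict[str, set] = {}
    for entry in spec.groups:
        for _ in range(entry.n):
            idx = counters.get(entry.group, 0)
            counters[entry.group] = idx + 1
            rec, truth = simulate_sequence(entry, idx, rng, utr_len=spec.utr_len)
            if entry.mu > 0 and not truth.has_indel:
                # distinct haplotypes within a group (identical transcripts are
                # collapsed upstream of assembly in the emulated design)
                mature = translate(rec.seq[truth.orf_start : truth.orf_end])[
                    truth.mature_start : -1
                ]
                pool = seen_matures.setdefault(entry.group, set())
                tries = 0
                while mature in pool and tries < 100:
                    rec, truth = simulate_sequence(entry, idx, rng, utr_len=spec.utr_len)
                    mature = translate(rec.seq[truth.orf_start : truth.orf_end])[
                        truth.mature_start : -1
                    ]
                    tries += 1
                pool.add(mature)
            contigs.append(rec)
            truths.append(truth)
    for i in range(spec.decoys):
        rec, truth = _simulate_decoy(i, rng, spec.utr_len)
        contigs.append(rec)
        truths.append(truth)
    for i in range(spec.random_contigs):
        seq = "".join(rng.choice("ACGT") for _ in range(500))
        contig_id = f"random_{i:04d}"
        contigs.append(
            SeqRecord(id=contig_id, seq=seq, moltype="nucleotide", group="random")
        )
        truths.append(
            TruthRecord(
                contig_id=contig_id,
                group="random",
                orf_start=-1,
                orf_end=-1,
                strand="",
                mature_start=-1,
                lineage="",
                type_label="",
                residue31="",
                codon31="",
                diagnostic="",
                is_decoy=False,
            )
        )
    order = list(range(len(contigs)))
    rng.shuffle(order)
    contigs = [contigs[i] for i in order]
    truths = [truths[i] for i in order]
    table = pd.DataFrame([t.__dict__ for t in truths])
    return contigs, table


def study_mirror_spec(seed: int = 0, mu: float = 0.02, indel_prob: float = 0.0) -> SimSpec:
    """A spec mirroring the study's cohort structure.

    29 longnose gar yielded 35 A-lineage sequences (8 A type, 24 S type with
    T31 encoded by ACC, 3 K type with AAG); 16 bowfin yielded 22 F-lineage
    sequences (6 F type, 16 S type with TCT). Group tags follow the
    species-abbreviation style of the display identifiers.
    """
    return SimSpec(
        groups=(
            GroupSpec("Leposs", 8, "A", "A", "GCC", mu=mu, indel_prob=indel_prob),
            GroupSpec("Leposs", 24, "A", "S", "ACC", mu=mu, indel_prob=indel_prob),
            GroupSpec("Leposs", 3, "A", "K", "AAG", mu=mu, indel_prob=indel_prob),
            GroupSpec("Amical", 6, "F", "F", "TTC", mu=mu, indel_prob=indel_prob),
            GroupSpec("Amical", 16, "F", "S", "TCT", mu=mu, indel_prob=indel_prob),
        ),
        decoys=3,
        random_contigs=3,
        utr_len=80,
        seed=seed,
    )
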