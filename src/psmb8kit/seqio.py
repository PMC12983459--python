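"""Sequence records, FASTA I/O, translation and ORF enumeration.

Conventions used throughout the package:

* coordinates are 0-based, half-open, on the forward strand of the input
  contig;
* minus-strand ORFs report forward-strand coordinates while ``nt_seq`` holds
  the reverse-complement slice (the reading-direction sequence);
* the standard genetic code only — every taxon this package targets is a
  vertebrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List

from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "SeqRecord",
    "Orf",
    "FastaFormatError",
    "read_fasta",
    "write_fasta",
    "translate",
    "reverse_complement",
    "find_orfs",
]

# IUPAC alphabets; ambiguity codes are legal input for nucleotides, X for protein.
NUCLEOTIDE_ALPHABET = frozenset("ACGTNRYSWKMBDHV")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)  # {TAA, TAG, TGA}

_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHVacgtnryswkmbdhv", "TGCANYRSWMKVHDBtgcanyrswmkvhdb"
)


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input (bad header, alphabet, duplicate id)."""


@dataclass(frozen=True)
class SeqRecord:
    """A named sequence with an optional group (species/population) tag.

    The group tag is parsed from the FASTA header as the text after the first
    ``|``; headers without a ``|`` get an empty group.
    """

    id: str
    seq: str
    moltype: str = "nucleotide"  # or "protein"
    group: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaFormatError("record id must be nonempty")
        if not self.seq:
            raise FastaFormatError(f"record {self.id!r}: sequence is empty")
        alphabet = (
            NUCLEOTIDE_ALPHABET if self.moltype == "nucleotide" else PROTEIN_ALPHABET
        )
        bad = set(self.seq) - alphabet
        if bad:
            raise FastaFormatError(
                f"record {self.id!r}: illegal {self.moltype} character(s) "
                f"{''.join(sorted(bad))!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Orf:
    """An open reading frame on a contig.

    ``start``/``end`` are forward-strand, 0-based, half-open; ``frame`` is the
    reading frame on the strand the ORF was read from; ``nt_seq`` runs in
    reading direction (ATG ... stop) and ``protein`` is its translation minus
    the terminal stop.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    frame: int
    nt_seq: str = field(repr=False)
    protein: str = field(repr=False)

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF span must be a multiple of 3")
        if not self.nt_seq.startswith("ATG"):
            raise ValueError("ORF must begin with ATG")
        if self.nt_seq[-3:] not in STOP_CODONS:
            raise ValueError("ORF must end with a stop codon")
        if len(self.protein) != (self.end - self.start) // 3 - 1:
            raise ValueError("protein length inconsistent with ORF span")


def read_fasta(path: str | Path, moltype: str = "nucleotide") -> List[SeqRecord]:
    """Read a (possibly empty) multi-record FASTA file.

    Sequences are upper-cased and validated against the declared alphabet;
    duplicate ids and illegal characters raise :class:`FastaFormatError`
    naming the offending record.
    """
    if moltype not in ("nucleotide", "protein"):
        raise ValueError(f"unknown moltype {moltype!r}")
    records: List[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description or rec.id
        rec_id = header.split("|")[0].split()[0] if header else ""
        group = header.split("|", 1)[1].strip() if "|" in header else ""
        if not rec_id:
            raise FastaFormatError(f"{path}: record with empty id")
        if rec_id in seen:
            raise FastaFormatError(f"{path}: duplicate record id {rec_id!r}")
        seen.add(rec_id)
        records.append(
            SeqRecord(id=rec_id, seq=str(rec.seq).upper(), moltype=moltype, group=group)
        )
    return records


def write_fasta(
    records: Iterable[SeqRecord], path: str | Path, width: int = 60
) -> None:
    """Write records as FASTA, wrapped at ``width`` columns.

    Headers are ``id`` or ``id|group`` when a group tag is present, so
    :func:`read_fasta` round-trips both fields.
    """
    with open(path, "w") as fh:
        for rec in records:
            header = f"{rec.id}|{rec.group}" if rec.group else rec.id
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def reverse_complement(nt: str) -> str:
    return nt.translate(_COMPLEMENT)[::-1]


def translate(nt: str, frame: int = 0) -> str:
    """Translate ``nt`` from ``frame`` with the standard genetic code.

    Stops render as ``*``; a trailing partial codon is dropped; any codon
    containing an ambiguity code renders as ``X``.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    out: list[str] = []
    for i in range(frame, len(nt) - 2, 3):
        codon = nt[i : i + 3].upper()
        if codon in _CODON_TO_AA:
            out.append(_CODON_TO_AA[codon])
        elif codon in STOP_CODONS:
            out.append("*")
        else:
            out.append("X")
    return "".join(out)


def _scan_strand(seq: str, min_protein_len: int) -> list[tuple[int, int, int]]:
    """All maximal ATG..stop spans on one strand: (start, end, frame) local coords.

    Per (frame, stop) group only the 5'-most ATG is reported, i.e. nested ORFs
    collapse to the longest.
    """
    spans: list[tuple[int, int, int]] = []
    n = len(seq)
    for frame in range(3):
        start: int | None = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if start is not None and (i + 3 - start) // 3 - 1 >= min_protein_len:
                    spans.append((start, i + 3, frame))
                start = None
            elif codon == "ATG" and start is None:
                start = i
    return spans


def find_orfs(contig: SeqRecord, min_protein_len: int = 1) -> List[Orf]:
    """Enumerate ATG-to-stop ORFs on both strands of a nucleotide contig.

    Results are sorted by descending protein length, then forward-strand
    offset, then strand (``+`` before ``-``).
    """
    if contig.moltype != "nucleotide":
        raise ValueError(f"contig {contig.id!r} is not nucleotide")
    n = len(contig.seq)
    orfs: list[Orf] = []
    for strand, seq in (("+", contig.seq), ("-", reverse_complement(contig.seq))):
        for s, e, frame in _scan_strand(seq, min_protein_len):
            nt_seq = seq[s:e]
            prot = translate(nt_seq)
            if strand == "+":
                start, end = s, e
            else:
                start, end = n - e, n - s
            orfs.append(
                Orf(
                    contig_id=contig.id,
                    start=start,
                    end=end,
                    strand=strand,
                    frame=frame,
                    nt_seq=nt_seq,
                    protein=prot[:-1],
                )
            )
    orfs.sort(key=lambda o: (-len(o.protein), o.start, o.strand))
    return orfs
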