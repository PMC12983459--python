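"""Reference-guided screening of contigs for PSMB8 candidate ORFs.

The screen mirrors a transcriptome BLAST search: every ORF above a length
floor is locally aligned against a reference panel (PSMB8 exemplars of both
allelic lineages plus PSMB5 decoys), and hits are retained on a
score-and-identity threshold. Candidates whose best reference is the
constitutive paralog PSMB5 are kept but flagged so downstream stages can
exclude them.

Maturation uses the conserved TTTL (Thr-Thr-Thr-Leu) motif that marks the
propeptide cleavage site: the first residue of the mature protein is the
catalytic Thr1, and every mature-coordinate convention in this package counts
from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

from .align import ScoringScheme, blosum62_scheme, map_ref_position, pairwise_align, percent_identity
from .seqio import Orf, SeqRecord, find_orfs

__all__ = [
    "ScreenConfig",
    "Candidate",
    "MatureMap",
    "Rejection",
    "screen_candidates",
    "detect_mature_start",
    "determine_position31",
    "apply_qc",
    "write_rejection_log",
]

TTTL = "TTTL"
#: propeptides of proteasome beta subunits are short; the motif search window
#: keeps spurious internal TTTL matches out.
DEFAULT_TTTL_WINDOW = 90


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and reference panel for the candidate screen.

    ``references`` carry their family in the record ``group`` tag
    ("PSMB8" or "PSMB5"); at least one PSMB5 decoy is required so paralogs are
    flagged rather than silently absorbed.
    """

    references: Tuple[SeqRecord, ...]
    min_score: int = 100
    min_identity: float = 0.40
    min_protein_len: int = 50
    tttl_window: int = DEFAULT_TTTL_WINDOW
    scheme: ScoringScheme = field(default_factory=blosum62_scheme)

    def __post_init__(self) -> None:
        if self.min_score <= 0 or self.min_identity <= 0 or self.min_protein_len <= 0:
            raise ValueError("screen thresholds must be positive")
        if not self.references:
            raise ValueError("reference panel is empty")
        families = {r.group.split(";")[0] for r in self.references}
        if "PSMB5" not in families:
            raise ValueError("reference panel must include a PSMB5 decoy reference")


@dataclass(frozen=True)
class Candidate:
    orf: Orf
    best_ref: str
    score: float
    identity: float
    best_ref_family: str
    group: str = ""


@dataclass(frozen=True)
class MatureMap:
    """Links a precursor protein to mature-protein numbering (Thr1 = 1)."""

    precursor: str
    mature_start: int

    def __post_init__(self) -> None:
        if self.precursor[self.mature_start : self.mature_start + 4] != TTTL:
            raise ValueError("mature_start does not point at a TTTL motif")

    @property
    def mature(self) -> str:
        return self.precursor[self.mature_start :]

    def residue(self, mature_pos: int) -> str | None:
        """Residue at a 1-based mature position, None past the end."""
        if mature_pos < 1:
            raise ValueError("mature positions are 1-based")
        idx = self.mature_start + mature_pos - 1
        if idx >= len(self.precursor):
            return None
        return self.precursor[idx]


@dataclass(frozen=True)
class Rejection:
    seq_id: str
    group: str
    reason: str
    detail: str = ""


def screen_candidates(
    contigs: Sequence[SeqRecord], cfg: ScreenConfig
) -> List[Candidate]:
    """Local-align every qualifying ORF against the reference panel.

    Each ORF is scored against all references and keeps its best hit; the ORF
    is retained iff that hit reaches both ``cfg.min_score`` and
    ``cfg.min_identity``. The family of the best reference decides the
    ``best_ref_family`` flag.
    """
    candidates: List[Candidate] = []
    for contig in contigs:
        for orf in find_orfs(contig, cfg.min_protein_len):
            query = SeqRecord(
                id=contig.id, seq=orf.protein.replace("*", "X"), moltype="protein"
            )
            best: tuple[float, float, SeqRecord] | None = None
            for ref in cfg.references:
                aln = pairwise_align(query, ref, cfg.scheme, mode="local")
                ident = percent_identity(aln)
                if best is None or (aln.score, ident) > (best[0], best[1]):
                    best = (aln.score, ident, ref)
            score, ident, ref = best
            if score >= cfg.min_score and ident >= cfg.min_identity:
                candidates.append(
                    Candidate(
                        orf=orf,
                        best_ref=ref.id,
                        score=score,
                        identity=ident,
                        best_ref_family=ref.group.split(";")[0],
                        group=contig.group,
                    )
                )
    return candidates


def detect_mature_start(
    precursor: str, window: int = DEFAULT_TTTL_WINDOW
) -> MatureMap | Rejection:
    """Locate the mature-protein start at the first TTTL within ``window``.

    Returns a :class:`Rejection` (reason ``no_TTTL``) rather than raising when
    the motif is absent — exclusion is an expected outcome, not an error.
    """
    if not precursor:
        raise ValueError("empty precursor")
    idx = precursor.find(TTTL, 0, window + len(TTTL) - 1)
    if idx == -1:
        return Rejection(seq_id="", group="", reason="no_TTTL")
    return MatureMap(precursor=precursor, mature_start=idx)


def determine_position31(
    map_: MatureMap,
    reference_mature: str,
    scheme: ScoringScheme | None = None,
) -> int | None:
    """Mature position aligning to reference mature position 31, or None.

    Insertions or deletions around the S1 pocket can leave the 31st position
    without a residue (the denticle-herring situation); mapping through a
    global alignment with a reference detects this, where naive positional
    indexing would silently read a shifted residue.
    """
    query = SeqRecord(id="query", seq=map_.mature.replace("*", "X"), moltype="protein")
    ref = SeqRecord(id="ref", seq=reference_mature, moltype="protein")
    aln = pairwise_align(ref, query, scheme or blosum62_scheme(), mode="global")
    return map_ref_position(aln, "ref", 31, "query")


def apply_qc(
    candidates: Sequence[Candidate],
    maps: Dict[str, MatureMap | Rejection],
    position31: Dict[str, int | None] | None = None,
) -> Tuple[List[Tuple[Candidate, MatureMap]], List[Rejection]]:
    """Apply the exclusion rules, in fixed order, to screened candidates.

    Order of checks (each rejection carries the first failing reason):
    ``decoy_family`` (best reference is PSMB5), ``no_TTTL``,
    ``truncated_before_31`` (mature shorter than 31 residues),
    ``undefined_31`` (residue 31 is X, or maps to a gap per ``position31``),
    ``duplicate`` (identical mature protein within the same group tag; the
    first candidate by id is kept).

    ``maps`` is keyed by contig id; ``position31`` optionally supplies the
    alignment-mapped mature position of residue 31 (None meaning gap-mapped).
    """
    kept: List[Tuple[Candidate, MatureMap]] = []
    rejected: List[Rejection] = []
    seen_mature: Dict[Tuple[str, str], str] = {}
    for cand in candidates:
        cid = cand.orf.contig_id
        if cand.best_ref_family == "PSMB5":
            rejected.append(
                Rejection(cid, cand.group, "decoy_family", f"best_ref={cand.best_ref}")
            )
            continue
        m = maps.get(cid)
        if m is None or isinstance(m, Rejection):
            rejected.append(Rejection(cid, cand.group, "no_TTTL"))
            continue
        if len(m.mature) < 31:
            rejected.append(
                Rejection(
                    cid, cand.group, "truncated_before_31", f"mature_len={len(m.mature)}"
                )
            )
            continue
        pos31 = 31 if position31 is None else position31.get(cid, 31)
        if pos31 is None or m.residue(pos31) in (None, "X"):
            rejected.append(
                Rejection(
                    cid,
                    cand.group,
                    "undefined_31",
                    "gap_mapped" if pos31 is None else "residue_X",
                )
            )
            continue
        key = (cand.group, m.mature)
        if key in seen_mature:
            rejected.append(
                Rejection(cid, cand.group, "duplicate", f"same_as={seen_mature[key]}")
            )
            continue
        seen_mature[key] = cid
        kept.append((cand, m))
    return kept, rejected


def write_rejection_log(rejections: Sequence[Rejection], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tgroup\treason\tdetail\n")
        for r in rejections:
            fh.write(f"{r.seq_id}\t{r.group}\t{r.reason}\t{r.detail}\n")
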