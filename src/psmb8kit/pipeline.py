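"""End-to-end orchestration: screen → typing → codon usage → phylogeny → report.

The pipeline reports lineage from BOTH classifiers — the diagnostic-residue
match count and phylogenetic clade membership — and surfaces disagreements in
an agreement column instead of reconciling them; clade membership is the
recommended call when the two differ, since diagnostic residues can be
homoplasious while clade membership reflects descent.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import __version__
from .align import blosum62_scheme, progressive_msa
from .phylo import assign_lineage_by_clade, bootstrap_support, root_with_outgroup
from .screen import (
    Candidate,
    MatureMap,
    Rejection,
    ScreenConfig,
    apply_qc,
    detect_mature_start,
    determine_position31,
    screen_candidates,
    write_rejection_log,
)
from .seqio import SeqRecord, read_fasta
from .typing import (
    LineageProfile,
    TypeCall,
    call_type,
    classify_lineage,
    codon_usage_summary,
    conservation_summary,
    diagnostic_profile,
    s1_pocket,
)

__all__ = ["RunConfig", "Report", "default_references", "run", "summarize_types"]


def default_references() -> List[SeqRecord]:
    """The bundled reference panel (synthetic exemplars).

    Group tags encode family and lineage: ``PSMB8;A``, ``PSMB8;F`` or
    ``PSMB5``. Two exemplars per PSMB8 lineage anchor clade assignment; three
    PSMB5 records serve as screening decoys and the phylogenetic outgroup.
    """
    with resources.as_file(
        resources.files("psmb8kit").joinpath("data/references.fasta")
    ) as p:
        return read_fasta(p, moltype="protein")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run; exactly one input mode.

    ``contigs`` takes nucleotide transcript contigs through the full screen;
    ``mature_proteins`` takes already-matured protein sequences and skips the
    ORF/screen stages (codon fields then stay absent).
    """

    contigs: Optional[Sequence[SeqRecord]] = None
    mature_proteins: Optional[Sequence[SeqRecord]] = None
    references: Optional[Sequence[SeqRecord]] = None
    min_score: int = 100
    min_identity: float = 0.40
    min_protein_len: int = 50
    distance_model: str = "p"
    bootstrap_reps: int = 200
    seed: int = 42
    outdir: Optional[Path] = None

    def __post_init__(self) -> None:
        if (self.contigs is None) == (self.mature_proteins is None):
            raise ValueError("exactly one of contigs / mature_proteins is required")


@dataclass
class Report:
    typing_table: pd.DataFrame
    codon_usage: pd.DataFrame
    conservation: pd.DataFrame
    newick: str
    rejections: List[Rejection]
    meta: Dict

    def write(self, outdir: Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.typing_table.to_csv(outdir / "typing.tsv", sep="\t", index=False)
        self.codon_usage.to_csv(outdir / "codon_usage.tsv", sep="\t", index=False)
        self.conservation.to_csv(outdir / "conservation.tsv", sep="\t", index=False)
        (outdir / "tree.nwk").write_text(self.newick)
        write_rejection_log(self.rejections, outdir / "rejections.tsv")
        (outdir / "run_meta.json").write_text(json.dumps(self.meta, indent=2) + "\n")


def _pocket_string(profile) -> str:
    return " ".join(f"{p}:{r}" for p, r in profile.pocket.items())


def _screen_stage(
    contigs: Sequence[SeqRecord], cfg: RunConfig, references: Sequence[SeqRecord]
) -> Tuple[List[Tuple[Candidate, MatureMap, Optional[int]]], List[Rejection], Dict]:
    screen_cfg = ScreenConfig(
        references=tuple(references),
        min_score=cfg.min_score,
        min_identity=cfg.min_identity,
        min_protein_len=cfg.min_protein_len,
    )
    candidates = screen_candidates(contigs, screen_cfg)
    a_ref_mature = _reference_matures(references, "PSMB8;A")[0][1]
    maps: Dict[str, MatureMap | Rejection] = {}
    position31: Dict[str, Optional[int]] = {}
    for cand, _ in ((c, None) for c in candidates):
        cid = cand.orf.contig_id
        m = detect_mature_start(cand.orf.protein)
        maps[cid] = m
        if isinstance(m, MatureMap) and len(m.mature) >= 31:
            position31[cid] = determine_position31(m, a_ref_mature)
    kept_pairs, rejected = apply_qc(candidates, maps, position31)
    kept = [
        (cand, m, position31.get(cand.orf.contig_id, 31)) for cand, m in kept_pairs
    ]
    counts = {
        "contigs_in": len(contigs),
        "candidates": len(candidates),
        "kept": len(kept),
        "rejected": len(rejected),
    }
    return kept, rejected, counts


def _mature_stage(
    records: Sequence[SeqRecord], references: Sequence[SeqRecord]
) -> Tuple[List[Tuple[SeqRecord, MatureMap, Optional[int]]], List[Rejection]]:
    """QC for pre-matured protein input: same reasons, no ORF information."""
    a_ref_mature = _reference_matures(references, "PSMB8;A")[0][1]
    kept: List[Tuple[SeqRecord, MatureMap, Optional[int]]] = []
    rejected: List[Rejection] = []
    seen: Dict[Tuple[str, str], str] = {}
    for rec in records:
        m = detect_mature_start(rec.seq)
        if isinstance(m, Rejection):
            rejected.append(Rejection(rec.id, rec.group, "no_TTTL"))
            continue
        if len(m.mature) < 31:
            rejected.append(
                Rejection(rec.id, rec.group, "truncated_before_31",
                          f"mature_len={len(m.mature)}")
            )
            continue
        pos31 = determine_position31(m, a_ref_mature)
        if pos31 is None or m.residue(pos31) in (None, "X"):
            rejected.append(
                Rejection(rec.id, rec.group, "undefined_31",
                          "gap_mapped" if pos31 is None else "residue_X")
            )
            continue
        key = (rec.group, m.mature)
        if key in seen:
            rejected.append(
                Rejection(rec.id, rec.group, "duplicate", f"same_as={seen[key]}")
            )
            continue
        seen[key] = rec.id
        kept.append((rec, m, pos31))
    return kept, rejected


def _reference_matures(
    references: Sequence[SeqRecord], family_prefix: str
) -> List[Tuple[str, str]]:
    """(id, mature-or-trimmed sequence) for references in a family."""
    out = []
    for ref in references:
        if not ref.group.startswith(family_prefix):
            continue
        m = detect_mature_start(ref.seq)
        seq = m.mature if isinstance(m, MatureMap) else ref.seq[20:]
        out.append((ref.id, seq))
    if not out:
        raise ValueError(f"no references with family tag {family_prefix!r}")
    return out


def run(cfg: RunConfig) -> Report:
    """Execute the full workflow and assemble the report.

    Deterministic for a fixed config and seed; every input sequence ends up
    either in the typing table or in the rejection log.
    """
    references = list(cfg.references) if cfg.references else default_references()

    entries: List[Tuple[str, str, MatureMap, Optional[int], Optional[object]]] = []
    # (seq_id, group, map, position31, orf-or-None)
    if cfg.contigs is not None:
        kept, rejected, counts = _screen_stage(cfg.contigs, cfg, references)
        for cand, m, pos31 in kept:
            entries.append((cand.orf.contig_id, cand.group, m, pos31, cand.orf))
    else:
        kept_m, rejected = _mature_stage(cfg.mature_proteins, references)
        counts = {
            "proteins_in": len(cfg.mature_proteins),
            "kept": len(kept_m),
            "rejected": len(rejected),
        }
        for rec, m, pos31 in kept_m:
            entries.append((rec.id, rec.group, m, pos31, None))

    type_calls: List[TypeCall] = []
    profiles: List[LineageProfile] = []
    rows = []
    for seq_id, group, m, pos31, orf in entries:
        tc = call_type(m, seq_id, orf=orf, position31=pos31, group=group)
        type_calls.append(tc)
        profile = diagnostic_profile(m, seq_id, group=group)
        profiles.append(profile)
        lineage = classify_lineage(profile)
        try:
            pocket = _pocket_string(s1_pocket(m, seq_id))
        except ValueError:
            pocket = ""
        rows.append(
            {
                "seq_id": seq_id,
                "group": group,
                "residue31": tc.residue31 or "",
                "type_label": tc.type_label,
                "codon31": tc.codon31 or "",
                "matches_A": lineage.matches_A,
                "matches_F": lineage.matches_F,
                "lineage_diagnostic": lineage.call,
                "s1_pocket": pocket,
            }
        )
    typing_table = pd.DataFrame(
        rows,
        columns=[
            "seq_id", "group", "residue31", "type_label", "codon31",
            "matches_A", "matches_F", "lineage_diagnostic", "s1_pocket",
        ],
    )

    # phylogeny over kept matures + PSMB8 reference exemplars + PSMB5 outgroup
    psmb8_refs = _reference_matures(references, "PSMB8")
    psmb5_refs = _reference_matures(references, "PSMB5")
    ref_labels = {
        ref.id: ref.group.split(";")[1]
        for ref in references
        if ref.group.startswith("PSMB8;")
    }
    tip_records = [
        SeqRecord(id=seq_id, seq=m.mature.replace("*", "X"), moltype="protein")
        for seq_id, _, m, _, _ in entries
    ] + [
        SeqRecord(id=rid, seq=seq, moltype="protein")
        for rid, seq in psmb8_refs + psmb5_refs
    ]
    newick = ""
    clade_lineage: Dict[str, str] = {}
    if len(tip_records) >= 4:
        msa = progressive_msa(tip_records, blosum62_scheme())
        tree = bootstrap_support(
            msa, model=cfg.distance_model, n_reps=cfg.bootstrap_reps, seed=cfg.seed
        )
        tree = root_with_outgroup(tree, {rid for rid, _ in psmb5_refs})
        for seq_id, _, _, _, _ in entries:
            clade_lineage[seq_id] = assign_lineage_by_clade(tree, ref_labels, seq_id)
        newick = tree.as_string(schema="newick", suppress_rooting=True)

    if not typing_table.empty:
        typing_table["lineage_clade"] = [
            clade_lineage.get(s, "unresolved") for s in typing_table["seq_id"]
        ]
        typing_table["lineage_agreement"] = (
            typing_table["lineage_diagnostic"] == typing_table["lineage_clade"]
        )
    else:
        typing_table["lineage_clade"] = pd.Series(dtype=str)
        typing_table["lineage_agreement"] = pd.Series(dtype=bool)

    codon_table = codon_usage_summary(type_calls)
    conservation = conservation_summary(profiles)

    config_desc = {
        "min_score": cfg.min_score,
        "min_identity": cfg.min_identity,
        "min_protein_len": cfg.min_protein_len,
        "distance_model": cfg.distance_model,
        "bootstrap_reps": cfg.bootstrap_reps,
        "seed": cfg.seed,
    }
    meta = {
        "version": __version__,
        "config": config_desc,
        "config_hash": hashlib.sha256(
            json.dumps(config_desc, sort_keys=True).encode()
        ).hexdigest()[:16],
        "counts": counts,
    }
    report = Report(
        typing_table=typing_table,
        codon_usage=codon_table,
        conservation=conservation,
        newick=newick,
        rejections=rejected,
        meta=meta,
    )
    if cfg.outdir is not None:
        report.write(cfg.outdir)
    return report


def summarize_types(report: Report) -> pd.DataFrame:
    """Counts of sequences per (group, lineage, type).

    Lineage is the clade call where resolved, otherwise the diagnostic-residue
    call; undefined and other types are listed, never dropped.
    """
    if report.typing_table.empty:
        return pd.DataFrame(columns=["group", "lineage", "type_label", "count"])
    t = report.typing_table.copy()
    t["lineage"] = [
        clade if clade in ("A", "F") else diag
        for clade, diag in zip(t["lineage_clade"], t["lineage_diagnostic"])
    ]
    out = (
        t.groupby(["group", "lineage", "type_label"])
        .size()
        .reset_index(name="count")
        .sort_values(["group", "lineage", "type_label"])
        .reset_index(drop=True)
    )
    return out
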