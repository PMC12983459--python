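"""PSMB8 type calls, S1-pocket profiles, lineage classification, codon usage.

Biology in brief: the immunoproteasome subunit PSMB8 exists as two ancient
allelic lineages (A and F) maintained by trans-species polymorphism. The
residue at mature position 31 sits in the substrate-binding S1 pocket and
defines the functional *type*: A-type carries alanine or valine, F-type
phenylalanine or tyrosine, and holosteans add an S-type (serine or the
structurally equivalent threonine) and a K-type (lysine, uniquely charged).
Type (a residue) and lineage (a clade) are distinct — a type can be regained
by point mutation inside the other lineage — so lineage is diagnosed either
from eight diagnostic residues or from phylogenetic placement.

All positions are mature-protein coordinates with the catalytic Thr1 = 1
(the first T of the TTTL cleavage motif).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import pandas as pd

from .screen import MatureMap
from .seqio import Orf, translate

__all__ = [
    "DIAGNOSTIC_POSITIONS",
    "A_LINEAGE_REFERENCE",
    "F_LINEAGE_REFERENCE",
    "S1_POCKET_POSITIONS",
    "TypeCall",
    "S1PocketProfile",
    "LineageProfile",
    "LineageCall",
    "residue_to_type",
    "call_type",
    "codon_at",
    "codon_usage_summary",
    "s1_pocket",
    "diagnostic_profile",
    "classify_lineage",
    "conservation_summary",
]

#: Eight mature-protein positions whose residues discriminate the A and F
#: allelic lineages.
DIAGNOSTIC_POSITIONS: Tuple[int, ...] = (13, 99, 147, 150, 156, 188, 189, 194)

#: Reference residues of the A lineage at the diagnostic positions.
A_LINEAGE_REFERENCE: Dict[int, str] = dict(
    zip(DIAGNOSTIC_POSITIONS, ("I", "S", "M", "E", "G", "C", "K", "E"))
)

#: Reference residues of the F lineage at the diagnostic positions.
F_LINEAGE_REFERENCE: Dict[int, str] = dict(
    zip(DIAGNOSTIC_POSITIONS, ("M", "T", "L", "P", "A", "S", "Q", "D"))
)

#: The six S1-pocket positions (excluding the catalytic Thr1).
S1_POCKET_POSITIONS: Tuple[int, ...] = (20, 31, 35, 45, 49, 53)

_RESIDUE_CLASS = {
    **{r: "positive" for r in "KRH"},
    **{r: "negative" for r in "DE"},
    **{r: "polar-hydroxyl" for r in "ST"},
    **{r: "aromatic" for r in "FYW"},
    **{r: "small-nonpolar" for r in "AGVLIMPC"},
}


def residue_class(residue: str) -> str:
    return _RESIDUE_CLASS.get(residue, "other")


def load_lineage_profiles(path=None) -> Tuple[Dict[int, str], Dict[int, str]]:
    """Load (A, F) diagnostic reference profiles from a JSON config.

    Without ``path`` the bundled config is used; it matches
    :data:`A_LINEAGE_REFERENCE` / :data:`F_LINEAGE_REFERENCE`.
    """
    import json
    from importlib import resources

    if path is None:
        text = (
            resources.files("psmb8kit").joinpath("data/lineage_profiles.json").read_text()
        )
    else:
        text = open(path).read()
    cfg = json.loads(text)
    positions = [int(p) for p in cfg["positions"]]
    a = {int(k): v for k, v in cfg["A"].items()}
    f = {int(k): v for k, v in cfg["F"].items()}
    if set(a) != set(positions) or set(f) != set(positions):
        raise ValueError("lineage profile config: positions and profiles disagree")
    return a, f


def residue_to_type(residue: str | None) -> str:
    """Map a residue-31 identity to a PSMB8 type label.

    A for A/V, F for F/Y, S for S/T, K for K; ``undefined`` for a missing or
    ambiguous residue; any other residue yields ``other(<residue>)`` so novel
    residues are surfaced, never collapsed — the S and K types themselves were
    found this way.
    """
    if residue is None or residue == "X":
        return "undefined"
    if residue in ("A", "V"):
        return "A"
    if residue in ("F", "Y"):
        return "F"
    if residue in ("S", "T"):
        return "S"
    if residue == "K":
        return "K"
    return f"other({residue})"


@dataclass(frozen=True)
class TypeCall:
    seq_id: str
    residue31: str | None
    type_label: str
    codon31: str | None = None
    group: str = ""


@dataclass(frozen=True)
class S1PocketProfile:
    seq_id: str
    pocket: Dict[int, str]
    catalytic_thr1: str
    annotations: Dict[int, str]


@dataclass(frozen=True)
class LineageProfile:
    seq_id: str
    residues: Dict[int, str | None]
    group: str = ""


@dataclass(frozen=True)
class LineageCall:
    seq_id: str
    matches_A: int
    matches_F: int
    call: str  # A, F or ambiguous


def call_type(
    map_: MatureMap,
    seq_id: str,
    orf: Orf | None = None,
    position31: int | None = 31,
    group: str = "",
) -> TypeCall:
    """Call the PSMB8 type from the residue at mature position 31.

    ``position31`` is the mature position holding the residue homologous to
    reference position 31 — normally 31 itself, but alignment mapping may
    shift it or return None when an indel removed it, in which case the call
    is ``undefined``.
    """
    residue = None if position31 is None else map_.residue(position31)
    if residue == "X":
        residue = None
    label = residue_to_type(residue)
    codon = None
    if orf is not None and residue is not None and position31 is not None:
        codon = codon_at(orf, map_, position31)
    return TypeCall(
        seq_id=seq_id, residue31=residue, type_label=label, codon31=codon, group=group
    )


def codon_at(orf: Orf, map_: MatureMap, mature_pos: int) -> str:
    """Codon of the residue at a 1-based mature position, from the source ORF."""
    if not orf.protein.startswith(map_.precursor[: len(orf.protein)]):
        raise ValueError("ORF translation inconsistent with precursor")
    aa_index = map_.mature_start + mature_pos - 1
    if aa_index >= len(orf.protein):
        raise IndexError(
            f"mature position {mature_pos} beyond protein of length "
            f"{len(orf.protein) - map_.mature_start} (mature)"
        )
    triplet = orf.nt_seq[3 * aa_index : 3 * aa_index + 3]
    assert translate(triplet) == orf.protein[aa_index]
    return triplet


def codon_usage_summary(
    calls: Iterable[TypeCall],
) -> pd.DataFrame:
    """Codon-31 usage per (group, type): counts and a conservation flag.

    A (group, type) cell is *conserved* iff a single codon accounts for all
    of its counts — the pattern reported for the holostean S and K types.
    """
    counters: Dict[Tuple[str, str], Counter] = {}
    for c in calls:
        if c.codon31 is None:
            continue
        counters.setdefault((c.group, c.type_label), Counter())[c.codon31] += 1
    rows = []
    for (group, label), counter in sorted(counters.items()):
        total = sum(counter.values())
        for codon, n in sorted(counter.items()):
            rows.append(
                {
                    "group": group,
                    "type_label": label,
                    "codon31": codon,
                    "count": n,
                    "conserved": len(counter) == 1,
                    "fraction": n / total,
                }
            )
    return pd.DataFrame(
        rows, columns=["group", "type_label", "codon31", "count", "conserved", "fraction"]
    )


def s1_pocket(map_: MatureMap, seq_id: str) -> S1PocketProfile:
    """Profile the six S1-pocket residues plus the catalytic Thr1."""
    if len(map_.mature) < max(S1_POCKET_POSITIONS):
        raise ValueError(
            f"{seq_id}: mature protein has {len(map_.mature)} residues; "
            f"{max(S1_POCKET_POSITIONS)} needed for the S1 pocket"
        )
    pocket = {p: map_.residue(p) for p in S1_POCKET_POSITIONS}
    return S1PocketProfile(
        seq_id=seq_id,
        pocket=pocket,
        catalytic_thr1=map_.residue(1),
        annotations={p: residue_class(r) for p, r in pocket.items()},
    )


def diagnostic_profile(map_: MatureMap, seq_id: str, group: str = "") -> LineageProfile:
    """Residues at the eight diagnostic positions; None where unavailable."""
    residues: Dict[int, str | None] = {}
    for p in DIAGNOSTIC_POSITIONS:
        r = map_.residue(p)
        residues[p] = None if r in (None, "X") else r
    return LineageProfile(seq_id=seq_id, residues=residues, group=group)


def classify_lineage(
    profile: LineageProfile,
    refs: Tuple[Mapping[int, str], Mapping[int, str]] = (
        A_LINEAGE_REFERENCE,
        F_LINEAGE_REFERENCE,
    ),
) -> LineageCall:
    """Classify A vs F lineage by diagnostic-residue match counts.

    Undefined residues match neither reference; equal counts give
    ``ambiguous`` rather than a forced call (phylogenetic placement is the
    recommended tie-breaker).
    """
    a_ref, f_ref = refs
    for ref in refs:
        if set(ref) != set(DIAGNOSTIC_POSITIONS):
            raise ValueError("reference profile must cover all 8 diagnostic positions")
    matches_a = sum(
        1 for p in DIAGNOSTIC_POSITIONS if profile.residues.get(p) == a_ref[p]
    )
    matches_f = sum(
        1 for p in DIAGNOSTIC_POSITIONS if profile.residues.get(p) == f_ref[p]
    )
    if matches_a > matches_f:
        call = "A"
    elif matches_f > matches_a:
        call = "F"
    else:
        call = "ambiguous"
    return LineageCall(
        seq_id=profile.seq_id, matches_A=matches_a, matches_F=matches_f, call=call
    )


def conservation_summary(profiles: Sequence[LineageProfile]) -> pd.DataFrame:
    """Per-group, per-position modal residue, frequency and reference match.

    Reproduces the layout of a diagnostic-residue table: for each group and
    diagnostic position, the modal residue, its frequency among defined
    residues, and whether it matches the A reference, the F reference, both
    or neither.
    """
    rows = []
    groups: Dict[str, List[LineageProfile]] = {}
    for p in profiles:
        groups.setdefault(p.group, []).append(p)
    for group in sorted(groups):
        for pos in DIAGNOSTIC_POSITIONS:
            observed = [
                pr.residues.get(pos)
                for pr in groups[group]
                if pr.residues.get(pos) is not None
            ]
            if not observed:
                rows.append(
                    {
                        "group": group,
                        "position": pos,
                        "modal_residue": None,
                        "frequency": float("nan"),
                        "matches": "neither",
                        "n": 0,
                    }
                )
                continue
            counter = Counter(observed)
            top = max(counter.items(), key=lambda kv: (kv[1], kv[0]))
            modal, count = top[0], top[1]
            in_a = modal == A_LINEAGE_REFERENCE[pos]
            in_f = modal == F_LINEAGE_REFERENCE[pos]
            matches = (
                "both" if in_a and in_f else "A" if in_a else "F" if in_f else "neither"
            )
            rows.append(
                {
                    "group": group,
                    "position": pos,
                    "modal_residue": modal,
                    "frequency": count / len(observed),
                    "matches": matches,
                    "n": len(observed),
                }
            )
    return pd.DataFrame(
        rows, columns=["group", "position", "modal_residue", "frequency", "matches", "n"]
    )
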