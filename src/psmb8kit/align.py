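"""Pairwise and progressive protein alignment with coordinate mapping.

The pairwise engine is a three-state Gotoh dynamic program (Needleman–Wunsch
for global mode, Smith–Waterman for local mode) with affine gaps: the first
residue of a gap costs ``gap_open`` and each further residue ``gap_extend``.
The default scoring scheme is BLOSUM62 with gap_open −11 / gap_extend −1,
the canonical protein-BLAST parameters.

The multiple aligner is progressive: a 3-mer count distance matrix, a UPGMA
guide tree with lexicographic-by-id tie-breaking, and profile–profile global
alignment under sum-of-pairs column scoring. It is deterministic and
seed-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from Bio.Align import substitution_matrices

from .seqio import SeqRecord

__all__ = [
    "ScoringScheme",
    "PairAlignment",
    "Msa",
    "blosum62_scheme",
    "pairwise_align",
    "percent_identity",
    "progressive_msa",
    "map_ref_position",
    "write_msa_fasta",
    "write_msa_clustal",
]

_AA_ORDER = "ACDEFGHIKLMNPQRSTVWYX"
_AA_INDEX = {aa: i for i, aa in enumerate(_AA_ORDER)}
_GAP_INDEX = len(_AA_ORDER)  # 21
_NEG = -1e18  # effective -infinity, safe under float addition


@dataclass(frozen=True)
class ScoringScheme:
    """Symmetric substitution matrix plus affine gap penalties.

    ``gap_open`` is the score of the first gap residue, ``gap_extend`` of each
    subsequent one; the invariant ``gap_open <= gap_extend < 0`` must hold.
    """

    matrix: Dict[Tuple[str, str], int]
    gap_open: int = -11
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValueError("require gap_open <= gap_extend < 0")
        for (a, b), s in self.matrix.items():
            if self.matrix.get((b, a), s) != s:
                raise ValueError(f"matrix not symmetric at ({a},{b})")

    def score(self, a: str, b: str) -> int:
        return self.matrix[(a, b)]

    def as_array(self) -> np.ndarray:
        """Dense (22, 22) array over the package alphabet + gap (last index)."""
        arr = np.zeros((22, 22))
        for i, a in enumerate(_AA_ORDER):
            for j, b in enumerate(_AA_ORDER):
                arr[i, j] = self.matrix.get((a, b), 0)
        arr[_GAP_INDEX, :21] = self.gap_extend
        arr[:21, _GAP_INDEX] = self.gap_extend
        arr[_GAP_INDEX, _GAP_INDEX] = 0.0
        return arr


def blosum62_scheme(gap_open: int = -11, gap_extend: int = -1) -> ScoringScheme:
    """BLOSUM62 with protein-BLAST default gap penalties."""
    blosum = substitution_matrices.load("BLOSUM62")
    mat: Dict[Tuple[str, str], int] = {}
    for a in _AA_ORDER:
        for b in _AA_ORDER:
            mat[(a, b)] = int(blosum[a, b])
    return ScoringScheme(matrix=mat, gap_open=gap_open, gap_extend=gap_extend)


@dataclass(frozen=True)
class PairAlignment:
    a_id: str
    b_id: str
    a_row: str
    b_row: str
    score: float
    mode: str
    a_span: Tuple[int, int]
    b_span: Tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.a_row) != len(self.b_row):
            raise ValueError("alignment rows differ in length")
        if any(x == "-" and y == "-" for x, y in zip(self.a_row, self.b_row)):
            raise ValueError("gap/gap column in alignment")


@dataclass(frozen=True)
class Msa:
    """A multiple alignment: ordered (id, gapped-row) pairs of equal length."""

    rows: Tuple[Tuple[str, str], ...]

    def __post_init__(self) -> None:
        lengths = {len(r) for _, r in self.rows}
        if len(lengths) > 1:
            raise ValueError("MSA rows differ in length")

    @property
    def length(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def ids(self) -> List[str]:
        return [i for i, _ in self.rows]

    def row(self, seq_id: str) -> str:
        for i, r in self.rows:
            if i == seq_id:
                return r
        raise KeyError(f"no row with id {seq_id!r}")


# ---------------------------------------------------------------------------
# DP core
# ---------------------------------------------------------------------------

def _affine_dp(
    S: np.ndarray, gap_open: float, gap_extend: float, mode: str
) -> tuple[float, list[str], tuple[int, int]]:
    """Gotoh DP over a precomputed (n, m) column-score matrix.

    Returns (score, moves, end) where moves is the traceback path from the
    alignment start as a list of 'D' (diagonal), 'X' (gap in a / consume b),
    'Y' (gap in b / consume a), and end is the (i, j) cell where the
    alignment ends (== (n, m) for global mode).

    Traceback ties break deterministically: diagonal, then gap-in-a, then
    gap-in-b.
    """
    n, m = S.shape
    go, ge = float(gap_open), float(gap_extend)
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in a (moves along j)
    Y = np.full((n + 1, m + 1), _NEG)  # gap in b (moves along i)
    local = mode == "local"
    M[0, 0] = 0.0
    if not local:
        if m > 0:
            X[0, 1:] = go + ge * np.arange(m)
        if n > 0:
            Y[1:, 0] = go + ge * np.arange(n)
    else:
        M[0, :] = 0.0
        M[:, 0] = 0.0

    js = np.arange(m + 1)
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = S[i - 1] + prev_best[:-1]
        if local:
            np.maximum(M[i, 1:], 0.0, out=M[i, 1:])
        Y[i, 1:] = np.maximum(M[i - 1, 1:] + go, Y[i - 1, 1:] + ge)
        # X[i, j] = max(M[i, j-1] + go, X[i, j-1] + ge): a running max after
        # subtracting the linear extension term.
        t = np.empty(m + 1)
        t[0] = X[i, 0]
        t[1:] = M[i, :-1] + go - ge * js[1:]
        np.maximum.accumulate(t, out=t)
        X[i] = t + ge * js

    if local:
        end = np.unravel_index(int(np.argmax(M)), M.shape)
        score = float(M[end])
    else:
        end = (n, m)
        score = float(max(M[n, m], X[n, m], Y[n, m]))

    # traceback
    moves: list[str] = []
    i, j = end
    if local:
        state = "D"
    else:
        if M[n, m] == score:
            state = "D"
        elif X[n, m] == score:
            state = "X"
        else:
            state = "Y"
    while i > 0 or j > 0:
        if state == "D":
            if local and M[i, j] == 0.0:
                break
            moves.append("D")
            prev = (
                "D"
                if M[i - 1, j - 1] >= max(X[i - 1, j - 1], Y[i - 1, j - 1])
                else ("X" if X[i - 1, j - 1] >= Y[i - 1, j - 1] else "Y")
            )
            if local and max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) <= 0.0:
                i, j = i - 1, j - 1
                break
            i, j, state = i - 1, j - 1, prev
        elif state == "X":
            moves.append("X")
            state = "D" if M[i, j - 1] + go == X[i, j] else "X"
            j -= 1
        else:
            moves.append("Y")
            state = "D" if M[i - 1, j] + go == Y[i, j] else "Y"
            i -= 1
        if local and state == "D" and (i == 0 or j == 0):
            break
    moves.reverse()
    return score, moves, (i, j) if local else (0, 0)


def pairwise_align(
    a: SeqRecord,
    b: SeqRecord,
    scheme: ScoringScheme | None = None,
    mode: str = "global",
) -> PairAlignment:
    """Optimal pairwise protein alignment (global NW / local SW, affine gaps)."""
    if scheme is None:
        scheme = blosum62_scheme()
    if mode not in ("global", "local"):
        raise ValueError(f"mode must be 'global' or 'local', got {mode!r}")
    if not a.seq or not b.seq:
        raise ValueError("cannot align empty sequences")
    arr = scheme.as_array()
    ai = np.array([_AA_INDEX[c] for c in a.seq])
    bi = np.array([_AA_INDEX[c] for c in b.seq])
    S = arr[np.ix_(ai, bi)]
    score, moves, start = _affine_dp(S, scheme.gap_open, scheme.gap_extend, mode)

    a_row, b_row = [], []
    i, j = start
    a0, b0 = i, j
    for mv in moves:
        if mv == "D":
            a_row.append(a.seq[i])
            b_row.append(b.seq[j])
            i += 1
            j += 1
        elif mv == "X":
            a_row.append("-")
            b_row.append(b.seq[j])
            j += 1
        else:
            a_row.append(a.seq[i])
            b_row.append("-")
            i += 1
    return PairAlignment(
        a_id=a.id,
        b_id=b.id,
        a_row="".join(a_row),
        b_row="".join(b_row),
        score=score,
        mode=mode,
        a_span=(a0, i),
        b_span=(b0, j),
    )


def percent_identity(aln: PairAlignment) -> float:
    """Identical columns over aligned (both-residue) columns."""
    pairs = [
        (x, y) for x, y in zip(aln.a_row, aln.b_row) if x != "-" and y != "-"
    ]
    if not pairs:
        raise ValueError("alignment has no aligned columns")
    return sum(x == y for x, y in pairs) / len(pairs)


# ---------------------------------------------------------------------------
# progressive MSA
# ---------------------------------------------------------------------------

def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    """Fractional common k-mer distance (1 − shared / smaller count)."""
    from collections import Counter

    ca = Counter(a[i : i + k] for i in range(len(a) - k + 1))
    cb = Counter(b[i : i + k] for i in range(len(b) - k + 1))
    shared = sum(min(ca[w], cb[w]) for w in ca)
    denom = min(max(len(a) - k + 1, 1), max(len(b) - k + 1, 1))
    return 1.0 - shared / denom


def _upgma_order(ids: List[str], dist: Dict[Tuple[str, str], float]) -> list:
    """UPGMA merge tree as nested tuples of ids; ties break lexicographically.

    Each cluster is keyed by its lexicographically smallest member so that the
    merge order — and hence the final alignment — is independent of input
    order.
    """
    clusters: Dict[str, list] = {i: i for i in sorted(ids)}
    sizes: Dict[str, int] = {i: 1 for i in ids}
    d = {frozenset(p): v for p, v in dist.items()}

    def get(x: str, y: str) -> float:
        return d[frozenset((x, y))]

    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for x in keys:
            for y in keys:
                if y <= x:
                    continue
                cand = (get(x, y), x, y)
                if best is None or cand < best:
                    best = cand
        _, x, y = best
        merged = [clusters[x], clusters[y]]
        nx, ny = sizes[x], sizes[y]
        for z in keys:
            if z in (x, y):
                continue
            d[frozenset((x, z))] = (nx * get(x, z) + ny * get(y, z)) / (nx + ny)
        del clusters[y], sizes[y]
        clusters[x] = merged
        sizes[x] = nx + ny
    return next(iter(clusters.values()))


def _profile_counts(rows: Sequence[str]) -> np.ndarray:
    """(columns, 22) residue/gap count matrix for a set of gapped rows."""
    L = len(rows[0])
    counts = np.zeros((L, 22))
    for r in rows:
        idx = np.fromiter(
            (_AA_INDEX.get(c, _GAP_INDEX) if c != "-" else _GAP_INDEX for c in r),
            dtype=np.int64,
            count=L,
        )
        np.add.at(counts, (np.arange(L), idx), 1.0)
    return counts


def _merge_profiles(
    rows_a: List[Tuple[str, str]],
    rows_b: List[Tuple[str, str]],
    scheme: ScoringScheme,
    pair_matrix: np.ndarray,
) -> List[Tuple[str, str]]:
    """Globally align two profiles under sum-of-pairs column scoring."""
    ca = _profile_counts([r for _, r in rows_a])
    cb = _profile_counts([r for _, r in rows_b])
    S = ca @ pair_matrix @ cb.T
    # sum-of-pairs column scores grow like na*nb, so gap penalties must scale
    # the same way or gaps become asymptotically free in deep profiles
    na, nb = len(rows_a), len(rows_b)
    scale = na * nb
    _, moves, _ = _affine_dp(
        S, scheme.gap_open * scale, scheme.gap_extend * scale, "global"
    )
    out_a = {i: [] for i, _ in rows_a}
    out_b = {i: [] for i, _ in rows_b}
    i = j = 0
    for mv in moves:
        if mv == "D":
            for rid, r in rows_a:
                out_a[rid].append(r[i])
            for rid, r in rows_b:
                out_b[rid].append(r[j])
            i += 1
            j += 1
        elif mv == "X":
            for rid, _ in rows_a:
                out_a[rid].append("-")
            for rid, r in rows_b:
                out_b[rid].append(r[j])
            j += 1
        else:
            for rid, r in rows_a:
                out_a[rid].append(r[i])
            for rid, _ in rows_b:
                out_b[rid].append("-")
            i += 1
    return [(rid, "".join(out_a[rid])) for rid, _ in rows_a] + [
        (rid, "".join(out_b[rid])) for rid, _ in rows_b
    ]


def progressive_msa(
    seqs: Sequence[SeqRecord], scheme: ScoringScheme | None = None
) -> Msa:
    """Progressive multiple alignment along a UPGMA 3-mer guide tree."""
    if scheme is None:
        scheme = blosum62_scheme()
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    by_id = {s.id: s for s in seqs}
    dist = {
        (a.id, b.id): _kmer_distance(a.seq, b.seq)
        for i, a in enumerate(seqs)
        for b in seqs[i + 1 :]
    }
    guide = _upgma_order(ids, dist)
    pair_matrix = scheme.as_array()

    def build(node) -> List[Tuple[str, str]]:
        if isinstance(node, str):
            return [(node, by_id[node].seq)]
        left, right = node
        return _merge_profiles(build(left), build(right), scheme, pair_matrix)

    aligned = dict(build(guide))
    return Msa(rows=tuple((i, aligned[i]) for i in ids))


# ---------------------------------------------------------------------------
# coordinate mapping
# ---------------------------------------------------------------------------

def _rows_of(aln: PairAlignment | Msa) -> List[Tuple[str, str]]:
    if isinstance(aln, PairAlignment):
        return [(aln.a_id, aln.a_row), (aln.b_id, aln.b_row)]
    return list(aln.rows)


def map_ref_position(
    aln: PairAlignment | Msa, ref_id: str, ref_pos: int, target_id: str
) -> int | None:
    """Map a 1-based ungapped position in ``ref_id`` to one in ``target_id``.

    Returns ``None`` when the target carries a gap in the reference position's
    column — e.g. a deletion spanning the queried residue.
    """
    rows = dict(_rows_of(aln))
    if ref_id not in rows:
        raise KeyError(f"unknown reference id {ref_id!r}")
    if target_id not in rows:
        raise KeyError(f"unknown target id {target_id!r}")
    ref_row, tgt_row = rows[ref_id], rows[target_id]
    if ref_pos < 1:
        raise ValueError("ref_pos is 1-based and must be >= 1")
    seen = 0
    col = -1
    for c, ch in enumerate(ref_row):
        if ch != "-":
            seen += 1
            if seen == ref_pos:
                col = c
                break
    if col == -1:
        raise ValueError(f"ref_pos {ref_pos} beyond reference length {seen}")
    if tgt_row[col] == "-":
        return None
    return sum(1 for ch in tgt_row[: col + 1] if ch != "-")


def write_msa_fasta(msa: Msa, path) -> None:
    with open(path, "w") as fh:
        for rid, row in msa.rows:
            fh.write(f">{rid}\n")
            for i in range(0, len(row), 60):
                fh.write(row[i : i + 60] + "\n")


def write_msa_clustal(msa: Msa, path) -> None:
    """Clustal-style block layout, for eyeballing only."""
    width = 60
    name_w = max((len(i) for i, _ in msa.rows), default=0) + 2
    with open(path, "w") as fh:
        fh.write("CLUSTAL-like multiple sequence alignment\n\n")
        for start in range(0, msa.length, width):
            for rid, row in msa.rows:
                fh.write(f"{rid:<{name_w}}{row[start:start + width]}\n")
            fh.write("\n")
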