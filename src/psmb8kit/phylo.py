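"""Distance-based phylogenetics: NJ trees, bootstrap supports, rooting,
clade-membership lineage assignment.

The engine is deliberately a neighbor-joining one: NJ is exact on additive
distance matrices, deterministic, and fast enough to bootstrap thousands of
times, which is what the lineage-monophyly questions asked of the tree
require. Trees are returned as :class:`dendropy.Tree` objects and serialized
as Newick with bootstrap supports stored as internal-node labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Mapping, Sequence, Set, Tuple

import dendropy
import numpy as np

from .align import Msa

__all__ = [
    "DistMatrix",
    "distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "root_with_outgroup",
    "is_monophyletic",
    "assign_lineage_by_clade",
    "write_newick",
    "read_newick",
]


@dataclass(frozen=True)
class DistMatrix:
    ids: Tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("nonzero diagonal")
        if (self.d < -1e-12).any():
            raise ValueError("negative distances")


def _encode_msa(msa: Msa) -> tuple[list[str], np.ndarray]:
    """One-hot encode rows over a 22-letter alphabet; gaps get no channel."""
    alphabet = "ACDEFGHIKLMNPQRSTVWYX*"
    index = {c: i for i, c in enumerate(alphabet)}
    ids = [i for i, _ in msa.rows]
    n, L = len(ids), msa.length
    onehot = np.zeros((n, L, len(alphabet)))
    for r, (_, row) in enumerate(msa.rows):
        for c, ch in enumerate(row):
            if ch != "-":
                onehot[r, c, index[ch]] = 1.0
    return ids, onehot


def _pdist_from_onehot(onehot: np.ndarray) -> np.ndarray:
    """Pairwise p-distance over columns where both rows are non-gap."""
    n, L, A = onehot.shape
    flat = onehot.reshape(n, L * A)
    matches = flat @ flat.T
    valid = onehot.sum(axis=2)  # 1 where non-gap
    shared = valid @ valid.T
    if (shared[~np.eye(n, dtype=bool)] == 0).any():
        raise ValueError("a sequence pair shares zero aligned columns")
    p = 1.0 - matches / shared
    np.fill_diagonal(p, 0.0)
    return np.clip(p, 0.0, 1.0)


def distance_matrix(msa: Msa, model: str = "p") -> DistMatrix:
    """Pairwise distances from an MSA: p-distance or its Poisson correction.

    The Poisson correction −ln(1 − p) assumes equal substitution rates across
    sites and no back-substitution bias; it diverges as p → 1, which is
    reported as a saturation error rather than an infinite branch.
    """
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    if len(msa.rows) < 3:
        raise ValueError("need at least 3 sequences for a distance matrix")
    ids, onehot = _encode_msa(msa)
    p = _pdist_from_onehot(onehot)
    if model == "poisson":
        if (p >= 1.0 - 1e-12).any():
            raise ValueError("saturated p-distance (p = 1): Poisson correction undefined")
        p = -np.log1p(-p)
    return DistMatrix(ids=tuple(ids), d=p)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def _nj_core(
    d: np.ndarray, labels: Sequence[str]
) -> tuple[str, List[FrozenSet[str]]]:
    """Saitou–Nei NJ.

    Returns a Newick string (trifurcating unrooted root) and the list of
    non-trivial tip clusters, one per internal edge. Ties in the Q criterion
    break on the lowest (i, j) index pair; negative branch-length estimates
    are clamped to zero with the deficit moved to the sister branch.
    """
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = d.astype(float).copy()
    frags: List[str] = [_quote(l) for l in labels]
    tipsets: List[FrozenSet[str]] = [frozenset([l]) for l in labels]
    clusters: List[FrozenSet[str]] = []
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # first min in row-major order = lowest (i, j) pair
        ii, jj = np.unravel_index(int(np.argmin(Q)), Q.shape)
        if ii > jj:
            ii, jj = jj, ii
        i, j = active[ii], active[jj]
        dij = sub[ii, jj]
        li = 0.5 * dij + (r[ii] - r[jj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new_frag = f"({frags[i]}:{li:.6f},{frags[j]}:{lj:.6f})"
        new_tips = tipsets[i] | tipsets[j]
        # distances from the new node to every other active node
        others = [a for a in active if a not in (i, j)]
        newd = 0.5 * (D[i, others] + D[j, others] - dij)
        u = len(frags)
        frags.append(new_frag)
        tipsets.append(new_tips)
        clusters.append(new_tips)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[u, others] = np.maximum(newd, 0.0)
        D[others, u] = D[u, others]
        active = others + [u]

    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = max(0.0, 0.5 * (dab + dac - dbc))
    lb = max(0.0, 0.5 * (dab + dbc - dac))
    lc = max(0.0, 0.5 * (dac + dbc - dab))
    newick = (
        f"({frags[a]}:{la:.6f},{frags[b]}:{lb:.6f},{frags[c]}:{lc:.6f});"
    )
    all_tips = frozenset(labels)
    clusters = [c for c in clusters if 1 < len(c) < len(all_tips) - 1]
    return newick, clusters


def _quote(label: str) -> str:
    return f"'{label}'" if any(ch.isspace() for ch in label) else label


def neighbor_joining(dm: DistMatrix) -> dendropy.Tree:
    """Build the unrooted NJ tree for a distance matrix."""
    newick, _ = _nj_core(dm.d, dm.ids)
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = False
    return tree


def _bipart_key(tips: FrozenSet[str], all_tips: FrozenSet[str]) -> FrozenSet[str]:
    """Canonical side of a bipartition: the smaller side, ties by smallest id."""
    other = all_tips - tips
    if len(tips) < len(other):
        return tips
    if len(other) < len(tips):
        return other
    return tips if min(tips) < min(other) else other


def bootstrap_support(
    msa: Msa, model: str = "p", n_reps: int = 200, seed: int = 42
) -> dendropy.Tree:
    """NJ point tree with nonparametric bootstrap supports.

    Alignment columns are resampled with replacement ``n_reps`` times; each
    replicate tree is rebuilt by NJ and the support of an internal edge of the
    point tree is the percentage of replicates containing the same
    bipartition. Rows are canonically sorted by id first, so supports do not
    depend on input order. Supports land in the internal-node labels.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    sorted_msa = Msa(rows=tuple(sorted(msa.rows)))
    ids, onehot = _encode_msa(sorted_msa)
    all_tips = frozenset(ids)
    p = _pdist_from_onehot(onehot)
    if model == "poisson":
        p = -np.log1p(-np.clip(p, 0.0, 1.0 - 1e-12))
    newick, clusters = _nj_core(p, ids)
    counts = {_bipart_key(c, all_tips): 0 for c in clusters}

    rng = np.random.default_rng(seed)
    L = onehot.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rep = onehot[:, cols, :]
        try:
            prep = _pdist_from_onehot(rep)
        except ValueError:  # a pair lost all shared columns in this replicate
            continue
        if model == "poisson":
            prep = -np.log1p(-np.clip(prep, 0.0, 1.0 - 1e-12))
        _, rep_clusters = _nj_core(prep, ids)
        rep_keys = {_bipart_key(c, all_tips) for c in rep_clusters}
        for key in counts:
            if key in rep_keys:
                counts[key] += 1

    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = False
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        tips = frozenset(lf.taxon.label for lf in node.leaf_iter())
        key = _bipart_key(tips, all_tips)
        if key in counts:
            support = 100.0 * counts[key] / n_reps
            node.label = f"{support:g}"
    return tree


def _tipset(node: dendropy.Node) -> FrozenSet[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def root_with_outgroup(
    tree: dendropy.Tree, outgroup_ids: Set[str]
) -> dendropy.Tree:
    """Root at the midpoint of the branch separating outgroup from ingroup.

    The outgroup must be monophyletic in the unrooted tree, i.e. form one side
    of some branch; otherwise the conflicting tips are reported. Internal-node
    labels (bootstrap supports) are remapped by bipartition, since rerooting
    changes which side of each bipartition a node subtends.
    """
    outgroup = frozenset(outgroup_ids)
    if not outgroup:
        raise ValueError("outgroup_ids is empty")
    tree = tree.clone(depth=1)
    all_tips = _tipset(tree.seed_node)
    missing = outgroup - all_tips
    if missing:
        raise ValueError(f"outgroup tips not in tree: {sorted(missing)}")
    support_by_bipart: Dict[FrozenSet[str], str] = {}
    target = None
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        tips = _tipset(node)
        if not node.is_leaf() and node.label is not None:
            support_by_bipart[_bipart_key(tips, all_tips)] = node.label
        if target is None and (tips == outgroup or (all_tips - tips) == outgroup):
            target = node
    if target is None:
        raise ValueError(
            f"outgroup is not monophyletic: {sorted(outgroup)} do not form one "
            "side of any branch"
        )
    edge = target.edge
    half = (edge.length or 0.0) / 2.0
    tree.reroot_at_edge(edge, length1=half, length2=half)
    tree.is_rooted = True
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        key = _bipart_key(_tipset(node), all_tips)
        node.label = support_by_bipart.get(key)
    return tree


def is_monophyletic(tree: dendropy.Tree, tips: Set[str]) -> bool:
    """True iff some node's descendant tip set equals ``tips`` exactly."""
    tips = frozenset(tips)
    all_tips = _tipset(tree.seed_node)
    unknown = tips - all_tips
    if unknown:
        raise ValueError(f"unknown tips: {sorted(unknown)}")
    for node in tree.preorder_node_iter():
        if _tipset(node) == tips:
            return True
    return False


def assign_lineage_by_clade(
    tree: dendropy.Tree, labeled_refs: Mapping[str, str], query: str
) -> str:
    """Assign A/F lineage by the smallest reference-containing clade.

    Walk from the query tip toward the root; the first ancestor with any
    reference descendants decides: uniformly one label gives that label,
    mixed labels give ``unresolved``.
    """
    if query in labeled_refs:
        raise ValueError(f"query {query!r} is itself a labeled reference")
    labels = set(labeled_refs.values())
    if not {"A", "F"} <= labels:
        raise ValueError("references of both labels (A and F) are required")
    leaf = None
    for lf in tree.leaf_node_iter():
        if lf.taxon is not None and lf.taxon.label == query:
            leaf = lf
            break
    if leaf is None:
        raise ValueError(f"query tip {query!r} not in tree")
    node = leaf.parent_node
    while node is not None:
        seen = {
            labeled_refs[t]
            for t in _tipset(node)
            if t in labeled_refs
        }
        if len(seen) == 1:
            return seen.pop()
        if len(seen) > 1:
            return "unresolved"
        node = node.parent_node
    return "unresolved"


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
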