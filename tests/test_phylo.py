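import itertools
import math
import random

import dendropy
import numpy as np
import pytest

from psmb8kit.align import Msa
from psmb8kit.phylo import (
    DistMatrix,
    assign_lineage_by_clade,
    bootstrap_support,
    distance_matrix,
    is_monophyletic,
    neighbor_joining,
    root_with_outgroup,
)

# ---------------------------------------------------------------------------
# topology enumeration + least-squares oracle
# ---------------------------------------------------------------------------


def four_taxon_topologies(labels):
    a, b, c, d = labels
    return [
        ((a, b), (c, d)),
        ((a, c), (b, d)),
        ((a, d), (b, c)),
    ]


def five_taxon_topologies(labels):
    out = []
    for mid in labels:
        rest = [l for l in labels if l != mid]
        a = rest[0]
        for partner in rest[1:]:
            pair1 = (a, partner)
            pair2 = tuple(l for l in rest[1:] if l != partner)
            out.append((mid, pair1, pair2))
    return out


def path_vectors_4(topology, labels):
    """Pair -> indicator over (4 pendant + 1 internal) branch parameters."""
    (a, b), (c, d) = topology
    idx = {l: i for i, l in enumerate(labels)}
    e = 4
    vecs = {}
    for x, y in itertools.combinations(labels, 2):
        v = np.zeros(5)
        v[idx[x]] = v[idx[y]] = 1
        same_cherry = {x, y} in ({a, b}, {c, d})
        if not same_cherry:
            v[e] = 1
        vecs[(x, y)] = v
    return vecs


def path_vectors_5(topology, labels):
    mid, (a, b), (c, d) = topology
    idx = {l: i for i, l in enumerate(labels)}
    e1, e2 = 5, 6
    side = {a: "L", b: "L", c: "R", d: "R", mid: "M"}
    vecs = {}
    for x, y in itertools.combinations(labels, 2):
        v = np.zeros(7)
        v[idx[x]] = v[idx[y]] = 1
        s = {side[x], side[y]}
        if s == {"L", "M"}:
            v[e1] = 1
        elif s == {"R", "M"}:
            v[e2] = 1
        elif s == {"L", "R"}:
            v[e1] = v[e2] = 1
        vecs[(x, y)] = v
    return vecs


def least_squares_topology(D, labels, topologies, path_fn):
    """Best-fit topology by branch-length least squares (the NJ oracle)."""
    best = None
    for topo in topologies:
        vecs = path_fn(topo, labels)
        A = np.array([vecs[p] for p in itertools.combinations(labels, 2)])
        y = np.array([D[p] for p in itertools.combinations(labels, 2)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        rss = float(((A @ coef - y) ** 2).sum())
        if best is None or rss < best[0]:
            best = (rss, topo)
    return best[1]


def tree_bipartitions(tree):
    all_tips = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        tips = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(tips) < len(all_tips) - 1:
            side = min(tips, key=sorted) if False else tips
            other = all_tips - tips
            out.add(tips if (len(tips), sorted(tips)) <= (len(other), sorted(other)) else other)
    return out


def additive_matrix_4(topology, lengths, labels):
    vecs = path_vectors_4(topology, labels)
    return {p: float(v @ lengths) for p, v in vecs.items()}


def additive_matrix_5(topology, lengths, labels):
    vecs = path_vectors_5(topology, labels)
    return {p: float(v @ lengths) for p, v in vecs.items()}


def as_distmatrix(D, labels):
    n = len(labels)
    arr = np.zeros((n, n))
    for (x, y), v in D.items():
        i, j = labels.index(x), labels.index(y)
        arr[i, j] = arr[j, i] = v
    return DistMatrix(ids=tuple(labels), d=arr)


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------


class TestDistanceMatrix:
    def test_identical_rows_zero(self):
        msa = Msa(rows=(("a", "MKVL"), ("b", "MKVL"), ("c", "MKVL")))
        dm = distance_matrix(msa, "p")
        assert np.allclose(dm.d, 0.0)

    def test_p_distance_definition(self):
        row = "A" * 100
        other = "C" + "A" * 99
        msa = Msa(rows=(("a", row), ("b", other), ("c", row)))
        dm = distance_matrix(msa, "p")
        i, j = dm.ids.index("a"), dm.ids.index("b")
        assert dm.d[i, j] == pytest.approx(0.01)

    def test_poisson_closed_form(self):
        row = "A" * 100
        other = "C" + "A" * 99
        msa = Msa(rows=(("a", row), ("b", other), ("c", row)))
        dm = distance_matrix(msa, "poisson")
        i, j = dm.ids.index("a"), dm.ids.index("b")
        assert dm.d[i, j] == pytest.approx(-math.log(0.99))

    def test_gap_columns_excluded_from_denominator(self):
        msa = Msa(rows=(("a", "AC-L"), ("b", "ACK-"), ("c", "ACKL")))
        dm = distance_matrix(msa, "p")
        i, j = dm.ids.index("a"), dm.ids.index("b")
        assert dm.d[i, j] == 0.0  # only AC shared, identical

    def test_poisson_saturation_error(self):
        msa = Msa(rows=(("a", "AAAA"), ("b", "CCCC"), ("c", "AAAA")))
        with pytest.raises(ValueError, match="[Ss]aturat"):
            distance_matrix(msa, "poisson")

    def test_zero_shared_columns_error(self):
        msa = Msa(rows=(("a", "AA--"), ("b", "--AA"), ("c", "AAAA")))
        with pytest.raises(ValueError, match="zero aligned"):
            distance_matrix(msa, "p")

    def test_unknown_model(self):
        msa = Msa(rows=(("a", "AA"), ("b", "AA"), ("c", "AA")))
        with pytest.raises(ValueError):
            distance_matrix(msa, "jc")


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistMatrix(
            ids=("a", "b", "c"),
            d=np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]]),
        )
        tree = neighbor_joining(dm)
        lengths = {
            l.taxon.label: l.edge.length for l in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_four_taxon_additive_recovery(self):
        labels = ["a", "b", "c", "d"]
        rng = np.random.default_rng(0)
        for rep in range(20):
            topo = four_taxon_topologies(labels)[rng.integers(0, 3)]
            lengths = rng.uniform(0.05, 0.3, size=5)
            D = additive_matrix_4(topo, lengths, labels)
            tree = neighbor_joining(as_distmatrix(D, labels))
            expected_split = frozenset(topo[0])
            other = frozenset(topo[1])
            got = tree_bipartitions(tree)
            assert got in ({expected_split}, {other}), (topo, got)
            # least-squares oracle agrees
            ls = least_squares_topology(
                D, labels, four_taxon_topologies(labels), path_vectors_4
            )
            assert frozenset(map(frozenset, ls)) == frozenset(map(frozenset, topo))
            # branch lengths reproduce path distances
            pdm = tree.phylogenetic_distance_matrix()
            taxa = {t.label: t for t in tree.taxon_namespace}
            for (x, y), v in D.items():
                # newick serializes branch lengths at 6 decimals
                assert pdm.patristic_distance(taxa[x], taxa[y]) == pytest.approx(
                    v, abs=1e-5
                )

    def test_five_taxon_additive_recovery_vs_brute_force(self):
        labels = ["a", "b", "c", "d", "e"]
        topos = five_taxon_topologies(labels)
        assert len(topos) == 15
        rng = np.random.default_rng(1)
        for rep in range(20):
            topo = topos[rng.integers(0, 15)]
            lengths = rng.uniform(0.05, 0.3, size=7)
            D = additive_matrix_5(topo, lengths, labels)
            tree = neighbor_joining(as_distmatrix(D, labels))
            mid, pair1, pair2 = topo
            expected = {frozenset(pair1), frozenset(pair2)}
            got = tree_bipartitions(tree)
            normalized = {
                s if len(s) == 2 else frozenset(labels) - s for s in got
            }
            assert normalized == expected, (topo, got)
            ls_mid, ls_p1, ls_p2 = least_squares_topology(
                D, labels, topos, path_vectors_5
            )
            assert {frozenset(ls_p1), frozenset(ls_p2)} == expected

    def test_nonfinite_distances_rejected(self):
        with pytest.raises(ValueError):
            DistMatrix(ids=("a", "b", "c"), d=np.array(
                [[0, np.inf, 1], [np.inf, 0, 1], [1, 1, 0.0]]
            ))

    def test_branch_lengths_never_negative(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = 6
            # noisy, non-additive distances provoke negative NJ estimates
            base = rng.uniform(0.05, 0.5, size=(n, n))
            d = (base + base.T) / 2
            np.fill_diagonal(d, 0.0)
            dm = DistMatrix(ids=tuple("abcdef"), d=d)
            tree = neighbor_joining(dm)
            for edge in tree.preorder_edge_iter():
                if edge.length is not None:
                    assert edge.length >= 0.0


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def two_clade_msa(n_per_clade=4, length=120, seed=0):
    rng = random.Random(seed)
    AA = "ACDEFGHIKLMNPQRSTVWY"
    base1 = [rng.choice(AA) for _ in range(length)]
    base2 = list(base1)
    for i in rng.sample(range(length), int(0.35 * length)):
        base2[i] = rng.choice([c for c in AA if c != base2[i]])
    rows = []
    for k, base in (("x", base1), ("y", base2)):
        for i in range(n_per_clade):
            row = list(base)
            for j in rng.sample(range(length), 2):
                row[j] = rng.choice(AA)
            rows.append((f"{k}{i}", "".join(row)))
    return Msa(rows=tuple(rows))


class TestBootstrap:
    def test_single_replicate_supports_are_binary(self):
        msa = two_clade_msa()
        tree = bootstrap_support(msa, n_reps=1, seed=3)
        supports = [
            float(n.label)
            for n in tree.preorder_node_iter()
            if not n.is_leaf() and n.label is not None
        ]
        assert supports
        assert set(supports) <= {0.0, 100.0}

    def test_fixed_seed_is_bit_identical(self):
        msa = two_clade_msa()
        t1 = bootstrap_support(msa, n_reps=25, seed=11).as_string(schema="newick")
        t2 = bootstrap_support(msa, n_reps=25, seed=11).as_string(schema="newick")
        assert t1 == t2

    def test_invariant_to_row_order(self):
        msa = two_clade_msa()
        shuffled = Msa(rows=tuple(reversed(msa.rows)))
        t1 = bootstrap_support(msa, n_reps=25, seed=11).as_string(schema="newick")
        t2 = bootstrap_support(shuffled, n_reps=25, seed=11).as_string(schema="newick")
        assert t1 == t2

    def test_well_separated_clades_get_high_support(self):
        msa = two_clade_msa()
        tree = bootstrap_support(msa, n_reps=100, seed=5)
        clade_x = frozenset(f"x{i}" for i in range(4))
        clade_y = frozenset(f"y{i}" for i in range(4))
        found = {}
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            tips = frozenset(l.taxon.label for l in node.leaf_iter())
            if tips in (clade_x, clade_y) and node.label is not None:
                found[tips] = float(node.label)
        assert found  # at least one clade appears as an internal bipartition
        assert all(v >= 95.0 for v in found.values())


# ---------------------------------------------------------------------------
# rooting, monophyly, clade assignment
# ---------------------------------------------------------------------------


def get_tree(newick):
    return dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )


class TestRooting:
    def test_single_outgroup_tip(self):
        tree = get_tree("(A:1,B:1,(C:1,D:1):2);")
        rooted = root_with_outgroup(tree, {"A"})
        assert rooted.is_rooted
        children = rooted.seed_node.child_nodes()
        sides = [frozenset(l.taxon.label for l in c.leaf_iter()) for c in children]
        assert frozenset({"A"}) in sides
        assert frozenset({"B", "C", "D"}) in sides

    def test_ingroup_composition_with_clade_outgroup(self):
        tree = get_tree("((O1:1,O2:1):1,A:1,(B:1,C:1):1);")
        rooted = root_with_outgroup(tree, {"O1", "O2"})
        sides = [
            frozenset(l.taxon.label for l in c.leaf_iter())
            for c in rooted.seed_node.child_nodes()
        ]
        assert frozenset({"O1", "O2"}) in sides
        assert frozenset({"A", "B", "C"}) in sides

    def test_scattered_outgroup_raises(self):
        tree = get_tree("(A:1,B:1,(C:1,D:1):2);")
        with pytest.raises(ValueError, match="monophyletic"):
            root_with_outgroup(tree, {"A", "C"})

    def test_missing_outgroup_tip_raises(self):
        tree = get_tree("(A:1,B:1,(C:1,D:1):2);")
        with pytest.raises(ValueError, match="not in tree"):
            root_with_outgroup(tree, {"Z"})


class TestMonophyly:
    def test_full_tip_set(self):
        tree = get_tree("((A:1,B:1):1,(C:1,D:1):1);")
        assert is_monophyletic(tree, {"A", "B", "C", "D"})

    def test_single_tip(self):
        tree = get_tree("((A:1,B:1):1,(C:1,D:1):1);")
        assert is_monophyletic(tree, {"A"})

    def test_clade_and_non_clade(self):
        tree = get_tree("((A:1,B:1):1,(C:1,D:1):1);")
        assert is_monophyletic(tree, {"A", "B"})
        assert not is_monophyletic(tree, {"A", "C"})

    def test_unknown_tip_raises(self):
        tree = get_tree("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(ValueError):
            is_monophyletic(tree, {"A", "Z"})


class TestCladeAssignment:
    REFS = {"ra1": "A", "ra2": "A", "rf1": "F", "rf2": "F"}

    def test_query_inside_pure_clade(self):
        tree = get_tree("((q:1,ra1:1):1,(ra2:1,(rf1:1,rf2:1):1):1);")
        assert assign_lineage_by_clade(tree, self.REFS, "q") == "A"

    def test_query_at_root_between_clades(self):
        tree = get_tree("(q:1,(ra1:1,ra2:1):1,(rf1:1,rf2:1):1);")
        assert assign_lineage_by_clade(tree, self.REFS, "q") == "unresolved"

    def test_query_is_reference_error(self):
        tree = get_tree("((q:1,ra1:1):1,(ra2:1,(rf1:1,rf2:1):1):1);")
        with pytest.raises(ValueError):
            assign_lineage_by_clade(tree, self.REFS, "ra1")
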