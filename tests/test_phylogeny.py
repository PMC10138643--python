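"""NJ/Poisson/bootstrap/logo, checked against closed forms and brute force."""

import math

import numpy as np
import pytest

from cuticula.phylogeny_logo import (
    DistanceMatrix,
    Msa,
    Tree,
    bootstrap_support,
    logo_matrix,
    nj_tree,
    poisson_distance,
    poisson_distance_matrix,
    star_align,
    write_newick,
)
from cuticula.sequence_io import ProteinRecord
from cuticula.synthetic_data import make_clade_msa


# ---------------------------------------------------------------- oracles

def enumerate_topologies(leaves):
    """All unrooted binary topologies over `leaves` as edge lists."""
    assert len(leaves) >= 3
    base = [("I0", leaves[0]), ("I0", leaves[1]), ("I0", leaves[2])]
    trees = [base]
    counter = [0]
    for leaf in leaves[3:]:
        nxt = []
        for edges in trees:
            for k, (u, v) in enumerate(edges):
                counter[0] += 1
                w = f"I{counter[0]}"
                new = edges[:k] + edges[k + 1:] + [(u, w), (v, w), (leaf, w)]
                nxt.append(new)
        trees = nxt
    return trees


def tree_splits(edges, leaves):
    """Canonical bipartitions of a topology given as an edge list."""
    import networkx as nx
    g = nx.Graph(edges)
    leafset = frozenset(leaves)
    splits = set()
    for u, v in edges:
        if u in leafset or v in leafset:
            continue
        h = g.copy()
        h.remove_edge(u, v)
        side = frozenset(n for n in nx.node_connected_component(h, u)
                         if n in leafset)
        other = leafset - side
        if side and other:
            splits.add(frozenset(min(side, other,
                                     key=lambda s: (len(s), sorted(s)))))
    return splits


def least_squares_length(edges, leaves, dm):
    """LS-fit branch lengths for a topology; returns (residual, total)."""
    import networkx as nx
    g = nx.Graph()
    for i, e in enumerate(edges):
        g.add_edge(*e, idx=i)
    pairs = [(a, b) for i, a in enumerate(leaves) for b in leaves[i + 1:]]
    A = np.zeros((len(pairs), len(edges)))
    d = np.zeros(len(pairs))
    idx = {a: i for i, a in enumerate(dm.ids)}
    for r, (a, b) in enumerate(pairs):
        path = nx.shortest_path(g, a, b)
        for u, v in zip(path, path[1:]):
            A[r, g[u][v]["idx"]] = 1.0
        d[r] = dm.matrix[idx[a], idx[b]]
    x, *_ = np.linalg.lstsq(A, d, rcond=None)
    resid = float(np.linalg.norm(A @ x - d))
    return resid, float(x.sum())


def random_additive_matrix(n, rng):
    """Random binary tree with positive branch lengths -> path distances."""
    import networkx as nx
    leaves = [f"T{i}" for i in range(n)]
    edges = [("I0", leaves[0]), ("I0", leaves[1]), ("I0", leaves[2])]
    counter = 0
    for leaf in leaves[3:]:
        k = int(rng.integers(len(edges)))
        u, v = edges.pop(k)
        counter += 1
        w = f"J{counter}"
        edges += [(u, w), (v, w), (leaf, w)]
    g = nx.Graph()
    for u, v in edges:
        g.add_edge(u, v, weight=float(rng.uniform(0.1, 1.0)))
    m = np.zeros((n, n))
    for i, a in enumerate(leaves):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = nx.shortest_path_length(
                g, a, leaves[j], weight="weight")
    return DistanceMatrix(leaves, m), tree_splits(edges, leaves)


# ------------------------------------------------------------- distances

class TestPoissonDistance:
    def test_identical_rows_are_zero(self):
        msa = Msa(["a", "b"], ["MKVL", "MKVL"])
        assert poisson_distance(msa, "a", "b") == 0.0

    def test_closed_form_half_different(self):
        msa = Msa(["a", "b"], ["AACC", "AAGG"])
        assert poisson_distance(msa, "a", "b") == pytest.approx(-math.log(0.5))

    def test_pairwise_deletion_hand_count(self):
        msa = Msa(["a", "b"], ["AC-G", "AT-G"])
        assert poisson_distance(msa, "a", "b") == pytest.approx(-math.log(2 / 3))

    def test_x_treated_as_missing(self):
        msa = Msa(["a", "b"], ["AXCG", "AACG"])
        assert poisson_distance(msa, "a", "b") == 0.0

    def test_no_shared_columns_is_error(self):
        msa = Msa(["a", "b"], ["A--", "--A"])
        with pytest.raises(ValueError, match="no shared"):
            poisson_distance(msa, "a", "b")

    def test_saturated_pair_is_infinite(self):
        msa = Msa(["a", "b"], ["AAAA", "CCCC"])
        assert math.isinf(poisson_distance(msa, "a", "b"))

    def test_matrix_agrees_with_pairwise_function(self, rng):
        msa, _ = make_clade_msa(2, 3, 0.1, 0.4, length=60, seed=5)
        dm = poisson_distance_matrix(msa)
        for i, a in enumerate(msa.ids):
            for j, b in enumerate(msa.ids):
                if i < j:
                    assert dm.matrix[i, j] == pytest.approx(
                        poisson_distance(msa, a, b))


# -------------------------------------------------------------------- NJ

class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float))
        tree = nj_tree(dm)
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths == {"A": pytest.approx(1.0), "B": pytest.approx(1.0),
                           "C": pytest.approx(2.0)}

    def test_additive_four_taxon_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)): path distances below
        m = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
                     float)
        tree = nj_tree(DistanceMatrix(list("ABCD"), m))
        assert tree.bipartitions() == {frozenset({"A", "B"})}
        lengths = {}
        def walk(n):
            for c in n.children:
                if c.is_leaf():
                    lengths[c.name] = c.length
                else:
                    lengths["internal"] = c.length
                    walk(c)
        walk(tree.root)
        assert lengths == {"A": pytest.approx(1), "B": pytest.approx(2),
                           "C": pytest.approx(3), "D": pytest.approx(4),
                           "internal": pytest.approx(1)}

    def test_five_taxa_vs_exhaustive_topology_search(self, rng):
        """NJ equals brute-force least-squares search over all 15
        unrooted 5-taxon topologies on additive matrices."""
        for _ in range(3):
            dm, true_splits = random_additive_matrix(5, rng)
            topologies = enumerate_topologies(dm.ids)
            assert len(topologies) == 15
            scored = [(least_squares_length(t, dm.ids, dm)[0], i)
                      for i, t in enumerate(topologies)]
            best = min(scored)[1]
            assert tree_splits(topologies[best], dm.ids) == true_splits
            assert nj_tree(dm).bipartitions() == true_splits

    @pytest.mark.parametrize("n", [6, 8])
    def test_additive_recovery_up_to_eight_taxa(self, n, rng):
        for _ in range(3):
            dm, true_splits = random_additive_matrix(n, rng)
            assert nj_tree(dm).bipartitions() == true_splits

    def test_agrees_with_independent_nj_implementation(self, rng):
        """Cross-check topology against dendropy's NJ on an additive matrix."""
        dendropy = pytest.importorskip("dendropy")
        import io
        dm, true_splits = random_additive_matrix(6, rng)
        csv = "," + ",".join(dm.ids) + "\n"
        for i, a in enumerate(dm.ids):
            csv += a + "," + ",".join(str(x) for x in dm.matrix[i]) + "\n"
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            io.StringIO(csv), delimiter=",")
        dtree = pdm.nj_tree()
        leafset = frozenset(dm.ids)
        dsplits = set()
        for node in dtree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            side = frozenset(l.taxon.label for l in node.leaf_iter())
            other = leafset - side
            if side and other:
                dsplits.add(frozenset(min(side, other,
                                          key=lambda s: (len(s), sorted(s)))))
        assert nj_tree(dm).bipartitions() == dsplits == true_splits

    def test_infinite_entry_is_refused(self):
        m = np.array([[0, np.inf, 1], [np.inf, 0, 1], [1, 1, 0]])
        with pytest.raises(ValueError, match="infinite"):
            nj_tree(DistanceMatrix(list("ABC"), m))

    def test_needs_three_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["A", "B"], np.zeros((2, 2))))


# --------------------------------------------------------------- bootstrap

class TestBootstrap:
    def test_planted_clades_get_full_support(self):
        msa, truth = make_clade_msa(2, 4, 0.05, 0.6, length=200, seed=1)
        tree = bootstrap_support(msa, 100, seed=3)
        clade = frozenset(truth[truth.clade == 1].leaf_id)
        leafset = frozenset(msa.ids)
        canon = frozenset(min(clade, leafset - clade,
                              key=lambda s: (len(s), sorted(s))))
        supports = {}
        def walk(n):
            for c in n.children:
                if not c.is_leaf():
                    side = frozenset(c.leaves())
                    key = frozenset(min(side, leafset - side,
                                        key=lambda s: (len(s), sorted(s))))
                    supports[key] = c.support
                    walk(c)
        walk(tree.root)
        assert supports[canon] >= 95

    def test_identical_sequences_degenerate_with_warning(self, caplog):
        import logging
        msa = Msa([f"s{i}" for i in range(4)], ["MKVL"] * 4)
        with caplog.at_level(logging.WARNING):
            tree = bootstrap_support(msa, 5, seed=0)
        assert any("unresolved" in r.message for r in caplog.records)
        assert sorted(tree.root.leaves()) == sorted(msa.ids)

    def test_single_replicate_support_is_zero_or_hundred(self):
        msa, _ = make_clade_msa(2, 3, 0.1, 0.5, length=80, seed=2)
        tree = bootstrap_support(msa, 1, seed=9)
        vals = []
        def walk(n):
            for c in n.children:
                if not c.is_leaf():
                    vals.append(c.support)
                    walk(c)
        walk(tree.root)
        assert vals and all(v in (0.0, 100.0) for v in vals)

    def test_seeded_reproducibility(self):
        msa, _ = make_clade_msa(2, 4, 0.1, 0.5, length=100, seed=4)
        t1 = bootstrap_support(msa, 20, seed=5)
        t2 = bootstrap_support(msa, 20, seed=5)
        assert write_newick(t1) == write_newick(t2)


# -------------------------------------------------------------------- logo

class TestLogo:
    def test_invariant_column_information(self):
        lm = logo_matrix(Msa(["a", "b"], ["G", "G"]))
        assert lm.information[0] == pytest.approx(math.log2(20))

    def test_two_state_column(self):
        lm = logo_matrix(Msa(["a", "b"], ["G", "A"]))
        assert lm.information[0] == pytest.approx(math.log2(20) - 1)

    def test_uniform_limit_is_zero(self):
        residues = "ACDEFGHIKLMNPQRSTVWY"
        lm = logo_matrix(Msa([f"s{i}" for i in range(20)], list(residues)))
        assert lm.information[0] == pytest.approx(0.0, abs=1e-12)

    def test_all_gap_column_missing(self):
        lm = logo_matrix(Msa(["a", "b"], ["-A", "-A"]))
        assert math.isnan(lm.information[0]) and lm.frequencies[0] is None

    def test_frequencies_sum_to_one_and_uniformity_lowers_information(self):
        sharp = logo_matrix(Msa(["a", "b", "c", "d"], ["G", "G", "G", "A"]))
        flat = logo_matrix(Msa(["a", "b", "c", "d"], ["G", "G", "A", "A"]))
        assert sum(sharp.frequencies[0].values()) == pytest.approx(1.0)
        assert flat.information[0] < sharp.information[0]


# ------------------------------------------------------------ newick / msa

class TestNewickAndAlignment:
    def test_newick_round_trip_topology(self, rng):
        dendropy = pytest.importorskip("dendropy")
        dm, true_splits = random_additive_matrix(6, rng)
        tree = nj_tree(dm)
        text = write_newick(tree)
        parsed = dendropy.Tree.get(data=text, schema="newick")
        leafset = frozenset(dm.ids)
        splits = set()
        for node in parsed.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            side = frozenset(l.taxon.label for l in node.leaf_iter())
            other = leafset - side
            if side and other:
                splits.add(frozenset(min(side, other,
                                         key=lambda s: (len(s), sorted(s)))))
        assert splits == tree.bipartitions()

    def test_empty_tree_is_error(self):
        from cuticula.phylogeny_logo import TreeNode
        with pytest.raises(ValueError):
            write_newick(Tree(TreeNode()))

    def test_star_align_preserves_residues(self, rng):
        recs = [ProteinRecord("a", "MKVLLGAY"),
                ProteinRecord("b", "MKVGAY"),
                ProteinRecord("c", "MKVLLGAYWW")]
        msa = star_align(recs)
        assert len(msa) == 3
        for rec in recs:
            assert msa.row(rec.id).replace("-", "") == rec.sequence
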