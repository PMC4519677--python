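"""NJ exactness on additive matrices, bootstrap determinism, monophyly."""

import io

import numpy as np
import pytest

from barcodekit.distances import DistanceMatrix, distance_matrix
from barcodekit.errors import TreeError
from barcodekit.nj_phylo import (
    bootstrap_support,
    nj,
    species_monophyly_check,
)
from barcodekit.seqio import LabeledAlignment


def dmat(labels, d):
    return DistanceMatrix(labels=labels, d=np.asarray(d, dtype=float),
                          sites_used=None, model="K2P")


def random_additive_tree(n_taxa, rng):
    """Random binary topology + branch lengths; returns (split_lengths,
    distance matrix, labels) via path-length additivity."""
    labels = [f"t{i}" for i in range(n_taxa)]
    # grow an unrooted tree by attaching each new leaf to a random edge
    # representation: adjacency dict node -> {neighbor: length}
    adj = {0: {}, 1: {}}
    next_node = n_taxa  # internal node ids sit above the leaf ids
    edge_len = lambda: float(rng.uniform(0.05, 1.0))
    l0 = edge_len()
    adj[0][1] = l0
    adj[1][0] = l0
    edges = [(0, 1)]
    for leaf in range(2, n_taxa):
        u, v = edges[rng.integers(0, len(edges))]
        w = next_node; next_node += 1  # new internal node on edge (u, v)
        lu = adj[u].pop(v); adj[v].pop(u)
        split = float(rng.uniform(0.2, 0.8)) * lu
        adj.setdefault(w, {})
        adj[u][w] = split; adj[w][u] = split
        adj[v][w] = lu - split; adj[w][v] = lu - split
        ln = edge_len()
        adj[leaf] = {w: ln}; adj[w][leaf] = ln
        edges.remove((u, v))
        edges += [(u, w), (v, w), (leaf, w)]
    # all-pairs path lengths among leaves 0..n_taxa-1
    import networkx as nx

    g = nx.Graph()
    for u in adj:
        for v, l in adj[u].items():
            g.add_edge(u, v, weight=l)
    d = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        lengths = nx.single_source_dijkstra_path_length(g, i)
        for j in range(n_taxa):
            d[i, j] = lengths[j]
    return labels, d, g


def tree_split_lengths_from_graph(g, labels):
    """Branch length per bipartition of the true tree (oracle)."""
    import networkx as nx

    leaf_ids = set(range(len(labels)))
    out = {}
    first = min(labels)
    for u, v, data in g.edges(data=True):
        h = g.copy()
        h.remove_edge(u, v)
        comp = nx.node_connected_component(h, u)
        side = frozenset(labels[i] for i in comp & leaf_ids)
        if 0 < len(side) < len(labels):
            if first in side:
                side = frozenset(set(labels) - side)
            out[side] = out.get(side, 0.0) + data["weight"]
    return out


class TestNJ:
    def test_four_taxon_additive_example(self):
        labels = ["A", "B", "C", "D"]
        d = [[0, 0.2, 0.3, 0.35],
             [0.2, 0, 0.3, 0.35],
             [0.3, 0.3, 0, 0.35],
             [0.35, 0.35, 0.35, 0]]
        tree = nj(dmat(labels, d))
        splits = tree.splits()
        assert splits == {tree.canonical(frozenset({"A", "B"}))}
        lengths = tree.split_lengths()
        assert lengths[tree.canonical(frozenset({"A", "B"}))] == pytest.approx(0.05)
        assert lengths[tree.canonical(frozenset({"A"}))] == pytest.approx(0.1)
        assert lengths[tree.canonical(frozenset({"C"}))] == pytest.approx(0.15)
        assert lengths[tree.canonical(frozenset({"D"}))] == pytest.approx(0.2)

    def test_three_taxa_closed_form(self):
        d = [[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]]
        tree = nj(dmat(["a", "b", "c"], d))
        lengths = tree.split_lengths()
        assert lengths[tree.canonical(frozenset({"a"}))] == pytest.approx(0.1)
        assert lengths[tree.canonical(frozenset({"b"}))] == pytest.approx(0.2)
        assert lengths[tree.canonical(frozenset({"c"}))] == pytest.approx(0.4)

    def test_equal_distances_deterministic(self):
        d = np.full((4, 4), 0.1); np.fill_diagonal(d, 0)
        t1 = nj(dmat(list("abcd"), d))
        t2 = nj(dmat(list("abcd"), d))
        assert t1.newick() == t2.newick()

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(TreeError):
            nj(dmat(["a", "b"], [[0, 1], [1, 0]]))

    def test_undefined_distance_rejected(self):
        d = np.array([[0, np.nan, 1.0], [np.nan, 0, 1], [1, 1, 0]])
        with pytest.raises(TreeError):
            nj(dmat(list("abc"), d))

    def test_additive_matrices_recovered_exactly(self):
        rng = np.random.default_rng(99)
        for _ in range(25):
            n = int(rng.integers(4, 9))
            labels, d, g = random_additive_tree(n, rng)
            tree = nj(dmat(labels, d))
            truth = tree_split_lengths_from_graph(g, labels)
            mine = tree.split_lengths()
            assert set(mine) == set(truth)
            for split, length in truth.items():
                assert mine[split] == pytest.approx(length, abs=1e-9)

    def test_leaf_permutation_invariance(self):
        rng = np.random.default_rng(123)
        labels, d, _ = random_additive_tree(6, rng)
        t1 = nj(dmat(labels, d))
        perm = rng.permutation(6)
        t2 = nj(dmat([labels[k] for k in perm], d[np.ix_(perm, perm)]))
        assert t1.splits() == t2.splits()

    def test_agrees_with_dendropy_nj(self):
        import dendropy

        rng = np.random.default_rng(17)
        labels, d, _ = random_additive_tree(7, rng)
        mine = nj(dmat(labels, d))
        header = "," + ",".join(labels)
        rows = [f"{labels[i]}," + ",".join(f"{d[i, j]:.10f}" for j in range(7))
                for i in range(7)]
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=io.StringIO(header + "\n" + "\n".join(rows)), delimiter=",")
        their = pdm.nj_tree()
        their.encode_bipartitions()
        their_splits = set()
        all_lab = set(labels)
        first = min(labels)
        for edge in their.preorder_edge_iter():
            node = edge.head_node
            side = frozenset(l.taxon.label for l in node.leaf_iter())
            if 1 < len(side) < len(labels) - 1:
                if first in side:
                    side = frozenset(all_lab - side)
                their_splits.add(side)
        assert mine.splits() == their_splits


def two_clade_alignment(rng, n_per=4, length=400, inter=0.10):
    """Two clearly separated clades: identical within, divergent between."""
    base = rng.choice(list("ACGT"), size=length)
    other = base.copy()
    mut = rng.random(length) < inter
    repl = rng.choice(list("ACGT"), size=int(mut.sum()))
    other[mut] = repl
    rows, ids, species = [], [], {}
    for i in range(n_per):
        ids.append(f"x{i}"); rows.append("".join(base)); species[f"x{i}"] = "X"
    for i in range(n_per):
        ids.append(f"y{i}"); rows.append("".join(other)); species[f"y{i}"] = "Y"
    return LabeledAlignment(ids=ids, rows=rows, species_of=species), species


class TestBootstrap:
    def test_separated_clades_get_high_support(self):
        rng = np.random.default_rng(8)
        aln, species = two_clade_alignment(rng)
        tree, dropped = bootstrap_support(aln, replicates=100, seed=5)
        assert dropped == 0
        supports = tree.support_of()
        clade = tree.canonical(frozenset({"x0", "x1", "x2", "x3"}))
        assert clade in supports
        assert supports[clade] >= 99

    def test_single_replicate_supports_are_binary(self):
        rng = np.random.default_rng(9)
        aln, _ = two_clade_alignment(rng, n_per=3, length=200)
        tree, _ = bootstrap_support(aln, replicates=1, seed=3)
        vals = {v for v in tree.support_of().values() if v is not None}
        assert vals <= {0, 100}

    def test_same_seed_reproduces_supports(self):
        rng = np.random.default_rng(10)
        aln, _ = two_clade_alignment(rng, n_per=3, length=200, inter=0.05)
        t1, _ = bootstrap_support(aln, replicates=50, seed=21)
        t2, _ = bootstrap_support(aln, replicates=50, seed=21)
        assert t1.support_of() == t2.support_of()


class TestMonophyly:
    def test_species_clusters_detected(self):
        rng = np.random.default_rng(12)
        aln, species = two_clade_alignment(rng)
        tree = nj(distance_matrix(aln))
        assert species_monophyly_check(tree, species) == {"X": True, "Y": True}

    def test_single_leaf_species_true_by_convention(self):
        rng = np.random.default_rng(13)
        aln, species = two_clade_alignment(rng, n_per=3)
        species = dict(species)
        species["x0"] = "Z"  # split one leaf into its own species
        tree = nj(distance_matrix(aln))
        assert species_monophyly_check(tree, species)["Z"] is True

    def test_mixed_cluster_fails_monophyly(self):
        # species whose members sit in both clades cannot form a clade
        rng = np.random.default_rng(14)
        aln, species = two_clade_alignment(rng)
        mixed = dict(species)
        mixed["x0"], mixed["y0"] = "M", "M"
        tree = nj(distance_matrix(aln))
        assert species_monophyly_check(tree, mixed)["M"] is False
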