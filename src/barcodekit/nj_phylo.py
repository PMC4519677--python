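"""Neighbor-joining trees with nonparametric bootstrap support.

The Saitou-Nei agglomeration with the standard Q-criterion: exact on
additive matrices, deterministic under ties (the pair whose sorted
representative labels are lexicographically smallest wins).  Negative
branch-length estimates are clamped to zero with the deficit transferred to
the sister branch, the conventional remedy.  Bootstrap support values are
the percentage of column-resampled replicate trees containing each
bipartition of the point-estimate tree; replicates with saturated distances
are dropped and counted.

Trees are held in a light local structure; :meth:`PhyloTree.to_dendropy`
bridges to dendropy for interoperability and Newick parsing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .distances import DistanceMatrix, k2p_matrix_from_pq, _encode_rows, _pairwise_pq
from .errors import TreeError
from .seqio import LabeledAlignment

Split = frozenset  # canonical bipartition side (the side without the first label)


@dataclass
class _Node:
    label: str | None = None
    children: list[tuple["_Node", float]] = field(default_factory=list)
    support: int | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """Unrooted tree: a degree-3 (or higher) root node over labelled leaves."""

    root: _Node
    labels: list[str]

    # -- structure queries ---------------------------------------------------

    def _leafset(self, node: _Node, cache: dict[int, frozenset]) -> frozenset:
        if id(node) in cache:
            return cache[id(node)]
        if node.is_leaf:
            s = frozenset([node.label])
        else:
            s = frozenset().union(*(self._leafset(c, cache) for c, _ in node.children))
        cache[id(node)] = s
        return s

    def canonical(self, side: frozenset) -> Split:
        """Canonical form of a bipartition: the side NOT containing the
        lexicographically first leaf label."""
        first = min(self.labels)
        return Split(set(self.labels) - side) if first in side else Split(side)

    def splits(self, trivial: bool = False) -> set[Split]:
        """Bipartitions induced by edges; nontrivial only unless asked."""
        out: set[Split] = set()
        cache: dict[int, frozenset] = {}

        def walk(node: _Node) -> None:
            for child, _ in node.children:
                side = self._leafset(child, cache)
                if trivial or 1 < len(side) < len(self.labels) - 1:
                    out.add(self.canonical(side))
                walk(child)

        walk(self.root)
        return out

    def split_lengths(self) -> dict[Split, float]:
        """Branch length of every edge, keyed by canonical bipartition
        (leaf edges included, keyed by their singleton side's canonical form)."""
        out: dict[Split, float] = {}
        cache: dict[int, frozenset] = {}

        def walk(node: _Node) -> None:
            for child, bl in node.children:
                side = self._leafset(child, cache)
                key = self.canonical(side)
                out[key] = out.get(key, 0.0) + bl
                walk(child)

        walk(self.root)
        return out

    def support_of(self) -> dict[Split, int | None]:
        out: dict[Split, int | None] = {}
        cache: dict[int, frozenset] = {}

        def walk(node: _Node) -> None:
            for child, _ in node.children:
                side = self._leafset(child, cache)
                if 1 < len(side) < len(self.labels) - 1:
                    out[self.canonical(side)] = child.support
                walk(child)

        walk(self.root)
        return out

    # -- serialization -------------------------------------------------------

    def newick(self, decimals: int = 6, min_support: int | None = None) -> str:
        """Newick string with branch lengths and integer support labels.

        ``min_support`` suppresses supports below a display threshold (they
        remain available programmatically).
        """

        def render(node: _Node, bl: float | None) -> str:
            if node.is_leaf:
                body = node.label or ""
            else:
                inner = ",".join(render(c, l) for c, l in node.children)
                sup = ""
                if node.support is not None and (
                    min_support is None or node.support >= min_support
                ):
                    sup = str(int(node.support))
                body = f"({inner}){sup}"
            if bl is None:
                return body
            return f"{body}:{bl:.{decimals}f}"

        inner = ",".join(render(c, l) for c, l in self.root.children)
        return f"({inner});"

    def to_dendropy(self):
        import dendropy

        return dendropy.Tree.get(data=self.newick(decimals=12), schema="newick")


def _pair_tiebreak_key(reps: list[str], i: int, j: int) -> tuple[str, str]:
    return tuple(sorted((reps[i], reps[j])))  # type: ignore[return-value]


def nj(matrix: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Exact (topology and branch lengths) on additive matrices; requires at
    least 3 labels and no undefined distances.
    """
    n = len(matrix.labels)
    if n < 3:
        raise TreeError("neighbor joining needs at least 3 taxa")
    if np.isnan(matrix.d).any():
        raise TreeError("matrix contains undefined distances")
    d = matrix.d.astype(float).copy()
    nodes: list[_Node] = [_Node(label=l) for l in matrix.labels]
    reps: list[str] = list(matrix.labels)  # smallest leaf label per cluster

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best: tuple[str, str] | None = None
        bi = bj = -1
        for i in range(m):
            for j in range(i + 1, m):
                if q[i, j] <= qmin + 1e-12:
                    key = _pair_tiebreak_key(reps, i, j)
                    if best is None or key < best:
                        best, bi, bj = key, i, j
        i, j = bi, bj
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp negatives, transferring the deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        dnew = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.empty((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = dnew[keep]
        d2[:-1, -1] = dnew[keep]
        d2[-1, -1] = 0.0
        d = d2
        new_rep = min(reps[i], reps[j])
        nodes = [nodes[k] for k in keep] + [new]
        reps = [reps[k] for k in keep] + [new_rep]

    # closed-form join of the final three clusters at an unrooted center
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    lens = [max(x, 0.0) for x in (la, lb, lc)]
    root = _Node(children=[(nodes[0], lens[0]), (nodes[1], lens[1]),
                           (nodes[2], lens[2])])
    return PhyloTree(root=root, labels=list(matrix.labels))


def bootstrap_support(aln: LabeledAlignment, replicates: int = 1000,
                      seed: int | None = None, model: str = "K2P"
                      ) -> tuple[PhyloTree, int]:
    """NJ tree of the full alignment with bootstrap supports attached.

    Alignment columns are resampled with replacement per replicate; each
    replicate's K2P + NJ tree contributes its bipartitions.  Support of an
    internal edge of the point-estimate tree is the percentage (rounded to
    the nearest integer) of successful replicates containing that
    bipartition.  Returns (tree, number_of_dropped_replicates).
    """
    from .distances import distance_matrix

    if len(aln) < 3:
        raise TreeError("bootstrap needs at least 3 rows")
    if replicates < 1:
        raise TreeError("replicates must be >= 1")
    point = nj(distance_matrix(aln, model=model))
    target_splits = point.splits()
    counts = {s: 0 for s in target_splits}
    rng = np.random.default_rng(seed)
    enc = _encode_rows(aln.rows)
    ncol = enc.shape[1]
    dropped = 0
    for _ in range(replicates):
        cols = rng.integers(0, ncol, size=ncol)
        sub = enc[:, cols]
        P, Q, nmat = _pairwise_pq(sub)
        if model == "K2P":
            dmat = k2p_matrix_from_pq(P, Q)
        else:
            dmat = P + Q
        np.fill_diagonal(dmat, 0.0)
        if np.isnan(dmat).any():
            dropped += 1
            continue
        rep_tree = nj(DistanceMatrix(labels=list(aln.ids), d=dmat,
                                     sites_used=nmat, model=model))
        for s in rep_tree.splits() & target_splits:
            counts[s] += 1
    ok = replicates - dropped
    if dropped:
        warnings.warn(f"{dropped} bootstrap replicate(s) dropped (saturation)")
    if ok == 0:
        raise TreeError("all bootstrap replicates were saturated")

    support = {s: round(100.0 * c / ok) for s, c in counts.items()}
    cache: dict[int, frozenset] = {}

    def annotate(node: _Node) -> None:
        for child, _ in node.children:
            side = point._leafset(child, cache)
            if 1 < len(side) < len(point.labels) - 1:
                child.support = support[point.canonical(side)]
            annotate(child)

    annotate(point.root)
    return point, dropped


def species_monophyly_check(tree: PhyloTree, species_of: Mapping[str, str]
                            ) -> dict[str, bool]:
    """True for a species iff its leaves form a clade on some rooting,
    i.e. a bipartition separates exactly that species.  Single-leaf species
    are monophyletic by convention."""
    splits = tree.splits(trivial=True)
    all_leaves = set(tree.labels)
    by_species: dict[str, set[str]] = {}
    for leaf in tree.labels:
        by_species.setdefault(species_of[leaf], set()).add(leaf)
    out = {}
    for sp, leaves in by_species.items():
        if len(leaves) <= 1 or leaves == all_leaves:
            out[sp] = True
        else:
            out[sp] = tree.canonical(frozenset(leaves)) in splits
    return out
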