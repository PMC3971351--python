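"""Parsimony lineage reconstruction from ternary fingerprint characters.

Cell types are taxa; each pathway's consensus ternary score is one character
with states {-1, 0, +1}. Tree length is scored by Sankoff dynamic
programming under a symmetric cost matrix, by default the absolute score
difference cost(a, b) = |a - b| (so a -1 <-> +1 change costs two one-step
changes). The maximum-parsimony tree is sought by nearest-neighbor
interchange (NNI) hill-climbing from a neighbor-joining start tree, and edge
support is estimated by the nonparametric bootstrap over characters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "CharacterMatrix",
    "StateCostMatrix",
    "Tree",
    "Phylogeny",
    "sankoff_score",
    "parsimony_search",
    "bootstrap_support",
    "robinson_foulds",
    "nj_start_tree",
    "read_newick",
    "write_newick",
]

STATES = (-1, 0, 1)


@dataclass
class CharacterMatrix:
    """Taxa-by-characters ternary matrix (e.g. consensus fingerprints at t=0.75)."""

    data: pd.DataFrame  # taxa x characters, entries in {-1,0,1}

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("taxa names must be unique")
        if self.data.shape[0] < 3:
            raise ValueError("need at least 3 taxa")
        vals = self.data.to_numpy()
        if not np.isin(vals, STATES).all():
            raise ValueError("character states must be -1, 0, or +1")

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_characters(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class StateCostMatrix:
    """Symmetric substitution costs between ternary states, zero on the diagonal."""

    costs: np.ndarray  # 3x3, indexed by state + 1

    def __post_init__(self) -> None:
        c = np.asarray(self.costs, dtype=float)
        object.__setattr__(self, "costs", c)
        if c.shape != (3, 3):
            raise ValueError("cost matrix must be 3x3")
        if not np.allclose(np.diag(c), 0):
            raise ValueError("cost matrix diagonal must be zero")
        if not np.allclose(c, c.T):
            raise ValueError("cost matrix must be symmetric")
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    if c[i, j] > c[i, k] + c[k, j] + 1e-12:
                        raise ValueError("cost matrix violates the triangle inequality")

    @classmethod
    def difference(cls) -> "StateCostMatrix":
        """cost(a, b) = |a - b|: the fingerprint score-difference cost."""
        s = np.array(STATES, dtype=float)
        return cls(np.abs(s[:, None] - s[None, :]))

    def cost(self, a: int, b: int) -> float:
        return float(self.costs[a + 1, b + 1])


class Tree:
    """Unrooted tree as an undirected adjacency structure with labeled leaves.

    Internal nodes of binary trees have degree 3; this class only supports
    what the parsimony machinery needs (copying, splits, NNI, traversal).
    """

    def __init__(self) -> None:
        self.adj: dict[int, set[int]] = {}
        self.labels: dict[int, str] = {}  # leaf node -> taxon name
        self._next = 0

    # -- construction -------------------------------------------------------

    def _new_node(self, label: str | None = None) -> int:
        nid = self._next
        self._next += 1
        self.adj[nid] = set()
        if label is not None:
            self.labels[nid] = label
        return nid

    def _link(self, a: int, b: int) -> None:
        self.adj[a].add(b)
        self.adj[b].add(a)

    def _unlink(self, a: int, b: int) -> None:
        self.adj[a].discard(b)
        self.adj[b].discard(a)

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        """Build from a newick string (parsed by dendropy); unroots degree-2 nodes."""
        dt = dendropy.Tree.get(data=newick, schema="newick")
        t = cls()
        node_id: dict[object, int] = {}
        for nd in dt.preorder_node_iter():
            label = nd.taxon.label if nd.taxon is not None else None
            node_id[nd] = t._new_node(label)
            if nd.parent_node is not None:
                t._link(node_id[nd.parent_node], node_id[nd])
        t._suppress_degree_two()
        return t

    def _suppress_degree_two(self) -> None:
        for nid in list(self.adj):
            if nid not in self.labels and len(self.adj[nid]) == 2:
                a, b = sorted(self.adj[nid])
                self._unlink(nid, a)
                self._unlink(nid, b)
                del self.adj[nid]
                self._link(a, b)

    def copy(self) -> "Tree":
        t = Tree()
        t.adj = {k: set(v) for k, v in self.adj.items()}
        t.labels = dict(self.labels)
        t._next = self._next
        return t

    # -- queries ------------------------------------------------------------

    @property
    def leaves(self) -> list[int]:
        return sorted(self.labels)

    @property
    def taxa(self) -> list[str]:
        return sorted(self.labels.values())

    def internal_edges(self) -> list[tuple[int, int]]:
        """Edges with both endpoints internal (the NNI-eligible edges), sorted."""
        out = []
        for u in sorted(self.adj):
            for v in sorted(self.adj[u]):
                if u < v and u not in self.labels and v not in self.labels:
                    out.append((u, v))
        return out

    def _side_leaves(self, u: int, v: int) -> frozenset[str]:
        """Taxa on v's side of the edge (u, v)."""
        seen = {u, v}
        stack = [v]
        out = []
        while stack:
            n = stack.pop()
            if n in self.labels:
                out.append(self.labels[n])
            for m in self.adj[n]:
                if m not in seen:
                    seen.add(m)
                    stack.append(m)
        return frozenset(out)

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each canonicalized as the side without the
        lexicographically smallest taxon."""
        ref = min(self.taxa)
        out: set[frozenset[str]] = set()
        for u, v in self.internal_edges():
            side = self._side_leaves(u, v)
            if ref in side:
                side = frozenset(self.taxa) - side
            if 2 <= len(side) <= len(self.taxa) - 2:
                out.add(side)
        return out

    # -- rearrangement ------------------------------------------------------

    def nni_neighbors(self) -> list["Tree"]:
        """All trees one nearest-neighbor interchange away, in a fixed order."""
        out = []
        for u, v in self.internal_edges():
            a, b = sorted(self.adj[u] - {v})
            c, d = sorted(self.adj[v] - {u})
            for x, y in ((a, c), (a, d)):  # the two distinct swaps across (u, v)
                t = self.copy()
                t._unlink(u, x)
                t._unlink(v, y)
                t._link(v, x)
                t._link(u, y)
                out.append(t)
        return out

    # -- newick -------------------------------------------------------------

    def to_newick(self, supports: dict[frozenset[str], float] | None = None) -> str:
        """Newick string rooted at an arbitrary internal node; bootstrap
        supports, if given, become internal node labels."""
        internals = [n for n in sorted(self.adj) if n not in self.labels]
        root = internals[0] if internals else min(self.adj)
        ref = min(self.taxa)
        all_taxa = frozenset(self.taxa)

        def render(node: int, parent: int | None) -> str:
            if node in self.labels:
                return self.labels[node]
            parts = [render(c, node) for c in sorted(self.adj[node]) if c != parent]
            label = ""
            if supports is not None and parent is not None:
                side = self._side_leaves(parent, node)
                key = side if ref not in side else all_taxa - side
                if key in supports:
                    label = f"{supports[key]:g}"
            return "(" + ",".join(parts) + ")" + label

        return render(root, None) + ";"


@dataclass
class Phylogeny:
    """A point-estimate tree, its parsimony score, and optional edge supports."""

    tree: Tree
    score: float
    supports: dict[frozenset[str], float] | None = None


def _state_codes(cm: CharacterMatrix) -> dict[str, np.ndarray]:
    return {t: cm.data.loc[t].to_numpy() + 1 for t in cm.taxa}


def sankoff_score(
    tree: Tree, cm: CharacterMatrix, costs: StateCostMatrix | None = None
) -> float:
    """Exact minimum total substitution cost of the data on the tree.

    Bottom-up dynamic programming over all internal state assignments,
    vectorized across characters; rooting is arbitrary because the cost
    matrix is symmetric.
    """
    if costs is None:
        costs = StateCostMatrix.difference()
    if set(tree.taxa) != set(cm.taxa):
        raise ValueError("tree leaves do not match the character matrix taxa")
    codes = _state_codes(cm)
    n_chars = cm.n_characters
    c = costs.costs

    internals = [n for n in sorted(tree.adj) if n not in tree.labels]
    root = internals[0] if internals else min(tree.adj)

    # iterative postorder
    order: list[tuple[int, int | None]] = []
    stack: list[tuple[int, int | None]] = [(root, None)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        for child in sorted(tree.adj[node]):
            if child != parent:
                stack.append((child, node))

    table: dict[int, np.ndarray] = {}
    for node, parent in reversed(order):
        if node in tree.labels:
            m = np.full((3, n_chars), np.inf)
            m[codes[tree.labels[node]], np.arange(n_chars)] = 0.0
        else:
            m = np.zeros((3, n_chars))
        for child in sorted(tree.adj[node]):
            if child != parent:
                m = m + (c[:, :, None] + table[child][None, :, :]).min(axis=1)
                del table[child]
        table[node] = m
    return float(table[root].min(axis=0).sum())


def nj_start_tree(cm: CharacterMatrix) -> Tree:
    """Neighbor-joining tree on normalized Manhattan distances between taxa.

    A data-informed, deterministic starting point for the NNI search.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    x = cm.data.to_numpy(dtype=float)
    d = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2) / (2 * cm.n_characters)
    np.fill_diagonal(d, 0.0)
    sk = nj(DistanceMatrix(d, ids=cm.taxa))
    return Tree.from_newick(str(sk))


def parsimony_search(
    cm: CharacterMatrix,
    costs: StateCostMatrix | None = None,
    seed: int = 0,
    start: Tree | None = None,
) -> Phylogeny:
    """NNI hill-climb to a local maximum-parsimony tree.

    From the NJ start (or ``start``), all NNI neighbors are evaluated in a
    fixed edge order and the first strict improvement is accepted, repeating
    until none improves. Fully deterministic; ``seed`` is accepted for
    interface symmetry with the stochastic operations.
    """
    if len(cm.taxa) < 4:
        raise ValueError("NNI search needs at least 4 taxa")
    if costs is None:
        costs = StateCostMatrix.difference()
    tree = (start or nj_start_tree(cm)).copy()
    score = sankoff_score(tree, cm, costs)
    improved = True
    while improved:
        improved = False
        for cand in tree.nni_neighbors():
            s = sankoff_score(cand, cm, costs)
            if s < score:
                tree, score = cand, s
                improved = True
                break
    return Phylogeny(tree=tree, score=score)


def bootstrap_support(
    cm: CharacterMatrix,
    costs: StateCostMatrix | None = None,
    n_reps: int = 100,
    seed: int = 0,
) -> Phylogeny:
    """Nonparametric bootstrap over characters (pathways).

    Characters are resampled with replacement, the parsimony search re-run
    per replicate, and each internal edge of the point-estimate tree gets the
    fraction of replicate trees containing its bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    point = parsimony_search(cm, costs=costs, seed=seed)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {s: 0 for s in point.tree.splits()}
    for _ in range(n_reps):
        cols = rng.integers(0, cm.n_characters, size=cm.n_characters)
        resampled = cm.data.iloc[:, cols]
        resampled.columns = [f"c{i}" for i in range(cm.n_characters)]
        rep = parsimony_search(CharacterMatrix(resampled), costs=costs, seed=seed)
        rep_splits = rep.tree.splits()
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    supports = {s: n / n_reps for s, n in counts.items()}
    return Phylogeny(tree=point.tree, score=point.score, supports=supports)


def robinson_foulds(a: Tree, b: Tree) -> int:
    """Symmetric-difference (Robinson-Foulds) distance between two unrooted trees."""
    if set(a.taxa) != set(b.taxa):
        raise ValueError("trees are over different taxa")
    return len(a.splits() ^ b.splits())


def read_newick(path: str | Path) -> Tree:
    with open(path) as fh:
        return Tree.from_newick(fh.read())


def write_newick(phy: Phylogeny | Tree, path: str | Path) -> None:
    if isinstance(phy, Tree):
        newick = phy.to_newick()
    else:
        newick = phy.tree.to_newick(supports=phy.supports)
    with open(path, "w") as fh:
        fh.write(newick + "\n")
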