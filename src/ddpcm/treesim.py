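"""Rooted phylogenies: Newick I/O, node heights, and stochastic tree simulation.

The in-memory :class:`Tree` is a flat, array-based structure (parent pointers,
edge lengths, postorder) optimized for repeated likelihood evaluation.  Newick
reading and writing are delegated to :mod:`dendropy`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Tree",
    "parse_newick",
    "write_newick",
    "node_heights",
    "simulate_pure_birth",
    "make_nonultrametric",
]


class TreeError(ValueError):
    """Raised for malformed or invalid phylogenies."""


@dataclass
class Tree:
    """A rooted phylogeny with branch lengths.

    Nodes are integer ids ``0 .. n_nodes-1``.  ``parent[i]`` is the parent id
    of node ``i`` (``-1`` for the root); ``edge_length[i]`` is the length of
    the branch subtending node ``i`` (0 for the root).  ``labels[i]`` is the
    taxon label for tips and ``None`` for unlabeled internal nodes.
    """

    parent: np.ndarray
    edge_length: np.ndarray
    labels: list
    root: int
    _children: list = field(default=None, repr=False, compare=False)
    _postorder: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.edge_length = np.asarray(self.edge_length, dtype=float)
        n = self.parent.size
        if self.edge_length.size != n or len(self.labels) != n:
            raise TreeError("parent, edge_length and labels must have equal size")
        if (self.parent == -1).sum() != 1 or self.parent[self.root] != -1:
            raise TreeError("tree must have exactly one root")
        nonroot = np.arange(n) != self.root
        if np.any(~np.isfinite(self.edge_length[nonroot])):
            raise TreeError("all non-root nodes need finite branch lengths")
        if np.any(self.edge_length[nonroot] < 0):
            raise TreeError("negative branch length")
        tips = self.tip_ids
        names = [self.labels[i] for i in tips]
        if any(l is None for l in names):
            raise TreeError("every tip must be labeled")
        if len(set(names)) != len(names):
            raise TreeError("duplicate tip labels")

    # -- derived structure -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def children(self) -> list:
        if self._children is None:
            ch = [[] for _ in range(self.n_nodes)]
            for i, p in enumerate(self.parent):
                if p >= 0:
                    ch[p].append(i)
            self._children = ch
        return self._children

    @property
    def tip_ids(self) -> np.ndarray:
        has_child = np.zeros(self.n_nodes, dtype=bool)
        has_child[self.parent[self.parent >= 0]] = True
        return np.flatnonzero(~has_child)

    @property
    def tip_labels(self) -> list:
        return [self.labels[i] for i in self.tip_ids]

    @property
    def n_tips(self) -> int:
        return self.tip_ids.size

    @property
    def postorder(self) -> np.ndarray:
        """Node ids ordered so every child precedes its parent."""
        if self._postorder is None:
            order, stack = [], [self.root]
            while stack:
                node = stack.pop()
                order.append(node)
                stack.extend(self.children[node])
            self._postorder = np.array(order[::-1], dtype=np.int64)
        return self._postorder

    def heights(self) -> np.ndarray:
        """Height above the root of every node (root has height 0)."""
        h = np.zeros(self.n_nodes)
        for node in self.postorder[::-1]:  # preorder
            p = self.parent[node]
            if p >= 0:
                h[node] = h[p] + self.edge_length[node]
        return h

    @property
    def depth(self) -> float:
        return float(self.heights().max())

    def is_ultrametric(self, tol: float = 1e-8) -> bool:
        th = self.heights()[self.tip_ids]
        return bool(np.ptp(th) <= tol * max(1.0, th.max()))

    def tip_index(self) -> dict:
        """Map taxon label -> row index in ``tip_ids`` order."""
        return {self.labels[t]: j for j, t in enumerate(self.tip_ids)}

    def rescaled(self, factor: float) -> "Tree":
        el = self.edge_length * factor
        el[self.root] = 0.0
        return Tree(self.parent.copy(), el, list(self.labels), self.root)

    def copy(self) -> "Tree":
        return Tree(self.parent.copy(), self.edge_length.copy(), list(self.labels), self.root)

    def mrca(self, i: int, j: int) -> int:
        anc = set()
        a = i
        while a >= 0:
            anc.add(a)
            a = self.parent[a]
        b = j
        while b not in anc:
            b = self.parent[b]
        return b


# -- Newick I/O ------------------------------------------------------------

def _from_dendropy(dtree: dendropy.Tree) -> Tree:
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, -1, dtype=np.int64)
    elen = np.zeros(n)
    labels = [None] * n
    for i, nd in enumerate(nodes):
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                raise TreeError("branch lengths are required")
            elen[i] = float(nd.edge.length)
        if nd.taxon is not None:
            labels[i] = nd.taxon.label
        elif nd.is_leaf():
            raise TreeError("unlabeled tip in Newick string")
    return Tree(parent, elen, labels, root=0)


def parse_newick(text: str) -> Tree:
    """Parse a Newick string (branch lengths required) into a :class:`Tree`."""
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises various parse errors
        raise TreeError(f"malformed Newick: {exc}") from exc
    return _from_dendropy(dtree)


def write_newick(tree: Tree) -> str:
    """Serialize a :class:`Tree` to a Newick string with branch lengths."""
    taxa = dendropy.TaxonNamespace()
    dnodes = [dendropy.Node() for _ in range(tree.n_nodes)]
    for i in range(tree.n_nodes):
        p = tree.parent[i]
        if p >= 0:
            dnodes[p].add_child(dnodes[i])
            dnodes[i].edge.length = float(tree.edge_length[i])
        if tree.labels[i] is not None:
            dnodes[i].taxon = taxa.new_taxon(tree.labels[i])
    dtree = dendropy.Tree(taxon_namespace=taxa)
    dtree.seed_node = dnodes[tree.root]
    out = io.StringIO()
    dtree.write(file=out, schema="newick", suppress_rooting=True,
                unquoted_underscores=True, real_value_format_specifier=".12g")
    return out.getvalue().strip()


def node_heights(tree: Tree) -> np.ndarray:
    """Per-node height above the root (time units); see :meth:`Tree.heights`."""
    return tree.heights()


# -- simulation ------------------------------------------------------------

def simulate_pure_birth(n_taxa: int, depth: float, seed=None) -> Tree:
    """Simulate a pure-birth (Yule) tree and rescale it to a fixed total depth.

    Lineages split at unit rate; growth stops at ``n_taxa`` tips, a final
    waiting time is appended so tips do not end exactly at a speciation event,
    and all branches are rescaled multiplicatively so every root-to-tip path
    equals ``depth``.
    """
    if n_taxa < 2:
        raise TreeError("need at least 2 taxa")
    if depth <= 0:
        raise TreeError("depth must be positive")
    rng = np.random.default_rng(seed)
    parent = [-1, 0, 0]
    birth = [0.0, 0.0, 0.0]  # time at which the node's branch began
    active = [1, 2]
    t = 0.0
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / k)
        j = active.pop(rng.integers(k))
        for _ in range(2):
            parent.append(j)
            birth.append(t)
            active.append(len(parent) - 1)
    t += rng.exponential(1.0 / n_taxa)

    n = len(parent)
    elen = np.zeros(n)
    end = np.full(n, t)
    is_tip = np.ones(n, dtype=bool)
    for i in range(1, n):
        is_tip[parent[i]] = False
    for i in range(1, n):
        child_births = [birth[j] for j in range(n) if parent[j] == i]
        end[i] = child_births[0] if child_births else t
        elen[i] = end[i] - birth[i]
    labels = [None] * n
    tip_no = 1
    for i in range(n):
        if is_tip[i]:
            labels[i] = f"t{tip_no}"
            tip_no += 1
    tree = Tree(np.array(parent), elen, labels, root=0)
    return tree.rescaled(depth / tree.depth)


def make_nonultrametric(tree: Tree, seed=None, max_fraction: float = 0.5) -> Tree:
    """Shorten terminal branches at random so tip heights vary.

    Each terminal edge is shortened by ``U(0, max_fraction) * length``; the
    whole tree is then rescaled so the maximum tip height equals the original
    depth.  The transform is a pragmatic stand-in for an unspecified sampling
    process; the shortening distribution is exposed via ``max_fraction``.
    """
    if not tree.is_ultrametric():
        raise TreeError("input must be ultrametric")
    if not 0 <= max_fraction < 1:
        raise TreeError("max_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out = tree.copy()
    depth0 = tree.depth
    for i in out.tip_ids:
        out.edge_length[i] *= 1.0 - rng.uniform(0.0, max_fraction)
    out = Tree(out.parent, out.edge_length, out.labels, out.root)
    if max_fraction > 0:
        out = out.rescaled(depth0 / out.depth)
    return out
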