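"""Unrooted bifurcating tree topologies: container, I/O, enumeration, distances.

The central object is :class:`TreeTopology`, an unrooted leaf-labelled tree in
which every internal node has degree 3 and every leaf degree 1.  Branch
lengths are deliberately absent -- the models in this package are over
topologies only.  Leaves carry species names and a total order (by default
lexicographic on the names); the order is what makes the integer codec in
:mod:`treevae.codec` well defined.

Newick/Nexus reading and writing is delegated to dendropy; everything that
needs direct adjacency access (splits, distances, enumeration) runs on the
package's own adjacency-dict representation.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np

__all__ = [
    "TreeTopology",
    "TreeCollection",
    "parse_trees",
    "write_trees",
    "enumerate_topologies",
    "same_topology",
    "rf_distance",
    "path_difference_distance",
    "num_topologies",
]


class TreeError(ValueError):
    """Raised for invalid tree structures or mismatched leaf sets."""


def num_topologies(n_leaves: int) -> int:
    """Number of unrooted bifurcating topologies on ``n_leaves`` labelled
    leaves: the double factorial (2N-5)!!."""
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    out = 1
    for k in range(3, n_leaves):
        out *= 2 * k - 3
    return out


@dataclass
class TreeTopology:
    """Unrooted bifurcating tree over labelled leaves.

    Parameters
    ----------
    adjacency:
        node id -> set of neighbouring node ids.  Leaves have degree 1,
        internal nodes degree 3.
    leaf_labels:
        leaf node id -> species name.  Must cover exactly the degree-1 nodes.
    leaf_order:
        optional explicit ordering of the species names (rank 1..N).  When
        omitted, names are ordered lexicographically.
    """

    adjacency: Dict[int, Set[int]]
    leaf_labels: Dict[int, str]
    leaf_order: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.adjacency = {u: set(vs) for u, vs in self.adjacency.items()}
        if self.leaf_order is None:
            self.leaf_order = sorted(self.leaf_labels.values())
        else:
            self.leaf_order = list(self.leaf_order)
            if sorted(self.leaf_order) != sorted(self.leaf_labels.values()):
                raise TreeError("leaf_order must be a permutation of the leaf labels")
        self._validate()

    # -- basic structure ---------------------------------------------------

    def _validate(self) -> None:
        n_leaf = len(self.leaf_labels)
        if n_leaf < 3:
            raise TreeError("a topology needs at least 3 leaves")
        if len(set(self.leaf_labels.values())) != n_leaf:
            raise TreeError("duplicate leaf labels")
        degs = {u: len(vs) for u, vs in self.adjacency.items()}
        for u, vs in self.adjacency.items():
            for v in vs:
                if u not in self.adjacency.get(v, ()):  # symmetry
                    raise TreeError(f"asymmetric adjacency at edge ({u},{v})")
        leaves = {u for u, d in degs.items() if d == 1}
        if leaves != set(self.leaf_labels):
            raise TreeError("leaf_labels must map exactly the degree-1 nodes")
        internal = set(degs) - leaves
        if any(degs[u] != 3 for u in internal):
            bad = [u for u in internal if degs[u] != 3]
            raise TreeError(f"internal nodes must have degree 3; offenders: {bad}")
        if len(internal) != n_leaf - 2:
            raise TreeError("wrong internal node count (tree disconnected or cyclic?)")
        n_edges = sum(degs.values()) // 2
        if n_edges != 2 * n_leaf - 3:
            raise TreeError("wrong edge count")
        # connectivity
        seen = {next(iter(self.adjacency))}
        stack = list(seen)
        while stack:
            u = stack.pop()
            for v in self.adjacency[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        if len(seen) != len(self.adjacency):
            raise TreeError("tree is disconnected")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def leaves(self) -> List[int]:
        """Leaf node ids in leaf_order (rank 1..N)."""
        by_label = {lab: u for u, lab in self.leaf_labels.items()}
        return [by_label[lab] for lab in self.leaf_order]

    @property
    def internal_nodes(self) -> List[int]:
        return sorted(u for u in self.adjacency if len(self.adjacency[u]) > 1)

    def leaf_rank(self, node: int) -> int:
        """1-based rank of a leaf node in leaf_order."""
        return self.leaves.index(node) + 1

    # -- splits ------------------------------------------------------------

    def splits(self) -> Set[int]:
        """Nontrivial splits as canonical leaf-rank bitmasks.

        Each internal edge induces a bipartition of the leaves; the side not
        containing rank-1 leaf x1 is encoded as a bitmask over ranks
        (bit i-1 = rank-i leaf).  Pendant edges (trivial splits) are skipped.
        """
        rank = {u: i for i, u in enumerate(self.leaves)}  # 0-based
        masks: Dict[Tuple[int, int], int] = {}

        # root at an arbitrary leaf; accumulate leaf masks bottom-up
        root = self.leaves[0]
        parent = {root: None}
        order = []
        dq = deque([root])
        while dq:
            u = dq.popleft()
            order.append(u)
            for v in self.adjacency[u]:
                if v != parent[u]:
                    parent[v] = u
                    dq.append(v)
        below = {u: (1 << rank[u]) if u in self.leaf_labels else 0 for u in order}
        for u in reversed(order):
            p = parent[u]
            if p is not None:
                below[p] = below.get(p, 0) | below[u]
        out: Set[int] = set()
        full = (1 << self.n_leaves) - 1
        for u in order:
            p = parent[u]
            if p is None or u in self.leaf_labels:
                continue
            m = below[u]
            comp = full & ~m
            if m & 1:  # canonical side excludes x1
                m = comp
            if bin(m).count("1") >= 2 and bin(full & ~m).count("1") >= 2:
                out.add(m)
        return out

    # -- serialization -----------------------------------------------------

    def to_newick(self) -> str:
        """Canonical unrooted Newick: traversal rooted at the internal node
        adjacent to the rank-1 leaf, trifurcating root, children ordered by
        smallest contained leaf rank (deterministic output)."""
        x1 = self.leaves[0]
        root = next(iter(self.adjacency[x1]))
        rank = {u: i for i, u in enumerate(self.leaves)}

        def min_rank(u: int, par: int) -> int:
            if u in self.leaf_labels:
                return rank[u]
            return min(min_rank(v, u) for v in self.adjacency[u] if v != par)

        def render(u: int, par: int) -> str:
            if u in self.leaf_labels:
                return self.leaf_labels[u]
            kids = sorted(
                (v for v in self.adjacency[u] if v != par),
                key=lambda v: min_rank(v, u),
            )
            return "(" + ",".join(render(v, u) for v in kids) + ")"

        kids = sorted(self.adjacency[root], key=lambda v: min_rank(v, root))
        return "(" + ",".join(render(v, root) for v in kids) + ");"

    @classmethod
    def from_newick(cls, newick: str, leaf_order: Optional[Sequence[str]] = None) -> "TreeTopology":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(tree, leaf_order=leaf_order)

    @classmethod
    def from_dendropy(cls, tree: "dendropy.Tree", leaf_order: Optional[Sequence[str]] = None) -> "TreeTopology":
        """Convert a dendropy tree, suppressing a bifurcating root if present."""
        tree = tree.clone(depth=1)
        # unroot: dendropy keeps a root node; collapse degree-2 root
        tree.is_rooted = False
        tree.suppress_unifurcations()
        if tree.seed_node.num_child_nodes() == 2:
            tree.collapse_basal_bifurcation()
        adjacency: Dict[int, Set[int]] = {}
        labels: Dict[int, str] = {}
        ids: Dict[object, int] = {}

        def nid(nd) -> int:
            if nd not in ids:
                ids[nd] = len(ids)
                adjacency[ids[nd]] = set()
            return ids[nd]

        for edge in tree.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            u, v = nid(edge.tail_node), nid(edge.head_node)
            adjacency[u].add(v)
            adjacency[v].add(u)
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None:
                raise TreeError("leaf without a taxon label")
            labels[nid(leaf)] = leaf.taxon.label
        for u, vs in adjacency.items():
            d = len(vs)
            if u not in labels and d != 3:
                raise TreeError(
                    f"multifurcation or unifurcation (internal degree {d}); "
                    "only bifurcating trees are supported"
                )
        return cls(adjacency, labels, leaf_order=leaf_order)

    def relabel_nodes(self, mapping: Dict[int, int]) -> "TreeTopology":
        """Return a structurally identical topology with node ids renamed."""
        adj = {mapping[u]: {mapping[v] for v in vs} for u, vs in self.adjacency.items()}
        labs = {mapping[u]: lab for u, lab in self.leaf_labels.items()}
        return TreeTopology(adj, labs, leaf_order=self.leaf_order)

    def __repr__(self) -> str:  # pragma: no cover
        return f"TreeTopology(N={self.n_leaves}, {self.to_newick()})"


@dataclass
class TreeCollection:
    """Weighted set of topologies sharing one leaf set: the data distribution.

    Duplicate topologies (by split-set identity) are merged on construction,
    their weights added; the total weight must be 1 within 1e-10.
    """

    items: List[Tuple[TreeTopology, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.items:
            return
        ref = self.items[0][0]
        merged: Dict[frozenset, int] = {}
        out: List[Tuple[TreeTopology, float]] = []
        for i, (t, w) in enumerate(self.items):
            if w < 0:
                raise TreeError(f"negative weight at item {i}")
            if set(t.leaf_order) != set(ref.leaf_order):
                raise TreeError(f"tree {i} has a different leaf set")
            key = frozenset(t.splits())
            if key in merged:
                j = merged[key]
                out[j] = (out[j][0], out[j][1] + w)
            else:
                merged[key] = len(out)
                out.append((t, w))
        total = sum(w for _, w in out)
        if abs(total - 1.0) > 1e-10:
            raise TreeError(f"weights sum to {total!r}, not 1")
        self.items = out

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    @property
    def topologies(self) -> List[TreeTopology]:
        return [t for t, _ in self.items]

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.items], dtype=float)

    @property
    def leaf_order(self) -> List[str]:
        return list(self.items[0][0].leaf_order)


# ---------------------------------------------------------------------------
# parsing / writing


def parse_trees(path: str, format: str = "newick", weights: Optional[str] = None) -> TreeCollection:
    """Read a multi-tree file into a weighted :class:`TreeCollection`.

    Without a weights file each unique topology is weighted by its frequency
    among the parsed trees.  A weights file is a two-column TSV
    (0-based tree index, weight).  Rooted inputs with a bifurcating root are
    silently unrooted.  Trees must all share one leaf label set.
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"unknown format {format!r}")
    tlist = dendropy.TreeList.get(path=path, schema=format)
    if len(tlist) == 0:
        return TreeCollection([])
    tops: List[TreeTopology] = []
    ref_labels: Optional[Set[str]] = None
    for i, t in enumerate(tlist):
        try:
            top = TreeTopology.from_dendropy(t)
        except TreeError as e:
            raise TreeError(f"tree {i}: {e}") from e
        if ref_labels is None:
            ref_labels = set(top.leaf_labels.values())
        elif set(top.leaf_labels.values()) != ref_labels:
            raise TreeError(f"tree {i} has leaf set differing from tree 0")
        tops.append(top)
    if weights is None:
        w = np.full(len(tops), 1.0 / len(tops))
    else:
        w = np.zeros(len(tops))
        with open(weights) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                idx_s, w_s = line.split("\t")
                w[int(idx_s)] = float(w_s)
        s = w.sum()
        if s <= 0:
            raise TreeError("weights file sums to zero")
        w = w / s
    return TreeCollection(list(zip(tops, w)))


def write_trees(collection: TreeCollection, path: str, weights_path: Optional[str] = None) -> None:
    """Write one canonical Newick per line; optionally a weight TSV."""
    with open(path, "w") as fh:
        for t, _ in collection:
            fh.write(t.to_newick() + "\n")
    if weights_path is not None:
        with open(weights_path, "w") as fh:
            for i, (_, w) in enumerate(collection):
                fh.write(f"{i}\t{float(w)!r}\n")


# ---------------------------------------------------------------------------
# enumeration


def enumerate_topologies(labels: Sequence[str]) -> List[TreeTopology]:
    """All distinct unrooted bifurcating topologies on the given leaves.

    Generated by recursive leaf insertion in leaf order: the k-th leaf is
    attached to every edge of every (k-1)-leaf tree, which yields each
    topology exactly once ((2N-5)!! in total).  Edges are visited in a fixed
    canonical order so the output index of a topology is stable.
    """
    labels = list(labels)
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 leaves")
    if n > 9:
        raise ValueError(
            f"refusing to enumerate N={n}: (2N-5)!! = {num_topologies(n)} topologies"
        )
    order = sorted(labels)
    # edge-list representation during recursion; leaves 0..n-1 in sorted order,
    # internal nodes numbered from n upward in creation order.
    base_edges = [(0, n), (1, n), (2, n)]
    states = [base_edges]
    next_internal = n + 1
    for k in range(3, n):
        new_states = []
        for edges in states:
            for j in range(len(edges)):
                u, v = edges[j]
                t = next_internal
                new = edges[:j] + edges[j + 1 :] + [(u, t), (v, t), (k, t)]
                new_states.append(new)
        states = new_states
        next_internal += 1
    out = []
    for edges in states:
        adj: Dict[int, Set[int]] = {}
        for u, v in edges:
            adj.setdefault(u, set()).add(v)
            adj.setdefault(v, set()).add(u)
        labs = {i: order[i] for i in range(n)}
        out.append(TreeTopology(adj, labs, leaf_order=order))
    return out


# ---------------------------------------------------------------------------
# comparisons / distances


def _check_same_leafset(a: TreeTopology, b: TreeTopology) -> None:
    if set(a.leaf_labels.values()) != set(b.leaf_labels.values()):
        raise TreeError("topologies have different leaf sets")
    if list(a.leaf_order) != list(b.leaf_order):
        raise TreeError("topologies have different leaf orders")


def same_topology(a: TreeTopology, b: TreeTopology) -> bool:
    """True iff the two trees induce the same set of leaf bipartitions."""
    _check_same_leafset(a, b)
    return a.splits() == b.splits()


def rf_distance(a: TreeTopology, b: TreeTopology) -> int:
    """Robinson-Foulds distance: |symmetric difference of nontrivial splits|."""
    _check_same_leafset(a, b)
    return len(a.splits() ^ b.splits())


def _path_length_vector(t: TreeTopology) -> np.ndarray:
    """Topological path lengths (edge counts) for all leaf pairs, ordered by
    (rank_i, rank_j), i < j."""
    leaves = t.leaves
    n = len(leaves)
    dist = np.zeros((n, n))
    pos = {u: i for i, u in enumerate(leaves)}
    for i, src in enumerate(leaves):
        seen = {src: 0}
        dq = deque([src])
        while dq:
            u = dq.popleft()
            for v in t.adjacency[u]:
                if v not in seen:
                    seen[v] = seen[u] + 1
                    dq.append(v)
        for u, d in seen.items():
            if u in pos:
                dist[i, pos[u]] = d
    iu = np.triu_indices(n, k=1)
    return dist[iu]


def path_difference_distance(a: TreeTopology, b: TreeTopology) -> float:
    """Path-difference distance: Euclidean norm of the difference between the
    two trees' leaf-pair path-length vectors."""
    _check_same_leafset(a, b)
    return float(np.linalg.norm(_path_length_vector(a) - _path_length_vector(b)))
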