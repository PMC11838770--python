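"""Bijective integer encoding of unrooted tree topologies, in linear time.

A topology on N ordered leaves x1 < x2 < ... < xN is identified with the
length-(N-3) integer vector s = (s3, ..., s_{N-1}).  The encoding runs two
loops:

* decomposition — strip leaves xN, x_{N-1}, ..., x4; removing xn suppresses
  its attachment node tn and records the edge decision e_{n-1} = (u, v)
  joining tn's two remaining neighbours;
* reconstruction — start from the 3-leaf star (leaves indexed 1, 2, 3,
  centre r left unindexed) and re-attach x4..xN.  At step n the recorded
  edge e_n = (u_n, v_n) is oriented away from r, v_n being the endpoint
  farther from r, and s_n = Index(v_n).  The new attachment node t_{n+1}
  gets Index N+n-2 and the new leaf x_{n+1} gets Index n+1.

Because every step touches a constant number of nodes (orientation is read
off stored parent pointers, never searched), encoding and decoding are O(N).

At step n the admissible values form S_n = {1..n} ∪ {N+1 .. N+n-3}
(the 2n-3 edges of the rank-n intermediate tree, named by their far
endpoints); the product of |S_n| over n recovers the (2N-5)!! count, and the
masks of the generative model are built from exactly these sets.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Set, Tuple

from .trees import TreeError, TreeTopology

__all__ = ["encode", "decode", "allowed_index_set", "validate_encoding"]


def allowed_index_set(n: int, n_leaves: int) -> Set[int]:
    """Admissible node indices S_n at reconstruction step n (3 <= n < N).

    S_n = {1..n} ∪ {N+1..N+n-3}; |S_n| = 2n-3, one per edge of the rank-n
    intermediate tree.
    """
    if not 3 <= n <= n_leaves - 1:
        raise ValueError(f"position n={n} out of range [3, {n_leaves - 1}]")
    return set(range(1, n + 1)) | set(range(n_leaves + 1, n_leaves + n - 2))


def validate_encoding(s: Sequence[int], n_leaves: int) -> None:
    """Raise ValueError if s is not a valid encoding vector for N leaves."""
    if len(s) != n_leaves - 3:
        raise ValueError(f"encoding length {len(s)} != N-3 = {n_leaves - 3}")
    for pos, sn in enumerate(s):
        n = pos + 3
        if sn not in allowed_index_set(n, n_leaves):
            raise ValueError(f"entry s_{n}={sn} not in S_{n} for N={n_leaves}")


def encode(topology: TreeTopology) -> List[int]:
    """Encoding vector s(τ) of a topology; empty for N=3. O(N) time."""
    n_leaves = topology.n_leaves
    leaves = topology.leaves  # rank order
    adj = {u: set(vs) for u, vs in topology.adjacency.items()}

    # --- decomposition: remove x_N .. x_4, remembering each suppressed
    # attachment node t_n and the edge decision (u, v) it leaves behind.
    removed_t: Dict[int, int] = {}
    decisions: Dict[int, Tuple[int, int]] = {}  # key n -> e_n on τ_n
    for n in range(n_leaves, 3, -1):
        xn = leaves[n - 1]
        (tn,) = adj[xn]
        u, v = (w for w in adj[tn] if w != xn)
        decisions[n - 1] = (u, v)
        removed_t[n] = tn
        del adj[xn], adj[tn]
        adj[u] = (adj[u] - {tn}) | {v}
        adj[v] = (adj[v] - {tn}) | {u}

    # --- reconstruction: re-attach the same nodes, assigning indices.
    x1 = leaves[0]
    (r,) = adj[x1]
    index = {leaves[i]: i + 1 for i in range(3)}
    parent = {leaf: r for leaf in leaves[:3]}

    s: List[int] = []
    for n in range(3, n_leaves):
        u, v = decisions[n]
        # orient away from r: v_n is the child endpoint
        if parent.get(u) == v:
            u, v = v, u
        elif parent.get(v) != u:
            raise TreeError(f"edge decision {(u, v)} is not an edge of τ_{n}")
        s.append(index[v])
        t_new, x_new = removed_t[n + 1], leaves[n]
        parent[t_new] = u
        parent[v] = t_new
        parent[x_new] = t_new
        index[t_new] = n_leaves + n - 2
        index[x_new] = n + 1
    return s


def decode(s: Sequence[int], labels: Sequence[str]) -> TreeTopology:
    """Topology for an encoding vector, inverse of :func:`encode`. O(N) time.

    ``labels`` gives the leaf names in leaf order (rank 1..N).  Node ids in
    the result: leaf of rank k has id k, the internal node created at step n
    has id equal to its index N+n-2, and r has id 0.
    """
    n_leaves = len(labels)
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    s = list(s)
    validate_encoding(s, n_leaves)

    R = 0  # the unindexed reconstruction root r
    adjacency: Dict[int, Set[int]] = {R: {1, 2, 3}, 1: {R}, 2: {R}, 3: {R}}
    parent: Dict[int, int] = {1: R, 2: R, 3: R}
    node_of_index: Dict[int, int] = {1: 1, 2: 2, 3: 3}

    for pos, sn in enumerate(s):
        n = pos + 3
        v = node_of_index[sn]
        u = parent[v]
        t = n_leaves + n - 2  # id == Index(t_{n+1})
        x = n + 1
        adjacency[u].remove(v)
        adjacency[v].remove(u)
        adjacency[t] = {u, v, x}
        adjacency[u].add(t)
        adjacency[v].add(t)
        adjacency[x] = {t}
        parent[t] = u
        parent[v] = t
        parent[x] = t
        node_of_index[n_leaves + n - 2] = t
        node_of_index[n + 1] = x

    leaf_labels = {k + 1: labels[k] for k in range(n_leaves)}
    return TreeTopology(adjacency, leaf_labels, leaf_order=list(labels))
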