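"""Simulated study inputs: weighted tree spaces and peaked posteriors.

Two families of training distributions are generated here, both over fully
enumerated small tree spaces:

* a symmetric-Dirichlet random weight vector over all topologies of a given
  leaf count (the five-leaf task uses Dirichlet(0.75·1) over all 15 trees);
* mixtures of "peaked" distributions: each component is the exact posterior
  over all topologies given a Jukes–Cantor alignment simulated on a random
  ground-truth topology with every edge length fixed at 1 and a uniform
  topology prior (the eight-leaf task mixes three such posteriors evenly
  over all 10,395 trees, 500 sites each).

Likelihoods use Felsenstein pruning with the closed-form JC transition
probabilities P(same) = 1/4 + (3/4)e^{-4t/3}, P(diff) = 1/4 - (1/4)e^{-4t/3}
and a uniform stationary root distribution; sites are compressed to unique
patterns before pruning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.special import logsumexp as sp_logsumexp

from .trees import TreeCollection, TreeTopology, enumerate_topologies

__all__ = [
    "Alignment",
    "PeakedDistribution",
    "PeakedMixture",
    "dirichlet_weighted_space",
    "simulate_jc_alignment",
    "jc_log_likelihood",
    "exact_posterior",
    "peaked_mixture",
    "default_labels",
]

_BASES = "ACGT"


def default_labels(n_leaves: int) -> List[str]:
    """t1..tN — lexicographic order equals numeric order for N <= 9."""
    return [f"t{i}" for i in range(1, n_leaves + 1)]


@dataclass
class Alignment:
    """Equal-length ungapped nucleotide sequences, one per leaf.

    ``matrix`` holds base indices 0..3 (ACGT), shape (taxa, sites); ``names``
    gives the taxon of each row.
    """

    names: List[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.names):
            raise ValueError("matrix must be (n_taxa, n_sites)")
        if self.matrix.size and (self.matrix.min() < 0 or self.matrix.max() > 3):
            raise ValueError("states must be in 0..3 (ACGT)")

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, name: str) -> str:
        row = self.matrix[self.names.index(name)]
        return "".join(_BASES[s] for s in row)

    def to_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for name in self.names:
                fh.write(f">{name}\n{self.sequence(name)}\n")

    @classmethod
    def from_fasta(cls, path: str) -> "Alignment":
        names: List[str] = []
        seqs: List[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    names.append(line[1:].split()[0])
                    seqs.append("")
                else:
                    seqs[-1] += line
        lut = {b: i for i, b in enumerate(_BASES)}
        matrix = np.array([[lut[c] for c in s] for s in seqs], dtype=np.int8)
        return cls(names, matrix)


def jc_transition_matrix(t: float) -> np.ndarray:
    """4x4 JC69 transition probabilities for branch length t."""
    same = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
    diff = 0.25 - 0.25 * np.exp(-4.0 * t / 3.0)
    p = np.full((4, 4), diff)
    np.fill_diagonal(p, same)
    return p


def dirichlet_weighted_space(
    n_leaves: int,
    beta: float = 0.75,
    seed: int = 0,
    labels: Optional[Sequence[str]] = None,
) -> TreeCollection:
    """All topologies on N leaves with one symmetric-Dirichlet weight draw."""
    if beta <= 0:
        raise ValueError("Dirichlet concentration must be positive")
    if n_leaves > 8:
        raise ValueError("full enumeration limited to N <= 8")
    labels = list(labels) if labels is not None else default_labels(n_leaves)
    tops = enumerate_topologies(labels)
    rng = np.random.default_rng(seed)
    w = rng.dirichlet(np.full(len(tops), beta))
    return TreeCollection(list(zip(tops, w)))


def _rooted_traversal(topology: TreeTopology):
    """(root, preorder list, parent map) rooted at the internal node next to x1."""
    root = next(iter(topology.adjacency[topology.leaves[0]]))
    parent = {root: None}
    order = [root]
    stack = [root]
    while stack:
        u = stack.pop()
        for v in topology.adjacency[u]:
            if v not in parent:
                parent[v] = u
                order.append(v)
                stack.append(v)
    return root, order, parent


def simulate_jc_alignment(
    topology: TreeTopology, edge_length: float = 1.0, n_sites: int = 500, seed: int = 0
) -> Alignment:
    """Simulate sequences site-independently under JC69 on the topology.

    Root states are uniform over ACGT; each edge applies the closed-form JC
    transition kernel with the given (shared) edge length.
    """
    if edge_length <= 0:
        raise ValueError("edge_length must be positive")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    root, order, parent = _rooted_traversal(topology)
    p_same = 0.25 + 0.75 * np.exp(-4.0 * edge_length / 3.0)
    states: Dict[int, np.ndarray] = {root: rng.integers(0, 4, size=n_sites)}
    for u in order[1:]:
        par = states[parent[u]]
        stay = rng.random(n_sites) < p_same
        # mutate uniformly among the three other bases
        shift = rng.integers(1, 4, size=n_sites)
        states[u] = np.where(stay, par, (par + shift) % 4)
    names = [topology.leaf_labels[u] for u in topology.leaves]
    matrix = np.stack([states[u] for u in topology.leaves])
    return Alignment(names, matrix.astype(np.int8))


def jc_log_likelihood(
    topology: TreeTopology, alignment: Alignment, edge_length: float = 1.0
) -> float:
    """Felsenstein-pruning log-likelihood with all edges at ``edge_length``.

    The unrooted tree is rooted (arbitrarily, at the internal node adjacent
    to x1 — JC is reversible, so the value is rooting-invariant) and per-site
    conditional likelihood vectors are propagated to the root with a uniform
    1/4 prior."""
    names = {topology.leaf_labels[u] for u in topology.leaves}
    if names != set(alignment.names):
        raise ValueError("alignment taxa do not match topology leaves")
    pattern, counts = np.unique(alignment.matrix, axis=1, return_counts=True)
    p = jc_transition_matrix(edge_length)
    root, order, parent = _rooted_traversal(topology)
    row = {name: i for i, name in enumerate(alignment.names)}
    partial: Dict[int, np.ndarray] = {}
    for u in reversed(order):
        if u in topology.leaf_labels:
            obs = pattern[row[topology.leaf_labels[u]]]
            vec = np.zeros((4, pattern.shape[1]))
            vec[obs, np.arange(pattern.shape[1])] = 1.0
        else:
            vec = np.ones((4, pattern.shape[1]))
            for v in topology.adjacency[u]:
                if parent.get(v) == u:
                    vec = vec * (p @ partial[v])
        partial[u] = vec
    site_log_lik = np.log(0.25 * partial[root].sum(axis=0))
    return float(site_log_lik @ counts)


@dataclass
class PeakedDistribution:
    """Exact topology posterior over a fully enumerated space."""

    collection: TreeCollection
    log_likelihoods: np.ndarray
    mode_index: int

    @property
    def mode(self) -> TreeTopology:
        return self.collection.topologies[self.mode_index]


def exact_posterior(
    alignment: Alignment, edge_length: float = 1.0, labels: Optional[Sequence[str]] = None
) -> PeakedDistribution:
    """Posterior over all topologies: uniform prior, fixed edge lengths.

    Weight of τ ∝ exp(log L(τ)); normalisation happens in log space.  With a
    0-site alignment this recovers the uniform prior."""
    labels = sorted(alignment.names) if labels is None else list(labels)
    if len(labels) > 8:
        raise ValueError("full enumeration limited to N <= 8")
    tops = enumerate_topologies(labels)
    log_l = np.array([jc_log_likelihood(t, alignment, edge_length) for t in tops])
    log_w = log_l - sp_logsumexp(log_l)
    weights = np.exp(log_w)
    weights = weights / weights.sum()
    coll = TreeCollection(list(zip(tops, weights)))
    return PeakedDistribution(coll, log_l, int(np.argmax(log_l)))


@dataclass
class PeakedMixture:
    """Evenly mixed peaked posteriors with their generating topologies."""

    collection: TreeCollection
    components: List[PeakedDistribution]
    ground_truth: List[TreeTopology]

    def metadata(self) -> Dict[str, object]:
        return {
            "n_peaks": len(self.components),
            "ground_truth_newicks": [t.to_newick() for t in self.ground_truth],
            "mode_newicks": [c.mode.to_newick() for c in self.components],
        }


def peaked_mixture(
    n_leaves: int,
    n_peaks: int = 3,
    n_sites: int = 500,
    edge_length: float = 1.0,
    seed: int = 0,
    labels: Optional[Sequence[str]] = None,
) -> PeakedMixture:
    """Mixture of ``n_peaks`` exact posteriors, equal mixing weights.

    Ground-truth topologies are drawn uniformly without replacement from the
    enumerated space; each gets its own simulated JC alignment."""
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    labels = list(labels) if labels is not None else default_labels(n_leaves)
    tops = enumerate_topologies(labels)
    if n_peaks > len(tops):
        raise ValueError(f"n_peaks={n_peaks} exceeds the {len(tops)} topologies")
    rng = np.random.default_rng(seed)
    truth_idx = rng.choice(len(tops), size=n_peaks, replace=False)
    components = []
    for j, ti in enumerate(truth_idx):
        aln = simulate_jc_alignment(
            tops[ti], edge_length=edge_length, n_sites=n_sites,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        components.append(exact_posterior(aln, edge_length=edge_length, labels=labels))
    weights = np.mean([c.collection.weights for c in components], axis=0)
    # components enumerate the same space in the same order, so weights align
    coll = TreeCollection(list(zip(tops, weights)))
    return PeakedMixture(coll, components, [tops[i] for i in truth_idx])
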