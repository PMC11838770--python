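"""Latent-space analysis: embeddings, grid decoding, distance correlations.

μ_τ, the mean of q(z|τ), is the model's deterministic low-dimensional
representation of a topology.  This module extracts those representations
for a collection, decodes a lattice of Gaussian quantiles back to trees
(the latent-manifold picture for d=2), and reports how latent L2 distance
correlates with the classical Robinson–Foulds and path-difference
distances.  A classical-MDS helper is included purely as a baseline for
comparison plots; it is not part of the model.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List

import numpy as np
import pandas as pd
from scipy.stats import norm, pearsonr

from .generative_model import sample_topology
from .inference_model import posterior_params
from .trees import TreeCollection, TreeTopology, path_difference_distance, rf_distance
from .training import ModelBundle

__all__ = [
    "embed_collection",
    "LatentGrid",
    "decode_latent_grid",
    "distance_report",
    "classical_mds",
]


def embed_collection(bundle: ModelBundle, data: TreeCollection) -> pd.DataFrame:
    """One row per unique topology: μ, σ, weight, canonical newick."""
    rows = []
    for i, (topology, weight) in enumerate(data):
        pp = posterior_params(topology, bundle.inference)
        rec: Dict[str, object] = {"tree": i, "weight": weight, "newick": topology.to_newick()}
        for j, (m, s) in enumerate(zip(pp.mu, pp.sigma)):
            rec[f"mu{j}"] = m
            rec[f"sigma{j}"] = s
        rows.append(rec)
    return pd.DataFrame(rows)


@dataclass
class LatentGrid:
    """Regular quantile lattice in (0,1)² mapped into latent space, with the
    argmax-decoded topology at each point."""

    u: np.ndarray  # (res, res, 2) lattice in (0,1)^2
    z: np.ndarray  # (res, res, 2) Gaussian quantiles
    topologies: List[List[TreeTopology]]
    first_decisions: np.ndarray  # s3 at each grid point (grid metadata)

    @property
    def resolution(self) -> int:
        return self.u.shape[0]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        res = self.resolution
        for i in range(res):
            for j in range(res):
                rows.append(
                    {
                        "u1": self.u[i, j, 0],
                        "u2": self.u[i, j, 1],
                        "z1": self.z[i, j, 0],
                        "z2": self.z[i, j, 1],
                        "s3": int(self.first_decisions[i, j]),
                        "newick": self.topologies[i][j].to_newick(),
                    }
                )
        return pd.DataFrame(rows)


def decode_latent_grid(bundle: ModelBundle, resolution: int = 10) -> LatentGrid:
    """Decode the interior quantile lattice u_k = k/(res+1) by argmax.

    Requires a 2-dimensional latent space; endpoints u ∈ {0, 1} are excluded
    so every quantile is finite.  Deterministic (argmax decoding)."""
    from . import codec

    if bundle.config.latent_dim != 2:
        raise ValueError("latent grid decoding needs a 2-D model (latent_dim=2)")
    ticks = np.arange(1, resolution + 1) / (resolution + 1)
    u = np.stack(np.meshgrid(ticks, ticks, indexing="ij"), axis=-1)
    z = norm.ppf(u)
    tops: List[List[TreeTopology]] = []
    s3 = np.zeros((resolution, resolution), dtype=int)
    for i in range(resolution):
        row = []
        for j in range(resolution):
            t = sample_topology(bundle.generative, z[i, j], bundle.leaf_order, mode="argmax")
            row.append(t)
            enc = codec.encode(t)
            s3[i, j] = enc[0] if enc else 0
        tops.append(row)
    return LatentGrid(u, z, tops, s3)


def distance_report(
    bundle: ModelBundle,
    data: TreeCollection,
    seed: int = 0,
    max_pairs: int = 20_000,
) -> Dict[str, object]:
    """Pearson correlation of latent L2 distance against RF and PD distances.

    All pairs are used when the collection has at most 200 unique trees;
    otherwise ``max_pairs`` random pairs are sampled (seeded)."""
    tops = data.topologies
    if len(tops) < 2:
        raise ValueError("need at least 2 unique topologies")
    mus = np.stack([posterior_params(t, bundle.inference).mu for t in tops])
    if len(tops) <= 200:
        pairs = list(combinations(range(len(tops)), 2))
    else:
        rng = np.random.default_rng(seed)
        a = rng.integers(0, len(tops), size=max_pairs)
        b = rng.integers(0, len(tops) - 1, size=max_pairs)
        b = np.where(b >= a, b + 1, b)
        pairs = list(zip(a.tolist(), b.tolist()))
    l2 = np.array([np.linalg.norm(mus[i] - mus[j]) for i, j in pairs])
    rf = np.array([rf_distance(tops[i], tops[j]) for i, j in pairs], dtype=float)
    pd_dist = np.array([path_difference_distance(tops[i], tops[j]) for i, j in pairs])
    out: Dict[str, object] = {"n_pairs": len(pairs), "l2": l2, "rf": rf, "pd": pd_dist}
    out["pearson_l2_rf"] = float(pearsonr(l2, rf)[0]) if np.std(rf) > 0 and np.std(l2) > 0 else float("nan")
    out["pearson_l2_pd"] = float(pearsonr(l2, pd_dist)[0]) if np.std(pd_dist) > 0 and np.std(l2) > 0 else float("nan")
    return out


def classical_mds(distances: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Classical (Torgerson) scaling of a symmetric distance matrix.

    Baseline only: double-centres the squared distances and embeds with the
    top eigenvectors; negative eigenvalues are truncated at zero."""
    d2 = np.asarray(distances, dtype=float) ** 2
    m = d2.shape[0]
    j = np.eye(m) - np.full((m, m), 1.0 / m)
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:n_components]
    return vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
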