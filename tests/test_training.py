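"""IWAE bound properties, gradient correctness, training behaviour."""

import math

import numpy as np
import pytest

from treevae.autodiff import logsumexp
from treevae.generative_model import log_prob_given_z, marginal_log_prob
from treevae.trees import TreeCollection
from treevae.training import (
    ModelBundle,
    TrainingConfig,
    _collection_tensors,
    _log_weights_from_tensors,
    kl_to_reference,
    multi_sample_bound,
    train,
)

from conftest import labels


def small_bundle(n_leaves=5, seed=0, **overrides):
    cfg = TrainingConfig(
        latent_dim=2,
        decoder_hidden=(16, 16),
        gnn_hidden=12,
        seed=seed,
        **overrides,
    )
    return ModelBundle.create(labels(n_leaves), cfg)


def quadrature_log_marginal(bundle, topology, n_nodes=40):
    """2-D Gauss-Hermite integration of p(τ) = ∫ p(τ|z) N(z;0,I) dz."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    zz = np.array([[a, b] for a in nodes for b in nodes])
    ww = np.array([wa * wb for wa in weights for wb in weights]) / (2 * np.pi)
    probs = np.array([np.exp(log_prob_given_z(bundle.generative, topology, z)) for z in zz])
    return float(np.log(np.sum(ww * probs)))


class TestMultiSampleBound:
    def test_exact_posterior_makes_elbo_tight(self, five_leaf_space):
        """With a constant decoder, p(z|τ) = p(z); zeroing the encoder heads
        makes q exactly that posterior, so the K=1 bound equals log p(τ)."""
        bundle = small_bundle()
        for name, t in bundle.generative.parameters().items():
            t.data[:] = 0.0  # p(τ|z) uniform = 1/15 for every z
        for name, t in bundle.inference.parameters().items():
            if name.startswith("head"):
                t.data[:] = 0.0  # μ=0, logσ=0 -> q = N(0, I) = p(z|τ)
        val = multi_sample_bound(bundle, five_leaf_space[0], n_particles=1, seed=3)
        assert val == pytest.approx(-math.log(15), abs=1e-10)

    def test_bound_nondecreasing_in_particle_count(self, five_leaf_space):
        bundle = small_bundle(seed=11)
        t = five_leaf_space[4]
        means = {}
        for k in (1, 8, 32):
            vals = [multi_sample_bound(bundle, t, n_particles=k, seed=s) for s in range(400)]
            means[k] = np.mean(vals)
        assert means[1] <= means[8] <= means[32]

    def test_bound_below_quadrature_log_marginal(self, five_leaf_space):
        bundle = small_bundle(seed=7)
        t = five_leaf_space[9]
        exact = quadrature_log_marginal(bundle, t)
        vals = [multi_sample_bound(bundle, t, n_particles=8, seed=s) for s in range(600)]
        mean = np.mean(vals)
        se = np.std(vals) / np.sqrt(len(vals))
        assert mean <= exact + 3 * se

    def test_bound_nonpositive_in_expectation(self, five_leaf_space):
        # log p(τ) <= 0 for a discrete model, so the bound must not exceed 0
        bundle = small_bundle(seed=23)
        vals = [
            multi_sample_bound(bundle, five_leaf_space[s % 15], n_particles=4, seed=s)
            for s in range(1000)
        ]
        assert np.mean(vals) + 3 * np.std(vals) / np.sqrt(len(vals)) <= 0.0


class TestGradients:
    def test_finite_difference_check_on_single_sample_bound(self, five_leaf_space):
        """Frozen-noise single-sample bound: implemented gradient vs central
        differences, relative error < 1e-4."""
        bundle = small_bundle(seed=5)
        tops = [five_leaf_space[2]]
        s_cols, f0, adj = _collection_tensors(bundle, tops)
        eps = np.random.default_rng(9).standard_normal((1, 1, 2))

        def loss_value():
            lw = _log_weights_from_tensors(bundle, s_cols, f0, adj, eps)
            return logsumexp(lw, axis=-1)

        out = loss_value()
        for p in bundle.parameters().values():
            p.zero_grad()
        out.backward(np.ones(1))

        rng = np.random.default_rng(17)
        params = bundle.parameters()
        checked = 0
        for name in ["gen.mlp.layers.0.W", "gen.mlp.layers.2.b", "inf.proj.W",
                     "inf.gru.0.Wc", "inf.head_mu.layers.1.W", "inf.head_log_sigma.layers.0.b"]:
            p = params[name]
            flat_idx = rng.integers(0, p.data.size, size=3)
            for fi in flat_idx:
                idx = np.unravel_index(fi, p.data.shape)
                h = 1e-5
                orig = p.data[idx]
                p.data[idx] = orig + h
                up = float(loss_value().numpy()[0])
                p.data[idx] = orig - h
                down = float(loss_value().numpy()[0])
                p.data[idx] = orig
                fd = (up - down) / (2 * h)
                an = p.grad[idx]
                denom = max(abs(fd), abs(an), 1e-8)
                assert abs(fd - an) / denom < 1e-4, name
                checked += 1
        assert checked == 18


class TestTraining:
    def test_overfits_a_single_topology(self, five_leaf_space):
        target = five_leaf_space[6]
        coll = TreeCollection([(target, 1.0)])
        bundle = small_bundle(seed=2, n_iterations=1200, learning_rate=3e-3)
        train(bundle, coll)
        lp = marginal_log_prob(bundle.generative, bundle.inference, target,
                               n_particles=1000, seed=4)
        assert math.exp(min(lp, 0.0)) >= 0.99

    def test_identical_seeds_give_identical_traces(self, five_leaf_space):
        w = np.full(15, 1 / 15)
        coll = TreeCollection(list(zip(five_leaf_space, w)))
        traces = []
        for _ in range(2):
            bundle = small_bundle(seed=31, n_iterations=60, log_every=10)
            traces.append([m["bound"] for m in train(bundle, coll)])
        assert traces[0] == traces[1]

    def test_empty_collection_rejected(self):
        bundle = small_bundle()
        with pytest.raises(ValueError):
            train(bundle, TreeCollection([]))

    def test_checkpoint_round_trip(self, tmp_path, five_leaf_space):
        bundle = small_bundle(seed=13)
        path = tmp_path / "ckpt.npz"
        bundle.save(str(path))
        back = ModelBundle.load(str(path))
        assert back.leaf_order == bundle.leaf_order
        v1 = multi_sample_bound(bundle, five_leaf_space[1], n_particles=4, seed=1)
        v2 = multi_sample_bound(back, five_leaf_space[1], n_particles=4, seed=1)
        assert v1 == v2


class TestKL:
    def test_self_consistency_against_exact_model_distribution(self, five_leaf_space):
        """Reference = the model's own exact marginals (by quadrature):
        KL should be ~0 up to importance-sampling noise."""
        bundle = small_bundle(seed=19)
        # q = N(0, I): importance weights are then bounded by 1, keeping the
        # log-estimator's Jensen bias negligible at this particle count
        for name, t in bundle.inference.parameters().items():
            if name.startswith("head"):
                t.data[:] = 0.0
        log_marginals = np.array(
            [quadrature_log_marginal(bundle, t) for t in five_leaf_space]
        )
        w = np.exp(log_marginals)
        w = w / w.sum()
        ref = TreeCollection(list(zip(five_leaf_space, w)))
        res = kl_to_reference(bundle, ref, n_particles=4000, seed=3)
        assert abs(res["kl"]) < 0.01

    def test_perfectly_trained_point_mass(self, five_leaf_space):
        target = five_leaf_space[0]
        coll = TreeCollection([(target, 1.0)])
        bundle = small_bundle(seed=3, n_iterations=1200, learning_rate=3e-3)
        train(bundle, coll)
        res = kl_to_reference(bundle, coll, n_particles=1000, seed=8)
        assert res["kl"] == pytest.approx(0.0, abs=0.02)

    def test_nonnegative_up_to_noise_for_random_pairs(self, five_leaf_space, rng):
        for trial in range(5):
            bundle = small_bundle(seed=100 + trial)
            w = rng.dirichlet(np.ones(15))
            ref = TreeCollection(list(zip(five_leaf_space, w)))
            res = kl_to_reference(bundle, ref, n_particles=500, seed=trial)
            assert res["kl"] > -0.05  # Gibbs inequality modulo estimator noise
            assert res["n_particles"] == 500
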