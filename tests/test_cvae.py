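import numpy as np
import pytest
from scipy import stats

import protomap as pm
from protomap.cvae import LikelihoodParams, _softmax


def tiny_model(likelihood="negative_binomial", n_covariates=1, dims=(2,), seed=3,
               G=7, D=3):
    covs = {f"cov{i}": ["a", "b", "c"] for i in range(n_covariates)}
    cfg = pm.ModelConfig(embedding_dim=dims[0], latent_dim=D, hidden_width=5,
                         likelihood=likelihood, encoder_depth=2, decoder_depth=1,
                         seed=seed)
    return pm.CVAEModel.create(cfg, [f"g{i}" for i in range(G)], covs)


def tiny_batch(rng, n=6, G=7, n_covariates=1):
    x = rng.poisson(3.0, size=(n, G)).astype(float)
    conds = {f"cov{i}": rng.choice(["a", "b", "c"], size=n) for i in range(n_covariates)}
    return x, conds


class TestLikelihoods:
    def test_nb_matches_scipy_logpmf(self):
        """Gamma-function NB NLL equals scipy's nbinom on 50 random triples."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.integers(0, 40, size=(1, 4)).astype(float)
            mu = rng.uniform(0.1, 20.0, size=(1, 4))
            alpha = rng.uniform(0.2, 30.0, size=4)
            ours = pm.nb_negative_log_likelihood(x, LikelihoodParams(mu=mu, alpha=alpha))
            ref = -stats.nbinom.logpmf(x, n=alpha, p=alpha / (alpha + mu)).sum(axis=1)
            np.testing.assert_allclose(ours, ref, rtol=1e-6)

    def test_nb_limits(self):
        # alpha -> inf approaches the Poisson NLL at the same mean
        x = np.array([[0.0, 3.0, 7.0]])
        mu = np.array([[0.5, 3.0, 6.0]])
        nb = pm.nb_negative_log_likelihood(x, LikelihoodParams(mu=mu, alpha=np.full(3, 1e6)))
        po = pm.poisson_negative_log_likelihood(x, LikelihoodParams(lam=mu))
        np.testing.assert_allclose(nb, po, atol=1e-3)
        # zero counts at vanishing mean carry no penalty
        small = pm.nb_negative_log_likelihood(
            np.zeros((1, 2)), LikelihoodParams(mu=np.full((1, 2), 1e-13), alpha=np.ones(2)))
        assert small[0] < 1e-9

    def test_nb_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            pm.nb_negative_log_likelihood(
                np.ones((1, 2)), LikelihoodParams(mu=np.ones((1, 2)), alpha=np.array([1.0, -1.0])))

    def test_poisson_closed_form_and_oracle(self):
        one = pm.poisson_negative_log_likelihood(
            np.array([[1.0]]), LikelihoodParams(lam=np.array([[1.0]])))
        np.testing.assert_allclose(one, [1.0], rtol=1e-12)
        zero = pm.poisson_negative_log_likelihood(
            np.array([[0.0]]), LikelihoodParams(lam=np.array([[0.0]])))
        assert zero[0] == 0.0
        rng = np.random.default_rng(1)
        x = rng.poisson(4.0, size=(50, 5)).astype(float)
        lam = rng.uniform(0.1, 10.0, size=(50, 5))
        ours = pm.poisson_negative_log_likelihood(x, LikelihoodParams(lam=lam))
        ref = -stats.poisson.logpmf(x, lam).sum(axis=1)
        np.testing.assert_allclose(ours, ref, rtol=1e-8)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            pm.poisson_negative_log_likelihood(
                np.array([[-1.0]]), LikelihoodParams(lam=np.array([[1.0]])))


class TestKL:
    def test_closed_form_values(self):
        zero = pm.kl_divergence(pm.LatentRepresentation(
            np.zeros((1, 3)), np.zeros((1, 3)), np.zeros((1, 3))))
        np.testing.assert_allclose(zero, [0.0], atol=1e-12)
        half = pm.kl_divergence(pm.LatentRepresentation(
            np.ones((1, 1)), np.zeros((1, 1)), np.ones((1, 1))))
        np.testing.assert_allclose(half, [0.5], rtol=1e-12)

    def test_nonnegative_on_random_latents(self):
        rng = np.random.default_rng(2)
        rep = pm.LatentRepresentation(rng.normal(size=(1000, 4)),
                                      rng.uniform(-3, 3, size=(1000, 4)),
                                      np.zeros((1000, 4)))
        assert np.all(pm.kl_divergence(rep) >= 0)


class TestEncodeDecode:
    def test_inference_mode_deterministic(self):
        m = tiny_model()
        x, conds = tiny_batch(np.random.default_rng(0))
        a = m.encode(x, conds, mode="mean")
        b = m.encode(x, conds, mode="mean")
        np.testing.assert_array_equal(a.mean, b.mean)
        np.testing.assert_array_equal(a.z, a.mean)

    def test_two_covariate_input_width(self):
        """Encoder input = transformed features + one embedding block per covariate."""
        m = tiny_model(n_covariates=2)
        x, conds = tiny_batch(np.random.default_rng(1), n_covariates=2)
        xin = m.build_encoder_input(x, conds)
        E = m.config.embedding_dim
        assert xin.shape[1] == x.shape[1] + 2 * E

    def test_permuting_cells_permutes_outputs(self):
        m = tiny_model()
        x, conds = tiny_batch(np.random.default_rng(2), n=8)
        perm = np.random.default_rng(3).permutation(8)
        a = m.encode(x, conds).mean
        b = m.encode(x[perm], {k: v[perm] for k, v in conds.items()}).mean
        np.testing.assert_allclose(a[perm], b, atol=1e-12)

    def test_unknown_condition_identifies_covariate(self):
        m = tiny_model()
        x, conds = tiny_batch(np.random.default_rng(4))
        conds["cov0"][0] = "zzz"
        with pytest.raises(LookupError, match="cov0"):
            m.encode(x, conds)

    def test_nb_decoder_means_sum_to_library_size(self):
        m = tiny_model()
        rng = np.random.default_rng(5)
        z = rng.normal(size=(5, 3))
        lib = np.array([100.0, 5.0, 73.0, 1.0, 999.0])
        conds = {"cov0": np.array(["a", "b", "c", "a", "b"])}
        params = m.decode(z, conds, lib)
        np.testing.assert_allclose(params.mu.sum(axis=1), lib, rtol=1e-10)

    def test_poisson_rates_nonnegative_and_row_consistency(self):
        m = tiny_model(likelihood="poisson")
        z = np.zeros((3, 3))
        z[2] = 1.0
        conds = {"cov0": np.array(["a", "a", "a"])}
        params = m.decode(z, conds, np.array([10.0, 10.0, 10.0]))
        assert np.all(params.lam >= 0)
        # identical (z, condition) rows give identical parameter rows
        np.testing.assert_array_equal(params.lam[0], params.lam[1])


class TestLossAndGradients:
    def test_loss_components_bookkeeping(self):
        m = tiny_model()
        x, conds = tiny_batch(np.random.default_rng(6))
        comps, _ = m.loss_and_grads(x, conds, kl_weight=0.0, sample=False,
                                    compute_grads=False)
        np.testing.assert_allclose(comps["total"], comps["reconstruction"], rtol=1e-12)
        comps, _ = m.loss_and_grads(x, conds, kl_weight=0.3, sample=False,
                                    compute_grads=False)
        np.testing.assert_allclose(
            comps["total"],
            comps["reconstruction"] + 0.3 * comps["kl"] + m.config.prototype_loss_weight
            * comps["prototype"], rtol=1e-12)

    @pytest.mark.parametrize("likelihood", ["negative_binomial", "poisson"])
    def test_gradients_match_finite_differences(self, likelihood):
        """Analytic backprop agrees with central differences for every
        parameter group, including embeddings and the prototype term."""
        rng = np.random.default_rng(0)
        m = tiny_model(likelihood=likelihood)
        x, conds = tiny_batch(rng)
        P = rng.normal(size=(2, 3))
        assign = np.array([0, 1, -1, 0, 1, 0])
        kw = dict(kl_weight=0.7, sample=False, proto_targets=[(P, assign)], eta=0.5)
        _, grads = m.loss_and_grads(x, conds, **kw)
        full = dict(m.params)
        for c in m.covariate_order:
            full[f"emb.{c}"] = m.tables[c].matrix
        h = 1e-6
        pick = np.random.default_rng(1)
        for key, arr in full.items():
            for flat in pick.choice(arr.size, size=min(arr.size, 3), replace=False):
                ix = np.unravel_index(flat, arr.shape)
                orig = arr[ix]
                arr[ix] = orig + h
                lp = m.loss_and_grads(x, conds, compute_grads=False, **kw)[0]["total"]
                arr[ix] = orig - h
                lm = m.loss_and_grads(x, conds, compute_grads=False, **kw)[0]["total"]
                arr[ix] = orig
                num = (lp - lm) / (2 * h)
                ana = np.asarray(grads[key])[ix]
                assert abs(num - ana) <= 1e-4 * max(1.0, abs(num)), (key, ix)

    def test_single_adam_step_decreases_loss(self):
        from protomap.nn import Adam

        m = tiny_model()
        rng = np.random.default_rng(7)
        x, conds = tiny_batch(rng, n=32)
        before, grads = m.loss_and_grads(x, conds, kl_weight=1.0, sample=False)
        opt = Adam(m.all_trainable(), lr=1e-3)
        full = dict(m.params)
        for c in m.covariate_order:
            full[f"emb.{c}"] = m.tables[c].matrix
        opt.step(full, grads)
        for k in m.params:
            m.params[k] = full[k]
        for c in m.covariate_order:
            m.tables[c].matrix = full[f"emb.{c}"]
        after, _ = m.loss_and_grads(x, conds, kl_weight=1.0, sample=False,
                                    compute_grads=False)
        assert after["total"] < before["total"]

    def test_training_mode_varies_z_but_not_mean(self):
        m = tiny_model()
        x, conds = tiny_batch(np.random.default_rng(8))
        a = m.encode(x, conds, mode="sample", rng=np.random.default_rng(1))
        b = m.encode(x, conds, mode="sample", rng=np.random.default_rng(2))
        np.testing.assert_array_equal(a.mean, b.mean)
        assert not np.array_equal(a.z, b.z)


class TestParameterCounting:
    def test_boundary_equality(self):
        """At E = N*H/(N+H) both variants count the same parameters."""
        cfg = pm.ModelConfig(embedding_dim=10, latent_dim=4, hidden_width=10)
        # H_enc = H_dec = 10, H = 20, N = 20 -> threshold = 400/40 = 10 = E
        assert (pm.count_trainable_parameters(cfg, 50, 20, "scpoli")
                == pm.count_trainable_parameters(cfg, 50, 20, "onehot_cvae"))

    def test_crossover_example(self):
        # G=100, D=10, H_enc=H_dec=10, N=50: threshold = 1000/70 ~ 14.29
        fewer = pm.ModelConfig(embedding_dim=14, latent_dim=10, hidden_width=10)
        more = pm.ModelConfig(embedding_dim=15, latent_dim=10, hidden_width=10)
        assert pm.fewer_parameters_than_onehot(fewer, 100, 50)
        assert not pm.fewer_parameters_than_onehot(more, 100, 50)

    def test_single_condition_never_fewer(self):
        for e in (1, 2, 8, 50):
            cfg = pm.ModelConfig(embedding_dim=e, latent_dim=10, hidden_width=100)
            assert not pm.fewer_parameters_than_onehot(cfg, 500, 1)


class TestOneHotEquivalence:
    def test_identity_embedding_reproduces_onehot_input(self):
        """With E = N and the table fixed to the identity, the encoder input
        is bitwise the one-hot CVAE input."""
        levels = ["a", "b", "c", "d"]
        cfg = pm.ModelConfig(embedding_dim=4, latent_dim=3, hidden_width=5, seed=0)
        m = pm.CVAEModel.create(cfg, [f"g{i}" for i in range(6)], {"cov0": levels})
        m.tables["cov0"].matrix = np.eye(4)
        rng = np.random.default_rng(0)
        x = rng.poisson(2.0, size=(8, 6)).astype(float)
        conds = {"cov0": rng.choice(levels, size=8)}
        xin = m.build_encoder_input(x, conds)
        onehot = np.zeros((8, 4))
        for i, c in enumerate(conds["cov0"]):
            onehot[i, levels.index(c)] = 1.0
        expected = np.concatenate([np.log1p(x), onehot], axis=1)
        assert np.array_equal(xin, expected)


class TestSerialization:
    def test_round_trip_forward_bitwise(self, tmp_path):
        m = tiny_model()
        rng = np.random.default_rng(9)
        x, conds = tiny_batch(rng)
        m.prototypes["cell_type"] = pm.compute_labeled_prototypes(
            rng.normal(size=(10, 3)), np.array(["T"] * 5 + ["B"] * 5, dtype=object))
        path = str(tmp_path / "model.npz")
        m.save(path)
        back = pm.CVAEModel.load(path)
        a = m.encode(x, conds).mean
        b = back.encode(x, conds).mean
        assert np.array_equal(a, b)
        la = m.loss_and_grads(x, conds, sample=False, compute_grads=False)[0]
        lb = back.loss_and_grads(x, conds, sample=False, compute_grads=False)[0]
        assert la == lb
        np.testing.assert_array_equal(
            m.prototypes["cell_type"].matrix(), back.prototypes["cell_type"].matrix())


def test_softmax_rows_normalized():
    rng = np.random.default_rng(0)
    f = _softmax(rng.normal(scale=30, size=(20, 9)))
    np.testing.assert_allclose(f.sum(axis=1), 1.0, rtol=1e-12)
    assert np.all(f > 0)
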