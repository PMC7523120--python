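"""Tests for the objective, the mini-max trainer, and checkpointing."""

import copy

import numpy as np
import pytest
from autograd import grad
from autograd.misc import flatten

from vie import training
from vie.simulate import SimulationConfig, simulate_dataset, train_val_test_split
from vie.training import FittedModel, TrainingConfig, VARIANTS


FAST = dict(latent_dim=3, flow_depth=1, hidden=8, amnn_hidden=8, critic_hidden=16,
            context_dim=4, n_grid=8, batch_size=128, max_epochs=2,
            encoder_extra_steps=1, patience=5)


@pytest.fixture(scope="module")
def toy_data():
    data = simulate_dataset(SimulationConfig(n=800, d=5, target_event_rate=0.1, seed=0))
    tr, va, _ = train_val_test_split(800, seed=0)
    return data.X[tr], data.y[tr], data.X[va], data.y[va]


class TestConfig:
    def test_invalid_variant(self):
        with pytest.raises(ValueError):
            TrainingConfig(variant="boosting")

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            TrainingConfig(beta=-1.0)

    def test_wiring_matrix_matches_ablation_grid(self):
        """The five variants wire prior/encoder/decoder/prior-match exactly."""
        grid = {
            "vae":         ("gaussian", "gaussian", "mlp", True),
            "vae_gpd":     ("mixed_gpd", "gaussian", "amnn", False),
            "iaf_gpd":     ("mixed_gpd", "iaf", "amnn", False),
            "fenchel_gpd": ("mixed_gpd", "implicit", "amnn", True),
            "vie":         ("mixed_gpd", "iaf", "amnn", True),
        }
        assert set(VARIANTS) == set(grid)
        for name, (prior, enc, dec, match) in grid.items():
            w = VARIANTS[name]
            assert (w["prior"], w["encoder"], w["decoder"], w["prior_match"]) == \
                (prior, enc, dec, match)

    def test_component_wiring_reflected_in_params(self):
        rng = np.random.default_rng(0)
        for name, w in VARIANTS.items():
            cfg = TrainingConfig(variant=name, **FAST)
            params = training.init_params(cfg, 5, rng)
            assert ("prior" in params) == (w["prior"] == "mixed_gpd")
            assert ("implicit" in params) == (w["encoder"] == "implicit")
            assert ("critic" in params) == w["prior_match"]
            if w["encoder"] == "iaf":
                assert len(params["flows"]) == cfg.flow_depth
            elif w["encoder"] == "gaussian":
                assert params["flows"] == []


class TestObjective:
    def test_bias_only_decoder_equals_bernoulli_cll(self):
        """With beta=0 and a bias-only decoder at the prevalence, Psi equals the
        closed-form Bernoulli CLL log-likelihood."""
        rng = np.random.default_rng(1)
        cfg = TrainingConfig(variant="vie", beta=0.0, **FAST)
        d, n = 4, 200
        aux = training._build_aux(cfg, d)
        params = training.init_params(cfg, d, rng)
        pi = 0.2
        y = (rng.uniform(size=n) < pi).astype(float)
        X = rng.standard_normal((n, d))
        # bias-only: zero direction weights, gamma at CLL^-1(prevalence)
        params["decoder"]["alpha"] = np.zeros(cfg.latent_dim)
        params["decoder"]["gamma"] = np.array(np.log(-np.log1p(-pi)))
        eps = rng.standard_normal((1, n, cfg.latent_dim))
        psi = float(training.objective_psi(params, X, y, eps, cfg, aux))
        expected = np.mean(y * np.log(pi) + (1 - y) * np.log1p(-pi))
        assert psi == pytest.approx(expected, abs=1e-10)

    def test_perfect_fit_limit_vanishes(self):
        rng = np.random.default_rng(2)
        cfg = TrainingConfig(variant="vie", beta=0.0, **FAST)
        aux = training._build_aux(cfg, 4)
        params = training.init_params(cfg, 4, rng)
        params["decoder"]["alpha"] = np.zeros(cfg.latent_dim)
        params["decoder"]["gamma"] = np.array(-30.0)  # risk -> 0
        y = np.zeros(50)
        X = rng.standard_normal((50, 4))
        eps = rng.standard_normal((1, 50, cfg.latent_dim))
        assert float(training.objective_psi(params, X, y, eps, cfg, aux)) == \
            pytest.approx(0.0, abs=1e-10)

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(3)
        cfg = TrainingConfig(variant="vie", **FAST)
        aux = training._build_aux(cfg, 4)
        params = training.init_params(cfg, 4, np.random.default_rng(9))
        X = rng.standard_normal((20, 4))
        y = rng.integers(0, 2, 20).astype(float)
        eps = np.random.default_rng(5).standard_normal((1, 20, cfg.latent_dim))
        a = float(training.objective_psi(params, X, y, eps, cfg, aux))
        b = float(training.objective_psi(params, X, y, eps, cfg, aux))
        assert a == b

    def test_gradient_reaches_every_component(self):
        """All learnable tensors (psi, phi, theta, omega) get nonzero gradients."""
        rng = np.random.default_rng(4)
        cfg = TrainingConfig(variant="vie", beta=0.1, lam=0.5, **FAST)
        d = 4
        aux = training._build_aux(cfg, d)
        params = training.init_params(cfg, d, rng)
        X = rng.standard_normal((64, d))
        y = rng.integers(0, 2, 64).astype(float)
        eps = rng.standard_normal((1, 64, cfg.latent_dim))
        # tail parameters only see gradient through exceedances of u, so use
        # enough prior draws that some land in the tail (P(none) ~ 1e-13)
        uniforms = rng.uniform(size=(1000, cfg.latent_dim))

        def loss(tree):
            full = {**params, **tree}
            psi = training.objective_psi(full, X, y, eps, cfg, aux)
            return psi - cfg.lam * training.gamma_value(
                full, X, eps, uniforms, cfg, aux)

        mtree = {k: params[k] for k in ("prior", "encoder", "flows", "decoder")}
        g = grad(loss)(mtree)
        for key in mtree:
            flat, _ = flatten(g[key])
            assert np.any(flat != 0), f"no gradient reached {key}"
        g_critic = grad(lambda c: training.gamma_value(
            params, X, eps, uniforms, cfg, aux, critic=c))(params["critic"])
        flat, _ = flatten(g_critic)
        assert np.any(flat != 0)


class TestTrainLoop:
    def test_invalid_labels_rejected(self, toy_data):
        X, y, Xv, yv = toy_data
        cfg = TrainingConfig(variant="vae", **FAST)
        with pytest.raises(ValueError):
            training.train(X, y * 3, Xv, yv, cfg)
        with pytest.raises(ValueError):
            training.train(X, np.zeros_like(y), Xv, yv, cfg)

    def test_vae_degenerate_wiring_trains_and_improves(self, toy_data):
        X, y, Xv, yv = toy_data
        cfg = TrainingConfig(variant="vae", lam=0.0, beta=1e-4, lr=3e-3,
                             **{**FAST, "max_epochs": 6})
        model = training.train(X, y, Xv, yv, cfg)
        objs = [h["objective"] for h in model.history]
        assert objs[-1] > objs[0]  # ascending the objective
        assert model.history[-1]["val_auc"] > 0.5

    def test_identical_config_identical_history(self, toy_data):
        X, y, Xv, yv = toy_data
        cfg = TrainingConfig(variant="vie", seed=7, **FAST)
        m1 = training.train(X, y, Xv, yv, cfg)
        m2 = training.train(X, y, Xv, yv, cfg)
        assert m1.history == m2.history

    @pytest.mark.parametrize("variant", sorted(VARIANTS))
    def test_all_variants_train_and_predict(self, toy_data, variant):
        X, y, Xv, yv = toy_data
        cfg = TrainingConfig(variant=variant, **{**FAST, "max_epochs": 1})
        model = training.train(X, y, Xv, yv, cfg)
        risk = training.predict_risk(model, Xv[:10], s_eval=2, seed=0)
        assert risk.shape == (10,)
        assert np.all((risk >= 0) & (risk <= 1))


class TestPrediction:
    @pytest.fixture(scope="class")
    def fitted(self):
        data = simulate_dataset(SimulationConfig(n=600, d=4, target_event_rate=0.1, seed=1))
        tr, va, _ = train_val_test_split(600, seed=1)
        cfg = TrainingConfig(variant="vie", **FAST)
        return training.train(data.X[tr], data.y[tr], data.X[va], data.y[va], cfg), data

    def test_same_seed_same_output(self, fitted):
        model, data = fitted
        a = training.predict_risk(model, data.X[:20], s_eval=1, seed=3)
        b = training.predict_risk(model, data.X[:20], s_eval=1, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_bias_only_decoder_constant_risk(self, fitted):
        model, data = fitted
        model2 = copy.deepcopy(model)
        model2.params["decoder"]["alpha"] = np.zeros_like(model2.params["decoder"]["alpha"])
        model2.params["decoder"]["gamma"] = np.array(0.3)
        risk = training.predict_risk(model2, data.X[:15], s_eval=4, seed=0)
        np.testing.assert_allclose(risk, 1 - np.exp(-np.exp(0.3)), atol=1e-12)

    def test_dimension_mismatch(self, fitted):
        model, _ = fitted
        with pytest.raises(ValueError):
            training.predict_risk(model, np.zeros((3, 9)))

    def test_checkpoint_round_trip_bitwise(self, fitted, tmp_path):
        model, data = fitted
        before = training.predict_risk(model, data.X[:30], seed=5)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = FittedModel.load(path)
        after = training.predict_risk(loaded, data.X[:30], seed=5)
        np.testing.assert_array_equal(before, after)

    def test_risk_monotone_along_positive_direction(self, fitted):
        """Predicted risk rises along a latent coordinate with alpha_j > 0."""
        from vie import amnn
        model, _ = fitted
        params = model.params["decoder"]
        cfg = model.config
        j = int(np.argmax(np.abs(params["alpha"])))
        sign = np.sign(params["alpha"][j])
        grid = np.linspace(-3, 3, 25)
        z = np.zeros((25, cfg.latent_dim))
        z[:, j] = sign * grid
        dec = {**params, "lower_end": cfg.lower_end, "n_grid": cfg.n_grid}
        scores = np.asarray(amnn.amnn_forward(dec, z))
        assert np.all(np.diff(scores) > -1e-12)
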