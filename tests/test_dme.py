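import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import norm

from mixsel.dme import (
    DMEParams,
    GeneBatch,
    TrainConfig,
    _forward_cached,
    _gene_nll_and_grads,
    _node_ll_sums,
    _params_to_values,
    _values_to_params,
    eta,
    forward_fixed_effect,
    gene_log_marginal_likelihood,
    grid_search,
    init_params,
    split_genes,
    standardize_features,
    train,
)
from mixsel.simulate import simulate_missense_dataset


def random_batch(rng, n=10, k=3, p_obs=0.2):
    return GeneBatch(
        "g", rng.normal(size=(n, k)), rng.beta(2, 50, size=n),
        (rng.random(n) < p_obs).astype(float),
    )


class TestStandardize:
    def test_population_sd_convention(self):
        X = np.array([[1.0], [2.0], [3.0]])
        Xs, rec = standardize_features(X, ["continuous"])
        assert np.allclose(Xs.ravel(), [-1.2247448, 0.0, 1.2247448])

    def test_binary_untouched(self):
        X = np.array([[0.0], [1.0], [0.0]])
        Xs, rec = standardize_features(X)
        assert np.array_equal(Xs, X)
        assert rec.kinds == ["binary"]

    def test_idempotent_for_continuous(self):
        rng = np.random.default_rng(0)
        X = rng.normal(3.0, 2.0, size=(50, 2))
        X1, _ = standardize_features(X)
        X2, _ = standardize_features(X1)
        assert np.allclose(X1, X2)

    def test_zero_variance_column_named(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ValueError, match="column 0"):
            standardize_features(X, ["continuous", "continuous"])

    def test_record_reapplies_verbatim(self):
        rng = np.random.default_rng(1)
        X = rng.normal(5, 3, size=(100, 2))
        Xs, rec = standardize_features(X)
        assert np.allclose(rec.apply(X), Xs)


class TestForward:
    def test_zero_weights_give_zero(self):
        rng = np.random.default_rng(2)
        p = DMEParams(W_output=np.zeros(4), b_output=0.0, sigma=1.0)
        assert np.all(forward_fixed_effect(rng.normal(size=(7, 4)), p) == 0.0)

    def test_linear_dot_product(self):
        p = DMEParams(W_output=np.array([1.0, -1.0]), b_output=0.0, sigma=1.0)
        assert forward_fixed_effect(np.array([[2.0, 3.0]]), p)[0] == pytest.approx(-1.0)

    def test_nonlinear_matches_hand_rolled_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            p = init_params(4, 6, rng, dropout_rate=0.5)
            X = rng.normal(size=(9, 4))
            z = forward_fixed_effect(X, p, mode="infer")
            # brute-force forward pass written out independently
            expected = []
            for row in X:
                h = [max(0.0, sum(row[i] * p.W_hidden[i, j] for i in range(4))
                         + p.B_hidden[j]) for j in range(6)]
                expected.append(sum(h[j] * p.W_output[j] for j in range(6)) + p.b_output)
            assert np.allclose(z, expected)

    def test_dropout_mask_seeded_and_scaled(self):
        rng = np.random.default_rng(4)
        p = init_params(3, 16, rng, dropout_rate=0.5)
        X = rng.normal(size=(5, 3))
        z1 = forward_fixed_effect(X, p, mode="train", rng=99)
        z2 = forward_fixed_effect(X, p, mode="train", rng=99)
        assert np.array_equal(z1, z2)
        # expectation over masks equals the deterministic pass
        zs = np.mean(
            [forward_fixed_effect(X, p, mode="train", rng=s) for s in range(4000)],
            axis=0,
        )
        assert np.allclose(zs, forward_fixed_effect(X, p, mode="infer"), atol=0.08)

    def test_shape_mismatch_raises(self):
        p = DMEParams(W_output=np.zeros(4), b_output=0.0, sigma=1.0)
        with pytest.raises(Exception, match="feature count"):
            forward_fixed_effect(np.zeros((3, 5)), p)


class TestEta:
    @pytest.mark.parametrize(
        "z,u,expected", [(0, 0, 0.5), (2, -2, 0.5), (1, 0.5, expit(1.5))]
    )
    def test_values(self, z, u, expected):
        assert eta(z, u) == pytest.approx(expected)


class TestMarginalLikelihood:
    def test_degenerate_prior_equals_fixed_effect_likelihood(self):
        rng = np.random.default_rng(5)
        b = random_batch(rng, n=20)
        p = DMEParams(W_output=rng.normal(size=3), b_output=0.2, sigma=1e-8)
        z = forward_fixed_effect(b.X, p)
        prob = expit(z) * b.mu
        direct = float(np.sum(b.Y * np.log(prob) + (1 - b.Y) * np.log1p(-prob)))
        assert gene_log_marginal_likelihood(b, p, 20) == pytest.approx(direct, abs=1e-6)

    def test_single_variant_matches_dense_trapezoid(self):
        b = GeneBatch("g", np.zeros((1, 1)), np.array([0.5]), np.array([1.0]))
        p = DMEParams(W_output=np.zeros(1), b_output=0.0, sigma=1.0)
        got = gene_log_marginal_likelihood(b, p, 20)
        u = np.linspace(-10, 10, 20_001)
        integrand = expit(u) * 0.5 * norm.pdf(u)
        expected = np.log(np.trapezoid(integrand, u))
        assert got == pytest.approx(expected, rel=1e-8)

    def test_order_20_vs_60_self_consistency(self):
        rng = np.random.default_rng(6)
        b = random_batch(rng, n=50)
        p = DMEParams(W_output=rng.normal(size=3), b_output=0.0, sigma=1.2)
        l20 = gene_log_marginal_likelihood(b, p, 20)
        l60 = gene_log_marginal_likelihood(b, p, 60)
        assert l20 == pytest.approx(l60, rel=1e-6)

    def test_invalid_mu_rejected(self):
        with pytest.raises(ValueError, match="mu"):
            GeneBatch("g", np.zeros((1, 1)), np.array([1.0]), np.array([0.0]))

    def test_empty_gene_contributes_nothing(self):
        b = GeneBatch("g", np.zeros((0, 2)), np.zeros(0), np.zeros(0))
        p = DMEParams(W_output=np.zeros(2), b_output=0.0, sigma=1.0)
        assert gene_log_marginal_likelihood(b, p, 20) == 0.0


class TestGradients:
    @pytest.mark.parametrize("hidden", [0, 8])
    def test_analytic_matches_finite_differences(self, hidden):
        rng = np.random.default_rng(7)
        params = init_params(3, hidden, rng, dropout_rate=0.0)
        b = random_batch(rng, n=10, p_obs=0.3)
        vals = _params_to_values(params)
        p = _values_to_params(vals, params)
        z, cache = _forward_cached(b.X, p, "infer", None)
        nll, grads = _gene_nll_and_grads(b, p, 20, cache, z)
        eps = 1e-6
        for key in vals:
            grad = np.atleast_1d(np.asarray(grads[key]))
            for idx in np.ndindex(np.atleast_1d(np.asarray(vals[key])).shape):
                bumped = dict(vals)
                arr = np.atleast_1d(np.asarray(vals[key], dtype=float)).copy()
                arr[idx] += eps
                bumped[key] = (
                    arr.reshape(np.shape(vals[key])) if np.ndim(vals[key]) else float(arr[0])
                )
                p2 = _values_to_params(bumped, params)
                z2, c2 = _forward_cached(b.X, p2, "infer", None)
                nll2, _ = _gene_nll_and_grads(b, p2, 20, c2, z2)
                assert (nll2 - nll) / eps == pytest.approx(grad[idx], abs=5e-5)


@pytest.fixture(scope="module")
def small_data():
    batches, truth = simulate_missense_dataset(
        40, 80, 3, weights=np.array([-0.8, 0.0, 0.8]), sigma_true=0.8, seed=3
    )
    return batches, truth


class TestTraining:
    def test_objective_decreases_early(self, small_data):
        batches, _ = small_data
        tc = TrainConfig(learning_rate=1e-4, hidden_units=0, max_epochs=3,
                         patience=5, seed=0, refine_sigma=False)
        _, log = train(batches, tc)
        objs = [e["train_objective"] for e in log]
        assert objs[0] >= objs[1] >= objs[2]

    def test_bit_identical_under_same_seed(self, small_data):
        batches, _ = small_data
        tc = TrainConfig(learning_rate=1e-3, hidden_units=4, max_epochs=5,
                         patience=5, seed=11, refine_sigma=False)
        p1, log1 = train(batches, tc)
        p2, log2 = train(batches, tc)
        assert np.array_equal(p1.W_hidden, p2.W_hidden)
        assert np.array_equal(p1.W_output, p2.W_output)
        assert p1.sigma == p2.sigma
        assert log1 == log2

    def test_split_fractions_and_determinism(self):
        ids = [f"g{i}" for i in range(100)]
        s1 = split_genes(ids, (0.8, 0.1, 0.1), seed=5)
        s2 = split_genes(ids, (0.8, 0.1, 0.1), seed=5)
        assert s1 == s2
        assert len(s1["train"]) == 80 and len(s1["validation"]) == 10
        assert sorted(s1["train"] + s1["validation"] + s1["test"]) == sorted(ids)

    def test_grid_single_cell_returned(self, small_data):
        batches, _ = small_data
        tc = TrainConfig(learning_rate=1e-2, hidden_units=0, max_epochs=10, seed=0,
                         hyper_grid={"learning_rate": [1e-2], "hidden_units": [0]})
        params, report = grid_search(batches, tc)
        assert len(report) == 1
        assert params.hidden_units == 0

    def test_grid_linear_cell_competitive_on_linear_data(self, small_data):
        batches, _ = small_data
        tc = TrainConfig(learning_rate=1e-2, hidden_units=0, max_epochs=40,
                         patience=5, seed=0,
                         hyper_grid={"learning_rate": [1e-2], "hidden_units": [0, 16]})
        params, report = grid_search(batches, tc)
        assert len(report) == 2
        objs = report.set_index("hidden_units")["selection_objective"]
        assert objs[0] <= objs.min() * 1.01 + 1e-9

    def test_likelihood_dominance_at_truth(self, linear_fixture):
        """The generating parameters beat singly-perturbed alternatives."""
        batches, truth = linear_fixture
        p_true = DMEParams(
            W_output=truth.weights.copy(), b_output=truth.bias, sigma=truth.sigma_true
        )

        def total(p):
            return sum(gene_log_marginal_likelihood(b, p, 20) for b in batches[:100])

        base = total(p_true)
        for j in range(len(truth.weights)):
            for delta in (-0.5, 0.5):
                w = truth.weights.copy()
                w[j] += delta
                assert total(DMEParams(W_output=w, b_output=truth.bias,
                                       sigma=truth.sigma_true)) < base
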