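import numpy as np
import pytest
from scipy.optimize import least_squares
from scipy.special import expit

from ftirmw import (
    AnnModel,
    LMRegressor,
    evaluate,
    forward,
    forward_matrix,
    load_model,
    save_model,
    split_dataset,
    train_lm,
)


def random_model(rng, sizes=(3, 4, 1), activation="sigmoid"):
    weights = [rng.normal(0, 1, (sizes[l + 1], sizes[l])) for l in range(len(sizes) - 1)]
    biases = [rng.normal(0, 0.5, sizes[l + 1]) for l in range(len(sizes) - 1)]
    return AnnModel(
        layer_sizes=sizes,
        weights=weights,
        biases=biases,
        input_mean=rng.normal(0, 1, sizes[0]),
        input_scale=rng.uniform(0.5, 2.0, sizes[0]),
        output_offset=rng.normal(),
        output_slope=rng.uniform(0.5, 2.0),
        hidden_activation=activation,
    )


class TestForward:
    def test_zero_weights_return_inverse_scaled_output_bias(self, rng):
        m = AnnModel(
            layer_sizes=(2, 3, 1),
            weights=[np.zeros((3, 2)), np.zeros((1, 3))],
            biases=[np.zeros(3), np.array([0.42])],
            input_mean=np.zeros(2),
            input_scale=np.ones(2),
            output_offset=0.1,
            output_slope=2.0,
        )
        for x in ([0.0, 0.0], [5.0, -3.0]):
            assert forward(m, x) == pytest.approx((0.42 - 0.1) / 2.0)

    def test_single_unit_closed_form_sigmoid(self):
        m = AnnModel(
            layer_sizes=(1, 1, 1),
            weights=[np.array([[1.0]]), np.array([[1.0]])],
            biases=[np.zeros(1), np.zeros(1)],
            input_mean=np.zeros(1),
            input_scale=np.ones(1),
            output_offset=0.0,
            output_slope=1.0,
        )
        for x in (-2.0, 0.0, 1.3):
            assert forward(m, [x]) == pytest.approx(1.0 / (1.0 + np.exp(-x)))

    def test_matches_handrolled_layer_arithmetic(self, rng):
        m = random_model(rng, sizes=(4, 5, 3, 1))
        X = rng.normal(0, 1, (10, 4))
        got = forward_matrix(m, X)
        Xs = (X - m.input_mean) / m.input_scale
        a = Xs
        for w, b in zip(m.weights[:-1], m.biases[:-1]):
            a = expit(a @ w.T + b)
        ys = (a @ m.weights[-1].T + m.biases[-1]).ravel()
        expect = (ys - m.output_offset) / m.output_slope
        np.testing.assert_allclose(got, expect, atol=1e-12)

    def test_feature_length_mismatch_raises(self, rng):
        m = random_model(rng)
        with pytest.raises(ValueError, match="features"):
            forward(m, [1.0, 2.0])

    def test_sigmoid_output_lipschitz_bound(self, rng):
        """Sensitivity to one input is bounded by the weight-path product with
        the 1/4 sigmoid slope cap."""
        for _ in range(5):
            m = random_model(rng, sizes=(3, 4, 1))
            x = rng.normal(0, 1, 3)
            j = int(rng.integers(0, 3))
            eps = 1e-3
            dx = np.zeros(3)
            dx[j] = eps
            change = abs(forward(m, x + dx) - forward(m, x))
            L = (
                np.abs(m.weights[1]) @ (0.25 * np.abs(m.weights[0][:, j]))
            ).item() / m.input_scale[j] / m.output_slope
            assert change <= L * eps * (1 + 1e-9)


class TestSerialization:
    def test_round_trip_bit_exact(self, tmp_path, rng):
        m = random_model(rng, sizes=(5, 4, 3, 1))
        path = tmp_path / "model.json"
        save_model(m, path)
        back = load_model(path)
        for a, b in zip(m.weights, back.weights):
            np.testing.assert_array_equal(a, b)
        X = rng.normal(0, 1, (20, 5))
        np.testing.assert_array_equal(forward_matrix(m, X), forward_matrix(back, X))


class TestSplit:
    def test_seventy_spectra_split_56_14(self, rng):
        X = rng.normal(0, 1, (70, 3))
        y = rng.uniform(1, 2, 70)
        sids = [f"S{k}" for k in np.repeat(range(7), 10)]
        Xtr, Xva, ytr, yva, itr, iva = split_dataset(X, y, sample_ids=sids, seed=0)
        assert (len(ytr), len(yva)) == (56, 14)
        assert set(itr) | set(iva) == set(range(70))
        assert set(itr) & set(iva) == set()
        # stratified: every sample contributes 2 validation replicates
        counts = {s: 0 for s in set(sids)}
        for i in iva:
            counts[sids[i]] += 1
        assert all(c == 2 for c in counts.values())

    def test_two_rows_half_split(self, rng):
        X = rng.normal(0, 1, (2, 1))
        out = split_dataset(X, [1.0, 2.0], train_fraction=0.5, stratify_by_sample=False)
        assert (out[0].shape[0], out[1].shape[0]) == (1, 1)

    def test_same_seed_reproduces_split(self, rng):
        X = rng.normal(0, 1, (30, 2))
        y = rng.uniform(0, 1, 30)
        a = split_dataset(X, y, seed=7)
        b = split_dataset(X, y, seed=7)
        np.testing.assert_array_equal(a[4], b[4])

    def test_bad_fraction_rejected(self, rng):
        with pytest.raises(ValueError, match="train_fraction"):
            split_dataset(np.zeros((4, 1)), np.zeros(4), train_fraction=1.2)


class TestTrainLm:
    def test_linear_data_fit_to_machine_precision(self):
        X = np.linspace(-1, 1, 40)[:, None]
        y = 3.0 * X.ravel()
        model, report = train_lm(X, y, hidden_layer_sizes=(3,), n_restarts=3, seed=0)
        sse = float(np.sum((forward_matrix(model, X) - y) ** 2))
        # SSE measured in scaled output space, per the training objective
        assert sse * model.output_slope**2 < 1e-8
        assert report.best_restart >= 0

    def test_fixed_seed_is_bit_reproducible(self, rng):
        X = rng.normal(0, 1, (50, 2))
        y = np.sin(X[:, 0]) + 0.5 * X[:, 1]
        m1, r1 = train_lm(X, y, hidden_layer_sizes=(3,), n_restarts=4, seed=11)
        m2, r2 = train_lm(X, y, hidden_layer_sizes=(3,), n_restarts=4, seed=11)
        assert r1.final_sse == r2.final_sse
        assert r1.statuses == r2.statuses
        for a, b in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(a, b)

    def test_identity_activation_reproduces_ols(self, rng):
        """A linear network trained by LM must land on the least-squares plane."""
        X = rng.normal(0, 1, (60, 3))
        beta = np.array([1.5, -2.0, 0.7])
        y = X @ beta + 0.3 + rng.normal(0, 0.05, 60)
        reg = LMRegressor(
            hidden_layer_sizes=(2,), hidden_activation="identity",
            n_restarts=3, random_state=0,
        ).fit(X, y)
        design = np.column_stack([X, np.ones(60)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        ols_pred = design @ coef
        np.testing.assert_allclose(reg.predict(X), ols_pred, atol=1e-6)

    def test_overparameterization_warns(self, rng):
        X = rng.normal(0, 1, (10, 4))
        y = rng.uniform(0, 1, 10)
        with pytest.warns(UserWarning, match="overparameterized"):
            LMRegressor(hidden_layer_sizes=(4,), n_restarts=1, max_iter=20,
                        random_state=0).fit(X, y)

    def test_matches_scipy_least_squares_on_overdetermined_problem(self, rng):
        """Dual-route check: our LM and MINPACK reach the same SSE floor."""
        X = rng.normal(0, 1, (200, 2))
        y = np.tanh(X[:, 0]) - 0.5 * X[:, 1] + rng.normal(0, 0.02, 200)
        reg = LMRegressor(hidden_layer_sizes=(3,), n_restarts=5, random_state=2).fit(X, y)
        ours = float(np.min(reg.report_.final_sse))

        mu, sd = X.mean(0), X.std(0)
        Xs = (X - mu) / sd
        span = np.ptp(y)
        slope = 0.8 / span
        ys = 0.1 + slope * (y - y.min())

        def resid(theta):
            W1 = theta[:6].reshape(3, 2)
            b1 = theta[6:9]
            W2 = theta[9:12].reshape(1, 3)
            b2 = theta[12:]
            return (expit(Xs @ W1.T + b1) @ W2.T + b2).ravel() - ys

        best = np.inf
        for s in range(5):
            r0 = np.random.default_rng(s).normal(0, 0.5, 13)
            sol = least_squares(resid, r0, method="lm", max_nfev=20000)
            best = min(best, 2 * sol.cost)
        assert ours == pytest.approx(best, rel=0.05)

    def test_teacher_student_with_mild_noise(self, rng):
        """Validation RMSE approaches the injected noise level (no bias)."""
        teacher = random_model(rng, sizes=(4, 3, 1))
        X = rng.normal(0, 1, (300, 4))
        clean = forward_matrix(teacher, X)
        sigma = 0.01 * np.ptp(clean)
        y = clean + rng.normal(0, sigma, clean.size)
        Xtr, Xva, ytr, yva, _, _ = split_dataset(X, y, stratify_by_sample=False, seed=1)
        reg = LMRegressor(hidden_layer_sizes=(3,), n_restarts=6, random_state=5).fit(Xtr, ytr)
        rmse = float(np.sqrt(np.mean((reg.predict(Xva) - yva) ** 2)))
        assert 0.5 * sigma < rmse < 2.0 * sigma


class TestEvaluate:
    def test_perfect_predictions_zero_rmse(self, rng):
        y = rng.uniform(1e4, 1e6, 20)
        rep = evaluate(None, None, y, predictions=y.copy())
        assert rep.rmse == 0.0
        assert (rep.frame["rel_error"] == 0).all()

    def test_constant_mean_predictor_rmse_is_population_sd(self, rng):
        y = rng.uniform(1e4, 1e6, 50)
        rep = evaluate(None, None, y, predictions=np.full(50, y.mean()))
        assert rep.rmse == pytest.approx(y.std(ddof=0), rel=1e-12)

    def test_region_binning_at_200_kda(self):
        y = np.array([5e4, 1e5, 3e5, 7e5])
        pred = np.array([5.5e4, 0.9e5, 4e5, 5e5])
        rep = evaluate(None, None, y, predictions=pred)
        regions = dict(zip(rep.by_region["region"], rep.by_region["n"]))
        assert regions == {"< 200 kDa": 2, ">= 200 kDa": 2}
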