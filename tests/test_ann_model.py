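"""Network forward pass, gradients, Adam training, metrics, serialization."""

import math

import numpy as np
import pytest

from stoverann import preprocessing as pp
from stoverann.ann_model import (
    NetworkParams,
    TrainingConfig,
    evaluate_parity,
    forward,
    init_network,
    load_weights,
    loss_and_grads,
    params_from_json,
    params_to_json,
    predict_conditions,
    rmse,
    save_weights,
    train_adam,
)
from stoverann.dataset_io import CONDITION_VARS, OUTPUT_VARS, split_dataset

from conftest import dataset_from_arrays, random_conditions


def forward_oracle(params, x):
    """Straight-line double-loop evaluation of the 6-n-2 forward pass."""
    n = params.n_hidden
    h = np.empty(n)
    for j in range(n):
        z = params.b1[j]
        for i in range(6):
            z += params.IW[j, i] * x[i]
        h[j] = math.tanh(z)
    y = np.empty(2)
    for k in range(2):
        z = params.b2[k]
        for j in range(n):
            z += params.LW[k, j] * h[j]
        y[k] = z
    return y


class TestInit:
    def test_seeded_init_is_reproducible_and_shaped(self):
        a, b = init_network(12, 7), init_network(12, 7)
        np.testing.assert_array_equal(a.IW, b.IW)
        np.testing.assert_array_equal(a.LW, b.LW)
        c = init_network(3, 0)
        assert c.IW.shape == (3, 6) and c.LW.shape == (2, 3)
        assert np.all(c.b1 == 0) and np.all(c.b2 == 0)
        assert np.all(np.abs(c.IW) < 0.5)

    def test_hidden_size_below_one_rejected(self):
        with pytest.raises(ValueError):
            init_network(0, 0)


class TestForward:
    def test_zero_weights_return_output_bias(self):
        p = NetworkParams(np.zeros((4, 6)), np.zeros(4), np.zeros((2, 4)), np.array([1.5, -2.0]))
        np.testing.assert_allclose(forward(p, np.ones(6)), [1.5, -2.0])

    def test_zero_input_zero_bias_gives_zero(self):
        p = init_network(5, 3)
        p.b1[:] = 0
        p.b2[:] = 0
        out = forward(p, np.zeros(6))
        np.testing.assert_allclose(out, p.LW @ np.tanh(np.zeros(5)), atol=1e-15)
        np.testing.assert_allclose(out, 0.0, atol=1e-15)

    def test_reference_weights_at_origin_match_brute_force(self, reference_params):
        # value b2 + LW . tanh(b1), computed by the independent summation oracle
        x = np.zeros(6)
        expected = forward_oracle(reference_params, x)
        np.testing.assert_allclose(forward(reference_params, x), expected, atol=1e-12)
        np.testing.assert_allclose(
            expected,
            reference_params.b2 + reference_params.LW @ np.tanh(reference_params.b1),
            atol=1e-12,
        )

    def test_agrees_with_double_loop_oracle_on_100_random_networks(self):
        rng = np.random.default_rng(0)
        for trial in range(100):
            n = int(rng.integers(1, 15))
            p = init_network(n, trial)
            p.b1[:] = rng.normal(size=n)
            p.b2[:] = rng.normal(size=2)
            x = rng.normal(size=6)
            np.testing.assert_allclose(forward(p, x), forward_oracle(p, x), atol=1e-12)

    def test_dimension_mismatch_rejected(self, random_params):
        with pytest.raises(ValueError):
            forward(random_params(), np.zeros(5))


class TestGradients:
    def test_analytic_gradients_match_central_differences(self):
        rng = np.random.default_rng(5)
        p = init_network(3, 5)
        X = rng.normal(size=(5, 6))
        Y = rng.normal(size=(5, 2))
        _, grads = loss_and_grads(p, X, Y)
        eps = 1e-6
        for key in ("IW", "b1", "LW", "b2"):
            arr = getattr(p, key)
            num = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + eps
                lp, _ = loss_and_grads(p, X, Y)
                arr[idx] = orig - eps
                lm, _ = loss_and_grads(p, X, Y)
                arr[idx] = orig
                num[idx] = (lp - lm) / (2 * eps)
            denom = np.maximum(np.abs(num), 1e-8)
            rel = np.max(np.abs(grads[key] - num) / denom)
            assert rel < 1e-5, f"{key}: rel err {rel}"


class TestRmse:
    @pytest.mark.parametrize(
        "pred,exp,expected",
        [([1.0, 2.0], [1.0, 2.0], 0.0), ([3.0], [0.0], 3.0), ([1.0, -1.0], [0.0, 0.0], 1.0)],
    )
    def test_hand_examples(self, pred, exp, expected):
        assert rmse(pred, exp) == pytest.approx(expected)

    def test_invalid_lengths_rejected(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            rmse([], [])

    def test_permutation_invariant_and_scales_linearly(self):
        rng = np.random.default_rng(2)
        p, e = rng.normal(size=30), rng.normal(size=30)
        perm = rng.permutation(30)
        assert rmse(p, e) == pytest.approx(rmse(p[perm], e[perm]))
        assert rmse(3.5 * p, 3.5 * e) == pytest.approx(3.5 * rmse(p, e))


class TestParity:
    def test_perfect_and_scaled_parity(self):
        e = np.array([1.0, 2.0, 3.0, 4.0])
        assert evaluate_parity(e, e) == pytest.approx((1.0, 1.0))
        assert evaluate_parity(2 * e, e) == pytest.approx((2.0, 1.0))

    def test_matches_closed_form_ols_on_noisy_data(self):
        rng = np.random.default_rng(4)
        e = rng.uniform(5, 25, 100)
        p = e + rng.normal(0, 0.5, 100)
        slope, r2 = evaluate_parity(p, e)
        # closed-form simple-regression oracle
        slope_cf = np.sum((e - e.mean()) * (p - p.mean())) / np.sum((e - e.mean()) ** 2)
        r2_cf = np.corrcoef(e, p)[0, 1] ** 2
        assert slope == pytest.approx(slope_cf, abs=1e-10)
        assert r2 == pytest.approx(r2_cf, abs=1e-10)
        assert 0.9 < slope < 1.1

    def test_constant_measurements_rejected(self):
        with pytest.raises(ValueError):
            evaluate_parity([1.0, 2.0], [3.0, 3.0])


def _linear_dataset(n=77, seed=7):
    X = random_conditions(n, seed=seed)
    y = 5.0 + 20.0 * X[:, 0]
    return dataset_from_arrays(X, np.column_stack([y, y]))


class TestTraining:
    def test_zero_iterations_returns_initial_params(self):
        data = _linear_dataset(20)
        tr, va, _ = split_dataset(data, seed=0)
        p0 = init_network(3, 1)
        p1, hist = train_adam(p0, tr, va, TrainingConfig(iterations=0, seed=1))
        np.testing.assert_array_equal(p0.IW, p1.IW)
        assert hist.iterations == []

    def test_same_seed_gives_identical_histories(self):
        data = _linear_dataset(30)
        tr, va, _ = split_dataset(data, seed=2)
        cfg = TrainingConfig(iterations=20, seed=3, checkpoint_every=5)
        _, h1 = train_adam(init_network(4, 3), tr, va, cfg)
        _, h2 = train_adam(init_network(4, 3), tr, va, cfg)
        assert h1.rmse_train == h2.rmse_train
        assert h1.rmse_val == h2.rmse_val

    def test_linear_map_is_learned_to_small_normalized_error(self):
        # y is affine in one input: a 3-neuron tanh net fits it almost exactly
        data = _linear_dataset()
        tr, va, _ = split_dataset(data, seed=1)
        p, _ = train_adam(
            init_network(3, 1), tr, va, TrainingConfig(iterations=800, seed=1), checkpoints=[800]
        )
        ispec = pp.fit_normalizer(tr.condition_matrix(), CONDITION_VARS)
        tspec = pp.fit_normalizer(tr.output_matrix(), OUTPUT_VARS)
        Xn = pp.normalize_matrix(tr.condition_matrix(), CONDITION_VARS, ispec)
        Yn = pp.normalize_matrix(tr.output_matrix(), OUTPUT_VARS, tspec)
        pred = forward(p, Xn)
        assert rmse(pred.ravel(), Yn.ravel()) < 0.05
        # sanity: least-squares on the normalized design is the representable optimum
        A = np.column_stack([Xn, np.ones(len(Xn))])
        resid = Yn - A @ np.linalg.lstsq(A, Yn, rcond=None)[0]
        assert np.sqrt(np.mean(resid**2)) < 1e-10

    def test_recovers_teacher_network_predictions(self):
        # noiseless targets from a random 6-12-2 teacher: test RMSE < 2% of range
        X = random_conditions(77, seed=7)
        ispec = pp.fit_normalizer(X, CONDITION_VARS)
        teacher = init_network(12, 42)
        Y = 10.0 + 5.0 * forward(teacher, pp.normalize_matrix(X, CONDITION_VARS, ispec))
        data = dataset_from_arrays(X, Y)
        tr, va, te = split_dataset(data, seed=7)
        p, _ = train_adam(
            init_network(12, 7), tr, va, TrainingConfig(iterations=2000, seed=7), checkpoints=[2000]
        )
        isp = pp.fit_normalizer(tr.condition_matrix(), CONDITION_VARS)
        tsp = pp.fit_normalizer(tr.output_matrix(), OUTPUT_VARS)
        Yhat = predict_conditions(p, te.condition_matrix(), isp, tsp)
        Yexp = te.output_matrix()
        for j in range(2):
            assert rmse(Yhat[:, j], Yexp[:, j]) < 0.02 * np.ptp(data.output_matrix()[:, j])

    def test_missing_outputs_rejected(self):
        data = dataset_from_arrays(random_conditions(10, seed=0))  # no outputs
        tr, va, _ = split_dataset(data, seed=0)
        with pytest.raises(ValueError):
            train_adam(init_network(3, 0), tr, va, TrainingConfig(iterations=1))


class TestWeightsSerialization:
    def test_reference_table_spot_values(self, reference_params):
        p = reference_params
        assert p.n_hidden == 12
        assert p.IW[0, 0] == pytest.approx(0.4211)
        assert p.IW[11, 1] == pytest.approx(0.5409)
        assert p.b1[0] == pytest.approx(-0.0095)
        assert p.LW[0, 3] == pytest.approx(0.6842)
        assert p.LW[1, 9] == pytest.approx(0.6152)
        assert p.b2[0] == pytest.approx(-0.0381)
        assert p.b2[1] == pytest.approx(-0.0051)

    def test_csv_roundtrip_is_lossless(self, tmp_path, random_params):
        p = random_params(n=9, seed=13)
        p.b1[:] = np.random.default_rng(1).normal(size=9)
        path = tmp_path / "w.csv"
        save_weights(p, path)
        q = load_weights(path)
        for key in ("IW", "b1", "LW", "b2"):
            np.testing.assert_array_equal(getattr(p, key), getattr(q, key))

    def test_row_count_contradiction_rejected(self, tmp_path, random_params):
        path = tmp_path / "w.csv"
        save_weights(random_params(n=11, seed=0), path)
        with pytest.raises(ValueError, match="12"):
            load_weights(path, expected_n=12)

    def test_malformed_cell_rejected(self, tmp_path, random_params):
        path = tmp_path / "w.csv"
        save_weights(random_params(n=3, seed=0), path)
        text = path.read_text().replace("0.", "0x.", 1)
        path.write_text(text)
        with pytest.raises(ValueError, match="malformed"):
            load_weights(path)

    def test_json_roundtrip(self, tmp_path, random_params):
        p = random_params(n=6, seed=2)
        path = tmp_path / "w.json"
        params_to_json(p, path)
        q = params_from_json(path)
        np.testing.assert_array_equal(p.IW, q.IW)
        assert q.hidden_activation == p.hidden_activation
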