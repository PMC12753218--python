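"""Linear / neural-network estimators, the 6 g/L gate, LOO and Pearson."""

import numpy as np
import pytest

from clotwave import (
    FeatureVector,
    LinearModel,
    NNModel,
    SampleRecord,
    Standardizer,
    TrainConfig,
    extract_features,
    fit_linear,
    fit_nn,
    fit_standardizer,
    loo_evaluate,
    nn_forward,
    pearson_eval,
    predict_combined,
)
from clotwave.estimators import EstimatorError, PredictionSet, Prediction

from conftest import sigmoid_transparency


def toy_records(toy_waveforms, beta=(1.0, -0.002, 3.0, 40.0, 40.0),
                noise_sd=0.0, seed=0):
    """Records whose truth is an exact (or noisy) linear map of features."""
    rng = np.random.default_rng(seed)
    records = []
    for i, wf in enumerate(toy_waveforms):
        f = extract_features(wf).as_array()
        y = beta[0] + float(np.dot(beta[1:], f))
        y += rng.normal(0, noise_sd)
        records.append(SampleRecord(
            sample_id=wf.sample_id, fibrinogen_ref=max(y, 0.01), inr=1.0,
            waveforms={"pt": wf}))
    return records


class TestStandardizer:
    def test_transform_centres_and_scales(self):
        rng = np.random.default_rng(0)
        X = rng.normal(5, 3, size=(50, 4))
        std = fit_standardizer(X)
        Z = std.transform(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1.0, rtol=1e-12)

    def test_hand_computed_three_vectors(self):
        X = np.array([[1.0, 2.0, 0.0, 4.0],
                      [3.0, 2.5, 1.0, 0.0],
                      [5.0, 6.0, 2.0, 2.0]])
        std = fit_standardizer(X)
        # hand arithmetic: means and sample SDs per column
        np.testing.assert_allclose(std.means, [3.0, 3.5, 1.0, 2.0])
        np.testing.assert_allclose(
            std.sds, [2.0, np.sqrt(4.75), 1.0, 2.0])

    def test_zero_variance_feature_named(self):
        X = np.array([[1.0, 2.0, 3.0, 4.0]] * 5)
        X[:, 0] = [1, 2, 3, 4, 5]
        with pytest.raises(EstimatorError, match="g_max"):
            fit_standardizer(X)


class TestLinear:
    def test_exact_recovery(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 4))
        beta = np.array([1.5, -2.0, 0.5, 3.0])
        y = 0.7 + X @ beta
        m = fit_linear(X, y)
        assert m.intercept == pytest.approx(0.7, abs=1e-9)
        np.testing.assert_allclose(m.coefficients, beta, atol=1e-9)
        assert m.predict(X[0]) == pytest.approx(y[0], abs=1e-9)

    def test_constant_targets(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 4))
        m = fit_linear(X, np.full(10, 4.2))
        assert m.intercept == pytest.approx(4.2, abs=1e-9)
        np.testing.assert_allclose(m.coefficients, 0.0, atol=1e-9)

    def test_noisy_coefficients_within_3_se(self):
        rng = np.random.default_rng(3)
        n = 200
        X = rng.normal(size=(n, 4))
        beta = np.array([2.0, -1.0, 0.5, 0.0])
        sigma = 0.1
        y = 1.0 + X @ beta + rng.normal(0, sigma, n)
        m = fit_linear(X, y)
        A = np.column_stack([np.ones(n), X])
        resid = y - A @ np.concatenate([[m.intercept], m.coefficients])
        s2 = resid @ resid / (n - 5)
        se = np.sqrt(s2 * np.diag(np.linalg.inv(A.T @ A)))
        assert abs(m.intercept - 1.0) < 3 * se[0]
        assert np.all(np.abs(m.coefficients - beta) < 3 * se[1:])

    def test_rank_deficient_rejected(self):
        X = np.ones((10, 4))
        X[:, 0] = np.arange(10)
        X[:, 1] = 2 * X[:, 0]
        with pytest.raises(EstimatorError):
            fit_linear(X, np.arange(10.0))

    def test_too_few_samples_rejected(self):
        with pytest.raises(EstimatorError):
            fit_linear(np.eye(4), np.ones(4))


def hand_nn(W1=None, b1=None, W2=None, b2=0.0):
    std = Standardizer(means=np.zeros(4), sds=np.ones(4))
    return NNModel(
        W1=np.zeros((3, 4)) if W1 is None else np.asarray(W1, float),
        b1=np.zeros(3) if b1 is None else np.asarray(b1, float),
        W2=np.zeros((1, 3)) if W2 is None else np.asarray(W2, float),
        b2=b2, standardizer=std)


class TestNNForward:
    def test_zero_weights_return_bias(self):
        m = hand_nn(b2=2.5)
        assert nn_forward(m, np.array([9.0, -4.0, 7.0, 1.0])) == 2.5

    def test_hand_computed_single_path(self):
        # one significant weight: y = 2 * tanh(0.5 * x1 + 0.1) + 1
        W1 = np.zeros((3, 4)); W1[0, 0] = 0.5
        W2 = np.zeros((1, 3)); W2[0, 0] = 2.0
        m = hand_nn(W1=W1, b1=[0.1, 0, 0], W2=W2, b2=1.0)
        x = np.array([0.8, 5.0, -3.0, 2.0])
        expected = 2.0 * np.tanh(0.5 * 0.8 + 0.1) + 1.0
        assert nn_forward(m, x) == pytest.approx(expected, abs=1e-12)

    def test_saturation_bound(self):
        rng = np.random.default_rng(4)
        W1 = rng.normal(size=(3, 4)) * 1e6
        W2 = rng.normal(size=(1, 3))
        m = hand_nn(W1=W1, b1=rng.normal(size=3), W2=W2, b2=-0.3)
        bound = abs(m.b2) + np.abs(W2).sum()
        for _ in range(20):
            x = rng.normal(scale=100.0, size=4)
            assert abs(nn_forward(m, x)) <= bound + 1e-12

    def test_shape_validation(self):
        with pytest.raises(EstimatorError):
            NNModel(W1=np.zeros((2, 4)), b1=np.zeros(3),
                    W2=np.zeros((1, 3)), b2=0.0,
                    standardizer=Standardizer(np.zeros(4), np.ones(4)))


class TestNNTraining:
    def test_constant_targets_converge(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 4))
        y = np.full(12, 2.5)
        m = fit_nn(X, y, TrainConfig(seed=1))
        mse = np.mean([(nn_forward(m, x) - 2.5) ** 2 for x in X])
        assert mse <= 1e-3

    def test_same_seed_bit_identical(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 4))
        y = rng.uniform(1, 10, 10)
        cfg = TrainConfig(seed=3, epochs=500)
        m1 = fit_nn(X, y, cfg)
        m2 = fit_nn(X, y, cfg)
        np.testing.assert_array_equal(m1.W1, m2.W1)
        np.testing.assert_array_equal(m1.W2, m2.W2)
        assert m1.b2 == m2.b2

    def test_loss_decreases_on_learnable_toy(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 4))
        std_x1 = (X[:, 0] - X[:, 0].mean()) / X[:, 0].std(ddof=1)
        y = 2.0 * std_x1
        init = fit_nn(X, y, TrainConfig(seed=2, epochs=1))
        final = fit_nn(X, y, TrainConfig(seed=2, epochs=4000))
        mse0 = np.mean([(nn_forward(init, x) - t) ** 2
                        for x, t in zip(X, y)])
        mse1 = np.mean([(nn_forward(final, x) - t) ** 2
                        for x, t in zip(X, y)])
        assert mse1 < mse0 / 10

    def test_too_few_samples_rejected(self):
        with pytest.raises(EstimatorError):
            fit_nn(np.eye(4), np.ones(4), TrainConfig())


class TestCombinedRule:
    def _pair(self, nn_value, lr_value):
        lr = LinearModel(intercept=lr_value, coefficients=np.zeros(4))
        nn = hand_nn(b2=nn_value)
        return lr, nn

    @pytest.mark.parametrize("nn_v,lr_v,expected", [
        (5.0, 4.2, 4.2),   # NN below the gate -> linear prediction
        (7.0, 6.5, 7.0),   # NN above the gate -> NN prediction
        (6.0, 5.8, 6.0),   # boundary belongs to the NN branch
    ])
    def test_gate_cases(self, nn_v, lr_v, expected):
        lr, nn = self._pair(nn_v, lr_v)
        x = np.zeros(4)
        assert predict_combined(lr, nn, x) == expected

    def test_output_is_one_of_inputs(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            lr, nn = self._pair(rng.uniform(0, 12), rng.uniform(0, 12))
            x = rng.normal(size=4)
            out = predict_combined(lr, nn, x)
            assert out in (nn_forward(nn, x), lr.predict(x))


class TestLOO:
    def test_exactly_linear_targets_recovered(self, toy_waveforms):
        records = toy_records(toy_waveforms)
        preds = loo_evaluate(records, "PT", methods=("linear",))
        for p in preds.retained:
            assert p.linear == pytest.approx(p.truth, abs=1e-6)
        r, pv, n = pearson_eval(preds, "linear")
        assert r == pytest.approx(1.0, abs=1e-9)
        assert n == len(records)

    def test_matches_per_fold_refit_oracle(self, toy_waveforms):
        records = toy_records(toy_waveforms, noise_sd=0.4)
        preds = loo_evaluate(records, "PT", methods=("linear",))
        feats = np.vstack([extract_features(r.waveforms["pt"]).as_array()
                           for r in records])
        y = np.array([r.fibrinogen_ref for r in records])
        for i, p in enumerate(preds.retained):
            mask = np.arange(len(records)) != i
            A = np.column_stack([np.ones(mask.sum()), feats[mask]])
            beta = np.linalg.solve(A.T @ A, A.T @ y[mask])
            oracle = beta[0] + feats[i] @ beta[1:]
            assert p.linear == pytest.approx(oracle, rel=1e-9)

    def test_missing_waveform_excluded_with_reason(self, toy_waveforms):
        records = toy_records(toy_waveforms)
        records[3].waveforms.pop("pt")
        preds = loo_evaluate(records, "PT", methods=("linear",))
        assert len(preds.retained) == len(records) - 1
        excl = preds.excluded[0]
        assert excl.sample_id == records[3].sample_id
        assert "waveform" in excl.reason
        assert excl.linear is None

    def test_no_leakage_from_held_out_sample(self, toy_waveforms):
        """Changing a held-out sample's waveform leaves its fold's fitted
        model untouched: the new prediction equals the old model applied
        to the new features."""
        tampered = toy_records(toy_waveforms, noise_sd=0.3)
        new_wf = sigmoid_transparency(3500.0, t50=40.0,
                                      sample_id=tampered[5].sample_id)
        # fold-5 oracle model fitted on everyone else (unaffected by the
        # tampering below)
        others = [r for i, r in enumerate(tampered) if i != 5]
        feats = np.vstack([extract_features(r.waveforms["pt"]).as_array()
                           for r in others])
        y = np.array([r.fibrinogen_ref for r in others])
        A = np.column_stack([np.ones(len(others)), feats])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        tampered[5].waveforms["pt"] = new_wf
        preds = loo_evaluate(tampered, "PT", methods=("linear",))
        new_feats = extract_features(new_wf).as_array()
        expected = beta[0] + new_feats @ beta[1:]
        assert preds.retained[5].linear == pytest.approx(expected, rel=1e-9)

    def test_too_few_records_rejected(self, toy_waveforms):
        records = toy_records(toy_waveforms[:5])
        with pytest.raises(EstimatorError):
            loo_evaluate(records, "PT", methods=("linear",))


class TestLeakage:
    def test_standardizer_ignores_held_out_fold(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(12, 4))
        y = rng.uniform(1, 10, 12)
        train = np.arange(12) != 4
        m1 = fit_nn(X[train], y[train], TrainConfig(seed=5, epochs=300))
        X2 = X.copy()
        X2[4] = 1e3  # wildly different held-out features
        m2 = fit_nn(X2[train], y[train], TrainConfig(seed=5, epochs=300))
        np.testing.assert_array_equal(m1.W1, m2.W1)
        np.testing.assert_array_equal(m1.standardizer.means,
                                      m2.standardizer.means)


class TestPearson:
    def _preds(self, truths, values):
        ps = PredictionSet(assay="PT")
        for i, (t, v) in enumerate(zip(truths, values)):
            ps.predictions.append(Prediction(
                sample_id=f"s{i}", truth=t, linear=v, nn=v, combined=v))
        return ps

    def test_perfect_and_anti_correlation(self):
        t = [1.0, 2.0, 3.0, 4.0]
        r, p, n = pearson_eval(self._preds(t, t), "linear")
        assert r == pytest.approx(1.0)
        r, p, n = pearson_eval(self._preds(t, [-x for x in t]), "linear")
        assert r == pytest.approx(-1.0)

    def test_five_pairs_match_textbook_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 2.9, 4.2, 3.9, 5.1])
        r, p, n = pearson_eval(self._preds(x, y), "combined")
        # textbook sums-of-squares oracle
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        oracle = sxy / np.sqrt(np.sum((x - x.mean()) ** 2)
                               * np.sum((y - y.mean()) ** 2))
        assert r == pytest.approx(oracle, abs=1e-12)
        assert n == 5
        # two-sided p from the t distribution with n-2 df
        from scipy import stats
        tstat = oracle * np.sqrt(3 / (1 - oracle ** 2))
        assert p == pytest.approx(2 * stats.t.sf(abs(tstat), df=3),
                                  rel=1e-9)

    def test_strata_filter_drops_challenging(self):
        ps = self._preds([1.0, 2.0, 3.0, 4.0, 5.0],
                         [1.1, 2.1, 2.9, 4.2, 5.0])
        ps.predictions[0].inr_stratum = "high"
        ps.predictions[1].antixa_positive = True
        r, p, n = pearson_eval(ps, "linear", strata_filter="regular_only")
        assert n == 3

    def test_too_few_pairs_rejected(self):
        with pytest.raises(EstimatorError):
            pearson_eval(self._preds([1.0, 2.0], [1.0, 2.0]), "linear")
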