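"""Lagged ridge models: solvers, cross-validation, lambda selection,
PCA reduction, decoding, single-lag analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stmtrf.features import envelope_feature, prepare
from stmtrf.simulate import (
    make_design,
    make_ground_truth,
    synth_neural,
    synth_word_audio,
)
from stmtrf.trf import (
    DEFAULT_LAMBDA_GRID,
    LagSpec,
    RidgeConfig,
    decode_setup,
    fit_banded,
    fit_ridge,
    lag_matrix,
    loto_cv,
    select_lambda,
    single_lag_decode,
)

SEED = 1234


class TestLagSpec:
    def test_counts_at_80hz(self):
        ls = LagSpec()
        assert ls.n_lags == 33  # -100..300 ms in 12.5 ms steps
        assert ls.predict_mask.sum() == 21  # 0..250 ms

    def test_non_multiple_lag_rejected(self):
        with pytest.raises(ValueError):
            LagSpec(fit_min_ms=-105.0)

    def test_predict_range_must_be_contained(self):
        with pytest.raises(ValueError):
            LagSpec(fit_max_ms=200.0, predict_max_ms=250.0)


class TestLagMatrix:
    def test_zero_lag_identity(self):
        x = np.random.default_rng(0).standard_normal((10, 3))
        np.testing.assert_array_equal(lag_matrix(x, np.array([0])), x)

    def test_column_layout_feature_major(self):
        x = np.arange(12.0).reshape(6, 2)
        X = lag_matrix(x, np.array([0, 1]))
        assert X.shape == (6, 4)
        np.testing.assert_array_equal(X[:, 0], x[:, 0])
        np.testing.assert_array_equal(X[1:, 1], x[:-1, 0])  # feature 0, lag 1
        assert X[0, 1] == 0.0
        np.testing.assert_array_equal(X[:, 2], x[:, 1])

    def test_shifting_input_moves_weight_mass_one_lag(self):
        """Fitting on data shifted by one sample relocates the recovered
        response function by exactly one lag."""
        rng = np.random.default_rng(3)
        x = rng.standard_normal((300, 1))
        lags = np.arange(0, 6)
        w_true = np.zeros(6)
        w_true[2] = 1.0
        y = lag_matrix(x, lags) @ w_true
        w1 = fit_ridge(lag_matrix(x, lags), y, 1e-8)
        x_shift = np.vstack([np.zeros((1, 1)), x[:-1]])
        w2 = fit_ridge(lag_matrix(x_shift, lags), y, 1e-8)
        assert np.argmax(np.abs(w1)) == 2
        assert np.argmax(np.abs(w2)) == 1


class TestFitRidge:
    def test_lambda_zero_is_least_squares(self):
        rng = np.random.default_rng(0)
        X, y = rng.standard_normal((30, 4)), rng.standard_normal(30)
        np.testing.assert_allclose(
            fit_ridge(X, y, 0.0), np.linalg.lstsq(X, y, rcond=None)[0], atol=1e-10
        )

    def test_norm_shrinks_monotonically(self):
        rng = np.random.default_rng(1)
        X, y = rng.standard_normal((40, 6)), rng.standard_normal(40)
        norms = [np.linalg.norm(fit_ridge(X, y, lam)) for lam in DEFAULT_LAMBDA_GRID]
        assert np.all(np.diff(norms) < 0)

    def test_small_instance_matches_normal_equations(self):
        rng = np.random.default_rng(2)
        X, y = rng.standard_normal((3, 2)), rng.standard_normal(3)
        lam = 0.7
        oracle = np.linalg.solve(X.T @ X + lam * np.eye(2), X.T @ y)
        np.testing.assert_allclose(fit_ridge(X, y, lam), oracle, atol=1e-10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        n=st.integers(3, 20),
        p=st.integers(1, 8),
        lam_exp=st.floats(-2, 4),
        seed=st.integers(0, 10_000),
    )
    def test_oracle_equivalence_property(self, n, p, lam_exp, seed):
        """Primal/dual closed forms match brute-force normal equations."""
        rng = np.random.default_rng(seed)
        X, y = rng.standard_normal((n, p)), rng.standard_normal(n)
        lam = 10.0**lam_exp
        oracle = np.linalg.solve(X.T @ X + lam * np.eye(p), X.T @ y)
        np.testing.assert_allclose(fit_ridge(X, y, lam), oracle, atol=1e-8)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            fit_ridge(np.eye(2), np.ones(2), -1.0)


class TestFitBanded:
    def test_equal_lambdas_reduce_to_ridge(self):
        rng = np.random.default_rng(4)
        X, y = rng.standard_normal((15, 8)), rng.standard_normal(15)
        bands = [slice(0, 5), slice(5, 8)]
        np.testing.assert_allclose(
            fit_banded(X, y, bands, (3.0, 3.0)), fit_ridge(X, y, 3.0), atol=1e-10
        )

    def test_two_band_grid_is_289(self):
        assert len(RidgeConfig().band_grid(2)) == 289

    def test_infinite_penalty_silences_band(self):
        rng = np.random.default_rng(5)
        X, y = rng.standard_normal((40, 8)), rng.standard_normal(40)
        bands = [slice(0, 4), slice(4, 8)]
        w = fit_banded(X, y, bands, (1e12, 2.0))
        assert np.max(np.abs(w[:4])) < 1e-4
        solo = fit_ridge(X[:, 4:], y, 2.0)
        np.testing.assert_allclose(w[4:], solo, atol=1e-3)

    def test_bands_must_partition(self):
        X = np.zeros((5, 4))
        with pytest.raises(ValueError):
            fit_banded(X, np.zeros(5), [slice(0, 2)], (1.0,))


@pytest.fixture(scope="module")
def cv_world():
    """12-trial envelope world with a noiseless linear response."""
    design = make_design(2, seed=SEED)
    ls = LagSpec()
    feats = {
        w: prepare(
            envelope_feature(synth_word_audio(w, seed=SEED)), ls.fit_min_ms, ls.fit_max_ms
        )
        for w in design["word_id"]
    }
    truth = make_ground_truth(1, 8, ls, noise_sd=0.0, seed=SEED)
    neural = synth_neural(feats, truth, design, 8)
    X = [feats[w].values for w in design["word_id"]]
    Y = list(neural.trials)
    return {"X": X, "Y": Y, "ls": ls, "truth": truth}


class TestLotoCV:
    def test_noiseless_accuracy_near_one(self, cv_world):
        cv = loto_cv(
            cv_world["X"], cv_world["Y"], cv_world["ls"], RidgeConfig(lambda_grid=(1e-4,))
        )
        assert cv.mean_accuracy().iloc[0] > 0.99

    def test_pure_noise_accuracy_near_zero(self, cv_world):
        rng = np.random.default_rng(0)
        Y = [rng.standard_normal(y.shape) for y in cv_world["Y"]]
        cv = loto_cv(cv_world["X"], Y, cv_world["ls"], RidgeConfig(lambda_grid=(32.0,)))
        n_eff = sum(y.size for y in Y)
        assert abs(cv.mean_accuracy().iloc[0]) < 2 / np.sqrt(n_eff / 8)

    def test_training_order_invariance(self, cv_world):
        """Weight averaging makes predictions invariant to trial order."""
        cfg = RidgeConfig(lambda_grid=(10.0,))
        cv1 = loto_cv(cv_world["X"], cv_world["Y"], cv_world["ls"], cfg)
        order = [5, 2, 7, 0, 1, 9, 3, 11, 4, 8, 10, 6]
        cv2 = loto_cv(
            [cv_world["X"][i] for i in order],
            [cv_world["Y"][i] for i in order],
            cv_world["ls"],
            cfg,
        )
        a1 = cv1.accuracy.sort_values(["trial", "output"])["r"].to_numpy()
        a2 = (
            cv2.accuracy.assign(trial=lambda d: [order[t] for t in d["trial"]])
            .sort_values(["trial", "output"])["r"]
            .to_numpy()
        )
        np.testing.assert_allclose(a1, a2, atol=1e-10)

    def test_short_trial_excluded_with_warning(self, cv_world):
        X = cv_world["X"][:4] + [cv_world["X"][4][:10]]
        Y = cv_world["Y"][:4] + [cv_world["Y"][4][:10]]
        with pytest.warns(UserWarning, match="shorter"):
            cv = loto_cv(X, Y, cv_world["ls"], RidgeConfig(lambda_grid=(1.0,)))
        assert cv.accuracy["trial"].nunique() == 4

    def test_needs_three_trials(self, cv_world):
        with pytest.raises(ValueError):
            loto_cv(cv_world["X"][:2], cv_world["Y"][:2], cv_world["ls"])

    def test_regularization_path_unimodal(self, cv_world):
        """Mean CV accuracy as a function of lambda rises then falls (small
        tolerance for sampling noise)."""
        rng = np.random.default_rng(1)
        noise_sd = np.sqrt(np.mean([np.mean(y**2) for y in cv_world["Y"]]))
        Y = [y + noise_sd * rng.standard_normal(y.shape) for y in cv_world["Y"]]
        cv = loto_cv(cv_world["X"], Y, cv_world["ls"], RidgeConfig())
        curve = cv.mean_accuracy().to_numpy()
        peak = int(np.argmax(curve))
        tol = 0.005
        assert np.all(np.diff(curve[: peak + 1]) > -tol)
        assert np.all(np.diff(curve[peak:]) < tol)

    def test_peak_latency_recovered_at_0db(self, cv_world):
        """TRF peak latency within one sample of truth at SNR 0 dB."""
        rng = np.random.default_rng(2)
        sd = np.sqrt(np.mean([np.mean(y**2) for y in cv_world["Y"]]))
        Y = [y + sd * rng.standard_normal(y.shape) for y in cv_world["Y"]]
        cv = loto_cv(cv_world["X"], Y, cv_world["ls"], RidgeConfig())
        lam = float(cv.mean_accuracy().idxmax())
        model = cv.model(lam)
        truth_peak = cv_world["truth"].trf.peak_latency_ms()
        assert abs(model.peak_latency_ms() - truth_peak) <= 12.5


class TestSelectLambda:
    def _table(self, picks):
        rows = []
        grid = [2.0**e for e in (3, 4, 5)]
        for i, peak in enumerate(picks):
            for lam in grid:
                rows.append(
                    {
                        "participant": i,
                        "condition": "c",
                        "lambda": lam,
                        "accuracy": 1.0 - abs(np.log2(lam) - peak),
                    }
                )
        return pd.DataFrame(rows)

    def test_unanimous_peak(self):
        assert select_lambda(self._table([4, 4, 4])) == 2.0**4

    def test_mode_of_argmax(self):
        assert select_lambda(self._table([3, 3, 3, 3, 5, 5])) == 2.0**3

    def test_tie_breaks_toward_smaller(self):
        assert select_lambda(self._table([3, 3, 5, 5])) == 2.0**3

    def test_pooled_peak_method(self):
        assert select_lambda(self._table([3, 5, 5]), method="pooled_peak") == 2.0**5

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            select_lambda(pd.DataFrame(columns=["participant", "condition", "lambda", "accuracy"]))


class TestDecodeSetup:
    def test_variance_ordering_and_rank(self):
        rng = np.random.default_rng(6)
        base = rng.standard_normal((400, 10)) @ rng.standard_normal((10, 30))
        trials = [base[i * 40 : (i + 1) * 40] for i in range(10)]
        red, pca = decode_setup(trials, n_components=20)
        assert np.all(np.diff(pca.explained_variance) <= 1e-10)
        assert pca.explained_variance[10:].sum() < 1e-20 * pca.explained_variance[0]

    def test_reconstruction_error_bounded_by_discarded_variance(self):
        rng = np.random.default_rng(7)
        trials = [rng.standard_normal((50, 12)) for _ in range(4)]
        red, pca = decode_setup(trials, n_components=5)
        stacked = np.vstack(trials)
        recon = pca.inverse_transform(pca.transform(stacked))
        err = ((stacked - recon) ** 2).sum()
        discarded = (stacked.shape[0] - 1) * (
            np.var(stacked - stacked.mean(0), axis=0).sum() * 0 + 0
        )
        # total variance minus retained variance, scaled back to SS
        total_ss = ((stacked - stacked.mean(0)) ** 2).sum()
        retained_ss = (stacked.shape[0] - 1) * pca.explained_variance.sum()
        assert err == pytest.approx(total_ss - retained_ss, rel=1e-8)

    def test_fewer_sensors_than_components_reduces_with_warning(self):
        rng = np.random.default_rng(8)
        trials = [rng.standard_normal((30, 6)) for _ in range(3)]
        with pytest.warns(UserWarning, match="components"):
            red, pca = decode_setup(trials, n_components=50)
        assert red[0].shape[1] == 6


class TestSingleLagDecode:
    def test_lag_count_and_latency_recovery(self):
        """25 single-lag models over [-50, 250] ms; with a ground truth
        concentrated at 50 ms the accuracy curve peaks there."""
        design = make_design(2, seed=SEED)
        ls = LagSpec()
        feats = {
            w: prepare(
                envelope_feature(synth_word_audio(w, seed=SEED)),
                ls.fit_min_ms,
                ls.fit_max_ms,
            )
            for w in design["word_id"]
        }
        truth = make_ground_truth(
            1, 10, ls, peak_ms=(50.0,), peak_width_ms=10.0, noise_sd=0.0, seed=SEED
        )
        neural = synth_neural(feats, truth, design, 10)
        red, _ = decode_setup(list(neural.trials), 50)
        Y = [feats[w].values for w in design["word_id"]]
        tab = single_lag_decode(red, Y, ridge_config=RidgeConfig())
        curve = tab.groupby("lag_ms")["r"].mean()
        assert curve.size == 25
        assert curve.idxmax() == pytest.approx(50.0)

    def test_white_noise_neural_gives_flat_near_zero_curve(self):
        rng = np.random.default_rng(9)
        design = make_design(1, seed=SEED)
        ls = LagSpec()
        feats = {
            w: prepare(
                envelope_feature(synth_word_audio(w, seed=SEED)),
                ls.fit_min_ms,
                ls.fit_max_ms,
            )
            for w in design["word_id"]
        }
        Y = [feats[w].values for w in design["word_id"]]
        X = [rng.standard_normal((y.shape[0], 10)) for y in Y]
        tab = single_lag_decode(X, Y, ridge_config=RidgeConfig(lambda_grid=(100.0,)))
        curve = tab.groupby("lag_ms")["r"].mean()
        assert np.max(np.abs(curve)) < 0.35  # 6 trials only; loose null band
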