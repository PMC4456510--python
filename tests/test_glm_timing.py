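"""History-filter logistic GLM: design building, sparse recovery,
deviance reduction, bootstrap, stepwise selection."""

import numpy as np
import pytest

from virduet import (build_history_design, filter_peak_lag,
                     fit_sparse_logistic, relative_deviance_reduction,
                     stepwise_two_variable)
from virduet.glm_timing import (FrameSeries, HistoryFilter,
                                SparseHistoryLogistic, bootstrap_filters,
                                _deviance)


def series(tracks, fps=60.0):
    return FrameSeries({k: np.asarray(v, dtype=np.int8) for k, v in tracks.items()},
                       fps=fps)


class TestBuildHistoryDesign:
    def test_shape_is_rows_by_lags(self):
        fs = series({"b": np.zeros(100), "target_song": np.zeros(100)})
        X, y = build_history_design(fs, ["b"])
        assert X.shape == (36, 64)
        assert y.shape == (36,)

    def test_all_zero_behavior_gives_all_zero_columns(self):
        fs = series({"b": np.zeros(100), "target_song": np.ones(100)})
        X, _ = build_history_design(fs, ["b"])
        assert not np.any(X)

    def test_impulse_fills_the_matching_anti_diagonal(self):
        n = 80
        b = np.zeros(n)
        k = 70
        b[k] = 1
        fs = series({"b": b, "target_song": np.zeros(n)})
        X, _ = build_history_design(fs, ["b"])
        rows, lags = np.nonzero(X)
        # row t (absolute frame 64 + t) sees the impulse at lag (64+t) - k
        for r, lag in zip(rows, lags):
            assert (64 + r) - (lag + 1) == k
        # one hit per row whose 64-lag window reaches back to frame k
        expected_rows = len(range(max(0, k + 1 - 64), n - 64))
        assert rows.size == expected_rows

    def test_unknown_behavior_rejected(self):
        fs = series({"b": np.zeros(100), "target_song": np.zeros(100)})
        with pytest.raises(ValueError, match="unknown"):
            build_history_design(fs, ["nope"])

    def test_short_series_rejected(self):
        fs = series({"b": np.zeros(50), "target_song": np.zeros(50)})
        with pytest.raises(ValueError, match="shorter"):
            build_history_design(fs, ["b"])


def single_lag_data(seed, n=20_000, lag=12, beta=4.0, bias=-3.0):
    rng = np.random.default_rng(seed)
    b = (rng.random(n) < 0.2).astype(np.int8)
    eta = bias + beta * np.roll(b, lag)
    eta[:lag] = bias
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(np.int8)
    fs = series({"b": b, "target_song": y})
    return build_history_design(fs, ["b"])


class TestSparseFit:
    def test_recovers_single_informative_lag(self):
        X, y = single_lag_data(0)
        est = fit_sparse_logistic(X, y, seed=0)
        w = est.coef_[0]
        assert np.argmax(w) + 1 == 12
        off = np.delete(np.abs(w), 11)
        assert np.median(off) < 0.1 * w[11]

    def test_infinite_penalty_zeroes_all_weights(self):
        X, y = single_lag_data(1)
        est = fit_sparse_logistic(X, y, penalty_weight=1e6, seed=0)
        assert not np.any(est.coef_)

    def test_tiny_penalty_matches_unpenalized_logistic(self):
        # near-orthogonal design: sparse impulses far apart
        import statsmodels.api as sm
        rng = np.random.default_rng(2)
        n = 4000
        b = np.zeros(n, dtype=np.int8)
        b[np.arange(100, n - 100, 130)] = 1
        eta = -2.5 + 3.0 * np.roll(b, 5)
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(np.int8)
        fs = series({"b": b, "target_song": y})
        X, yy = build_history_design(fs, ["b"])
        est = fit_sparse_logistic(X, yy, penalty_weight=1e-9, seed=0)
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            ref = sm.Logit(yy, sm.add_constant(X)).fit(disp=0, maxiter=200)
        # quasi-separated lags diverge in both fits; compare the
        # well-identified coefficients and the fitted probabilities
        ident = np.abs(ref.params[1:]) < 5
        assert np.allclose(est.coef_[0][ident], ref.params[1:][ident], atol=1e-3)
        assert np.allclose(est.predict_proba(X)[:, 1], ref.predict(), atol=1e-4)

    def test_constant_response_rejected(self):
        X = np.zeros((100, 64))
        with pytest.raises(ValueError, match="constant"):
            fit_sparse_logistic(X, np.zeros(100))

    def test_all_zero_design_gives_bias_only_model(self):
        rng = np.random.default_rng(3)
        y = (rng.random(500) < 0.3).astype(float)
        with pytest.warns(UserWarning, match="bias-only"):
            est = fit_sparse_logistic(np.zeros((500, 64)), y)
        assert not np.any(est.coef_)
        p = est.predict_proba(np.zeros((1, 64)))[0, 1]
        assert p == pytest.approx(y.mean(), abs=1e-9)

    def test_prediction_invariant_to_behavior_order(self):
        rng = np.random.default_rng(4)
        a = (rng.random(2000) < 0.2).astype(np.int8)
        b = (rng.random(2000) < 0.2).astype(np.int8)
        y = ((np.roll(a, 3) + np.roll(b, 7)) > 0).astype(np.int8)
        fs = series({"a": a, "b": b, "target_song": y})
        X1, yy = build_history_design(fs, ["a", "b"])
        X2, _ = build_history_design(fs, ["b", "a"])
        e1 = fit_sparse_logistic(X1, yy, penalty_weight=1e-4, seed=0)
        e2 = fit_sparse_logistic(X2, yy, penalty_weight=1e-4, seed=0)
        p1 = e1.predict_proba(X1)[:, 1]
        p2 = e2.predict_proba(X2)[:, 1]
        # L1 solutions on correlated designs are only near-unique, so the
        # invariance holds to solver tolerance, not exactly
        assert np.allclose(p1, p2, atol=1e-3)


class TestDevianceReduction:
    def test_perfectly_predictable_target_approaches_one(self):
        b = np.tile(np.r_[np.ones(30), np.zeros(30)], 40).astype(np.int8)
        y = np.roll(b, 10)
        fs = series({"b": b, "target_song": y})
        X, yy = build_history_design(fs, ["b"])
        perf = relative_deviance_reduction(X, yy, n_splits=3, seed=0)
        assert perf.relative_deviance_reduction > 0.9

    def test_independent_behavior_reduces_nothing(self):
        rng = np.random.default_rng(5)
        n = 50_000
        b = (rng.random(n) < 0.2).astype(np.int8)
        y = (rng.random(n) < 0.3).astype(np.int8)
        fs = series({"b": b, "target_song": y})
        X, yy = build_history_design(fs, ["b"])
        perf = relative_deviance_reduction(X, yy, penalty_weight=1e-3,
                                           n_splits=3, seed=0)
        assert abs(perf.relative_deviance_reduction) < 0.02

    def test_bias_only_on_itself_is_zero(self):
        rng = np.random.default_rng(6)
        y = (rng.random(1000) < 0.4).astype(float)
        p0 = y.mean()
        dev = _deviance(y, np.full(y.size, p0))
        assert 1.0 - dev / dev == 0.0


class TestFilterPeakLag:
    def test_lag_to_ms_conversion(self):
        w = np.zeros(64)
        w[0] = 1.0
        f = HistoryFilter(w, 0.0, "b", fps=60.0)
        assert filter_peak_lag(f)["peak_lag_ms"] == pytest.approx(1000.0 / 60.0)

    def test_lag_12_is_200ms(self):
        w = np.zeros(64)
        w[11] = 2.0
        f = HistoryFilter(w, 0.0, "b", fps=60.0)
        assert filter_peak_lag(f)["peak_lag_ms"] == pytest.approx(200.0)

    def test_tie_breaks_to_smaller_lag_and_flags(self):
        w = np.zeros(64)
        w[[4, 9]] = 1.5
        res = filter_peak_lag(HistoryFilter(w, 0.0, "b", fps=60.0))
        assert res["peak_lag_ms"] == pytest.approx(5 * 1000.0 / 60.0)
        assert res["tie"]

    def test_all_zero_filter_has_no_peak(self):
        res = filter_peak_lag(HistoryFilter(np.zeros(64), 0.0, "b"))
        assert res["peak_lag_ms"] is None


class TestBootstrapFilters:
    def tracks(self, seed=0, n=6000):
        rng = np.random.default_rng(seed)
        b = (rng.random(n) < 0.2).astype(np.int8)
        eta = -2.5 + 3.5 * np.roll(b, 12)
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(np.int8)
        return series({"b": b, "target_song": y})

    def test_fixed_seed_reproducible(self):
        fs = self.tracks()
        a = bootstrap_filters(fs, ["b"], n_boot=5, seed=3, penalty_weight=1e-4)
        b = bootstrap_filters(fs, ["b"], n_boot=5, seed=3, penalty_weight=1e-4)
        assert np.array_equal(a["filter_sem"], b["filter_sem"])

    def test_sem_shrinks_with_more_data(self):
        sems = []
        for n in (4000, 8000, 16_000):
            fs = self.tracks(seed=1, n=n)
            bs = bootstrap_filters(fs, ["b"], n_boot=20, seed=0,
                                   penalty_weight=1e-4)
            sems.append(bs["filter_sem"][11])
        assert sems[2] < sems[0]

    def test_two_replicates_flagged(self):
        fs = self.tracks()
        bs = bootstrap_filters(fs, ["b"], n_boot=2, seed=0, penalty_weight=1e-4)
        assert bs["flagged"]


class TestStepwise:
    def build(self, seed=0, n=30_000):
        rng = np.random.default_rng(seed)
        a = (rng.random(n) < 0.2).astype(np.int8)
        noise = (rng.random(n) < 0.2).astype(np.int8)
        eta = -2.5 + 3.5 * np.roll(a, 5)
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(np.int8)
        return series({"a": a, "noise": noise, "target_song": y})

    def test_informative_behavior_ranks_first_and_noise_adds_little(self):
        res = stepwise_two_variable(self.build(), ["a", "noise"], n_splits=3)
        assert res["best"] == "a"
        assert res["extensions"]["noise"]["relative_gain"] < 0.05

    def test_duplicated_behavior_adds_nothing(self):
        fs = self.build(seed=1)
        fs.tracks["a2"] = fs.tracks["a"].copy()
        res = stepwise_two_variable(fs, ["a", "a2"], n_splits=3)
        assert abs(res["extensions"][[k for k in res["extensions"]][0]]["gain"]) < 0.02

    def test_two_independent_signals_beat_each_single(self):
        rng = np.random.default_rng(2)
        n = 30_000
        a = (rng.random(n) < 0.2).astype(np.int8)
        b = (rng.random(n) < 0.2).astype(np.int8)
        eta = -3.0 + 2.5 * np.roll(a, 5) + 2.5 * np.roll(b, 20)
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(np.int8)
        fs = series({"a": a, "b": b, "target_song": y})
        res = stepwise_two_variable(fs, ["a", "b"], n_splits=3)
        other = [k for k in res["extensions"]][0]
        assert res["extensions"][other]["performance"] > max(
            res["singles"].values()) + 0.02

    def test_requires_two_behaviors(self):
        with pytest.raises(ValueError, match=">= 2"):
            stepwise_two_variable(self.build(), ["a"])
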