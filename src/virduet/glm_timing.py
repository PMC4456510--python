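"""Sparse logistic history-filter GLMs for framewise song prediction.

Each model predicts the presence/absence of a target song track at frame
t from the preceding ~1 s of one or more binary behavior tracks (64 lags
at 60 fps). Behavior tracks are strongly autocorrelated and
cross-correlated, so the filters carry an L1 (sparsity) penalty that
suppresses weights that are large only through correlation; the penalty
strength is chosen by cross-validated held-out deviance over a small
grid. Performance is the relative deviance reduction over a bias-only
model on held-out data (80/20 random subsampling), and uncertainty comes
from refits on random 75% subsets drawn as contiguous 1-s frame blocks,
which respects the autocorrelation of the tracks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression

__all__ = [
    "FrameSeries",
    "HistoryFilter",
    "ModelPerformance",
    "build_history_design",
    "SparseHistoryLogistic",
    "fit_sparse_logistic",
    "relative_deviance_reduction",
    "bootstrap_filters",
    "filter_peak_lag",
    "stepwise_two_variable",
]

N_LAGS = 64
BEHAVIORS = ("tarsal_vibration", "tarsal_pause", "proboscis_lick",
             "partner_song")


@dataclass
class FrameSeries:
    """Named binary frame tracks at a common frame rate."""

    tracks: dict
    fps: float = 60.0

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.tracks.values()}
        if len(lengths) > 1:
            raise ValueError("all tracks must have equal length")
        for name, v in self.tracks.items():
            arr = np.asarray(v)
            if not np.all(np.isin(arr, (0, 1))):
                raise ValueError(f"track {name!r} must be binary")
            self.tracks[name] = arr.astype(np.int8)

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.tracks.values()))) if self.tracks else 0


@dataclass
class HistoryFilter:
    """Lag-indexed weights; lag 1 is the frame immediately preceding the
    predicted frame."""

    weights: np.ndarray
    bias: float
    behavior: str
    fps: float = 60.0
    boot_sem: np.ndarray | None = None


@dataclass
class ModelPerformance:
    relative_deviance_reduction: float
    per_split: np.ndarray
    n_splits: int
    boot_sem: float | None = None


def build_history_design(fs: FrameSeries, behaviors: list,
                         target: str = "target_song", n_lags: int = N_LAGS,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Lagged design matrix and binary response.

    Row t holds [b(t-1) ... b(t-n_lags)] for each behavior, concatenated
    in the given order; the first n_lags frames are dropped.
    """
    for name in list(behaviors) + [target]:
        if name not in fs.tracks:
            raise ValueError(f"unknown track {name!r}")
    n = fs.n_frames
    if n <= n_lags:
        raise ValueError("series shorter than the history window")
    cols = []
    for name in behaviors:
        b = fs.tracks[name]
        # column for lag k is b shifted right by k
        lagged = np.empty((n - n_lags, n_lags), dtype=np.float64)
        for k in range(1, n_lags + 1):
            lagged[:, k - 1] = b[n_lags - k:n - k]
        cols.append(lagged)
    X = np.concatenate(cols, axis=1)
    y = np.asarray(fs.tracks[target][n_lags:], dtype=np.float64)
    return X, y


def _deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -2.0 * float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _null_deviance(y_train: np.ndarray, y_test: np.ndarray) -> float:
    p0 = np.clip(y_train.mean(), 1e-12, 1 - 1e-12)
    return _deviance(y_test, np.full(y_test.size, p0))


class SparseHistoryLogistic(BaseEstimator, ClassifierMixin):
    """L1-penalized logistic regression over lagged behavior histories.

    ``penalty_weight`` is the per-sample L1 strength (sklearn's
    ``C = 1 / (n * penalty_weight)``); when None it is selected by
    cross-validated held-out deviance over ``penalty_grid``. ``penalty``
    may be set to ``'l2'`` for a ridge alternative. The intercept is
    never penalized.
    """

    def __init__(self, penalty_weight: float | None = None,
                 penalty: str = "l1",
                 penalty_grid: tuple = (3e-5, 1e-4, 3e-4, 1e-3),
                 cv_folds: int = 3, random_state: int = 0):
        self.penalty_weight = penalty_weight
        self.penalty = penalty
        self.penalty_grid = penalty_grid
        self.cv_folds = cv_folds
        self.random_state = random_state

    def _fit_one(self, X, y, w):
        if self.penalty not in ("l1", "l2"):
            raise ValueError("penalty must be 'l1' or 'l2'")
        C = 1.0 / max(X.shape[0] * w, 1e-12)
        clf = LogisticRegression(
            C=C, l1_ratio=1.0 if self.penalty == "l1" else 0.0,
            solver="liblinear", max_iter=2000, random_state=self.random_state)
        clf.fit(X, y)
        return clf

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("response is constant; nothing to fit")
        if not np.any(X):
            warnings.warn("all-zero design; returning bias-only model")
            p = y.mean()
            self.coef_ = np.zeros((1, X.shape[1]))
            self.intercept_ = np.array([np.log(p / (1 - p))])
            self.penalty_weight_ = 0.0
            self.classes_ = classes
            return self

        if self.penalty_weight is None:
            rng = np.random.default_rng(self.random_state)
            n = X.shape[0]
            order = rng.permutation(n)
            folds = np.array_split(order, self.cv_folds)
            scores = []
            for w in self.penalty_grid:
                dev = 0.0
                for k in range(self.cv_folds):
                    test = folds[k]
                    train = np.concatenate([folds[j] for j in range(self.cv_folds)
                                            if j != k])
                    if np.unique(y[train]).size < 2 or np.unique(y[test]).size < 2:
                        continue
                    clf = self._fit_one(X[train], y[train], w)
                    dev += _deviance(y[test], clf.predict_proba(X[test])[:, 1])
                scores.append(dev)
            w_best = self.penalty_grid[int(np.argmin(scores))]
        else:
            w_best = self.penalty_weight

        clf = self._fit_one(X, y, w_best)
        self.coef_ = clf.coef_
        self.intercept_ = clf.intercept_
        self.penalty_weight_ = w_best
        self.classes_ = clf.classes_
        return self

    def predict_proba(self, X):
        eta = np.asarray(X, float) @ self.coef_[0] + self.intercept_[0]
        p1 = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def filters(self, behaviors: list, fps: float = 60.0,
                n_lags: int = N_LAGS) -> dict:
        """Split the coefficient vector into per-behavior history filters."""
        out = {}
        for i, name in enumerate(behaviors):
            w = self.coef_[0][i * n_lags:(i + 1) * n_lags]
            out[name] = HistoryFilter(w.copy(), float(self.intercept_[0]),
                                      name, fps)
        return out


def fit_sparse_logistic(X: np.ndarray, y: np.ndarray,
                        penalty_weight: float | None = None,
                        seed: int = 0) -> SparseHistoryLogistic:
    est = SparseHistoryLogistic(penalty_weight=penalty_weight, random_state=seed)
    return est.fit(X, y)


def relative_deviance_reduction(X: np.ndarray, y: np.ndarray,
                                penalty_weight: float | None = None,
                                train_frac: float = 0.8, n_splits: int = 20,
                                seed: int = 0) -> ModelPerformance:
    """Cross-validated relative deviance reduction.

    Per split: fit on a random ``train_frac`` of frames, then
    1 - deviance(model) / deviance(bias-only) on the held-out remainder;
    the mean over splits is reported. Held-out folds with constant
    response are skipped and counted.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    n_train = int(round(train_frac * n))
    if n_train < 1 or n_train >= n:
        raise ValueError("split leaves an empty train or test set")
    vals = []
    skipped = 0
    w = penalty_weight
    for _ in range(n_splits):
        idx = rng.permutation(n)
        tr, te = idx[:n_train], idx[n_train:]
        if np.unique(y[tr]).size < 2 or np.unique(y[te]).size < 2:
            skipped += 1
            continue
        est = SparseHistoryLogistic(penalty_weight=w, random_state=seed)
        est.fit(X[tr], y[tr])
        if w is None:
            w = est.penalty_weight_  # select once, reuse across splits
        dev = _deviance(y[te], est.predict_proba(X[te])[:, 1])
        vals.append(1.0 - dev / _null_deviance(y[tr], y[te]))
    vals = np.asarray(vals)
    mean = float(vals.mean()) if vals.size else float("nan")
    return ModelPerformance(mean, vals, int(vals.size))


def bootstrap_filters(fs: FrameSeries, behaviors: list,
                      target: str = "target_song", n_boot: int = 1000,
                      subsample_frac: float = 0.75, seed: int = 0,
                      block_s: float = 1.0, n_lags: int = N_LAGS,
                      penalty_weight: float | None = None) -> dict:
    """Filter and performance s.e.m. from subsampled refits.

    Each replicate refits on a random ``subsample_frac`` of the data drawn
    as contiguous blocks of ``block_s`` seconds, preserving local
    autocorrelation within blocks.
    """
    X, y = build_history_design(fs, behaviors, target, n_lags)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    block = max(1, int(round(block_s * fs.fps)))
    n_blocks = int(np.ceil(n / block))
    take = max(1, int(round(subsample_frac * n_blocks)))

    if penalty_weight is None:
        sel = SparseHistoryLogistic(random_state=seed)
        sel.fit(X, y)
        penalty_weight = sel.penalty_weight_

    weights = []
    perfs = []
    failures = 0
    for _ in range(n_boot):
        blocks = rng.choice(n_blocks, take, replace=False)
        idx = np.concatenate([np.arange(b * block, min((b + 1) * block, n))
                              for b in blocks])
        try:
            if np.unique(y[idx]).size < 2:
                raise ValueError("constant response in subsample")
            est = SparseHistoryLogistic(penalty_weight=penalty_weight,
                                        random_state=seed)
            est.fit(X[idx], y[idx])
            weights.append(est.coef_[0].copy())
            perf = relative_deviance_reduction(
                X[idx], y[idx], penalty_weight=penalty_weight, n_splits=1,
                seed=seed)
            perfs.append(perf.relative_deviance_reduction)
        except Exception:
            failures += 1
    weights = np.asarray(weights)
    perfs = np.asarray(perfs)
    low_n = weights.shape[0] < 3
    sem_w = (weights.std(axis=0, ddof=1) if weights.shape[0] > 1
             else np.zeros(X.shape[1]))
    sem_p = float(perfs.std(ddof=1)) if perfs.size > 1 else 0.0
    return {"filter_sem": sem_w, "performance_sem": sem_p,
            "n_success": int(weights.shape[0]), "n_failures": failures,
            "flagged": low_n or failures > 0.1 * n_boot}


def filter_peak_lag(f: HistoryFilter, fps: float | None = None) -> dict:
    """Lag of the maximum filter weight, in ms (lag * 1000 / fps).

    Ties break toward the smaller lag and are flagged; an all-zero filter
    has no peak.
    """
    fps = fps or f.fps
    w = np.asarray(f.weights, dtype=float)
    if not np.any(w):
        return {"peak_lag_ms": None, "tie": False}
    m = w.max()
    at = np.flatnonzero(w == m)
    lag = int(at[0]) + 1
    return {"peak_lag_ms": lag * 1000.0 / fps, "tie": at.size > 1}


def stepwise_two_variable(fs: FrameSeries, behaviors: list,
                          target: str = "target_song", n_splits: int = 10,
                          seed: int = 0, n_lags: int = N_LAGS) -> dict:
    """Rank single-behavior models, then extend the best by one behavior.

    Returns per-behavior single-variable performance, and for the best
    single predictor every two-variable extension with its absolute and
    relative gain.
    """
    if len(behaviors) < 2:
        raise ValueError("need >= 2 behaviors")
    singles = {}
    for name in behaviors:
        X, y = build_history_design(fs, [name], target, n_lags)
        perf = relative_deviance_reduction(X, y, n_splits=n_splits, seed=seed)
        singles[name] = perf.relative_deviance_reduction
    best = max(singles, key=singles.get)
    pairs = {}
    for name in behaviors:
        if name == best:
            continue
        X, y = build_history_design(fs, [best, name], target, n_lags)
        perf = relative_deviance_reduction(X, y, n_splits=n_splits, seed=seed)
        gain = perf.relative_deviance_reduction - singles[best]
        pairs[name] = {
            "performance": perf.relative_deviance_reduction,
            "gain": gain,
            "relative_gain": gain / singles[best] if singles[best] > 0 else np.inf,
        }
    return {"singles": singles, "best": best, "extensions": pairs}
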