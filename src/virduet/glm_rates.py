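"""Poisson GLM linking sensory channels or mating state to song rates.

The design codes the presence/absence of each channel as +1/-1 per
courtship pair. Rates are bounded below by zero, so the model uses a
Poisson family with log link (mean = exp(eta)); when song counts and
courtship durations are available the count is the response with
log-duration as an exposure offset, which respects the Poisson assumption
exactly. Predictor columns are standardized before fitting so the
coefficients are comparable across channels; responses are left on their
natural scale (z-scoring a Poisson response would break its support).
Coefficient uncertainty comes from both the analytic Wald standard errors
and a pairs (case-resampling) bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

__all__ = ["RateDesign", "PoissonRateGLM", "fit_rate_glm", "bootstrap_coefficients"]


@dataclass
class RateDesign:
    """Pairs x predictors design with +/-1 coding and per-pair responses.

    ``response`` is either a rate (Hz) or, when ``exposure_s`` is given,
    a count with the courtship duration as exposure.
    """

    design: np.ndarray
    response: np.ndarray
    predictor_names: list
    exposure_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.design = np.asarray(self.design, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.design.ndim != 2:
            raise ValueError("design must be 2-D (pairs x predictors)")
        if self.design.shape[0] != self.response.size:
            raise ValueError("one response per design row required")
        if not np.all(np.isin(self.design, (-1.0, 1.0))):
            raise ValueError("design entries must be exactly +/-1")
        if np.any(self.response < 0):
            raise ValueError("responses (rates or counts) must be >= 0")
        if len(self.predictor_names) != self.design.shape[1]:
            raise ValueError("one name per predictor column required")
        if self.exposure_s is not None:
            self.exposure_s = np.asarray(self.exposure_s, dtype=float)
            if np.any(self.exposure_s <= 0):
                raise ValueError("exposures must be > 0")


class PoissonRateGLM(BaseEstimator):
    """Sklearn-style Poisson GLM with +/-1 channel designs.

    Parameters
    ----------
    standardize : bool
        Z-score predictor columns before fitting (the response is never
        transformed).
    use_exposure : bool
        When the design carries exposures, fit counts with a log-exposure
        offset; otherwise fit the rate response directly.
    """

    def __init__(self, standardize: bool = True, use_exposure: bool = True):
        self.standardize = standardize
        self.use_exposure = use_exposure

    def fit(self, X, y, exposure=None, feature_names=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be 2-D with one response per row")
        if np.unique(X, axis=0).shape[0] < 2:
            raise ValueError("need >= 2 distinct design rows")
        names = list(feature_names) if feature_names is not None else [
            f"x{j}" for j in range(X.shape[1])]

        keep = []
        for j in range(X.shape[1]):
            if np.ptp(X[:, j]) == 0:
                warnings.warn(f"constant predictor column {names[j]!r} dropped")
            else:
                keep.append(j)
        X = X[:, keep]
        self.feature_names_ = [names[j] for j in keep]

        if self.standardize:
            self.center_ = X.mean(axis=0)
            self.scale_ = X.std(axis=0)
            Xs = (X - self.center_) / self.scale_
        else:
            self.center_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
            Xs = X

        exog = sm.add_constant(Xs, has_constant="add")
        kw = {}
        if self.use_exposure and exposure is not None:
            kw["exposure"] = np.asarray(exposure, dtype=float)
        model = sm.GLM(y, exog, family=sm.families.Poisson(), **kw)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit()
        if not res.converged:
            warnings.warn("IRLS did not converge; coefficients may be unstable")
        self.converged_ = bool(res.converged)
        self.intercept_ = float(res.params[0])
        self.coef_ = np.asarray(res.params[1:])
        self.bse_ = np.asarray(res.bse[1:])
        self.pvalues_ = np.asarray(res.pvalues[1:])
        self.result_ = res
        return self

    def predict(self, X, exposure=None):
        X = (np.asarray(X, dtype=float) - self.center_) / self.scale_
        eta = self.intercept_ + X @ self.coef_
        mu = np.exp(eta)
        if self.use_exposure and exposure is not None:
            mu = mu * np.asarray(exposure, dtype=float)
        return mu

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "name": self.feature_names_,
            "beta": self.coef_,
            "se": self.bse_,
            "p": self.pvalues_,
        })


def fit_rate_glm(d: RateDesign, standardize: bool = True) -> PoissonRateGLM:
    """Fit the channel/rate Poisson GLM and return the fitted estimator."""
    est = PoissonRateGLM(standardize=standardize,
                         use_exposure=d.exposure_s is not None)
    return est.fit(d.design, d.response, exposure=d.exposure_s,
                   feature_names=d.predictor_names)


def bootstrap_coefficients(d: RateDesign, n_boot: int = 1000, seed: int = 0,
                           standardize: bool = True) -> dict:
    """Pairs bootstrap of the GLM coefficients.

    Resamples courtship pairs with replacement, refits, and reports the
    standard deviation of each coefficient across successful refits.
    Failed refits are skipped and counted; more than 10% failures sets a
    flag.
    """
    rng = np.random.default_rng(seed)
    n = d.response.size
    coefs = []
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est = PoissonRateGLM(standardize=standardize,
                                     use_exposure=d.exposure_s is not None)
                est.fit(d.design[idx], d.response[idx],
                        exposure=None if d.exposure_s is None else d.exposure_s[idx],
                        feature_names=d.predictor_names)
            if est.coef_.size != d.design.shape[1] or not np.all(
                    np.isfinite(est.coef_)):
                raise ValueError("degenerate refit")
            coefs.append(est.coef_)
        except Exception:
            failures += 1
    coefs = np.asarray(coefs)
    if coefs.shape[0] < 2:
        sem = np.zeros(d.design.shape[1])
        degenerate = True
    else:
        sem = coefs.std(axis=0, ddof=1)
        degenerate = False
    return {
        "boot_sem": sem,
        "n_success": int(coefs.shape[0]) if coefs.size else 0,
        "n_failures": failures,
        "flagged": degenerate or failures > 0.1 * n_boot,
        "samples": coefs,
    }
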