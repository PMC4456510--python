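"""Wavelet-template likelihood classification of song.

Each song class (male M, female F, overlap O, noise N) is summarized by a
template: the mean wavelet spectrum of its annotated examples, an
orthonormal basis from a principal-components rotation of those examples,
and a one-dimensional Gaussian-mixture density along each retained axis.
A spectrum's log-likelihood under a template is the sum of the per-axis
mixture log-densities of its projections; with a uniform class prior the
per-time posterior is the softmax of the four log-likelihoods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .wavelets import WaveletSpectrogram

__all__ = [
    "Template",
    "PosteriorTrack",
    "fit_template",
    "fit_noise_template",
    "classify",
    "TemplateClassifier",
]

LABELS = ("M", "F", "O", "N")


@dataclass
class Template:
    """One class's wavelet-spectral signature."""

    label: str
    mean_spectrum: np.ndarray          # (n_freqs,)
    basis: np.ndarray                  # (n_freqs, n_axes), orthonormal columns
    mix_weights: np.ndarray            # (n_axes, n_components), rows sum to 1
    mix_means: np.ndarray              # (n_axes, n_components)
    mix_vars: np.ndarray               # (n_axes, n_components), > 0

    def project(self, spectra: np.ndarray) -> np.ndarray:
        return (np.asarray(spectra, dtype=np.float64) - self.mean_spectrum) @ self.basis

    def _quad_coeffs(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-(axis, component) quadratic expansion of the log density:
        log N(x; mu, v) + log w = a x^2 + b x + c."""
        a = -0.5 / self.mix_vars
        b = self.mix_means / self.mix_vars
        c = (np.log(self.mix_weights)
             - 0.5 * np.log(2.0 * np.pi * self.mix_vars)
             - 0.5 * self.mix_means ** 2 / self.mix_vars)
        return a, b, c

    def log_likelihood(self, spectra: np.ndarray) -> np.ndarray:
        """Sum over axes of the log mixture density of each projection."""
        proj = self.project(spectra)  # (n, n_axes)
        a, b, c = self._quad_coeffs()
        comp = proj[:, :, None] ** 2 * a + proj[:, :, None] * b + c
        m = comp.max(axis=2)
        with np.errstate(under="ignore"):
            ll_axis = m + np.log(np.exp(comp - m[:, :, None]).sum(axis=2))
        return ll_axis.sum(axis=1)

    def check(self) -> None:
        gram = self.basis.T @ self.basis
        if not np.allclose(gram, np.eye(self.basis.shape[1]), atol=1e-8):
            raise ValueError("template basis is not orthonormal")
        if not np.allclose(self.mix_weights.sum(axis=1), 1.0):
            raise ValueError("mixture weights must sum to 1 per axis")
        if np.any(self.mix_vars <= 0):
            raise ValueError("mixture variances must be positive")


@dataclass
class PosteriorTrack:
    """Per-time class posteriors, columns ordered (M, F, O, N)."""

    probs: np.ndarray  # (n_times, 4), rows sum to 1
    rate: float
    labels: tuple = LABELS


def fit_template(spectra: np.ndarray, label: str, pca_dims: int = 8,
                 gmm_components: int = 3, seed: int = 0,
                 var_floor: float = 1e-10) -> Template:
    """Fit a class template from annotated wavelet spectra.

    The spectra are mean-centered and rotated by PCA; the first ``pca_dims``
    axes are kept and each axis's projection distribution is fit with an
    EM Gaussian mixture. Deterministic given the seed.
    """
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}")
    spectra = np.asarray(spectra, dtype=np.float64)
    if spectra.ndim != 2:
        raise ValueError("spectra must be 2-D (examples x frequencies)")
    n = spectra.shape[0]
    if n < 10 * gmm_components:
        raise ValueError(
            f"need >= {10 * gmm_components} annotated spectra, got {n}")
    max_dims = min(spectra.shape)
    if pca_dims > max_dims:
        warnings.warn(f"pca_dims reduced from {pca_dims} to {max_dims}")
        pca_dims = max_dims

    pca = PCA(n_components=pca_dims, svd_solver="full", random_state=seed)
    proj = pca.fit_transform(spectra)
    basis = pca.components_.T.copy()
    # sign convention: largest-magnitude loading positive, for determinism
    for j in range(basis.shape[1]):
        k = np.argmax(np.abs(basis[:, j]))
        if basis[k, j] < 0:
            basis[:, j] *= -1
            proj[:, j] *= -1

    weights = np.empty((pca_dims, gmm_components))
    means = np.empty((pca_dims, gmm_components))
    variances = np.empty((pca_dims, gmm_components))
    floored = False
    for j in range(pca_dims):
        gm = GaussianMixture(n_components=gmm_components, covariance_type="diag",
                             reg_covar=max(var_floor, 1e-10),
                             random_state=seed, n_init=1, max_iter=200)
        gm.fit(proj[:, j:j + 1])
        weights[j] = gm.weights_
        means[j] = gm.means_[:, 0]
        v = gm.covariances_[:, 0]
        if np.any(v <= var_floor):
            floored = True
        variances[j] = np.maximum(v, var_floor)
    if floored:
        warnings.warn(f"degenerate mixture variance floored at {var_floor} "
                      f"for template {label}")
    return Template(label, spectra.mean(axis=0), basis, weights, means, variances)


def fit_noise_template(spec: WaveletSpectrogram, low_amplitude_quantile: float = 0.2,
                       pca_dims: int = 8, gmm_components: int = 3, seed: int = 0,
                       max_examples: int = 20_000) -> Template:
    """Fit the noise template from a recording's own low-amplitude epochs.

    Time points whose broadband wavelet magnitude falls below the stated
    quantile of the recording are taken as noise examples, so the template
    adapts to each recording's noise conditions.
    """
    if not 0.0 < low_amplitude_quantile < 1.0:
        raise ValueError("low_amplitude_quantile must lie in (0, 1)")
    broadband = spec.magnitudes.sum(axis=1)
    cutoff = np.quantile(broadband, low_amplitude_quantile)
    idx = np.flatnonzero(broadband <= cutoff)
    if idx.size > max_examples:
        idx = idx[np.linspace(0, idx.size - 1, max_examples).astype(int)]
    return fit_template(spec.magnitudes[idx], "N", pca_dims, gmm_components, seed)


def noise_example_times(spec: WaveletSpectrogram,
                        low_amplitude_quantile: float) -> np.ndarray:
    """Times (s) of the points a noise-template fit would select."""
    broadband = spec.magnitudes.sum(axis=1)
    cutoff = np.quantile(broadband, low_amplitude_quantile)
    return np.flatnonzero(broadband <= cutoff) / spec.rate


def classify(spec: WaveletSpectrogram, templates: dict[str, Template],
             chunk: int = 200_000) -> PosteriorTrack:
    """Posterior class probabilities per time point under a uniform prior.

    The four log-likelihoods are softmaxed per time point, which realizes
    "posterior proportional to likelihood" stably in the log domain.
    """
    missing = set(LABELS) - set(templates)
    if missing:
        raise ValueError(f"missing templates for {sorted(missing)}")
    X = spec.magnitudes
    if not np.all(np.isfinite(X)):
        raise ValueError("spectrogram contains non-finite values")
    n = X.shape[0]

    # single-precision fast path; the softmax normalization is float64
    pre = []
    for lab in LABELS:
        T = templates[lab]
        a, b, c = T._quad_coeffs()
        pre.append((T.mean_spectrum.astype(np.float32),
                    T.basis.astype(np.float32), a.astype(np.float32),
                    b.astype(np.float32), c.astype(np.float32)))

    probs = np.empty((n, 4), dtype=np.float64)
    for start in range(0, n, chunk):
        block = X[start:start + chunk]
        if block.dtype != np.float32:
            block = block.astype(np.float32)
        lls = []
        for mean, basis, a, b, c in pre:
            proj = (block - mean) @ basis
            comp = proj[:, :, None] ** 2 * a + proj[:, :, None] * b + c
            m = comp.max(axis=2)
            with np.errstate(under="ignore"):
                lls.append((m + np.log(np.exp(comp - m[:, :, None]).sum(axis=2))
                            ).sum(axis=1))
        ll = np.column_stack(lls).astype(np.float64)
        ll -= ll.max(axis=1, keepdims=True)
        np.exp(ll, out=ll)
        probs[start:start + chunk] = ll / ll.sum(axis=1, keepdims=True)
    return PosteriorTrack(probs, spec.rate)


class TemplateClassifier(BaseEstimator):
    """Sklearn-style wrapper around template fitting and classification.

    ``fit(X, y)`` takes annotated wavelet spectra (rows) with class labels
    in {M, F, O, N}; ``predict_proba`` returns per-row posteriors in that
    column order and ``predict`` the argmax label.
    """

    def __init__(self, pca_dims: int = 8, gmm_components: int = 3,
                 var_floor: float = 1e-10, random_state: int = 0):
        self.pca_dims = pca_dims
        self.gmm_components = gmm_components
        self.var_floor = var_floor
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        self.templates_ = {}
        for lab in LABELS:
            rows = X[y == lab]
            if rows.shape[0] == 0:
                continue
            self.templates_[lab] = fit_template(
                rows, lab, self.pca_dims, self.gmm_components,
                seed=self.random_state, var_floor=self.var_floor)
        if not self.templates_:
            raise ValueError("no labeled examples provided")
        self.n_features_in_ = X.shape[1]
        return self

    def _check_fitted(self):
        if not hasattr(self, "templates_"):
            raise ValueError("TemplateClassifier is not fitted")
        if set(self.templates_) != set(LABELS):
            raise ValueError(
                "all four templates (M, F, O, N) are required for posteriors; "
                f"have {sorted(self.templates_)}")

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        X = np.asarray(X, dtype=np.float64)
        ll = np.column_stack(
            [self.templates_[lab].log_likelihood(X) for lab in LABELS])
        ll -= ll.max(axis=1, keepdims=True)
        np.exp(ll, out=ll)
        return ll / ll.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        p = self.predict_proba(X)
        return np.array(LABELS)[p.argmax(axis=1)]
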