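"""Continuous wavelet front-end for song segmentation.

The raw microphone trace is transformed with a frequency B-spline (fbsp)
mother wavelet at log-spaced center frequencies spanning 100-900 Hz, one
magnitude column per audio sample.

The fbsp wavelet ``psi(t) = sqrt(B) * sinc(B t / M)**M * exp(2*pi*i*C*t)``
has a compactly supported Fourier transform — a cardinal B-spline of order
M, width B, centered on C — so the transform is computed exactly in the
frequency domain: one FFT of the signal, then per scale a band-limited
multiply and inverse FFT. The order/bandwidth/center parameters trade
temporal against spectral resolution; the defaults give a time support
wide enough that the short gaps between successive pulses of a bout stay
above the noise floor, which the downstream rule cascade relies on to keep
a bout as one connected non-noise segment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy.fft import fft, ifft, next_fast_len
from scipy.interpolate import BSpline

from .simulate import AudioTrace

__all__ = ["WaveletSpectrogram", "wavelet_transform", "default_freqs",
           "fbsp_frequency_response"]

FMIN, FMAX = 100.0, 900.0
_FBSP_RE = re.compile(r"^fbsp(\d+)-([\d.]+)-([\d.]+)$")


@dataclass
class WaveletSpectrogram:
    """Time x frequency wavelet magnitudes (float32), one column per sample."""

    magnitudes: np.ndarray  # shape (n_samples, n_freqs)
    freqs_hz: np.ndarray
    rate: float


def default_freqs(n_freqs: int = 33) -> np.ndarray:
    return np.geomspace(FMIN, FMAX, n_freqs)


def _parse_fbsp(name: str) -> tuple[int, float, float]:
    m = _FBSP_RE.match(name)
    if not m:
        raise ValueError(
            f"wavelet must be of the form fbsp{{order}}-{{bandwidth}}-{{center}}, got {name!r}")
    return int(m.group(1)), float(m.group(2)), float(m.group(3))


def fbsp_frequency_response(f: np.ndarray, order: int, bandwidth: float,
                            center: float) -> np.ndarray:
    """Fourier transform of the fbsp mother wavelet at frequencies ``f``
    (in mother-wavelet units, i.e. the passband is centered on ``center``)."""
    a = bandwidth / order
    spline = BSpline.basis_element(np.arange(order + 1) - order / 2.0,
                                   extrapolate=False)
    v = spline((np.asarray(f, dtype=float) - center) / a)
    return np.sqrt(bandwidth) / a * np.nan_to_num(v)


def wavelet_transform(trace: AudioTrace, n_freqs: int = 33,
                      wavelet: str = "fbsp2-0.5-1") -> WaveletSpectrogram:
    """Wavelet magnitude spectrogram of an audio trace.

    Parameters
    ----------
    trace : AudioTrace
        Mono signal; the sampling rate must resolve the 900 Hz band edge.
    n_freqs : int
        Number of log-spaced analysis frequencies in [100, 900] Hz.
    wavelet : str
        fbsp family name, ``fbsp{order}-{bandwidth}-{center}``.
    """
    if trace.samples.size == 0:
        raise ValueError("trace is empty")
    if n_freqs < 8:
        raise ValueError("n_freqs must be >= 8")
    if trace.rate < 2 * FMAX:
        raise ValueError(
            f"sampling rate {trace.rate} Hz cannot resolve the {FMAX} Hz band edge")
    if not np.all(np.isfinite(trace.samples)):
        raise ValueError("trace contains non-finite samples")
    order, bandwidth, center = _parse_fbsp(wavelet)
    freqs = default_freqs(n_freqs)

    n = trace.samples.size
    # padding > wavelet time support at the lowest frequency avoids wrap-around
    pad = int(10 * order / bandwidth * center * trace.rate / FMIN)
    nfft = next_fast_len(n + pad, real=False)
    X = fft(trace.samples, nfft)
    fgrid = np.fft.fftfreq(nfft, 1.0 / trace.rate)

    mags = np.empty((n, n_freqs), dtype=np.float32)
    for j, f0 in enumerate(freqs):
        scale = center * trace.rate / f0
        h = np.sqrt(scale) * fbsp_frequency_response(
            scale * fgrid / trace.rate, order, bandwidth, center)
        mags[:, j] = np.abs(ifft(X * h)[:n]).astype(np.float32)
    return WaveletSpectrogram(mags, freqs, trace.rate)
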