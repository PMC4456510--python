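"""Rule-based song segmentation on top of template posteriors.

The cascade: time points with noise posterior above 1/2 are zeroed out;
each remaining connected segment is assigned to male song if its mean
male+overlap posterior exceeds its mean female posterior and it is at
least 100 ms long; remaining segments at least 15 ms long become female
song; finally, runs inside a male segment where the pointwise female+
overlap posterior exceeds 0.8 for at least 15 ms are marked as embedded
female pulses. Pulse events are then localized on the smoothed amplitude
envelope within each segment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert, find_peaks
from scipy.ndimage import uniform_filter1d
from sklearn.base import BaseEstimator

from .simulate import AudioTrace, GroundTruth
from .wavelets import wavelet_transform, WaveletSpectrogram
from .templates import (PosteriorTrack, Template, TemplateClassifier,
                        fit_noise_template, classify)

__all__ = [
    "SegmenterConfig",
    "LabeledSegment",
    "PulseEvent",
    "label_segments",
    "extract_pulse_events",
    "score_segmentation",
    "training_set_from_truth",
    "WaveletSongSegmenter",
]


@dataclass
class SegmenterConfig:
    noise_posterior_cutoff: float = 0.5
    male_min_ms: float = 100.0
    female_min_ms: float = 15.0
    embedded_female_cutoff: float = 0.8
    embedded_min_ms: float = 15.0
    n_freqs: int = 33
    wavelet: str = "fbsp2-0.5-1"
    pca_dims: int = 8
    gmm_components: int = 3
    noise_quantile: float = 0.5
    posterior_smooth_ms: float = 5.0
    envelope_smooth_ms: float = 2.0
    peak_threshold_k: float = 3.0
    peak_threshold_floor: float = 0.0
    male_min_peak_sep_ms: float = 10.0
    female_min_peak_sep_ms: float = 15.0

    def validate(self) -> None:
        for name in ("noise_posterior_cutoff", "embedded_female_cutoff"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        for name in ("male_min_ms", "female_min_ms", "embedded_min_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class LabeledSegment:
    onset: float
    offset: float
    label: str  # 'M' or 'F'
    embedded_female: list = field(default_factory=list)  # [(onset, offset)]


@dataclass
class PulseEvent:
    center: float
    sex: str
    peak_amplitude: float = 0.0


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True."""
    if mask.size == 0:
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, mask.size]
    return list(zip(starts, stops))


def label_segments(post: PosteriorTrack,
                   cfg: SegmenterConfig | None = None) -> list[LabeledSegment]:
    """Apply the threshold cascade to a posterior track."""
    cfg = cfg or SegmenterConfig()
    cfg.validate()
    p = post.probs
    if p.size == 0:
        return []
    rate = post.rate
    if cfg.posterior_smooth_ms > 0:
        # sub-pulse-scale flicker in the per-sample posteriors would
        # fragment connected segments; smooth briefly and renormalize
        w = max(1, int(round(cfg.posterior_smooth_ms / 1000.0 * rate)))
        if w > 1 and p.shape[0] > w:
            p = uniform_filter1d(p, w, axis=0)
            p = p / p.sum(axis=1, keepdims=True)
    pM, pF, pO, pN = p[:, 0], p[:, 1], p[:, 2], p[:, 3]

    segments: list[LabeledSegment] = []
    non_noise = pN <= cfg.noise_posterior_cutoff
    for i0, i1 in _runs(non_noise):
        dur_ms = (i1 - i0) / rate * 1000.0
        mean_MO = pM[i0:i1].mean() + pO[i0:i1].mean()
        mean_F = pF[i0:i1].mean()
        if mean_MO > mean_F and dur_ms >= cfg.male_min_ms:
            seg = LabeledSegment(i0 / rate, i1 / rate, "M")
            emb = (pF[i0:i1] + pO[i0:i1]) > cfg.embedded_female_cutoff
            for j0, j1 in _runs(emb):
                if (j1 - j0) / rate * 1000.0 >= cfg.embedded_min_ms:
                    seg.embedded_female.append(((i0 + j0) / rate, (i0 + j1) / rate))
            segments.append(seg)
        elif dur_ms >= cfg.female_min_ms:
            segments.append(LabeledSegment(i0 / rate, i1 / rate, "F"))
    return segments


def _envelope(trace: AudioTrace, smooth_ms: float) -> np.ndarray:
    env = np.abs(hilbert(trace.samples))
    w = max(1, int(round(smooth_ms / 1000.0 * trace.rate)))
    if w > 1:
        env = np.convolve(env, np.ones(w) / w, mode="same")
    return env


def extract_pulse_events(trace: AudioTrace, segments: list[LabeledSegment],
                         cfg: SegmenterConfig | None = None) -> list[PulseEvent]:
    """Localize pulses inside labeled segments.

    Pulses are local maxima of the smoothed analytic-signal envelope above
    an adaptive threshold (a multiple of the segment's median envelope),
    with a sex-specific minimum peak separation. Embedded female intervals
    inside male segments each yield one female pulse at their envelope
    maximum.
    """
    cfg = cfg or SegmenterConfig()
    if not segments:
        return []
    env = _envelope(trace, cfg.envelope_smooth_ms)
    rate = trace.rate
    events: list[PulseEvent] = []
    for seg in segments:
        i0, i1 = int(round(seg.onset * rate)), int(round(seg.offset * rate))
        e = env[i0:i1]
        if e.size == 0:
            continue
        thresh = max(cfg.peak_threshold_k * float(np.median(e)),
                     cfg.peak_threshold_floor)
        sep_ms = (cfg.male_min_peak_sep_ms if seg.label == "M"
                  else cfg.female_min_peak_sep_ms)
        dist = max(1, int(round(sep_ms / 1000.0 * rate)))
        peaks, props = find_peaks(e, height=thresh, distance=dist)
        emb = seg.embedded_female if seg.label == "M" else []
        for pk, h in zip(peaks, props["peak_heights"]):
            t = (i0 + pk) / rate
            if any(a <= t < b for a, b in emb):
                continue  # claimed by an embedded female pulse
            events.append(PulseEvent(t, seg.label, float(h)))
        for a, b in emb:
            j0, j1 = int(round(a * rate)), int(round(b * rate))
            if j1 > j0:
                k = j0 + int(np.argmax(env[j0:j1]))
                events.append(PulseEvent(k / rate, "F", float(env[k])))
    events.sort(key=lambda ev: ev.center)
    return events


def score_segmentation(predicted: np.ndarray, truth: np.ndarray,
                       match_tol_ms: float = 10.0) -> dict:
    """Event-level sensitivity, positive predictive value and their
    harmonic mean, from greedy one-to-one matching within a tolerance."""
    if match_tol_ms < 0:
        raise ValueError("match tolerance must be >= 0")
    predicted = np.sort(np.asarray(predicted, dtype=float))
    truth = np.sort(np.asarray(truth, dtype=float))
    tol = match_tol_ms / 1000.0

    pairs = []
    j0 = 0
    for i, p in enumerate(predicted):
        j0 = np.searchsorted(truth, p - tol)
        j = j0
        while j < truth.size and truth[j] <= p + tol:
            pairs.append((abs(p - truth[j]), i, j))
            j += 1
    pairs.sort()
    used_p: set[int] = set()
    used_t: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        tp += 1
    fp = predicted.size - tp
    fn = truth.size - tp
    degenerate = predicted.size == 0 or truth.size == 0
    sens = tp / (tp + fn) if (tp + fn) else 0.0
    ppv = tp / (tp + fp) if (tp + fp) else 0.0
    f = 2 * sens * ppv / (sens + ppv) if (sens + ppv) else 0.0
    return {"sensitivity": sens, "ppv": ppv, "f": f,
            "tp": tp, "fp": fp, "fn": fn, "degenerate": degenerate}


def training_set_from_truth(trace: AudioTrace, truth: GroundTruth,
                            spec: WaveletSpectrogram | None = None,
                            n_freqs: int = 33, wavelet: str = "fbsp2-0.5-1",
                            jitter_ms: float = 8.0, draws_per_pulse: int = 3,
                            overlap_boost: int = 5,
                            seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Build labeled wavelet spectra from a recording with known events.

    Spectra are sampled at each pulse center plus uniform offsets up to
    ``jitter_ms``, so the class densities cover the magnitude range seen
    across a pulse, not just its peak. Female pulses that fall inside a
    male bout are labeled overlap (O); overlap pulses are rare, so they
    get ``overlap_boost`` times as many offset draws.
    """
    if spec is None:
        spec = wavelet_transform(trace, n_freqs, wavelet)
    rng = np.random.default_rng(seed)
    male_bouts = truth.bouts("M")

    rows, labels = [], []
    for t, sex in truth.pulse_events:
        label = sex
        if sex == "F" and any(a - 1e-9 <= t <= b + 1e-9 for a, b in male_bouts):
            label = "O"
        draws = draws_per_pulse * (overlap_boost if label == "O" else 1)
        offsets = np.r_[0.0, rng.uniform(-jitter_ms, jitter_ms, draws - 1)]
        for off in offsets:
            i = int(round((t + off / 1000.0) * spec.rate))
            if 0 <= i < spec.magnitudes.shape[0]:
                rows.append(spec.magnitudes[i])
                labels.append(label)
    return np.asarray(rows, dtype=np.float64), np.asarray(labels)


class WaveletSongSegmenter(BaseEstimator):
    """End-to-end segmenter: wavelet transform, template posteriors, rule
    cascade, pulse extraction.

    ``fit`` consumes annotated recordings (audio plus event tables) and
    trains the male/female/overlap templates; the noise template is refit
    from each recording's own low-amplitude epochs at predict time, so the
    classifier adapts to per-recording noise conditions.
    """

    def __init__(self, config: SegmenterConfig | None = None,
                 random_state: int = 0):
        self.config = config
        self.random_state = random_state

    @property
    def cfg_(self) -> SegmenterConfig:
        return self.config or SegmenterConfig()

    def fit(self, annotated: list, y=None):
        """``annotated``: list of (AudioTrace, GroundTruth) pairs."""
        cfg = self.cfg_
        X_all, y_all = [], []
        for trace, truth in annotated:
            X, labs = training_set_from_truth(
                trace, truth, n_freqs=cfg.n_freqs, wavelet=cfg.wavelet,
                seed=self.random_state)
            X_all.append(X)
            y_all.append(labs)
        X = np.concatenate(X_all)
        labs = np.concatenate(y_all)
        self.classifier_ = TemplateClassifier(
            cfg.pca_dims, cfg.gmm_components, random_state=self.random_state)
        # overlap examples may be absent at low overlap rates
        present = set(np.unique(labs))
        if "O" not in present:
            raise ValueError("training data holds no overlap (O) examples; "
                             "simulate with a higher overlap_probability")
        self.classifier_.fit(X, labs)
        return self

    def posterior(self, trace: AudioTrace) -> PosteriorTrack:
        if not hasattr(self, "classifier_"):
            raise ValueError("segmenter is not fitted")
        cfg = self.cfg_
        spec = wavelet_transform(trace, cfg.n_freqs, cfg.wavelet)
        templates = dict(self.classifier_.templates_)
        templates["N"] = fit_noise_template(
            spec, cfg.noise_quantile, cfg.pca_dims, cfg.gmm_components,
            seed=self.random_state)
        return classify(spec, templates)

    def predict(self, trace: AudioTrace
                ) -> tuple[list[LabeledSegment], list[PulseEvent]]:
        cfg = self.cfg_
        post = self.posterior(trace)
        segments = label_segments(post, cfg)
        pulses = extract_pulse_events(trace, segments, cfg)
        return segments, pulses
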