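"""Synthetic two-singer courtship recordings.

Generates seeded duet audio with exact ground truth: alternating male pulse
bouts (short, stereotyped inter-pulse intervals) and female pulse trains
(longer, variable intervals), coupled by unimodal response latencies in both
directions. Also generates 60-fps behavior annotation tracks temporally
locked to song, and the band-limited playback stimulus used in playback
assays. All randomness flows from an explicit integer seed.

Times are seconds internally; configuration fields use milliseconds where
the field name says so. Intervals are half-open ``[onset, offset)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "DuetParams",
    "CouplingParams",
    "GroundTruth",
    "AudioTrace",
    "render_pulse",
    "simulate_duet",
    "simulate_behavior_tracks",
    "simulate_playback_stimulus",
]


@dataclass
class AudioTrace:
    """A uniformly sampled mono microphone signal."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("audio samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.rate


@dataclass
class DuetParams:
    """Generator parameters for a simulated courtship duet.

    Defaults encode wild-type song structure: male bouts of 6.9 +/- 1.2
    pulses at 21.2 +/- 1.9 ms IPI, female trains of 7.2 pulses (strongly
    overdispersed) at 55.2 +/- 26.3 ms IPI, a female answer latency whose
    distribution peaks 409 ms after male bout onset, and a male latency
    peaking 110 ms after the last female pulse. Carrier frequencies are not
    constrained by measurement; 400/250 Hz are well separated inside the
    100-900 Hz analysis band.
    """

    sample_rate: float = 10_000.0
    duration: float = 120.0

    male_ipi_mean: float = 21.2           # ms
    male_ipi_sd: float = 1.9              # ms
    male_pulses_per_bout_mean: float = 6.9
    male_pulses_per_bout_sd: float = 1.2

    female_ipi_mean: float = 55.2         # ms
    female_ipi_sd: float = 26.3           # ms
    female_pulses_per_bout_mean: float = 7.2
    female_pulses_per_bout_sd: float = 6.2

    male_carrier_hz: float = 400.0
    female_carrier_hz: float = 250.0
    male_pulse_duration_ms: float = 15.0
    female_pulse_duration_ms: float = 18.0
    male_pulse_amplitude: float = 1.0
    female_pulse_amplitude: float = 0.8

    # log-normal answer latencies, parameterized by mode and log-sd
    female_latency_mode: float = 409.0    # ms after male bout onset
    female_latency_spread: float = 0.2
    male_latency_mode: float = 110.0      # ms after last female pulse
    male_latency_spread: float = 0.35

    inter_exchange_gap_mean: float = 4.0  # s, exponential silent stretches
    gap_probability: float = 0.2          # fraction of exchanges followed by a gap
    noise_sd: float = 0.05
    overlap_probability: float = 0.01

    def validate(self) -> None:
        positive = (
            "sample_rate duration male_ipi_mean male_ipi_sd "
            "male_pulses_per_bout_mean female_ipi_mean female_ipi_sd "
            "female_pulses_per_bout_mean male_carrier_hz female_carrier_hz "
            "male_pulse_duration_ms female_pulse_duration_ms "
            "female_latency_mode female_latency_spread male_latency_mode "
            "male_latency_spread inter_exchange_gap_mean"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name, hz in (("male_carrier_hz", self.male_carrier_hz),
                         ("female_carrier_hz", self.female_carrier_hz)):
            if not (100.0 <= hz <= 900.0):
                raise ValueError(f"{name} must lie within the 100-900 Hz analysis band")
        if not 0.0 <= self.overlap_probability <= 1.0:
            raise ValueError("overlap_probability must lie in [0, 1]")
        if not 0.0 <= self.gap_probability <= 1.0:
            raise ValueError("gap_probability must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CouplingParams:
    """Temporal coupling of annotated behaviors to song.

    Both tactile behaviors occur in two kinds of episodes, mirroring the
    tactile-contact sequence of courtship: an episode that tracks each
    female pulse train (lag ``*_female_lag_ms``, near-zero: contact
    co-occurs with female song), and a bout-length episode preceding each
    male bout by the behavior's lead (``tarsal_lead_ms`` /
    ``lick_lead_ms``: vibration starts well before male song, licking
    just before it). Tarsal-pause episodes fill the gaps between
    vibration episodes. All episode boundaries get Gaussian jitter of sd
    ``jitter_sd_ms``.
    """

    tarsal_lead_ms: float = 200.0
    lick_lead_ms: float = 50.0
    lick_female_lag_ms: float = 0.0
    tarsal_female_lag_ms: float = 0.0
    jitter_sd_ms: float = 5.0

    def validate(self) -> None:
        if self.tarsal_lead_ms < 0 or self.lick_lead_ms < 0:
            raise ValueError("behavior leads must be >= 0")
        if self.jitter_sd_ms < 0:
            raise ValueError("jitter_sd_ms must be >= 0")


@dataclass
class GroundTruth:
    """Exact event record emitted by the simulator.

    ``pulse_events``: (center_s, sex) for every pulse; ``bout_intervals``:
    (onset_s, offset_s, sex) spanning first to last pulse center of each
    bout; ``behavior_intervals``: (onset_s, offset_s, behavior).
    """

    pulse_events: list = field(default_factory=list)
    bout_intervals: list = field(default_factory=list)
    behavior_intervals: list = field(default_factory=list)
    copulation_time: float | None = None

    def pulse_times(self, sex: str) -> np.ndarray:
        return np.array([t for t, s in self.pulse_events if s == sex], dtype=float)

    def bouts(self, sex: str) -> list:
        return [(a, b) for a, b, s in self.bout_intervals if s == sex]

    def ipis(self, sex: str) -> np.ndarray:
        """Within-bout inter-pulse intervals, in seconds."""
        out = []
        times = self.pulse_times(sex)
        for a, b in self.bouts(sex):
            in_bout = times[(times >= a - 1e-9) & (times <= b + 1e-9)]
            out.extend(np.diff(in_bout))
        return np.asarray(out)


def render_pulse(carrier_hz: float, duration_ms: float, amplitude: float,
                 sample_rate: float) -> np.ndarray:
    """Render one song pulse: a sinusoid under a Gaussian envelope (Gabor).

    The envelope sd is duration/6, so the rendered window holds ~3 sd each
    side of the center and the spectral peak sits at the carrier.
    """
    if not 0 < carrier_hz < sample_rate / 2:
        raise ValueError(
            f"carrier {carrier_hz} Hz must lie in (0, Nyquist={sample_rate / 2} Hz)")
    if duration_ms <= 0:
        raise ValueError("duration_ms must be > 0")
    n = int(round(duration_ms * sample_rate / 1000.0))
    t = (np.arange(n) - (n - 1) / 2) / sample_rate
    sigma = (duration_ms / 1000.0) / 6.0
    return amplitude * np.exp(-0.5 * (t / sigma) ** 2) * np.cos(2 * np.pi * carrier_hz * t)


def _lognormal_latency(rng: np.random.Generator, mode_ms: float, spread: float) -> float:
    """Draw a latency (seconds) from a log-normal with the given mode (ms)."""
    mu = np.log(mode_ms) + spread ** 2
    return float(np.exp(rng.normal(mu, spread))) / 1000.0


def _add_pulse(samples: np.ndarray, pulse: np.ndarray, center_s: float,
               rate: float) -> None:
    c = int(round(center_s * rate))
    half = pulse.size // 2
    lo, hi = c - half, c - half + pulse.size
    plo = max(0, -lo)
    phi = pulse.size - max(0, hi - samples.size)
    if phi <= plo:
        return
    samples[lo + plo:lo + phi] += pulse[plo:phi]


def simulate_duet(params: DuetParams | None = None, seed: int = 0,
                  ) -> tuple[AudioTrace, GroundTruth]:
    """Simulate one courtship duet.

    Exchanges strictly alternate: a male bout, then a female train whose
    first pulse follows the male bout onset at a log-normal latency, then
    the next male bout at a log-normal latency after the last female pulse.
    A fraction of exchanges is followed by an exponential silent gap. With
    probability ``overlap_probability`` per exchange an extra female pulse
    is placed inside the male bout. Gaussian background noise is added.
    """
    params = params or DuetParams()
    params.validate()
    rng = np.random.default_rng(seed)
    rate = params.sample_rate
    n = int(round(params.duration * rate))
    samples = np.zeros(n)

    male_pulse = render_pulse(params.male_carrier_hz, params.male_pulse_duration_ms,
                              params.male_pulse_amplitude, rate)
    female_pulse = render_pulse(params.female_carrier_hz, params.female_pulse_duration_ms,
                                params.female_pulse_amplitude, rate)

    truth = GroundTruth()
    margin = max(params.male_pulse_duration_ms, params.female_pulse_duration_ms) / 1000.0
    t = 0.3 + margin  # lead-in silence

    while True:
        # --- male bout ---
        n_pulses = max(4, int(round(rng.normal(params.male_pulses_per_bout_mean,
                                               params.male_pulses_per_bout_sd))))
        ipis = rng.normal(params.male_ipi_mean, params.male_ipi_sd, n_pulses - 1)
        ipis = np.clip(ipis, 5.0, None) / 1000.0
        m_times = t + np.concatenate([[0.0], np.cumsum(ipis)])
        bout_on, bout_off = m_times[0], m_times[-1]

        # --- female train ---
        latency = _lognormal_latency(rng, params.female_latency_mode,
                                     params.female_latency_spread)
        # strict alternation: the answering pulse never lands inside the bout
        latency = max(latency, bout_off - bout_on + margin)
        n_f = max(1, int(round(rng.normal(params.female_pulses_per_bout_mean,
                                          params.female_pulses_per_bout_sd))))
        f_ipis = rng.normal(params.female_ipi_mean, params.female_ipi_sd, n_f - 1)
        f_ipis = np.clip(f_ipis, 15.0, None) / 1000.0
        f_times = bout_on + latency + np.concatenate([[0.0], np.cumsum(f_ipis)])

        end_of_exchange = f_times[-1]
        if end_of_exchange + margin > params.duration:
            break

        for mt in m_times:
            _add_pulse(samples, male_pulse, mt, rate)
            truth.pulse_events.append((float(mt), "M"))
        truth.bout_intervals.append((float(bout_on), float(bout_off), "M"))

        # rare overlap: an extra female pulse inside the male bout
        if rng.random() < params.overlap_probability:
            ot = float(rng.uniform(bout_on, bout_off))
            _add_pulse(samples, female_pulse, ot, rate)
            truth.pulse_events.append((ot, "F"))

        for ft in f_times:
            _add_pulse(samples, female_pulse, ft, rate)
            truth.pulse_events.append((float(ft), "F"))
        truth.bout_intervals.append((float(f_times[0]), float(f_times[-1]), "F"))

        # --- next male bout onset ---
        t = end_of_exchange + _lognormal_latency(rng, params.male_latency_mode,
                                                 params.male_latency_spread)
        if rng.random() < params.gap_probability:
            t += rng.exponential(params.inter_exchange_gap_mean)

    if not truth.pulse_events:
        warnings.warn("duration too short for a single exchange; empty ground truth")
    truth.pulse_events.sort(key=lambda e: e[0])
    truth.bout_intervals.sort(key=lambda e: e[0])

    if params.noise_sd > 0:
        samples += rng.normal(0.0, params.noise_sd, n)
    return AudioTrace(samples, rate), truth


def _merge_intervals(intervals: Sequence[tuple[float, float]]
                     ) -> list[tuple[float, float]]:
    out: list[list[float]] = []
    for a, b in sorted(intervals):
        if out and a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [(a, b) for a, b in out]


def rasterize_intervals(intervals: Sequence[tuple[float, float]], duration: float,
                        fps: float = 60.0) -> np.ndarray:
    """Binary frame track: 1 where the frame center falls in an interval."""
    if fps <= 0:
        raise ValueError("fps must be > 0")
    centers = (np.arange(int(round(duration * fps))) + 0.5) / fps
    track = np.zeros(centers.size, dtype=np.int8)
    for a, b in intervals:
        track[(centers >= a) & (centers < b)] = 1
    return track


def simulate_behavior_tracks(truth: GroundTruth,
                             coupling: CouplingParams | None = None,
                             fps: float = 60.0, seed: int = 0,
                             duration: float | None = None,
                             ) -> tuple[GroundTruth, dict[str, np.ndarray]]:
    """Attach behavior episodes to a duet and rasterize them at ``fps``.

    Returns the ground truth (with ``behavior_intervals`` filled in) and a
    dict of framewise binary tracks, including ``male_song`` and
    ``female_song`` rasterized from the bout intervals.
    """
    if fps <= 0:
        raise ValueError("fps must be > 0")
    coupling = coupling or CouplingParams()
    coupling.validate()
    rng = np.random.default_rng(seed)

    male_bouts = truth.bouts("M")
    female_bouts = truth.bouts("F")
    jit = coupling.jitter_sd_ms / 1000.0

    vib: list[tuple[float, float]] = []
    lick: list[tuple[float, float]] = []
    for on, off in male_bouts:
        # bout-length episodes leading the bout by each behavior's lead
        lead = coupling.tarsal_lead_ms / 1000.0 - rng.normal(0.0, jit)
        vib.append((on - lead, off - lead))
        lead = coupling.lick_lead_ms / 1000.0 - rng.normal(0.0, jit)
        lick.append((on - lead, off - lead))
    for on, off in female_bouts:
        lag = coupling.tarsal_female_lag_ms / 1000.0 + rng.normal(0.0, jit)
        vib.append((on + lag, off + lag))
        lag = coupling.lick_female_lag_ms / 1000.0 + rng.normal(0.0, jit)
        lick.append((on + lag, off + lag))

    vib = _merge_intervals([(max(0.0, a), b) for a, b in vib if b > 0])
    lick = _merge_intervals([(max(0.0, a), b) for a, b in lick if b > 0])
    pause = [(b0, a1) for (_, b0), (a1, _) in zip(vib[:-1], vib[1:]) if a1 > b0]

    truth.behavior_intervals = (
        [(a, b, "tarsal_vibration") for a, b in vib]
        + [(a, b, "proboscis_lick") for a, b in lick]
        + [(a, b, "tarsal_pause") for a, b in pause]
    )
    truth.behavior_intervals.sort(key=lambda e: e[0])

    if duration is None:
        events = [b for _, b, _ in truth.bout_intervals] + [b for _, b in vib + lick]
        duration = (max(events) + 0.5) if events else 0.0

    # female song presence includes the final pulse's extent
    tracks = {
        "tarsal_vibration": rasterize_intervals(vib, duration, fps),
        "proboscis_lick": rasterize_intervals(lick, duration, fps),
        "tarsal_pause": rasterize_intervals(pause, duration, fps),
        "male_song": rasterize_intervals(male_bouts, duration, fps),
        "female_song": rasterize_intervals(female_bouts, duration, fps),
    }
    return truth, tracks


def simulate_playback_stimulus(bout_waveform: np.ndarray, sample_rate: float,
                               bout_interval_s: float = 1.2,
                               bouts_per_group: int = 6,
                               group_interval_s: float = 30.0,
                               total_duration_s: float = 600.0) -> AudioTrace:
    """Construct the playback stimulus: a low-pass-filtered bout repeated
    6 times at 1.2-s onsets, the group repeated every 30 s for 10 min."""
    bout_waveform = np.asarray(bout_waveform, dtype=float)
    if bout_waveform.size == 0:
        raise ValueError("bout waveform must be non-empty")
    if bout_waveform.size / sample_rate > bout_interval_s:
        raise ValueError("bout longer than the within-group interval would self-overlap")
    sos = butter(4, 300.0, btype="low", fs=sample_rate, output="sos")
    filtered = sosfiltfilt(sos, bout_waveform)

    n = int(round(total_duration_s * sample_rate))
    samples = np.zeros(n)
    g = 0.0
    while g < total_duration_s:
        for k in range(bouts_per_group):
            start = int(round((g + k * bout_interval_s) * sample_rate))
            stop = min(start + filtered.size, n)
            if start < n:
                samples[start:stop] += filtered[: stop - start]
        g += group_interval_s
    return AudioTrace(samples, sample_rate)
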