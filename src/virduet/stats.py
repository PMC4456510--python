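"""Song-structure statistics: bouts, inter-pulse intervals, rates,
overlap, pulse spectra and the pre-copulation song profile.

Conventions: a male bout is a maximal run of male pulses with successive
IPIs under 25 ms and at least four pulses; a female bout is a maximal run
with IPIs under 100 ms. Per-individual IPI medians use wider thresholds
(100 ms male, 500 ms female). Total courtship time runs from the first to
the last pulse of either sex. Rates are counts per second of courtship,
forced to 0 when a sex's cumulative song time is under 20 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import periodogram

from .simulate import AudioTrace

__all__ = [
    "Bout",
    "CourtshipRecord",
    "assemble_bouts",
    "median_ipi",
    "song_rate",
    "percent_overlap",
    "pulse_spectrum",
    "pre_copulation_profile",
    "BOUT_IPI_MAX_MS",
    "IPI_THRESHOLD_MS",
]

# maximal within-bout IPI per sex, and minimum male bout size
BOUT_IPI_MAX_MS = {"M": 25.0, "F": 100.0}
MALE_MIN_PULSES = 4
# IPI-reporting thresholds per sex
IPI_THRESHOLD_MS = {"M": 100.0, "F": 500.0}
MIN_SONG_S = 20.0


@dataclass
class Bout:
    onset: float
    offset: float
    sex: str
    pulse_centers: np.ndarray

    @property
    def n_pulses(self) -> int:
        return len(self.pulse_centers)

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    def __post_init__(self) -> None:
        self.pulse_centers = np.asarray(self.pulse_centers, dtype=float)


@dataclass
class CourtshipRecord:
    """One courtship pairing's pulses, bouts and metadata."""

    male_pulses: np.ndarray
    female_pulses: np.ndarray
    metadata: dict = field(default_factory=dict)
    copulation_time: float | None = None

    def __post_init__(self) -> None:
        self.male_pulses = np.asarray(self.male_pulses, dtype=float)
        self.female_pulses = np.asarray(self.female_pulses, dtype=float)
        self.male_bouts = assemble_bouts(self.male_pulses, "M")
        self.female_bouts = assemble_bouts(self.female_pulses, "F")

    @property
    def total_courtship_time(self) -> float:
        allp = np.concatenate([self.male_pulses, self.female_pulses])
        if allp.size == 0:
            return 0.0
        return float(allp.max() - allp.min())


def assemble_bouts(pulses: np.ndarray, sex: str) -> list[Bout]:
    """Group one sex's pulse times into bouts.

    Male: maximal runs with successive IPIs < 25 ms; runs with fewer than
    four pulses are discarded. Female: maximal runs with IPIs < 100 ms.
    Bout onset/offset are the first/last pulse centers.
    """
    if sex not in BOUT_IPI_MAX_MS:
        raise ValueError("sex must be 'M' or 'F'")
    pulses = np.asarray(pulses, dtype=float)
    if pulses.size == 0:
        return []
    if np.any(np.diff(pulses) < 0):
        raise ValueError("pulse times must be sorted")
    gap = BOUT_IPI_MAX_MS[sex] / 1000.0
    breaks = np.flatnonzero(np.diff(pulses) >= gap) + 1
    bouts = []
    for run in np.split(pulses, breaks):
        if sex == "M" and run.size < MALE_MIN_PULSES:
            continue
        if run.size == 0:
            continue
        bouts.append(Bout(float(run[0]), float(run[-1]), sex, run))
    return bouts


def median_ipi(pulses: np.ndarray, sex: str) -> float | None:
    """Per-individual median inter-pulse interval in ms.

    Successive differences under the sex threshold (100 ms male, 500 ms
    female) qualify; returns None when no interval qualifies.
    """
    pulses = np.asarray(pulses, dtype=float)
    if pulses.size < 2:
        return None
    d = np.diff(pulses) * 1000.0
    d = d[d < IPI_THRESHOLD_MS[sex]]
    if d.size == 0:
        return None
    return float(np.median(d))


def _cumulative_song_s(record: CourtshipRecord, sex: str) -> float:
    """Cumulative singing time: the spanned duration of the sex's bouts.

    A single-pulse female bout contributes one nominal pulse length (20 ms)
    so sparse female song still accumulates duration.
    """
    bouts = record.male_bouts if sex == "M" else record.female_bouts
    return sum(max(b.duration, 0.02) for b in bouts)


def song_rate(record: CourtshipRecord, sex: str, unit: str = "bout",
              sqrt_transform: bool = False) -> float:
    """Song rate in Hz: bout or pulse count over total courtship time.

    Forced to 0 when the sex's cumulative song time is under 20 s. The
    square-root transform is presentation-only; statistics use raw rates.
    """
    if unit not in ("bout", "pulse"):
        raise ValueError("unit must be 'bout' or 'pulse'")
    total = record.total_courtship_time
    if total <= 0:
        return 0.0
    if _cumulative_song_s(record, sex) < MIN_SONG_S:
        return 0.0
    if unit == "bout":
        count = len(record.male_bouts if sex == "M" else record.female_bouts)
    else:
        count = (record.male_pulses if sex == "M" else record.female_pulses).size
    rate = count / total
    return float(np.sqrt(rate)) if sqrt_transform else float(rate)


def percent_overlap(record: CourtshipRecord) -> float | None:
    """Percent of male bouts containing at least one female pulse."""
    if not record.male_bouts:
        return None
    f = record.female_pulses
    n_overlap = sum(
        bool(np.any((f >= b.onset) & (f <= b.offset))) for b in record.male_bouts)
    return 100.0 * n_overlap / len(record.male_bouts)


def pulse_spectrum(trace: AudioTrace, pulses: np.ndarray, window_ms: float = 40.0
                   ) -> tuple[np.ndarray, np.ndarray, int]:
    """Average unit-power periodogram of windows around pulse centers.

    Returns (freqs_hz, normalized PSD, n_skipped); pulses whose window
    falls outside the trace are skipped and counted.
    """
    pulses = np.asarray(pulses, dtype=float)
    if pulses.size == 0:
        return np.array([]), np.array([]), 0
    half = int(round(window_ms / 2000.0 * trace.rate))
    acc = None
    skipped = 0
    for t in pulses:
        c = int(round(t * trace.rate))
        if c - half < 0 or c + half > trace.samples.size:
            skipped += 1
            continue
        f, p = periodogram(trace.samples[c - half:c + half], fs=trace.rate)
        acc = p if acc is None else acc + p
    if acc is None:
        return np.array([]), np.array([]), skipped
    total = acc.sum()
    if total > 0:
        acc = acc / total
    return f, acc, skipped


def pre_copulation_profile(records: list[CourtshipRecord], bin_s: float = 10.0,
                           horizon_s: float = 400.0, normalize: str = "max",
                           ) -> dict:
    """Mean normalized female pulse counts in fixed bins before copulation.

    Per record, female pulses in the ``horizon_s`` before copulation are
    counted in ``bin_s`` bins and normalized (per-record max = 1 by
    default; ``normalize='sum'`` divides by the total count instead).
    Records without a copulation time are excluded and counted.
    """
    if normalize not in ("max", "sum"):
        raise ValueError("normalize must be 'max' or 'sum'")
    edges = np.arange(-horizon_s, bin_s / 2, bin_s)
    profiles = []
    excluded = 0
    all_zero = 0
    for rec in records:
        if rec.copulation_time is None:
            excluded += 1
            continue
        rel = rec.female_pulses - rec.copulation_time
        counts, _ = np.histogram(rel, bins=edges)
        counts = counts.astype(float)
        denom = counts.max() if normalize == "max" else counts.sum()
        if denom == 0:
            all_zero += 1
        else:
            counts = counts / denom
        profiles.append(counts)
    if not profiles:
        return {"bin_edges_s": edges, "mean": np.array([]), "sem": np.array([]),
                "n_records": 0, "n_excluded": excluded, "n_all_zero": all_zero}
    arr = np.vstack(profiles)
    sem = (arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
           if arr.shape[0] > 1 else np.zeros(arr.shape[1]))
    return {"bin_edges_s": edges, "mean": arr.mean(axis=0), "sem": sem,
            "n_records": arr.shape[0], "n_excluded": excluded,
            "n_all_zero": all_zero}
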