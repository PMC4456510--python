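"""File formats: WAV audio, CSV event tables, YAML configs, JSON manifests.

All event tables use 0-based seconds and half-open [onset, offset)
intervals. Pulse tables have columns (center_s, sex); interval tables
(onset_s, offset_s, label); frame tables a ``frame`` column plus one
binary column per track.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from . import __version__ as _version
from .simulate import AudioTrace, DuetParams, CouplingParams
from .segment import SegmenterConfig

__all__ = [
    "read_wav", "write_wav", "read_events", "write_pulses", "write_intervals",
    "write_frames", "load_config", "dump_config", "RunManifest",
]

SCHEMAS = {
    "pulses": ("center_s", "sex"),
    "intervals": ("onset_s", "offset_s", "label"),
    "frames": ("frame",),
}


def write_wav(path, trace: AudioTrace, pcm16: bool = False) -> None:
    """Write a mono WAV, float32 by default or 16-bit PCM."""
    if pcm16:
        peak = np.abs(trace.samples).max()
        scaled = trace.samples / peak if peak > 0 else trace.samples
        data = (scaled * 32767).astype(np.int16)
    else:
        data = trace.samples.astype(np.float32)
    wavfile.write(path, int(trace.rate), data)


def read_wav(path) -> AudioTrace:
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        raise ValueError("expected mono audio")
    if data.dtype == np.int16:
        data = data.astype(np.float64) / 32768.0
    return AudioTrace(np.asarray(data, dtype=np.float64), float(rate))


def read_events(path, schema: str) -> pd.DataFrame:
    """Read and validate an event table.

    Malformed rows are rejected with their (1-based, header-inclusive)
    line numbers; an empty file yields an empty table with a warning.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"schema must be one of {sorted(SCHEMAS)}")
    df = pd.read_csv(path)
    required = SCHEMAS[schema]
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)} "
                         f"for schema {schema!r}")
    if df.empty:
        warnings.warn(f"{path}: empty event table")
        return df

    def bad(mask, reason):
        lines = (np.flatnonzero(mask.to_numpy()) + 2).tolist()
        raise ValueError(f"{path}: {reason} at line(s) {lines[:10]}")

    if schema == "pulses":
        if not np.issubdtype(df["center_s"].dtype, np.number):
            bad(pd.to_numeric(df["center_s"], errors="coerce").isna(),
                "non-numeric center_s")
        m = ~df["sex"].isin(["M", "F"])
        if m.any():
            bad(m, "sex must be 'M' or 'F'")
        m = df["center_s"] < 0
        if m.any():
            bad(m, "negative center_s")
    elif schema == "intervals":
        m = df["offset_s"] < df["onset_s"]
        if m.any():
            bad(m, "offset_s < onset_s")
        m = df["onset_s"] < 0
        if m.any():
            bad(m, "negative onset_s")
    else:  # frames
        tracks = [c for c in df.columns if c != "frame"]
        for c in tracks:
            m = ~df[c].isin([0, 1])
            if m.any():
                bad(m, f"non-binary entry in track {c!r}")
    return df


def write_pulses(path, events) -> None:
    """``events``: iterable of objects with .center/.sex, or (center, sex)."""
    rows = []
    for e in events:
        if hasattr(e, "center"):
            rows.append((e.center, e.sex))
        else:
            rows.append((e[0], e[1]))
    pd.DataFrame(rows, columns=["center_s", "sex"]).to_csv(path, index=False)


def write_intervals(path, intervals) -> None:
    """``intervals``: iterable of (onset, offset, label)."""
    pd.DataFrame(list(intervals), columns=["onset_s", "offset_s", "label"]
                 ).to_csv(path, index=False)


def write_frames(path, tracks: dict) -> None:
    df = pd.DataFrame({k: np.asarray(v, dtype=int) for k, v in tracks.items()})
    df.insert(0, "frame", np.arange(len(df)))
    df.to_csv(path, index=False)


_CONFIG_SECTIONS = {
    "duet": DuetParams,
    "coupling": CouplingParams,
    "segmenter": SegmenterConfig,
}


def load_config(path) -> dict:
    """Load a nested YAML config into parameter objects.

    Recognized sections: ``duet``, ``coupling``, ``segmenter``; unknown
    keys within a section are rejected. Missing sections get defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {}
    for name, cls in _CONFIG_SECTIONS.items():
        section = raw.pop(name, {}) or {}
        valid = set(cls.__dataclass_fields__)
        unknown = set(section) - valid
        if unknown:
            raise ValueError(f"unknown keys in config section {name!r}: "
                             f"{sorted(unknown)}")
        out[name] = cls(**section)
    out["extra"] = raw
    return out


def dump_config(path, config: dict) -> None:
    raw = {name: asdict(obj) for name, obj in config.items()
           if name in _CONFIG_SECTIONS}
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to re-run a pipeline invocation bit-identically."""

    seed: int
    config: dict = field(default_factory=dict)
    version: str = _version
    input_digests: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)
    stages_completed: list = field(default_factory=list)

    def record(self, stage: str, **counts) -> None:
        self.stages_completed.append(stage)
        self.stage_counts[stage] = counts

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)
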