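"""End-to-end pipeline: simulate (or ingest) -> segment -> song statistics
-> response timing -> GLMs, with a manifest that makes the run repeatable."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from .simulate import (DuetParams, CouplingParams, simulate_duet,
                       simulate_behavior_tracks)
from .segment import SegmenterConfig, WaveletSongSegmenter, score_segmentation
from .stats import CourtshipRecord, median_ipi, song_rate, percent_overlap
from .timing import (response_times, shuffle_null, summarize_distribution,
                     ks_compare, ResponseTimeSet)
from .glm_timing import (FrameSeries, build_history_design,
                         SparseHistoryLogistic, relative_deviance_reduction,
                         filter_peak_lag)
from . import io as vio

log = logging.getLogger("virduet")

__all__ = ["run_pipeline"]


def _train_segmenter(cfg_seg: SegmenterConfig, duet: DuetParams, seed: int
                     ) -> WaveletSongSegmenter:
    """Train templates on a dedicated simulated recording with frequent
    overlaps, standing in for a manually annotated training data set."""
    train_params = DuetParams(**{**duet.to_dict(),
                                 "duration": 60.0, "overlap_probability": 0.5})
    trace, truth = simulate_duet(train_params, seed=seed + 90_001)
    seg = WaveletSongSegmenter(cfg_seg, random_state=seed % (2**31))
    seg.fit([(trace, truth)])
    return seg


def run_pipeline(config: dict, seed: int, out_dir, n_recordings: int = 3,
                 skip_segmentation: bool = False,
                 pulses_csv=None) -> vio.RunManifest:
    """Run the full analysis on simulated (or supplied) data.

    When ``pulses_csv`` is given, segmentation is skipped and the pulse
    table is used directly for the downstream statistics.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    duet: DuetParams = config.get("duet") or DuetParams()
    coupling: CouplingParams = config.get("coupling") or CouplingParams()
    seg_cfg: SegmenterConfig = config.get("segmenter") or SegmenterConfig()
    manifest = vio.RunManifest(seed=seed, config={
        k: getattr(v, "__dict__", v) for k, v in config.items() if v})

    t0 = time.time()
    records = []
    segmenter = None
    if pulses_csv is None and not skip_segmentation:
        segmenter = _train_segmenter(seg_cfg, duet, seed)
        manifest.record("train_templates", seconds=round(time.time() - t0, 2))

    if pulses_csv is not None:
        df = vio.read_events(pulses_csv, "pulses")
        rec = CourtshipRecord(
            np.sort(df.loc[df.sex == "M", "center_s"].to_numpy()),
            np.sort(df.loc[df.sex == "F", "center_s"].to_numpy()))
        records.append(rec)
        manifest.input_digests[str(pulses_csv)] = vio.file_digest(pulses_csv)
        manifest.record("ingest", pulses=len(df))
    else:
        for k in range(n_recordings):
            rec_seed = seed + k
            trace, truth = simulate_duet(duet, seed=rec_seed)
            truth, tracks = simulate_behavior_tracks(
                truth, coupling, seed=rec_seed, duration=duet.duration)
            vio.write_wav(out / f"rec{k:02d}.wav", trace)
            vio.write_pulses(out / f"rec{k:02d}_truth_pulses.csv",
                             truth.pulse_events)
            vio.write_intervals(out / f"rec{k:02d}_behaviors.csv",
                                truth.behavior_intervals)
            vio.write_frames(out / f"rec{k:02d}_frames.csv", tracks)
            if skip_segmentation:
                m = truth.pulse_times("M")
                f = truth.pulse_times("F")
            else:
                t1 = time.time()
                segments, pulses = segmenter.predict(trace)
                log.info("segmented rec%02d in %.1fs: %d segments, %d pulses",
                         k, time.time() - t1, len(segments), len(pulses))
                vio.write_pulses(out / f"rec{k:02d}_pred_pulses.csv", pulses)
                m = np.array([e.center for e in pulses if e.sex == "M"])
                f = np.array([e.center for e in pulses if e.sex == "F"])
                sc = score_segmentation(
                    m, truth.pulse_times("M")), score_segmentation(
                    f, truth.pulse_times("F"))
                log.info("rec%02d f-scores M=%.3f F=%.3f", k,
                         sc[0]["f"], sc[1]["f"])
            records.append(CourtshipRecord(np.sort(m), np.sort(f)))
        manifest.record("simulate_segment", recordings=len(records))

    # --- song statistics ---
    stats_rows = []
    for i, rec in enumerate(records):
        stats_rows.append({
            "recording": i,
            "median_ipi_m_ms": median_ipi(rec.male_pulses, "M"),
            "median_ipi_f_ms": median_ipi(rec.female_pulses, "F"),
            "male_bout_rate_hz": song_rate(rec, "M", "bout"),
            "female_pulse_rate_hz": song_rate(rec, "F", "pulse"),
            "percent_overlap": percent_overlap(rec),
            "n_male_bouts": len(rec.male_bouts),
            "n_male_pulses": rec.male_pulses.size,
            "n_female_pulses": rec.female_pulses.size,
        })
    import pandas as pd
    pd.DataFrame(stats_rows).to_csv(out / "song_stats.csv", index=False)
    manifest.record("song_stats", rows=len(stats_rows))

    # --- response timing ---
    lat_f, lat_m = [], []
    for rec in records:
        lat_f.append(response_times(rec.male_bouts, rec.female_pulses,
                                    "female_after_male_onset").latencies)
        lat_m.append(response_times(rec.male_bouts, rec.female_pulses,
                                    "male_onset_after_female_pulse").latencies)
    rts_f = ResponseTimeSet(np.concatenate(lat_f), "female_after_male_onset")
    rts_m = ResponseTimeSet(np.concatenate(lat_m), "male_onset_after_female_pulse")
    report = {}
    for name, rts in (("female", rts_f), ("male", rts_m)):
        if rts.n < 5:
            continue
        summ = summarize_distribution(rts, seed=seed)
        report[name] = {"n": rts.n, "peak_ms": summ.peak_latency_ms}
    # shuffled-null comparison on the pooled female direction
    if rts_f.n >= 20:
        null_lat = []
        for i, rec in enumerate(records):
            if rec.female_pulses.size < 3:
                continue
            shuffled = shuffle_null(rec.female_pulses, "female_ipis", seed + i)
            null_lat.append(response_times(
                rec.male_bouts, shuffled, "female_after_male_onset").latencies)
        null = ResponseTimeSet(np.concatenate(null_lat),
                               "female_after_male_onset")
        if null.n:
            report["female_vs_null_ks"] = ks_compare(rts_f, null)
    with open(out / "response_timing.json", "w") as fh:
        json.dump(report, fh, indent=2)
    manifest.record("response_timing", n_female=rts_f.n, n_male=rts_m.n)

    manifest.save(out / "manifest.json")
    return manifest
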