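# virduet

Quantitative analysis of acoustic duetting in two-singer pulse-song
courtship, modeled on *Drosophila virilis*: males produce stereotyped
bouts of wing-vibration pulses, females answer with longer, more variable
pulse trains, and the two singers alternate with predictable response
latencies. The package provides the complete analysis chain for such
recordings, exercised end-to-end on a built-in synthetic duet simulator:

- **Simulation** (`virduet.simulate`): seeded two-singer audio with exact
  ground-truth events, 60-fps behavior annotation tracks (tarsal
  vibration, tarsal pause, proboscis licking) temporally locked to song,
  and the band-limited playback stimulus used in playback assays.
- **Segmentation** (`virduet.segment`, `virduet.templates`,
  `virduet.wavelets`): a reimplementation of wavelet-template song
  segmentation. The microphone trace is transformed with a frequency
  B-spline wavelet at 33 log-spaced frequencies spanning 100–900 Hz; each
  song class (male M, female F, overlap O, noise N) is a template — mean
  wavelet spectrum, PCA basis, per-axis Gaussian-mixture densities — and
  per-time posteriors under a uniform prior drive a rule cascade:
  points with p(N|x(t)) > 1/2 are zeroed; connected segments with
  mean p(M)+p(O) > p(F) and ≥ 100 ms become male song; remaining segments
  ≥ 15 ms become female song; runs with pointwise p(F)+p(O) > 0.8 for
  ≥ 15 ms inside a male segment are embedded female pulses.
- **Song statistics** (`virduet.stats`): bout assembly (male: ≥ 4 pulses,
  IPI < 25 ms; female: IPI < 100 ms), per-individual median inter-pulse
  intervals (100/500-ms thresholds), song rates with the 20-s/0-Hz rule,
  percent overlap, pulse power spectra, pre-copulation song profiles.
- **Duet timing** (`virduet.timing`): female response times (male bout
  onset → next female pulse ≤ 1.5 s), male response times (bout onset ←
  chosen pulse of the preceding female train), interval-shuffled nulls,
  bootstrap confidence bands, KDE distribution peaks, two-sample
  Kolmogorov–Smirnov tests and Kullback–Leibler divergences.
- **GLMs** (`virduet.glm_rates`, `virduet.glm_timing`): a Poisson GLM
  (log link, ±1 channel coding, pairs bootstrap) linking sensory channels
  to song rates, and L1-penalized logistic history-filter GLMs (64 lags
  at 60 fps ≈ 1 s) predicting framewise song presence from behavior
  tracks, scored by cross-validated relative deviance reduction.

Model-like components are scikit-learn-style estimators
(`WaveletSongSegmenter`, `TemplateClassifier`, `SparseHistoryLogistic`,
`PoissonRateGLM`) with `fit`/`predict` and `get_params`/`set_params`;
module-level functions wrap them.

## Worked example

```python
import numpy as np
from virduet import (DuetParams, WaveletSongSegmenter, simulate_duet,
                     assemble_bouts, median_ipi, response_times,
                     summarize_distribution, ResponseTimeSet)

# templates from a simulated "annotated" recording with frequent overlaps
trace_tr, truth_tr = simulate_duet(
    DuetParams(duration=60.0, overlap_probability=0.5), seed=90001)
seg = WaveletSongSegmenter(random_state=0).fit([(trace_tr, truth_tr)])

# a fresh wild-type courtship, segmented from raw audio
trace, truth = simulate_duet(DuetParams(duration=60.0), seed=1)
segments, pulses = seg.predict(trace)
m = np.sort([e.center for e in pulses if e.sex == "M"])
f = np.sort([e.center for e in pulses if e.sex == "F"])
print(len(assemble_bouts(m, "M")), "male bouts")
print(round(median_ipi(m, "M"), 1), "ms male median IPI")
print(round(median_ipi(f, "F"), 1), "ms female median IPI")

rts = response_times(assemble_bouts(m, "M"), f, "female_after_male_onset")
print(round(summarize_distribution(rts, seed=0).peak_latency_ms), "ms female RT peak")
```

prints

```
34 male bouts
21.1 ms male median IPI
55.7 ms female median IPI
414 ms female RT peak
```

— the segmenter recovers the generating song structure (male IPI
21.2 ms, female IPI 55.2 ms) and the female answer latency mode (409 ms)
from the audio alone.

A CLI mirrors the library: `virduet simulate|train-templates|segment|
score|stats|respond|glm-rates|glm-timing|run`, each with `--seed`,
`--config` (YAML) and `--out`; `virduet run` executes the whole pipeline
and writes a manifest sufficient to reproduce the run bit-identically.

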