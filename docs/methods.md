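# Methods

## The duet model

The simulator generates a single-microphone courtship recording of two
singers under a strict-alternation exchange model. One exchange is:

1. a **male bout** — `N_m ~ round(Normal(6.9, 1.2))`, floored at 4,
   pulses with inter-pulse intervals `Normal(21.2, 1.9)` ms (clipped at
   5 ms);
2. a **female train** — first pulse at a log-normal latency after the
   male bout onset with density mode 409 ms; `N_f ~ round(Normal(7.2,
   6.2))`, floored at 1 (a deliberately overdispersed count, matching
   the high variability of female bout length), IPIs
   `Normal(55.2, 26.3)` ms clipped at 15 ms;
3. the **next male bout** at a log-normal latency after the last female
   pulse, density mode 110 ms. After 20% of exchanges an exponential
   silent gap (mean 4 s) is inserted, emulating the long silent
   stretches of real courtship.

Pulses are Gabor wavelets (sinusoid under a Gaussian envelope, envelope
sd = duration/6): male 15 ms at 400 Hz, female 18 ms at 250 Hz. The
carriers are design choices, not measured values — what matters is that
male pulses peak at a higher frequency than female pulses and both lie
well inside the 100–900 Hz analysis band; both are configurable.
Gaussian background noise (sd 0.05 against unit male pulse amplitude)
is added. With probability 0.01 per exchange an extra female pulse is
placed inside the male bout; song overlap is extremely rare in this
system (population median 0%), and 0.01 keeps the per-pairing overlap
percentage at a population median of zero while still exercising the
overlap machinery.

Latency spreads (log-sd 0.2 female, 0.35 male) are not measured
quantities either. They were fixed once so the simulated response-time
distributions are unimodal, right-skewed and wide (sd ≈ 85 ms and
≈ 45 ms), while keeping the density mode recoverable by a 25-ms-bandwidth
KDE to well within one bandwidth at n ≈ 1000 latencies — the package's
own invariant for the timing pipeline.

### Behavior tracks

Three annotated behaviors are generated at 60 fps. Both tactile
behaviors occur in two kinds of episodes, reflecting the tactile-contact
sequence of courtship (vibration → licking → male song, with contact
continuing through female song):

- an episode spanning each female train (lag ≈ 0: tactile contact
  co-occurs with female song);
- a bout-length episode preceding each male bout by the behavior's lead
  (tarsal vibration 200 ms, proboscis licking 50 ms).

Episode boundaries get Gaussian jitter (default sd 5 ms, under one video
frame). Tarsal-pause episodes fill the gaps between vibration episodes.
Matching the lead episode's duration to the bout it precedes makes the
lead lag a (nearly) sufficient single predictor of framewise song, so
the planted leads are identifiable by a sparse filter fit; with centered
fixed-length episodes the most predictive lag would be the lead plus
half the bout duration, which no estimator could undo.

### What the simulator does not emulate

Real recordings contain nonstationary broadband noise, amplitude
variation with the singer's position relative to the microphone,
grooming/locomotion artifacts, and female IPI autocorrelation; pulses
are not exact Gabors and carriers drift. Passing tests therefore
demonstrate the correctness and internal consistency of the analysis
chain under the stated statistical structure — not segmentation
performance on real microphone data.

## Segmentation

The trace is transformed with a frequency B-spline (fbsp) wavelet,
`fbsp2-0.5-1` by default, at 33 log-spaced center frequencies in
100–900 Hz. The fbsp Fourier transform is a compactly supported cardinal
B-spline, so the transform is computed exactly in the frequency domain
(one FFT of the signal, one band-limited multiply + inverse FFT per
scale); a pywt cross-check on the in-band response is part of the test
suite. The default order/bandwidth give a time support of roughly
±10 ms at 400 Hz — wide enough that the ~6 ms silent gaps between male
pulses (IPI 21 ms) stay above the noise floor and a bout remains one
connected non-noise segment, while the ≥ 40 ms gaps between female
pulses fall back to noise and female pulses segment individually.

Templates: per class, examples are wavelet spectra sampled at annotated
pulse centers plus uniform offsets up to ±8 ms (3 draws per pulse,
15 for the rare overlap class), so each class density covers the
magnitude range across a pulse rather than only its peak. The examples
are mean-centered, rotated by PCA (8 axes kept by default, orthonormal
by construction), and each axis's projections are fit with a 3-component
EM Gaussian mixture (variance floored at 1e-10 with a warning on
degeneracy). The noise template is refit from every analyzed recording:
time points whose broadband magnitude lies below the 0.5 quantile of
that recording are taken as noise examples, adapting the classifier to
per-recording noise conditions.

Classification: a spectrum's log-likelihood under a template is the sum
over axes of the per-axis mixture log-densities of its projections
(axis independence is the template model's assumption); per-time
posteriors are the softmax of the four log-likelihoods, i.e. posterior ∝
likelihood under a uniform class prior, computed stably in the log
domain. The production path runs in single precision (the double
precision path is retained on the template object and the two are
checked against each other and against a direct-probability oracle).

Labeling uses the fixed rule cascade (1/2 noise cutoff, 100-ms male
minimum, 15-ms female minimum, 0.8 pointwise embedded-female cutoff over
≥ 15 ms). Two numerical choices:

- the M-vs-F comparison is taken on the segment's **mean** posterior —
  robust and deterministic for whole-segment assignment — while the
  embedded-female rule is **pointwise** run-length, since it describes a
  sub-region of a male segment;
- posteriors are smoothed with a 5-ms moving average (renormalized)
  before the cascade. At 10 kHz the per-sample posterior flickers on
  sub-millisecond scales, which would fragment connected segments;
  5 ms is far below every rule threshold. Config-exposed
  (`posterior_smooth_ms`), set to 0 to apply the cascade verbatim.

Pulse localization within segments (a step the template classifier does
not define): local maxima of the Hilbert envelope smoothed by a 2-ms
moving average, above `max(3 × segment median envelope, floor)`, with
minimum peak separation 10 ms (male) / 15 ms (female). The multiplier 3
rejects noise wiggles in segments that are mostly envelope tails; each
embedded-female interval contributes one female pulse at its envelope
maximum. A known consequence of the 100-ms rule: 4-pulse male bouts span
only ~63 ms and are labeled female unless wavelet smear carries the
segment over 100 ms; at the default bout-size distribution ~2% of bouts
are affected, which biases mean pulses per bout upward by < 0.1.

Segmentation is evaluated by greedy one-to-one event matching within
±10 ms (config-exposed): sensitivity TP/(TP+FN), positive predictive
value TP/(TP+FP), and their harmonic mean. On low-noise synthetic duets
the per-sex pulse f-score exceeds 0.95 (typically ≈ 0.99).

## Duet timing

Female response time: male bout onset → next female pulse within 1.5 s.
Male response time: male bout onset → back to a chosen pulse (default
the last) of the preceding female train, within 1.5 s; a bout with no
preceding train is skipped. The playback variant measures from the bout
offset and ignores overlaps. Nulls permute female IPIs (or male
inter-bout gaps, keeping each bout's internal structure) within a
recording and rebuild times by cumulative sum, preserving interval
statistics while destroying alignment; shuffling is per-recording,
pooled afterwards. Distribution summaries: 50-ms histogram bins on
[0, 1.5] s, 95% bootstrap bands from 500 resamples, and a peak taken as
the argmax of a fixed-bandwidth (25 ms) Gaussian KDE on a 1-ms grid —
robust to bin placement, unlike a histogram argmax. KS comparisons use
the asymptotic two-sample test; KL divergence is computed on the shared
bin grid in nats with additive smoothing ε = 1e-6 per bin (ε reported
with the value).

## Rate GLM

Song rates are non-negative counts per unit time, so the channel model
is a Poisson GLM with log link on ±1 channel codes. "Standardizing the
data" is implemented as z-scoring the **predictor columns only**: rates
are left on their natural scale because z-scoring a Poisson response
would break its support. When counts and courtship durations are
available the model uses the count response with a log-duration exposure
offset (the default, exact under the Poisson assumption); otherwise the
rate itself is the response. Uncertainty: analytic Wald standard errors
plus a pairs (case-resampling) bootstrap; refit failures are skipped,
counted, and flagged above 10%.

## History-filter GLM

For each frame t, the design row concatenates the previous 64 frames
(≈ 1 s at 60 fps) of each chosen behavior track; the response is the
target song track at t. Behavior tracks are strongly auto- and
cross-correlated, so the logistic fit carries an L1 penalty (liblinear
coordinate descent; the intercept is unpenalized) that suppresses
weights that would be large only through correlation; ridge is available
behind a flag. The per-sample penalty weight is selected by 3-fold
cross-validated held-out deviance over a small grid
(3e-5 … 1e-3) when not supplied. Performance is relative deviance
reduction, 1 − deviance(model)/deviance(bias-only), on held-out data
from 80/20 random subsampling (20 splits by default; the penalty is
selected once and reused across splits). Bootstrap uncertainty refits on
random 75% subsets drawn as contiguous 1-s frame blocks, respecting the
autocorrelation that frame-level resampling would destroy. Filter peak
lag = argmax weight × 1000/fps ms, ties broken toward the smaller lag
and flagged. Stepwise comparison fits all single-behavior models, takes
the best, and reports the absolute and relative gain of every
two-variable extension.

## Problem sizes

The package's reference computations use 13 two-minute courtships for
song-structure recovery, 10 three-minute courtships (≈ 1000 exchanges)
for response-time modes, 89 pairings of 45–60 s for the overlap
statistic, and 10 ten-minute annotated courtships for the history-filter
fits. These sizes give estimator noise comfortably inside each check's
tolerance while keeping a full run in the minutes range on one CPU.

## Known limitations

- The segmenter's accuracy claims hold for the simulator's noise model;
  real recordings need retrained templates and possibly different
  wavelet bandwidth and envelope thresholds.
- The manual-correction pass of a semi-automated pipeline is out of
  scope; reproducible corrections can be applied by editing the pulse
  CSVs between stages.
- L1 solutions on heavily collinear designs are near-unique rather than
  unique: permuting behaviors in a joint design changes fitted
  probabilities at the solver-tolerance level.
- KL divergence values depend on the smoothing ε in empty bins; ε is
  always reported alongside the value.
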