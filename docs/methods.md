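# Methods

This note documents the models, parameters, numerical choices, and known
limitations behind `p3net`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The analysis model

The pipeline treats each subject as contributing two measurements:

* a **task response** — P3 amplitude (μV) and latency (ms) from the
  averaged target ERP of an oddball task, and
* a **resting network** — a 21×21 matrix of band-averaged
  magnitude-squared coherences between scalp electrodes, summarized by
  five weighted graph indexes,

and asks, across subjects, whether the two covary (Pearson correlation).

### P3 measurement

Processing order: average re-reference → 0.5–6 Hz zero-phase 4th-order
Butterworth band-pass → stimulus-locked epochs (−200…800 ms, half-open
sample windows, 0-based onsets) → baseline correction (−200…0 ms) →
rejection of any trial with |sample| > 75 μV on any scalp channel →
condition-wise averaging. The peak is the target-ERP maximum in
300–500 ms post-stimulus, with exact ties resolved to the *earliest*
sample (deterministic and order-independent). Amplitude is the mean over
peak ± 50 ms inclusive — 51 samples at 500 Hz — which trades peak height
for noise robustness; latency is the peak time. Subject-level values
average the five centro-parietal electrodes (CPz, CP1, CP2, Cz, Pz).

The epoch and baseline windows are conventional choices; the method that
defines the measurement only fixes the search window, the ±50 ms averaging
rule, and the five electrodes.

### Coherence networks

Resting EEG is average-referenced, band-passed to 1–30 Hz, cut into
contiguous 10-s segments (trailing remainder dropped), and screened at
±100 μV — an automated, reproducible proxy for visual artifact inspection;
the threshold is configurable. Per segment, Welch cross- and auto-spectra
use 2-s Hann windows with 50% overlap (K = 9 windows, 0.5 Hz resolution),
and

    Coh(f) = |Pxy(f)|² / (Pxx(f) Pyy(f))

is averaged over the closed band [1, 30] Hz (59 bins at 0.5 Hz), then over
segments. Magnitude-*squared* coherence is used; the magnitude variant is
a monotone transform of it, so correlation-sign conclusions are unchanged,
but absolute edge weights would differ. All surviving segments are used
and their count recorded (no subsampling to a fixed segment number).

With K averaged windows the coherence of independent signals is biased
upward by ≈ 1/K; at K = 9 the floor is ≈ 0.11 (slightly higher in
practice because 50%-overlapped windows are not independent). The
acceptance checks treat [1/K, 2/K] as the admissible floor and verify
that averaging over segments tightens the estimate onto it.

### Graph indexes

On the weight matrix W (weights in [0,1], zero diagonal, dense in
practice), edge lengths are l = 1/w — the standard weighted-network
transform. Indexes:

* **C** — per node, Σ_{j≠h} (w_ij w_jh w_hi)^{1/3} / (k_i(k_i−1)) on the
  *raw* weights (no per-graph max normalization: normalizing would erase
  exactly the between-subject overall-strength differences the
  cross-subject correlations depend on); C_i = 0 for degree < 2.
* **Ge** — mean of 1/d_ij over ordered pairs (1/∞ = 0).
* **Le** — Ge of the subgraph induced by each node's neighbours.
* **L** — mean d_ij; errors on disconnected graphs unless the
  harmonic-mean fallback (1/Ge) is requested. Disconnection cannot occur
  for coherence matrices, whose weights are strictly positive.
* **MFC** — mean of the 210 pairwise weights.

Dense matrices are analyzed without thresholding or binarization. For a
complete uniform graph of weight w these definitions give
C = Ge = Le = w and L = 1/w, which the tests verify along with exact
agreement (1e−10) against exhaustive simple-path enumeration on random
graphs of 4–8 nodes.

### Correlation statistics

Pearson r with two-sided p from the exact t-distribution
(t = r√((n−2)/(1−r²)), n−2 df) — preferred over the Fisher-z
approximation at cohort sizes around 20. Edge-wise screening tests all
210 edges at uncorrected p < 0.01 by default; this mirrors the common
practice the pipeline models and is deliberately surfaced (not silently
"fixed") — a Benjamini–Hochberg option (`correction="bh"`) is exposed for
honest error control. The amplitude–latency correlation is reported
alongside.

## The synthetic cohort generator

The generator emulates the study design the pipeline targets, with known
ground truth:

* **Montage/sampling** — 21 channels at 500 Hz. The channel set is the
  10–20 layout with the centro-parietal row (CP1, CPz, CP2) included so
  all five P3 electrodes exist; coordinates ship as fixed constants.
* **Background** — each channel mixes *shared* narrowband oscillators
  (Gaussian-spectrum alpha at ~10 Hz, posterior-weighted; theta at ~6 Hz,
  frontal-weighted) with *channel-private* 1/f pink noise (band-limited to
  45 Hz; all analysis lives below 30 Hz), at total RMS `noise_sd`
  (default 15 μV, a typical adult eyes-closed scalp RMS). The fixed
  anterior–posterior gain gradients are what lets shared activity survive
  average re-referencing.
* **Latent efficiency** — each subject draws a latent score uniformly on
  [0.2, 0.8]; it sets the shared-variance fraction of the *resting*
  background linearly. More shared variance → higher pairwise coherence →
  higher MFC/C/Ge/Le and lower L, monotonically. The *task* background
  uses the same process family but a fixed shared fraction (0.3):
  letting the latent score also modulate task noise would couple the P3
  *measurement error* to the latent variable through the re-reference
  step — a spurious pathway a recovery study must not contain.
* **P3** — target trials (exact-count randomization:
  round(n_trials·target_prob) targets, shuffled; defaults 150 trials, 20%)
  receive a half-cosine bump, peak `true_amp` at `true_lat` ms
  post-stimulus (snapped to the sample grid), support ±150 ms, scaled by a
  fixed centro-parietal weight table (1.0 at CPz/Pz, 0.9 at CP1/CP2/Cz,
  decaying frontally). Across subjects `true_amp` ~ affine(latent) +
  Gaussian noise, calibrated so corr(latent, true_amp) = `coupling_rho`
  exactly in population; `true_lat` ~ N(401, 34²) ms clipped to
  310–490 ms. Amplitude/latency moments default to 4.27 ± 1.14 μV and
  401 ± 34 ms.
* **Artifacts** — round(rate · count) trials/segments receive a 2 Hz,
  150 μV, 0.5 s sinusoidal burst on the frontal channels. A sinusoid in
  the pass-band (rather than a square pulse) guarantees the burst survives
  both band-pass filters with gain ≈ 1, so rejection counts are exact by
  construction. Default rate 0.1 → exactly 15 of 150 trials and 2 of 24
  rest segments.
* **Determinism** — one cohort seed fans out through
  `SeedSequence(seed, spawn_key=(subject, stream))`; identical spec + seed
  reproduce byte-identical cohorts.

What the generator does **not** emulate: volume conduction and realistic
forward models, eye-blink/EMG waveform morphology, non-stationarity,
between-channel noise correlations, or any empirical spectrum beyond the
alpha/theta-over-1/f caricature. Passing tests therefore demonstrate that
the *pipeline* recovers structure it is pointed at under controlled
conditions — not that real recordings satisfy these assumptions.

## Measurement attenuation and the recovery study

The measured quantities are noisy, nonlinear functions of the latent
truth, so the pipeline's cross-subject correlation is attenuated relative
to `coupling_rho`. The recovery study therefore compares the pipeline's
mean r(index, amplitude) not with ρ itself but with the *measured*
attenuation product r(latent, true_amp) · r(index, latent) ·
r(amplitude, true_amp), all three factors computed per cohort from the
generator's own ground truth. Two further scale notes:

* after average re-referencing the measured amplitude equals the planted
  peak times a fixed spatial constant (≈ 0.44 for the default weight
  table and 51-sample window) — correlations are unaffected;
* peak-picking on noisy ERPs inflates small amplitudes (argmax selection
  bias), one of the reasons the amplitude-reliability factor sits well
  below 1 at the default noise level.

## Problem sizes

Simulation studies in the test suite and acceptance script are sized for
a single CPU: the coupling-recovery study runs 20 cohorts of 40 subjects
at ρ = 0.6, the null calibration 50 cohorts of 19 subjects (the cohort
size the method is typically applied at) at ρ = 0, both with 120 s of
rest per subject — 12 ten-second segments, matching the roughly ten
analyzed segments per subject the protocol assumes — and float32
synthesis (filter accuracy ~5e−4 relative, ample for noisy-cohort
statistics). Exactness tests (closed-form P3 recovery, round-trips,
graph identities) run in float64. Generator defaults keep the full
protocol: 240 s rest, 150 trials, 500 Hz.

## Known limitations

* EDF output writes 1-s records and therefore whole seconds only; TSV is
  the lossless general-purpose format.
* The edge-wise screen at uncorrected p < 0.01 over 210 tests has a
  substantial family-wise false-positive probability; use the BH option
  for inference rather than exploration.
* Magnitude-squared vs. magnitude coherence changes absolute edge weights
  (see above); comparisons of absolute MFC across software should fix the
  convention first.
* With the default noise level the single-subject latency estimate is
  noisy (the amplitude is averaged over 51 samples, the latency is a
  single argmax); latency-based correlations are correspondingly weak.
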