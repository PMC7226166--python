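# Methods

This note documents the models, defaults, and numerical choices behind
`catlearn_eeg`, and what the synthetic-data tests do and do not establish
about real recordings.

## 1. The synthetic study

### 1.1 Task schedule and behavior

`ScheduleSpec` defaults encode the task design: 9 trained stimuli (3 per
category), 8 training blocks × 10 exposures per stimulus (90 trials/block, 80
exposures per stimulus in total), then a generalization block in which the 9
trained and 9 novel stimuli each appear 5 times (90 trials). Orders are
shuffled within block from the supplied seed.

Simulated accuracy for category *c* follows an exponential approach to
asymptote over 1-based stimulus presentations *e*:

    p_c(e) = a_c − (a_c − ⅓)·exp(−r_c·e)

with defaults r = 0.30 / 0.12 / 0.12 and a = 0.99 / 0.97 / 0.97 for the
distinct / similar₁ / similar₂ categories. Those values put trial-weighted
mean training accuracy at ≈96% (distinct) vs ≈90% (similar) and make the
distinct category the first one acquired, the orderings the analysis is meant
to expose. Error responses on a similar category land on the *other* similar
category with probability 0.8 (else distinct); errors on distinct split
evenly. A per-subject lognormal learning-rate gain (σ = 0.3) creates
behavioral heterogeneity. In the feedback-free generalization block accuracy
is frozen at its end-of-training value; novel stimuli receive the
above-chance part scaled by a transfer fraction (default 0.9).

The 1-based presentation index makes the *rate → ∞, asymptote 1* limit an
always-correct subject, and a zero rate a flat chance performer — the two
analytic anchors the behavior tests use.

### 1.2 EEG generation

Each trial's epoch is

    x(ch, t) = Σ_k  A_k(cond) · K(t − τ_k(cond); W_k) · g_k(ch)  +  ε(ch, t)

where `K` is a raised-cosine bump with half-support `W` (smooth, compactly
supported, analytically integrable — so window averages have closed forms),
`g_k` is the component's topography, and ε is independent Gaussian noise per
channel and sample (default sd 5 µV; an optional 1/f-amplitude surrogate is
provided, default off). Topographies are +1 on the component's electrode
cluster with a uniform negative counterweight on channels outside every
region and cluster, so each scalp field sums to zero — like a physiological
dipolar field, it is then invariant under average referencing, and no other
cluster or decoding region picks up leakage.

**Amplitude convention.** Component amplitudes are conventionally reported as
*adaptive means* (mean over ±h ms around the detected peak), which shrink a
kernel peak by the factor s = mean of K over the on-grid window. Calibrated
default specs therefore state amplitudes in adaptive-mean units and scale the
kernel peak by 1/s, so a noiseless measurement reproduces the configured
value exactly; bare `ComponentSpec`s default to peak units. This matters most
for the P200, whose support must end by 228 ms (to stay out of the MFN
averaging window), making its shrinkage otherwise non-negligible.

**Calibrated defaults** (per condition, adaptive-mean µV; latencies ms;
half-supports ms):

| component | distinct | similar | latency | W |
|---|---|---|---|---|
| P200 | +1.50 | +1.50 | 168 | 56 |
| MFN (raw) | −0.81 | −0.57 | 248 | 52 |
| P3b | +6.02 | +5.34 | 560 | 300 |
| LIAN left | −7.06 | −5.54 | 640 | 300 |
| LIAN right | −2.92 | −3.55 | 640 | 300 |

The raw MFN values are the target peak-to-peak amplitudes (−2.31 distinct /
−2.07 similar) plus the P200 reference amplitude, so the referenced measure
reproduces the targets. The P200 amplitude itself (not reported in the source
analyses) is set to a modest 1.5 µV so the raw MFN trough stays clearly
negative — an additive-offset subject model could flip its sign, which is why
between-subject variability is **multiplicative**: each subject draws one
lognormal gain per component (σ = 0.15, shared across conditions, preserving
polarity and contrast sign) plus one latency offset (sd 5 ms, clipped at
±10 ms, shared across conditions). Realized per-subject values are stored as
ground truth, so recovery tests compare against what was actually generated.

The P3b latency (560 ms) is set earlier than the LIAN latency (640 ms) within
their shared 450–950 ms window. This is the generator-level encoding of the
finding that the posterior-parietal region's condition information arises
earlier than the frontal regions'.

Kernel supports were chosen so measurement windows are temporally clean: the
P200 (112–224 ms) is zero throughout the MFN averaging window (≥228 ms), and
the MFN (196–300 ms) is zero throughout the P200 averaging window (≤188 ms);
the late components start well after the baseline and end before the epoch.

**Artifacts.** With probability `artifact_rate` (default 0.05) a trial
receives a ±300 µV, 200 ms pulse on 12 random channels — enough to trip the
≥10-channels-beyond-140 µV rejection rule even after band-pass filtering.

**Timing.** Trial onsets are spaced 1.3–1.4 s apart (the task's real trial
period is ~6 s). Epochs are 1.2 s and every kernel vanishes by +940 ms, so
adjacent epochs carry no component bleed-over; the compression only keeps
full-scale simulations tractable. Recordings are float32; events land on
exact sample indices.

Determinism: all randomness derives from `SimulationConfig.seed` through
per-subject seed sequences; identical (config, seed) reproduce bit-identical
recordings, and the HDF5 writer disables timestamps so containers are
byte-reproducible.

### 1.3 Montage

The published cluster memberships exist only as sensor-layout figures, so the
default 256-channel montage is a synthetic-but-plausible partition: ten
regions of 16–24 channels (198 total), component clusters of the stated sizes
(MFN 12, P3b 17, LIAN 22+22) nested in their host regions, and 58 unassigned
outer-ring channels that serve as the counterweight pool. Everything is
overridable via YAML. `scaled_montage(n)` shrinks the same structure
proportionally for reduced-size simulations.

## 2. Analysis choices

* **Time axis.** Sample *k* covers [4k, 4k+4) ms from stimulus onset; the
  baseline is the 50 samples with negative times (half-open window [−200, 0)),
  and peak/averaging windows are inclusive on sample centres. The ±22 ms
  halfwidth spans the same 11 samples as ±20 ms on the 4 ms grid; both are
  kept distinct in the definitions as stated.
* **Artifact rule.** Strictly greater than 140 µV on ≥10 channels, evaluated
  on filtered, pre-baseline voltages; both the comparison and the stage are
  configurable, since the source description fixes neither.
* **Filter.** 4th-order Butterworth band-pass applied forward–backward
  (zero-phase preserves latencies), with reflection padding of
  3·fs/low_hz samples — the 0.1 Hz cut has a ~1.6 s transient that the
  default padding would leave in the data.
* **Post-learning trials** for ERP averaging and decoding patterns are
  training trials at/after the stimulus's FCCR criterion (the
  criterion-completing trial included) *and* answered correctly; error trials
  carry feedback-related activity. Stimuli that never reach criterion
  contribute none (logged), and subjects left without a single usable trial in
  any condition are excluded (logged). Non-responses count as incorrect; by
  default they also break an FCCR run (a flag restores the lenient reading in
  which a non-response continues the run).
* **Contrast pooling.** Per-subject accuracy and amplitude contrasts compare
  distinct against the mean of the two similar categories (amplitudes are
  measured on the merged similar-trials ERP); the similar₁-vs-similar₂
  equivalence t-test is reported alongside. Accuracy is trial-weighted by
  default (block-weighted available).
* **Decoding.** Evidence is the signed distance to the SVM hyperplane
  oriented toward the similar class — monotone-equivalent to a probability
  estimate for forced choice. C = 1; features standardized with training-fold
  statistics (both configurable, as neither is pinned by the source). Exact
  evidence ties score 0.5; a fold whose training patterns are all identical is
  scored at chance with a warning. Per-timepoint p-values are uncorrected
  two-sided one-sample t-tests vs 0.5 (Benjamini–Hochberg available as an
  option); "significant" additionally requires above-chance accuracy.
* **Degenerate statistics.** Zero-variance paired differences report t = ±∞
  (p = 0) with a warning, or t = 0, p = 1 when identically zero; zero-variance
  correlations are reported as missing, never 0.

## 3. What the tests show — and what they cannot

The synthetic generator reproduces the *statistical skeleton* the analysis
assumes: condition-dependent component amplitudes on fixed topographies,
learning curves with similar-category confusions, threshold-exceeding
artifacts, between-subject gain/latency variability. It does **not** model
volume conduction from real dipole sources, ocular or muscle activity beyond
the artifact pulses, non-stationary or spatially correlated background EEG,
or latency/amplitude changes over the course of learning. Passing recovery
tests therefore demonstrates that the pipeline measures what the generator
embeds at realistic SNR — not that real recordings meet these assumptions.

Problem sizes in the test suite are chosen per check: ground-truth recovery
runs the full design (40 subjects, 256 channels, 8 blocks; group-mean
amplitude error ≤ 0.15 µV, latency error ≤ 8 ms), while Monte-Carlo suites use
scaled studies (null calibration: 20 seeds × 24 subjects, 64 channels, 1
block; contrast signs: 20 seeds × 8 subjects, 4 blocks; region timing: 20
seeds × 6 subjects, 2 blocks).

Two calibration findings are worth stating plainly:

* **The per-timepoint t-test over LOSO folds is anti-conservative.** Fold
  outcomes are positively dependent — every subject's patterns appear in all
  other folds' training sets (measured cross-subject correctness correlation
  ≈ 0.036 at n = 24, design effect ≈ 1.9). Under a null generator with
  identical conditions the empirical p < 0.05 rate is ≈ 0.15–0.18 rather than
  0.05, and a pattern-level control with i.i.d. Gaussian patterns (no EEG
  pipeline at all) already yields ≈ 0.14. Group *accuracy* remains unbiased
  at 0.5. This is a property of the prescribed analysis, not of its
  implementation; the null-calibration suite records it, and single isolated
  significant bins should be read accordingly (the acceptance script reports
  a sustained onset requiring ≥ 2 consecutive significant bins alongside the
  raw one).
* **Ceiling effects hide peak timing.** At the generator's SNR, decoding
  accuracy saturates at 1.0 over a plateau, so the argmax bin is a
  tie-breaking artifact. Relative timing across regions is therefore
  assessed with the above-chance-mass centroid of the timecourse, which
  recovers the posterior-parietal-before-frontal ordering robustly.

In the null suite, patterns are averaged over *all* training trials (correct
and incorrect) so the three conditions are exchangeable with exactly equal
trial counts; restricting to correct trials at the reduced 1-block size would
give conditions systematically different trial counts (hence pattern
variances) purely through the behavioral model.

## 4. Known limitations

* The default montage's channel-to-region assignment is synthetic; analyses
  of real recordings must supply their own montage YAML.
* EDF ingestion requires the optional `mne` dependency and an external event
  table; no other vendor formats are supported.
* No ICA/regression ocular correction and no channel interpolation — the
  artifact rule is the only cleaning step, as in the modeled pipeline.
* `preprocess` (the epochs-writing CLI stage) materializes one subject's
  epochs in memory/disk; `run` streams subjects and never stores the full
  epochs tensor.
* The behavior–decoding correlation uses overall training accuracy by
  default; late-blocks-only accuracy is a caller choice, not a flag.
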