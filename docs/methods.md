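# Methods

## Scientific setting

Ten-ish older adults take an intensive beginner's L2 course.  Resting EEG
is recorded before (T1) and after (T2) training; three L2 tests are taken
at both time points; after training, a language-switching ERP experiment
presents L2 sentences whose final noun may switch into the L1 and/or be
semantically incongruent.  Two questions are analysed: whether band power
at rest — beta1 (13–14.5 Hz) in particular — predicts the corrected
learning gain, and whether the N400/LPC responses to switching and
incongruence scale with attained proficiency.  No recorded data ship with
the package; a synthetic generator with logged ground truth stands in for
the study and defines what "recovery" means for every test.

## Synthetic signal model

**Resting EEG.**  Each channel is pink (1/f-power) background noise plus
one narrowband oscillator per frequency band.  An oscillator is a sinusoid
at a carrier drawn uniformly from its band (per subject), with a random
phase per channel and a slow random amplitude envelope (nodes every 2 s,
modulation depth 0.25, clipped at zero).  A sinusoid-based oscillator was
chosen over filtered noise because its band power has a closed form
(A²/2 at the carrier bin), which the spectral tests exploit.  Default
amplitudes (µV): theta 3, alpha 6, beta1 1.5, beta2 1.2, beta3 1.0;
background sd 10 µV.  Per-subject log-normal jitters (sd 0.15 on band
amplitudes, 0.10 on the background) create band-specific between-subject
variance, and a shared whole-signal scale (log-normal, sd 0.15, standing in
for skull/scalp conductivity differences) moves all bands of a subject
together — the component the mixed model's random intercept absorbs and
the reason power values are non-independent within subjects.

**The brain–behaviour link.**  A latent aptitude z-score per subject (i)
adds `0.5 µV × aptitude` to the beta1 amplitude and (ii) sets the true
corrected gain through a logistic link, `CorP = 15 + 70·sigmoid(1.2·apt) +
N(0, 5)`, giving gains spanning roughly 20–90% of attainable improvement
with mean ≈ 50 — the realistic spread for motivated beginners.  T1 test
percentiles are a shared ability (mean 40, sd 18) plus independent test
noise sized so the inter-test correlation is 0.85 (first principal
component ≈ 90% of variance); T2 percentiles are back-computed from the
true CorP so the realized gain matches it up to small test noise (sd 2.5).
At T2 the beta1 amplitude is scaled by 10^(−0.04/2), injecting the small
training-related power decline.  The paper-free parameters here (effect
size of the link, noise levels) are simulation defaults, stated once and
not tuned per test.

**Artifacts.**  Blinks (biphasic 0.4-s template, 100–200 µV, on the most
anterior ~12% of channels), voltage steps (60–150 µV, 0.5–2 s) and
flatline segments (0.35–1 s) are injected at Poisson rates (default 4,
0.5, 0.2 events/min) and every event is logged (channel, start sample,
kind), so detector and ocular-correction tests have an oracle.

**ERP trials.**  Each trial is −100…1000 ms of pink noise (sd 6 µV)
plus Gaussian-windowed components on the pool channels: a central
negativity (peak −2 µV, centre 375 ms, sd 40 ms) scaled per condition as
switch-incongruent 1.4, switch-congruent 1.0, no-switch-incongruent 0.4,
no-switch-congruent 0.0 — the qualitative four-level ordering of the
grand-average waveforms, with the switch-minus-no-switch mean difference
exactly 1.0 × peak — and a parietal positivity (peak +1.5 µV, centre
700 ms, sd 60 ms) on incongruent trials.  The negativity is multiplied by
`max(0, 1 − 0.3 · aptitude)`, so more proficient learners show smaller
switch effects; that attenuation is what the N400-effect/proficiency
regression must recover with a negative slope.  The trial noise sd and the
congruency modulation were set so that a study-sized group's grand average
reproduces the injected condition ordering reliably; larger noise makes the
four-level ordering unrecoverable at n = 10 no matter the analysis.
Comprehension responses are generated for one third of trials with
per-subject accuracy `0.81 + 0.10·apt + N(0, 0.04)` clipped to [0.5, 0.98].

**Determinism.**  Every generator draws from
`numpy.random.default_rng([seed, stream, subject])`; identical configs give
byte-identical outputs and subjects can be regenerated in isolation.

## Preprocessing conventions

* Sample indexing is 0-based; all intervals are half-open `[start, end)`.
* Filtering: zero-phase Butterworth, orders mapped from the quoted
  roll-offs at 6 dB/octave/order (high-pass order 2 at 0.1 Hz, low-pass
  order 8 at 30 Hz).  Forward–backward application doubles the effective
  slope; the quoted roll-off is therefore a lower bound.
* Artifact criteria: (a) |x[t] − x[t−1]| > 50 µV flags sample t; (b) any
  200-ms window with peak-to-peak > 200 µV flags the whole window; (c) any
  100-ms window with peak-to-peak < 0.5 µV flags the whole window (the
  flatline reading of the "activity not lower than 0.5 µV" criterion,
  matching the commercial software's low-activity rejector).  Windows slide
  sample-by-sample (every enclosing window is checked), the strictly more
  conservative mode; disjoint-block mode is available via config.  Flags
  are padded by 200 ms per side and merged.  Window lengths are
  `round(ms·fs/1000)` samples; peak-to-peak is computed in float64 so the
  vectorized implementation is bit-identical to a naive scan.
* Interpolation: channels whose flagged fraction exceeds 10% are replaced
  by the unweighted mean of their 4 nearest good channels (Euclidean
  distance on montage positions); more than 5 qualifying channels aborts
  the run.  The montage is the BioSemi-128 template (via mne) at 128
  channels, otherwise a deterministic Fibonacci hemisphere.
* Pipeline order is fixed: interpolate, then average-reference (the two
  only commute when nothing is replaced).
* The Experiment-1 composition slices the two eyes-closed segments first
  and runs the chain per segment (interpolation decision pooled across
  segments); only eyes-closed data are analysed, and the 5-s adjustment
  trim is applied at epoching, where it also absorbs filter edge effects.
* Epoch lengths are `round(epoch_s · fs)` with round-half-to-even; 2-s
  epochs at 50% overlap tile each segment (a clean 110-s segment yields
  109 epochs).
* Ocular correction is a pluggable contract (blink-window variance on
  frontal channels reduced ≥ 50%, data outside detected windows changed
  ≤ 10%).  The default backend is template regression confined to detected
  blink windows: a proxy (low-passed mean of frontal channels) defines the
  windows, and each channel's projection on the demeaned proxy is removed
  within them — deterministic, and exactly identity elsewhere.  A FastICA
  backend is available; ICA internals are out of scope.  The study's
  semi-automatic review step is replaced by the fully automatic criteria
  for reproducibility.

## Spectral conventions

One-sided per-epoch periodograms, Hann taper by default with coherent-gain
compensation (`--taper none` available), no detrending, scaled so a
sinusoid of amplitude A yields A²/2 at its bin and (taper-free) the bins
sum to the mean square (Parseval, verified to < 1%).  Band statistic is
the **mean** over bins with centre frequency in the half-open `(low,
high]` band (12.5 Hz is alpha, not beta1); pooling averages member
channels before the log10 transform (log-after-pooling; the alternative is
not distinguishable from the source description).  50%-overlap epochs are
averaged without extra weighting.  Gamma (30–40 Hz) is off by default
because it lies above the default 30 Hz low-pass; enabling it is only
meaningful with a wider filter, and the config makes that explicit.

## Statistical conventions

* Spearman correlations use average ranks, Fisher-z CIs, and
  Benjamini–Hochberg adjustment across all pool × band cells; undefined
  cells (constant columns) are excluded from the family.
* ICC(1) is the one-way ANOVA form `(MSB − MSW)/(MSB + (k̄ − 1)MSW)` with
  the harmonic-mean-adjusted group size; negative values are reported as
  computed.
* Mixed models are random-intercept models estimated by ML (not REML) so
  nested comparisons remain valid; CIs are Wald intervals on t quantiles
  with residual-df approximation (n_obs − n_fixed) — quoted t statistics
  are therefore approximate, and no exact small-sample df convention is
  attempted.  Marginal pseudo-R² = var(Xβ̂)/(var(Xβ̂) + σ²_subject +
  σ²_residual).  Treatment coding with alpha as the reference band;
  electrode pools enter as replicate rows (not averaged), which is what
  makes the ICC-based justification of the random intercept meaningful.
  A boundary fit (subject variance → 0) falls back to OLS and is flagged,
  never silent.
* CorP is computed on the composite percentile with max = 100, and the
  learning-gain outcome is z-scored over the analysed subjects.
* Wilcoxon signed-rank: zero differences dropped, W+ reported, exact
  p-values where scipy's exact path applies; effect size is matched-rank
  r = |Z|/√n by default (the rank-biserial correlation via flag — the
  source's effect-size convention is not recoverable, so both common ones
  are offered); the CI is the Hodges–Lehmann interval from Walsh averages
  with exact signed-rank critical values up to n = 60, normal
  approximation beyond.
* The N400 effect is no-switch minus switch (positive for the canonical
  switch negativity), averaged over congruency; regressions on proficiency
  use standardized variables, so slopes are comparable across replicates.
* Peak latencies (descriptive only) are window-restricted extrema of the
  pool-mean waveform.

## Validation design and problem sizes

The acceptance suite exercises, at sizes chosen to keep the full test run
in minutes:

* exact worked examples (CorP, Wilcoxon 2¹⁰ enumeration, epoch counts of
  the 8-min protocol);
* a brute-force DFT oracle for the periodogram normalization;
* exact interval equivalence of the vectorized artifact detector with a
  naive sample-by-sample scan on 100 random artifact-bearing traces;
* full-pipeline recovery of the beta1→gain link: 100 replicates of 40
  subjects at 16 channels with 2 × 60 s eyes-closed segments (a reduced
  montage and shortened rest protocol: both reductions *lower* the SNR of
  the power estimates relative to the full protocol, so they are
  conservative for a recovery claim), requiring the CorP × beta1
  interaction to be positive in ≥ 80% of replicates;
* CI calibration under the null at the band-power level (the generative
  model of the fitted LMM with the link removed, 1000 replicates of 10
  subjects) — full-EEG replication at that count would add nothing to the
  calibration question and is computationally out of proportion;
* ERP recovery: 100 replicates of 10 subjects for the sign of the
  N400-effect/proficiency slope, and a noise-free single run for the LPC
  congruency effect against the closed-form template mean.

## What passing tests do and do not show

The generator produces stationary oscillators with fixed carriers, spatially
uniform pool amplitudes, white-across-channels pink noise, and stylized
artifacts.  Real resting EEG has non-stationary band power, correlated
channel noise through volume conduction, alpha reactivity to eye state, and
far messier ocular activity; real ERP components vary in latency and
topography across subjects.  Passing recovery tests therefore shows the
*analysis chain* is correct and calibrated under its stated assumptions —
not that the study's empirical effect sizes would replicate.  The study's
own coefficients are not reproducible here because its recordings are not
public; nothing in the test suite asserts them.

## Known limitations

* The published stimulus quotas (each noun four times, each verb twice,
  80 two-noun sentences) are arithmetically over-constrained
  (80 × 2 = 160 noun slots ≠ 20 × 4); the generator uses balanced
  round-robin quotas with collision shifts instead, and placeholder
  course-level lexicons.
* The published Parietal-pool channel list names two frontopolar labels
  (D16/D17) alongside centro-parietal sites; the listed labels are used
  verbatim and the inconsistency is noted here.  Resting-pool memberships
  are only depicted schematically in the source material and are assigned
  geometrically; both are configurable.
* EDF can be read but not written (BrainVision is the native output
  format).
* Ocular correction by windowed template regression can leave small
  discontinuities at window edges; these fall inside the ±200 ms artifact
  padding in practice.
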