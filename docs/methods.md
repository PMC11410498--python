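# Methods

This note documents the statistical procedures implemented in `herdrhythm`,
the choices made where the underlying methodology admits more than one
reading, and what the synthetic tests do and do not demonstrate.

## Timeline and cleaning

All analysis happens on a single UTC timeline. Input timestamps are local
(CET/CEST by default) and converted first; "days" downstream are civil days
on the UTC axis. A continuously logging accelerometer emits one sample per
UTC minute, so daylight-saving transitions change labels only — no minute is
duplicated or dropped.

Cleaning rules, in order:

* **Zero-run rule.** A day is unreliable if either the step or the
  motion-index channel is zero for *strictly more than* 12 h. A zero-run may
  span midnight; the run is then attributed to every day it touches. This is
  the conservative reading — the alternative (per-day clipping of runs)
  would keep a day that carries 12 h of a 20-h outage.
* **Edge days.** The first and last calendar day of a recording are dropped
  (device mounted/removed mid-day), as are days with fewer than 1440
  minutes. Edge trimming is applied once: a series already marked clean is
  not re-trimmed, which makes cleaning idempotent.
* **Analysis window.** Only days with 59–83 days in milk are analyzed;
  datasets with fewer than 15 such days are excluded entirely.

15-min resampling sums the 15 constituent minutes and anchors bins at UTC
midnight (:00/:15/:30/:45). The anchor phase is a convention; it is
configurable at the reader level and documented here because spectral power
at harmonic frequencies is invariant to it on complete windows.

Steps are carried through the pipeline, but only the motion index feeds the
DFC and DI.

## Spectral estimation

Each 7-day window of 15-min bins (possibly with whole days missing) is
analyzed with a Lomb–Scargle periodogram — the least-squares spectral
estimator that remains valid on gapped sampling — after mean subtraction,
with no further detrending. Power uses the standard normalization
`z(f) = 1 − SSR(f)/SS₀ ∈ [0, 1]`, the fractional residual-variance
reduction of a per-frequency sinusoid fit. The implementation delegates to
`scipy.signal.lombscargle(normalize=True)`; the test suite pins it against
a brute-force per-frequency least-squares oracle at 1e-8 relative.

**Frequency grid.** A Fourier-style grid `k/(168 h), k = 1 … 336` (up to
the Nyquist frequency of 15-min sampling). On this grid every harmonic
period `24/n h` is an exact grid point (`k = 7n`, n ≤ 48), which makes the
harmonic/non-harmonic classification exact rather than tolerance-based.
Oversampling is configurable; off-grid use falls back to matching within
half a grid step.

**Significance.** Per frequency, the Baluev (2008) aliasing-free upper
bound on the false-alarm probability of a peak of that height anywhere on
the searched range:

    FAP(z) ≤ 1 − (1 − (1−z)^((N−3)/2)) · exp(−τ(z)),
    τ(z) = γ · f_max √(4π·var(t)) · (1−z)^((N−4)/2) · √((N−1) z / 2),
    γ = √(2/(N−1)) · Γ((N−1)/2) / Γ((N−2)/2).

Being an upper bound on the FAP, it is conservative: over 1,000 simulated
white-noise windows the empirical rate of min-FAP ≤ 0.05 is ≈ 0.02 (the
acceptance suite re-measures this). Applying the *global* bound to every
grid frequency (not only the peak) makes the "set of significant
frequencies" well-defined and errs further on the conservative side.
Frequencies with FAP ≤ α (default 0.05) count as significant. Windows with
fewer than 8 samples or zero variance are flagged "no rhythm evaluable".

## Degree of functional coupling

Per window, DFC = (sum of *power* over significant harmonic frequencies) /
(sum of power over all significant frequencies). Two open points in the
literature are resolved as follows and treated as this package's
conventions:

* **Power, not amplitude, sums.** The functional-coupling literature has
  described both; spectral power is used here because it is the quantity
  the significance bound is formulated for.
* **Degenerate windows.** No significant frequency means the ratio is 0/0.
  Expressing no significant rhythm is read, biologically, like expressing
  no harmonic rhythm: the window gets DFC = 0 and a `degenerate` flag —
  *before* any median computation, so degenerate windows participate in the
  median-split statistics.

Windows slide by one day and are labeled by their last day (the first day
that "has" 7 days of history). Windows with fewer than 5 of 7 retained days
are skipped, not zeroed — degeneracy is reserved for "no significant
rhythm", absence of data is not evidence of arrhythmia.

**Median split.** The DFC distribution in well-entrained herds piles up at
1, so the modeled outcome is binary: 1 iff DFC = 1 (within 1e-9). The
empirical median is returned and a warning raised when it is not 1, since
the split is only meaningful under that precondition.

**Harmonic catalog.** Significant harmonic periods are counted per
treatment group, reported as proportions per period length (rounded to one
decimal, e.g. 3.4 h for 24/7 h) and as average periods per cow.

## Diurnality index

Day runs from the end of morning milking to the start of evening milking
(≈ 7–9 h), night from the end of evening milking to the next morning start
(≈ 10–11 h); the milking intervals belong to neither. Boundaries use the
sliding mean of milking times over the 7-day window **centered** on the day
(the day ± 3 neighbors), computed on the UTC timeline — so when milking is
held at local clock time across a DST change, the boundaries glide by
≤ 60/7 min per day instead of jumping an hour. Whether the original
boundary smoothing was centered or trailing is not documented anywhere we
could find; centered is this package's choice (the forward-looking window
is reserved for the deviation covariate, where it is explicit).

Because day and night have unequal lengths, activity is converted to
per-hour *rates* before the contrast: `DI = (R_d − R_n)/(R_d + R_n)`.
Without duration normalization DI = 0 would not mean "no preference" — this
is flagged prominently because the index is sometimes written with raw
sums. DI is undefined when both rates are zero (day skipped with warning).

**Milking deviation.** deviation(d) = start(d) − mean(start(d … d+6)),
minutes, separately for morning and evening, missing when the forward
window is incomplete. Adding a constant to all starts leaves deviations
unchanged; a DST step enters each deviation only transiently — which is
precisely why the covariate, not the raw milking time, carries the
short-term information.

## Mixed models

* **DFC model** — binomial (logit): `dfc_binary ~ treatment + estrus +
  milk_dev_evening + (1 | cluster)` with NOC/diestrus reference levels and
  cluster = cow dataset (cow × lactation). Fitted by maximum likelihood
  with **adaptive Gauss–Hermite quadrature** (15 nodes centered on each
  cluster's posterior mode — the nAGQ scheme): no installed Python package
  fits conditional binomial GLMMs by ML, so the fitter is implemented here
  and cross-checked in the test suite against R's glmmTMB (Laplace) on a
  common frame, agreeing to ≲ 0.05 on all coefficients. Wald 95% CIs on the
  link scale, exponentiated to odds ratios.
* **DI model** — Gaussian: `di ~ treatment + estrus + parity +
  (1 | cluster)`, REML via statsmodels `MixedLM`, after the 1.5-IQR outlier
  filter (quartiles by linear interpolation, R type 7). Estimated marginal
  means per treatment are computed at diestrus with parity averaged at
  equal weights.

Clusters whose binary outcome never varies are excluded before the DFC fit
by default (they carry no within-cluster information, and dropping them
mirrors standard practice for this design); the exclusions are logged. The
recovery harness fits with `exclude_novar=False`, because the exclusion
truncates the random-effect distribution and visibly biases the intercept
and variance when the cluster SD is large — the estrus effect is robust to
either choice.

**AR(1).** Day-to-day serial correlation within a cow belongs in both
models but is not expressible in the chosen backends (MixedLM has no
residual correlation structure; the GHQ fitter integrates one random
intercept). It is therefore omitted, with a note attached to every fitted
result. The harness accepts `ar1_rho`/`ar1_sd` to inject serial latent
noise into simulated frames and quantify the impact: Gaussian fixed effects
remain unbiased under ignored serial correlation (their SEs grow mildly
optimistic); the logistic effects attenuate by ≈ `1/√(1 + 0.346·σ²_extra)`
for unmodeled latent variance, i.e. ≈ 4% at σ = 0.5. Designs with constant
or collinear predictors (single-arm subsets, no estrus days) have those
columns dropped from the fit rather than imputed, with a note.

## Synthetic herd generator

Per-minute activity is `max(0, step + harmonics + milking bumps + noise)`:

* **Day/night step** at rates `2·B·f` (day) and `2·B·(1−f)` (night), with
  baseline B = 20 MI/min and diurnal share f = 0.55, giving a true
  rate-based DI of `2f − 1 = 0.10` — the level a moderately diurnal
  lactating herd shows. Milking intervals get the mean rate.
* **Cosine components** at configured periods, default amplitudes
  {24 h: 6, 12 h: 3, 4.8 h: 5, 3.43 h: 8} MI/min with cow-specific phases —
  the 24/7 h component dominant, matching the short activity/rest
  alternation (~1.7 h bouts) lactating cows actually show.
* **Milking bumps**: symmetric triangular peaks of 30-min width and 15
  MI/min height at each (jittered, SD 5 min) milking start — cows get up
  and queue.
* **Noise**: additive Gaussian, SD 4 MI/min, rectified with everything
  else.
* **Estrus** (probability 0.6 of one day per cow in the span): cosine
  amplitudes × 0.1 and noise × 2 on that day. This is a deliberately simple
  stand-in producing rhythm loss; no quantitative description of real
  estrus-day activity shape was available to emulate, and no behavioral
  realism is claimed.
* **Dropout**: with probability 0.01 per cow-day, a zero-run of 2–16 h in
  both channels — long runs trigger the 12-h exclusion rule.

Group sizes default to 36/25/18 (NOC/DTC/WDC) cow datasets and the span
covers days-in-milk 58–84, so 25 analysis days remain per cow after edge
trimming — ≈ 1.7k cow-days, the scale of the motivating design. One root
seed; per-cow child streams are derived by stable hashing (CRC-32) of the
cow id, so adding a cow never perturbs existing cows, and identical
scenarios reproduce bit-for-bit.

**What the generator does not emulate:** treatment effects on rhythm (all
groups share the same generating process — the pipeline should and does
find no contact-time effect), calf-side behavior, weather/season, estrus
hyperactivity (only arrhythmia), health events, or device-specific noise
spectra. Passing tests therefore demonstrate the *correctness of the
computational chain* and the recoverability of known effects at study
scale, not biological claims about real herds.

The model-recovery harness simulates outcome frames directly from the
fitted model classes (cluster variance 9.21 for the binomial model, 0.001
for the Gaussian; residual SD 0.25 for DI; an estrus odds ratio of 0.10 and
DI shift of +0.12 as generating truths) and refits them 100×; acceptance
requires < 25% bias on the estrus log-odds, the Gaussian estrus estimate
within ±2 SE on average, and ≥ 85% CI coverage.

## Numerical details and degenerate inputs

* Normalized power is clipped to [0, 1]; power exactly 1 (noiseless single
  tone) is accepted and maps to FAP 0.
* The Nyquist gridpoint of an evenly sampled window is degenerate for the
  sine basis; scipy's τ-shifted formula handles it, the least-squares test
  oracle excludes it.
* Logistic likelihood evaluations use `logaddexp`; cluster-mode Newton
  steps are clipped to ±4 per iteration; `log σ` is capped at 5.
* `MixedLM` falls back to Powell when the gradient optimizers fail at the
  zero-variance boundary.
* Sizes used by the default test/acceptance runs: 672-sample windows, 336
  grid frequencies, 1,000 null windows for the FAP calibration, 100
  recovery replicates, a 12-cow demo herd for determinism checks.

## Known limitations

* No AR(1) serial structure in the fitted models (see above); no AICc-based
  model selection, residual-diagnostic simulation, or post-hoc power
  machinery — the two final models are fitted directly.
* The per-frequency Baluev bound is conservative; counts of significant
  frequencies are best compared within, not across, sampling designs.
* The estrus-day coding accepts any precomputed flag; the generator codes
  single days.
* DFC conventions (power vs amplitude sums; when degenerate windows enter
  the median) follow the choices documented above; results are comparable
  across studies only under the same conventions.
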