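# herdrhythm

Activity-rhythm analysis for dairy-herd accelerometer data.

Leg-mounted 3-axis accelerometers on dairy cows deliver a per-minute step
count and a *motion index* (MI). Chronobiologists and precision-livestock
researchers use such records to ask whether management factors — here,
daily cow–calf contact time (no contact **NOC**, daytime contact **DTC**,
whole-day contact **WDC**) — disturb the cows' circadian and ultradian
activity rhythms, and how strongly estrus and shifts of the milking routine
do. `herdrhythm` packages that analysis end to end:

1. **Cleaning** — conversion of local CET/CEST timestamps (incl. DST
   transitions) to a single UTC timeline; exclusion of days with a zero-run
   longer than 12 h in either channel, of first/last/incomplete days, and of
   cow datasets with fewer than 15 days inside the 59–83 days-in-milk
   window; resampling to 15-min bins by summation.
2. **Spectral estimation** — Lomb–Scargle periodogram of each sliding 7-day
   window (tolerates missing days), standard normalization
   `z(f) = 1 − SSR(f)/SS₀ ∈ [0, 1]`, with the Baluev (2008) aliasing-free
   upper bound on the per-frequency false-alarm probability; frequencies
   with FAP ≤ 0.05 count as significant.
3. **Degree of functional coupling (DFC)** — per window,

   `DFC = Σ power over significant harmonic frequencies / Σ power over all
   significant frequencies`,

   where *harmonic* periods are 24/n h (24, 12, 8, 6, 4.8, … h). DFC = 1
   means every significant rhythm is synchronized with the 24-h day; a
   window with no significant frequency is assigned DFC = 0 (degenerate
   flag). Because the DFC distribution piles up at 1, it is binarized by a
   median split (1 iff DFC = 1) before modeling.
4. **Diurnality index (DI)** — day = span between (7-day sliding mean)
   morning-milking end and evening-milking start; night = evening-milking
   end to next morning start. With duration-normalized rates R_d, R_n:
   `DI = (R_d − R_n)/(R_d + R_n) ∈ [−1, 1]`.
5. **Milking-start deviation** — per day, that day's milking start minus
   the mean start over the day and the following 6 days (minutes), the
   short-term covariate that remains informative when milking is held at
   local clock time across DST changes.
6. **Mixed models** — binomial (logit) mixed model for the median-split DFC
   (fixed: contact time, estrus, evening milking deviation; random
   intercept per cow dataset; maximum likelihood by adaptive Gauss–Hermite
   quadrature) and a Gaussian mixed model for the 1.5-IQR-filtered DI
   (fixed: contact time, estrus, parity; REML via statsmodels `MixedLM`),
   with odds ratios / estimates, Wald 95% CIs, and estimated marginal
   means.
7. **Synthetic herd generator** — minute-level activity with configurable
   harmonic components, a day/night step targeting a diurnal share,
   milking-anchored activity peaks, estrus attenuation, sensor dropout, and
   per-cow reproducible RNG streams — so every stage is testable with known
   ground truth, plus a frame-level simulation harness that verifies the
   models recover their generating coefficients at study scale.

## Worked example

```python
from herdrhythm import RunConfig, run_pipeline

cfg = RunConfig(
    scenario=dict(n_cows_per_group={"NOC": 4, "DTC": 4, "WDC": 4}, days=27),
    seed=42, out_dir="demo_run",
)
res = run_pipeline(cfg)
print(len(res["dfc_records"]), res["di_records"]["di"].mean())
```

On this 12-cow demo the run prints/writes (excerpt):

```
DFC windows: 228   median DFC: 1.0   share DFC=1: 0.978
DI records:  238   mean DI: 0.112
harmonic periods per cow: DTC 76.0  NOC 76.0  WDC 76.0
most frequent harmonic period length: 3.4 h
```

Read: almost every 7-day window is fully coupled to the 24-h day (DFC = 1),
mean DI ≈ 0.11 indicates moderately diurnal activity (the generator's
diurnal share is 0.55, i.e. true DI 0.10), and the modal significant
harmonic period is 3.4 h (= 24/7 h, the generator's strongest ultradian
component). The same numbers land in `demo_run/` as tidy CSVs together with
exclusion logs and a `manifest.json`; rerunning with the same config and
seed reproduces them bit-for-bit.

The model-recovery harness exercises the inferential layer at study scale
(79 cow datasets, ~1.7k cow-days). For the binomial DFC model with a
generating estrus odds ratio of 0.10:

```python
from herdrhythm import recovery_study
print(recovery_study(n_reps=20, seed=1, model="dfc").round(3))
```

```
            term  truth  mean_estimate  sd_estimate  rel_bias  coverage
       intercept  1.191          1.168        0.560    -0.020      0.95
          estrus -2.303         -2.324        0.449    -0.009      1.00
...
```

i.e. the estrus log-odds (−2.303 = log 0.10) is recovered with under 1%
bias and nominal CI coverage.

There is also a CLI:

```sh
herdrhythm simulate --out tables --seed 1        # write the input CSVs
herdrhythm all --config run.yaml --out results   # full pipeline
```

## Layout

```
src/herdrhythm/
  activity_io.py     reading, validation, UTC conversion, cleaning, resampling
  spectral.py        Lomb-Scargle + Baluev false-alarm probabilities
  rhythm_metrics.py  DFC, sliding windows, median split, harmonic catalog
  diurnality.py      day/night windows, DI, milking-start deviation
  mixed_models.py    IQR filter, binomial/Gaussian mixed models, recovery harness
  synthetic_data.py  herd generator with ground truth
  pipeline.py, cli.py, plotting.py
```

See `docs/methods.md` for the modeling choices and their rationale.
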