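# Methods

## Measurement model

Each measurement cycle of the MOS array has three phases: 100 s of
stabilization in clean air, 200 s of exposure to the dough headspace, and
500 s of recovery, sampled at 1 Hz (800 samples; the phase durations, not a
rounded total, define the cycle length). The simulator uses the standard
first-order adsorption/desorption model for an n-type chemiresistor
responding to reducing gases: during exposure the resistance relaxes toward
R₀·(1 − A) with time constant τ_resp (default 20 s), and after the purge it
relaxes back toward R₀ with τ_rec (default 60 s). A ∈ [0, 1) is the
fractional resistance drop at saturation; A ≥ 1 is rejected because the
resistance would cross zero. The model captures the qualitative shape of a
real calibration curve (baseline → drop → recovery); it does not model gas
diffusion, surface chemistry, humidity or temperature, and its scales are
free parameters — no numeric dough-headspace amplitudes are published for
this device class.

Two disturbances exercise the preprocessing: a linear baseline drift
(fraction of R₀ per second, default 0) and multiplicative log-normal noise
with coefficient of variation `noise_cv` (default 0.05). The log-normal
multiplier has mean one, so the expected curve is unbiased, and resistance
stays strictly positive for every valid parameter set.

## Study conditions encoded in the generator

* **Design**: triplicate dough samples per condition, 10 replicate cycles
  per sample — the standard protocol for this kind of study.
* **Phase effect**: base amplitudes A_PRE = 0.2, A_POST = 0.5,
  A_CONTINUOUS = 0.35. Fermentation increases the emitted volatile load,
  so POST > PRE by construction.
* **Flour effect**: flours modulate the *pattern* across sensor materials
  rather than the overall amplitude — Pd/Au factors (0.7, 1.3) for W200,
  (1.0, 1.0) for W250, (1.3, 0.7) for W390, SnO₂ fixed at 1.0. This keeps
  the PRE/POST base amplitudes at exactly 0.2/0.5 for every flour while
  making the three flours separable in continuous monitoring, mirroring how
  doped MOS elements achieve selectivity.
* **Intra-class variance ordering**: the between-sample amplitude spread is
  `amplitude_cv` = 0.15 (W200) > 0.10 (W250) > 0.05 (W390) — the weak
  flour ferments least reproducibly. One amplitude factor is drawn per
  sample and shared across its replicates and sensors; a separate
  `replicate_cv` = 0.02 models cycle-to-cycle jitter. Putting the large
  spread at the sample level (not the replicate level) is what makes the
  10% replicate-uncertainty gate meaningful: replicate scatter reflects
  instrument repeatability, sample scatter reflects biology.
* **Seeding**: one global seed fans out to per-(cell, sample, replicate,
  sensor) streams through `SeedSequence` spawn keys, so datasets are
  bit-reproducible and insensitive to generation order.

What the generator does **not** emulate: sensor poisoning and long-term
drift across cycles, humidity/temperature covariates, correlated noise
between sensors, compound-level response chemistry. Passing tests therefore
demonstrate that the analysis chain is correct and leak-free under the
stated statistical structure, not that a physical device achieves these
accuracies.

## Preprocessing

Normalization divides by the baseline R₀; the default estimate is the mean
of the stabilization segment (robust to noise), with the literal first
sample available as `first_sample`. Normalization precedes smoothing.
Smoothing is a Savitzky–Golay filter, default window 31 s and polyorder 3 —
typical for 1 Hz chemiresistor data — using polynomial edge fitting so the
output length equals the input and polynomials up to the polyorder pass
through unchanged. Segmentation assigns half-open index ranges
[0, 100), [100, 300), [300, end) at 1 Hz, scaled by the sampling rate.

## Features

Fifteen descriptors per trace: Sharpe indices (mean / sample SD, ddof 1) of
the leading and trailing 25% and 50% of samples; min/max derivative
(central differences, one-sided at the ends, on the smoothed response);
composite Simpson integral (with a single trapezoid patch when the interval
count is odd); excursion range ΔR = max − min; Σ ln(y) (the "sum of
logarithms" reading of the log feature; ln Σ y is not used); min; max; mean
of the last 60 samples; overall mean; difference between the last-five and
first-five averages; and SNR = overall mean / sample SD of the
stabilization segment (baseline noise, not whole-trace noise). Features are
computed per sensor on the normalized response. A zero-variance segment
(exactly noiseless data) makes a Sharpe index or the SNR undefined; those
emit a NaN sentinel that is imputed with the column median before
modelling rather than crashing the pipeline.

One caveat found during development: Savitzky–Golay smoothing overshoots at
the exposure-onset corner by ≈3.5% of A, inflating ΔR accordingly.
Amplitude recovery from ΔR is therefore exact (to ~10⁻⁹) on the normalized
*unsmoothed* response, and that is what the parameter-recovery checks use;
for classification the bias is irrelevant because it is common to all
classes.

## Quality control and classification

* **Replicate-uncertainty gate**: per (sample, sensor), the relative SD of
  the per-cycle response minima across replicates; a sample is excluded if
  any sensor exceeds 10%. Single-replicate samples pass with a warning.
* **Outlier screen**: an observation is flagged when any feature deviates
  more than 3 within-class sample SDs from its class mean (99.7% retention
  on Gaussian data, per feature). Flagged rows are excluded from modelling.
  With 45 features the familywise false-positive rate per observation is
  ≈ 1 − 0.997⁴⁵ ≈ 12%, so on clean synthetic data roughly 7 of 60 cycles
  are screened out; this is the intended behavior of a per-feature 3σ rule.
* **Feature ranking**: random-forest mean impurity decrease (default 300
  trees, √p features per split, seeded; rankings on ≤45 features are stable
  at this size), ties broken by column order. The default panel keeps the
  top 7 features.
* **LDA**: features are standardized (train-fold statistics), and the
  pooled covariance is stabilized with a 10⁻⁶ shrinkage toward the scaled
  identity. Cross-validation leaves one *sample* out, keeping all replicate
  cycles of a dough on one side of every split; feature ranking and scaling
  are re-fit inside each fold, so the held-out sample never influences
  selection ("in_fold"; an optimistically biased "pre" mode that ranks once
  on the full data exists for comparison). When `k_features` ≥ p, selection
  is a no-op and the forest is skipped. A C-class LDA has C−1 genuine
  discriminant axes; when a 3D view of a 2-class task is requested, axes 2
  and 3 are principal components of the within-class residuals and are
  labelled `PC*(suppl)` so the plot never misrepresents LDA's rank.

The permutation-null check shuffles class labels at the sample level and
re-runs the full cross-validation; the mean accuracy over 50 permutations
sits near chance (individual 3+3-sample permutations can hit 0 or 1 by
symmetry, so the mean, not each draw, is the meaningful statistic). The
null runs use 100 trees; the ranking is identical in distribution and the
50-fold repetition stays fast on one CPU.

## VOC inventory

Compound identity is the exact normalized string (lowercase, whitespace
collapsed) — no synonym resolution, since only counts matter. Presence is
binary; abundances are out of scope. The overlap partition satisfies
n_pre = n_common + n_pre_only, n_post = n_common + n_post_only,
n_total = n_common + n_pre_only + n_post_only (property-tested against a
brute-force oracle). The class census orders chemical classes by the
conventional abundance ranking alkanes → nitriles. The pooled 108-compound
total is the union over flours, consistent with the 34 + 38 + 36 overlap
arithmetic.

## Problem sizes

The shipped defaults run the full standard design (3 samples × 10 cycles
per condition). The end-to-end demo and determinism tests use a scaled
design (3 samples × 3 cycles, 60-tree forests), which exercises every stage
with identical code paths; accuracy on the default separation is 100% in
both regimes.

## Known limitations

* Simulator scales (baselines, time constants, amplitudes) are plausible
  but not calibrated to any published dough dataset — none exists.
* The QC gate treats the 10% uncertainty bound as a sample-exclusion rule;
  alternative readings (e.g., down-weighting) are not implemented.
* Drift correction beyond baseline normalization, humidity/temperature
  compensation, and classifiers other than the RF-ranker + LDA pair are out
  of scope.
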