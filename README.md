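# doughnose

Electronic-nose chemometrics for monitoring dough leavening.

During fermentation, baker's yeast (*Saccharomyces cerevisiae*) converts the
sugars in a dough into CO₂, ethanol and a broad spectrum of volatile organic
compounds (VOCs). An array of partially selective metal-oxide (MOS)
chemiresistors — SnO₂, SnO₂+Pd and SnO₂+Au — sampling the dough headspace
produces a joint response pattern that fingerprints this volatile mixture,
so the leavening state (pre- vs post-fermentation) and even the strength of
the flour (Chopin-alveograph W value: W200, W250, W390) can be read out
without touching the dough. `doughnose` is a reusable pipeline for that
analysis, aimed at e-nose and food-quality researchers:

* **simulate** labelled sensor-trace datasets with realistic measurement
  structure — 100 s stabilization + 200 s exposure + 500 s recovery cycles
  at 1 Hz, triplicate samples with 10 replicate cycles each, first-order
  adsorption/desorption kinetics, baseline drift and multiplicative noise —
  plus GC-MS-style compound presence tables (no public e-nose dough dataset
  exists, so every stage is testable from synthetic data);
* **preprocess**: baseline normalization to R/R₀, Savitzky–Golay smoothing,
  cycle-phase segmentation;
* **featurize**: 15 per-trace descriptors (Sharpe variability indices on
  leading/trailing signal fractions, derivative extrema, Simpson-rule
  integral, excursion range ΔR, log-sum, extrema, tail means,
  signal-to-noise ratio) × 3 sensors = 45 features per measurement cycle;
* **classify**: replicate-uncertainty gating (10% relative spread), 3σ
  within-class outlier screening, random-forest feature ranking and linear
  discriminant analysis (LDA) under leave-one-*sample*-out cross-validation,
  with ranking and scaling re-fit inside every fold;
* **summarize VOC inventories**: presence/absence set algebra over
  compound × condition tables (per-phase counts, PRE/POST overlap
  partition, per-chemical-class census).

## The model in brief

A sensor's clean-air resistance is R₀. On exposure to the headspace the
resistance of an n-type MOS element drops toward a saturation level set by
the class amplitude A ∈ [0, 1):

    R(t) = R₀ · (1 − A·(1 − e^{−(t−t_on)/τ_resp}))        (exposure)
    R(t) = R₀ · (1 − D·e^{−(t−t_off)/τ_rec}),  D = A·(1 − e^{−t_exp/τ_resp})   (recovery)

with linear baseline drift and mean-one multiplicative log-normal noise on
top. Fermented (POST) dough emits more reducing volatiles than unfermented
(PRE) dough, so A_POST > A_PRE; flour strength modulates the selectivity
pattern across the three sensor materials. LDA projects the selected
features onto at most C−1 discriminant axes for C classes; accuracy is
estimated by leave-one-sample-out cross-validation so replicate cycles of
one dough never straddle a train/test split.

## Worked example

```python
import doughnose as dn
from doughnose.chemometrics import classify_features

records = dn.simulate_dataset(
    [("W390", "PRE", 3, 10), ("W390", "POST", 3, 10)], seed=42
)
features = dn.featurize_dataset(records)
result, qc, counts = classify_features(
    features, task="prepost", flour="W390", seed=42
)
print(counts["observations_in"], counts["outliers_removed"], result.accuracy)
print(result.confusion)

table = dn.simulate_voc_table(34, 38, 36, seed=42)
print(dn.overlap_summary(table).as_dict())
```

prints

```
60 11 1.0
predicted  POST  PRE
true
POST         26    0
PRE           0   23
{'n_total': 108, 'n_pre': 72, 'n_post': 70, 'n_common': 34, 'n_pre_only': 38, 'n_post_only': 36}
```

60 measurement cycles (2 classes × 3 samples × 10 cycles) enter; no sample
fails the 10% replicate-uncertainty gate; 11 cycles are screened out by the
3σ within-class rule; the remaining 49 are classified PRE vs POST with
100% leave-one-sample-out accuracy. The VOC table built with 34 shared, 38
PRE-only and 36 POST-only compounds yields 72 pre-leavening and 70
post-leavening compounds out of 108 total — pure set arithmetic, checked
exactly.

The same chain is available from the shell:

```sh
doughnose demo --seed 42 --out out/           # full study end to end
doughnose simulate --out out/sim              # traces.csv + metadata.csv
doughnose featurize --in out/sim/traces.csv --meta out/sim/metadata.csv --out out/features.csv
doughnose classify --features out/features.csv --task prepost --flour W390 --out out/lda
doughnose voc-summary --in voc.csv --out out/voc.json
doughnose validate                            # echo resolved default config
```

`demo` writes `report.json`, `manifest.json`, per-task projection and
confusion CSVs, and is byte-for-byte reproducible given a seed.

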