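# fimsquant

Chromatography-free quantitation of complex herbal extracts by
flow-injection mass spectrometry (FI/MS) fingerprinting. The package is
aimed at analytical chemists who want a model-driven alternative to
targeted chromatographic assays for materials — such as *Cordyceps
sinensis* (C) and *Ganoderma lucidum* (G) extracts in beverage matrices —
whose marker compounds are not fully known: the whole positive-mode scan
spectrum (m/z 100–700, summed over the 0–1 min injection window) is the
analytical signal.

The workflow has two statistical cores:

**Principal m/z selection.** Channels whose max-normalized intensity
correlates with concentration at Pearson **r ≥ 0.995** across a
single-analyte calibration series become the analyte's feature set.

**Neural calibration.** A single hidden layer of exactly three tanh nodes
maps the feature intensities to concentration,

```
Hₖ = tanh(0.5·(aₖ + Σⱼ wₖⱼ zⱼ)),   k = 1, 2, 3
ŷ  = α·H₁ + β·H₂ + μ·H₃ + constant,     tanh(x) = (e²ˣ − 1)/(e²ˣ + 1)
```

with no penalty term, trained by multi-start quasi-Newton least squares and
selected by concentration-stratified K-fold cross-validation (the model
with the best validation statistics wins). Around the calibration sits the
full method-validation battery: spiking-level arithmetic
(level = conc × volume / weight, truncated), matrix
enhancement/suppression from predicted concentrations
((Cpm/Cps − 1)·100), spike recovery with intra-/inter-day RSDs, LOD/LOQ
from signal-to-noise against solvent blanks (S/N = 3 / 10), and a
noise-injection robustness check.

Because no public acquisitions exist for this assay, the package ships a
synthetic-spectra generator that emulates the study design (6 levels at
2–400 μg mL⁻¹ × 5 replicates × 3 sets × matrix-free/matrix-matched = 180
spectra; per-analyte disjoint linear channels; 2% replicate CV; −5…+3%
per-level matrix factors) with known ground truth, so every stage is
testable end-to-end. See `docs/methods.md` for the full model description
and design choices.

## Worked example

```python
from fimsquant import StudyConfig, run_calibration_study, run_recovery_study

cfg = StudyConfig(seed=42)                       # the emulated 180-spectrum design
report = run_calibration_study(cfg)
report = run_recovery_study(cfg, calibration=report)

print(report.models[("C", "matrix_matched")].selection.summary())
print(report.recovery_frame().to_string(index=False))
```

prints (abridged):

```
K-fold selection (K=5, ...): fold 3 selected
  training   RMSE%   0.1631   r² 0.999998
  validation RMSE%   0.3367   r² 0.999990
  pooled     RMSE%   0.2096   r² 0.999996

Neural calibration (1 hidden layer, 3 tanh nodes, no penalty)
==============================================================
observations:   72    features: 9
...
output: α=116.332  β=337.019  μ=-202.224  constant=150.378

analyte  spike_level  spike_level_mg_kg  mean_recovery  rsd_intra  rsd_inter  n
      C         50.0                 83     100.004900   1.144008   0.024297 60
      C        100.0                166     100.391509   0.796120   0.081999 60
      C        200.0                333     100.012137   0.053750   0.004738 60
      G         50.0                 83     100.137102   0.655014   0.029383 60
      G        100.0                166     100.069100   1.139320   0.008964 60
      G        200.0                333      99.994532   0.151184   0.024888 60
```

Reading this: the matrix-matched calibration for analyte C used 9 principal
channels and 72 of the 90 condition spectra for training; the selected
fold's held-out validation error is 0.34% of the mean concentration with
r² = 0.99999, i.e. the three-node network reproduces the linear working
range essentially exactly at 2% replicate noise. The recovery table is the
2-day spiked-blank study (spikes at 50/100/200 μg mL⁻¹ ≡ 83/166/333
mg kg⁻¹ through the 3:5 scaled-down extraction on 5 g): recoveries sit at
~100% with sub-1.2% intra-day RSDs because the matrix-matched models absorb
the generated matrix factors.

The same stages are scriptable from the shell:

```
fims simulate --out spectra.csv
fims featsel --input spectra.csv --analyte C --threshold 0.995 --out features.json
fims train --input spectra.csv --features features.json --k 5 --out model.json
fims run-all --outdir study_out --seed 42
```

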