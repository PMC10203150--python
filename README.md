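# delmep-toolkit

Automated annotation of **motor evoked potential (MEP) onset latencies**
from TMS-evoked EMG epochs.

When a transcranial magnetic stimulation (TMS) pulse is delivered over the
motor cortex, the target muscle's EMG shows an MEP whose *latency* — the
time from the pulse to the onset of the deflection, in ms — indexes
corticospinal conduction. Latencies are traditionally annotated by visual
inspection, which is slow and operator-dependent; a single study can
produce tens of thousands of epochs. This package automates the annotation
and provides everything needed to benchmark it:

* **MLP latency regressor** ("DELMEP"-style): each epoch is trimmed to the
  10–50 ms post-stimulus window (120 samples at 3 kHz), smoothed with a
  3-sample moving average, centered on the mean of its first 15 samples
  (5 ms), and min–max normalized to [0, 1]; a fully connected network
  120 → 30 → 30 → 1 with ReLU hidden units (4591 parameters) maps the
  normalized shape x ∈ [0,1]¹²⁰ to the latency L̂ in ms. Training minimizes
  the mean squared error with Adam (batch 32, ≤ 200 epochs, early stopping
  on a 10 % validation split). The preprocessing makes the prediction
  exactly invariant to a positive gain on the raw trace.
* **Four rule-based reference estimators**: Signal Hunter
  (argmaxᵢ |Δxᵢ| − SD(Δx), minus a 5-sample magic number), AHTE (first
  crossing of 10 % of max|x|, minus 5 samples), SHTE (same on x²), and
  Bigoni's derivative method (first sample of the longest run of
  consecutive positive derivatives of |x| before the peak; runs < 5
  samples discard the epoch).
* **Synthetic epoch generator** with exactly known onsets: biphasic
  gamma-envelope × sinusoid waveform, 10–500 Hz band-limited noise, slow
  baseline drift, multi-subject latency structure, and peak-to-peak
  amplitude strata (13 % ≤ 100 µV, 18 % 100–200 µV, 69 % > 200 µV).
* **Evaluation harnesses**: MAE, amplitude-stratified MAE, error
  fractions, 80/20 splits, within-subject 5-fold CV, leave-one-subject-out
  CV, and multi-estimator comparison on the common kept-trace set.

See `docs/methods.md` for the model and generator details.

## Worked example

```python
from delmep import (SyntheticConfig, generate_dataset, split_train_test,
                    ModelSpec, stratify_errors, bigoni_latency, trim)
from delmep.model import fit_on_dataset, annotate_dataset

cfg = SyntheticConfig(n_subjects=9, traces_per_subject=300, seed=7)
ds = generate_dataset(cfg)                      # 2700 annotated epochs
train_ds, test_ds = split_train_test(ds, ratio=0.8, seed=7)

model = fit_on_dataset(train_ds, ModelSpec(seed=7))
report = stratify_errors(annotate_dataset(model, test_ds), test_ds)
print(f"held-out MAE: {report.mae_ms:.2f} ms on n={report.n_total} epochs")
print("per stratum :", {k: round(v, 2) for k, v in report.mae_by_class.items()})
print(f"|error| < 1 ms: {100 * report.frac_err_below[1.0]:.0f}% of epochs")

est = bigoni_latency(trim(ds.traces["s00_t0000"]), fs_hz=3000.0)
truth = ds.annotations["s00_t0000"].latency_ms
print(f"Bigoni on one epoch: {est.latency_ms:.2f} ms (truth {truth:.2f} ms)")
```

prints

```
held-out MAE: 0.31 ms on n=540 epochs
per stratum : {'low': 0.9, 'medium': 0.29, 'high': 0.18}
|error| < 1 ms: 94% of epochs
Bigoni on one epoch: 24.00 ms (truth 24.82 ms)
```

The held-out MAE is the mean |L̂ − L| against the generator's exact onset
parameters; the per-stratum numbers show the accuracy declining with the
signal-to-noise ratio of the epoch (low-amplitude MEPs, V_PP ≤ 100 µV, are
the hard regime). The trained network beats the rule-based estimators on
exactly this stratum.

The same pipeline is available from the shell:

```sh
delmep simulate --seed 1 --meta meta.csv --samples samples.csv
delmep train    --seed 1 --meta meta.csv --samples samples.csv --model-out model.json
delmep annotate --method delmep --model model.json \
                --meta meta.csv --samples samples.csv --out est_delmep.csv
delmep annotate --method bigoni --meta meta.csv --samples samples.csv --out est_bigoni.csv
delmep evaluate --meta meta.csv --samples samples.csv \
                --estimates est_delmep.csv --estimates est_bigoni.csv --out report.csv
delmep crossval --mode loso --seed 1 --meta meta.csv --samples samples.csv --out loso.csv
```

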