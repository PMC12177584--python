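# flimdose

Dosage regression from chlorophyll-*a* fluorescence decay curves.

## The problem

Microalgae under heavy-metal stress change the decay kinetics of their
spontaneous chlorophyll-*a* fluorescence: the effective lifetime of the
emission shortens as the photosynthetic apparatus is damaged.
Fluorescence lifetime imaging (FLIM) with time-correlated single photon
counting (TCSPC) records, per cell, a decay curve — photon counts versus
time after the excitation pulse, a pulse-shaped rise followed by a
near-exponential decay.  `flimdose` asks the inverse question: **given
only the shape of a cell's decay curve, how much Cu(II) stress has it
received?**  Stress is quantified as the *dosage*
d = concentration × exposure time (µg mL⁻¹ h).

The package is aimed at people analysing single-cell FLIM screens —
curated decay curves in, interpretable dosage predictions and feature
rankings out.  Because raw microscope data are bulky and rarely
shareable, a synthetic decay-curve generator with known ground truth
stands in for the instrument, so the whole pipeline is testable offline.

## The method

1. **Curation** (`flimdose.dataset`) — decay curves are exchanged as a
   JSON file (one object per record: sample id, time grid in ns, photon
   counts, date, exposure in h, concentration in µg mL⁻¹, cell id);
   acquisitions of slightly heterogeneous length are conformed by
   trimming every curve to its first 1643 points (Δt = 0.008 ns).
2. **Featurization** (`flimdose.features`) — each curve collapses to
   seven scalars: the photon-count mean, standard deviation, skewness,
   maximum, and time-of-maximum, plus the decay rate *b* and offset *c*
   of a least-squares fit of

   f(t) = a·exp(−b·t) + c

   to the decaying tail below 95 % of the peak.  Pairwise products of
   the 7 base features add 21 interaction columns (28 total).
3. **Regression suite** (`flimdose.regression`) — linear (`Lin`), ridge
   (`Rid`), random-forest (`For`) and gradient-boosting (`GBR`)
   regressors under a seeded protocol: 80/20 stratified train/test
   split, 5-fold stratified cross-validation repeated 10 times on the
   training share (strata from the binned continuous target), R² and
   MAE per fold, predictions clipped at zero.  Feature relevance is read
   from the forest's Gini importances.
4. **Neural baselines** (`flimdose.neural`) — a fully connected net on
   the 7 standardized features (80 hidden ReLU units, rectified output)
   and a 1-D CNN on the raw count series, trained with AdamW
   (lr 0.0035), MSE loss and early stopping.  Implemented as a compact,
   fully deterministic numpy trainer.
5. **Synthetic data** (`flimdose.synthetic`) — a 6-concentration ×
   5-exposure × 10-cell design; curves are exponentially modified
   Gaussians (exponential decay convolved with a Gaussian instrument
   response), the lifetime follows a saturating dose response
   τ(d) = τ_s + (τ_h − τ_s)·e^(−d/d₀), with lognormal cell-to-cell
   variability and Poisson counting noise.

## Worked example

```python
from flimdose import (GeneratorConfig, conform_lengths, generate_dataset,
                      run_dosage_experiment)

ds, truth = generate_dataset(GeneratorConfig(seed=1))
ds = conform_lengths(ds)
scores, importances, detail = run_dosage_experiment(ds, seed=1)
print(scores.round(3).to_string(index=False))
```

prints

```
model  r2_mean  r2_std  mae_mean  mae_std  test_r2  test_mae
  Lin    0.884   0.034  3806.013  549.104    0.855  3585.269
  Rid    0.879   0.034  3898.923  447.867    0.858  4028.174
  For    0.885   0.031  3746.684  442.480    0.833  3970.120
  GBR    0.866   0.038  3975.781  426.151    0.829  4129.051
```

— per model, the fold-averaged cross-validation R²/MAE with their
spread over the 50 folds, and the scores on the 60 held-out test
records.  MAE is in µg mL⁻¹ h against dosages spanning 0–67 200.  The
top Gini importances for the same run are `fit_rate` (0.181),
`counts_tix*fit_rate` (0.164) and `counts_skew` (0.156): the tail decay
rate — the reciprocal of the effective lifetime — carries the dosage
signal, as it should by construction of the generator.

The scripts in `examples/` walk through each capability (simulation,
featurization, the regression suite, the neural baselines, the
fixed-label screen) and print annotated output.

## Command line

```sh
flimdose simulate  --seed 1 --out-dir run/
flimdose featurize --dataset run/dataset.json --out-dir run/
flimdose evaluate  --dataset run/dataset.json --models Lin,Rid,For,GBR,NN --out-dir run/
flimdose report    --out-dir run/        # figures from the evaluate CSVs
```

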