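# Methods

This note records the models, conventions and design choices behind
`flimdose`, in the spirit of a model-documentation page: what is
computed, under which assumptions, with which defaults, and what the
synthetic benchmark does and does not demonstrate.

## Data model

A record is one cell's aggregated TCSPC decay curve: the photon counts
of all pixels of a FLIM map summed per time bin, on a uniform grid
(default Δt = 0.008 ns, ~13 ns span).  Labels are the Cu(II)
concentration (µg mL⁻¹), the exposure time (h) and a cell serial
number; the regression target of interest is their product, the dosage
(µg mL⁻¹ h), which unifies the two stress axes into one physically
meaningful scalar.

Curves from an acquisition series differ slightly in length; they are
conformed by **prefix trimming** to a common 1643 points, never by
resampling — the discarded samples sit in the far exponential tail where
the signal has decayed to baseline, so the statistical features are
unaffected.

## Featurization

Five moments/extremes of the count array: mean, standard deviation,
skewness, maximum and time of the (first) maximum.  Conventions: the
**population** standard deviation (divisor *n*) and the **biased
Fisher–Pearson skewness** g₁ = m₃/m₂^{3/2}, the common defaults of
scientific toolkits.  With 1643-point curves the estimator variant is
immaterial (relative difference ~n⁻¹), but it is fixed and tested so
results are exactly reproducible.  Exactly constant curves get std = 0
and skew defined as 0 (a logged guard).

The tail of the curve — from the first sample after the peak that drops
below 95 % of the maximum — is fitted with

    f(t) = a·exp(−b·t) + c

by bounded least squares (trust-region reflective, b ≥ 0), on the raw
time coordinates (no shift of the tail origin).  Initialization is
data-driven: c₀ = mean of the last 5 % of tail samples, a₀ = first tail
value − c₀ (floored positive), b₀ from a log-linear regression of the
offset-subtracted counts.  Only *b* (`fit_rate`, ns⁻¹, the reciprocal
of an effective lifetime) and *c* (`fit_const`) are kept; the amplitude
*a* duplicates scale information already carried by the mean and the
maximum.  A non-converged or degenerate fit (constant tail, vanishing
amplitude) drops the record from the feature table with a logged count;
strict mode raises instead.

Interactions are the products of every **unordered pair of distinct**
base features — 21 columns named `x*y` — no squares: squared columns
would only duplicate scale information, while cross-products let linear
models express simple curvature.  Counts are used unscaled by default;
a per-record max-normalization flag exists for emissivity-corrected
analyses.

Standardization (for the neural models) is per column, (x − μ)/σ with
population σ, with statistics computed on the training rows only and
applied everywhere; a constant column is an error naming the column.

## Evaluation protocol

All models share one protocol: 20 % of records (rounded) are held out
by a stratified split; on the remaining 80 %, stratified K-fold
cross-validation (K = 5) is repeated 10 times with reshuffling, scoring
R² and MAE on each validation fold; means and standard deviations are
taken over the 50 fold scores; the final test scores come from the
held-out share.  Since the targets are continuous, strata are defined
by a documented rule: targets with ≤ 10 distinct values stratify on the
values directly, otherwise on 5 quantile bins.  When strata are too
small for a requested split the code falls back to the unstratified
variant with a warning.  Predictions are clipped at zero — dosages,
concentrations and exposures are physically non-negative.  A
zero-variance fold target makes R² undefined; it is reported as a NaN
flag, never ±∞, and fold averages use the NaN-aware mean.

Every randomized component (splits, forests, boosting, network
initialization, batch shuffling) is seeded from one integer, default 1.
The per-fold score lists are bit-identical across processes for a fixed
seed — asserted in the tests by running the protocol in two fresh
interpreters.

Models: ordinary least squares, ridge (α = 1.0), random forest
(100 trees), gradient boosting (library defaults).  No hyperparameter
search — the point of the four-model suite is a robust baseline
comparison, not leaderboard tuning.  Feature relevance is the forest's
Gini importance (mean decrease in impurity), normalized to sum to one.

## Neural baselines

Two small rectified networks trained on mean squared error with AdamW
(learning rate 0.0035, decoupled weight decay 0.004), batch size 32, up
to 3000 epochs with early stopping (patience 100 on validation loss,
best weights restored):

* **FCNN** — 7 standardized features → dense(80, ReLU) → dense(1,
  ReLU).  The rectified output guarantees non-negative predictions by
  construction.  Standardized inputs are required (the net trains
  poorly otherwise — asserted as a property test) and checked at entry.
* **CNN** — per-time-point standardized raw series → one conv1d layer
  (16 filters, kernel 32, stride 4, ReLU) → flatten → dense(80, ReLU) →
  dense(1, ReLU).  The conv geometry, like the patience and batch size,
  is an implementer default, configurable in `CNNConfig`.

The trainer is a compact numpy implementation (forward/backward for the
two architectures, AdamW with bias-free weight decay).  All randomness
flows from one seeded generator, so training is reproducible to the
bit on a fixed numpy version — a property the test suite relies on.
Numerical choices worth noting: the output bias is initialized at the
training-target mean so the rectified output neuron starts in its
active region rather than dead at zero (dosage targets are ~10⁴, far
from a zero-initialized output's range); weight decay is skipped on
biases; dropout on the hidden layer exists behind a flag and defaults
off.  Validation inside training is a seeded random 20 % split unless
an explicit validation set is passed (as the CV driver does).

## Synthetic benchmark

The generator emulates the statistical structure the analysis assumes,
not any particular instrument:

* **Design**: 6 concentrations {0, 30, 100, 300, 500, 700} µg mL⁻¹ ×
  5 exposures {0, 24, 48, 72, 96} h × 10 cells = 300 curves, 1643
  points at Δt = 0.008 ns, with 0–6 extra points of acquisition-length
  jitter (so length conformation is exercised).
* **Curve shape**: exponentially modified Gaussian — the closed-form
  convolution of an exponential decay (lifetime τ) with a Gaussian
  instrument response (σ = 0.05 ns, pulse centred at 1.0 ns), peak
  amplitude 5·10⁴ counts over a 50-count baseline.  Evaluation is
  piecewise-stable (scaled-erfcx form near the peak, plain form in the
  deep tail) so no overflow occurs for σ ≪ τ.
* **Dose response**: τ(d) = τ_s + (τ_h − τ_s)·e^(−d/d₀) with
  τ_h = 0.60 ns, τ_s = 0.25 ns, d₀ = 20 000 µg mL⁻¹ h (a linear-ramp
  option exists).  These values are **assumptions**: chlorophyll decay
  curves of stressed cells shorten with dose, but no specific lifetime
  law is implied by the data format, so the defaults are chosen to put
  the downstream regression in a realistic difficulty regime (dosage
  R² around 0.7–0.9) rather than to mimic a particular organism.
* **Cell variability**: mean-one lognormal multipliers (CV 0.1) applied
  per record to amplitude and lifetime.  This is the dominant noise
  source; Poisson counting noise at a 5·10⁴-count peak is comparatively
  small.
* **Ground truth** (per-record τ, amplitude, baseline, dosage) is
  returned alongside the dataset, enabling parameter-recovery tests:
  noise-free, the fitted `fit_rate` matches 1/τ within 2 % (the
  residual bias comes from pulse-smeared samples just after the 95 %
  threshold) and is monotone in dosage.

What passing on synthetic data shows — and what it does not: the
pipeline recovers a lifetime-encoded dosage signal through the full
curation → featurization → regression chain, ranks the decay rate as a
top feature, and degrades monotonically with cell-level noise.  It does
**not** show that any particular real organism/toxicant pair yields
those scores: real data add instrument drift, multi-exponential decay
physics, pigment-pool heterogeneity and day effects that the generator
deliberately omits (as it omits pixel-resolved maps, photon-stream
formats, afterpulsing and repetition-rate wraparound).

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the full default design
(300 curves) for the end-to-end claims, and reduced designs (2 cells
per condition, 500-point curves) where the claim under test is
structural (determinism, shapes, error paths).  The CNN is trained with
a 600-epoch budget (patience 60) — it converges after roughly 200
epochs on the default design — while the FCNN keeps the full
3000-epoch/patience-100 schedule, stopping near epoch 1000.

## Known limitations

* The exponential-plus-offset tail fit is single-lifetime by design;
  genuinely multi-exponential decays are summarized, not resolved.
* Gini importances are known to favour high-cardinality/high-variance
  features; they are reported as relative rankings, not effect sizes.
* The ridge model sees raw interaction columns spanning ~10 orders of
  magnitude; its solver warning is silenced, the regularization path is
  still exercised.  Standardizing features before the linear models
  would change the paper-shaped protocol and is left to the user.
* Bit-level NN reproducibility is scoped to a fixed numpy version and
  single-threaded BLAS behaviour for reductions of identical shapes.
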