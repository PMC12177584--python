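"""Predict Cu(II) dosage from curve shape with the four-model suite.

Protocol: 80/20 stratified train/test split, then 5-fold stratified
cross-validation repeated 10 times on the training share (strata from the
binned dosage), everything seeded.  Reported per model: fold-averaged
R2/MAE with their spread, and the held-out-test scores.  The forest's
Gini importances say which curve features carry the dosage signal.
"""

from flimdose import GeneratorConfig, conform_lengths, generate_dataset, run_dosage_experiment

ds, _ = generate_dataset(GeneratorConfig(seed=1))
ds = conform_lengths(ds)

scores, importances, detail = run_dosage_experiment(ds, seed=1)
print(scores.round(3).to_string(index=False))
print("\nheld-out test set:", len(detail["test_idx"]), "records; "
      "MAE in ug/mL h (dosage spans 0..67200)")

print("\ntop-8 Gini importances (forest):")
for name, value in importances.ranked:
    print(f"  {name:28s} {value:.3f}")
print("\nfit_rate (the decay rate of the exponential tail) and its\n"
      "interactions dominate: the lifetime shortening IS the dosage signal.")
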