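"""Stratified 5-fold cross-validation on a small phantom cohort.

Builds 40 labelled phantoms, runs segment -> enhance -> classify with
the reference tinycnn backend, and prints per-metric mean +- sd over the
folds.  Accuracy and recall coincide because the cohort is exactly
class-balanced and metrics are macro-averaged.
"""

from pleurakit import PhantomConfig, generate_samples, kfold_cross_validate

samples = generate_samples(20, PhantomConfig(noise_sd=0.05), seed=5,
                           fill_range=(0.3, 0.7))
report = kfold_cross_validate(samples, k=5, seed=0)

print(f"{len(samples)} phantoms, {report.k}-fold cross-validation")
print(report.summary())
for i, fold in enumerate(report.folds):
    print(f"  fold {i}: accuracy {fold.accuracy:.3f}")
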