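"""Compare input modes (left / right / whole lung) on one phantom cohort.

Mirrors the single-lung versus whole-lung experiment: each column is a
cross-validated pipeline variant, the average_lungs column is the
arithmetic mean of the two single-lung columns, and values are percent.
"""

from pleurakit import (PhantomConfig, generate_samples, input_mode_grid,
                       run_comparison)

samples = generate_samples(25, PhantomConfig(noise_sd=0.08), seed=9,
                           fill_range=(0.15, 0.5))
table = run_comparison(samples, input_mode_grid(), k=5, seed=0)
print(table.to_string())
print("\ncolumns are cross-validated metrics in percent; whole-lung input "
      "sees both costophrenic angles, single-lung only one.")
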