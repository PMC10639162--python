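"""Generate the two synthetic datasets the analysis runs on.

Builds 25 districts with smooth spatially varying coefficient surfaces and
2,000 survey-like individual records, then prints the pieces of ground truth
that later examples try to recover.
"""

import numpy as np

from obesifact.synthetic import (default_truth, generate_district_panel,
                                 generate_districts, generate_individual_records,
                                 records_to_frame)

truth = default_truth(seed=0)
geoms = generate_districts(25, seed=0)
panel, true_coefs = generate_district_panel(geoms, truth)
records = generate_individual_records(2000, truth, districts=geoms)
df = records_to_frame(records)

print(f"districts: {len(panel)}, individual records: {len(df)}")
print(f"district obesity rates span [{panel.obesity_rate.min():.3f}, "
      f"{panel.obesity_rate.max():.3f}]  (baseline surface ~0.29-0.33)")
print(f"individual prevalence: {df.obese.mean():.3f}  (logistic model targets ~0.30)")
print("\ntrue district coefficient ranges over space (what GWLASSO must recover):")
for f in truth.district_factor_names:
    lo, hi = true_coefs[f].min(), true_coefs[f].max()
    print(f"  {f:22s} [{lo:+.3f}, {hi:+.3f}]")
print("\ninjected pathologies:", truth.null_features, "have zero effect;",
      list(truth.duplicate_features), "exactly duplicates its source feature")
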