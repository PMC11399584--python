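"""Absolute lipid quantification with class-matched internal standards.

Each species' concentration is its peak area divided by the area of the
labeled standard of the same class, times the known standard concentration.
The ratio cancels any per-sample global intensity factor.
"""

import numpy as np

from plasmaome import SimConfig, generate_study, quantify_lipids

study = generate_study(SimConfig(seed=1))
conc = quantify_lipids(study.lipids, study.species, study.is_map)

wide = conc.pivot()
print(f"quantified {wide.shape[0]} species in {wide.shape[1]} samples "
      f"({conc.units or 'IS units'}, method={conc.method})")
print("\nCE 20:4 across the first 5 samples (uM):")
print(wide.loc["CE 20:4"].head().round(3).to_string())

# sanity: quantification inverts the generated concentrations exactly
truth = study.truth.set_index("feature_id")
err = np.abs(np.log2(wide.loc["CE 20:4"]).mean()
             - truth.loc["CE 20:4", "alpha"]
             - truth.loc["CE 20:4", "beta_diet"] / 3  # 1/3 of samples are HFD
             )
print(f"\nmean log2 concentration sits near alpha + design-weighted effects "
      f"(gap {err:.2f} log2 units, from batch/age terms and noise)")
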