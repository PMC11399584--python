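"""How much dataset variability does each experimental factor explain?

Per feature, a sequential (Type-I) ANOVA in the order age, diet, draw
batch, mouse splits the total sum of squares; summing each factor's ESS
over features and dividing by the summed TSS gives the dataset-level
fraction of variance explained.
"""

import numpy as np

from plasmaome import (SimConfig, anova_all, dataset_variance_explained,
                       generate_study, quantify_lipids)

study = generate_study(SimConfig(seed=1))
conc = quantify_lipids(study.lipids, study.species, study.is_map)
log2c = conc.data.assign(value=np.log2(conc.data["value"]))

decomps = anova_all(log2c, study.design)
fractions = dataset_variance_explained(decomps)
print("fraction of lipidome variance explained:")
print((100 * fractions).round(1).astype(str).add(" %").to_string())

gap = (decomps.filter(like="ESS").sum(axis=1) + decomps["RSS"] - decomps["TSS"]).abs().max()
print(f"\nESS terms + RSS reconstruct TSS exactly (max gap {gap:.2e})")
print("Diet dominates: the generator plants strong diet effects on most "
      "species, mirroring a high-fat-diet study; mouse identity captures "
      "the random intercepts.")
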