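"""Generate a synthetic 90-sample plasma study and inspect its structure.

The generator emulates a repeated-measures design: 3 groups (young-chow,
adult-chow, adult-HFD) x 10 mice x 3 blood-draw batches, with lipid peak
areas, metabolite intensities, TMT-style protein reporter values, and a
ground-truth table of every planted effect.
"""

from plasmaome import SimConfig, generate_study

study = generate_study(SimConfig(seed=1))

bio = study.design[~study.design["is_bridge"]]
print(f"samples: {len(bio)} biological + "
      f"{study.design['is_bridge'].sum()} bridge channels "
      f"in {study.design['plex'].nunique()} plexes")
print(f"lipid species: {study.config.n_lipids}, "
      f"metabolites: {study.config.n_metabolites}, "
      f"proteins: {study.config.n_proteins}")

truth = study.truth
planted = truth[truth["planted"] != ""]
print(f"\nplanted set effects cover {len(planted)} lipid species, e.g.:")
print(planted[["feature_id", "beta_diet", "planted"]].head(5).to_string(index=False))
print("\nThese diet coefficients (log2 units) are what the mixed model and "
      "the enrichment test should recover.")

# study.write("study_dir")  # writes samples.csv, lipid.csv, ... truth.csv
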