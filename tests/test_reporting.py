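"""Class/acyl/omega aggregation and group statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plasmaome.annotation import OmegaLookup, parse_lipid_name
from plasmaome.core_io import ProcessingReport, group_label
from plasmaome.reporting import (acyl_class_totals, class_totals, group_t_test,
                                 log2_ratio_of_group_means, omega_ratio,
                                 omega_totals, p_to_stars, within_group_anova)
from plasmaome.synthetic import (PlantedSet, SimConfig, generate_study,
                                 make_design)
from plasmaome.quantify import quantify_lipids

from conftest import toy_design


def _conc(rows):
    return pd.DataFrame(rows, columns=["feature_id", "sample_id", "value"])


def test_class_totals_sum():
    names = ["TG 16:0_18:1_20:4", "TG 52:3"]
    species = {n: parse_lipid_name(n) for n in names}
    df = _conc([(names[0], "s1", 1.0), (names[1], "s1", 2.0)])
    out = class_totals(df, species)
    assert out.loc["s1", "TG"] == pytest.approx(3.0)


def test_class_totals_excludes_unannotated_with_report():
    species = {"CE 20:4": parse_lipid_name("CE 20:4")}
    df = _conc([("CE 20:4", "s1", 1.0), ("mystery", "s1", 5.0)])
    report = ProcessingReport()
    out = class_totals(df, species, report)
    assert out.loc["s1", "CE"] == pytest.approx(1.0)
    assert len(report) == 1


def test_class_totals_conservation(default_study, default_results):
    """Sum over classes equals the sum over species concentrations."""
    conc = default_results.lipid_concentrations
    totals = default_results.class_totals
    per_sample = conc.data.groupby("sample_id")["value"].sum()
    assert np.allclose(totals.sum(axis=1).sort_index(), per_sample.sort_index())


def test_acyl_multiplicity_counted():
    names = ["PC 16:0_20:4", "TG 16:0_20:4_20:4"]
    species = {n: parse_lipid_name(n) for n in names}
    df = _conc([(names[0], "s1", 2.0), (names[1], "s1", 1.0)])
    out = acyl_class_totals(df, species).set_index(["lipid_class", "acyl"])
    assert out.loc[("PC", "20:4"), "value"] == pytest.approx(2.0)
    # the doubled chain contributes twice its species concentration
    assert out.loc[("TG", "20:4"), "value"] == pytest.approx(2.0)
    assert out.loc[("TG", "16:0"), "value"] == pytest.approx(1.0)


def test_acyl_totals_chain_count_conservation(default_results, default_study):
    """Per class, acyl totals sum to concentration x chain count."""
    atot = default_results.acyl_totals
    conc = default_results.lipid_concentrations.data
    species = default_study.species
    got = atot.groupby("lipid_class")["value"].sum()
    expected = {}
    for _, row in conc.iterrows():
        sp = species[row["feature_id"]]
        if sp.level != "molecular_species":
            continue
        expected[sp.subclass_key] = expected.get(sp.subclass_key, 0.0) + \
            row["value"] * len(sp.chains)
    for cls, tot in expected.items():
        assert got[cls] == pytest.approx(tot)


def test_sum_composition_excluded_and_logged():
    species = {"TG 52:3": parse_lipid_name("TG 52:3"),
               "CE 20:4": parse_lipid_name("CE 20:4")}
    df = _conc([("TG 52:3", "s1", 1.0), ("CE 20:4", "s1", 1.0)])
    report = ProcessingReport()
    out = acyl_class_totals(df, species, report)
    assert set(out["lipid_class"]) == {"CE"}
    assert any("sum-composition" in e["message"] for e in report.entries)


def test_omega_ratio_arithmetic():
    lookup = OmegaLookup({(20, 4): "omega-6", (20, 5): "omega-3"})
    atot = pd.DataFrame({"sample_id": ["s1", "s1", "s2", "s2"],
                         "lipid_class": ["CE"] * 4,
                         "acyl": ["20:4", "20:5"] * 2,
                         "value": [1.0, 1.0, 4.0, 2.0]})
    ratio = omega_ratio(atot, lookup)
    assert ratio["s1"] == pytest.approx(1.0)
    assert ratio["s2"] == pytest.approx(2.0)


def test_omega_ratio_zero_denominator_reported():
    lookup = OmegaLookup({(20, 4): "omega-6"})
    atot = pd.DataFrame({"sample_id": ["s1"], "lipid_class": ["CE"],
                         "acyl": ["20:4"], "value": [1.0]})
    report = ProcessingReport()
    ratio = omega_ratio(atot, lookup, report)
    assert np.isnan(ratio["s1"]) and len(report) == 1


def test_hfd_raises_omega_ratio(default_study, default_results):
    """Planted AA-up/EPA-down diet effects push the HFD ratio above chow."""
    ratio = default_results.omega_ratio
    labels = group_label(default_study.design.set_index("sample_id"))
    labels = labels.reindex(ratio.index)
    assert (ratio[labels == "adult-hfd"].mean()
            > ratio[labels == "adult-chow"].mean())


def test_group_t_test_matches_closed_form(rng):
    design = toy_design(n_mice=8)
    labels = group_label(design.set_index("sample_id"))
    values = pd.Series(rng.normal(size=len(design)),
                       index=design["sample_id"])
    t, p = group_t_test(values, design, ("adult-hfd", "adult-chow"))
    x = values[labels == "adult-hfd"]
    y = values[labels == "adult-chow"]
    nx, ny = len(x), len(y)
    sp2 = (((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1))
           / (nx + ny - 2))
    t_hand = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    assert t == pytest.approx(t_hand)
    assert p == pytest.approx(2 * stats.t.sf(abs(t_hand), nx + ny - 2))
    # symmetry up to sign
    t2, p2 = group_t_test(values, design, ("adult-chow", "adult-hfd"))
    assert t2 == pytest.approx(-t) and p2 == pytest.approx(p)


def test_group_t_test_identical_groups():
    design = toy_design(n_mice=8)
    values = pd.Series(np.tile([1.0, 2.0, 3.0], 8), index=design["sample_id"])
    t, p = group_t_test(values, design, ("adult-hfd", "adult-chow"))
    assert t == pytest.approx(0.0, abs=1e-12)


def test_group_t_test_small_group_errors():
    design = toy_design(n_mice=4, n_draws=1)
    values = pd.Series(np.arange(4.0), index=design["sample_id"])
    with pytest.raises(ValueError):
        group_t_test(values, design, ("adult-hfd", "adult-chow"))


def test_within_group_anova_null_p_uniformish():
    """No batch/mouse effect: batch p should not pile up near 0."""
    design = make_design(10, with_plexes=False)
    rng = np.random.default_rng(50)
    ps = []
    for _ in range(200):
        values = pd.Series(rng.normal(size=90),
                           index=design["sample_id"])
        out = within_group_anova(values, design, "adult-chow")
        ps.append(out.set_index("factor").loc["batch", "p"])
    ks = stats.kstest(ps, "uniform")
    assert ks.pvalue > 0.01


def test_within_group_anova_detects_planted_batch_effect():
    # plant a clear (~3x) Z10 elevation of every TG species
    cfg = SimConfig(seed=60, n_lipids=20, n_metabolites=2, n_proteins=2,
                    planted_sets=(PlantedSet("class:TG", "batch", 1.5),))
    study = generate_study(cfg)
    conc = quantify_lipids(study.lipids, study.species, study.is_map)
    species = study.species
    totals = class_totals(conc, species)
    out = within_group_anova(totals["TG"], study.design, "adult-chow")
    assert out.set_index("factor").loc["batch", "p"] < 0.001
    assert out.set_index("factor").loc["batch", "stars"] == "***"


def test_within_group_anova_constant_is_na():
    design = make_design(10, with_plexes=False)
    values = pd.Series(1.0, index=design["sample_id"])
    out = within_group_anova(values, design, "adult-chow")
    assert np.isnan(out.set_index("factor").loc["batch", "p"])


def test_within_group_anova_missing_batch_errors():
    design = toy_design(n_mice=4, n_draws=2)
    values = pd.Series(np.arange(8.0), index=design["sample_id"])
    with pytest.raises(ValueError, match="draw batches"):
        within_group_anova(values, design, "adult-chow")


def test_log2_ratio_of_group_means():
    design = toy_design(n_mice=8)
    labels = group_label(design.set_index("sample_id"))
    vals = pd.DataFrame(index=design["sample_id"], data={"CE": 1.0})
    vals.loc[labels == "adult-hfd", "CE"] = 4.0
    out = log2_ratio_of_group_means(vals, design)
    assert out["CE"] == pytest.approx(2.0)


def test_p_to_stars_thresholds():
    assert p_to_stars(0.0005) == "***"
    assert p_to_stars(0.005) == "**"
    assert p_to_stars(0.05) == "*"
    assert p_to_stars(0.2) == ""
    assert p_to_stars(float("nan")) == ""
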