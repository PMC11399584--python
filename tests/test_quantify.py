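"""Quantification arithmetic, normalizations, and extraction-QC metrics."""

import numpy as np
import pandas as pd
import pytest

from plasmaome.annotation import parse_lipid_name
from plasmaome.core_io import FeatureTable, ProcessingReport, ValidationError
from plasmaome.quantify import (bridge_normalize, carryover_fraction, cv_percent,
                                extraction_recovery, linearity_check,
                                log2_normalize_to_reference, quantify_lipids)
from plasmaome.synthetic import make_design

from conftest import toy_design


def _lipid_table(rows):
    return FeatureTable("lipid", pd.DataFrame(rows,
                        columns=["feature_id", "sample_id", "value"]))


IS_MAP = pd.DataFrame({"lipid_class": ["CE"], "is_feature_id": ["d7-IS CE"],
                       "is_concentration": [0.5]})
SPECIES = {"CE 20:4": parse_lipid_name("CE 20:4")}


def test_quantify_ratio_definition():
    table = _lipid_table([("CE 20:4", "s1", 2.0), ("d7-IS CE", "s1", 1.0)])
    conc = quantify_lipids(table, SPECIES, IS_MAP)
    assert conc.data["value"].iloc[0] == pytest.approx(1.0)
    assert conc.method == "is_ratio"


def test_quantify_equal_area_gives_is_concentration():
    table = _lipid_table([("CE 20:4", "s1", 7.7), ("d7-IS CE", "s1", 7.7)])
    conc = quantify_lipids(table, SPECIES, IS_MAP)
    assert conc.data["value"].iloc[0] == pytest.approx(0.5)


def test_quantify_matches_elementwise_oracle(rng):
    samples = [f"s{i}" for i in range(3)]
    feats = [f"CE {c}:4" for c in (18, 20, 22)] + [f"TG 5{i}:2" for i in (0, 2)]
    species = {f: parse_lipid_name(f) for f in feats}
    is_map = pd.DataFrame({"lipid_class": ["CE", "TG"],
                           "is_feature_id": ["isCE", "isTG"],
                           "is_concentration": [0.5, 2.0]})
    rows = []
    areas = {}
    for f in feats + ["isCE", "isTG"]:
        for s in samples:
            v = rng.lognormal()
            areas[(f, s)] = v
            rows.append((f, s, v))
    conc = quantify_lipids(_lipid_table(rows), species, is_map)
    got = conc.data.set_index(["feature_id", "sample_id"])["value"]
    for f in feats:
        cls = species[f].lipid_class
        is_id, is_c = ("isCE", 0.5) if cls == "CE" else ("isTG", 2.0)
        for s in samples:
            expected = areas[(f, s)] / areas[(is_id, s)] * is_c
            assert got[(f, s)] == pytest.approx(expected)


def test_quantify_scale_invariant_to_sample_factor(rng):
    rows = [("CE 20:4", s, v) for s, v in [("s1", 2.0), ("s2", 4.0)]]
    rows += [("d7-IS CE", "s1", 1.0), ("d7-IS CE", "s2", 8.0)]
    base = quantify_lipids(_lipid_table(rows), SPECIES, IS_MAP)
    scaled_rows = [(f, s, v * (10.0 if s == "s1" else 0.3)) for f, s, v in rows]
    scaled = quantify_lipids(_lipid_table(scaled_rows), SPECIES, IS_MAP)
    pd.testing.assert_frame_equal(base.data, scaled.data)


def test_quantify_zero_is_area_is_error():
    table = _lipid_table([("CE 20:4", "s1", 2.0), ("d7-IS CE", "s1", 0.0)])
    with pytest.raises(ValidationError, match="s1"):
        quantify_lipids(table, SPECIES, IS_MAP)


def test_log2_reference_normalization():
    design = toy_design()  # m0, m1 young-chow; reference group
    rows = []
    for sid in design["sample_id"]:
        mouse = sid.split("_")[0][1]
        rows.append(("f1", sid, 4.0 if mouse in "01" else 16.0))
    table = FeatureTable("metabolite", pd.DataFrame(
        rows, columns=["feature_id", "sample_id", "value"]))
    out = log2_normalize_to_reference(table, design, reference="young-chow")
    got = out.data.set_index("sample_id")["value"]
    assert got["s0_0"] == pytest.approx(0.0)  # reference maps to 0
    assert got["s3_0"] == pytest.approx(2.0)  # 4x the reference mean -> +2
    ref_ids = design.loc[design["age_group"] == "young", "sample_id"]
    assert got[ref_ids].mean() == pytest.approx(0.0, abs=1e-12)


def test_log2_reference_drops_nonpositive_with_report():
    design = toy_design()
    rows = [("f1", sid, 2.0) for sid in design["sample_id"]]
    rows[5] = ("f1", design["sample_id"].iloc[5], -1.0)
    table = FeatureTable("metabolite", pd.DataFrame(
        rows, columns=["feature_id", "sample_id", "value"]))
    report = ProcessingReport()
    out = log2_normalize_to_reference(table, design, report=report)
    assert len(out.data) == len(design) - 1
    assert len(report) == 1 and report.entries[0]["stage"] == "log2_ref"


def test_log2_reference_matches_two_pass_oracle(rng):
    design = toy_design(n_mice=6)
    rows = [("f1", sid, rng.lognormal()) for sid in design["sample_id"]]
    df = pd.DataFrame(rows, columns=["feature_id", "sample_id", "value"])
    out = log2_normalize_to_reference(FeatureTable("metabolite", df), design)
    ref_ids = set(design.loc[(design["age_group"] == "young")
                             & (design["diet"] == "chow"), "sample_id"])
    ref_mean = np.mean([np.log2(v) for _, s, v in rows if s in ref_ids])
    for _, row in out.data.iterrows():
        raw = df.set_index("sample_id").loc[row["sample_id"], "value"]
        assert row["value"] == pytest.approx(np.log2(raw) - ref_mean)


def _bridge_setup(scale2=1.0):
    design = make_design(1, with_plexes=True, plex_size=3)
    bio = design[~design["is_bridge"]]
    rows = []
    for i, sid in enumerate(bio["sample_id"]):
        rows.append(("p1", sid, 8.0, 100.0))
    for plex, scale in (("plex1", 1.0), ("plex2", scale2), ("plex3", 1.0)):
        rows.append(("p1", f"bridge_{plex}", 8.0 * scale, 100.0))
    # scale all member samples of plex2 by the same factor
    df = pd.DataFrame(rows, columns=["feature_id", "sample_id", "value", "ion_count"])
    in2 = df["sample_id"].isin(design.loc[design["plex"] == "plex2", "sample_id"])
    df.loc[in2 & ~df["sample_id"].str.startswith("bridge"), "value"] *= scale2
    return design, FeatureTable("protein", df)


def test_bridge_normalize_sample_equal_to_bridge_is_zero():
    design, table = _bridge_setup()
    out = bridge_normalize(table, design)
    assert np.allclose(out.data["value"], 0.0)
    assert not out.data["sample_id"].str.startswith("bridge").any()


def test_bridge_normalize_removes_plex_offset():
    base_design, base = _bridge_setup(scale2=1.0)
    design, scaled = _bridge_setup(scale2=2.0)
    out_a = bridge_normalize(base, base_design).data.set_index("sample_id")["value"]
    out_b = bridge_normalize(scaled, design).data.set_index("sample_id")["value"]
    pd.testing.assert_series_equal(out_a, out_b)


def test_bridge_normalize_missing_bridge_flagged():
    design, table = _bridge_setup()
    trimmed = FeatureTable("protein",
                           table.data[table.data["sample_id"] != "bridge_plex2"])
    report = ProcessingReport()
    out = bridge_normalize(trimmed, design, report=report)
    assert len(report) == 1 and report.entries[0]["plex"] == "plex2"
    assert not out.data["sample_id"].isin(
        design.loc[design["plex"] == "plex2", "sample_id"]).any()


def test_extraction_recovery():
    assert extraction_recovery([2.0, 2.0], [2.0]) == pytest.approx((0.0, 100.0))
    log2r, pct = extraction_recovery([1.0], [2.0])
    assert (log2r, pct) == pytest.approx((-1.0, 50.0))
    pre, post = [1.1, 0.9, 1.05], [2.2, 1.9]
    log2r, pct = extraction_recovery(pre, post)
    assert pct == pytest.approx(100 * np.mean(pre) / np.mean(post))
    with pytest.raises(ValueError):
        extraction_recovery([0.0], [1.0])


def test_linearity_check():
    prepared = [0.25, 1.0, 4.0]
    slope, intercept, r2 = linearity_check(prepared, prepared)
    assert (slope, r2) == pytest.approx((1.0, 1.0))
    _, _, r2 = linearity_check(prepared, [1.0, 1.0, 1.0])
    assert r2 == pytest.approx(0.0)
    measured = [0.3, 0.9, 4.4]
    slope, intercept, r2 = linearity_check(prepared, measured)
    x, y = np.log2(prepared), np.log2(measured)
    b = np.polyfit(x, y, 1)
    assert slope == pytest.approx(b[0])
    with pytest.raises(ValueError):
        linearity_check([1, 2], [1, 2])


def test_cv_percent():
    assert cv_percent([10, 10, 10]) == pytest.approx(0.0)
    assert cv_percent([8, 12]) == pytest.approx(100 * np.std([8, 12], ddof=1) / 10)
    with pytest.raises(ValueError):
        cv_percent([5.0])


def test_carryover_fraction():
    assert carryover_fraction(0.0, 10.0) == pytest.approx(0.0)
    assert carryover_fraction(10.0, 10.0) == pytest.approx(100.0)
    assert carryover_fraction(0.37, 20.0) == pytest.approx(100 * 0.37 / 20.0)
    with pytest.raises(ValueError):
        carryover_fraction(1.0, 0.0)
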