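"""Internal-standard absolute quantification, normalizations, and extraction QC.

Lipid concentrations come from class-matched isotopically labeled internal
standards: concentration(f, s) = area(f, s) / area(IS of f's class, s) x
IS concentration.  Any per-sample global area factor cancels in the ratio.
Metabolite/protein intensities are expressed as log2 values relative either
to the mean of a reference group or to the bridge channel of each plex.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import LipidSpecies
from .core_io import FeatureTable, ProcessingReport, ValidationError, group_label

__all__ = [
    "QuantifiedTable",
    "quantify_lipids",
    "log2_normalize_to_reference",
    "bridge_normalize",
    "extraction_recovery",
    "linearity_check",
    "cv_percent",
    "carryover_fraction",
]


@dataclass
class QuantifiedTable:
    """Long table of quantified/normalized values plus the method that made it."""

    data: pd.DataFrame  # feature_id, sample_id, value
    method: str  # is_ratio | log2_ref | bridge
    units: str = ""

    def pivot(self) -> pd.DataFrame:
        return self.data.pivot(index="feature_id", columns="sample_id", values="value")


def quantify_lipids(areas: FeatureTable,
                    species: Mapping[str, LipidSpecies],
                    is_map: pd.DataFrame,
                    report: ProcessingReport | None = None) -> QuantifiedTable:
    """Absolute lipid quantification from peak areas via class-matched standards.

    Parameters
    ----------
    areas : peak-area feature table including the internal-standard features.
    species : parsed annotation per feature_id (IS features need no entry).
    is_map : columns lipid_class, is_feature_id, is_concentration. The class
        key is the species' ``subclass_key`` (ether subclasses have their own
        standard).

    Returns per-feature concentrations in the IS concentration units;
    internal-standard rows are excluded from the output.
    """
    if report is None:
        report = ProcessingReport()
    df = areas.data
    is_info = is_map.set_index("lipid_class")
    is_ids = set(is_map["is_feature_id"])

    # per (IS feature, sample) areas
    is_areas = df[df["feature_id"].isin(is_ids)].pivot(
        index="feature_id", columns="sample_id", values="value")

    rows = []
    for fid, grp in df[~df["feature_id"].isin(is_ids)].groupby("feature_id", sort=True):
        sp = species.get(fid)
        if sp is None:
            report.add("quantify", "feature lacks annotation; skipped", feature_id=fid)
            continue
        cls = sp.subclass_key
        if cls not in is_info.index:
            report.add("quantify", f"no internal standard for class {cls}",
                       feature_id=fid)
            continue
        is_fid = is_info.loc[cls, "is_feature_id"]
        conc_is = float(is_info.loc[cls, "is_concentration"])
        if is_fid not in is_areas.index:
            raise ValidationError(
                f"internal standard {is_fid!r} for class {cls!r} absent from areas")
        ref = is_areas.loc[is_fid].reindex(grp["sample_id"])
        bad = ref.isna() | (ref <= 0)
        if bad.any():
            sample = grp["sample_id"].to_numpy()[bad.to_numpy()][0]
            raise ValidationError(
                f"internal standard area for class {cls!r} missing or zero "
                f"in sample {sample!r}")
        conc = grp["value"].to_numpy() / ref.to_numpy() * conc_is
        rows.append(pd.DataFrame({"feature_id": fid,
                                  "sample_id": grp["sample_id"].to_numpy(),
                                  "value": conc}))
    if not rows:
        raise ValidationError("no quantifiable lipid features")
    units = ""
    if "units" in is_map.columns and is_map["units"].nunique() == 1:
        units = str(is_map["units"].iloc[0])
    out = pd.concat(rows, ignore_index=True)
    return QuantifiedTable(out, method="is_ratio", units=units)


def log2_normalize_to_reference(values: FeatureTable | QuantifiedTable,
                                design: pd.DataFrame,
                                reference: str | tuple[str, str] = "young-chow",
                                report: ProcessingReport | None = None
                                ) -> QuantifiedTable:
    """log2 of each value minus the mean log2 of the reference group per feature.

    Nonpositive values cannot be log-transformed; their rows are dropped with
    a report entry.  Output over the reference samples has exact mean 0.
    """
    if report is None:
        report = ProcessingReport()
    if isinstance(reference, tuple):
        reference = "-".join(reference)
    labels = group_label(design)
    ref_samples = set(design.loc[labels == reference, "sample_id"])
    if not ref_samples:
        raise ValidationError(f"reference group {reference!r} has no samples")

    df = (values.data if isinstance(values, (FeatureTable, QuantifiedTable))
          else values).copy()
    pos = df["value"] > 0
    if (~pos).any():
        for _, row in df[~pos].iterrows():
            report.add("log2_ref", "nonpositive value dropped",
                       feature_id=row["feature_id"], sample_id=row["sample_id"])
        df = df[pos]
    df["log2"] = np.log2(df["value"].to_numpy(dtype=float))
    in_ref = df["sample_id"].isin(ref_samples)
    ref_mean = df[in_ref].groupby("feature_id")["log2"].mean()
    missing_ref = set(df["feature_id"]) - set(ref_mean.index)
    for fid in sorted(missing_ref):
        report.add("log2_ref", "feature has no reference observations; dropped",
                   feature_id=fid)
    df = df[df["feature_id"].isin(ref_mean.index)].copy()
    df["value"] = df["log2"] - df["feature_id"].map(ref_mean)
    return QuantifiedTable(df[["feature_id", "sample_id", "value"]].reset_index(drop=True),
                           method="log2_ref")


def bridge_normalize(values: FeatureTable,
                     design: pd.DataFrame,
                     report: ProcessingReport | None = None) -> QuantifiedTable:
    """log2(value) minus log2(bridge value of the sample's plex), per feature.

    Removes any per-plex multiplicative offset exactly.  Bridge rows are
    removed from the output; a feature missing its bridge value in a plex is
    dropped in that plex with a report entry.  ion_count columns pass through
    so that downstream model weights remain available.
    """
    if report is None:
        report = ProcessingReport()
    dsn = design.set_index("sample_id")
    bridges = design[design["is_bridge"]]
    if bridges.empty:
        raise ValidationError("design contains no bridge samples")
    bridge_of_plex = bridges.set_index("plex")["sample_id"]

    df = values.data.copy()
    df["plex"] = df["sample_id"].map(dsn["plex"])
    if df["plex"].isna().any():
        sid = df.loc[df["plex"].isna(), "sample_id"].iloc[0]
        raise ValidationError(f"sample {sid!r} absent from design or has no plex")
    df["is_bridge"] = df["sample_id"].map(dsn["is_bridge"]).astype(bool)

    bdf = df[df["is_bridge"]]
    bval = bdf.set_index(["feature_id", "plex"])["value"]
    out = df[~df["is_bridge"]].copy()
    key = pd.MultiIndex.from_arrays([out["feature_id"], out["plex"]])
    ref = bval.reindex(key).to_numpy(dtype=float)
    ok = np.isfinite(ref) & (ref > 0) & (out["value"].to_numpy(dtype=float) > 0)
    if (~ok).any():
        for _, row in out[~ok].drop_duplicates(["feature_id", "plex"]).iterrows():
            report.add("bridge", "missing/nonpositive bridge or value; dropped",
                       feature_id=row["feature_id"], plex=row["plex"])
    out = out[ok].copy()
    out["value"] = np.log2(out["value"].to_numpy(dtype=float)) - np.log2(ref[ok])
    cols = ["feature_id", "sample_id", "value"]
    if out["ion_count"].notna().any():
        cols.append("ion_count")
    return QuantifiedTable(out[cols].reset_index(drop=True), method="bridge")


# ---------------------------------------------------------------------------
# extraction QC metrics


def extraction_recovery(pre_spike, post_spike) -> tuple[float, float]:
    """Recovery of a standard spiked before vs after extraction.

    Returns (log2 ratio of means, percent recovery).  Ratio of means, not
    mean of ratios: replicates are pooled measurements of the same spike.
    """
    pre = np.asarray(pre_spike, dtype=float)
    post = np.asarray(post_spike, dtype=float)
    if pre.size < 1 or post.size < 1:
        raise ValueError("need at least one replicate in each arm")
    if (pre <= 0).any() or (post <= 0).any():
        raise ValueError("areas must be positive")
    ratio = pre.mean() / post.mean()
    if ratio <= 0 or not np.isfinite(ratio):
        raise ValueError("zero or invalid mean area")
    return float(np.log2(ratio)), float(100.0 * ratio)


def linearity_check(prepared_ratios, measured_ratios) -> tuple[float, float, float]:
    """Least-squares fit of log2 measured vs log2 prepared mixing ratios.

    Returns (slope, intercept, R^2).  A dilution series that is read back
    proportionally gives slope 1, R^2 1.
    """
    x = np.log2(np.asarray(prepared_ratios, dtype=float))
    y = np.log2(np.asarray(measured_ratios, dtype=float))
    if x.size < 3 or y.size != x.size:
        raise ValueError("need >= 3 matched points")
    if np.var(y) == 0:  # flat response explains nothing of the dilution
        return 0.0, float(y.mean()), 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def cv_percent(values) -> float:
    """Coefficient of variation, percent, with the n-1 sample SD."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least 2 replicates")
    mean = v.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / mean)


def carryover_fraction(blank_signal: float, sample_signal: float) -> float:
    """Percent of sample signal found in a following blank injection."""
    if sample_signal <= 0:
        raise ValueError("sample signal must be positive")
    return float(100.0 * blank_signal / sample_signal)
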