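"""Class/acyl/omega aggregation of quantified lipids and group statistics.

Aggregates per-sample molar concentrations into lipid-class totals,
(class, acyl) totals — counting a chain twice when it occurs twice in a
species, so the totals are molar acyl abundances — and omega-6/omega-3
pools whose ratio summarizes the polyunsaturated acyl balance.  Group
comparisons use the equal-variance two-tailed Student's t test (Welch by
flag), and repeated-draw effects within a group are tested with a two-factor
(draw batch, mouse) ANOVA, starred at the conventional 0.05/0.01/0.001
levels.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import MOLECULAR_SPECIES, LipidSpecies, OmegaLookup
from .core_io import ProcessingReport, group_label
from .quantify import QuantifiedTable
from .variance import sequential_anova

__all__ = [
    "class_totals",
    "acyl_class_totals",
    "omega_totals",
    "omega_ratio",
    "group_t_test",
    "within_group_anova",
    "log2_ratio_of_group_means",
    "p_to_stars",
]


def _data(quantified) -> pd.DataFrame:
    return quantified.data if isinstance(quantified, QuantifiedTable) else quantified


def class_totals(quantified, species: Mapping[str, LipidSpecies],
                 report: ProcessingReport | None = None) -> pd.DataFrame:
    """Per-sample molar total of each lipid class (linear-scale input).

    Returns a sample x class DataFrame; unannotated features are excluded
    with a report entry.
    """
    if report is None:
        report = ProcessingReport()
    df = _data(quantified).copy()
    known = df["feature_id"].isin(species.keys())
    for fid in sorted(df.loc[~known, "feature_id"].unique()):
        report.add("class_totals", "unannotated feature excluded", feature_id=fid)
    df = df[known]
    df["lipid_class"] = df["feature_id"].map(
        {fid: sp.subclass_key for fid, sp in species.items()})
    out = (df.groupby(["sample_id", "lipid_class"])["value"].sum()
             .unstack(fill_value=0.0))
    out.columns.name = None
    return out


def acyl_class_totals(quantified, species: Mapping[str, LipidSpecies],
                      report: ProcessingReport | None = None) -> pd.DataFrame:
    """Per-sample molar total of each (class, acyl) pair with chain multiplicity.

    A species at concentration c with the acyl occurring twice contributes
    2c to that (class, acyl) total.  Sum-composition species contribute
    nothing (logged).  Returns a long DataFrame: sample_id, lipid_class,
    acyl, value.
    """
    if report is None:
        report = ProcessingReport()
    df = _data(quantified)
    rows = []
    for fid, grp in df.groupby("feature_id", sort=True):
        sp = species.get(fid)
        if sp is None:
            report.add("acyl_totals", "unannotated feature excluded", feature_id=fid)
            continue
        if sp.level != MOLECULAR_SPECIES:
            report.add("acyl_totals", "sum-composition species excluded",
                       feature_id=fid)
            continue
        counts: dict[tuple[int, int], int] = {}
        for ch in sp.chains:
            counts[(ch.carbons, ch.double_bonds)] = counts.get(
                (ch.carbons, ch.double_bonds), 0) + 1
        for (c, d), mult in counts.items():
            rows.append(pd.DataFrame({
                "sample_id": grp["sample_id"].to_numpy(),
                "lipid_class": sp.subclass_key,
                "acyl": f"{c}:{d}",
                "value": mult * grp["value"].to_numpy(dtype=float)}))
    if not rows:
        raise ValueError("no molecular-species-level lipid to aggregate")
    out = pd.concat(rows, ignore_index=True)
    return (out.groupby(["sample_id", "lipid_class", "acyl"], as_index=False)["value"]
               .sum())


def omega_totals(acyl_totals: pd.DataFrame,
                 lookup: OmegaLookup | None = None) -> pd.DataFrame:
    """Per-sample molar totals of each omega class (summed across lipid classes)."""
    if lookup is None:
        lookup = OmegaLookup.default()
    df = acyl_totals.copy()
    cd = df["acyl"].str.split(":", expand=True).astype(int)
    df["omega"] = [lookup.assign((c, d)) for c, d in zip(cd[0], cd[1])]
    out = df.groupby(["sample_id", "omega"])["value"].sum().unstack(fill_value=0.0)
    out.columns.name = None
    return out


def omega_ratio(acyl_totals: pd.DataFrame,
                lookup: OmegaLookup | None = None,
                report: ProcessingReport | None = None) -> pd.Series:
    """Per-sample omega-6 / omega-3 molar ratio (NaN where omega-3 total is 0)."""
    if report is None:
        report = ProcessingReport()
    tot = omega_totals(acyl_totals, lookup)
    w6 = tot.get("omega-6", pd.Series(0.0, index=tot.index))
    w3 = tot.get("omega-3", pd.Series(0.0, index=tot.index))
    ratio = pd.Series(np.where(w3 > 0, w6 / w3, np.nan), index=tot.index,
                      name="omega6_omega3_ratio")
    for sid in ratio.index[ratio.isna()]:
        report.add("omega_ratio", "zero omega-3 total; ratio undefined",
                   sample_id=sid)
    return ratio


def group_t_test(values: pd.Series, design: pd.DataFrame,
                 groups: tuple[str, str], welch: bool = False
                 ) -> tuple[float, float]:
    """Two-sample two-tailed t test of a per-sample aggregate between groups.

    ``values`` is indexed by sample_id; ``groups`` are labels like
    ``("adult-hfd", "adult-chow")``.  Student's equal-variance form by
    default; ``welch=True`` drops the equal-variance assumption.
    """
    labels = group_label(design.set_index("sample_id")).reindex(values.index)
    x = values[labels == groups[0]].dropna().to_numpy(dtype=float)
    y = values[labels == groups[1]].dropna().to_numpy(dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 samples")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("degenerate (zero) variance in both groups")
    res = stats.ttest_ind(x, y, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def within_group_anova(values: pd.Series, design: pd.DataFrame,
                       group: str) -> pd.DataFrame:
    """Two-factor (draw batch, mouse) ANOVA of an aggregate within one group.

    Tests whether repeated blood draws differ within e.g. ``adult-chow``
    mice, with the mouse factor absorbing between-animal variation.
    Returns per-factor F, p, and a star annotation; constant input yields
    NA p-values rather than an error.
    """
    dsn = design.set_index("sample_id")
    labels = group_label(dsn)
    sids = values.index.intersection(labels.index[labels == group])
    sub = dsn.loc[sids]
    batches = set(sub["draw_batch"])
    if batches != {"Z10", "Z22", "Z15"}:
        raise ValueError(f"group {group!r} must contain all 3 draw batches, "
                         f"has {sorted(batches)}")
    y = values.loc[sids].to_numpy(dtype=float)
    factors = pd.DataFrame({"batch": sub["draw_batch"].to_numpy(),
                            "mouse": sub["mouse_id"].to_numpy()})
    ss = sequential_anova(y, factors, order=["batch", "mouse"])
    n = len(y)
    degenerate = ss["TSS"] <= 1e-12 * n * (1.0 + float(np.mean(y)) ** 2)
    df_batch = factors["batch"].nunique() - 1
    df_mouse = factors["mouse"].nunique() - 1
    df_resid = n - 1 - df_batch - df_mouse
    rows = []
    for fac, dfree in (("batch", df_batch), ("mouse", df_mouse)):
        ess = ss[f"ESS_{fac}"]
        if degenerate or df_resid <= 0 or ss["RSS"] <= 0 or dfree <= 0:
            f = p = np.nan
        else:
            f = (ess / dfree) / (ss["RSS"] / df_resid)
            p = float(stats.f.sf(f, dfree, df_resid))
        rows.append({"factor": fac, "df": dfree, "SS": ess, "F": f, "p": p,
                     "stars": p_to_stars(p)})
    rows.append({"factor": "residual", "df": df_resid, "SS": ss["RSS"],
                 "F": np.nan, "p": np.nan, "stars": ""})
    return pd.DataFrame(rows)


def log2_ratio_of_group_means(values: pd.DataFrame, design: pd.DataFrame,
                              numerator: str = "adult-hfd",
                              denominator: str = "adult-chow") -> pd.Series:
    """log2 of the ratio of group means of per-sample totals (linear scale).

    ``values`` is a sample x quantity DataFrame (e.g. class or acyl totals);
    group means are taken on the linear scale, then log2 of their ratio —
    the convention of fold-change heatmaps over absolute concentrations.
    """
    labels = group_label(design.set_index("sample_id")).reindex(values.index)
    num = values[labels == numerator].mean(axis=0)
    den = values[labels == denominator].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2(num / den)
    return pd.Series(out, index=values.columns, name=f"log2({numerator}/{denominator})")


def p_to_stars(p: Optional[float]) -> str:
    """Printed significance convention: *** <=0.001, ** <=0.01, * <=0.05."""
    if p is None or not np.isfinite(p):
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""
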