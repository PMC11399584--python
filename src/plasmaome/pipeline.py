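"""End-to-end study analysis: quantify -> fit -> decompose -> enrich -> report.

Thin orchestration over the library modules, used by the CLI and by
integration tests.  Each stage writes a tidy TSV; warnings accumulate in a
JSON processing report.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import enrichment as enr
from . import inference, quantify, reporting, variance
from .annotation import LipidSpecies, OmegaLookup, parse_lipid_name
from .core_io import FeatureTable, ProcessingReport, validate_design
from .synthetic import SyntheticStudy

__all__ = ["StudyResults", "analyze_study"]


@dataclass
class StudyResults:
    """Per-stage outputs of a full study analysis."""

    lipid_concentrations: quantify.QuantifiedTable
    lipid_fits: pd.DataFrame
    metabolite_fits: pd.DataFrame
    protein_fits: pd.DataFrame
    lipid_variance: pd.DataFrame
    lipid_variance_fractions: pd.Series
    metabolite_variance_fractions: pd.Series
    enrichment: pd.DataFrame
    class_totals: pd.DataFrame
    acyl_totals: pd.DataFrame
    omega_ratio: pd.Series
    heatmap: pd.DataFrame
    group_tests: pd.DataFrame
    report: ProcessingReport

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.lipid_concentrations.data.to_csv(
            outdir / "lipid_concentrations.tsv", sep="\t", index=False)
        for name, fits in (("lipid", self.lipid_fits),
                           ("metabolite", self.metabolite_fits),
                           ("protein", self.protein_fits)):
            if fits is not None:
                inference.fits_long(fits).to_csv(
                    outdir / f"fits_{name}.tsv", sep="\t", index=False)
        self.lipid_variance.to_csv(outdir / "variance.tsv", sep="\t")
        pd.DataFrame({
            "lipid": self.lipid_variance_fractions,
            "metabolite": self.metabolite_variance_fractions,
        }).to_csv(outdir / "variance_summary.tsv", sep="\t")
        self.enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        self.class_totals.to_csv(outdir / "class_totals.tsv", sep="\t")
        self.acyl_totals.to_csv(outdir / "acyl_totals.tsv", sep="\t", index=False)
        self.omega_ratio.to_csv(outdir / "omega_ratio.tsv", sep="\t")
        self.heatmap.to_csv(outdir / "heatmap_matrix.tsv", sep="\t")
        self.group_tests.to_csv(outdir / "group_tests.tsv", sep="\t", index=False)
        self.report.to_json(outdir / "processing_report.json")


def analyze_study(design: pd.DataFrame,
                  lipids: FeatureTable,
                  metabolites: Optional[FeatureTable],
                  proteins: Optional[FeatureTable],
                  is_map: pd.DataFrame,
                  species: Optional[dict[str, LipidSpecies]] = None,
                  rank_coefficient: str = "beta_diet",
                  n_perm: int = 10_000,
                  seed: int = 0,
                  omega_lookup: Optional[OmegaLookup] = None) -> StudyResults:
    """Run the full analysis on one study's tables.

    Lipids are quantified against class-matched standards and modeled as
    log2 concentration; metabolites are log2-normalized to the young-chow
    mean; proteins are bridge-normalized per plex and weighted by inverse
    ion count.  Raises if the design fails validation.
    """
    report = ProcessingReport()
    tables = [t for t in (lipids, metabolites, proteins) if t is not None]
    check = validate_design(design, tables)
    if not check.empty:
        raise ValueError(f"design validation failed: {check.to_dict()}")

    if species is None:
        is_ids = set(is_map["is_feature_id"])
        species = {}
        for fid in lipids.data["feature_id"].unique():
            if fid in is_ids:
                continue
            try:
                species[fid] = parse_lipid_name(fid)
            except Exception:
                report.add("annotate", "unparseable lipid name", feature_id=fid)

    conc = quantify.quantify_lipids(lipids, species, is_map, report)
    log2_conc = conc.data.copy()
    log2_conc["value"] = np.log2(log2_conc["value"])
    lipid_fits = inference.fit_all(log2_conc, design, report=report)

    metabolite_fits = None
    met_fractions = pd.Series(dtype=float)
    if metabolites is not None:
        met_norm = quantify.log2_normalize_to_reference(
            metabolites, design, reference="young-chow", report=report)
        metabolite_fits = inference.fit_all(met_norm.data, design, report=report)
        met_fractions = variance.dataset_variance_explained(
            variance.anova_all(met_norm.data, design))

    protein_fits = None
    if proteins is not None:
        prot_norm = quantify.bridge_normalize(proteins, design, report=report)
        protein_fits = inference.fit_all(prot_norm.data, design,
                                         weight_col="ion_count", report=report)

    lipid_var = variance.anova_all(log2_conc, design)
    lipid_fractions = variance.dataset_variance_explained(lipid_var)

    sets = enr.build_sets(species, report)
    ranked = enr.rank_features(lipid_fits, rank_coefficient)
    enrich = enr.permutation_test(ranked, sets, n_perm=n_perm, seed=seed,
                                  report=report)

    ctotals = reporting.class_totals(conc, species, report)
    atotals = reporting.acyl_class_totals(conc, species, report)
    ratio = reporting.omega_ratio(atotals, omega_lookup, report)

    acyl_wide = (atotals.assign(key=atotals["lipid_class"] + "|" + atotals["acyl"])
                 .pivot(index="sample_id", columns="key", values="value")
                 .fillna(0.0))
    heatmap = pd.concat([
        reporting.log2_ratio_of_group_means(ctotals, design).rename("log2fc").to_frame()
        .assign(level="class"),
        reporting.log2_ratio_of_group_means(acyl_wide, design).rename("log2fc").to_frame()
        .assign(level="class_acyl"),
    ])

    tests = []
    for cls in ctotals.columns:
        try:
            t, p = reporting.group_t_test(ctotals[cls], design,
                                          ("adult-hfd", "adult-chow"))
        except ValueError:
            t = p = np.nan
        tests.append({"quantity": f"class:{cls}", "t": t, "p": p,
                      "stars": reporting.p_to_stars(p)})
    ok = ratio.dropna()
    if len(ok) >= 4:
        t, p = reporting.group_t_test(ok, design, ("adult-hfd", "adult-chow"))
        tests.append({"quantity": "omega6_omega3_ratio", "t": t, "p": p,
                      "stars": reporting.p_to_stars(p)})
    group_tests = pd.DataFrame(tests)

    return StudyResults(
        lipid_concentrations=conc,
        lipid_fits=lipid_fits,
        metabolite_fits=metabolite_fits,
        protein_fits=protein_fits,
        lipid_variance=lipid_var,
        lipid_variance_fractions=lipid_fractions,
        metabolite_variance_fractions=met_fractions,
        enrichment=enrich,
        class_totals=ctotals,
        acyl_totals=atotals,
        omega_ratio=ratio,
        heatmap=heatmap,
        group_tests=group_tests,
        report=report)


def analyze_synthetic(study: SyntheticStudy, **kwargs) -> StudyResults:
    """Convenience wrapper: analyze a generated study with its own annotations."""
    return analyze_study(study.design, study.lipids, study.metabolites,
                         study.proteins, study.is_map, species=study.species,
                         **kwargs)
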