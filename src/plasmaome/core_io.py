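"""Data model, validation, and CSV readers/writers for all pipeline tables.

All tables travel as long (tidy) CSVs: ``samples.csv`` for the study design,
``<modality>.csv`` feature tables with columns ``feature_id, sample_id,
value[, ion_count]``, and ``is_map.csv`` mapping each quantified lipid class
to its internal standard.  Long form is robust to unbalanced designs — the
mixed model simply drops missing cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "ValidationError",
    "ValidationReport",
    "ProcessingReport",
    "read_feature_table",
    "write_feature_table",
    "read_design",
    "write_design",
    "read_is_map",
    "write_is_map",
    "validate_design",
    "group_label",
    "MODALITIES",
    "AGE_GROUPS",
    "DIETS",
    "DRAW_BATCHES",
    "REFERENCE_BATCH",
]

MODALITIES = ("lipid", "metabolite", "protein")
AGE_GROUPS = ("young", "adult")
DIETS = ("chow", "hfd")
DRAW_BATCHES = ("Z10", "Z22", "Z15")  # Z10 is the model reference level
REFERENCE_BATCH = "Z10"

DESIGN_COLUMNS = ["sample_id", "mouse_id", "age_group", "diet", "draw_batch",
                  "plex", "channel", "is_bridge"]


class ValidationError(ValueError):
    """A table violates its contract; message names the offending row(s)."""


@dataclass
class FeatureTable:
    """Feature x sample observations for one modality.

    ``data`` columns: feature_id, sample_id, value, ion_count (ion_count is
    required for proteins — it drives the 1/ion-count observation weights —
    and must be absent/NaN otherwise).
    """

    modality: str
    data: pd.DataFrame
    scale: str = "intensity"  # intensity | concentration | log2

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        df = self.data
        required = {"feature_id", "sample_id", "value"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"missing column(s): {sorted(missing)}")
        if "ion_count" not in df.columns:
            df = df.assign(ion_count=np.nan)
        df = df[["feature_id", "sample_id", "value", "ion_count"]].copy()
        dup = df.duplicated(["feature_id", "sample_id"])
        if dup.any():
            first = df.loc[dup.idxmax(), ["feature_id", "sample_id"]]
            raise ValidationError(
                f"duplicate (feature_id, sample_id) key: "
                f"({first['feature_id']!r}, {first['sample_id']!r})")
        if not np.isfinite(df["value"].to_numpy(dtype=float)).all():
            bad = df.index[~np.isfinite(df["value"].astype(float))][0]
            raise ValidationError(f"non-finite value at row {bad}")
        ion = df["ion_count"].to_numpy(dtype=float)
        if self.modality == "protein":
            if np.isnan(ion).any():
                bad = int(np.flatnonzero(np.isnan(ion))[0])
                raise ValidationError(f"protein table requires ion_count (row {bad})")
            if (ion <= 0).any():
                bad = int(np.flatnonzero(ion <= 0)[0])
                raise ValidationError(f"ion_count must be positive (row {bad})")
        else:
            if not np.isnan(ion).all():
                bad = int(np.flatnonzero(~np.isnan(ion))[0])
                raise ValidationError(
                    f"ion_count only allowed for proteins (row {bad})")
        self.data = df.reset_index(drop=True)

    @property
    def feature_ids(self) -> list[str]:
        return sorted(self.data["feature_id"].unique())

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.data["sample_id"].unique())

    def pivot(self) -> pd.DataFrame:
        """Wide feature x sample matrix of values."""
        return self.data.pivot(index="feature_id", columns="sample_id", values="value")


def read_feature_table(path: str | Path, modality: str) -> FeatureTable:
    """Read and validate a long-format feature CSV. Row order is irrelevant."""
    df = pd.read_csv(path, dtype={"feature_id": str, "sample_id": str})
    return FeatureTable(modality, df)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    df = table.data
    if table.modality != "protein":
        df = df.drop(columns=["ion_count"])
    df.to_csv(path, index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={c: str for c in DESIGN_COLUMNS if c != "is_bridge"})
    missing = set(DESIGN_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"design missing column(s): {sorted(missing)}")
    df["is_bridge"] = df["is_bridge"].astype(int).astype(bool)
    return df[DESIGN_COLUMNS]


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    out = design.copy()
    out["is_bridge"] = out["is_bridge"].astype(int)
    out.to_csv(path, index=False)


def read_is_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"lipid_class": str, "is_feature_id": str})
    required = {"lipid_class", "is_feature_id", "is_concentration"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"is_map missing column(s): {sorted(missing)}")
    if df["lipid_class"].duplicated().any():
        dup = df.loc[df["lipid_class"].duplicated(), "lipid_class"].iloc[0]
        raise ValidationError(f"duplicate internal-standard entry for class {dup!r}")
    if (df["is_concentration"] <= 0).any():
        bad = df.loc[df["is_concentration"] <= 0, "lipid_class"].iloc[0]
        raise ValidationError(f"is_concentration must be > 0 (class {bad!r})")
    return df[["lipid_class", "is_feature_id", "is_concentration"]]


def write_is_map(is_map: pd.DataFrame, path: str | Path) -> None:
    is_map.to_csv(path, index=False)


def group_label(design: pd.DataFrame) -> pd.Series:
    """Experimental group of each sample, e.g. ``young-chow`` (bridges -> NA)."""
    lab = design["age_group"].str.cat(design["diet"], sep="-")
    return lab.mask(design["is_bridge"])


@dataclass
class ValidationReport:
    """Report-only design/table consistency check; callers decide to abort."""

    missing_samples: list[dict] = field(default_factory=list)
    inconsistent_mice: list[dict] = field(default_factory=list)
    plexes_without_bridge: list[str] = field(default_factory=list)
    other: list[str] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not (self.missing_samples or self.inconsistent_mice
                    or self.plexes_without_bridge or self.other)

    def to_dict(self) -> dict:
        return {
            "missing_samples": self.missing_samples,
            "inconsistent_mice": self.inconsistent_mice,
            "plexes_without_bridge": self.plexes_without_bridge,
            "other": self.other,
        }


def validate_design(design: pd.DataFrame,
                    tables: Sequence[FeatureTable] = ()) -> ValidationReport:
    """Cross-check a study design against feature tables (pure, report-only)."""
    report = ValidationReport()
    if design["sample_id"].duplicated().any():
        dup = design.loc[design["sample_id"].duplicated(), "sample_id"].iloc[0]
        report.other.append(f"duplicate sample_id {dup!r}")

    bio = design[~design["is_bridge"]]
    for mouse, grp in bio.groupby("mouse_id"):
        if grp["age_group"].nunique() > 1 or grp["diet"].nunique() > 1:
            report.inconsistent_mice.append({
                "mouse_id": mouse,
                "age_groups": sorted(grp["age_group"].unique()),
                "diets": sorted(grp["diet"].unique()),
            })

    for table in tables:
        expected = set(bio["sample_id"])
        if table.modality == "protein":
            expected = set(design["sample_id"])
        present = set(table.data["sample_id"].unique())
        for sid in sorted(expected - present):
            report.missing_samples.append(
                {"sample_id": sid, "modality": table.modality})

    has_protein = any(t.modality == "protein" for t in tables)
    if has_protein or design["is_bridge"].any():
        for plex, grp in design.dropna(subset=["plex"]).groupby("plex"):
            n_bridge = int(grp["is_bridge"].sum())
            if n_bridge != 1:
                report.plexes_without_bridge.append(str(plex))
    return report


class ProcessingReport:
    """Accumulates machine-readable warnings instead of aborting."""

    def __init__(self):
        self.entries: list[dict] = []

    def add(self, stage: str, message: str, **context) -> None:
        self.entries.append({"stage": stage, "message": message, **context})

    def __len__(self) -> int:
        return len(self.entries)

    def to_json(self, path: Optional[str | Path] = None) -> str:
        text = json.dumps(self.entries, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text
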