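"""Synthetic multi-omic plasma studies with the structure the inference assumes.

The generator emulates the repeated-measures design the pipeline targets:
3 groups (young-chow, adult-chow, adult-HFD) x 10 mice x 3 blood-draw
batches (Z10, Z22, Z15) = 90 samples.  Every feature's log2 signal follows
the additive model the inference module fits,

    log2 y = alpha + beta_age*a + beta_diet*d + beta_batch[k] + b_m + eps,

with mouse random intercepts b_m ~ N(0, tau2) and residuals eps ~
N(0, sigma2) — for proteins, N(0, sigma2 / ion_count) with per-scan ion
counts drawn log-uniformly.  Lipids are generated as log2 concentrations
and converted to peak areas through a class response factor and the
internal-standard area, so internal-standard quantification inverts the
areas back to the generated concentrations exactly.  Proteins are laid out
in 16-channel plexes (15 samples + 1 bridge); the bridge is a pooled
control combining all samples (identical expected composition in every
plex) plus noise, and every channel in a plex shares a multiplicative plex
offset that bridge normalization removes.

Planted set effects (e.g. all CE species up with diet, all 20:5 chains
down) override the per-feature diet/age coefficients of member species and
are recorded in the ground-truth table for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import (MOLECULAR_SPECIES, LipidSpecies,
                         format_lipid_name, parse_lipid_name)
from .core_io import (DRAW_BATCHES, FeatureTable, write_design,
                      write_feature_table, write_is_map)

__all__ = ["SimConfig", "PlantedSet", "SyntheticStudy", "generate_study",
           "catalog_species", "make_design", "simulate_features"]

GROUPS = (("young", "chow"), ("adult", "chow"), ("adult", "hfd"))

#: TMTpro 16-plex reporter channels; 134N is the bridge channel.
TMT_CHANNELS = ["126", "127N", "127C", "128N", "128C", "129N", "129C", "130N",
                "130C", "131N", "131C", "132N", "132C", "133N", "133C", "134N"]
BRIDGE_CHANNEL = "134N"

#: acyl pool used when sampling molecular species (plasma-typical chains)
ACYL_POOL = [(14, 0), (16, 0), (16, 1), (17, 0), (18, 0), (18, 1), (18, 2),
             (18, 3), (20, 3), (20, 4), (20, 5), (22, 4), (22, 5), (22, 6),
             (24, 1)]

#: the 16 lipid classes/subclasses of the built-in catalog
CATALOG_CLASSES = ["CE", "FA", "MG", "LPC", "LPE",
                   "PC", "PE", "PI", "PS", "PG", "PA", "DG", "SM",
                   "PC O-", "PE P-", "TG"]

#: log2 baseline abundance offset per class, loosely mirroring mouse plasma
#: (CE and TG dominate the molar pool; ether species are minor)
CLASS_BASELINE = {"CE": 3.0, "TG": 2.5, "PC": 2.0, "SM": 1.0, "LPC": 1.0,
                  "FA": 1.5, "PE": 0.5, "PI": 0.0, "DG": 0.0, "MG": -1.0,
                  "LPE": -0.5, "PS": -1.0, "PG": -1.5, "PA": -1.5,
                  "PC O-": -0.5, "PE P-": -0.5}

_FACTORS = ("age", "diet", "batch")


@dataclass(frozen=True)
class PlantedSet:
    """A set-level effect planted into the truth: all members of a lipid
    class (``class:CE``) or acyl (``acyl:20:5``) get this signed coefficient
    for the given factor (overriding their individual draw)."""

    set_id: str       # "class:<subclass key>" or "acyl:<c>:<d>"
    factor: str       # age | diet | batch
    effect: float     # signed log2 effect


@dataclass
class SimConfig:
    """Study-generator configuration; defaults are the emulated study design."""

    n_mice_per_group: int = 10
    n_lipids: int = 160
    n_metabolites: int = 60
    n_proteins: int = 60
    #: per-factor fraction of non-null features
    pi1: dict = field(default_factory=lambda: {"age": 0.5, "diet": 0.9, "batch": 0.3})
    #: per-factor (mean, sd) of the non-null log2 effect draw
    effect_dist: dict = field(default_factory=lambda: {
        "age": (0.0, 1.0), "diet": (0.0, 1.5), "batch": (0.0, 0.4)})
    tau2: float = 0.15
    sigma2: float = 0.35
    ion_count_range: tuple[float, float] = (1e2, 1e6)
    plex_offset_sd: float = 1.0  # log2 sd of the per-plex technical offset
    planted_sets: tuple[PlantedSet, ...] = (
        PlantedSet("class:CE", "diet", 2.0),
        PlantedSet("acyl:20:4", "diet", 1.5),
        PlantedSet("acyl:20:5", "diet", -1.5),
    )
    dropout: float = 0.0  # MCAR missingness rate
    sample_loading_sd: float = 0.0  # log2 sd of per-sample global area factor
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.pi1, (int, float)):
            self.pi1 = {f: float(self.pi1) for f in _FACTORS}
        if (isinstance(self.effect_dist, tuple)
                and not isinstance(self.effect_dist, dict)):
            self.effect_dist = {f: tuple(self.effect_dist) for f in _FACTORS}
        for f in _FACTORS:
            if not 0.0 <= self.pi1[f] <= 1.0:
                raise ValueError(f"pi1[{f}] must be in [0, 1]")
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        lo, hi = self.ion_count_range
        if not lo < hi:
            raise ValueError("ion_count_range must satisfy low < high")
        self.planted_sets = tuple(
            p if isinstance(p, PlantedSet) else PlantedSet(*p)
            for p in self.planted_sets)


@dataclass
class SyntheticStudy:
    """Everything :func:`generate_study` produces, plus the ground truth."""

    design: pd.DataFrame
    lipids: FeatureTable          # peak areas incl. internal-standard rows
    metabolites: FeatureTable     # raw intensities
    proteins: FeatureTable        # reporter intensities with ion counts
    is_map: pd.DataFrame
    truth: pd.DataFrame           # per-feature true parameters and flags
    species: dict[str, LipidSpecies]
    config: SimConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_design(self.design, outdir / "samples.csv")
        write_feature_table(self.lipids, outdir / "lipid.csv")
        write_feature_table(self.metabolites, outdir / "metabolite.csv")
        write_feature_table(self.proteins, outdir / "protein.csv")
        write_is_map(self.is_map, outdir / "is_map.csv")
        self.truth.to_csv(outdir / "truth.csv", index=False)


def _rng(seed: int, stream: int) -> np.random.Generator:
    # named substreams so adding a modality does not shift the others' draws
    return np.random.default_rng([int(seed) % (2**31), stream])


def make_design(n_mice_per_group: int = 10, with_plexes: bool = True,
                plex_size: int = 15) -> pd.DataFrame:
    """90-sample design: 3 groups x n mice x 3 draw batches, plus bridges.

    Proteomics plexes hold ``plex_size`` biological samples plus one bridge
    channel each (16-plex layout); assignment follows sample order.
    """
    rows = []
    mouse_no = 0
    for age, diet in GROUPS:
        for _ in range(n_mice_per_group):
            mouse_no += 1
            mouse_id = f"m{mouse_no:02d}"
            for batch in DRAW_BATCHES:
                rows.append({"sample_id": f"s{len(rows) + 1:03d}",
                             "mouse_id": mouse_id, "age_group": age,
                             "diet": diet, "draw_batch": batch,
                             "plex": None, "channel": None, "is_bridge": False})
    design = pd.DataFrame(rows)
    if with_plexes:
        n = len(design)
        channels = [c for c in TMT_CHANNELS if c != BRIDGE_CHANNEL]
        plex_ids, chan = [], []
        for i in range(n):
            plex_ids.append(f"plex{i // plex_size + 1}")
            chan.append(channels[i % plex_size])
        design["plex"] = plex_ids
        design["channel"] = chan
        bridges = []
        for plex in design["plex"].unique():
            bridges.append({"sample_id": f"bridge_{plex}", "mouse_id": "pooled",
                            "age_group": None, "diet": None, "draw_batch": None,
                            "plex": plex, "channel": BRIDGE_CHANNEL,
                            "is_bridge": True})
        design = pd.concat([design, pd.DataFrame(bridges)], ignore_index=True)
    return design


def catalog_species(n_lipids: int, seed: int = 0) -> list[str]:
    """Molecular-species catalog covering all 16 built-in classes.

    Guarantees one species per class, the presence of ``CE 20:4``, and at
    least one species per acyl in {16:0, 18:1, 20:4, 20:5, 22:4, 22:6};
    remaining species are sampled with plasma-typical chains.  Names are
    valid shorthand and re-parse without error.
    """
    if n_lipids < 16:
        raise ValueError("catalog needs n_lipids >= 16 (one species per class)")
    rng = _rng(seed, 4)
    names: list[str] = []
    seen: set[str] = set()

    def add(name: str) -> None:
        canon = format_lipid_name(parse_lipid_name(name))
        if canon not in seen:
            seen.add(canon)
            names.append(canon)

    # one representative per class first (n=16 covers every class), chosen so
    # the 16 together span the required acyls incl. 20:5 and 22:4
    add("CE 20:4")
    add("FA 18:1")
    add("MG 16:0")
    add("LPC 16:0")
    add("LPE 18:0")
    add("PC 16:0_20:4")
    add("PE 18:0_22:6")
    add("PI 18:0_20:4")
    add("PS 18:0_18:1")
    add("PG 16:0_18:1")
    add("PA 16:0_18:2")
    add("DG 18:1_18:2")
    add("SM d18:1/16:0")
    add("PC O-16:0/18:1")
    add("PE P-16:0/22:6")
    add("TG 18:1_20:5_22:4")
    # further plasma staples for larger catalogs
    add("CE 20:5")
    add("CE 22:6")
    add("TG 16:0_18:1_22:4")
    add("TG 16:0_18:1_20:5")

    def random_species(cls: str) -> str:
        base = cls.split(" ")[0]
        n_chain = {"CE": 1, "FA": 1, "MG": 1, "LPC": 1, "LPE": 1, "TG": 3}.get(base, 2)
        chains = [ACYL_POOL[rng.integers(len(ACYL_POOL))] for _ in range(n_chain)]
        if cls == "SM":
            body = f"d18:1/{chains[0][0]}:{chains[0][1]}"
            return f"SM {body}"
        if cls == "PC O-":
            return f"PC O-{chains[0][0]}:{chains[0][1]}/{chains[1][0]}:{chains[1][1]}"
        if cls == "PE P-":
            return f"PE P-{chains[0][0]}:{chains[0][1]}/{chains[1][0]}:{chains[1][1]}"
        return f"{base} " + "_".join(f"{c}:{d}" for c, d in chains)

    attempts = 0
    while len(names) < n_lipids and attempts < 100 * n_lipids:
        cls = CATALOG_CLASSES[rng.integers(len(CATALOG_CLASSES))]
        add(random_species(cls))
        attempts += 1
    if len(names) > n_lipids:
        names = names[:n_lipids]
    return names


def _planted_members(planted: PlantedSet,
                     species: dict[str, LipidSpecies]) -> set[str]:
    kind, _, key = planted.set_id.partition(":")
    if kind == "class":
        members = {fid for fid, sp in species.items() if sp.subclass_key == key}
    elif kind == "acyl":
        c, _, d = key.partition(":")
        chain = (int(c), int(d))
        members = {fid for fid, sp in species.items()
                   if sp.level == MOLECULAR_SPECIES
                   and any((ch.carbons, ch.double_bonds) == chain
                           for ch in sp.chains)}
    else:
        raise ValueError(f"unknown planted set kind {planted.set_id!r}")
    if not members:
        raise ValueError(f"planted set {planted.set_id!r} matches no species")
    return members


def _draw_truth(feature_ids: Sequence[str], cfg: SimConfig,
                rng: np.random.Generator,
                alpha_loc: float, alpha_sd: float,
                baselines: Optional[dict[str, float]] = None) -> pd.DataFrame:
    n = len(feature_ids)
    truth = pd.DataFrame({"feature_id": list(feature_ids)})
    alpha = rng.normal(alpha_loc, alpha_sd, size=n)
    if baselines:
        alpha += np.array([baselines.get(f, 0.0) for f in feature_ids])
    truth["alpha"] = alpha
    for fac, cols in (("age", ["beta_age"]), ("diet", ["beta_diet"]),
                      ("batch", ["beta_z22", "beta_z15"])):
        nonnull = rng.random(n) < cfg.pi1[fac]
        mean, sd = cfg.effect_dist[fac]
        for col in cols:
            beta = np.where(nonnull, rng.normal(mean, sd, size=n), 0.0)
            truth[col] = beta
        truth[f"nonnull_{fac}"] = nonnull
    truth["tau2"] = cfg.tau2
    truth["sigma2"] = cfg.sigma2
    truth["planted"] = ""
    return truth


def _apply_planted(truth: pd.DataFrame, cfg: SimConfig,
                   species: dict[str, LipidSpecies]) -> pd.DataFrame:
    truth = truth.set_index("feature_id")
    for planted in cfg.planted_sets:  # listed order; later entries win
        members = _planted_members(planted, species)
        idx = truth.index.intersection(members)
        if planted.factor == "age":
            truth.loc[idx, "beta_age"] = planted.effect
            truth.loc[idx, "nonnull_age"] = planted.effect != 0
        elif planted.factor == "diet":
            truth.loc[idx, "beta_diet"] = planted.effect
            truth.loc[idx, "nonnull_diet"] = planted.effect != 0
        elif planted.factor == "batch":
            # a Z10 elevation of `effect` = both non-reference batches lowered
            truth.loc[idx, "beta_z22"] = -planted.effect
            truth.loc[idx, "beta_z15"] = -planted.effect
            truth.loc[idx, "nonnull_batch"] = planted.effect != 0
        else:
            raise ValueError(f"unknown planted factor {planted.factor!r}")
        sep = truth.loc[idx, "planted"].str.len() > 0
        truth.loc[idx, "planted"] = (
            truth.loc[idx, "planted"] + np.where(sep, ";", "") + planted.set_id)
    return truth.reset_index()


def _signal_matrix(truth: pd.DataFrame, design_bio: pd.DataFrame,
                   rng: np.random.Generator, tau2: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free log2 signal (feature x sample) and the b_m draws."""
    a = (design_bio["age_group"] == "adult").to_numpy(dtype=float)
    d = (design_bio["diet"] == "hfd").to_numpy(dtype=float)
    t2 = (design_bio["draw_batch"] == "Z22").to_numpy(dtype=float)
    t3 = (design_bio["draw_batch"] == "Z15").to_numpy(dtype=float)
    mice, mouse_idx = np.unique(design_bio["mouse_id"].to_numpy(),
                                return_inverse=True)
    n_feat = len(truth)
    b = rng.normal(0.0, np.sqrt(tau2), size=(n_feat, mice.size))
    signal = (truth["alpha"].to_numpy()[:, None]
              + np.outer(truth["beta_age"], a)
              + np.outer(truth["beta_diet"], d)
              + np.outer(truth["beta_z22"], t2)
              + np.outer(truth["beta_z15"], t3)
              + b[:, mouse_idx])
    return signal, b


def simulate_features(design: pd.DataFrame, n_features: int, cfg: SimConfig,
                      stream: int = 9, prefix: str = "f"
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a plain log2 feature matrix (no modality plumbing).

    Convenience entry point for statistical calibration studies: returns a
    long value table (feature_id, sample_id, value on the log2 scale) and
    the ground-truth table, using the same model as the full generator.
    """
    rng = _rng(cfg.seed, stream)
    bio = design[~design["is_bridge"]]
    ids = [f"{prefix}{i + 1:05d}" for i in range(n_features)]
    truth = _draw_truth(ids, cfg, rng, alpha_loc=0.0, alpha_sd=1.0)
    signal, _ = _signal_matrix(truth, bio, rng, cfg.tau2)
    noise = rng.normal(0.0, np.sqrt(cfg.sigma2), size=signal.shape)
    log2v = signal + noise
    long = pd.DataFrame({
        "feature_id": np.repeat(ids, len(bio)),
        "sample_id": np.tile(bio["sample_id"].to_numpy(), n_features),
        "value": log2v.ravel(),
    })
    return long, truth


def _long(feature_ids, sample_ids, values: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({
        "feature_id": np.repeat(list(feature_ids), len(sample_ids)),
        "sample_id": np.tile(np.asarray(sample_ids), len(feature_ids)),
        "value": values.ravel(),
    })


def generate_study(config: SimConfig | None = None) -> SyntheticStudy:
    """Generate a complete synthetic study with ground truth.

    Lipid areas invert exactly under internal-standard quantification; the
    protein table carries per-observation ion counts, plex offsets, and a
    bridge channel per plex.  Identical configs (same seed) give
    bit-identical output.
    """
    cfg = config if config is not None else SimConfig()
    design = make_design(cfg.n_mice_per_group)
    bio = design[~design["is_bridge"]].reset_index(drop=True)
    sample_ids = bio["sample_id"].to_numpy()

    # ---- lipids: log2 concentration -> peak areas through class standards
    rng_l = _rng(cfg.seed, 1)
    names = catalog_species(cfg.n_lipids, cfg.seed)
    species = {name: parse_lipid_name(name) for name in names}
    baselines = {name: CLASS_BASELINE.get(sp.subclass_key, 0.0)
                 for name, sp in species.items()}
    truth_l = _draw_truth(names, cfg, rng_l, alpha_loc=1.0, alpha_sd=1.2,
                          baselines=baselines)
    truth_l = _apply_planted(truth_l, cfg, species)
    truth_l["modality"] = "lipid"
    signal, _ = _signal_matrix(truth_l, bio, rng_l, cfg.tau2)
    log2conc = signal + rng_l.normal(0.0, np.sqrt(cfg.sigma2), size=signal.shape)
    conc = 2.0 ** log2conc  # micromolar

    subclasses = sorted({sp.subclass_key for sp in species.values()})
    is_rows, is_area_of_class = [], {}
    loading = (2.0 ** rng_l.normal(0.0, cfg.sample_loading_sd, size=len(bio))
               if cfg.sample_loading_sd > 0 else np.ones(len(bio)))
    for cls in subclasses:
        is_conc = float(np.round(2.0 ** rng_l.normal(0.0, 0.5), 4))
        response = 2.0 ** rng_l.normal(0.0, 0.5)  # class response factor
        is_id = f"d7-IS {cls}"
        is_area_of_class[cls] = is_conc * response * 1e6 * loading
        is_rows.append({"lipid_class": cls, "is_feature_id": is_id,
                        "is_concentration": is_conc, "units": "uM"})
    is_map = pd.DataFrame(is_rows)

    area_rows = []
    for i, name in enumerate(names):
        cls = species[name].subclass_key
        is_conc = float(is_map.set_index("lipid_class").loc[cls, "is_concentration"])
        area = conc[i] / is_conc * is_area_of_class[cls]
        area_rows.append(pd.DataFrame({"feature_id": name,
                                       "sample_id": sample_ids, "value": area}))
    for row in is_rows:
        area_rows.append(pd.DataFrame({"feature_id": row["is_feature_id"],
                                       "sample_id": sample_ids,
                                       "value": is_area_of_class[row["lipid_class"]]}))
    lipid_df = pd.concat(area_rows, ignore_index=True)

    # ---- metabolites: raw intensities, log2-normal around alpha
    rng_m = _rng(cfg.seed, 2)
    met_ids = [f"met{i + 1:04d}" for i in range(cfg.n_metabolites)]
    truth_m = _draw_truth(met_ids, cfg, rng_m, alpha_loc=14.0, alpha_sd=2.0)
    truth_m["modality"] = "metabolite"
    sig_m, _ = _signal_matrix(truth_m, bio, rng_m, cfg.tau2)
    log2_m = sig_m + rng_m.normal(0.0, np.sqrt(cfg.sigma2), size=sig_m.shape)
    met_df = _long(met_ids, sample_ids, 2.0 ** log2_m)

    # ---- proteins: reporter intensities, ion-count weighted noise,
    #      per-plex offsets and bridge channels
    rng_p = _rng(cfg.seed, 3)
    prot_ids = [f"prot{i + 1:04d}" for i in range(cfg.n_proteins)]
    truth_p = _draw_truth(prot_ids, cfg, rng_p, alpha_loc=12.0, alpha_sd=1.5)
    truth_p["modality"] = "protein"
    sig_p, _ = _signal_matrix(truth_p, bio, rng_p, cfg.tau2)
    lo, hi = cfg.ion_count_range
    ion = np.exp(rng_p.uniform(np.log(lo), np.log(hi),
                               size=(cfg.n_proteins, len(bio))))
    eps = rng_p.normal(0.0, 1.0, size=sig_p.shape) * np.sqrt(cfg.sigma2 / ion)
    plex_of_sample = bio["plex"].to_numpy()
    plexes = design.loc[design["is_bridge"], "plex"].to_numpy()
    plex_offset = {pl: rng_p.normal(0.0, cfg.plex_offset_sd) for pl in plexes}
    offsets = np.array([plex_offset[pl] for pl in plex_of_sample])
    log2_p = sig_p + eps + offsets[None, :]
    prot_df = _long(prot_ids, sample_ids, 2.0 ** log2_p)
    prot_df["ion_count"] = ion.ravel()

    # the bridge is one pooled control combining ALL samples, labeled into
    # every plex: same expected composition everywhere, so normalizing to it
    # removes the plex offset without touching biological contrasts
    pooled = sig_p.mean(axis=1)
    bridge_rows = []
    for pl in plexes:
        ion_b = np.exp(rng_p.uniform(np.log(lo), np.log(hi), size=cfg.n_proteins))
        eps_b = rng_p.normal(0.0, 1.0, size=cfg.n_proteins) * np.sqrt(
            cfg.sigma2 / ion_b)
        log2_b = pooled + plex_offset[pl] + eps_b
        bridge_rows.append(pd.DataFrame({
            "feature_id": prot_ids, "sample_id": f"bridge_{pl}",
            "value": 2.0 ** log2_b, "ion_count": ion_b}))
    prot_df = pd.concat([prot_df] + bridge_rows, ignore_index=True)

    if cfg.dropout > 0:
        rng_d = _rng(cfg.seed, 5)
        for df in (lipid_df, met_df):
            keep = rng_d.random(len(df)) >= cfg.dropout
            df.drop(df.index[~keep], inplace=True)
        keep = ((rng_d.random(len(prot_df)) >= cfg.dropout)
                | prot_df["sample_id"].str.startswith("bridge_"))
        prot_df.drop(prot_df.index[~keep], inplace=True)

    truth = pd.concat([truth_l, truth_m, truth_p], ignore_index=True)
    return SyntheticStudy(
        design=design,
        lipids=FeatureTable("lipid", lipid_df.reset_index(drop=True)),
        metabolites=FeatureTable("metabolite", met_df.reset_index(drop=True)),
        proteins=FeatureTable("protein", prot_df.reset_index(drop=True)),
        is_map=is_map, truth=truth, species=species, config=cfg)
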