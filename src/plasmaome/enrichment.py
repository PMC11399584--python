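"""Preranked set enrichment of lipid classes and acyl chains by permutation.

Features (lipid species) are ranked by a model coefficient (the diet effect
estimate, by default).  Two set collections are tested: one set per lipid
class/subclass, and one per distinct acyl chain (``FA c:d``), where a
molecular species belongs to the acyl set of each chain it contains (once,
regardless of multiplicity; molar multiplicity matters only in aggregation,
see :mod:`plasmaome.reporting`).  Sum-composition species have unknown
chains and are excluded from acyl sets.

The enrichment score is the classic weighted Kolmogorov-Smirnov running-sum
statistic: walking down the ranking, hits advance by |score|^p normalized by
the in-set total, misses retreat by 1/(N-K); ES is the signed maximum
deviation from zero.  The permutation null draws random same-size member
sets from the ranked features; when C(N, K) <= 10,000 the null is enumerated
exhaustively instead.  NES = ES / mean(|null ES| of the matching sign), and
its sign gives the direction of change.  BH adjustment is applied across
sets within each collection.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .annotation import MOLECULAR_SPECIES, LipidSpecies
from .core_io import ProcessingReport

__all__ = [
    "RankedList",
    "build_sets",
    "enrichment_score",
    "permutation_test",
    "rank_features",
    "EXHAUSTIVE_LIMIT",
]

EXHAUSTIVE_LIMIT = 10_000


@dataclass
class RankedList:
    """Features sorted by decreasing score; ties broken by feature id."""

    feature_ids: np.ndarray
    scores: np.ndarray

    @classmethod
    def from_scores(cls, scores: Mapping[str, float] | pd.Series) -> "RankedList":
        s = pd.Series(scores, dtype=float).dropna()
        if not np.isfinite(s.to_numpy()).all():
            raise ValueError("scores must be finite")
        s = s.sort_index(kind="mergesort")  # stable id order for ties
        s = s.sort_values(ascending=False, kind="mergesort")
        return cls(s.index.to_numpy(), s.to_numpy())

    def __len__(self) -> int:
        return len(self.scores)


def rank_features(fits: pd.DataFrame, coefficient: str = "beta_diet") -> RankedList:
    """Rank by a fitted model coefficient (the estimate, not t or -log p)."""
    if coefficient not in fits.columns:
        raise KeyError(f"coefficient {coefficient!r} not in fits table")
    return RankedList.from_scores(fits[coefficient])


def build_sets(species: Mapping[str, LipidSpecies],
               report: ProcessingReport | None = None
               ) -> dict[str, dict[str, set[str]]]:
    """Build class and acyl set collections from parsed annotations.

    Returns ``{"class": {class_key: ids}, "acyl": {"FA c:d": ids}}``.
    """
    if report is None:
        report = ProcessingReport()
    class_sets: dict[str, set[str]] = {}
    acyl_sets: dict[str, set[str]] = {}
    for fid, sp in species.items():
        class_sets.setdefault(sp.subclass_key, set()).add(fid)
        if sp.level == MOLECULAR_SPECIES:
            for ch in sp.chains:
                acyl_sets.setdefault(f"FA {ch.carbons}:{ch.double_bonds}", set()).add(fid)
        else:
            report.add("build_sets", "sum-composition species excluded from acyl sets",
                       feature_id=fid)
    return {"class": class_sets, "acyl": acyl_sets}


def enrichment_score(ranked: RankedList, members: Iterable[str],
                     p: float = 1.0) -> float:
    """Weighted-KS running-sum enrichment score of a member set, in [-1, 1]."""
    ids = ranked.feature_ids
    member_set = set(members)
    in_set = np.fromiter((f in member_set for f in ids), dtype=bool, count=len(ids))
    return _es_from_mask(ranked.scores, in_set, p)


def _es_from_mask(scores: np.ndarray, in_set: np.ndarray, p: float = 1.0) -> float:
    N = scores.size
    K = int(in_set.sum())
    if K == 0:
        raise ValueError("set has empty intersection with the ranked list")
    if K == N:
        raise ValueError("set covers every ranked feature")
    hit = np.where(in_set, np.abs(scores) ** p, 0.0)
    nr = hit.sum()
    if nr == 0:  # all member scores exactly zero: fall back to uniform steps
        hit = in_set / K
    else:
        hit = hit / nr
    miss = np.where(in_set, 0.0, 1.0 / (N - K))
    run = np.cumsum(hit - miss)
    return float(run[np.argmax(np.abs(run))])


def _null_es_exhaustive(scores: np.ndarray, k: int, p: float) -> np.ndarray:
    N = scores.size
    out = np.empty(math.comb(N, k))
    mask = np.zeros(N, dtype=bool)
    for i, combo in enumerate(itertools.combinations(range(N), k)):
        mask[:] = False
        mask[list(combo)] = True
        out[i] = _es_from_mask(scores, mask, p)
    return out


def _null_es_sampled(scores: np.ndarray, k: int, p: float, n_perm: int,
                     rng: np.random.Generator) -> np.ndarray:
    N = scores.size
    out = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(N, size=k, replace=False)
        mask = np.zeros(N, dtype=bool)
        mask[idx] = True
        out[i] = _es_from_mask(scores, mask, p)
    return out


def permutation_test(ranked: RankedList,
                     sets: Mapping[str, Iterable[str]] | Mapping[str, Mapping],
                     n_perm: int = 10_000,
                     seed: int = 0,
                     weight_p: float = 1.0,
                     method: str = "auto",
                     report: ProcessingReport | None = None) -> pd.DataFrame:
    """Test each set for enrichment against a random-same-size-set null.

    Parameters
    ----------
    sets : either one collection ``{set_id: ids}`` or nested collections
        ``{"class": {...}, "acyl": {...}}``; BH adjustment is applied within
        each collection.
    method : "auto" enumerates all C(N, K) same-size sets when that count is
        at most 10,000 (exact p), else samples ``n_perm`` sets with the
        (b+1)/(n_perm+1) estimator; "sample"/"exhaustive" force a mode.

    Returns a DataFrame with set_id, collection, size, ES, NES, p_perm,
    p_bh, direction, and -log10(p_bh). Deterministic given ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if report is None:
        report = ProcessingReport()
    first_val = next(iter(sets.values()), None)
    if isinstance(first_val, Mapping):
        collections = {name: dict(coll) for name, coll in sets.items()}
    else:
        collections = {"sets": dict(sets)}

    rng = np.random.default_rng(seed)
    scores = ranked.scores
    id_index = {f: i for i, f in enumerate(ranked.feature_ids)}
    N = scores.size
    null_cache: dict[int, np.ndarray] = {}
    frames = []
    for coll_name, coll in collections.items():
        rows = []
        for set_id in sorted(coll):
            members = [f for f in coll[set_id] if f in id_index]
            k = len(members)
            if k == 0:
                report.add("enrich", "empty intersection; skipped",
                           set_id=set_id, collection=coll_name)
                continue
            if k >= N:
                report.add("enrich", "set covers all ranked features; skipped",
                           set_id=set_id, collection=coll_name)
                continue
            mask = np.zeros(N, dtype=bool)
            mask[[id_index[f] for f in members]] = True
            es = _es_from_mask(scores, mask, weight_p)

            if k not in null_cache:
                exhaustive = (method == "exhaustive"
                              or (method == "auto"
                                  and math.comb(N, k) <= EXHAUSTIVE_LIMIT))
                if exhaustive:
                    null_cache[k] = _null_es_exhaustive(scores, k, weight_p)
                else:
                    null_cache[k] = _null_es_sampled(scores, k, weight_p,
                                                     n_perm, rng)
            null = null_cache[k]
            is_exact = null.size == math.comb(N, k) and method != "sample"

            if es >= 0:
                b = int((null >= es).sum())
                same = null[null > 0]
            else:
                b = int((null <= es).sum())
                same = null[null < 0]
            if is_exact and (method == "exhaustive" or method == "auto"):
                p_perm = b / null.size
                p_perm = max(p_perm, 1.0 / null.size)
            else:
                p_perm = (b + 1) / (null.size + 1)
            denom = np.abs(same).mean() if same.size else np.abs(null).mean()
            nes = es / denom if denom > 0 else 0.0
            rows.append({"set_id": set_id, "collection": coll_name, "size": k,
                         "ES": es, "NES": nes, "p_perm": p_perm})
        if not rows:
            continue
        df = pd.DataFrame(rows)
        df["p_bh"] = multipletests(df["p_perm"].to_numpy(), method="fdr_bh")[1]
        frames.append(df)
    if not frames:
        raise ValueError("no testable set in any collection")
    out = pd.concat(frames, ignore_index=True)
    out["direction"] = np.where(out["NES"] >= 0, "+", "-")
    out["neg_log10_p_bh"] = -np.log10(np.maximum(out["p_bh"], np.finfo(float).tiny))
    return out
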