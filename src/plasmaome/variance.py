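"""Sequential (Type-I) ANOVA decomposition and dataset-level variance summaries.

Each feature's total sum of squares (TSS = Var(y)*N) is decomposed by fitting
nested fixed-factor models in the fixed order age, diet, draw batch, mouse:
ESS of a factor is the drop in residual SS when that factor's dummies are
added.  Mouse is entered last so that, with mice nested inside age x diet,
the mouse term absorbs only the remaining between-mouse variation.  Telescoping
makes ESS_age + ESS_diet + ESS_batch + ESS_mouse + RSS = TSS exact.

Dataset-level variance explained by a factor = sum of its ESS across features
divided by the summed TSS.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .inference import design_matrix

__all__ = ["sequential_anova", "anova_all", "dataset_variance_explained", "FACTORS"]

FACTORS = ["age", "diet", "batch", "mouse"]


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    return float(resid @ resid)


def _dummies(values: np.ndarray) -> np.ndarray:
    levels, idx = np.unique(values, return_inverse=True)
    out = np.zeros((values.size, levels.size))
    out[np.arange(values.size), idx] = 1.0
    return out


def sequential_anova(y, factors: pd.DataFrame,
                     order: list[str] | None = None) -> dict[str, float]:
    """Type-I sums of squares for one feature.

    Parameters
    ----------
    y : response values (one per observation).
    factors : DataFrame with columns age, diet, batch, mouse (factor labels
        or codes per observation).
    order : factor entry order; default ``["age", "diet", "batch", "mouse"]``.

    Returns ``{"ESS_age": ..., "ESS_diet": ..., "ESS_batch": ...,
    "ESS_mouse": ..., "RSS": ..., "TSS": ...}``.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("ANOVA needs at least 2 observations")
    if order is None:
        order = list(FACTORS)
    n = y.size
    X = np.ones((n, 1))
    tss = _rss(y, X)
    out = {"TSS": tss}
    prev = tss
    for fac in order:
        X = np.hstack([X, _dummies(factors[fac].to_numpy())])
        cur = _rss(y, X)
        out[f"ESS_{fac}"] = prev - cur
        prev = cur
    out["RSS"] = prev
    return out


def anova_all(values: pd.DataFrame, design: pd.DataFrame,
              min_obs: int = 4) -> pd.DataFrame:
    """Per-feature sequential ANOVA over a long value table.

    ``values``: feature_id, sample_id, value (any common scale; the study
    models log2 values).  Observations missing a sample in the design are
    dropped listwise per feature.
    """
    fac = design_matrix(design).set_index("sample_id")
    fac = fac.rename(columns={"a": "age", "d": "diet"})
    fac["batch"] = fac["t2"] + 2.0 * fac["t3"]  # 3-level code Z10/Z22/Z15
    rows = {}
    for fid, grp in values.groupby("feature_id", sort=True):
        obs = grp.join(fac, on="sample_id", how="inner")
        if len(obs) < min_obs:
            continue
        rows[fid] = sequential_anova(obs["value"].to_numpy(), obs)
    if not rows:
        raise ValueError("no feature had enough observations")
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "feature_id"
    return out


def dataset_variance_explained(decomps: pd.DataFrame) -> pd.Series:
    """Fraction of dataset variance per factor: sum(ESS_f) / sum(TSS).

    The residual fraction completes the set to 1.
    """
    total_tss = decomps["TSS"].sum()
    if total_tss <= 0:
        raise ValueError("zero total TSS: all features constant")
    fractions = {fac: decomps[f"ESS_{fac}"].sum() / total_tss
                 for fac in FACTORS if f"ESS_{fac}" in decomps.columns}
    fractions["residual"] = decomps["RSS"].sum() / total_tss
    return pd.Series(fractions)
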