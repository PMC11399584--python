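"""Per-feature weighted random-intercept linear mixed models and q-value FDR.

Model, per feature:

    y = alpha + beta_age*a + beta_diet*d + beta_z22*t2 + beta_z15*t3 + b_m + eps

with b_m ~ N(0, tau2) a random intercept per mouse and eps ~ N(0, w*sigma2),
where w is the inverse reporter ion count for proteomics and 1 otherwise.
Variance components are estimated by REML via a 1-D profile of the
restricted likelihood over the log variance ratio lambda = tau2/sigma2;
for fixed lambda the GLS solution and sigma2 are closed form through the
Woodbury identity on the block-diagonal mouse structure.  Fixed-effect
Wald tests use a t reference with Satterthwaite degrees of freedom by
default (a normal reference is available by option): with ~30 mice the
normal approximation is visibly anti-conservative for between-mouse
contrasts and inflates the realized false-discovery proportion.

FDR is controlled term by term (one p-value vector per coefficient across
features) with Storey q-values; calls are conventionally made at q < 0.01.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core_io import REFERENCE_BATCH

__all__ = [
    "COEF_NAMES",
    "ModelFit",
    "design_matrix",
    "fit_feature_model",
    "fit_all",
    "qvalues",
    "reml_profile_loglik",
]

COEF_NAMES = ["alpha", "beta_age", "beta_diet", "beta_z22", "beta_z15"]

_LOG_LAMBDA_BOUNDS = (-12.0, 12.0)
_SIGMA2_FLOOR = 1e-12


@dataclass
class ModelFit:
    """REML fit of the random-intercept model for one feature."""

    coef: dict[str, float]
    se: dict[str, float]
    p: dict[str, float]
    tau2: float
    sigma2: float
    blups: dict[str, float]
    converged: bool
    n_obs: int
    aliased: list[str] = field(default_factory=list)
    note: str = ""

    def as_row(self) -> dict:
        row: dict = {"tau2": self.tau2, "sigma2": self.sigma2,
                     "converged": self.converged, "n_obs": self.n_obs}
        for name in COEF_NAMES:
            row[name] = self.coef.get(name, np.nan)
            row[f"se_{name}"] = self.se.get(name, np.nan)
            row[f"p_{name}"] = self.p.get(name, np.nan)
        return row


def design_matrix(design: pd.DataFrame) -> pd.DataFrame:
    """Treatment-coded factors per sample: a, d, t2, t3, mouse.

    Age young->0/adult->1, diet chow->0/hfd->1, draw batch indicators with
    Z10 as the reference level.  Bridge samples are excluded.
    """
    bio = design[~design["is_bridge"]]
    return pd.DataFrame({
        "sample_id": bio["sample_id"].to_numpy(),
        "a": (bio["age_group"] == "adult").astype(float).to_numpy(),
        "d": (bio["diet"] == "hfd").astype(float).to_numpy(),
        "t2": (bio["draw_batch"] == "Z22").astype(float).to_numpy(),
        "t3": (bio["draw_batch"] == "Z15").astype(float).to_numpy(),
        "mouse": bio["mouse_id"].to_numpy(),
    })


def _estimable_columns(X: np.ndarray) -> list[int]:
    """Greedy left-to-right selection of a full-rank column subset."""
    keep: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(j)
    return keep


def _profile_pieces(lam: float, y: np.ndarray, X: np.ndarray, w: np.ndarray,
                    mouse_idx: np.ndarray, n_mice: int):
    """Woodbury pieces for V0 = diag(w) + lam * Z Z' (Z = mouse indicators).

    Returns (beta, XtViX, r_Vi_r, logdet_V0, logdet_XtViX).
    """
    inv_w = 1.0 / w
    s = np.bincount(mouse_idx, weights=inv_w, minlength=n_mice)
    c = lam / (1.0 + lam * s)  # diag of (I/lam + Z'A^-1 Z)^-1

    Aw_X = X * inv_w[:, None]
    Aw_y = y * inv_w
    GX = np.vstack([np.bincount(mouse_idx, weights=Aw_X[:, j], minlength=n_mice)
                    for j in range(X.shape[1])]).T  # n_mice x p
    Gy = np.bincount(mouse_idx, weights=Aw_y, minlength=n_mice)

    XtViX = X.T @ Aw_X - (GX * c[:, None]).T @ GX
    XtViy = X.T @ Aw_y - (GX * c[:, None]).T @ Gy
    beta = np.linalg.solve(XtViX, XtViy)

    r = y - X @ beta
    Aw_r = r * inv_w
    Gr = np.bincount(mouse_idx, weights=Aw_r, minlength=n_mice)
    r_Vi_r = float(r @ Aw_r - Gr @ (c * Gr))

    logdet_V0 = float(np.sum(np.log(w)) + np.sum(np.log1p(lam * s)))
    sign, logdet_XtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        logdet_XtViX = np.inf
    return beta, XtViX, r_Vi_r, logdet_V0, float(logdet_XtViX)


def reml_profile_loglik(lam: float, y: np.ndarray, X: np.ndarray, w: np.ndarray,
                        mouse_idx: np.ndarray, n_mice: int) -> float:
    """Restricted log-likelihood profiled over sigma2, up to a constant."""
    n, p = X.shape
    _, _, r_Vi_r, logdet_V0, logdet_XtViX = _profile_pieces(
        lam, y, X, w, mouse_idx, n_mice)
    sigma2 = max(r_Vi_r / (n - p), _SIGMA2_FLOOR)
    return -0.5 * ((n - p) * math.log(sigma2) + logdet_V0 + logdet_XtViX)


def _reml_loglik_2d(tau2: float, sigma2: float, y, X, w, mouse_idx, n_mice) -> float:
    """Unprofiled restricted log-likelihood at (tau2, sigma2), up to a constant."""
    n, p = X.shape
    lam = tau2 / sigma2
    _, _, r_Vi_r, logdet_V0, logdet_XtViX = _profile_pieces(
        lam, y, X, w, mouse_idx, n_mice)
    return -0.5 * ((n - p) * math.log(sigma2) + logdet_V0 + logdet_XtViX
                   + r_Vi_r / sigma2)


def _satterthwaite_df(tau2: float, sigma2: float, y, X, w, mouse_idx,
                      n_mice) -> np.ndarray:
    """Satterthwaite denominator df per fixed-effect coefficient.

    df_j = 2 Var(beta_j)^2 / (g_j' A g_j) with g_j the gradient of
    Var(beta_j) in (tau2, sigma2) and A the inverse REML information,
    both by central finite differences.  Falls back to the residual df
    n - p when the information matrix is not positive definite.
    """
    n, p = X.shape
    resid_df = float(n - p)

    def var_diag(t2: float, s2: float) -> np.ndarray:
        _, XtViX, _, _, _ = _profile_pieces(t2 / s2, y, X, w, mouse_idx, n_mice)
        return s2 * np.diag(np.linalg.inv(XtViX))

    h_t = max(1e-6, 1e-3 * max(tau2, sigma2))
    h_s = max(1e-6, 1e-3 * sigma2)
    theta = np.array([tau2, sigma2])
    steps = np.array([h_t, h_s])
    if tau2 - h_t < 0:  # one-sided near the boundary handled by shifting
        theta[0] = h_t

    # gradient of each Var(beta_j)
    grads = np.empty((p, 2))
    for k in range(2):
        hi, lo = theta.copy(), theta.copy()
        hi[k] += steps[k]
        lo[k] = max(lo[k] - steps[k], 1e-12 if k == 0 else 1e-10)
        dv = (var_diag(*hi) - var_diag(*lo)) / (hi[k] - lo[k])
        grads[:, k] = dv

    # observed REML information of (tau2, sigma2)
    def ll(t2, s2):
        return _reml_loglik_2d(max(t2, 0.0), s2, y, X, w, mouse_idx, n_mice)

    H = np.empty((2, 2))
    f0 = ll(*theta)
    for k in range(2):
        for l in range(k, 2):
            tpp = theta.copy(); tpp[k] += steps[k]; tpp[l] += steps[l]
            tpm = theta.copy(); tpm[k] += steps[k]; tpm[l] -= steps[l]
            tmp = theta.copy(); tmp[k] -= steps[k]; tmp[l] += steps[l]
            tmm = theta.copy(); tmm[k] -= steps[k]; tmm[l] -= steps[l]
            if min(tpm[0], tmp[0], tmm[0]) < 0:
                # forward-difference variant at the tau2 boundary
                H[k, l] = H[l, k] = np.nan
                continue
            H[k, l] = (ll(*tpp) - ll(*tpm) - ll(*tmp) + ll(*tmm)) / (
                4 * steps[k] * steps[l])
            H[l, k] = H[k, l]
    del f0
    info = -H
    try:
        if np.isnan(info).any():
            raise np.linalg.LinAlgError
        A = np.linalg.inv(info)
        if np.diag(A).min() <= 0:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        return np.full(p, resid_df)

    v = var_diag(*theta)
    denom = np.einsum("jk,kl,jl->j", grads, A, grads)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = 2.0 * v**2 / denom
    df = np.where(np.isfinite(df) & (df > 0), df, resid_df)
    return np.clip(df, 1.0, resid_df)


def fit_feature_model(obs: pd.DataFrame,
                      lambda_fixed: Optional[float] = None,
                      ddf: str = "satterthwaite") -> ModelFit:
    """Fit the weighted random-intercept model to one feature's observations.

    Parameters
    ----------
    obs : columns y, a, d, t2, t3, mouse, and optionally w (positive
        observation-variance weights; defaults to 1).
    lambda_fixed : fix the variance ratio tau2/sigma2 instead of estimating
        it (0 gives the weighted least-squares limit).
    ddf : "satterthwaite" (default) tests coefficients against a t
        reference with Satterthwaite denominator df; "normal" uses the
        large-sample normal reference; "residual" uses t with n - p df.

    The REML criterion is maximized over log(tau2/sigma2) with a bounded
    derivative-free search; the tau2 = 0 boundary is checked explicitly.
    Aliased (non-estimable) coefficients are reported as NaN, not dropped
    silently.
    """
    obs = obs.dropna(subset=["y"])
    y = obs["y"].to_numpy(dtype=float)
    n = y.size
    if n < 3:
        raise ValueError(f"too few observations ({n})")
    w = (obs["w"].to_numpy(dtype=float) if "w" in obs.columns
         else np.ones(n))
    if (w <= 0).any() or not np.isfinite(w).all():
        raise ValueError("weights must be positive and finite")
    mice, mouse_idx = np.unique(obs["mouse"].to_numpy(), return_inverse=True)
    n_mice = mice.size
    if n_mice < 2:
        raise ValueError("need observations from at least 2 mice")

    X_full = np.column_stack([np.ones(n),
                              obs["a"].to_numpy(dtype=float),
                              obs["d"].to_numpy(dtype=float),
                              obs["t2"].to_numpy(dtype=float),
                              obs["t3"].to_numpy(dtype=float)])
    keep = _estimable_columns(X_full)
    aliased = [COEF_NAMES[j] for j in range(5) if j not in keep]
    X = X_full[:, keep]
    p = X.shape[1]
    if n - p < 1:
        raise ValueError("no residual degrees of freedom")

    note = ""
    converged = True
    max_group = int(np.bincount(mouse_idx).max())
    if lambda_fixed is not None:
        lam = float(lambda_fixed)
    elif max_group == 1:
        # one observation per mouse: tau2 and sigma2 are confounded;
        # adopt the tau2 = 0 convention (fit reduces to weighted LS)
        lam = 0.0
        note = "tau2/sigma2 unidentifiable (one observation per mouse); tau2 set to 0"
    else:
        lo, hi = _LOG_LAMBDA_BOUNDS

        def neg(ll: float) -> float:
            return -reml_profile_loglik(math.exp(ll), y, X, w, mouse_idx, n_mice)

        res = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-7})
        converged = bool(res.success)
        ll_boundary = reml_profile_loglik(0.0, y, X, w, mouse_idx, n_mice)
        if ll_boundary >= -res.fun - 1e-10 or math.exp(res.x) < 1e-8:
            lam = 0.0
        else:
            lam = math.exp(float(res.x))

    beta_k, XtViX, r_Vi_r, _, _ = _profile_pieces(lam, y, X, w, mouse_idx, n_mice)
    sigma2 = r_Vi_r / (n - p)
    if sigma2 < _SIGMA2_FLOOR:
        sigma2 = _SIGMA2_FLOOR
        converged = converged and False
        note = (note + "; " if note else "") + "sigma2 floored (near-constant response)"
    tau2 = lam * sigma2

    cov = sigma2 * np.linalg.inv(XtViX)
    se_k = np.sqrt(np.diag(cov))

    # BLUPs: b_hat = lam * Z' V0^-1 r
    inv_w = 1.0 / w
    s = np.bincount(mouse_idx, weights=inv_w, minlength=n_mice)
    r = y - X @ beta_k
    Gr = np.bincount(mouse_idx, weights=r * inv_w, minlength=n_mice)
    blup_vals = lam * (Gr - (lam / (1.0 + lam * s)) * s * Gr)

    if ddf == "satterthwaite" and tau2 > 0:
        dfs = _satterthwaite_df(tau2, sigma2, y, X, w, mouse_idx, n_mice)
    elif ddf == "normal":
        dfs = np.full(p, np.inf)
    else:  # residual df; also the tau2 = 0 boundary (weighted LS limit)
        dfs = np.full(p, float(n - p))

    coef = {name: np.nan for name in COEF_NAMES}
    se = {name: np.nan for name in COEF_NAMES}
    pvals = {name: np.nan for name in COEF_NAMES}
    for pos, j in enumerate(keep):
        name = COEF_NAMES[j]
        coef[name] = float(beta_k[pos])
        se[name] = float(se_k[pos])
        z = beta_k[pos] / se_k[pos] if se_k[pos] > 0 else np.inf
        if np.isinf(dfs[pos]):
            pvals[name] = float(2.0 * stats.norm.sf(abs(z)))
        else:
            pvals[name] = float(2.0 * stats.t.sf(abs(z), dfs[pos]))

    return ModelFit(coef=coef, se=se, p=pvals, tau2=float(tau2),
                    sigma2=float(sigma2),
                    blups={str(m): float(b) for m, b in zip(mice, blup_vals)},
                    converged=converged, n_obs=n, aliased=aliased, note=note)


def fit_all(values: pd.DataFrame, design: pd.DataFrame,
            weight_col: Optional[str] = None,
            min_obs: int = 6,
            ddf: str = "satterthwaite",
            report=None) -> pd.DataFrame:
    """Fit every feature independently; assemble per-coefficient p and q vectors.

    Parameters
    ----------
    values : long table with feature_id, sample_id, value (log2 scale) and
        optionally an ion_count column used as 1/weight source.
    weight_col : column of ``values`` holding reporter ion counts; the model
        weight is its inverse ("ion_count" for proteomics, None otherwise).
    min_obs : features with fewer observations are skipped (report entry).

    Returns a DataFrame indexed by feature_id with estimates, SEs, p- and
    Storey q-values per coefficient, tau2, sigma2, and the convergence flag.
    q-values are computed term by term across features.
    """
    factors = design_matrix(design).set_index("sample_id")
    rows = {}
    for fid, grp in values.groupby("feature_id", sort=True):
        obs = grp.join(factors, on="sample_id", how="inner")
        obs = obs.rename(columns={"value": "y"})
        if weight_col is not None:
            obs["w"] = 1.0 / obs[weight_col].to_numpy(dtype=float)
        if len(obs) < min_obs or obs["mouse"].nunique() < 2:
            if report is not None:
                report.add("fit", "too few observations; skipped",
                           feature_id=fid, n_obs=len(obs))
            continue
        rows[fid] = fit_feature_model(obs, ddf=ddf).as_row()
    if not rows:
        raise ValueError("no feature had enough observations to fit")
    fits = pd.DataFrame.from_dict(rows, orient="index")
    fits.index.name = "feature_id"
    for name in COEF_NAMES:
        p = fits[f"p_{name}"]
        q = np.full(len(p), np.nan)
        ok = p.notna().to_numpy()
        if ok.any():
            q[ok] = qvalues(p.to_numpy()[ok])
        fits[f"q_{name}"] = q
    return fits


def fits_long(fits: pd.DataFrame) -> pd.DataFrame:
    """One row per (feature, coefficient): estimate, SE, p, q, tau2, sigma2."""
    recs = []
    for fid, row in fits.iterrows():
        for name in COEF_NAMES:
            recs.append({
                "feature_id": fid, "coefficient": name,
                "estimate": row[name], "se": row[f"se_{name}"],
                "p": row[f"p_{name}"], "q": row.get(f"q_{name}", np.nan),
                "tau2": row["tau2"], "sigma2": row["sigma2"],
                "converged": row["converged"],
            })
    return pd.DataFrame.from_records(recs)


def qvalues(p: Sequence[float], pi0: Optional[float] = None) -> np.ndarray:
    """Storey q-values with the cubic-smoother pi0 estimate.

    pi0 is estimated by fitting a cubic in lambda to pi0(lambda) =
    #{p > lambda} / (n (1 - lambda)) over lambda = 0.05 ... 0.95 and
    evaluating at 0.95.  Falls back to pi0 = 1 (Benjamini-Hochberg) when the
    estimate exceeds 1 or n < 100.  Output is monotone nondecreasing in p.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([])
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if pi0 is None:
        if n < 100:
            pi0 = 1.0
        else:
            lams = np.arange(0.05, 0.96, 0.05)
            pi0_l = np.array([(p > lam).sum() / (n * (1.0 - lam)) for lam in lams])
            coeffs = np.polyfit(lams, pi0_l, 3)
            pi0 = float(np.polyval(coeffs, lams[-1]))
            if pi0 > 1.0 or pi0 <= 0.0:
                pi0 = 1.0
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * n * ranked / np.arange(1, n + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(n)
    out[order] = q
    return out
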