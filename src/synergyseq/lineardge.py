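"""Moderated per-gene linear-model contrasts with precision weights.

The 2x2 diagnosis/treatment design is collapsed into one four-level group
factor and fitted gene-wise by weighted least squares under cell-means
coding (no intercept). Observation weights come from a smoothed
mean-variance trend of the log2 counts (voom-type): residual standard
deviations from unweighted fits are regressed on average log2 count by
locally weighted regression, each observation's predicted log2 count is
mapped through the trend, and the weight is the fourth inverse power of the
interpolated trend value.

Per-gene residual variances are then shrunk toward a common prior by
empirical-Bayes moderation: the sample variances are modeled as scaled F
draws around a prior (d0, s0^2), estimated in closed form by moment
matching of log variances via digamma/trigamma inversion. The moderated t
statistic is beta / (u * s_tilde) on d0 + d residual degrees of freedom,
with Benjamini-Hochberg adjustment across genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from synergyseq.simdata import GROUPS

#: contrast name -> weights over (CTRL_VEH, SZ_VEH, CTRL_JQ, SZ_JQ)
STANDARD_CONTRASTS = {
    "SZ_vs_CTRL": np.array([-1.0, 1.0, 0.0, 0.0]),
    "JQ_vs_CTRL": np.array([-1.0, 0.0, 1.0, 0.0]),
    "SZJQ_vs_CTRL": np.array([-1.0, 0.0, 0.0, 1.0]),
    "ADDITIVE": np.array([-2.0, 1.0, 1.0, 0.0]),
    "SYNERGY": np.array([1.0, -1.0, -1.0, 1.0]),
}


def build_design(samples: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Cell-means design (samples x 4 group indicators) plus the standard
    contrast vectors.

    Contrasts: SZ_vs_CTRL, JQ_vs_CTRL, SZJQ_vs_CTRL (each vs vehicle
    control), ADDITIVE (their sum for the two single perturbations), and
    SYNERGY, the interaction contrast SZ_JQ - SZ_VEH - CTRL_JQ + CTRL_VEH.
    """
    diag = samples["diagnosis"].astype(str)
    treat = samples["treatment"].astype(str)
    bad = set(diag) - {"CTRL", "SZ"}
    bad |= set(treat) - {"VEH", "JQ1"}
    if bad:
        raise ValueError(f"unknown factor level(s): {sorted(bad)}")
    group = np.where(diag == "SZ", "SZ", "CTRL") + "_" + np.where(
        treat == "JQ1", "JQ", "VEH"
    )
    design = pd.DataFrame(
        {g: (group == g).astype(float) for g in GROUPS},
        index=samples["sample_id"].to_numpy(),
    )
    used = design.sum(axis=0) > 0
    design = design.loc[:, used]
    contrasts = {}
    for name, c in STANDARD_CONTRASTS.items():
        if np.any((c != 0) & ~used.to_numpy()):
            continue  # contrast touches an empty group
        contrasts[name] = c[used.to_numpy()]
    if not contrasts:
        raise ValueError("no contrast is estimable from the given samples")
    return design, contrasts


def _batch_wls(y, w, x):
    """Gene-wise weighted least squares.

    y, w : (G, S); x : (S, P). Returns beta (G, P), xtwx_inv (G, P, P),
    sigma2 (G,), df (scalar)."""
    xtwx = np.einsum("sp,gs,sq->gpq", x, w, x)
    xtwy = np.einsum("sp,gs,gs->gp", x, w, y)
    xtwx_inv = np.linalg.inv(xtwx)
    beta = np.einsum("gpq,gq->gp", xtwx_inv, xtwy)
    fitted = beta @ x.T
    resid = y - fitted
    df = y.shape[1] - x.shape[1]
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = np.einsum("gs,gs->g", w, resid**2) / df
    return beta, xtwx_inv, sigma2, df


def mean_variance_weights(
    logexpr: pd.DataFrame,
    design: pd.DataFrame,
    span: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Precision weights from the smoothed mean-variance trend.

    Returns (weights, trend) where weights is genes x samples and trend is
    the fitted lowess curve (columns ``log2_count``, ``sqrt_sd``). Requires
    the effective library sizes recorded by :func:`normfilter.log_cpm`.
    """
    x = design.to_numpy()
    y = logexpr.to_numpy()
    if y.shape[1] < x.shape[1]:
        raise ValueError("fewer samples than design columns")
    eff = logexpr.attrs.get("effective_lib_sizes")
    if eff is None:
        eff = pd.Series(1e7, index=logexpr.columns)
    lib = np.asarray(eff, float) + 1.0

    ones = np.ones_like(y)
    beta, _, sigma2, _ = _batch_wls(y, ones, x)
    sqrt_sd = np.sqrt(np.sqrt(np.maximum(sigma2, 0.0)))

    # average log2 count per gene: mean log-CPM shifted back to count scale
    mean_logcount = y.mean(axis=1) + np.mean(np.log2(lib)) - np.log2(1e6)
    sm = lowess(sqrt_sd, mean_logcount, frac=span, return_sorted=True)
    tx, ty = sm[:, 0], sm[:, 1]

    # fitted log2 count per observation, mapped through the trend with
    # end clamping (np.interp clamps by construction)
    fitted_logcpm = beta @ x.T
    fitted_logcount = fitted_logcpm + np.log2(lib)[None, :] - np.log2(1e6)
    trend_val = np.interp(fitted_logcount, tx, ty)
    w = np.maximum(trend_val, 1e-6) ** -4
    weights = pd.DataFrame(w, index=logexpr.index, columns=logexpr.columns)
    trend = pd.DataFrame({"log2_count": tx, "sqrt_sd": ty})
    return weights, trend


@dataclass
class ContrastResult:
    """Per-gene statistics for a collection of named contrasts.

    ``coef``/``se_unscaled`` are genes x contrasts frames; ``sigma`` and
    ``df_residual`` per-gene. After :func:`moderate_statistics`,
    ``d0``/``s0_sq`` hold the prior, ``s2_post`` the posterior variances and
    ``t``/``p``/``q`` the moderated statistics.
    """

    coef: pd.DataFrame
    se_unscaled: pd.DataFrame  # u_g = sqrt(c' (X'WX)^-1 c)
    sigma: pd.Series  # residual sd s_g
    df_residual: float  # d_g (common across genes here)
    d0: float | None = None
    s0_sq: float | None = None
    s2_post: pd.Series | None = None
    t: pd.DataFrame | None = None
    p: pd.DataFrame | None = None
    q: pd.DataFrame | None = None
    contrasts: dict = field(default_factory=dict)

    @property
    def moderated(self) -> bool:
        return self.t is not None

    def to_frame(self, contrast: str) -> pd.DataFrame:
        """Tidy per-gene table (logFC, SE, t, P, adj.P) for one contrast."""
        out = pd.DataFrame(index=self.coef.index)
        out["logFC"] = self.coef[contrast]
        scale = np.sqrt(self.s2_post) if self.moderated else self.sigma
        out["SE"] = self.se_unscaled[contrast] * scale
        if self.moderated:
            out["t"] = self.t[contrast]
            out["P.Value"] = self.p[contrast]
            out["adj.P.Val"] = self.q[contrast]
        return out


def fit_contrasts(
    logexpr: pd.DataFrame,
    weights: pd.DataFrame | None,
    design: pd.DataFrame,
    contrasts: dict,
) -> ContrastResult:
    """Gene-wise weighted least squares refit to the given contrasts."""
    x = design.to_numpy()
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("design matrix is not of full column rank")
    y = logexpr.to_numpy()
    w = np.ones_like(y) if weights is None else weights.to_numpy()
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be positive and finite")
    beta, xtwx_inv, sigma2, df = _batch_wls(y, w, x)

    names = list(contrasts)
    cmat = np.column_stack([contrasts[n] for n in names])  # (P, C)
    coef = beta @ cmat
    u2 = np.einsum("pc,gpq,qc->gc", cmat, xtwx_inv, cmat)
    u = np.sqrt(u2)
    return ContrastResult(
        coef=pd.DataFrame(coef, index=logexpr.index, columns=names),
        se_unscaled=pd.DataFrame(u, index=logexpr.index, columns=names),
        sigma=pd.Series(np.sqrt(sigma2), index=logexpr.index, name="sigma"),
        df_residual=float(df),
        contrasts={n: np.asarray(contrasts[n], float) for n in names},
    )


def _trigamma_inverse(x: float, tol: float = 1e-8) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif / y) < tol:
            break
    return float(y)


def estimate_prior(sigma2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) of the scaled-F variance prior.

    Uses the closed-form log-variance moments: for s^2 ~ s0^2 * F(d, d0),
    E log s^2 and Var log s^2 are digamma/trigamma expressions in d and d0,
    so d0 follows from a trigamma inversion. Returns d0 = inf when the
    observed spread of log variances is no larger than expected from the
    residual chi-squared alone.
    """
    s2 = np.asarray(sigma2, float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least two positive residual variances")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = np.exp(
            emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
        )
    else:
        d0 = np.inf
        s0_sq = np.exp(emean)
    return float(d0), float(s0_sq)


def moderate_statistics(
    result: ContrastResult,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> ContrastResult:
    """Empirical-Bayes moderation of the contrast fit.

    Estimates (d0, s0^2) from the residual variances unless given, forms
    posterior variances s2_post = (d0 s0^2 + d s^2) / (d0 + d), moderated t
    = coef / (u * sqrt(s2_post)) on d0 + d degrees of freedom, two-sided p,
    and BH-adjusted q per contrast. ``d0=0`` reproduces the ordinary t test;
    ``d0=inf`` shrinks every gene to the common variance.
    """
    if len(result.sigma) < 10 and d0 is None:
        raise ValueError("too few genes to estimate the variance prior")
    s2 = result.sigma.to_numpy() ** 2
    d = result.df_residual
    if d0 is None or s0_sq is None:
        d0_est, s0_est = estimate_prior(s2, d)
        d0 = d0_est if d0 is None else d0
        s0_sq = s0_est if s0_sq is None else s0_sq
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d
    denom = result.se_unscaled.to_numpy() * np.sqrt(s2_post)[:, None]
    t = result.coef.to_numpy() / denom
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    cols = result.coef.columns
    q = np.column_stack([adjust_fdr(p[:, j]) for j in range(p.shape[1])])
    idx = result.coef.index
    return ContrastResult(
        coef=result.coef,
        se_unscaled=result.se_unscaled,
        sigma=result.sigma,
        df_residual=result.df_residual,
        d0=float(d0),
        s0_sq=float(s0_sq),
        s2_post=pd.Series(s2_post, index=idx, name="s2_post"),
        t=pd.DataFrame(t, index=idx, columns=cols),
        p=pd.DataFrame(p, index=idx, columns=cols),
        q=pd.DataFrame(q, index=idx, columns=cols),
        contrasts=result.contrasts,
    )


def adjust_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
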