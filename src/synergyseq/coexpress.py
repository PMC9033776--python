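"""Unsigned weighted co-expression network analysis.

Pairwise absolute Pearson correlations of gene expression profiles are
raised to a soft-thresholding power (default 7) to form an unsigned
adjacency, denoised into a topological overlap matrix (TOM), and clustered
on the 1 - TOM dissimilarity by average-linkage hierarchical clustering.
Clusters from a static height cut become modules, small clusters fall into
the "grey" module, and modules with highly correlated eigengenes (leading
principal components) are merged below a dissimilarity cutoff (default
0.17). Module-trait association uses weighted Pearson correlation of
eigengenes with one-hot group indicators and the Student asymptotic
p-value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

#: standard module color palette, in assignment order; "grey" is reserved
#: for unassigned genes
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)


def adjacency_matrix(expr: pd.DataFrame, power: int = 7) -> np.ndarray:
    """Unsigned adjacency a_ij = |cor(x_i, x_j)|^power (genes x genes)."""
    vals = expr.to_numpy(float)
    if np.any(vals.std(axis=1) == 0):
        raise ValueError("constant gene rows have undefined correlation")
    a = np.abs(np.corrcoef(vals)) ** power
    np.fill_diagonal(a, 1.0)
    return a


def pick_soft_threshold(
    expr: pd.DataFrame,
    powers=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20),
    n_bins: int = 10,
) -> pd.DataFrame:
    """Scale-free topology fit across candidate soft-thresholding powers.

    For each power, connectivities k_i = sum_{j != i} a_ij are binned and
    the R^2 of the log10(frequency) vs log10(mean k) regression is reported,
    signed negative when the slope is positive (no scale-free decay).
    """
    if expr.shape[0] < 20:
        raise ValueError("need at least 20 genes")
    if np.any(expr.to_numpy(float).std(axis=1) == 0):
        raise ValueError("constant gene rows have undefined correlation")
    corr = np.abs(np.corrcoef(expr.to_numpy(float)))
    np.fill_diagonal(corr, 0.0)
    rows = []
    for beta in powers:
        a = corr**beta
        k = a.sum(axis=1)
        rows.append(
            {
                "power": beta,
                "sft_r2": _scale_free_r2(k, n_bins),
                "mean_connectivity": float(k.mean()),
            }
        )
    return pd.DataFrame(rows)


def _scale_free_r2(k: np.ndarray, n_bins: int) -> float:
    """Signed R^2 of log10 p(k) against log10 k over connectivity bins."""
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_k, log_p = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        log_k.append(np.log10(k[sel].mean()))
        log_p.append(np.log10(sel.mean()))
    if len(log_k) < 3:
        return 0.0
    slope, _, r, _, _ = stats.linregress(log_k, log_p)
    return float(-np.sign(slope) * r**2) if slope > 0 else float(r**2)


def tom_dissimilarity(expr: pd.DataFrame, power: int = 7) -> pd.DataFrame:
    """1 - TOM dissimilarity of the unsigned adjacency.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j with TOM_ii = 1, where k_i excludes the diagonal.
    """
    a = adjacency_matrix(expr, power)
    if np.any(a < 0) or np.any(a > 1 + 1e-12):
        raise ValueError("adjacency outside [0, 1]")
    a_off = a.copy()
    np.fill_diagonal(a_off, 0.0)
    k = a_off.sum(axis=1)
    shared = a_off @ a_off
    num = shared + a_off
    den = np.minimum.outer(k, k) + 1.0 - a_off
    tom = num / den
    np.fill_diagonal(tom, 1.0)
    dissim = 1.0 - tom
    dissim = np.clip((dissim + dissim.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(dissim, 0.0)
    return pd.DataFrame(dissim, index=expr.index, columns=expr.index)


def detect_modules(
    dissim: pd.DataFrame,
    min_module_size: int = 30,
    cut_height: float | None = 0.98,
    cut_quantile: float | None = None,
) -> pd.Series:
    """Module labels from average-linkage clustering of the dissimilarity.

    The tree is cut at a fixed height (default 0.98, a static stand-in for
    the dynamic tree cut: under an unsigned power-7 adjacency, clusters of
    unrelated genes only assemble in the last few thousandths of the
    dissimilarity scale, while genuinely co-expressed blocks complete well
    below it). ``cut_quantile`` cuts at that quantile of the merge heights
    instead. Clusters smaller than ``min_module_size`` are assigned "grey";
    the rest are named by decreasing size from the standard color palette.
    """
    d = dissim.to_numpy(float)
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    n = d.shape[0]
    if n < min_module_size:
        return pd.Series("grey", index=dissim.index, name="module")
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    if cut_quantile is not None:
        height = np.quantile(link[:, 2], cut_quantile)
    else:
        height = cut_height
    raw = hierarchy.fcluster(link, t=height, criterion="distance")
    labels = pd.Series("grey", index=dissim.index, name="module")
    sizes = pd.Series(raw).value_counts()
    kept = [c for c in sizes.index if sizes[c] >= min_module_size]
    kept.sort(key=lambda c: -sizes[c])
    for color, c in zip(MODULE_COLORS, kept):
        labels.iloc[np.where(raw == c)[0]] = color
    return labels


def module_membership(expr: pd.DataFrame, eigengene: np.ndarray) -> np.ndarray:
    """kME: correlation of each gene's profile with a module eigengene."""
    vals = expr.to_numpy(float)
    z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(
        axis=1, keepdims=True
    )
    e = eigengene - eigengene.mean()
    e = e / np.linalg.norm(e)
    return (z @ e) / np.sqrt((z**2).sum(axis=1))


def refine_modules(
    expr: pd.DataFrame,
    labels: pd.Series,
    demote_p: float = 0.01,
    rescue_p: float = 0.001,
    max_iter: int = 5,
) -> pd.Series:
    """Clean up module assignments by eigengene-membership significance.

    A module member whose |kME| (correlation with its own module eigengene)
    is not significant at ``demote_p`` is moved to grey; a grey gene whose
    best |kME| is significant at the stricter ``rescue_p`` joins that
    module. Iterates until stable. Significance uses the Student asymptotic
    test on n - 2 degrees of freedom, so both thresholds adapt to the
    number of samples.
    """
    n = expr.shape[1]

    def r_crit(p):
        tcrit = stats.t.isf(p / 2.0, n - 2)
        return tcrit / np.sqrt(n - 2 + tcrit**2)

    demote_r, rescue_r = r_crit(demote_p), r_crit(rescue_p)
    labels = labels.copy()

    def core_eigengene(module):
        # anchor on the most central members so weakly attached genes
        # cannot tilt the eigengene toward themselves and self-justify
        members = expr.loc[labels.index[labels == module]]
        e = module_eigengene(members)
        if len(members) > 30:
            kme = np.abs(module_membership(members, e))
            core = members.iloc[np.argsort(kme)[-30:]]
            e = module_eigengene(core)
        return e

    for _ in range(max_iter):
        modules = [m for m in labels.unique() if m != "grey"]
        if not modules:
            break
        kme = np.column_stack(
            [
                np.abs(module_membership(expr, core_eigengene(m)))
                for m in modules
            ]
        )
        best = kme.argmax(axis=1)
        best_val = kme.max(axis=1)
        new = labels.copy()
        for i, g in enumerate(labels.index):
            if labels.iloc[i] == "grey":
                if best_val[i] >= rescue_r:
                    new.iloc[i] = modules[best[i]]
            elif kme[i, modules.index(labels.iloc[i])] < demote_r:
                new.iloc[i] = "grey"
        if new.equals(labels):
            break
        labels = new
    # drop modules that fell below viability
    for m in [m for m in labels.unique() if m != "grey"]:
        if (labels == m).sum() < 3:
            labels[labels == m] = "grey"
    return labels


def module_eigengene(expr: pd.DataFrame) -> np.ndarray:
    """Leading principal-component score vector of a module (over samples).

    Genes are standardized first; the unit-norm score vector's sign is
    chosen so its correlation with the module's mean expression profile is
    nonnegative. A single-gene module returns the standardized gene.
    """
    vals = expr.to_numpy(float)
    z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, keepdims=True)
    if z.shape[0] == 1:
        e = z[0]
        e = e / np.linalg.norm(e)
    else:
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        e = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(e, mean_profile) < 0:
        e = -e
    return e


def merge_modules(
    expr: pd.DataFrame,
    labels: pd.Series,
    merge_height: float = 0.17,
) -> tuple[pd.Series, pd.DataFrame]:
    """Iteratively merge modules with eigengene dissimilarity < merge_height.

    Eigengene dissimilarity is 1 - cor(E_a, E_b). At each step the closest
    pair below the cutoff is merged (keeping the larger module's label) and
    eigengenes are recomputed, until no pair remains below the cutoff.
    Returns the merged labels and a samples x modules eigengene frame
    (grey excluded).
    """
    labels = labels.copy()
    modules = [m for m in labels.unique() if m != "grey"]
    if not modules:
        raise ValueError("no non-grey module to merge")

    def eigengenes(mods):
        return {
            m: module_eigengene(expr.loc[labels.index[labels == m]])
            for m in mods
        }

    me = eigengenes(modules)
    while len(modules) > 1:
        best, best_d = None, np.inf
        for i in range(len(modules)):
            for j in range(i + 1, len(modules)):
                d = 1.0 - np.corrcoef(me[modules[i]], me[modules[j]])[0, 1]
                if d < best_d:
                    best_d, best = d, (modules[i], modules[j])
        if best_d >= merge_height:
            break
        a, b = best
        keep, drop = (a, b) if (labels == a).sum() >= (labels == b).sum() else (b, a)
        labels[labels == drop] = keep
        modules = [m for m in modules if m != drop]
        me[keep] = module_eigengene(expr.loc[labels.index[labels == keep]])
        me.pop(drop, None)
    eg = pd.DataFrame(
        {m: me[m] for m in modules}, index=expr.columns
    )
    return labels, eg


def module_trait_association(
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame,
    weights=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Weighted Pearson correlation of module eigengenes with trait columns.

    Traits are typically one-hot group indicators (samples x traits).
    Significance is the Student asymptotic p-value: t = r sqrt(n-2) /
    sqrt(1-r^2) on n - 2 degrees of freedom, two-sided. Uniform weights
    reduce to the ordinary Pearson correlation.
    """
    n = eigengenes.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    r = pd.DataFrame(index=eigengenes.columns, columns=traits.columns, dtype=float)
    p = r.copy()
    for m in eigengenes.columns:
        x = eigengenes[m].to_numpy(float)
        for t in traits.columns:
            y = traits[t].to_numpy(float)
            mx, my = np.sum(w * x), np.sum(w * y)
            cov = np.sum(w * (x - mx) * (y - my))
            vx = np.sum(w * (x - mx) ** 2)
            vy = np.sum(w * (y - my) ** 2)
            if vx == 0 or vy == 0:
                raise ValueError("zero-variance eigengene or trait")
            rij = float(np.clip(cov / np.sqrt(vx * vy), -1.0, 1.0))
            if abs(rij) == 1.0:
                pij = 0.0
            else:
                tstat = rij * np.sqrt(n - 2) / np.sqrt(1.0 - rij**2)
                pij = float(2.0 * stats.t.sf(abs(tstat), n - 2))
            r.loc[m, t] = rij
            p.loc[m, t] = pij
    return r, p
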