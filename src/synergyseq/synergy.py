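"""Additive/synergistic effect decomposition and gene categorization.

For the 2x2 design the expected additive effect of the combined
perturbation is the sum of the two single-perturbation contrasts,
A_g = logFC(SZ vs CTRL) + logFC(JQ1 vs CTRL), itself a single contrast
(SZ_VEH + CTRL_JQ - 2 CTRL_VEH). The synergistic effect is the departure of
the combinatorial contrast C_g = logFC(SZ+JQ1 vs CTRL) from that
prediction: S_g = C_g - A_g, the interaction contrast.

Genes are called positive synergy when S_g exceeds a global threshold tau
(the mean over genes of the moderated synergy-contrast standard error) and
negative synergy when S_g < -tau; a synergy call is promoted to
"more_up"/"more_down" only when the additive prediction points the same way
(or nowhere), i.e. the combined perturbation did more than predicted in the
direction it was already going. Everything else is "as_predicted".
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from synergyseq.lineardge import ContrastResult

CATEGORIES = ("more_down", "as_predicted", "more_up")


def additive_model(fit: ContrastResult) -> pd.DataFrame:
    """Per-gene additive log2FC with its proper contrast SE.

    Requires the fit to contain SZ_vs_CTRL and JQ_vs_CTRL (for the
    components) and the ADDITIVE sum contrast for the exact SE.
    """
    for name in ("SZ_vs_CTRL", "JQ_vs_CTRL", "ADDITIVE"):
        if name not in fit.coef.columns:
            raise ValueError(f"fit lacks the {name} contrast")
    scale = np.sqrt(fit.s2_post) if fit.moderated else fit.sigma
    return pd.DataFrame(
        {
            "A": fit.coef["ADDITIVE"],
            "SE_A": fit.se_unscaled["ADDITIVE"] * scale,
        }
    )


def synergy_table(fit: ContrastResult) -> pd.DataFrame:
    """Assemble the per-gene synergy decomposition from a moderated fit.

    Columns: A (additive log2FC), C (combinatorial log2FC), S (synergistic
    log2FC = C - A, equal to the SYNERGY interaction contrast), SE (moderated
    SE of the SYNERGY contrast), t, p, q of the SYNERGY contrast.
    """
    if not fit.moderated:
        raise ValueError("synergy_table expects a moderated fit")
    for name in ("SZJQ_vs_CTRL", "ADDITIVE", "SYNERGY"):
        if name not in fit.coef.columns:
            raise ValueError(f"fit lacks the {name} contrast")
    syn = fit.to_frame("SYNERGY")
    out = pd.DataFrame(
        {
            "A": fit.coef["ADDITIVE"],
            "C": fit.coef["SZJQ_vs_CTRL"],
            "S": fit.coef["SYNERGY"],
            "SE": syn["SE"],
            "t": syn["t"],
            "p": syn["P.Value"],
            "q": syn["adj.P.Val"],
        }
    )
    return out


def classify_synergy(
    table: pd.DataFrame,
    threshold: float | None = None,
    per_gene: bool = False,
    direction_zone: float = 0.0,
) -> pd.DataFrame:
    """Attach synergy categories to the decomposition table.

    The threshold tau defaults to the mean over genes of the per-gene
    synergy SE (``per_gene=True`` uses each gene's own SE instead).
    Positive synergy (S > tau) with a nonnegative additive prediction is
    "more_up"; negative synergy (S < -tau) with a nonpositive additive
    prediction is "more_down"; all other genes are "as_predicted".

    ``direction_zone`` widens the "no direction" reading of the additive
    prediction: an additive log2FC within +/- direction_zone is treated as
    directionless and never vetoes a synergy call. The default 0 is the
    strict sign rule.
    """
    out = table.copy()
    if threshold is None:
        tau = out["SE"].to_numpy() if per_gene else float(out["SE"].mean())
    else:
        tau = threshold
    if np.any(np.asarray(tau) <= 0):
        raise ValueError("threshold must be positive")
    if direction_zone < 0:
        raise ValueError("direction_zone must be nonnegative")
    s = out["S"].to_numpy()
    a = out["A"].to_numpy()
    pos = s > tau
    neg = s < -np.asarray(tau)
    cat = np.where(
        pos & (a >= -direction_zone),
        "more_up",
        np.where(neg & (a <= direction_zone), "more_down", "as_predicted"),
    )
    out["category"] = cat
    out.attrs["threshold"] = tau if per_gene else float(np.asarray(tau))
    return out


def summarize_synergy(table: pd.DataFrame) -> dict:
    """Counts and one-decimal percentages per category, plus the total
    number of "more" genes."""
    if "category" not in table.columns:
        raise ValueError("table is not classified; run classify_synergy")
    n = len(table)
    out = {"n_genes": n, "categories": {}}
    for cat in CATEGORIES:
        k = int((table["category"] == cat).sum())
        pct = round(100.0 * k / n, 1) if n else 0.0
        out["categories"][cat] = {"count": k, "percent": pct}
    out["n_more"] = (
        out["categories"]["more_down"]["count"]
        + out["categories"]["more_up"]["count"]
    )
    return out


def cluster_for_heatmap(
    matrix: pd.DataFrame,
    max_rows: int = 1000,
    k: int = 100,
    seed: int = 0,
) -> dict:
    """Row/column orderings for a clustered heatmap.

    Hierarchical clustering with Euclidean distance and complete linkage on
    rows and columns. When the matrix has more than ``max_rows`` rows, rows
    are first aggregated into ``k`` k-means clusters (fixed seed) and the
    cluster centroids are clustered instead; ``row_groups`` then maps each
    original row to its aggregated cluster.

    Returns dict with ``row_order``, ``col_order``, ``aggregated`` flag,
    and, when aggregated, ``row_groups`` and ``centroids``.
    """
    vals = matrix.to_numpy(float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("matrix must be finite")
    out: dict = {"aggregated": False}
    rows = vals
    if vals.shape[0] > max_rows:
        if k >= vals.shape[0]:
            raise ValueError("k must be smaller than the number of rows")
        km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(vals)
        rows = km.cluster_centers_
        out["aggregated"] = True
        out["row_groups"] = pd.Series(km.labels_, index=matrix.index)
        out["centroids"] = pd.DataFrame(rows, columns=matrix.columns)

    def _order(m: np.ndarray) -> np.ndarray:
        if m.shape[0] < 2:
            return np.arange(m.shape[0])
        link = hierarchy.linkage(pdist(m), method="complete")
        return np.asarray(hierarchy.leaves_list(link))

    out["row_order"] = _order(rows)
    out["col_order"] = _order(vals.T)
    out["row_linkage"] = (
        hierarchy.linkage(pdist(rows), method="complete")
        if rows.shape[0] >= 2
        else None
    )
    return out
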