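"""Gene-set I/O and enrichment tests.

Two complementary tests are provided. The competitive (camera-style) test
asks whether the genes of a set rank highly among all genes for a
differential-expression statistic, while accounting for inter-gene
correlation through a variance inflation factor VIF = 1 + (m - 1) * rho on
the in-set mean. The over-representation test is the upper-tail
hypergeometric probability of the observed overlap between a hit list and a
set, against a background universe of expressed genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from synergyseq.lineardge import adjust_fdr


@dataclass
class GeneSetCollection:
    """Named gene sets with optional category labels."""

    sets: dict
    categories: dict = field(default_factory=dict)
    source: str | None = None

    def __post_init__(self):
        if any(len(v) == 0 for v in self.sets.values()):
            raise ValueError("empty gene set")

    def __len__(self) -> int:
        return len(self.sets)

    def subset(self, category: str) -> "GeneSetCollection":
        names = [n for n, c in self.categories.items() if c == category]
        return GeneSetCollection(
            sets={n: self.sets[n] for n in names},
            categories={n: category for n in names},
            source=self.source,
        )


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name, description, members per tab-separated line).

    The description field is kept as the set's category label. Duplicate
    genes within a set are removed (first occurrence kept).
    """
    sets, categories = {}, {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: GMT line has < 3 fields")
            name, desc = fields[0], fields[1]
            members = list(dict.fromkeys(g for g in fields[2:] if g))
            sets[name] = members
            categories[name] = desc
    return GeneSetCollection(sets=sets, categories=categories, source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.categories.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def _zscore_t(t: np.ndarray, df: float) -> np.ndarray:
    """Normal-equivalent scores of t statistics (quantile transformation)."""
    if np.isinf(df):
        return np.asarray(t, float)
    # map through the t CDF in the numerically stable tail
    t = np.asarray(t, float)
    z = np.empty_like(t)
    neg = t < 0
    z[neg] = stats.norm.ppf(stats.t.cdf(t[neg], df))
    z[~neg] = -stats.norm.ppf(stats.t.sf(t[~neg], df))
    return z


def camera_test(
    gene_stats: pd.Series,
    sets: GeneSetCollection,
    inter_gene_cor: float | str = 0.01,
    df: float = np.inf,
    residuals: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Competitive gene-set test with inter-gene-correlation adjustment.

    ``gene_stats`` holds per-gene moderated t for one contrast (indexed by
    gene id); with finite ``df`` they are first converted to
    normal-equivalent scores. For each set of effective size m the in-set
    and out-of-set score means are compared by a two-sample t statistic
    whose in-set variance term is inflated by VIF = 1 + (m - 1) * rho, on
    G - 2 degrees of freedom. ``inter_gene_cor="estimate"`` estimates rho
    per set as the mean pairwise correlation of the supplied residual rows.

    Returns a per-set frame (m, rho, vif, direction, p, FDR) sorted by p;
    sets with fewer than 2 genes inside or outside the universe are skipped.
    """
    if inter_gene_cor == "estimate" and residuals is None:
        raise ValueError("rho estimation requires a residual matrix")
    scores = _zscore_t(gene_stats.to_numpy(), df)
    universe = pd.Index(gene_stats.index)
    G = len(universe)
    mean_all = scores.mean()
    var_all = scores.var(ddof=1)

    rows = []
    for name, members in sets.sets.items():
        idx = universe.get_indexer(pd.Index(members).unique())
        idx = idx[idx >= 0]
        m = idx.size
        m2 = G - m
        if m < 2 or m2 < 2:
            continue
        if inter_gene_cor == "estimate":
            sub = residuals.loc[universe[idx]].to_numpy()
            cors = np.corrcoef(sub)
            iu = np.triu_indices(m, k=1)
            rho = float(np.nanmean(cors[iu]))
            rho = max(rho, 0.0)
        else:
            rho = float(inter_gene_cor)
        vif = 1.0 + (m - 1) * rho
        mean_in = scores[idx].mean()
        delta = G / m2 * (mean_in - mean_all)
        var_pooled = ((G - 1) * var_all - delta**2 * m * m2 / G) / (G - 2)
        tstat = delta / np.sqrt(var_pooled * (vif / m + 1.0 / m2))
        p = 2.0 * stats.t.sf(abs(tstat), G - 2)
        rows.append(
            {
                "set": name,
                "category": sets.categories.get(name, "na"),
                "m": m,
                "rho": rho,
                "vif": vif,
                "direction": "up" if delta > 0 else "down",
                "statistic": tstat,
                "p": p,
            }
        )
    out = pd.DataFrame(rows).set_index("set")
    out["FDR"] = adjust_fdr(out["p"].to_numpy())
    return out.sort_values("p")


def hypergeometric_ora(
    hits,
    universe,
    sets: GeneSetCollection,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of a hit list.

    With N = |universe|, K = |set ∩ universe|, n = |hits| and k =
    |hits ∩ set|, the per-set p-value is P(X >= k) for X hypergeometric.
    Hits must be a subset of the universe (an outside hit is an error, not
    a silent drop). Results carry BH FDR and are ranked by -log10(p).
    """
    hits = pd.Index(hits).unique()
    universe = pd.Index(universe).unique()
    outside = hits.difference(universe)
    if len(outside):
        raise ValueError(
            f"{len(outside)} hit gene(s) not in the universe, e.g. {outside[0]}"
        )
    N, n = len(universe), len(hits)
    rows = []
    for name, members in sets.sets.items():
        inter = universe.intersection(pd.Index(members))
        K = len(inter)
        k = len(hits.intersection(inter))
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        expected = n * K / N if N else 0.0
        rows.append(
            {
                "set": name,
                "category": sets.categories.get(name, "na"),
                "K": K,
                "k": k,
                "expected": expected,
                "enrichment": (k / expected) if expected > 0 else np.nan,
                "p": p,
            }
        )
    out = pd.DataFrame(rows).set_index("set")
    out["FDR"] = adjust_fdr(out["p"].to_numpy())
    out["neg_log10_p"] = -np.log10(np.maximum(out["p"], 1e-300))
    return out.sort_values("neg_log10_p", ascending=False)
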