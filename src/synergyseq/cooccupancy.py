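"""Promoter definition, RPKM conversion, and occupancy rank correlation.

Promoters are symmetric windows of +/- 1 kb around each transcription
start site (0-based, half-open, clamped at the chromosome start). Raw
per-region read counts for two signals (e.g. BRD4 and acetylated-H2A.Z
ChIP) are converted to RPKM and compared by Spearman rank correlation with
midranks for ties and the large-sample t approximation for significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GenomicRegion:
    """0-based, half-open genomic interval (BED convention)."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    id: str = ""

    def __post_init__(self):
        if self.start < 0 or self.end < 0:
            raise ValueError("coordinates must be nonnegative")
        if self.start >= self.end:
            raise ValueError("start must be < end")
        if self.strand not in {"+", "-"}:
            raise ValueError("strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start


def define_promoters(tss_table: pd.DataFrame, flank_bp: int = 1000) -> list:
    """Symmetric promoter windows [tss - flank, tss + flank) around TSS.

    ``tss_table`` needs columns chrom, tss, strand, gene. The window is
    strand-invariant (the strand is recorded but the flank is symmetric)
    and clamped at position 0.
    """
    if flank_bp < 0:
        raise ValueError("flank must be nonnegative")
    regions = []
    for row in tss_table.itertuples(index=False):
        if row.tss < 0:
            raise ValueError(f"negative TSS for {row.gene}")
        start = max(0, int(row.tss) - flank_bp)
        end = int(row.tss) + flank_bp
        regions.append(
            GenomicRegion(
                chrom=str(row.chrom),
                start=start,
                end=end,
                strand=str(row.strand),
                id=str(row.gene),
            )
        )
    return regions


def regions_to_bed(regions, path) -> None:
    """Write regions as BED6 (score column 0)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.id}\t0\t{r.strand}\n")


def read_bed(path) -> list:
    regions = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            regions.append(
                GenomicRegion(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    id=f[3] if len(f) > 3 else "",
                    strand=f[5] if len(f) > 5 else "+",
                )
            )
    return regions


def rpkm(counts, lengths_bp, libsize) -> np.ndarray:
    """Reads per kilobase per million mapped reads:
    count * 1e9 / (length_bp * libsize)."""
    counts = np.asarray(counts, float)
    lengths_bp = np.asarray(lengths_bp, float)
    if np.any(lengths_bp <= 0):
        raise ValueError("region lengths must be positive")
    if libsize <= 0:
        raise ValueError("library size must be positive")
    return counts * 1e9 / (lengths_bp * libsize)


def rank_correlation(x, y) -> tuple[float, float]:
    """Spearman rho (midranks for ties) with the t-approximation p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector has undefined rank correlation")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def occupancy_correlation(
    table: pd.DataFrame,
    libsize_a: float | None = None,
    libsize_b: float | None = None,
) -> dict:
    """RPKM-convert a paired promoter count table and correlate the signals.

    ``table`` needs columns count_a, count_b, length_bp; library sizes
    default to the ``attrs`` recorded by the simulator, else column sums.
    """
    la = libsize_a or table.attrs.get("libsize_a") or table["count_a"].sum()
    lb = libsize_b or table.attrs.get("libsize_b") or table["count_b"].sum()
    ra = rpkm(table["count_a"], table["length_bp"], la)
    rb = rpkm(table["count_b"], table["length_bp"], lb)
    rho, p = rank_correlation(ra, rb)
    return {"rho": rho, "p": p, "n_regions": len(table)}
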