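"""Expression filtering, TMM normalization factors, and log2-CPM.

Counts live in a genes x samples integer DataFrame. The filter keeps genes
with more than ``min_count`` reads in at least ``min_samples`` samples
(strict inequality by default). Between-sample scaling uses the trimmed
mean of M-values (TMM): per-sample factors from a doubly trimmed,
precision-weighted mean of gene-wise log2 relative-abundance ratios against
a reference sample, rescaled to geometric mean one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def filter_low_expression(
    counts: pd.DataFrame,
    min_count: int = 15,
    min_samples: int = 2,
    strict: bool = True,
) -> pd.DataFrame:
    """Keep genes with count > min_count (or >= if strict=False) in at
    least ``min_samples`` samples. Gene order is preserved."""
    if counts.shape[1] == 0:
        raise ValueError("count matrix has no samples")
    if min_samples > counts.shape[1]:
        raise ValueError("min_samples exceeds the number of samples")
    vals = counts.to_numpy()
    hits = (vals > min_count) if strict else (vals >= min_count)
    keep = hits.sum(axis=1) >= min_samples
    return counts.loc[keep]


@dataclass
class NormFactors:
    """Per-sample TMM scaling factors (geometric mean 1) and the effective
    library sizes raw_libsize * factor."""

    factors: pd.Series
    lib_sizes: pd.Series

    @property
    def effective_lib_sizes(self) -> pd.Series:
        return self.lib_sizes * self.factors


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float,
    abs_trim: float,
) -> float:
    """Trimmed, inverse-variance-weighted mean of M-values for one sample
    against the reference; returns the log2 scaling factor."""
    pos = (obs > 0) & (ref > 0)
    obs, ref = obs[pos].astype(float), ref[pos].astype(float)
    if obs.size == 0:
        return 0.0
    m = np.log2((obs / n_obs) / (ref / n_ref))
    a = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
    # asymptotic variance of each M-value (delta method for binomial counts)
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)

    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    rm = pd.Series(m).rank().to_numpy()
    ra = pd.Series(a).rank().to_numpy()
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 0.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return 0.0 if not np.isfinite(f) else f


def tmm_factors(
    counts: pd.DataFrame,
    logratio_trim: float = 0.3,
    abs_trim: float = 0.05,
    ref_sample: str | None = None,
) -> NormFactors:
    """TMM normalization factors against a reference sample.

    The reference is the sample whose upper-quartile count fraction is
    closest to the mean upper-quartile fraction, unless given explicitly.
    Genes with a zero count in either member of a pair are excluded from
    that pair's trimmed mean. ``logratio_trim`` and ``abs_trim`` are the
    fractions trimmed from *each* tail of the M and A distributions.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    vals = counts.to_numpy().astype(float)
    lib = vals.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("a sample has zero total count")
    if ref_sample is None:
        uq = np.array(
            [np.quantile(vals[:, j], 0.75) / lib[j] for j in range(len(lib))]
        )
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = list(counts.columns).index(ref_sample)

    log_f = np.array(
        [
            _tmm_pair(
                vals[:, j], vals[:, ref_idx], lib[j], lib[ref_idx],
                logratio_trim, abs_trim,
            )
            for j in range(vals.shape[1])
        ]
    )
    factors = 2.0 ** (log_f - log_f.mean())  # geometric mean 1
    return NormFactors(
        factors=pd.Series(factors, index=counts.columns, name="factor"),
        lib_sizes=pd.Series(lib, index=counts.columns, name="lib_size"),
    )


def log_cpm(
    counts: pd.DataFrame,
    factors: NormFactors | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """log2 counts-per-million: log2((count + prior) / (eff_libsize + 1) * 1e6).

    Effective library sizes come from ``factors`` when given, else raw
    column sums. Attaches ``prior_count`` and the effective library sizes in
    ``DataFrame.attrs`` for downstream precision-weight estimation.
    """
    if prior_count < 0:
        raise ValueError("prior_count must be nonnegative")
    if factors is None:
        eff = counts.sum(axis=0).astype(float)
    else:
        eff = factors.effective_lib_sizes.reindex(counts.columns)
        if eff.isna().any():
            raise ValueError("normalization factors not aligned to samples")
    out = np.log2(
        (counts.to_numpy() + prior_count) / (eff.to_numpy() + 1.0)[None, :] * 1e6
    )
    df = pd.DataFrame(out, index=counts.index, columns=counts.columns)
    df.attrs["prior_count"] = prior_count
    df.attrs["effective_lib_sizes"] = eff
    return df
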