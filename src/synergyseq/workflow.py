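"""End-to-end convenience wrappers over the pipeline stages."""

from __future__ import annotations

import pandas as pd

from synergyseq import lineardge, normfilter, synergy


def run_differential_expression(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    min_count: int = 15,
    min_samples: int = 2,
    span: float = 0.5,
):
    """Filter, normalize, weight, fit, and moderate in one call.

    Returns (moderated ContrastResult, log-CPM matrix, weights).
    """
    filtered = normfilter.filter_low_expression(counts, min_count, min_samples)
    factors = normfilter.tmm_factors(filtered)
    logexpr = normfilter.log_cpm(filtered, factors)
    design, contrasts = lineardge.build_design(samples)
    weights, _ = lineardge.mean_variance_weights(logexpr, design, span=span)
    fit = lineardge.fit_contrasts(logexpr, weights, design, contrasts)
    fit = lineardge.moderate_statistics(fit)
    return fit, logexpr, weights


def run_synergy(counts: pd.DataFrame, samples: pd.DataFrame, **kwargs):
    """Differential expression plus the classified synergy table."""
    fit, logexpr, _ = run_differential_expression(counts, samples, **kwargs)
    table = synergy.synergy_table(fit)
    table = synergy.classify_synergy(table)
    return table, fit, logexpr
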