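"""Synthetic data with known ground truth.

Generates negative-binomial count matrices under a 2x2 diagnosis/treatment
design, gene-set collections with planted enrichment, correlated gene blocks
for co-expression testing, and paired promoter-occupancy tables. Every
generator is fully determined by an explicit integer seed.

The count model: gene g in sample s has mean

    mu_gs = libsize_s * p_gs,   p_gs  proportional to  exp(b0_g) * 2^(eta_gs)

with eta_gs = bD*[SZ] + bT*[JQ] + bS*[SZ][JQ] (log2 effects) and dispersion
following a decreasing trend phi(mu) = phi0 + phi1/mu, so the count variance
is mu + phi*mu^2. Genes assigned to a correlated block additionally share a
per-sample latent factor on the log2 scale, inducing a pairwise correlation
close to the requested block_cor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("CTRL_VEH", "SZ_VEH", "CTRL_JQ", "SZ_JQ")

#: per-group (diagnosis, treatment) factor levels
GROUP_FACTORS = {
    "CTRL_VEH": ("CTRL", "VEH"),
    "SZ_VEH": ("SZ", "VEH"),
    "CTRL_JQ": ("CTRL", "JQ1"),
    "SZ_JQ": ("SZ", "JQ1"),
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic RNA-seq experiment.

    Defaults emulate the study design: four groups with 4/3/4/3 samples,
    log-normal library sizes around 1e7 reads, a decreasing dispersion trend
    phi(mu) = phi0 + phi1/mu, and sparse log2 effects of mean magnitude 1.5
    for diagnosis, treatment, and their interaction (synergy).
    """

    n_genes: int = 2000
    group_sizes: dict = field(
        default_factory=lambda: {
            "CTRL_VEH": 4,
            "SZ_VEH": 3,
            "CTRL_JQ": 4,
            "SZ_JQ": 3,
        }
    )
    #: (mean, sd) of per-gene natural-log baseline expression
    baseline_logmean_dist: tuple = (4.0, 2.0)
    #: (log-mean, log-sd) of per-sample library size
    libsize_dist: tuple = (np.log(1e7), 0.3)
    #: (phi0, phi1) in phi(mu) = phi0 + phi1/mu
    dispersion_trend: tuple = (0.05, 2.0)
    #: fractions of genes with a nonzero diagnosis, treatment, synergy effect
    effect_fractions: tuple = (0.1, 0.1, 0.05)
    #: (mean |log2FC|, sd) of effect magnitudes; signs are random
    effect_size_dist: tuple = (1.5, 0.3)
    n_module_blocks: int = 0
    block_size: int = 50
    #: target pairwise correlation of genes within a block, in [0, 1)
    block_cor: float = 0.7
    #: sd (log2) of the per-sample latent variation given to block genes;
    #: large enough that counting noise barely attenuates block_cor
    block_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if set(self.group_sizes) != set(GROUPS):
            raise ValueError(f"group_sizes must have keys {GROUPS}")
        for g, n in self.group_sizes.items():
            if n <= 0:
                raise ValueError(f"non-positive group size for {g}")
        phi0, _ = self.dispersion_trend
        if phi0 <= 0:
            raise ValueError("phi0 must be > 0")
        for f in self.effect_fractions:
            if not 0 <= f <= 1:
                raise ValueError("effect fractions must be in [0, 1]")
        if not 0 <= self.block_cor < 1:
            raise ValueError("block_cor must be in [0, 1)")
        if self.n_module_blocks * self.block_size > self.n_genes:
            raise ValueError("blocks exceed the gene universe")


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def _classify(bD: np.ndarray, bT: np.ndarray, bS: np.ndarray) -> np.ndarray:
    """Ground-truth class from which effects are nonzero."""
    nz = (bD != 0).astype(int) + (bT != 0).astype(int) + (bS != 0).astype(int)
    label = np.where(nz == 0, "null", "mixed")
    only = nz == 1
    label = np.where(only & (bD != 0), "diag", label)
    label = np.where(only & (bT != 0), "treat", label)
    label = np.where(only & (bS != 0), "synergy", label)
    return label


def simulate_counts(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw a count matrix, sample sheet, and ground-truth table.

    Returns
    -------
    counts : DataFrame, genes x samples, nonnegative integers
    samples : DataFrame with sample_id, diagnosis, treatment, group, libsize
    truth : DataFrame with per-gene b0, bD, bT, bS, dispersion at the
        vehicle-control mean, class label, and block id (0 = no block)
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G = config.n_genes

    sample_ids, groups = [], []
    for g in GROUPS:
        for i in range(config.group_sizes[g]):
            sample_ids.append(f"{g}_{i + 1}")
            groups.append(g)
    S = len(sample_ids)
    is_sz = np.array([GROUP_FACTORS[g][0] == "SZ" for g in groups], float)
    is_jq = np.array([GROUP_FACTORS[g][1] == "JQ1" for g in groups], float)

    mu0, sd0 = config.baseline_logmean_dist
    b0 = rng.normal(mu0, sd0, size=G)  # natural-log baseline

    pD, pT, pS = config.effect_fractions
    es_mean, es_sd = config.effect_size_dist

    def draw_effects(p: float) -> np.ndarray:
        on = rng.random(G) < p
        mag = np.abs(rng.normal(es_mean, es_sd, size=G))
        sign = rng.choice([-1.0, 1.0], size=G)
        return np.where(on, sign * mag, 0.0)

    bD = draw_effects(pD)
    bT = draw_effects(pT)
    bS = draw_effects(pS)

    block_id = np.zeros(G, dtype=int)
    for b in range(config.n_module_blocks):
        lo = b * config.block_size
        block_id[lo : lo + config.block_size] = b + 1
    # co-expression blocks emulate co-regulated gene programs in the
    # mid-to-high expression range: at low counts the latent factor would
    # drown in sampling noise (realized correlation far below block_cor),
    # while letting blocks claim the extreme-abundance tail would couple
    # every other gene to the block factor through library-size closure
    in_block = block_id > 0
    b0[in_block] = mu0 + np.clip((b0[in_block] - mu0) / sd0, -0.5, 1.0) * sd0

    log_ls_mu, log_ls_sd = config.libsize_dist
    libsize = np.exp(rng.normal(log_ls_mu, log_ls_sd, size=S))

    # log2 expression offset per gene/sample from design effects
    eta = (
        np.outer(bD, is_sz) + np.outer(bT, is_jq) + np.outer(bS, is_sz * is_jq)
    )

    # correlated-block latent structure: block genes share a per-sample
    # factor; the shared variance fraction on the log2 scale is block_cor
    if config.n_module_blocks > 0 and config.block_sd > 0:
        rho, sd = config.block_cor, config.block_sd
        # realized factor draws are orthogonalized across blocks and
        # standardized across samples, so distinct blocks are exactly
        # uncorrelated and the shared variance fraction (hence pairwise
        # correlation) is block_cor itself, not a chi-squared-noisy
        # realization of it
        raw_f = rng.normal(0.0, 1.0, size=(S, config.n_module_blocks))
        raw_f -= raw_f.mean(axis=0, keepdims=True)
        factors = np.linalg.qr(raw_f)[0].T * np.sqrt(S)
        for b in range(1, config.n_module_blocks + 1):
            idx = np.where(block_id == b)[0]
            shared = _standardize(factors[b - 1])
            own = rng.normal(0.0, 1.0, size=(idx.size, S))
            own = (own - own.mean(axis=1, keepdims=True)) / own.std(
                axis=1, keepdims=True
            )
            eta[idx] += sd * (
                np.sqrt(rho) * shared[None, :] + np.sqrt(1 - rho) * own
            )

    rel = np.exp(b0)[:, None] * np.exp2(eta)
    p = rel / rel.sum(axis=0, keepdims=True)
    mu = p * libsize[None, :]

    phi0, phi1 = config.dispersion_trend
    phi = phi0 + phi1 / np.maximum(mu, 1e-8)
    # NB with var = mu + phi mu^2: size r = 1/phi, prob = r/(r+mu)
    r = 1.0 / phi
    counts = rng.negative_binomial(r, r / (r + mu))

    gene_ids = np.array([f"gene{i + 1:05d}" for i in range(G)])
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    counts_df.index.name = "gene_id"
    samples_df = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "diagnosis": [GROUP_FACTORS[g][0] for g in groups],
            "treatment": [GROUP_FACTORS[g][1] for g in groups],
            "group": groups,
            "libsize": libsize,
        }
    )
    mu_ctrl = p[:, 0] * np.exp(log_ls_mu)
    truth_df = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "b0": b0 / np.log(2),  # report baseline on the log2 scale
            "bD": bD,
            "bT": bT,
            "bS": bS,
            "dispersion": phi0 + phi1 / np.maximum(mu_ctrl, 1e-8),
            "class": _classify(bD, bT, bS),
            "block": block_id,
        }
    ).set_index("gene_id")
    return counts_df, samples_df, truth_df


#: the eight gene-set category labels used for the curated neural collection
SET_CATEGORIES = (
    "presynaptic",
    "postsynaptic",
    "glial",
    "brain_expression",
    "neuropsychiatric_disorder",
    "neurodevelopment",
    "ion_channel",
    "neurotransmitter",
)


def simulate_gene_sets(
    truth: pd.DataFrame,
    n_sets: int = 698,
    set_size_range: tuple = (20, 200),
    n_enriched: int = 0,
    enrich_class: str = "synergy",
    odds_ratio: float = 10.0,
    seed: int = 0,
):
    """Sample a categorized gene-set collection over the simulated universe.

    The first ``n_enriched`` sets oversample genes of ``enrich_class`` with
    the given odds ratio; all other sets sample uniformly without
    replacement. Each set is tagged with one of eight category labels.
    """
    from synergyseq.genesets import GeneSetCollection

    if len(truth) == 0:
        raise ValueError("empty ground truth")
    if n_enriched > n_sets:
        raise ValueError("n_enriched exceeds n_sets")
    lo, hi = set_size_range
    if hi > len(truth):
        raise ValueError("set size exceeds gene universe")
    rng = np.random.default_rng(seed)
    genes = np.asarray(truth.index)
    in_class = (truth["class"] == enrich_class).to_numpy()

    sets, categories = {}, {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        if i < n_enriched:
            w = np.where(in_class, odds_ratio, 1.0)
            members = rng.choice(genes, size=size, replace=False, p=w / w.sum())
        else:
            members = rng.choice(genes, size=size, replace=False)
        name = f"set{i + 1:04d}"
        sets[name] = list(members)
        categories[name] = SET_CATEGORIES[i % len(SET_CATEGORIES)]
    return GeneSetCollection(sets=sets, categories=categories)


def simulate_promoter_occupancy(
    n_regions: int = 5000,
    target_rho: float = 0.88,
    seed: int = 0,
    region_length: int = 2000,
    log_mean: float = 5.0,
    log_sd: float = 1.0,
) -> pd.DataFrame:
    """Paired promoter read-count tables with a calibrated rank correlation.

    Both signals derive from a shared standard-normal latent plus
    independent noise, mixed so that the Spearman correlation of the two
    count vectors is near ``target_rho`` (for bivariate normal latents,
    Spearman rho_s relates to the Pearson latent correlation r via
    r = 2 sin(pi * rho_s / 6)). Counts are a deterministic log-normal
    transform of the latents, so ``target_rho = 1`` gives identical ranks.

    Returns a DataFrame with columns count_a, count_b, length_bp and
    attributes ``libsize_a``/``libsize_b`` in ``attrs``.
    """
    if n_regions < 10:
        raise ValueError("n_regions must be >= 10")
    if not 0 <= target_rho <= 1:
        raise ValueError("target_rho must be in [0, 1]")
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n_regions)
    if target_rho >= 1.0:
        ga = gb = z
    else:
        r = 2.0 * np.sin(np.pi * target_rho / 6.0)
        a = np.sqrt(r)
        ea = rng.normal(size=n_regions)
        eb = rng.normal(size=n_regions)
        ga = a * z + np.sqrt(1 - r) * ea
        gb = a * z + np.sqrt(1 - r) * eb
    count_a = np.round(np.exp(log_mean + log_sd * ga)).astype(int)
    count_b = np.round(np.exp(log_mean + log_sd * gb)).astype(int)
    out = pd.DataFrame(
        {
            "region_id": [f"promoter{i + 1}" for i in range(n_regions)],
            "count_a": count_a,
            "count_b": count_b,
            "length_bp": region_length,
        }
    ).set_index("region_id")
    out.attrs["libsize_a"] = int(count_a.sum())
    out.attrs["libsize_b"] = int(count_b.sum())
    return out


def write_simulation(
    outdir,
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    truth: pd.DataFrame,
) -> None:
    """Write counts TSV, sample sheet CSV, and ground-truth TSV."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    samples.to_csv(outdir / "samples.csv", index=False)
    truth.to_csv(outdir / "truth.tsv", sep="\t")
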