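"""Synthetic genotype generation for fixtures and simulations.

All samplers use ``numpy.random.default_rng`` with an explicit mandatory
seed; there is no global RNG state.  Diploid genotypes are formed by
drawing two independent haplotypes per individual (random mating /
Hardy-Weinberg equilibrium).  The drift simulator and the panel generator
share the no-interference gamete rule of the deterministic recombination
recursion: the two inter-locus intervals recombine independently.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .admixture import AdmixtureScenario
from .em_estimator import GenotypeTripletCounts
from .io_scan import GenotypePanel
from .ld_core import HaplotypeFrequencies, params_to_haplotypes
from .recombination import RecombinationRates

__all__ = [
    "sample_triplet_genotypes",
    "sample_triplet_codes",
    "simulate_drift",
    "simulate_admixed_cohort",
    "generate_panel",
    "panel_from_triplet_haplotypes",
]

_HAP_ALLELES = np.array(
    [[a, b, c] for a in (0, 1) for b in (0, 1) for c in (0, 1)], dtype=np.int8
)


def _codes_from_gametes(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """1/2/3 genotype codes from two (n, loci) 0/1 allele arrays."""
    codes = np.where(g1 == g2, np.where(g1 == 0, 1, 2), 3)
    return codes.astype(np.int8)


def sample_triplet_codes(h: HaplotypeFrequencies, n: int, seed: int) -> np.ndarray:
    """Genotype codes (n, 3) for ``n`` HWE individuals drawn from ``h``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    p = h.to_flat()
    draws = rng.choice(8, size=(n, 2), p=p / p.sum())
    return _codes_from_gametes(_HAP_ALLELES[draws[:, 0]], _HAP_ALLELES[draws[:, 1]])


def sample_triplet_genotypes(h: HaplotypeFrequencies, n: int, seed: int) -> GenotypeTripletCounts:
    """Joint-genotype counts for ``n`` HWE individuals drawn from ``h``."""
    codes = sample_triplet_codes(h, n, seed)
    return GenotypeTripletCounts.from_codes(codes[:, 0], codes[:, 1], codes[:, 2])


def _recombine(
    hap_a: np.ndarray, hap_b: np.ndarray, rates: RecombinationRates, rng
) -> np.ndarray:
    """No-interference gametes from paired parental haplotypes (n, 3)."""
    n = len(hap_a)
    start = rng.integers(0, 2, size=n, dtype=np.int8)
    x12 = (rng.random(n) < rates.c12).astype(np.int8)
    x23 = (rng.random(n) < rates.c23).astype(np.int8)
    which1 = start
    which2 = which1 ^ x12
    which3 = which2 ^ x23
    stacked = np.stack([hap_a, hap_b])  # (2, n, 3)
    rows = np.arange(n)
    out = np.empty((n, 3), dtype=np.int8)
    out[:, 0] = stacked[which1, rows, 0]
    out[:, 1] = stacked[which2, rows, 1]
    out[:, 2] = stacked[which3, rows, 2]
    return out


def simulate_drift(
    h0: HaplotypeFrequencies,
    pop_size: int,
    generations: int,
    rates: RecombinationRates,
    seed: int,
) -> list[HaplotypeFrequencies]:
    """Wright-Fisher resampling of ``2 * pop_size`` gametes per generation.

    Each offspring gamete is produced by drawing two parental haplotypes
    from the current pool frequencies and recombining them with the
    no-interference rule.  Returns the frequency trajectory including the
    start state (length ``generations + 1``).
    """
    if pop_size < 2:
        raise ValueError("pop_size must be >= 2")
    if generations < 1:
        raise ValueError("generations must be >= 1")
    rng = np.random.default_rng(seed)
    n_gametes = 2 * pop_size
    freqs = h0.to_flat()
    out = [h0]
    for _ in range(generations):
        parents_a = _HAP_ALLELES[rng.choice(8, size=n_gametes, p=freqs / freqs.sum())]
        parents_b = _HAP_ALLELES[rng.choice(8, size=n_gametes, p=freqs / freqs.sum())]
        gametes = _recombine(parents_a, parents_b, rates, rng)
        idx = gametes[:, 0] * 4 + gametes[:, 1] * 2 + gametes[:, 2]
        freqs = np.bincount(idx, minlength=8) / float(n_gametes)
        out.append(HaplotypeFrequencies(freqs.reshape(2, 2, 2)))
    return out


def simulate_admixed_cohort(
    scenario: AdmixtureScenario, n: int, seed: int
) -> GenotypeTripletCounts:
    """HWE genotype counts drawn from the pooled gametes of a cross.

    The gamete pool is the tau-mixture of the parent haplotype frequencies,
    so EM estimation on the output recovers the cross decomposition within
    sampling error.
    """
    hx = params_to_haplotypes(scenario.pop_x).freq
    hy = params_to_haplotypes(scenario.pop_y).freq
    hz = HaplotypeFrequencies(scenario.tau * hx + (1.0 - scenario.tau) * hy)
    return sample_triplet_genotypes(hz, n, seed)


# ---------------------------------------------------------------------------
# multi-SNP panels


def _pool_matrix(depth: int, n_snps: int, rng) -> np.ndarray:
    """Random haplotype pool (depth, n_snps) of 0/1 alleles; every column is
    resampled until polymorphic within the pool."""
    pool = rng.integers(0, 2, size=(depth, n_snps), dtype=np.int8)
    for s in range(n_snps):
        while pool[:, s].min() == pool[:, s].max():
            pool[:, s] = rng.integers(0, 2, size=depth, dtype=np.int8)
    return pool


def generate_panel(
    n_samples: int,
    snps_per_chrom,
    seed: int,
    pool_depth: int = 4,
    spacing_bp: int = 100_000,
    switch_prob: float = 0.0,
    chrom_prefix: str = "chr",
) -> tuple[GenotypePanel, dict[str, np.ndarray]]:
    """Multi-chromosome diploid panel drawn from per-chromosome haplotype pools.

    Parameters
    ----------
    snps_per_chrom
        Either an int (same count for every chromosome, requires a sequence
        form below for heterogeneous counts) or a sequence of per-chromosome
        SNP counts; chromosome labels are ``chr1, chr2, ...``.
    pool_depth
        Number of founder haplotypes per chromosome.  Small pools create
        strong multi-locus LD (any triplet segregates at most ``pool_depth``
        haplotypes); chromosomes are generated independently, so there is
        no inter-chromosomal LD.
    switch_prob
        Per-interval probability that a sampled gamete switches to another
        random founder haplotype, creating LD that decays with distance.
        0 keeps each gamete a full founder haplotype.

    Returns the panel and a truth dict mapping chromosome label to its
    founder pool matrix (``pool_depth`` x n_snps of 0/1 alleles, 0 = allele
    a1).
    """
    if isinstance(snps_per_chrom, (int, np.integer)):
        snps_per_chrom = [int(snps_per_chrom)]
    rng = np.random.default_rng(seed)
    all_snps = []
    geno_blocks = []
    truth: dict[str, np.ndarray] = {}
    for c, n_snps in enumerate(snps_per_chrom, start=1):
        label = f"{chrom_prefix}{c}"
        pool = _pool_matrix(pool_depth, n_snps, rng)
        truth[label] = pool
        # gametes as founder-index mosaics along the chromosome
        idx = np.empty((2 * n_samples, n_snps), dtype=np.intp)
        idx[:, 0] = rng.integers(0, pool_depth, size=2 * n_samples)
        if switch_prob > 0.0:
            for s in range(1, n_snps):
                switch = rng.random(2 * n_samples) < switch_prob
                idx[:, s] = np.where(
                    switch, rng.integers(0, pool_depth, size=2 * n_samples), idx[:, s - 1]
                )
        else:
            idx[:, 1:] = idx[:, [0]]
        cols = np.arange(n_snps)
        gametes = pool[idx, cols]  # (2n, n_snps)
        g1 = gametes[0::2]
        g2 = gametes[1::2]
        codes = np.where(g1 == g2, np.where(g1 == 0, 1, 2), 3).astype(np.int8)
        geno_blocks.append(codes.T)  # (n_snps, n_samples)
        for s in range(n_snps):
            all_snps.append(
                (f"{label}_snp{s + 1:05d}", label, (s + 1) * spacing_bp, "A", "B")
            )
    samples = [f"ind{j + 1:04d}" for j in range(n_samples)]
    snps = pd.DataFrame(all_snps, columns=["snp", "chrom", "pos", "a1", "a2"])
    panel = GenotypePanel(samples, snps, np.vstack(geno_blocks))
    return panel, truth


def panel_from_triplet_haplotypes(
    h: HaplotypeFrequencies,
    n_samples: int,
    seed: int,
    chrom: str = "chr1",
    positions=(100_000, 200_000, 300_000),
) -> GenotypePanel:
    """Three-SNP panel on one chromosome drawn from explicit three-locus
    haplotype frequencies (HWE sampling); handy for scan oracles."""
    codes = sample_triplet_codes(h, n_samples, seed)
    snps = pd.DataFrame(
        {
            "snp": [f"{chrom}_snp{i + 1}" for i in range(3)],
            "chrom": chrom,
            "pos": list(positions),
            "a1": "A",
            "a2": "B",
        }
    )
    samples = [f"ind{j + 1:04d}" for j in range(n_samples)]
    return GenotypePanel(samples, snps, codes.T.copy())
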