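"""SNP panel input and genome-wide triplet scans.

Reads diploid genotype panels (PLINK .ped/.map text dialect, or VCF via
cyvcf2), applies MAF / call-rate filters, and runs three scan designs over
SNP triplets: consecutive triplets per chromosome, random inter-chromosomal
triplets, and all triplets within a rolling window on one chromosome.  Each
triplet is fitted with the EM estimator and reported with its full LD
decomposition, normalization, haplotype count and likelihood-ratio test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import em_estimator as em
from .ld_core import count_segregating_haplotypes, normalize_robinson

logger = logging.getLogger(__name__)

__all__ = [
    "MISSING",
    "GenotypePanel",
    "read_panel",
    "qc_filter",
    "enumerate_consecutive_triplets",
    "enumerate_window_triplets",
    "scan_consecutive",
    "scan_inter_chromosomal",
    "scan_window_all_triplets",
    "distance_ld_summary",
    "DistanceLDSummary",
    "SCAN_COLUMNS",
]

#: genotype code for a missing call (valid calls are 1, 2, 3)
MISSING = 0

SCAN_COLUMNS = [
    "snp1", "snp2", "snp3",
    "chr1", "chr2", "chr3",
    "pos1", "pos2", "pos3",
    "span_bp", "n",
    "f1", "f2", "f3", "d12", "d13", "d23", "d123",
    "beta", "norm_category", "norm_value", "n_haplotypes",
    "loglik", "lrt", "lrt_df", "lrt_pvalue", "iterations", "converged",
]


@dataclass
class GenotypePanel:
    """Biallelic SNP genotypes for a set of samples.

    ``snps`` holds one row per SNP (columns ``snp``, ``chrom``, ``pos``,
    ``a1``, ``a2``), sorted by chromosome then position; ``genotypes`` is an
    (n_snps, n_samples) array of codes 1 (hom a1), 2 (hom a2), 3 (het),
    0 (missing).  Allele ``a1`` is the first-listed allele of the input
    (first allele encountered in a .ped file, REF in VCF), so the signs of
    all LD coefficients downstream are orientation-dependent.
    """

    samples: list[str]
    snps: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.snps), len(self.samples)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.snps)} SNPs x {len(self.samples)} samples"
            )
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def chromosomes(self) -> list[str]:
        """Chromosome labels in panel order (first-appearance order)."""
        return list(dict.fromkeys(self.snps["chrom"]))

    def subset(self, indices) -> "GenotypePanel":
        indices = np.asarray(indices)
        return GenotypePanel(
            samples=list(self.samples),
            snps=self.snps.iloc[indices].reset_index(drop=True),
            genotypes=self.genotypes[indices],
        )

    def allele1_frequencies(self) -> np.ndarray:
        """Per-SNP frequency of allele a1 among non-missing calls."""
        g = self.genotypes
        called = g != MISSING
        n_called = called.sum(axis=1)
        a1 = 2 * (g == 1).sum(axis=1) + (g == 3).sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(n_called > 0, a1 / (2.0 * n_called), np.nan)

    def call_rates(self) -> np.ndarray:
        return (self.genotypes != MISSING).sum(axis=1) / float(self.n_samples)

    def sort(self) -> "GenotypePanel":
        """Sort SNPs by (chromosome, position), keeping chromosome groups."""
        order = self.snps.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
        return self.subset(order)

    # -- serialization ------------------------------------------------------

    def write_ped_map(self, prefix: str) -> None:
        """Write the panel as whitespace-delimited .ped/.map text files."""
        with open(f"{prefix}.map", "w") as fh:
            for row in self.snps.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.snp}\t0\t{row.pos}\n")
        code_to_pair = {
            1: ("a1", "a1"),
            2: ("a2", "a2"),
            3: ("a1", "a2"),
            MISSING: ("0", "0"),
        }
        a1 = self.snps["a1"].to_numpy()
        a2 = self.snps["a2"].to_numpy()
        with open(f"{prefix}.ped", "w") as fh:
            for j, sample in enumerate(self.samples):
                fields = [sample, sample, "0", "0", "0", "-9"]
                for i in range(self.n_snps):
                    kind = code_to_pair[int(self.genotypes[i, j])]
                    pair = [a1[i] if k == "a1" else a2[i] if k == "a2" else "0" for k in kind]
                    fields.extend(pair)
                fh.write(" ".join(fields) + "\n")


def _read_ped_map(prefix: str) -> GenotypePanel:
    try:
        map_rows = []
        with open(f"{prefix}.map") as fh:
            for lineno, line in enumerate(fh, 1):
                parts = line.split()
                if not parts:
                    continue
                if len(parts) < 4:
                    raise ValueError(f"{prefix}.map:{lineno}: expected 4 fields, got {len(parts)}")
                map_rows.append((parts[0], parts[1], int(parts[3])))
    except OSError as exc:
        raise FileNotFoundError(f"cannot read {prefix}.map: {exc}") from exc

    n_snps = len(map_rows)
    samples: list[str] = []
    raw: list[list[tuple[str, str]]] = []  # per sample, per SNP allele pair
    with open(f"{prefix}.ped") as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise ValueError(
                    f"{prefix}.ped:{lineno}: expected {6 + 2 * n_snps} fields "
                    f"for {n_snps} SNPs, got {len(parts)}"
                )
            samples.append(parts[1])
            alleles = parts[6:]
            raw.append([(alleles[2 * i], alleles[2 * i + 1]) for i in range(n_snps)])

    # allele "1" is the first non-missing allele encountered per SNP
    genotypes = np.zeros((n_snps, len(samples)), dtype=np.int8)
    keep = np.ones(n_snps, dtype=bool)
    snp_rows = []
    n_multi = 0
    for i, (chrom, snp, pos) in enumerate(map_rows):
        labels: list[str] = []
        for j in range(len(samples)):
            for a in raw[j][i]:
                if a != "0" and a not in labels:
                    labels.append(a)
        if len(labels) > 2:
            n_multi += 1
            keep[i] = False
            logger.warning("dropping SNP %s: more than two alleles %s", snp, labels)
            continue
        while len(labels) < 2:
            labels.append("?")  # monomorphic or fully missing: placeholder a2
        a1 = labels[0]
        for j in range(len(samples)):
            x, y = raw[j][i]
            if x == "0" or y == "0":
                genotypes[i, j] = MISSING
            elif x == y:
                genotypes[i, j] = 1 if x == a1 else 2
            else:
                genotypes[i, j] = 3
        snp_rows.append((snp, chrom, pos, labels[0], labels[1]))
    if n_multi:
        logger.info("dropped %d multi-allelic SNPs", n_multi)
    snps = pd.DataFrame(snp_rows, columns=["snp", "chrom", "pos", "a1", "a2"])
    return GenotypePanel(samples, snps, genotypes[keep]).sort()


def _read_vcf(path: str) -> GenotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    snp_rows = []
    geno_rows = []
    n_dropped = 0
    for idx, variant in enumerate(vcf):
        if len(variant.ALT) != 1:
            n_dropped += 1
            logger.warning(
                "dropping non-biallelic VCF record %s:%d (%d ALT alleles)",
                variant.CHROM, variant.POS, len(variant.ALT),
            )
            continue
        codes = np.empty(len(samples), dtype=np.int8)
        for j, gt in enumerate(variant.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                codes[j] = MISSING
            elif a == b:
                codes[j] = 1 if a == 0 else 2
            else:
                codes[j] = 3
        name = variant.ID if variant.ID else f"{variant.CHROM}:{variant.POS}"
        snp_rows.append((name, variant.CHROM, variant.POS, variant.REF, variant.ALT[0]))
        geno_rows.append(codes)
    if n_dropped:
        logger.info("dropped %d non-biallelic VCF records", n_dropped)
    snps = pd.DataFrame(snp_rows, columns=["snp", "chrom", "pos", "a1", "a2"])
    genotypes = np.array(geno_rows, dtype=np.int8) if geno_rows else np.empty((0, len(samples)), np.int8)
    return GenotypePanel(samples, snps, genotypes).sort()


def read_panel(path: str, format: str = "ped") -> GenotypePanel:
    """Read a genotype panel.

    ``format="ped"`` expects ``path`` to be the prefix of a ``.ped``/``.map``
    pair (a trailing ``.ped`` is stripped); ``format="vcf"`` reads a VCF 4.x
    file.  Multi-allelic records are dropped with a logged count.
    """
    if format == "ped":
        prefix = path[:-4] if path.endswith(".ped") else path
        return _read_ped_map(prefix)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown panel format {format!r} (expected 'ped' or 'vcf')")


def qc_filter(
    panel: GenotypePanel, maf_min: float = 0.05, call_rate_min: float = 0.99
) -> GenotypePanel:
    """Drop SNPs with minor-allele frequency <= ``maf_min`` or call rate
    < ``call_rate_min``; removal counts are logged."""
    if not (0.0 <= maf_min <= 1.0 and 0.0 <= call_rate_min <= 1.0):
        raise ValueError("thresholds must be in [0, 1]")
    p = panel.allele1_frequencies()
    maf = np.minimum(p, 1.0 - p)
    ok_maf = np.nan_to_num(maf, nan=0.0) > maf_min
    ok_call = panel.call_rates() >= call_rate_min
    keep = ok_maf & ok_call
    logger.info(
        "qc_filter: kept %d/%d SNPs (%d failed MAF, %d failed call rate)",
        int(keep.sum()), panel.n_snps, int((~ok_maf).sum()), int((~ok_call).sum()),
    )
    return panel.subset(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# triplet enumeration


def enumerate_consecutive_triplets(panel: GenotypePanel) -> list[tuple[int, int, int]]:
    """Sliding windows of 3 adjacent SNPs per chromosome (panel indices)."""
    out = []
    chrom = panel.snps["chrom"].to_numpy()
    for label in dict.fromkeys(chrom):
        idx = np.flatnonzero(chrom == label)
        for k in range(len(idx) - 2):
            out.append((int(idx[k]), int(idx[k + 1]), int(idx[k + 2])))
    return out


def enumerate_window_triplets(
    panel: GenotypePanel, chromosome: str, window_snps: int
) -> list[tuple[int, int, int]]:
    """All triplets whose outermost SNPs lie within ``window_snps``
    consecutive SNPs of one chromosome, deduplicated across rolling windows
    (equivalently: index span <= window_snps - 1)."""
    if window_snps < 3:
        raise ValueError("window_snps must be >= 3")
    idx = np.flatnonzero(panel.snps["chrom"].to_numpy() == chromosome)
    out = []
    n = len(idx)
    for a in range(n - 2):
        hi = min(n, a + window_snps)
        for c in range(a + 2, hi):
            for b in range(a + 1, c):
                out.append((int(idx[a]), int(idx[b]), int(idx[c])))
    return out


# ---------------------------------------------------------------------------
# triplet fitting


def _fit_triplet(panel: GenotypePanel, i: int, j: int, k: int) -> dict | None:
    """EM fit + summaries for one SNP triplet; None if degenerate."""
    g = panel.genotypes[[i, j, k]]
    counts = em.GenotypeTripletCounts.from_codes(g[0], g[1], g[2])
    n = counts.n
    if n == 0:
        logger.warning("triplet (%d,%d,%d): no complete cases, skipped", i, j, k)
        return None
    freqs = em.allele_frequencies(counts)
    if any(f <= 0.0 or f >= 1.0 for f in freqs):
        logger.warning(
            "triplet (%s,%s,%s): monomorphic locus among complete cases, skipped",
            panel.snps.at[i, "snp"], panel.snps.at[j, "snp"], panel.snps.at[k, "snp"],
        )
        return None
    lrt = em.lrt_full_vs_allele_only(counts)
    fit = lrt.fit
    dec = fit.decomposition
    norm = normalize_robinson(dec)
    meta = panel.snps
    pos = sorted(int(meta.at[x, "pos"]) for x in (i, j, k))
    same_chrom = len({meta.at[x, "chrom"] for x in (i, j, k)}) == 1
    span = pos[-1] - pos[0] if same_chrom else np.nan
    return {
        "snp1": meta.at[i, "snp"], "snp2": meta.at[j, "snp"], "snp3": meta.at[k, "snp"],
        "chr1": meta.at[i, "chrom"], "chr2": meta.at[j, "chrom"], "chr3": meta.at[k, "chrom"],
        "pos1": int(meta.at[i, "pos"]), "pos2": int(meta.at[j, "pos"]), "pos3": int(meta.at[k, "pos"]),
        "span_bp": span, "n": n,
        "f1": dec.f1, "f2": dec.f2, "f3": dec.f3,
        "d12": dec.d12, "d13": dec.d13, "d23": dec.d23, "d123": dec.d123,
        "beta": norm.beta, "norm_category": norm.category.value, "norm_value": norm.value,
        "n_haplotypes": count_segregating_haplotypes(fit.haplotypes, tol=1e-6),
        "loglik": fit.loglik, "lrt": lrt.statistic, "lrt_df": lrt.df,
        "lrt_pvalue": lrt.pvalue,
        "iterations": fit.iterations, "converged": fit.converged,
    }


def _records_frame(rows: list[dict]) -> pd.DataFrame:
    frame = pd.DataFrame(rows, columns=SCAN_COLUMNS)
    return frame


def scan_consecutive(panel: GenotypePanel) -> pd.DataFrame:
    """Fit every triplet of three consecutive SNPs per chromosome.

    Record count is ``sum over chromosomes of max(0, n_snps - 2)`` minus
    any degenerate (monomorphic / empty) triplets, which are skipped with a
    logged reason.
    """
    rows = []
    for i, j, k in enumerate_consecutive_triplets(panel):
        rec = _fit_triplet(panel, i, j, k)
        if rec is not None:
            rows.append(rec)
    return _records_frame(rows)


def scan_inter_chromosomal(
    panel: GenotypePanel, n_draws: int, seed: int
) -> pd.DataFrame:
    """Fit ``n_draws`` random triplets of one SNP from each of three
    distinct chromosomes; reproducible under ``seed``."""
    chroms = panel.chromosomes()
    if len(chroms) < 3:
        raise ValueError(f"inter-chromosomal scan needs >= 3 chromosomes, got {len(chroms)}")
    rng = np.random.default_rng(seed)
    chrom_col = panel.snps["chrom"].to_numpy()
    by_chrom = {c: np.flatnonzero(chrom_col == c) for c in chroms}
    rows = []
    for _ in range(n_draws):
        picked = rng.choice(len(chroms), size=3, replace=False)
        idx = sorted(int(rng.choice(by_chrom[chroms[c]])) for c in picked)
        rec = _fit_triplet(panel, *idx)
        if rec is not None:
            rows.append(rec)
    return _records_frame(rows)


def scan_window_all_triplets(
    panel: GenotypePanel, chromosome: str, window_snps: int
) -> pd.DataFrame:
    """Fit all triplets within a rolling ``window_snps`` window on one
    chromosome (deduplicated; see :func:`enumerate_window_triplets`)."""
    rows = []
    for i, j, k in enumerate_window_triplets(panel, chromosome, window_snps):
        rec = _fit_triplet(panel, i, j, k)
        if rec is not None:
            rows.append(rec)
    return _records_frame(rows)


@dataclass
class DistanceLDSummary:
    """Correlation of |third-order LD| with physical span, plus percentile
    curves of the coefficient by span bin."""

    correlation: float
    se: float
    n: int
    percentiles: pd.DataFrame  # columns: span_mid, q25, q50, q75, n


def distance_ld_summary(records: pd.DataFrame, n_bins: int = 10) -> DistanceLDSummary:
    """Pearson correlation between |d123| and span plus binned percentiles.

    The correlation is NaN (flagged, not raised) when either variable is
    constant across records.  Standard error is the large-sample
    ``sqrt((1 - r^2) / (n - 2))``.
    """
    if len(records) < 2:
        raise ValueError("distance_ld_summary needs at least 2 records")
    span = records["span_bp"].to_numpy(dtype=float)
    absd = records["d123"].abs().to_numpy(dtype=float)
    n = len(records)
    if np.ptp(span) == 0 or np.ptp(absd) == 0:
        corr, se = math.nan, math.nan
    else:
        corr = float(np.corrcoef(span, absd)[0, 1])
        se = math.sqrt(max(0.0, 1.0 - corr**2) / (n - 2))
    bins = np.quantile(span, np.linspace(0, 1, n_bins + 1))
    bins[-1] += 1.0
    which = np.clip(np.digitize(span, bins) - 1, 0, n_bins - 1)
    rows = []
    d123 = records["d123"].to_numpy(dtype=float)
    for b in range(n_bins):
        sel = which == b
        if not np.any(sel):
            continue
        rows.append(
            {
                "span_mid": float(np.median(span[sel])),
                "q25": float(np.quantile(d123[sel], 0.25)),
                "q50": float(np.quantile(d123[sel], 0.50)),
                "q75": float(np.quantile(d123[sel], 0.75)),
                "n": int(sel.sum()),
            }
        )
    return DistanceLDSummary(
        correlation=corr, se=se, n=n, percentiles=pd.DataFrame(rows)
    )
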