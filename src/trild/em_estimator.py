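"""Maximum-likelihood haplotype-frequency estimation from unphased genotypes.

Three biallelic SNPs genotyped in N diploid individuals give a 3x3x3 table
of joint-genotype counts (codes 1 = homozygous for allele "1",
2 = homozygous for allele "2", 3 = heterozygous).  Under Hardy-Weinberg
equilibrium the probability of each of the 27 joint genotypes is a sum of
products of two haplotype frequencies over the compatible (unordered)
haplotype pairs.  Individuals heterozygous at two or three loci are
phase-ambiguous; the EM algorithm apportions them between the alternative
pair resolutions (coupling/repulsion weights) and re-estimates haplotype
frequencies by gamete counting until convergence.

The E-step enumerates the compatible haplotype pairs per genotype class
(at most 4, for the triple heterozygote) rather than special-casing each
class, which keeps the machinery extensible beyond three loci.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .ld_core import (
    HAPLOTYPE_LABELS,
    HaplotypeFrequencies,
    LDDecomposition,
    haplotypes_to_params,
)

__all__ = [
    "GenotypeTripletCounts",
    "EMFit",
    "LRTResult",
    "genotype_probabilities",
    "em_fit",
    "loglikelihood",
    "allele_frequencies",
    "lrt_full_vs_allele_only",
    "read_counts_tsv",
    "write_counts_tsv",
]

_HAP_TRIPLES = tuple(itertools.product((0, 1), repeat=3))  # index order = labels


def _pair_genotype(a: tuple[int, ...], b: tuple[int, ...]) -> tuple[int, ...]:
    """Genotype codes (0-based: 0=hom1, 1=hom2, 2=het) of haplotype pair a/b."""
    out = []
    for x, y in zip(a, b):
        if x == y:
            out.append(x)  # 0 -> hom allele 1, 1 -> hom allele 2
        else:
            out.append(2)
    return tuple(out)


def _build_pair_table():
    """Static map from unordered haplotype pairs to genotype classes.

    Returns flat-index arrays: genotype class (0..26), haplotype indices of
    the pair, and the multiplicity (2 for heterodyad, 1 for a homodyad).
    """
    cls, ia, ib, mult = [], [], [], []
    for i, a in enumerate(_HAP_TRIPLES):
        for j in range(i, 8):
            b = _HAP_TRIPLES[j]
            g = _pair_genotype(a, b)
            cls.append(g[0] * 9 + g[1] * 3 + g[2])
            ia.append(i)
            ib.append(j)
            mult.append(1.0 if i == j else 2.0)
    return (
        np.array(cls, dtype=np.intp),
        np.array(ia, dtype=np.intp),
        np.array(ib, dtype=np.intp),
        np.array(mult),
    )


_PAIR_CLASS, _PAIR_A, _PAIR_B, _PAIR_MULT = _build_pair_table()


@dataclass(frozen=True)
class GenotypeTripletCounts:
    """3x3x3 table of individual counts by joint genotype.

    Index order is locus 1, 2, 3 with 0-based codes 0 = homozygous allele
    "1", 1 = homozygous allele "2", 2 = heterozygous (the conventional
    1/2/3 coding minus one).
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (3, 3, 3):
            raise ValueError(f"counts must have shape (3, 3, 3), got {arr.shape}")
        if np.any(arr < 0):
            raise ValueError("negative genotype counts")
        object.__setattr__(self, "counts", arr.astype(float))

    @property
    def n(self) -> int:
        return int(round(float(self.counts.sum())))

    @classmethod
    def from_codes(cls, g1, g2, g3) -> "GenotypeTripletCounts":
        """Tally 1/2/3-coded genotype calls; individuals with a missing
        (non-1/2/3) code at any locus are dropped (complete-case)."""
        g = np.stack([np.asarray(g1), np.asarray(g2), np.asarray(g3)])
        keep = np.all((g >= 1) & (g <= 3), axis=0)
        g = g[:, keep] - 1
        arr = np.zeros((3, 3, 3))
        np.add.at(arr, (g[0], g[1], g[2]), 1.0)
        return cls(arr)


@dataclass
class EMFit:
    """Converged EM state: haplotype frequencies and derived quantities."""

    haplotypes: HaplotypeFrequencies
    loglik: float
    iterations: int
    converged: bool
    #: log-likelihood after every iteration (non-decreasing)
    loglik_trace: np.ndarray = field(repr=False, default=None)
    #: final phase-ambiguity weights per multi-heterozygous genotype class:
    #: {"332": {("111", "122"): w, ("112", "121")): 1-w}, ...}
    weights: dict = field(repr=False, default_factory=dict)

    @property
    def decomposition(self) -> LDDecomposition:
        return haplotypes_to_params(self.haplotypes)


def genotype_probabilities(h: HaplotypeFrequencies) -> np.ndarray:
    """Probabilities of the 27 joint genotypes under HWE, shape (3, 3, 3).

    ``phi[g] = sum over unordered compatible haplotype pairs (a, b) of
    2 f_a f_b (a != b) or f_a^2 (a == b)``; the triple-heterozygote class
    sums over its 4 coupling/repulsion pair resolutions.
    """
    f = h.to_flat()
    phi = np.zeros(27)
    np.add.at(phi, _PAIR_CLASS, _PAIR_MULT * f[_PAIR_A] * f[_PAIR_B])
    return phi.reshape(3, 3, 3)


def loglikelihood(h: HaplotypeFrequencies, counts: GenotypeTripletCounts) -> float:
    """Multinomial log-likelihood ``sum n_g log phi_g`` (constant omitted).

    Returns ``-inf`` when an observed genotype class has zero probability.
    """
    phi = genotype_probabilities(h).reshape(27)
    n = counts.counts.reshape(27)
    obs = n > 0
    if np.any(phi[obs] <= 0.0):
        return -math.inf
    return float(np.sum(n[obs] * np.log(phi[obs])))


def _final_weights(f: np.ndarray) -> dict:
    """Coupling/repulsion weights of the multi-heterozygous classes."""
    pair_prob = _PAIR_MULT * f[_PAIR_A] * f[_PAIR_B]
    out: dict[str, dict[tuple[str, str], float]] = {}
    for cls in np.unique(_PAIR_CLASS):
        sel = np.flatnonzero(_PAIR_CLASS == cls)
        if len(sel) < 2:
            continue
        total = pair_prob[sel].sum()
        g = np.unravel_index(cls, (3, 3, 3))
        label = "".join(str(x + 1) for x in g)
        if total > 0:
            w = pair_prob[sel] / total
        else:
            w = np.full(len(sel), 1.0 / len(sel))
        out[label] = {
            (HAPLOTYPE_LABELS[_PAIR_A[k]], HAPLOTYPE_LABELS[_PAIR_B[k]]): float(wk)
            for k, wk in zip(sel, w)
        }
    return out


def em_fit(
    counts: GenotypeTripletCounts,
    init: HaplotypeFrequencies | None = None,
    tol: float = 1e-8,
    max_iter: int = 10000,
) -> EMFit:
    """EM estimation of the 8 haplotype frequencies from genotype counts.

    Parameters
    ----------
    counts
        Complete-case joint-genotype counts; must not be all zero.
    init
        Starting haplotype frequencies (default: uniform 1/8).  Different
        starts can reach different fixed points for pathological tables;
        run restarts and keep the best log-likelihood if in doubt.
    tol
        Convergence threshold on the maximum absolute change of any
        haplotype frequency between iterations.
    max_iter
        Iteration cap; if reached, the last state is returned with
        ``converged=False``.
    """
    n_flat = counts.counts.reshape(27)
    n_total = n_flat.sum()
    if n_total <= 0:
        raise ValueError("em_fit requires at least one observed individual")
    f = (init or HaplotypeFrequencies.uniform()).to_flat()

    trace: list[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        pair_prob = _PAIR_MULT * f[_PAIR_A] * f[_PAIR_B]
        phi = np.zeros(27)
        np.add.at(phi, _PAIR_CLASS, pair_prob)

        # guard: observed class with zero probability under the current
        # frequencies -> split its count equally across compatible pairs so
        # the iteration cannot get stuck in an absorbing state
        dead = (phi <= 0.0) & (n_flat > 0)
        if np.any(dead):
            fix = dead[_PAIR_CLASS]
            pair_prob = np.where(fix, 1.0, pair_prob)
            phi = np.zeros(27)
            np.add.at(phi, _PAIR_CLASS, pair_prob)

        obs = n_flat > 0
        trace.append(float(np.sum(n_flat[obs] * np.log(phi[obs]))))

        with np.errstate(invalid="ignore", divide="ignore"):
            post = np.where(
                phi[_PAIR_CLASS] > 0,
                n_flat[_PAIR_CLASS] * pair_prob / phi[_PAIR_CLASS],
                0.0,
            )
        hap_count = np.zeros(8)
        np.add.at(hap_count, _PAIR_A, post)
        np.add.at(hap_count, _PAIR_B, post)
        f_new = hap_count / (2.0 * n_total)

        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if delta < tol:
            converged = True
            break

    h = HaplotypeFrequencies(f.reshape(2, 2, 2))
    return EMFit(
        haplotypes=h,
        loglik=loglikelihood(h, counts),
        iterations=iterations,
        converged=converged,
        loglik_trace=np.array(trace),
        weights=_final_weights(f),
    )


def allele_frequencies(counts: GenotypeTripletCounts) -> tuple[float, float, float]:
    """Observed frequency of allele "1" at each locus (gamete counting)."""
    n2 = 2.0 * counts.counts.sum()
    freqs = []
    for axis in range(3):
        marg = counts.counts.sum(axis=tuple(i for i in range(3) if i != axis))
        freqs.append((2.0 * marg[0] + marg[2]) / n2)
    return tuple(freqs)


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test of the full haplotype model vs independence."""

    statistic: float
    df: int
    #: nominal p-value from the chi-square reference; the df=4 reference
    #: (7 free parameters vs 3 allele frequencies) is an asymptotic
    #: approximation, not an exact small-sample distribution
    pvalue: float
    fit: EMFit = field(repr=False, default=None)


def lrt_full_vs_allele_only(
    counts: GenotypeTripletCounts,
    tol: float = 1e-8,
    max_iter: int = 10000,
) -> LRTResult:
    """Full model (7 free parameters) against allele frequencies only (3).

    The null haplotype frequencies are the product of the observed allele
    frequencies (complete linkage equilibrium); the alternative is the EM
    optimum.  The statistic is ``2 (loglik_full - loglik_null)`` referred
    to chi-square with 4 degrees of freedom.
    """
    fit = em_fit(counts, tol=tol, max_iter=max_iter)
    p1, p2, p3 = allele_frequencies(counts)
    null = HaplotypeFrequencies(
        np.einsum(
            "i,j,k->ijk",
            np.array([p1, 1 - p1]),
            np.array([p2, 1 - p2]),
            np.array([p3, 1 - p3]),
        )
    )
    ll0 = loglikelihood(null, counts)
    stat = 2.0 * (fit.loglik - ll0)
    if stat < 0 and stat > -1e-8:  # numerical round-off at the null
        stat = 0.0
    return LRTResult(
        statistic=float(stat),
        df=4,
        pvalue=float(stats.chi2.sf(stat, df=4)),
        fit=fit,
    )


# ---------------------------------------------------------------------------
# plain-text count tables


def read_counts_tsv(path) -> GenotypeTripletCounts:
    """Read a count table, one line per class: ``g1 g2 g3 count`` (codes 1-3).

    Absent classes default to zero; repeated classes accumulate.
    """
    arr = np.zeros((3, 3, 3))
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 'g1 g2 g3 count'")
            g = [int(p) for p in parts[:3]]
            if any(x not in (1, 2, 3) for x in g):
                raise ValueError(f"{path}:{lineno}: genotype codes must be 1, 2 or 3")
            arr[g[0] - 1, g[1] - 1, g[2] - 1] += float(parts[3])
    return GenotypeTripletCounts(arr)


def write_counts_tsv(path, counts: GenotypeTripletCounts) -> None:
    with open(path, "w") as fh:
        fh.write("# g1 g2 g3 count\n")
        for g1 in range(3):
            for g2 in range(3):
                for g3 in range(3):
                    c = counts.counts[g1, g2, g3]
                    if c:
                        fh.write(f"{g1 + 1}\t{g2 + 1}\t{g3 + 1}\t{int(c)}\n")
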