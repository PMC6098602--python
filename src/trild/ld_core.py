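"""Canonical parameterization of a three-biallelic-locus system.

A system of three biallelic loci carries 8 gamete (haplotype) frequencies,
equivalently parameterized by three allele frequencies, three pairwise
linkage-disequilibrium coefficients and one third-order coefficient.  This
module converts between the two parameterizations, computes the admissible
range of the third-order coefficient given the lower-order parameters, and
provides normalization/summary statistics.

Conventions
-----------
Loci are numbered 1, 2, 3.  Allele index 0 refers to allele "1" (the
first-listed allele of the input data: A1 in .ped files, REF in VCF) and
index 1 to allele "2".  All disequilibrium coefficients are defined with
respect to allele "1"; relabeling the alleles at one locus flips the sign
of the third-order coefficient and of the two pairwise coefficients that
involve that locus.  Haplotype tensors have shape (2, 2, 2) with axis order
locus 1, 2, 3.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "SIMPLEX_TOL",
    "HAPLOTYPE_LABELS",
    "InvalidDecompositionError",
    "InfeasiblePairwiseSystemError",
    "LDDecomposition",
    "HaplotypeFrequencies",
    "Delta3Bounds",
    "NormCategory",
    "NormalizationResult",
    "params_to_haplotypes",
    "haplotypes_to_params",
    "delta3_bounds",
    "normalize_robinson",
    "beta_proportion",
    "count_segregating_haplotypes",
    "read_decompositions",
    "write_decompositions",
    "read_haplotype_frequencies",
    "write_haplotype_frequencies",
]

#: tolerance for simplex validity checks (non-negativity, sum to one)
SIMPLEX_TOL = 1e-9

#: haplotype labels in lexicographic allele order, "1" = first-listed allele
HAPLOTYPE_LABELS = ("111", "112", "121", "122", "211", "212", "221", "222")

_ALLELE_INDEX_TRIPLES = tuple(itertools.product((0, 1), repeat=3))


class InvalidDecompositionError(ValueError):
    """Parameter set implies a haplotype frequency outside [0, 1]."""


class InfeasiblePairwiseSystemError(ValueError):
    """No value of the third-order coefficient yields valid frequencies."""


@dataclass(frozen=True)
class LDDecomposition:
    """Allele frequencies plus pairwise and third-order LD coefficients.

    ``f1, f2, f3`` are the frequencies of allele "1" at each locus;
    ``d12, d13, d23`` the pairwise coefficients (two-locus haplotype
    frequency minus the product of allele frequencies); ``d123`` the
    third-order coefficient.
    """

    f1: float
    f2: float
    f3: float
    d12: float
    d13: float
    d23: float
    d123: float

    def as_tuple(self) -> tuple[float, ...]:
        return (self.f1, self.f2, self.f3, self.d12, self.d13, self.d23, self.d123)

    def validate(self) -> None:
        """Raise :class:`InvalidDecompositionError` if invalid."""
        params_to_haplotypes(self)


@dataclass(frozen=True)
class HaplotypeFrequencies:
    """The 8 three-locus haplotype frequencies as a (2, 2, 2) tensor."""

    freq: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.freq, dtype=float)
        if arr.shape != (2, 2, 2):
            raise ValueError(f"haplotype tensor must have shape (2, 2, 2), got {arr.shape}")
        if arr.min() < -SIMPLEX_TOL:
            raise ValueError(f"negative haplotype frequency {arr.min():g}")
        total = arr.sum()
        if abs(total - 1.0) > SIMPLEX_TOL:
            raise ValueError(f"haplotype frequencies sum to {total:.12g}, not 1")
        object.__setattr__(self, "freq", arr)

    @classmethod
    def from_flat(cls, values) -> "HaplotypeFrequencies":
        """Build from 8 values in lexicographic label order (111 .. 222)."""
        return cls(np.asarray(values, dtype=float).reshape(2, 2, 2))

    @classmethod
    def uniform(cls) -> "HaplotypeFrequencies":
        return cls(np.full((2, 2, 2), 0.125))

    @classmethod
    def from_labels(cls, mapping: dict[str, float]) -> "HaplotypeFrequencies":
        """Build from a ``{"111": freq, ...}`` mapping; absent labels are 0."""
        arr = np.zeros((2, 2, 2))
        for label, value in mapping.items():
            if label not in HAPLOTYPE_LABELS:
                raise ValueError(f"unknown haplotype label {label!r}")
            a, b, c = (int(ch) - 1 for ch in label)
            arr[a, b, c] = value
        return cls(arr)

    def to_flat(self) -> np.ndarray:
        return self.freq.reshape(8).copy()

    def as_dict(self) -> dict[str, float]:
        return dict(zip(HAPLOTYPE_LABELS, self.to_flat()))


@dataclass(frozen=True)
class Delta3Bounds:
    """Admissible extremes of the third-order coefficient.

    Given fixed allele frequencies and pairwise coefficients, every
    haplotype frequency is affine in the third-order coefficient with slope
    +1 or -1, so the admissible range is a closed interval and at either
    endpoint at least one haplotype frequency is exactly zero.
    """

    lower: float
    upper: float

    @property
    def width(self) -> float:
        return self.upper - self.lower


class NormCategory(str, Enum):
    """Outcome classes of range-based normalization."""

    UNDEFINED_SINGLE_VALUE = "undefined_single_value"
    ZERO = "zero"
    PLUS_ONE = "plus_one"
    MINUS_ONE = "minus_one"
    INTERIOR = "interior"


@dataclass(frozen=True)
class NormalizationResult:
    """Range-normalized third-order LD plus the third-order proportion beta."""

    category: NormCategory
    value: float
    beta: float


def _affine_parts(
    f1: float, f2: float, f3: float, d12: float, d13: float, d23: float
) -> tuple[np.ndarray, np.ndarray]:
    """Constant part and third-order sign of each haplotype frequency.

    freq[a,b,c] = const[a,b,c] + sign[a,b,c] * d123, with sign = s1*s2*s3
    where s = +1 for allele index 0 and -1 for index 1.
    """
    const = np.empty((2, 2, 2))
    sign = np.empty((2, 2, 2))
    p = ((f1, 1.0 - f1), (f2, 1.0 - f2), (f3, 1.0 - f3))
    for a, b, c in _ALLELE_INDEX_TRIPLES:
        s1, s2, s3 = 1 - 2 * a, 1 - 2 * b, 1 - 2 * c
        const[a, b, c] = (
            p[0][a] * p[1][b] * p[2][c]
            + p[0][a] * (s2 * s3) * d23
            + p[1][b] * (s1 * s3) * d13
            + p[2][c] * (s1 * s2) * d12
        )
        sign[a, b, c] = s1 * s2 * s3
    return const, sign


def _tensor_from_params(d: LDDecomposition) -> np.ndarray:
    """Raw (2, 2, 2) frequency tensor implied by ``d``, no range checks."""
    const, sign = _affine_parts(d.f1, d.f2, d.f3, d.d12, d.d13, d.d23)
    return const + sign * d.d123


def _params_from_tensor(t: np.ndarray) -> LDDecomposition:
    """Decomposition of a raw tensor (marginals + residuals), no checks."""
    f1 = t[0].sum()
    f2 = t[:, 0].sum()
    f3 = t[:, :, 0].sum()
    d12 = t[0, 0].sum() - f1 * f2
    d13 = t[0, :, 0].sum() - f1 * f3
    d23 = t[:, 0, 0].sum() - f2 * f3
    d123 = t[0, 0, 0] - f1 * f2 * f3 - f1 * d23 - f2 * d13 - f3 * d12
    return LDDecomposition(f1, f2, f3, d12, d13, d23, d123)


def params_to_haplotypes(d: LDDecomposition) -> HaplotypeFrequencies:
    """Haplotype frequencies implied by a parameter decomposition.

    Raises
    ------
    InvalidDecompositionError
        If any implied frequency lies outside [0, 1] beyond 1e-12; the
        message names the offending haplotype.
    """
    freq = _tensor_from_params(d)
    flat = freq.reshape(8)
    for label, value in zip(HAPLOTYPE_LABELS, flat):
        if value < -1e-12 or value > 1.0 + 1e-12:
            raise InvalidDecompositionError(
                f"decomposition implies frequency {value:.6g} for haplotype {label}"
            )
    return HaplotypeFrequencies(np.clip(freq, 0.0, 1.0))


def haplotypes_to_params(h: HaplotypeFrequencies) -> LDDecomposition:
    """Invert :func:`params_to_haplotypes`: marginals and LD coefficients.

    Allele frequencies are marginal sums; each pairwise coefficient is the
    two-locus "11" haplotype frequency minus the product of the two allele
    frequencies; the third-order coefficient is the residual of the 111
    haplotype frequency after removing all lower-order terms.
    """
    return _params_from_tensor(h.freq)


def delta3_bounds(
    f1: float,
    f2: float,
    f3: float,
    d12: float,
    d13: float,
    d23: float,
) -> Delta3Bounds:
    """Exact admissible range of the third-order coefficient.

    Each haplotype frequency is affine in the third-order coefficient with
    slope +1 or -1; non-negativity of the four +1 haplotypes gives the
    lower bound, of the four -1 haplotypes the upper bound.

    Raises
    ------
    InfeasiblePairwiseSystemError
        If no value of the coefficient makes all 8 frequencies >= 0.
    """
    const, sign = _affine_parts(f1, f2, f3, d12, d13, d23)
    lower = float((-const[sign > 0]).max())
    upper = float(const[sign < 0].min())
    if lower > upper + 1e-12:
        raise InfeasiblePairwiseSystemError(
            f"infeasible pairwise system: lower bound {lower:.6g} exceeds upper {upper:.6g}"
        )
    return Delta3Bounds(lower, upper)


def beta_proportion(d: LDDecomposition) -> float:
    """Proportion of third-order LD among all LD coefficients.

    ``|d123| / (|d123| + |d12| + |d13| + |d23|)``, in [0, 1]; 1 means all
    disequilibrium is third order, 0 that it is all pairwise.  Returns NaN
    when all four coefficients are zero (within 1e-12), where the
    proportion is undefined.
    """
    denom = abs(d.d123) + abs(d.d12) + abs(d.d13) + abs(d.d23)
    if denom < 1e-12:
        return math.nan
    return abs(d.d123) / denom


def normalize_robinson(d: LDDecomposition, tol: float = 1e-9) -> NormalizationResult:
    """Range-based normalization of the third-order coefficient.

    The observed coefficient is rescaled by the admissible range of its
    sign: the amount by which it exceeds the minimum possible value of that
    sign, divided by the length of the admissible range of that sign.

    Categories:

    * ``undefined_single_value`` — the full admissible range (or the range
      of the observed sign) has width < ``tol``: the coefficient can take
      only one value given the lower-order parameters, so normalization
      carries no information.
    * ``zero`` — observed coefficient is 0 within ``tol``.
    * ``plus_one`` / ``minus_one`` — normalized value within ``tol`` of ±1.
    * ``interior`` — anything else; ``value`` in (-1, 1).
    """
    bounds = delta3_bounds(d.f1, d.f2, d.f3, d.d12, d.d13, d.d23)
    beta = beta_proportion(d)
    if bounds.width < tol:
        return NormalizationResult(NormCategory.UNDEFINED_SINGLE_VALUE, math.nan, beta)
    if abs(d.d123) < tol:
        return NormalizationResult(NormCategory.ZERO, 0.0, beta)
    if d.d123 > 0:
        lo = max(0.0, bounds.lower)
        width = bounds.upper - lo
        if width < tol:
            # the observed sign admits a single value only
            return NormalizationResult(NormCategory.UNDEFINED_SINGLE_VALUE, math.nan, beta)
        value = (d.d123 - lo) / width
        if abs(value - 1.0) < tol:
            return NormalizationResult(NormCategory.PLUS_ONE, 1.0, beta)
    else:
        hi = min(0.0, bounds.upper)
        width = hi - bounds.lower
        if width < tol:
            return NormalizationResult(NormCategory.UNDEFINED_SINGLE_VALUE, math.nan, beta)
        value = (d.d123 - hi) / width
        if abs(value + 1.0) < tol:
            return NormalizationResult(NormCategory.MINUS_ONE, -1.0, beta)
    return NormalizationResult(NormCategory.INTERIOR, float(value), beta)


def count_segregating_haplotypes(h: HaplotypeFrequencies, tol: float = 1e-9) -> int:
    """Number of haplotypes with frequency above ``tol``."""
    return int((h.freq > tol).sum())


# ---------------------------------------------------------------------------
# plain-text parameter files


def read_decompositions(path) -> list[LDDecomposition]:
    """Read decompositions, one per line: ``f1 f2 f3 d12 d13 d23 d123``.

    Blank lines and lines starting with ``#`` are skipped.
    """
    out: list[LDDecomposition] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 fields, got {len(parts)}")
            out.append(LDDecomposition(*(float(x) for x in parts)))
    return out


def write_decompositions(path, decs) -> None:
    with open(path, "w") as fh:
        fh.write("# f1 f2 f3 d12 d13 d23 d123\n")
        for d in decs:
            fh.write(" ".join(f"{x:.12g}" for x in d.as_tuple()) + "\n")


def read_haplotype_frequencies(path) -> HaplotypeFrequencies:
    """Read 8 labeled haplotype frequencies (lines ``<label> <freq>``)."""
    mapping: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected '<label> <freq>'")
            mapping[parts[0]] = float(parts[1])
    missing = set(HAPLOTYPE_LABELS) - set(mapping)
    if missing:
        raise ValueError(f"{path}: missing haplotype labels {sorted(missing)}")
    return HaplotypeFrequencies.from_labels(mapping)


def write_haplotype_frequencies(path, h: HaplotypeFrequencies) -> None:
    with open(path, "w") as fh:
        for label, value in h.as_dict().items():
            fh.write(f"{label} {value:.12g}\n")
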