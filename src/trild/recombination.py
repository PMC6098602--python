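"""Deterministic break-up of three-locus LD by recombination.

One-generation recursion of the 8 haplotype frequencies under random
mating without crossover interference, and multi-generation trajectories
of the derived LD parameters.  The recursion is for an infinite
population: allele frequencies are exactly conserved and all LD
coefficients decay towards linkage equilibrium.  In the symmetric case
(zero pairwise LD throughout) the third-order coefficient declines
geometrically with per-generation factor ``(1-c12)(1-c23)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ld_core import (
    HAPLOTYPE_LABELS,
    HaplotypeFrequencies,
    LDDecomposition,
    haplotypes_to_params,
)

__all__ = ["RecombinationRates", "Trajectory", "next_generation", "trajectory"]


@dataclass(frozen=True)
class RecombinationRates:
    """Recombination fractions between loci 1-2 and 2-3, each in [0, 0.5]."""

    c12: float
    c23: float

    def __post_init__(self) -> None:
        for name, c in (("c12", self.c12), ("c23", self.c23)):
            if not 0.0 <= c <= 0.5:
                raise ValueError(f"{name} must be in [0, 0.5], got {c}")


def next_generation(h: HaplotypeFrequencies, r: RecombinationRates) -> HaplotypeFrequencies:
    """Haplotype frequencies after one generation of random mating.

    A gamete keeps its parental three-locus haplotype with probability
    ``(1-c12)(1-c23)``; with probability ``c12(1-c23)`` it combines a random
    allele at locus 1 with a random two-locus haplotype at loci 2-3; with
    ``c23(1-c12)`` a random 1-2 haplotype with a random allele at locus 3;
    and with ``c12 c23`` three independent random alleles.  No interference:
    the two intervals recombine independently.  Allele-frequency marginals
    are conserved exactly.
    """
    t = h.freq
    c12, c23 = r.c12, r.c23
    m1 = t.sum(axis=(1, 2))  # allele marginal, locus 1
    m2 = t.sum(axis=(0, 2))
    m3 = t.sum(axis=(0, 1))
    h23 = t.sum(axis=0)  # two-locus haplotype marginal, loci 2-3
    h12 = t.sum(axis=2)
    new = (
        (1 - c12) * (1 - c23) * t
        + c12 * (1 - c23) * np.einsum("i,jk->ijk", m1, h23)
        + c23 * (1 - c12) * np.einsum("ij,k->ijk", h12, m3)
        + c12 * c23 * np.einsum("i,j,k->ijk", m1, m2, m3)
    )
    # renormalize: the recursion is polynomial in the tensor, so a simplex
    # round-off of eps would otherwise be amplified geometrically over t
    new /= new.sum()
    return HaplotypeFrequencies(new)


@dataclass
class Trajectory:
    """Per-generation haplotype frequencies and derived LD parameters."""

    rates: RecombinationRates
    haplotypes: list[HaplotypeFrequencies] = field(default_factory=list)

    @property
    def generations(self) -> int:
        """Largest generation index (length of the trajectory minus one)."""
        return len(self.haplotypes) - 1

    @property
    def decompositions(self) -> list[LDDecomposition]:
        return [haplotypes_to_params(h) for h in self.haplotypes]

    def d123(self) -> np.ndarray:
        """Third-order coefficient at each generation."""
        return np.array([d.d123 for d in self.decompositions])

    def to_frame(self) -> pd.DataFrame:
        """One row per generation: 8 frequencies plus the 7 parameters."""
        rows = []
        for t, h in enumerate(self.haplotypes):
            row: dict[str, float] = {"t": t}
            row.update({f"h{lab}": v for lab, v in h.as_dict().items()})
            d = haplotypes_to_params(h)
            row.update(
                f1=d.f1, f2=d.f2, f3=d.f3, d12=d.d12, d13=d.d13, d23=d.d23, d123=d.d123
            )
            rows.append(row)
        frame = pd.DataFrame(rows)
        frame["t"] = frame["t"].astype(int)
        return frame


def trajectory(
    h0: HaplotypeFrequencies, r: RecombinationRates, generations: int
) -> Trajectory:
    """Iterate :func:`next_generation` for ``generations`` steps.

    The returned trajectory includes generation 0 (the start state), so it
    holds ``generations + 1`` records.
    """
    if generations < 0:
        raise ValueError("generations must be >= 0")
    traj = Trajectory(rates=r, haplotypes=[h0])
    h = h0
    for _ in range(generations):
        h = next_generation(h, r)
        traj.haplotypes.append(h)
    return traj
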