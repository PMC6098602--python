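"""Third-order LD generated by crossing two populations.

Pooling gametes from two populations that differ in allele frequencies and
in pairwise LD creates third-order LD in the cross, even when neither
parent population carries any.  Two equivalent routes are provided: a
closed-form expression in the parent parameters, and mixing the 8 parent
haplotype frequencies followed by re-decomposition.  The haplotype route
is the independent oracle for the closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .ld_core import (
    LDDecomposition,
    _params_from_tensor,
    _tensor_from_params,
)

__all__ = [
    "AdmixtureScenario",
    "admix_closed_form",
    "admix_via_haplotypes",
    "reproduce_reference_scenarios",
    "REFERENCE_SCENARIOS",
]


@dataclass(frozen=True)
class AdmixtureScenario:
    """Two parent populations and the mixing proportion of the first.

    With ``strict=True`` (the default) both parent decompositions must
    imply valid haplotype frequencies.  ``strict=False`` admits formally
    infeasible parents: both mixing routes are pure algebra and still agree
    exactly, which matters because some conventional reference scenarios
    pair two perfect pairwise couplings with a zero third coupling — a
    combination no real gamete pool can realize.
    """

    pop_x: LDDecomposition
    pop_y: LDDecomposition
    tau: float
    strict: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError(f"tau must be in [0, 1], got {self.tau}")
        if self.strict:
            # raises InvalidDecompositionError on an invalid parent
            self.pop_x.validate()
            self.pop_y.validate()


def admix_closed_form(s: AdmixtureScenario) -> LDDecomposition:
    """Decomposition of the cross, computed directly from parent parameters.

    Allele frequencies mix linearly.  Each pairwise coefficient mixes
    linearly plus the classical admixture term ``tau (1-tau) g g'`` in the
    parent allele-frequency differences ``g``.  The third-order coefficient
    is the 111-haplotype frequency of the cross minus all its lower-order
    terms, expanded in parent parameters.
    """
    x, y, t = s.pop_x, s.pop_y, s.tau
    u = 1.0 - t

    fz1 = t * x.f1 + u * y.f1
    fz2 = t * x.f2 + u * y.f2
    fz3 = t * x.f3 + u * y.f3

    g1 = x.f1 - y.f1
    g2 = x.f2 - y.f2
    g3 = x.f3 - y.f3

    dz23 = t * x.d23 + u * y.d23 + t * u * g2 * g3
    dz13 = t * x.d13 + u * y.d13 + t * u * g1 * g3
    dz12 = t * x.d12 + u * y.d12 + t * u * g1 * g2

    dz123 = (
        t * x.f1 * x.f2 * x.f3
        + t * x.f1 * x.d23
        + t * x.f2 * x.d13
        + t * x.f3 * x.d12
        + t * x.d123
        + u * y.f1 * y.f2 * y.f3
        + u * y.f1 * y.d23
        + u * y.f2 * y.d13
        + u * y.f3 * y.d12
        + u * y.d123
        - fz1 * fz2 * fz3
        - fz1 * dz23
        - fz2 * dz13
        - fz3 * dz12
    )
    return LDDecomposition(fz1, fz2, fz3, dz12, dz13, dz23, dz123)


def admix_via_haplotypes(s: AdmixtureScenario) -> LDDecomposition:
    """Decomposition of the cross via linear mixing of haplotype frequencies.

    Gamete pools mix linearly, so the 8 haplotype frequencies of the cross
    are ``tau hX + (1-tau) hY``; the result is re-decomposed.  Agrees with
    :func:`admix_closed_form` to floating-point precision.  The tensor
    arithmetic is done unchecked so that non-strict scenarios remain
    comparable between the two routes.
    """
    hx = _tensor_from_params(s.pop_x)
    hy = _tensor_from_params(s.pop_y)
    return _params_from_tensor(s.tau * hx + (1.0 - s.tau) * hy)


def _scenario(fx, fy, dx, dy=(0.0, 0.0, 0.0)) -> AdmixtureScenario:
    # dx/dy order: (d23, d13, d12); non-strict because two of the nine
    # conventional scenarios pair infeasible pairwise couplings
    x = LDDecomposition(*fx, d12=dx[2], d13=dx[1], d23=dx[0], d123=0.0)
    y = LDDecomposition(*fy, d12=dy[2], d13=dy[1], d23=dy[0], d123=0.0)
    return AdmixtureScenario(x, y, tau=0.5, strict=False)


#: nine reference crosses (tau = 0.5, parents without third-order LD)
REFERENCE_SCENARIOS: tuple[AdmixtureScenario, ...] = (
    _scenario((0.8, 0.8, 0.8), (0.2, 0.2, 0.2), (0.0, 0.0, 0.0)),
    _scenario((0.8, 0.2, 0.8), (0.2, 0.8, 0.2), (0.0, 0.0, 0.0)),
    _scenario((0.5, 0.5, 0.5), (0.5, 0.5, 0.5), (0.25, 0.25, 0.25)),
    _scenario((0.5, 0.5, 0.5), (0.5, 0.5, 0.5), (0.25, 0.25, 0.0)),
    _scenario((0.5, 0.5, 0.5), (0.5, 0.5, 0.5), (0.25, 0.0, 0.0)),
    _scenario((0.5, 0.5, 0.5), (0.2, 0.2, 0.2), (0.25, 0.25, 0.25)),
    _scenario((0.5, 0.5, 0.5), (0.2, 0.2, 0.2), (0.25, 0.25, 0.0)),
    _scenario((0.5, 0.5, 0.5), (0.1, 0.1, 0.1), (0.25, 0.25, 0.25)),
    _scenario((0.5, 0.5, 0.5), (0.01, 0.01, 0.01), (0.25, 0.25, 0.25)),
)


def reproduce_reference_scenarios() -> pd.DataFrame:
    """Third-order LD generated in the nine reference crosses.

    Returns one row per scenario with the parent inputs, the full-precision
    third-order coefficient of the cross and its value rounded to 3
    decimals (the conventional display precision).
    """
    rows = []
    for s in REFERENCE_SCENARIOS:
        z = admix_closed_form(s)
        rows.append(
            {
                "f1_x": s.pop_x.f1,
                "f2_x": s.pop_x.f2,
                "f3_x": s.pop_x.f3,
                "f1_y": s.pop_y.f1,
                "f2_y": s.pop_y.f2,
                "f3_y": s.pop_y.f3,
                "d23_x": s.pop_x.d23,
                "d13_x": s.pop_x.d13,
                "d12_x": s.pop_x.d12,
                "d23_y": s.pop_y.d23,
                "d13_y": s.pop_y.d13,
                "d12_y": s.pop_y.d12,
                "tau": s.tau,
                "d123_z": z.d123,
                "d123_z_rounded": round(z.d123, 3),
            }
        )
    return pd.DataFrame(rows)
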