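"""Linear-quadratic isoeffect conversion between fractionation schemes.

The LQ biologically effective dose of a total dose D delivered in n
fractions of d = D/n is

    BED = D * (1 + d / (alpha/beta))

Equating BEDs between schemes gives the closed-form rescale: the target
per-fraction dose solves d2^2/ab + d2 - BED/n2 = 0, whose positive root is

    d2 = ab/2 * (sqrt(1 + 4*BED/(n2*ab)) - 1)

The alpha/beta ratio is a required explicit parameter throughout: a value
of 2 Gy (RBE) is the conventional choice for late-responding central
nervous system tissue, but nothing here applies a default silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError


@dataclass(frozen=True)
class LQParams:
    """Tissue LQ parameter: the alpha/beta ratio in Gy (RBE)."""

    alpha_beta: float

    def __post_init__(self) -> None:
        if not (self.alpha_beta > 0 and math.isfinite(self.alpha_beta)):
            raise DomainError(f"alpha/beta must be positive and finite, got {self.alpha_beta}")


#: Conventional late-CNS alpha/beta, Gy (RBE) — documentation value, never applied implicitly.
LATE_CNS_ALPHA_BETA = 2.0


def bed(total_dose: float, n_fractions: int, lq: LQParams) -> float:
    """Biologically effective dose D * (1 + (D/n) / (alpha/beta)), Gy (RBE)."""
    if total_dose < 0:
        raise DomainError(f"total_dose must be >= 0, got {total_dose}")
    if n_fractions < 1:
        raise DomainError(f"n_fractions must be >= 1, got {n_fractions}")
    d = total_dose / n_fractions
    return total_dose * (1.0 + d / lq.alpha_beta)


def lq_rescale_total_dose(
    total_dose: float, n_from: int, n_to: int, lq: LQParams
) -> float:
    """Isoeffective total dose when moving from ``n_from`` to ``n_to`` fractions.

    Returns the unique non-negative D2 with ``bed(D2, n_to) == bed(total_dose,
    n_from)``, via the closed-form positive root of the per-fraction quadratic.
    """
    if total_dose < 0:
        raise DomainError(f"total_dose must be >= 0, got {total_dose}")
    if n_from < 1 or n_to < 1:
        raise DomainError("fraction counts must be >= 1")
    if total_dose == 0:
        return 0.0
    if n_from == n_to:
        return float(total_dose)
    target_bed = bed(total_dose, n_from, lq)
    ab = lq.alpha_beta
    d2 = 0.5 * ab * (math.sqrt(1.0 + 4.0 * target_bed / (n_to * ab)) - 1.0)
    return d2 * n_to
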