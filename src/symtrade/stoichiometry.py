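"""Organism-level stoichiometric types and the Liebig-minimum fitness.

An organism is described by two fitness coefficients ``k_N`` and ``k_C``
(fitness per unit N and C uptake) and an ATP budget per unit time.  The
fitness of an uptake bundle (x_N, x_C) is Liebig's law of the minimum,

    f = min(k_N * x_N, k_C * x_C),

so growth is limited by whichever element is scarcest relative to the
body's demand.  The ratio c = k_N / k_C is the slope of the *optimality
line* x_C = c * x_N on which both limbs of the minimum are equal; under
the model's assumptions c equals the organism's body molar C:N ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class StoichiometricProfile:
    """Fitness coefficients and ATP budget of one organism.

    Parameters
    ----------
    k_N, k_C
        Fitness gained per unit uptake of N and C respectively
        (dimensionless rates, > 0).  Only the ratio ``k_N / k_C``
        matters for allocations; absolute magnitudes set the (arbitrary)
        fitness unit used in welfare comparisons.
    budget_b
        ATP available per unit time (mol ATP / time, > 0).
    label
        Free-text organism name.
    """

    k_N: float
    k_C: float
    budget_b: float
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("k_N", "k_C", "budget_b"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")

    @classmethod
    def from_cn_ratio(
        cls, c: float, budget_b: float, label: str = "", k_C: float = 1.0
    ) -> "StoichiometricProfile":
        """Build a profile from a body C:N ratio ``c`` with ``k_C`` normalized.

        The body C:N ratio determines only the ratio of the fitness
        coefficients (C:N = 1/k_C : 1/k_N, hence k_N = c * k_C); absolute
        fitness values are then in arbitrary units.
        """
        if not (math.isfinite(c) and c > 0):
            raise ValueError(f"body C:N ratio must be finite and > 0, got {c!r}")
        return cls(k_N=c * k_C, k_C=k_C, budget_b=budget_b, label=label)


@dataclass(frozen=True)
class Uptake:
    """An uptake bundle: mol N and mol C acquired per unit time (>= 0)."""

    x_N: float
    x_C: float

    def __post_init__(self) -> None:
        if self.x_N < 0 or self.x_C < 0:
            raise ValueError(f"uptake components must be >= 0, got ({self.x_N}, {self.x_C})")


def optimality_slope(profile: StoichiometricProfile) -> float:
    """Slope ``c = k_N / k_C`` of the optimality line; equals body C:N."""
    return profile.k_N / profile.k_C


def fitness(uptake: Uptake, profile: StoichiometricProfile) -> float:
    """Liebig-minimum fitness ``min(k_N * x_N, k_C * x_C)``."""
    return min(profile.k_N * uptake.x_N, profile.k_C * uptake.x_C)
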