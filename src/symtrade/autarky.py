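"""Non-symbiotic (autarky) uptake: fitness maximization on a budget line.

An organism living alone spends its whole ATP budget on acquiring N and
C at fixed per-mol costs, ``a_N x_N + a_C x_C = b``.  With a Liebig
fitness function the optimum is the intersection of this budget line
with the optimality line ``x_C = c x_N``; any other point on the budget
line wastes budget on the non-limiting element.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .stoichiometry import StoichiometricProfile, Uptake, fitness, optimality_slope


@dataclass(frozen=True)
class BudgetLine:
    """ATP budget constraint ``a_N x_N + a_C x_C = b`` (slope -a_N/a_C)."""

    a_N: float
    a_C: float
    b: float

    def __post_init__(self) -> None:
        for name in ("a_N", "a_C", "b"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")

    def cost_ratio(self) -> float:
        """Cost of N in units of C (the absolute slope of the line)."""
        return self.a_N / self.a_C


def autarky_point(line: BudgetLine, profile: StoichiometricProfile) -> Uptake:
    """The fitness-maximizing uptake bundle on a budget line.

    Closed form: substituting the optimality line ``x_C = c x_N`` into the
    budget equation gives ``x_N = b / (a_N + a_C c)``.
    """
    c = optimality_slope(profile)
    x_N = line.b / (line.a_N + line.a_C * c)
    return Uptake(x_N=x_N, x_C=c * x_N)


def autarky_fitness(line: BudgetLine, profile: StoichiometricProfile) -> float:
    """Fitness achieved at the autarky point."""
    return fitness(autarky_point(line, profile), profile)


def specialization_point(line: BudgetLine, element: str) -> Uptake:
    """Budget-line axis intercept: spend the whole budget on one element.

    ``element="C"`` returns (0, b/a_C); ``element="N"`` returns (b/a_N, 0).
    For symbiotic Rhizobium the N intercept is taken with the fixation
    cost in place of the direct-uptake cost.
    """
    if element == "C":
        return Uptake(x_N=0.0, x_C=line.b / line.a_C)
    if element == "N":
        return Uptake(x_N=line.b / line.a_N, x_C=0.0)
    raise ValueError(f"element must be 'C' or 'N', got {element!r}")
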