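"""ATP cost bookkeeping: from metabolic step ledgers to per-element costs.

The energetic currency of the model is ATP.  Every uptake (or fixation)
pathway is written as a *ledger* of steps, each consuming some ATP
directly and some reductant molecules that are valued in ATP
equivalents (NADPH at 3, NADH at 2.5, reduced ferredoxin at 1.5 by
default; 2 per Fd_red inside the nitrogenase reaction).  Dividing the
total ATP-equivalent spend of a ledger by the number of element atoms
delivered per basis molecule gives the per-mol-element cost ``a``
(mol ATP / mol C or N).

Basis molecules: glyceraldehyde 3-phosphate (3 C) for the legume's
photosynthetic carbon, glucose (6 C) for free-living Rhizobium's carbon,
ammonium (1 N) for all nitrogen, and N2 (2 N) for fixation.  Costs that
are only bracketed by the physiology (e.g. nitrate assimilation) are
carried as intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

from ._interval import Cost, Interval, lower, truncate, upper

#: Default ATP-equivalent value per molecule of each reductant.
#: "NAD(P)H" denotes a step whose reductant may be either NADH or NADPH,
#: valued by the interval spanned by the two.  Ferredoxin reduced inside
#: the nitrogenase reaction is conventionally valued at 2 ATP, unlike the
#: 1.5 used elsewhere, so it gets its own key.
DEFAULT_EQUIVALENTS: Dict[str, Cost] = {
    "NADPH": 3.0,
    "NADH": 2.5,
    "Fd_red": 1.5,
    "Fd_red@nitrogenase": 2.0,
    "NAD(P)H": Interval(2.5, 3.0),
}


@dataclass(frozen=True)
class LedgerStep:
    """One metabolic step: direct ATP plus reductants in ATP equivalents.

    ``atp_count`` is mol ATP per basis molecule processed; it may be an
    :class:`Interval` when the measurement only brackets the cost.
    ``reductant_counts`` pairs each reductant name with its molecule
    count; the ATP-equivalent factor is resolved against an equivalents
    table at evaluation time.
    """

    atp_count: Cost = 0.0
    reductant_counts: Tuple[Tuple[str, float], ...] = ()
    note: str = ""

    def __post_init__(self) -> None:
        if lower(self.atp_count) < 0:
            raise ValueError("atp_count must be >= 0")
        for name, count in self.reductant_counts:
            if count < 0:
                raise ValueError(f"reductant count for {name!r} must be >= 0")

    def cost(self, equivalents: Mapping[str, Cost]) -> Cost:
        total: Cost = self.atp_count
        for name, count in self.reductant_counts:
            try:
                equiv = equivalents[name]
            except KeyError:
                raise KeyError(f"no ATP-equivalent factor for reductant {name!r}") from None
            if lower(equiv) <= 0:
                raise ValueError(f"ATP equivalent for {name!r} must be > 0")
            total = total + count * equiv
        return total


@dataclass(frozen=True)
class CostLedger:
    """An ordered list of steps delivering one basis molecule of C or N."""

    steps: Tuple[LedgerStep, ...]
    atoms_per_molecule: int
    element: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.atoms_per_molecule < 1:
            raise ValueError("atoms_per_molecule must be >= 1")
        if self.element not in ("C", "N"):
            raise ValueError(f"element must be 'C' or 'N', got {self.element!r}")


def cost_per_mol_element(
    ledger: CostLedger, equivalents: Optional[Mapping[str, Cost]] = None
) -> Cost:
    """Total ATP-equivalent spend of a ledger per mol of element delivered.

    Sums ``atp + sum(count * equivalent)`` over the steps and divides by
    the atoms of the element per basis molecule.  Interval-valued inputs
    propagate by endpoint arithmetic (all coefficients are positive, so
    the endpoints are attained at the input endpoints).
    """
    table = dict(DEFAULT_EQUIVALENTS)
    if equivalents:
        table.update(equivalents)
    total: Cost = 0.0
    for step in ledger.steps:
        total = total + step.cost(table)
    return total / ledger.atoms_per_molecule


# ---------------------------------------------------------------------------
# Built-in named ledgers
# ---------------------------------------------------------------------------

#: Calvin-Benson cycle: 9 ATP + 6 NADPH per G3P (3 C).
G3P_FIXATION = CostLedger(
    steps=(LedgerStep(atp_count=9.0, reductant_counts=(("NADPH", 6.0),)),),
    atoms_per_molecule=3,
    element="C",
    name="g3p_fixation",
)

#: Nitrate route: active transport (1-3 ATP), reduction to ammonium via
#: 1 NAD(P)H + 6 Fd_red, plus 1-2 ATP for transporter synthesis and
#: plastid nitrite transport (bracketed, no precise measurement exists).
NITRATE_UPTAKE = CostLedger(
    steps=(
        LedgerStep(atp_count=Interval(1.0, 3.0), note="nitrate transporter"),
        LedgerStep(
            reductant_counts=(("NAD(P)H", 1.0), ("Fd_red", 6.0)),
            note="NO3- -> NO2- -> NH4+ reduction",
        ),
        LedgerStep(
            atp_count=Interval(1.0, 2.0),
            note="transporter synthesis and plastid NO2- transport",
        ),
    ),
    atoms_per_molecule=1,
    element="N",
    name="nitrate_uptake",
)

#: Ammonium: passive at high concentration, 1 ATP (proton pump) at low;
#: half of uptakes assumed active, hence 0.5 ATP/mol N.
AMMONIUM_UPTAKE = CostLedger(
    steps=(LedgerStep(atp_count=0.5, note="half of uptakes active at 1 ATP"),),
    atoms_per_molecule=1,
    element="N",
    name="ammonium_uptake",
)

#: Glucose via ABC transporter: 2 ATP per glucose (6 C).
GLUCOSE_ABC = CostLedger(
    steps=(LedgerStep(atp_count=2.0, note="ABC transporter"),),
    atoms_per_molecule=6,
    element="C",
    name="glucose_abc",
)

#: Nitrogenase: 16 ATP + 8 Fd_red (valued at 2 each) per N2 (2 N).
N2_FIXATION = CostLedger(
    steps=(
        LedgerStep(
            atp_count=16.0,
            reductant_counts=(("Fd_red@nitrogenase", 8.0),),
            note="nitrogenase; NH3 -> NH4+ is free",
        ),
    ),
    atoms_per_molecule=2,
    element="N",
    name="n2_fixation",
)

BUILTIN_LEDGERS: Dict[str, CostLedger] = {
    ledger.name: ledger
    for ledger in (G3P_FIXATION, NITRATE_UPTAKE, AMMONIUM_UPTAKE, GLUCOSE_ABC, N2_FIXATION)
}


# ---------------------------------------------------------------------------
# Assembled cost set
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ATPCostSet:
    """Per-element ATP uptake costs for both species and both soil states.

    Soil state ``s`` is 1 when direct N uptake is ATP-demanding (nitrate-
    dominated aerobic soil) and 0 when it is cheap (ammonium available).
    ``a_RN_hat`` is the cost of N acquisition by fixation, which replaces
    direct uptake once the symbiosis is established.
    """

    a_LC: float
    a_LN: Mapping[int, Cost]
    a_RC: Mapping[int, Cost]
    a_RN: Mapping[int, Cost]
    a_RN_hat: float

    def __post_init__(self) -> None:
        if self.a_LC <= 0 or self.a_RN_hat <= 0:
            raise ValueError("a_LC and a_RN_hat must be > 0")
        for name, table in (("a_LN", self.a_LN), ("a_RC", self.a_RC), ("a_RN", self.a_RN)):
            for s in (0, 1):
                if s not in table:
                    raise ValueError(f"{name} must define soil states 0 and 1")
                if lower(table[s]) <= 0:
                    raise ValueError(f"{name}[{s}] must be > 0")
            if lower(table[1]) <= upper(table[0]):
                raise ValueError(f"{name}(1) must exceed {name}(0)")


def uptake_cost_ratio(a_N: Cost, a_C: Cost, reported: bool = False) -> Cost:
    """Cost of N in units of C, ``a_N / a_C``.

    With ``reported=True`` the result is truncated toward zero at two
    decimal places, the convention used for all printed-comparable
    ratios; full precision is returned otherwise.
    """
    if lower(a_C) <= 0:
        raise ValueError("a_C must be > 0")
    if isinstance(a_C, Interval):
        a_N_iv = a_N if isinstance(a_N, Interval) else Interval(float(a_N), float(a_N))
        ratio: Cost = Interval(a_N_iv.lo / a_C.hi, a_N_iv.hi / a_C.lo)
    else:
        ratio = a_N / float(a_C)
    return truncate(ratio) if reported else ratio


def default_cost_set(
    equivalents: Optional[Mapping[str, Cost]] = None,
    exact_fractions: bool = False,
) -> ATPCostSet:
    """Assemble the reference cost set from the built-in ledgers.

    Rhizobium is assumed to face the same nitrate and ammonium uptake
    costs as the legume.  Its C cost in the demanding soil state is not
    measured directly; it is derived from the assumption that the
    rhizosphere keeps Rhizobium's N:C cost ratio ``r_R`` constant across
    soil states, i.e. ``a_RC(1) = a_RN(1) / r_R``.

    By default ``a_RC(0)`` and ``r_R`` use the 2-dp truncated glucose
    cost 0.33 (the value all derived figures are quoted from);
    ``exact_fractions=True`` keeps the exact 1/3 instead.

    Parameters
    ----------
    equivalents
        Overrides for reductant ATP-equivalent factors, e.g.
        ``{"Fd_red@nitrogenase": 1.5}``.
    """
    a_LC = cost_per_mol_element(G3P_FIXATION, equivalents)
    a_N1 = cost_per_mol_element(NITRATE_UPTAKE, equivalents)
    a_N0 = cost_per_mol_element(AMMONIUM_UPTAKE, equivalents)
    a_RC0_exact = cost_per_mol_element(GLUCOSE_ABC, equivalents)
    a_hat = cost_per_mol_element(N2_FIXATION, equivalents)

    a_RC0 = a_RC0_exact if exact_fractions else truncate(a_RC0_exact)
    r_R = uptake_cost_ratio(a_N0, a_RC0, reported=not exact_fractions)
    a_RC1 = a_N1 / float(r_R)

    return ATPCostSet(
        a_LC=float(a_LC),
        a_LN={0: a_N0, 1: a_N1},
        a_RC={0: a_RC0, 1: a_RC1},
        a_RN={0: a_N0, 1: a_N1},
        a_RN_hat=float(a_hat),
    )
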