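"""Scenario configuration loading and the end-to-end runner.

A scenario is a single YAML file describing the two organisms, the cost
specification, the soil state, the exchange-ratio policy, the sweep
grid and the dynamics settings.  :func:`run_scenario` chains the whole
pipeline — costs -> symbiosis verdict -> exchange regime -> equilibrium
-> comparative-statics sweep -> biomass dynamics -> welfare — and
writes TSV/CSV tables, a plain-text report and (optionally) an SVG of
the Edgeworth box.  The model path contains no randomness, so a given
config always produces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._interval import Cost, Interval, lower, midpoint, truncate, upper
from .atp_costs import (
    ATPCostSet,
    BUILTIN_LEDGERS,
    CostLedger,
    LedgerStep,
    cost_per_mol_element,
    default_cost_set,
)
from .autarky import BudgetLine, autarky_point
from .conditions import (
    ExchangeRegime,
    SymbiosisVerdict,
    choose_exchange_ratio,
    symbiosis_verdict,
)
from .dynamics import (
    AdjustmentParams,
    AdjustmentTrajectory,
    analytic_solution,
    equilibrium_population,
    simulate_adjustment,
)
from .equilibrium import (
    EquilibriumAllocation,
    WelfareReport,
    equilibrium_allocation,
    welfare_comparison,
)
from .render import render_edgeworth
from .statics import SweepGrid, headline_bands, sweep_supply_ratios
from .stoichiometry import StoichiometricProfile, optimality_slope


class ScenarioError(ValueError):
    """Configuration or pipeline error, labelled with its stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


# ---------------------------------------------------------------------------
# Configuration schema
# ---------------------------------------------------------------------------

_TOP_KEYS = {"organisms", "costs", "equivalents", "soil_state", "exchange",
             "sweep", "dynamics", "outputs", "seed"}
_ORGANISM_KEYS = {"c", "k_N", "k_C", "budget_b", "label"}
_EXCHANGE_KEYS = {"policy", "r"}
_SWEEP_KEYS = {"c_L", "c_R", "r_values"}
_DYNAMICS_KEYS = {"sigma0", "t_end", "dt", "rate_constant", "beta"}


@dataclass(frozen=True)
class Scenario:
    """A validated scenario: organisms, costs, policy and run settings."""

    host: StoichiometricProfile
    symbiont: StoichiometricProfile
    costs: ATPCostSet
    soil_state: int
    policy: str
    explicit_r: Optional[float]
    sweep: SweepGrid
    sigma0: float
    t_end: float
    dt: Optional[float]
    rate_constant: float
    beta: Optional[float]
    seed: int
    config_hash: str


def _reject_unknown(mapping: Mapping[str, Any], allowed: set, section: str) -> None:
    for key in mapping:
        if key not in allowed:
            raise ScenarioError("schema", f"unknown key {key!r} in section {section!r}")


def _parse_organism(raw: Mapping[str, Any], role: str) -> StoichiometricProfile:
    _reject_unknown(raw, _ORGANISM_KEYS, f"organisms.{role}")
    label = raw.get("label", role)
    budget = float(raw.get("budget_b", 1.0))
    try:
        if "k_N" in raw or "k_C" in raw:
            return StoichiometricProfile(
                k_N=float(raw["k_N"]), k_C=float(raw["k_C"]),
                budget_b=budget, label=label,
            )
        return StoichiometricProfile.from_cn_ratio(
            c=float(raw["c"]), budget_b=budget, label=label
        )
    except KeyError as exc:
        raise ScenarioError("schema", f"organisms.{role} missing key {exc}") from None
    except ValueError as exc:
        raise ScenarioError("invariant", f"organisms.{role}: {exc}") from None


def _parse_cost_value(raw: Any, equivalents: Optional[Mapping[str, Cost]]) -> Cost:
    if isinstance(raw, (int, float)):
        return float(raw)
    if isinstance(raw, (list, tuple)) and len(raw) == 2:
        return Interval(float(raw[0]), float(raw[1]))
    if isinstance(raw, str):
        if raw not in BUILTIN_LEDGERS:
            raise ScenarioError("schema", f"unknown built-in ledger {raw!r}")
        return cost_per_mol_element(BUILTIN_LEDGERS[raw], equivalents)
    if isinstance(raw, Mapping):
        ledger = _parse_ledger(raw)
        return cost_per_mol_element(ledger, equivalents)
    raise ScenarioError("schema", f"cannot interpret cost value {raw!r}")


def _parse_ledger(raw: Mapping[str, Any]) -> CostLedger:
    _reject_unknown(raw, {"steps", "atoms", "element", "name"}, "ledger")
    steps = []
    for step in raw.get("steps", []):
        _reject_unknown(step, {"atp", "reductants", "note"}, "ledger.steps")
        atp = step.get("atp", 0.0)
        atp_cost: Cost = (
            Interval(float(atp[0]), float(atp[1]))
            if isinstance(atp, (list, tuple)) else float(atp)
        )
        reductants = tuple(
            (red["name"], float(red["count"])) for red in step.get("reductants", [])
        )
        steps.append(LedgerStep(atp_count=atp_cost, reductant_counts=reductants,
                                note=step.get("note", "")))
    try:
        return CostLedger(
            steps=tuple(steps),
            atoms_per_molecule=int(raw["atoms"]),
            element=raw["element"],
            name=raw.get("name", ""),
        )
    except (KeyError, ValueError) as exc:
        raise ScenarioError("schema", f"invalid ledger: {exc}") from None


def _parse_costs(raw: Any, equivalents: Optional[Mapping[str, Cost]]) -> ATPCostSet:
    if raw in (None, "defaults", "reference"):
        return default_cost_set(equivalents)
    if not isinstance(raw, Mapping):
        raise ScenarioError("schema", f"costs must be 'defaults' or a mapping, got {raw!r}")
    _reject_unknown(raw, {"a_LC", "a_LN", "a_RC", "a_RN", "a_RN_hat"}, "costs")
    try:
        def by_state(key: str) -> Dict[int, Cost]:
            table = raw[key]
            return {int(s): _parse_cost_value(v, equivalents) for s, v in table.items()}

        return ATPCostSet(
            a_LC=float(_parse_cost_value(raw["a_LC"], equivalents)),
            a_LN=by_state("a_LN"),
            a_RC=by_state("a_RC"),
            a_RN=by_state("a_RN"),
            a_RN_hat=float(_parse_cost_value(raw["a_RN_hat"], equivalents)),
        )
    except KeyError as exc:
        raise ScenarioError("schema", f"costs missing key {exc}") from None
    except ValueError as exc:
        raise ScenarioError("invariant", f"costs: {exc}") from None


def load_scenario(path: Optional[str] = None) -> Scenario:
    """Load and validate a scenario file; ``None`` loads the bundled defaults.

    Unknown keys are rejected with a message naming the offending key;
    schema violations (wrong types, soil state outside {0, 1}) and
    invariant violations (non-positive parameters) raise distinct
    :class:`ScenarioError` stages.
    """
    if path is None:
        text = (
            importlib.resources.files("symtrade")
            .joinpath("data/defaults.yaml")
            .read_text(encoding="utf-8")
        )
    else:
        p = Path(path)
        if not p.exists():
            raise ScenarioError("io", f"scenario file not found: {path}")
        text = p.read_text(encoding="utf-8")

    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ScenarioError("parse", f"invalid YAML: {exc}") from None
    if not isinstance(raw, Mapping):
        raise ScenarioError("parse", "scenario file must contain a mapping")
    _reject_unknown(raw, _TOP_KEYS, "<top level>")

    organisms = raw.get("organisms", {})
    extra_roles = set(organisms) - {"host", "symbiont"}
    if extra_roles:
        raise ScenarioError("schema", f"unknown organism role(s) {sorted(extra_roles)}")
    if set(organisms) != {"host", "symbiont"}:
        raise ScenarioError("schema", "organisms must define exactly 'host' and 'symbiont'")
    host = _parse_organism(organisms["host"], "host")
    symbiont = _parse_organism(organisms["symbiont"], "symbiont")

    equivalents = raw.get("equivalents") or None
    costs = _parse_costs(raw.get("costs", "defaults"), equivalents)

    soil_state = raw.get("soil_state", 1)
    if soil_state not in (0, 1):
        raise ScenarioError("schema", f"soil_state must be 0 or 1, got {soil_state!r}")

    exchange = raw.get("exchange", {})
    _reject_unknown(exchange, _EXCHANGE_KEYS, "exchange")
    policy = exchange.get("policy", "median")
    if policy not in ("lower", "median", "upper", "explicit"):
        raise ScenarioError("schema", f"unknown exchange policy {policy!r}")
    explicit_r = exchange.get("r")
    if explicit_r is not None:
        explicit_r = float(explicit_r)

    sweep_raw = raw.get("sweep", {})
    _reject_unknown(sweep_raw, _SWEEP_KEYS, "sweep")
    try:
        sweep = SweepGrid(
            c_L_range=tuple(sweep_raw.get("c_L", (11.0, 26.0, 0.01))),
            c_R_range=tuple(sweep_raw.get("c_R", (11.0, 12.0, 0.01))),
            r_values=tuple(sweep_raw.get("r_values", (1.51, 1.69, 1.88))),
        )
    except ValueError as exc:
        raise ScenarioError("invariant", f"sweep: {exc}") from None

    dyn = raw.get("dynamics", {})
    _reject_unknown(dyn, _DYNAMICS_KEYS, "dynamics")

    digest = hashlib.sha256(text.encode("utf-8")).hexdigest()[:16]
    return Scenario(
        host=host,
        symbiont=symbiont,
        costs=costs,
        soil_state=int(soil_state),
        policy=policy,
        explicit_r=explicit_r,
        sweep=sweep,
        sigma0=float(dyn.get("sigma0", 0.0)),
        t_end=float(dyn.get("t_end", 8.0)),
        dt=(float(dyn["dt"]) if dyn.get("dt") is not None else None),
        rate_constant=float(dyn.get("rate_constant", 1.0)),
        beta=(float(dyn["beta"]) if dyn.get("beta") is not None else None),
        seed=int(raw.get("seed", 0)),
        config_hash=digest,
    )


# ---------------------------------------------------------------------------
# Runner
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunReport:
    """All pipeline outputs plus provenance for one scenario run."""

    scenario: Scenario
    verdict: SymbiosisVerdict
    regime: ExchangeRegime
    allocation: EquilibriumAllocation
    welfare: WelfareReport
    sweep_rows: pd.DataFrame
    sweep_summary: pd.DataFrame
    trajectory: AdjustmentTrajectory
    sigma_star: float
    decay_rate: float
    provenance: Dict[str, Any] = field(default_factory=dict)

    def equilibrium_table(self) -> pd.DataFrame:
        """Allocation, supplies, supply ratios and box dimensions.

        Carries both the full-precision value and its 2-dp truncation so
        the reporting convention is explicit rather than silently lossy.
        """
        a = self.allocation
        b = a.box
        quantities = {
            "x_LN_star": a.legume_uptake.x_N,
            "x_LC_star": a.legume_uptake.x_C,
            "x_RN_star": a.rhizobium_uptake.x_N,
            "x_RC_star": a.rhizobium_uptake.x_C,
            "y_LC_star": a.supply_C,
            "y_RN_star": a.supply_N,
            "h": b.h,
            "w_star": b.w,
            "C_supply_ratio": a.supply_C / b.h,
            "N_supply_ratio": a.supply_N / b.w,
        }
        return pd.DataFrame(
            {
                "quantity": list(quantities),
                "value": list(quantities.values()),
                "reported_2dp": [truncate(v) for v in quantities.values()],
            }
        )

    def to_text(self) -> str:
        v = self.verdict
        eq = self.equilibrium_table()
        lines = [
            "symtrade scenario report",
            f"version {self.provenance.get('version')} | config {self.provenance.get('config_hash')} | seed {self.provenance.get('seed')}",
            "",
            "== symbiosis verdict ==",
        ]
        lines += [f"  {k:<28} {val}" for k, val in v.rows()]
        lines += ["", f"== equilibrium (r = {self.regime.r}) =="]
        for _, row in eq.iterrows():
            lines.append(f"  {row['quantity']:<16} {row['value']:.10f}  (reported {row['reported_2dp']})")
        lines += ["", "== sweep summary =="]
        for _, row in self.sweep_summary.iterrows():
            lines.append(
                f"  r={row['r']:<5} C ratio {row['C_ratio_min_2dp']:.2f}-{row['C_ratio_max_2dp']:.2f}"
                f"  N ratio {row['N_ratio_min_2dp']:.2f}-{row['N_ratio_max_2dp']:.2f}"
            )
        (c_lo, c_hi), (n_lo, n_hi) = headline_bands(self.sweep_summary)
        lines.append(
            f"  headline: host supplies {c_lo * 100:.0f}-{c_hi * 100:.0f}% of fixed C; "
            f"symbiont supplies {n_lo * 100:.0f}-{n_hi * 100:.0f}% of fixed N"
        )
        lines += [
            "",
            "== dynamics ==",
            f"  sigma_star        {self.sigma_star:.10f}",
            f"  decay_rate        {self.decay_rate:.10f}",
            f"  sigma(t_end)      {self.trajectory.sigma[-1]:.10f}",
            f"  |sigma-sigma*|    {abs(self.trajectory.sigma[-1] - self.sigma_star):.3e}",
            "",
            "== welfare (equilibrium vs autarky) ==",
            f"  host fitness      {self.welfare.legume_fitness_E:.10f} vs {self.welfare.legume_fitness_autarky:.10f}",
            f"  symbiont fitness  {self.welfare.rhizobium_fitness_E:.10f} vs {self.welfare.rhizobium_fitness_autarky:.10f}",
            f"  both strictly improved: {self.welfare.both_strictly_improved}",
        ]
        return "\n".join(lines) + "\n"


def _check_cross_consistency(alloc: EquilibriumAllocation, params: AdjustmentParams) -> None:
    """Abort the run if the equilibrium and dynamics modules disagree."""
    sigma_star = equilibrium_population(params)
    w_dyn = params.fixed_n(sigma_star)
    if not math.isclose(w_dyn, alloc.box.w, rel_tol=1e-12):
        raise ScenarioError(
            "consistency",
            f"w(sigma*)={w_dyn!r} disagrees with equilibrium w*={alloc.box.w!r}",
        )


def run_scenario(
    scenario: Scenario,
    out_dir: Optional[str] = None,
    fmt: str = "tsv",
    svg: bool = False,
) -> RunReport:
    """Run the full pipeline for a scenario and optionally write outputs.

    Stages: verdict -> exchange regime -> equilibrium -> sweep ->
    dynamics -> welfare.  Errors carry the failing stage's label.  The
    run is deterministic: identical configs give identical outputs.
    """
    sc = scenario
    try:
        verdict = symbiosis_verdict(sc.costs, policy="median")
    except Exception as exc:
        raise ScenarioError("verdict", str(exc)) from exc

    try:
        from .atp_costs import uptake_cost_ratio

        r_L1 = uptake_cost_ratio(sc.costs.a_LN[1], sc.costs.a_LC, reported=True)
        r = choose_exchange_ratio(r_L1, verdict.r_R, sc.policy, sc.explicit_r)
        regime = ExchangeRegime(
            r_L0=verdict.r_L0, r_L1=r_L1, r_R=verdict.r_R, r=r, policy=sc.policy
        )
    except Exception as exc:
        raise ScenarioError("exchange", str(exc)) from exc

    try:
        c_L = optimality_slope(sc.host)
        c_R = optimality_slope(sc.symbiont)
        h = sc.host.budget_b / sc.costs.a_LC
        alloc = equilibrium_allocation(h, c_L, c_R, r)
    except Exception as exc:
        raise ScenarioError("equilibrium", str(exc)) from exc

    try:
        sweep_rows, sweep_summary = sweep_supply_ratios(sc.sweep, h=h)
    except Exception as exc:
        raise ScenarioError("sweep", str(exc)) from exc

    try:
        params = AdjustmentParams(
            h=h, c_L=c_L, c_R=c_R, r=r,
            a_RN_hat=sc.costs.a_RN_hat, beta=sc.beta,
            rate_constant=sc.rate_constant,
        )
        _check_cross_consistency(alloc, params)
        trajectory = simulate_adjustment(sc.sigma0, params, sc.t_end, sc.dt)
        sigma_star = equilibrium_population(params)
    except ScenarioError:
        raise
    except Exception as exc:
        raise ScenarioError("dynamics", str(exc)) from exc

    try:
        welfare = welfare_comparison(alloc, sc.host, sc.symbiont, sc.costs, sc.soil_state)
    except Exception as exc:
        raise ScenarioError("welfare", str(exc)) from exc

    report = RunReport(
        scenario=sc,
        verdict=verdict,
        regime=regime,
        allocation=alloc,
        welfare=welfare,
        sweep_rows=sweep_rows,
        sweep_summary=sweep_summary,
        trajectory=trajectory,
        sigma_star=sigma_star,
        decay_rate=params.decay_rate,
        provenance={
            "version": __version__,
            "config_hash": sc.config_hash,
            "seed": sc.seed,
        },
    )

    if out_dir is not None:
        _write_outputs(report, Path(out_dir), fmt=fmt, svg=svg)
    return report


def _write_outputs(report: RunReport, out_dir: Path, fmt: str = "tsv", svg: bool = False) -> None:
    if fmt not in ("tsv", "csv"):
        raise ScenarioError("io", f"format must be 'tsv' or 'csv', got {fmt!r}")
    sep = "\t" if fmt == "tsv" else ","
    out_dir.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(report.verdict.rows(), columns=["key", "value"]).to_csv(
        out_dir / f"verdict.{fmt}", sep=sep, index=False
    )
    report.equilibrium_table().to_csv(out_dir / f"equilibrium.{fmt}", sep=sep, index=False)
    report.sweep_rows.to_csv(out_dir / f"sweep.{fmt}", sep=sep, index=False)
    report.sweep_summary.to_csv(out_dir / f"sweep_summary.{fmt}", sep=sep, index=False)
    pd.DataFrame(
        {
            "t": report.trajectory.times,
            "sigma": report.trajectory.sigma,
            "F": report.trajectory.excess_C,
        }
    ).to_csv(out_dir / f"dynamics.{fmt}", sep=sep, index=False)
    (out_dir / "report.txt").write_text(report.to_text(), encoding="utf-8")

    if svg:
        sc = report.scenario
        s = sc.soil_state
        legume_aut = autarky_point(
            BudgetLine(
                a_N=midpoint(sc.costs.a_LN[s]), a_C=sc.costs.a_LC, b=sc.host.budget_b
            ),
            sc.host,
        )
        b_R = sc.costs.a_RN_hat * report.allocation.box.w
        rhizobium_aut = autarky_point(
            BudgetLine(
                a_N=midpoint(sc.costs.a_RN[s]), a_C=midpoint(sc.costs.a_RC[s]), b=b_R
            ),
            sc.symbiont,
        )
        render_edgeworth(
            report.allocation,
            autarky_points={"legume": legume_aut, "rhizobium": rhizobium_aut},
            regime=report.regime,
            out=str(out_dir / "edgeworth.svg"),
        )
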