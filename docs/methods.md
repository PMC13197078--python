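# Methods

## Model and assumptions

The package implements a static trade model between a legume host
(taken per unit mass) and a *Rhizobium* population (size-variable),
plus the one-dimensional dynamics that carry the population to the
static equilibrium.

Assumptions, in the order they bite:

1. **Leontief fitness.** Fitness is `min(k_N x_N, k_C x_C)` — strict
   complementarity of C and N in fixed proportions. The ratio
   `c = k_N/k_C` is identified with the body molar C:N ratio; absolute
   `k` magnitudes are not identified by any observable used here, so
   scenario configs accept the ratio `c` directly and normalize
   `k_C = 1`. Fitness values are therefore in arbitrary units;
   *comparisons* of fitness (equilibrium vs autarky) are unaffected,
   since both sides share the same units.
2. **Linear ATP budgets.** Acquisition costs per mol of element are
   constant, so budget sets are lines. Autarky is the
   budget-line/optimality-line intersection; no interior trade-off
   exists under Leontief preferences.
3. **Constant rhizosphere cost ratio.** *Rhizobium*'s N:C cost ratio
   `r_R` is the same in both soil states (the rhizosphere buffers the
   soil C:N it sees); this is what lets `a_RC(1)` be derived as
   `a_RN(1)/r_R` instead of measured.
4. **Exogenous exchange ratio.** `r` is a constant of the scenario, not
   a price that adjusts. Imbalance at a given `r` is cleared by
   symbiont biomass, which is the appropriate margin when resources are
   demanded in fixed proportions.
5. **Budget proportional to population.** `b_R(σ) = β σ` with β > 0;
   the default β = â_RN makes `w(σ) = σ`, i.e. population is measured
   in units of N fixed per unit time.

## ATP cost ledgers

Costs are compiled from step ledgers (ATP counts plus reductants valued
in ATP equivalents: NADPH 3, NADH 2.5, Fd_red 1.5; Fd_red inside the
nitrogenase reaction 2). Basis molecules: G3P (3 C) for host carbon,
glucose (6 C) for free-living symbiont carbon, ammonium (1 N) for all
direct nitrogen, N₂ (2 N) for fixation. Two genuinely uncertain items
are carried as intervals rather than point guesses: the nitrate route's
transporter (1–3 ATP) plus auxiliary (1–2 ATP) costs and its
NAD(P)H step (valued 2.5–3), giving `a_LN(1) ∈ [13.5, 17]`; everything
downstream propagates intervals by endpoint arithmetic, exact here
because all coefficients are positive.

**Reporting convention.** Printed-comparable ratios are truncated
toward zero at two decimals; full precision is kept internally and
shown alongside in every table. `r_R` is derived from the truncated
glucose cost 0.33 (giving 1.51); the exact-1/3 alternative
(`exact_fractions=True`, giving 1.50) is available because the choice
is a convention, not physics.

**Fixation feasibility over an interval.** With
`a_RN(1) ∈ [13.5, 17]` and `â_RN = 16`, the condition
`a_RN(1) ≥ â_RN` holds only on [16, 17]. The package reports a
three-valued verdict (always / never / partially satisfied) instead of
collapsing the interval to a point; the overall "symbiosis favored"
flag treats *partially* as not-ruled-out.

## Exchange-ratio policies

The feasible range implied by the reference ledgers is
`[r_R, upper(r_L(1))] = [1.51, 1.88]`. Policies select `r` from it:
`lower` → `r_R` (host-favoring boundary; the symbiont's strict gain
vanishes at the margin), `median` → the truncated midpoint anchor of
the `r_L(1)` interval (1.69), `upper` → 1.88, `explicit` → any value
inside the closed range. The bundled scenario uses `median` so that the
headline run shows strict mutual gains.

## Equilibrium and its oracle

The closed forms for the allocation and box width are verified, rather
than assumed, against an independent geometric solver: for a trial box
width `w` it intersects the trade line with each optimality line by 2×2
linear solves and then root-finds (bracketed Brent, bracket grown by
doubling) on the scalar excess-N-demand `g(w) = x_LN + x_RN(w) − w`.
Agreement is required to 1e-10 over 1000 random draws
(`h ∈ [0.1, 10]`, slopes in `[0.5, 40]`, `r ∈ [0.1, 5]`); mass-balance,
optimality-line and trade-line identities hold to 1e-12.
`equilibrium_allocation` deliberately does *not* enforce
`r_R < r < r_L(1)` — comparative statics legitimately explore
infeasible `r` — but attaches a warning when a regime is supplied and
violated.

## Comparative statics

The four nonzero partials of the supply ratios and of `w*` are coded
analytically and checked against central finite differences
(step 1e-6, agreement 1e-6 relative, 100 random points). Sweeps include
the grid endpoints (the printed range bounds are attained there);
default step 0.01 on both C:N axes. The aging path is linear in
`(c_L, c_R)` between its endpoints — only the endpoints are
empirically anchored (young vs mature alfalfa: c_L 13→25; symbiont
c_R 12→11), so no functional form beyond monotonicity is claimed; both
supply ratios are non-increasing along any admissible path, while the
net change in `w*` is indefinite.

## Dynamics: numerical choices

`F(σ)` is affine with slope `−(c_R r/(c_R+r)) β/â_RN < 0`, so the exact
solution is exponential relaxation at rate
`λ = rate_constant · (c_R r/(c_R+r)) · β/â_RN`. The integrator is
classical fixed-step RK4 with default step `0.01/λ` on a uniform grid;
because the ODE is linear this is a wiring test, and the suite requires
1e-8 relative agreement with the analytic path at every sample. σ is
clipped at 0 after each step (population cannot be negative); at the
default step the clip never triggers. The `rate_constant` (default 1)
only rescales time, which the model leaves in arbitrary units.

## Scenario runner and determinism

The model path contains no randomness: a scenario config fully
determines every output, and rerunning writes byte-identical tables.
Configs are validated strictly (unknown keys rejected by name; schema,
invariant and parse failures carry distinct stage labels) and the
runner re-asserts cross-module identities (dynamics fixed point vs
equilibrium box width to 1e-12; every reported 2-dp value equals the
truncation of its full-precision twin) before writing. The Edgeworth
SVG embeds model-space coordinates in `data-model` attributes so the
rendered geometry can be re-extracted and checked mechanically.

## What the randomized checks do and do not show

Random parameter draws for the welfare and oracle properties span
scalar cost sets with `r_L(1)/r_R ∈ [1.05, 2.5]`, fixation costing
50–100% of direct uptake, body C:N in `[5, 30]` — a box deliberately
wider than the empirically cited ranges. Passing them shows the
*model's* internal claims (gains from trade under the stated
conditions, global stability, closed-form correctness) hold across
that box; it says nothing about whether real symbioses satisfy the
Leontief, linear-budget or constant-`r` assumptions, and the cited C:N
and cost figures enter only as the reference scenario's inputs, not as
fitted quantities.

## Known limitations

- Two elements only; no phosphorus, no CES-type smooth fitness.
- No nodule construction or maintenance costs, no nodule life cycle,
  no multi-partner markets, no price (exchange-ratio) dynamics.
- Interval costs are evaluated at midpoints where a scalar is required
  (welfare comparison, median anchor); endpoints are always available.
- The ledger equivalents are fixed conversion factors; no P/O-ratio,
  pH or temperature dependence.

## Problem sizes

Default sweeps evaluate ~4.5×10⁵ grid points in well under a second;
the oracle cross-check runs 1000 draws in a few seconds; dynamics
integrations use a few hundred RK4 steps. The whole suite and the
acceptance script each complete in well under a minute on one CPU.
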