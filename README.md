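# symtrade

Comparative-advantage model of carbon–nitrogen exchange in the
legume–*Rhizobium* symbiosis, under ATP budget constraints and with
supply–demand imbalance cleared by symbiont biomass adjustment.

## Who this is for

Researchers in stoichiometric ecology and biological market theory who
want to compute — rather than just sketch — the equilibrium of a
two-species resource trade: which cost conditions make root-nodule
symbiosis pay, what fraction of its fixed carbon the host plant should
cede to its symbiont (and of fixed nitrogen the symbiont to its host),
and how those fractions shift with the body C:N ratios of the partners.

## The model

Each organism has a Liebig-minimum fitness over its N and C uptakes,

    f = min(k_N x_N, k_C x_C),

and an ATP budget `b` spent at per-mol costs `a_N`, `a_C`
(`a_N x_N + a_C x_C = b`). The ratio `c = k_N/k_C` equals the body
molar C:N ratio and is the slope of the *optimality line* on which both
limbs of the minimum are equal. Alone, each species picks the
*autarky point* where its budget line crosses its optimality line.

ATP cost ledgers for the relevant pathways (Calvin–Benson C fixation,
nitrate and ammonium uptake, glucose ABC transport, nitrogenase) give
the cost of N in units of C for each partner: `r_L(s) = a_LN(s)/a_LC`
for the legume under soil state `s` (1 = nitrate-dominated, costly;
0 = ammonium available, cheap) and a constant `r_R = a_RN/a_RC` for
rhizosphere *Rhizobium*. Trade at exchange ratio `r` (mol C per mol N)
benefits both species exactly when

    r_L(1) > r > r_R      and      a_RN(1) >= â_RN,

i.e. *Rhizobium* has the comparative advantage in N, and N fixation
(cost `â_RN`) yields at least as much N per budget as direct uptake.
With the ledger values `a_LC = 9`, `a_LN(1) ∈ [13.5, 17]`,
`a_LN(0) = 0.5`, `a_RC(0) = 0.33`, `â_RN = 16`, the feasible range is
`1.51 ≤ r ≤ 1.88` — and symbiosis is favored only in the costly soil
state.

In the Edgeworth box (height `h = b_L/a_LC` = C fixed by the host,
width `w` = N fixed by the symbiont population) the trade equilibrium E
is the intersection of the two optimality lines with the trade line of
slope `−r` through the shared specialization corner:

    x_LN* = h/(c_L+r)                x_LC* = c_L h/(c_L+r)
    x_RN* = r h/(c_R (c_L+r))        x_RC* = r h/(c_L+r)
    w*    = (c_R+r) h / (c_R (c_L+r))

so the host supplies the fraction `r/(c_L+r)` of its fixed C and the
symbiont `c_R/(c_R+r)` of its fixed N. The box width is reached
dynamically by the population-size ODE `dσ/dt = F(σ)` with `F` the
excess C supply — affine in σ with negative slope, hence globally
asymptotically stable with fixed point `w(σ*) = w*`.

## Worked example

```sh
symtrade run
```

runs the bundled scenario (host body C:N 11, symbiont body C:N 11,
costly soil, exchange ratio at the median anchor r = 1.69) and prints,
among other sections:

```
== equilibrium (r = 1.69) ==
  x_LN_star        0.0788022065  (reported 0.07)
  x_LC_star        0.8668242711  (reported 0.86)
  x_RN_star        0.0121068844  (reported 0.01)
  x_RC_star        0.1331757289  (reported 0.13)
  ...
  w_star           0.0909090909  (reported 0.09)
  C_supply_ratio   0.1331757289  (reported 0.13)
  N_supply_ratio   0.8668242711  (reported 0.86)

== sweep summary ==
  r=1.51  C ratio 0.05-0.12  N ratio 0.87-0.88
  r=1.69  C ratio 0.06-0.13  N ratio 0.86-0.87
  r=1.88  C ratio 0.06-0.14  N ratio 0.85-0.86
  headline: host supplies 5-14% of fixed C; symbiont supplies 85-88% of fixed N
```

Reading: at equilibrium the host keeps ~87% of the carbon it fixes and
hands over ~13%, while the symbiont hands over ~87% of the nitrogen it
fixes — the characteristic asymmetry of the symbiosis, produced here by
nothing more than body C:N ratios and the ATP-cost-bounded exchange
ratio. Sweeping the empirical C:N ranges (host 11–26, symbiont 11–12)
bounds the supplies at 5–14% of fixed C and 85–88% of fixed N.
`symtrade verdict`, `sweep`, `equilibrium --svg` and `dynamics` expose
the individual stages; `--out DIR` writes TSV tables, a plain-text
report and an SVG of the Edgeworth box.

All printed-comparable values are truncated (not rounded) to two
decimals, with full precision kept alongside.

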