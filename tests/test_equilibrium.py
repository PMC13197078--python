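import numpy as np
import pytest

from symtrade import (
    ATPCostSet,
    ExchangeRegime,
    StoichiometricProfile,
    equilibrium_allocation,
    solve_equilibrium_geometric,
    supply_ratios,
    truncate,
    welfare_comparison,
)
from conftest import random_feasible_draw


def alloc_fields(alloc):
    return np.array(
        [
            alloc.legume_uptake.x_N,
            alloc.legume_uptake.x_C,
            alloc.rhizobium_uptake.x_N,
            alloc.rhizobium_uptake.x_C,
            alloc.supply_C,
            alloc.supply_N,
            alloc.box.w,
        ]
    )


class TestClosedForm:
    def test_symmetric_slopes_collapse_width(self, rng):
        for _ in range(20):
            h, c, r = rng.uniform(0.5, 10.0, size=3)
            alloc = equilibrium_allocation(h, c, c, r)
            assert alloc.box.w == pytest.approx(h / c, rel=1e-12)

    def test_reference_point_values(self):
        alloc = equilibrium_allocation(1.0, 11.0, 11.0, 1.51)
        assert alloc.legume_uptake.x_N == pytest.approx(0.0799361, abs=1e-7)
        assert alloc.legume_uptake.x_C == pytest.approx(0.8792966, abs=1e-7)
        assert alloc.rhizobium_uptake.x_C == pytest.approx(0.1207034, abs=1e-7)
        assert alloc.rhizobium_uptake.x_N == pytest.approx(0.0109730, abs=1e-7)
        assert alloc.box.w == pytest.approx(1.0 / 11.0, rel=1e-12)

    def test_supply_ratio_of_C_reference_cell(self):
        alloc = equilibrium_allocation(1.0, 11.0, 11.0, 1.51)
        assert truncate(alloc.supply_C / alloc.box.h) == pytest.approx(0.12)

    def test_rejects_nonpositive_arguments(self):
        with pytest.raises(ValueError):
            equilibrium_allocation(0.0, 11.0, 11.0, 1.51)

    def test_infeasible_r_warns_when_regime_given(self):
        regime = ExchangeRegime(r_L0=0.05, r_L1=1.69, r_R=1.51, r=3.0, policy="explicit")
        with pytest.warns(UserWarning):
            alloc = equilibrium_allocation(1.0, 11.0, 11.0, 3.0, regime=regime)
        assert alloc.feasibility_warning is not None


class TestSupplyRatios:
    @pytest.mark.parametrize(
        "c_L, c_R, r, expected_C, expected_N",
        [
            (26.0, 11.0, 1.51, 0.05, None),   # lean host: lowest C supply
            (11.0, 12.0, 1.51, None, 0.88),   # highest N supply
            (11.0, 11.0, 1.51, 0.12, 0.87),
        ],
    )
    def test_truncated_reference_cells(self, c_L, c_R, r, expected_C, expected_N):
        C_ratio, N_ratio = supply_ratios(c_L, c_R, r)
        if expected_C is not None:
            assert truncate(C_ratio) == pytest.approx(expected_C)
        if expected_N is not None:
            assert truncate(N_ratio) == pytest.approx(expected_N)

    def test_no_trade_limit(self):
        C_ratio, N_ratio = supply_ratios(11.0, 11.0, 1e-12)
        assert C_ratio == pytest.approx(0.0, abs=1e-12)
        assert N_ratio == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_exchange_ratio(self, rng):
        for _ in range(50):
            c_L, c_R = rng.uniform(1.0, 30.0, size=2)
            r1 = rng.uniform(0.1, 5.0)
            r2 = r1 * rng.uniform(1.01, 2.0)
            C1, N1 = supply_ratios(c_L, c_R, r1)
            C2, N2 = supply_ratios(c_L, c_R, r2)
            assert C2 > C1 and N2 < N1

    def test_ratios_strictly_inside_unit_interval(self, rng):
        for _ in range(100):
            c_L, c_R, r = rng.uniform(0.01, 50.0, size=3)
            C_ratio, N_ratio = supply_ratios(c_L, c_R, r)
            assert 0.0 < C_ratio < 1.0
            assert 0.0 < N_ratio < 1.0


class TestGeometricOracle:
    def test_reference_point_matches_closed_form(self):
        closed = equilibrium_allocation(1.0, 11.0, 11.0, 1.51)
        geom = solve_equilibrium_geometric(1.0, 11.0, 11.0, 1.51)
        assert np.allclose(alloc_fields(closed), alloc_fields(geom), rtol=1e-10, atol=1e-12)
        assert geom.box.w == pytest.approx(0.0909091, abs=1e-7)

    def test_oracle_equivalence_over_random_draws(self, rng):
        for _ in range(1000):
            h = rng.uniform(0.1, 10.0)
            c_L, c_R = rng.uniform(0.5, 40.0, size=2)
            r = rng.uniform(0.1, 5.0)
            closed = equilibrium_allocation(h, c_L, c_R, r)
            geom = solve_equilibrium_geometric(h, c_L, c_R, r)
            assert np.allclose(alloc_fields(closed), alloc_fields(geom),
                               rtol=1e-10, atol=1e-12)

    def test_homogeneous_in_height(self):
        base = solve_equilibrium_geometric(1.0, 13.0, 11.5, 1.7)
        scaled = solve_equilibrium_geometric(7.5, 13.0, 11.5, 1.7)
        assert np.allclose(alloc_fields(scaled), 7.5 * alloc_fields(base), rtol=1e-9)

    def test_supply_ratios_consistent_with_geometry(self):
        geom = solve_equilibrium_geometric(1.0, 26.0, 12.0, 1.88)
        C_ratio, N_ratio = supply_ratios(26.0, 12.0, 1.88)
        assert geom.supply_C / geom.box.h == pytest.approx(C_ratio, rel=1e-10)
        assert geom.supply_N / geom.box.w == pytest.approx(N_ratio, rel=1e-10)


class TestConservationInvariants:
    def test_mass_balance_optimality_and_trade_line(self, rng):
        for _ in range(200):
            h = rng.uniform(0.1, 10.0)
            c_L, c_R = rng.uniform(0.5, 40.0, size=2)
            r = rng.uniform(0.1, 5.0)
            a = equilibrium_allocation(h, c_L, c_R, r)
            # conservation of fixed C and N across the box
            assert a.legume_uptake.x_C + a.rhizobium_uptake.x_C == pytest.approx(
                h, rel=1e-12
            )
            assert a.legume_uptake.x_N + a.rhizobium_uptake.x_N == pytest.approx(
                a.box.w, rel=1e-12
            )
            # each species sits on its optimality line
            assert a.legume_uptake.x_C / a.legume_uptake.x_N == pytest.approx(
                c_L, rel=1e-12
            )
            assert a.rhizobium_uptake.x_C / a.rhizobium_uptake.x_N == pytest.approx(
                c_R, rel=1e-12
            )
            # the legume's bundle lies on the trade line through S=(0,h)
            assert a.legume_uptake.x_C == pytest.approx(
                h - r * a.legume_uptake.x_N, rel=1e-12
            )


def _scalar_cost_set(a_LC, a_LN1, a_RC1, a_RN1, a_hat):
    return ATPCostSet(
        a_LC=a_LC,
        a_LN={0: a_LN1 / 100.0, 1: a_LN1},
        a_RC={0: a_RC1 / 100.0, 1: a_RC1},
        a_RN={0: a_RN1 / 100.0, 1: a_RN1},
        a_RN_hat=a_hat,
    )


class TestWelfare:
    def test_reference_point_both_strictly_improved(self, costs):
        legume = StoichiometricProfile.from_cn_ratio(11.0, budget_b=9.0)
        rhizobium = StoichiometricProfile.from_cn_ratio(11.0, budget_b=1.0)
        alloc = equilibrium_allocation(1.0, 11.0, 11.0, 1.69)
        rep = welfare_comparison(alloc, legume, rhizobium, costs, s=1)
        assert rep.both_strictly_improved

    def test_trade_at_legume_cost_ratio_gives_no_strict_gain(self, costs):
        # r equal to the legume's own cost ratio: the trade line parallels
        # its budget line, so its equilibrium fitness equals autarky fitness
        from symtrade._interval import midpoint

        r = midpoint(costs.a_LN[1]) / costs.a_LC
        legume = StoichiometricProfile.from_cn_ratio(11.0, budget_b=9.0)
        rhizobium = StoichiometricProfile.from_cn_ratio(11.0, budget_b=1.0)
        alloc = equilibrium_allocation(1.0, 11.0, 11.0, r)
        rep = welfare_comparison(alloc, legume, rhizobium, costs, s=1)
        assert rep.legume_fitness_E == pytest.approx(rep.legume_fitness_autarky, rel=1e-12)

    def test_gains_from_trade_over_random_feasible_draws(self, rng):
        """Whenever Rhizobium has the comparative advantage, fixation is no
        costlier than direct uptake and r lies strictly inside the feasible
        interval, trade strictly improves both species over autarky."""
        for _ in range(100):
            a_LC, a_LN1, a_RC1, a_RN1, a_hat, r, c_L, c_R, b_L = random_feasible_draw(rng)
            cs = _scalar_cost_set(a_LC, a_LN1, a_RC1, a_RN1, a_hat)
            legume = StoichiometricProfile.from_cn_ratio(c_L, budget_b=b_L)
            rhizobium = StoichiometricProfile.from_cn_ratio(c_R, budget_b=1.0)
            alloc = equilibrium_allocation(b_L / a_LC, c_L, c_R, r)
            rep = welfare_comparison(alloc, legume, rhizobium, cs, s=1)
            assert rep.both_strictly_improved

    def test_no_exchange_ratio_benefits_both_in_cheap_soil(self, costs):
        """At s=0 the comparative advantage is reversed (r_L(0) < r_R): no
        exchange ratio makes trade better than autarky for both partners."""
        legume = StoichiometricProfile.from_cn_ratio(11.0, budget_b=9.0)
        rhizobium = StoichiometricProfile.from_cn_ratio(11.0, budget_b=1.0)
        for r in np.linspace(0.01, 3.0, 150):
            alloc = equilibrium_allocation(1.0, 11.0, 11.0, float(r))
            rep = welfare_comparison(alloc, legume, rhizobium, costs, s=0)
            assert not rep.both_strictly_improved
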