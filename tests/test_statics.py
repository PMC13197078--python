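import numpy as np
import pytest

from symtrade import (
    SweepGrid,
    aging_trajectory,
    headline_bands,
    sensitivities,
    supply_ratios,
    sweep_supply_ratios,
)


def central_diff(f, x, h=1e-6):
    return (f(x + h) - f(x - h)) / (2 * h)


class TestSensitivities:
    def test_signs_match_predictions(self, rng):
        # C supply ratio falls in c_L; N supply ratio rises in c_R;
        # box width falls in both C:N ratios
        for _ in range(50):
            c_L, c_R, r, h = rng.uniform(0.5, 30.0, size=4)
            assert sensitivities(c_L, c_R, r, h).signs == (-1, 1, -1, -1)

    def test_structural_zeros(self):
        s = sensitivities(11.0, 11.0, 1.51, 1.0)
        assert s.d_C_ratio_d_c_R == 0.0
        assert s.d_N_ratio_d_c_L == 0.0

    def test_reference_point_value(self):
        s = sensitivities(11.0, 11.0, 1.51, 1.0)
        assert s.d_C_ratio_d_c_L == pytest.approx(-1.51 / 12.51**2, rel=1e-12)
        assert s.d_C_ratio_d_c_L == pytest.approx(-0.0096486, abs=1e-7)

    def test_agree_with_central_finite_differences(self, rng):
        for _ in range(100):
            c_L, c_R, r, h = rng.uniform(1.0, 30.0, size=4)
            s = sensitivities(c_L, c_R, r, h)
            num_C = central_diff(lambda x: supply_ratios(x, c_R, r)[0], c_L)
            num_N = central_diff(lambda x: supply_ratios(c_L, x, r)[1], c_R)
            w = lambda cl, cr: (cr + r) * h / (cr * (cl + r))
            num_w_L = central_diff(lambda x: w(x, c_R), c_L)
            num_w_R = central_diff(lambda x: w(c_L, x), c_R)
            assert s.d_C_ratio_d_c_L == pytest.approx(num_C, rel=1e-6)
            assert s.d_N_ratio_d_c_R == pytest.approx(num_N, rel=1e-6)
            assert s.d_w_d_c_L == pytest.approx(num_w_L, rel=1e-6)
            assert s.d_w_d_c_R == pytest.approx(num_w_R, rel=1e-6)

    def test_vanishing_trade_limit(self):
        s = sensitivities(11.0, 11.0, 1e-14, 1.0)
        assert s.d_C_ratio_d_c_L == pytest.approx(0.0, abs=1e-12)
        assert s.d_N_ratio_d_c_R == pytest.approx(0.0, abs=1e-12)
        # dw*/dc_L tends to -h/c_L^2 as r -> 0
        assert s.d_w_d_c_L == pytest.approx(-1.0 / 11.0**2, rel=1e-9)

    def test_rejects_nonpositive_arguments(self):
        with pytest.raises(ValueError):
            sensitivities(-1.0, 11.0, 1.51)


@pytest.fixture(scope="module")
def summary():
    _, table = sweep_supply_ratios(SweepGrid())
    return table.set_index("r")


class TestSweep:
    @pytest.mark.parametrize(
        "r, C_lo, C_hi, N_lo, N_hi",
        [
            (1.51, 0.05, 0.12, 0.87, 0.88),
            (1.69, 0.06, 0.13, 0.86, 0.87),
            (1.88, 0.06, 0.14, 0.85, 0.86),
        ],
    )
    def test_supply_ratio_range_cells(self, summary, r, C_lo, C_hi, N_lo, N_hi):
        row = summary.loc[r]
        assert row["C_ratio_min_2dp"] == pytest.approx(C_lo)
        assert row["C_ratio_max_2dp"] == pytest.approx(C_hi)
        assert row["N_ratio_min_2dp"] == pytest.approx(N_lo)
        assert row["N_ratio_max_2dp"] == pytest.approx(N_hi)

    def test_headline_bands(self, summary):
        (c_lo, c_hi), (n_lo, n_hi) = headline_bands(summary.reset_index())
        assert (c_lo, c_hi) == (pytest.approx(0.05), pytest.approx(0.14))
        assert (n_lo, n_hi) == (pytest.approx(0.85), pytest.approx(0.88))

    def test_extrema_attained_at_grid_endpoints(self):
        rows, _ = sweep_supply_ratios(SweepGrid(r_values=(1.51,)))
        sub = rows[rows["r"] == 1.51]
        assert sub.loc[sub["C_ratio"].idxmax(), "c_L"] == pytest.approx(11.0)
        assert sub.loc[sub["C_ratio"].idxmin(), "c_L"] == pytest.approx(26.0)
        assert sub.loc[sub["N_ratio"].idxmax(), "c_R"] == pytest.approx(12.0)

    def test_rejects_invalid_grid(self):
        with pytest.raises(ValueError):
            SweepGrid(c_L_range=(26.0, 11.0, 0.01))
        with pytest.raises(ValueError):
            SweepGrid(r_values=())


class TestAgingTrajectory:
    def test_alfalfa_endpoints(self):
        # young (c_L=13, c_R=12) to mature (c_L=25, c_R=11) at r=1.69
        path = aging_trajectory(13.0, 25.0, 12.0, 11.0, r=1.69, steps=50)
        assert path["C_ratio"].iloc[0] == pytest.approx(1.69 / 14.69, rel=1e-12)
        assert path["C_ratio"].iloc[-1] == pytest.approx(1.69 / 26.69, rel=1e-12)
        assert path["N_ratio"].iloc[0] == pytest.approx(12.0 / 13.69, rel=1e-12)
        assert path["N_ratio"].iloc[-1] == pytest.approx(11.0 / 12.69, rel=1e-12)

    def test_both_supply_ratios_decline_with_age(self, rng):
        for _ in range(50):
            c_L_y = rng.uniform(8.0, 20.0)
            c_L_o = c_L_y + rng.uniform(0.5, 15.0)
            c_R_y = rng.uniform(10.0, 15.0)
            c_R_o = c_R_y - rng.uniform(0.1, 3.0)
            r = rng.uniform(1.0, 2.5)
            path = aging_trajectory(c_L_y, c_L_o, c_R_y, c_R_o, r=r, steps=30)
            assert (np.diff(path["C_ratio"]) <= 1e-15).all()
            assert (np.diff(path["N_ratio"]) <= 1e-15).all()

    def test_constant_path_gives_constant_ratios(self):
        path = aging_trajectory(13.0, 13.0, 12.0, 12.0, r=1.69, steps=10)
        assert path["C_ratio"].nunique() == 1
        assert path["N_ratio"].nunique() == 1

    def test_reversed_path_rejected(self):
        with pytest.raises(ValueError):
            aging_trajectory(25.0, 13.0, 12.0, 11.0, r=1.69)
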