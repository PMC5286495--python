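import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from algalipid import (
    BatchState,
    CompositionParams,
    KineticParams,
    Trajectory,
    adjustment,
    growth_rhs,
    lipid_content,
    nitrogen_quota,
    simulate,
    uptake_rhs,
)

from conftest import logistic_closed_form


class TestAdjustment:
    @pytest.mark.parametrize(
        "t, mu, h0, expected, tol",
        [
            (0.0, 0.313, -0.624, 1.8664, 5e-5),  # e^{0.624}, the lag prefactor
            (50.0, 0.3, -1.5, 1.0, 1e-3),
            (0.0, 1.0, 2.0, math.exp(-2.0), 1e-12),
        ],
    )
    def test_anchor_values(self, t, mu, h0, expected, tol):
        assert adjustment(t, mu, h0) == pytest.approx(expected, abs=tol)

    def test_zero_h0_collapses_to_one(self):
        t = np.linspace(0, 40, 7)
        assert np.all(adjustment(t, 0.5, 0.0) == 1.0)

    def test_initial_value_is_exp_minus_h0(self):
        for h0 in (-3.0, -0.624, 0.1, 2.5):
            assert adjustment(0.0, 0.4, h0) == pytest.approx(math.exp(-h0), rel=1e-14)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        mu=st.floats(0.05, 2.0),
        h0=st.one_of(st.just(0.0), st.floats(-4.0, -1e-3), st.floats(1e-3, 4.0)),
        t1=st.floats(0.0, 50.0),
        dt=st.floats(0.01, 20.0),
    )
    def test_monotone_with_correct_sign_class(self, mu, h0, t1, dt):
        a1, a2 = adjustment(t1, mu, h0), adjustment(t1 + dt, mu, h0)
        resolvable = mu * t1 < 30  # beyond this alpha - 1 is below float resolution
        if h0 < 0:
            assert a1 >= 1.0 and a2 <= a1
            if resolvable:
                assert a1 > 1.0
        elif h0 > 0:
            assert 0.0 <= a1 <= 1.0 and a2 >= a1
            if resolvable:
                assert a1 < 1.0
        else:
            assert a1 == a2 == 1.0

    def test_limit_is_one(self):
        for mu, h0 in [(0.2, -2.0), (1.0, 3.0)]:
            assert abs(adjustment(35.0 / mu, mu, h0) - 1.0) < 1e-6

    @pytest.mark.parametrize("bad", [dict(t=-1.0), dict(mu_max=0.0), dict(h0=np.nan)])
    def test_invalid_inputs_rejected(self, bad):
        kwargs = dict(t=1.0, mu_max=0.3, h0=-0.5)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            adjustment(kwargs["t"], kwargs["mu_max"], kwargs["h0"])


class TestRightHandSides:
    def test_growth_zero_at_carrying_capacity(self):
        p = KineticParams(0.3, -1.0, 0.2, 0.1, 2.0)
        assert growth_rhs(2.0, 5.0, p) == 0.0

    def test_growth_late_time_logistic_value(self):
        # alpha ~ 1, X = Xmax/2: rate = mu/4 * Xmax
        p = KineticParams(0.3, -1.0, 0.2, 0.1, 4.0)
        assert growth_rhs(2.0, 500.0, p) == pytest.approx(0.075 * 4.0, rel=1e-6)

    def test_growth_hand_evaluated_at_t0(self):
        p = KineticParams(0.313, -0.624, 0.298, 0.002, 1.454)
        expected = 0.313 * math.exp(0.624) * (1 - 0.1 / 1.454) * 0.1
        assert growth_rhs(0.1, 0.0, p) == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize(
        "N, X, vm, KN, expected",
        [
            (0.0, 3.0, 0.285, 0.198, 0.0),
            (0.198, 1.0, 0.285, 0.198, -0.1425),  # half saturation
            (0.9, 1.0, 0.285, 0.198, -0.285 * 0.9 / 1.098),
        ],
    )
    def test_uptake_values(self, N, X, vm, KN, expected):
        p = KineticParams(0.3, 0.0, vm, KN, 5.0)
        assert uptake_rhs(N, X, p) == pytest.approx(expected, abs=1e-10)

    def test_uptake_rejects_negative_nitrogen(self):
        p = KineticParams(0.3, 0.0, 0.285, 0.198, 5.0)
        with pytest.raises(ValueError):
            uptake_rhs(-0.01, 1.0, p)

    def test_uptake_saturates_at_vm_X(self):
        p = KineticParams(0.3, 0.0, 0.285, 1e-4, 5.0)
        assert uptake_rhs(5.0, 2.0, p) == pytest.approx(-0.285 * 2.0, rel=1e-4)


class TestQuotaAndLipid:
    def test_time_zero_identity(self):
        assert nitrogen_quota(0.29, 0.9, 0.9, 0.05) == pytest.approx(0.05 / 0.29)

    @pytest.mark.parametrize(
        "X, N, N0, phi, expected",
        [(2.0, 0.0, 0.9, 0.05, 0.475), (6.71, 0.0, 0.9, 0.0495, 0.1415)],
    )
    def test_depleted_quota(self, X, N, N0, phi, expected):
        assert nitrogen_quota(X, N, N0, phi) == pytest.approx(expected, abs=5e-5)

    def test_quota_rejects_nonpositive_biomass(self):
        with pytest.raises(ValueError):
            nitrogen_quota(0.0, 0.5, 0.9, 0.05)

    def test_lipid_examples(self):
        comp = CompositionParams(2.120, 0.44, 0.05)
        assert lipid_content(0.0, comp) == pytest.approx(0.56)
        assert lipid_content(0.1415, comp) == pytest.approx(0.260, abs=1e-3)
        assert lipid_content((1 - 0.44) / 2.120, comp) == pytest.approx(0.0, abs=1e-12)

    def test_lipid_not_clamped(self):
        comp = CompositionParams(2.120, 0.44, 0.05)
        assert lipid_content(0.5, comp) < 0.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(q=st.floats(0.0, 1.0), dq=st.floats(0.001, 0.5))
    def test_lipid_decreasing_in_quota_with_slope_k(self, q, dq):
        comp = CompositionParams(2.0, 0.3, 0.0)
        drop = lipid_content(q, comp) - lipid_content(q + dq, comp)
        assert drop == pytest.approx(comp.k * dq, rel=1e-9)


@pytest.fixture(scope="module")
def ha1_09():
    p = KineticParams(0.264, -1.593, 0.285, 0.198, 6.738)
    comp = CompositionParams(2.119, 0.440, 0.050)
    return p, comp


class TestSimulate:
    def test_single_point_grid_returns_initial_state(self, ha1_09):
        p, comp = ha1_09
        s0 = BatchState(0.1, 0.9)
        traj = simulate(p, comp, s0, [0.0])
        assert len(traj) == 1
        assert traj.X[0] == 0.1 and traj.N[0] == 0.9
        assert traj.Q[0] == pytest.approx(comp.phi / 0.1)
        assert traj.L[0] == pytest.approx(1 - comp.k * comp.phi / 0.1 - comp.c)

    def test_no_uptake_leaves_nitrogen_constant(self):
        p = KineticParams(0.3, -1.0, 0.0, 0.1, 2.0)
        comp = CompositionParams(2.0, 0.40, 0.05)
        traj = simulate(p, comp, BatchState(0.2, 0.6), np.arange(0, 25, 1.0))
        assert np.allclose(traj.N, 0.6, atol=1e-9)
        assert np.all(np.diff(traj.Q) < 0)  # quota diluted by growth
        assert np.all(np.diff(traj.L) > 0)
        assert np.all(traj.L < 1 - comp.c)

    def test_nitrogen_depletes_within_expected_window(self, ha1_09):
        p, comp = ha1_09
        traj = simulate(p, comp, BatchState(0.1, 0.9), np.arange(0, 25, 0.5))
        depleted = traj.t[traj.N < 0.01 * 0.9]
        assert len(depleted) and 4.0 < depleted[0] <= 12.0

    def test_mass_balance_by_construction(self, ha1_09):
        p, comp = ha1_09
        s0 = BatchState(0.05, 0.9)
        traj = simulate(p, comp, s0, np.arange(0, 25, 1.0))
        gap = traj.Q * traj.X - comp.phi - (s0.N0 - traj.N)
        assert np.max(np.abs(gap)) < 1e-7

    def test_biomass_monotone_and_nitrogen_nonincreasing(self, ha1_09):
        p, comp = ha1_09
        traj = simulate(p, comp, BatchState(0.05, 0.9), np.arange(0, 25, 0.5))
        assert np.all(np.diff(traj.X) > 0)
        assert np.all(np.diff(traj.N) <= 1e-12)
        assert np.all(traj.N >= 0)

    def test_matches_closed_form_logistic_when_h0_zero(self):
        p = KineticParams(0.35, 0.0, 0.2, 0.1, 3.0)
        comp = CompositionParams(2.0, 0.4, 0.02)
        t = np.arange(0, 25, 1.0)
        traj = simulate(p, comp, BatchState(0.07, 0.6), t, rtol=1e-10, atol=1e-12)
        oracle = logistic_closed_form(t, 0.07, 0.35, 3.0)
        assert np.max(np.abs(traj.X / oracle - 1)) < 1e-6

    def test_saturated_uptake_limit_small_KN(self):
        # with KN -> 0, uptake runs at vm*X until nitrogen runs out
        p = KineticParams(0.3, -1.0, 0.25, 1e-8, 3.0)
        comp = CompositionParams(2.0, 0.4, 0.02)
        t = np.arange(0, 16.05, 0.05)
        traj = simulate(p, comp, BatchState(0.1, 0.6), t)
        consumed = 0.6 - traj.N
        supply = p.vm * np.concatenate(
            [[0.0], np.cumsum(0.5 * (traj.X[1:] + traj.X[:-1]) * np.diff(t))]
        )
        expected = np.minimum(0.6, supply)
        assert np.max(np.abs(consumed - expected)) < 5e-3

    def test_rk4_and_rk45_agree(self, ha1_09):
        p, comp = ha1_09
        s0 = BatchState(0.05, 0.9)
        t = np.arange(0, 25, 2.0)
        a = simulate(p, comp, s0, t, method="rk45", rtol=1e-9, atol=1e-11)
        b = simulate(p, comp, s0, t, method="rk4", rk4_step=0.01)
        assert np.allclose(a.X, b.X, rtol=1e-6)
        assert np.allclose(a.N, b.N, atol=1e-6)

    def test_rk4_is_bit_reproducible(self, ha1_09):
        p, comp = ha1_09
        s0 = BatchState(0.05, 0.9)
        t = np.arange(0, 25, 2.0)
        a = simulate(p, comp, s0, t, method="rk4")
        b = simulate(p, comp, s0, t, method="rk4")
        assert np.array_equal(a.X, b.X) and np.array_equal(a.N, b.N)

    @pytest.mark.parametrize("grid", [[], [1.0, 2.0], [0.0, 2.0, 1.0], [0.0, 0.0, 1.0]])
    def test_bad_grids_rejected(self, ha1_09, grid):
        p, comp = ha1_09
        with pytest.raises(ValueError):
            simulate(p, comp, BatchState(0.05, 0.9), grid)

    def test_csv_round_trip(self, ha1_09, tmp_path):
        p, comp = ha1_09
        traj = simulate(p, comp, BatchState(0.05, 0.9), np.arange(0, 25, 2.0))
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = Trajectory.from_csv(path)
        for field in ("t", "X", "N", "Q", "L"):
            assert np.allclose(getattr(traj, field), getattr(back, field), rtol=1e-15)
        assert path.read_text().splitlines()[0] == "t_days,X_gdw_per_L,N_g_per_L,Q_gN_per_gdw,L_frac"
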