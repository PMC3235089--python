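"""Quarterly dynamics: Baranov conditioning, aging, recruitment, spin-up."""

import numpy as np
import pytest
from scipy.optimize import brentq

from mast.config import default_config
from mast.dynamics import (DynamicsError, Trajectory, recruit, run_model,
                           solve_fleet_F, spawning_biomass, spin_up,
                           step_quarter)
from mast.equilibrium import DerivedStock, StockParams, derive_stock_recruit
from mast.movement import MovementParams, build_all_matrices

from conftest import toy_stock_params


def bisection_oracle(catch, N, sel_age, M_q, weight, f_cap=2.0):
    """Independent single-fleet Baranov solve by scipy brentq."""

    def pred(F):
        Z = M_q + F * sel_age
        Zs = np.maximum(Z, 1e-30)
        return float(np.sum(weight * N * F * sel_age / Zs * (1 - np.exp(-Z))))

    if pred(f_cap) <= catch:
        return f_cap
    return brentq(lambda F: pred(F) - catch, 0.0, f_cap, xtol=1e-14)


class TestSolveFleetF:
    def test_zero_catch_zero_F(self):
        F, short = solve_fleet_F(
            np.zeros(2), np.array([[1000.0]]), np.ones((2, 1)),
            np.array([[0.05]]), np.array([[1.0]]),
        )
        np.testing.assert_array_equal(F, 0.0)
        np.testing.assert_array_equal(short, 0.0)

    def test_single_fleet_against_bisection(self):
        # 1000*(F/(F+0.05))*(1-e^-(F+0.05)) = 100
        F, short = solve_fleet_F(
            np.array([100.0]), np.array([[1000.0]]), np.ones((1, 1)),
            np.array([[0.05]]), np.array([[1.0]]),
        )
        expected = bisection_oracle(100.0, np.array([1000.0]), np.ones(1),
                                    np.array([0.05]), np.ones(1))
        assert F[0] == pytest.approx(expected, rel=1e-7)
        assert short[0] == 0.0

    def test_more_fish_means_lower_F(self):
        args = (np.ones((1, 1)), np.array([[0.05]]), np.array([[1.0]]))
        F1, _ = solve_fleet_F(np.array([100.0]), np.array([[1000.0]]), *args)
        F2, _ = solve_fleet_F(np.array([100.0]), np.array([[2000.0]]), *args)
        assert F2[0] < F1[0]

    def test_impossible_catch_capped_with_shortfall(self):
        F, short = solve_fleet_F(
            np.array([5000.0]), np.array([[1000.0]]), np.ones((1, 1)),
            np.array([[0.05]]), np.array([[1.0]]), f_cap=2.0,
        )
        assert F[0] == 2.0
        assert short[0] > 0

    @pytest.mark.parametrize("seed", range(3))
    def test_multifleet_reproduces_catch(self, seed):
        rng = np.random.default_rng(seed)
        n_stocks, n_ages, n_fleets = 2, 8, 4
        N = rng.random((n_stocks, n_ages)) * 1e3
        sel = rng.random((n_fleets, n_ages))
        M_q = np.full((n_stocks, n_ages), 0.04)
        weight = np.cumsum(rng.random((n_stocks, n_ages)), axis=1)
        vb = (weight * N).sum()
        catch = rng.random(n_fleets) * vb * 0.02
        F, short = solve_fleet_F(catch, N, sel, M_q, weight)
        assert np.all(short == 0)
        # realized catch from the Baranov identity
        Fsel = np.einsum("f,fa->a", F, sel)
        Z = M_q + Fsel[None, :]
        em = (1 - np.exp(-Z)) / np.maximum(Z, 1e-30)
        for f in range(n_fleets):
            realized = np.sum(weight * N * F[f] * sel[f][None, :] * em)
            assert realized == pytest.approx(catch[f], rel=1e-6)


@pytest.fixture(scope="module")
def small_setup():
    """Small single-area-friendly config with flat biology."""
    cfg = default_config()
    agg = cfg.aggregate_selectivity()
    derived = {}
    for s, msy, fmsy in (("west", 3900.0, 0.15), ("east", 25000.0, 0.2)):
        b = cfg.biology[s]
        derived[s] = derive_stock_recruit(
            StockParams(msy, fmsy, b.M, b.weight, b.maturity, agg))
    matrices = build_all_matrices(MovementParams.uniform(cfg.structure, 0.7),
                                  cfg.biology, cfg.structure)
    return cfg, derived, matrices


class TestStepQuarter:
    def test_no_mortality_identity_movement_only_ages(self, small_setup):
        cfg, derived, _ = small_setup
        st = cfg.structure
        import copy

        cfg0 = default_config()
        for s in cfg0.biology:
            cfg0.biology[s].M[:] = 0.0
            cfg0.biology[s].maturity[:] = 0.0  # no recruitment feedback
        eye = {
            s: np.stack([np.stack([np.eye(st.n_stock_areas(s))] * 4)] *
                        st.n_groups)
            for s in st.stocks
        }
        N = np.zeros((st.n_stocks, st.n_ages, st.n_areas))
        N[0, 3, 0] = 7.0
        N[1, 5, 4] = 2.0
        out = N.copy()
        for q in (1, 2, 3):
            out, _, _, _, _ = step_quarter(out, q, cfg0, eye, derived)
            np.testing.assert_array_equal(out, N)
        out, _, _, _, _ = step_quarter(out, 4, cfg0, eye, derived)
        assert out[0, 4, 0] == 7.0 and out[0, 3, 0] == 0.0  # aged
        assert out[1, 6, 4] == 2.0

    def test_plus_group_accumulation(self, small_setup):
        cfg, derived, _ = small_setup
        st = cfg.structure
        cfg0 = default_config()
        for s in cfg0.biology:
            cfg0.biology[s].M[:] = 0.0
            cfg0.biology[s].maturity[:] = 0.0
        eye = {
            s: np.stack([np.stack([np.eye(st.n_stock_areas(s))] * 4)] *
                        st.n_groups)
            for s in st.stocks
        }
        N = np.zeros((st.n_stocks, st.n_ages, st.n_areas))
        A = st.max_age
        N[0, A - 1, 0] = 1.0
        N[0, A, 0] = 1.0
        out, _, _, _, _ = step_quarter(N, 4, cfg0, eye, derived)
        assert out[0, A, 0] == 2.0  # plus group accumulates

    def test_cohort_declines_exactly_exp_minus_M(self, small_setup):
        cfg, derived, matrices = small_setup
        st = cfg.structure
        N0 = spin_up(cfg, derived, matrices, years=2)
        traj = run_model(cfg, derived, matrices, init_state=N0, n_quarters=4)
        M = cfg.biology["west"].M[5]
        before = traj.N[0, 0, 5, :].sum()
        after = traj.N[4, 0, 6, :].sum()  # same cohort, one year later
        assert after / before == pytest.approx(np.exp(-M), rel=1e-10)

    def test_negative_state_rejected(self, small_setup):
        cfg, derived, matrices = small_setup
        st = cfg.structure
        N = -np.ones((st.n_stocks, st.n_ages, st.n_areas))
        with pytest.raises(DynamicsError):
            step_quarter(N, 1, cfg, matrices, derived)


class TestRecruit:
    @pytest.fixture
    def derived_toy(self):
        return derive_stock_recruit(toy_stock_params())

    def test_unfished_fixed_point(self, derived_toy):
        d = derived_toy
        assert recruit(d.S0, d) == pytest.approx(d.R0, rel=1e-12)

    def test_zero_spawners_zero_recruits(self, derived_toy):
        assert recruit(0.0, derived_toy) == 0.0

    def test_compensation_form_direct_evaluation(self, derived_toy):
        # kappa=4, S=S0/3: R = 4*R0*(1/3) / (1 + 3*(1/3)) = (2/3) R0
        d = DerivedStock(kappa=4.0, R0=derived_toy.R0, S0=derived_toy.S0,
                         B0=derived_toy.B0, Smsy=derived_toy.Smsy,
                         params=derived_toy.params)
        assert recruit(d.S0 / 3, d) == pytest.approx(2 * d.R0 / 3, rel=1e-12)


class TestEquilibriumConsistency:
    def test_spun_up_ssb_matches_S0(self, small_setup):
        cfg, derived, matrices = small_setup
        st = cfg.structure
        N0 = spin_up(cfg, derived, matrices)
        traj = run_model(cfg, derived, matrices, init_state=N0, n_quarters=8)
        for s in st.stocks:
            assert traj.ssb(s, st.first_year) == pytest.approx(
                derived[s].S0, rel=5e-3)

    def test_spin_up_is_fixed_point(self, small_setup):
        cfg, derived, matrices = small_setup
        N0 = spin_up(cfg, derived, matrices)
        N1 = N0.copy()
        for q in (1, 2, 3, 4):
            N1, _, _, _, _ = step_quarter(N1, q, cfg, matrices, derived)
        mask = N0 > 1e-9 * N0.max()
        rel = np.abs(N1[mask] - N0[mask]) / N0[mask]
        assert rel.max() < 1e-3

    def test_identity_movement_stays_in_spawning_area(self, small_setup):
        cfg, derived, _ = small_setup
        st = cfg.structure
        eye = {
            s: np.stack([np.stack([np.eye(st.n_stock_areas(s))] * 4)] *
                        st.n_groups)
            for s in st.stocks
        }
        N0 = spin_up(cfg, derived, eye, years=5)
        for si, s in enumerate(st.stocks):
            sp = st.area_index(st.spawning_area[s])
            total = N0[si].sum()
            assert N0[si, :, sp].sum() == pytest.approx(total, rel=1e-12)

    def test_uniform_movement_reaches_uniform_shares(self):
        # M = 0, no recruitment, uniform rows: stationary distribution 1/n
        cfg = default_config()
        st = cfg.structure
        for s in cfg.biology:
            cfg.biology[s].M[:] = 0.0
            cfg.biology[s].maturity[:] = 0.0
        uni = {
            s: np.full((st.n_groups, 4, st.n_stock_areas(s),
                        st.n_stock_areas(s)), 1.0 / st.n_stock_areas(s))
            for s in st.stocks
        }
        d = derive_stock_recruit(toy_stock_params())
        derived = {s: d for s in st.stocks}
        N = np.zeros((st.n_stocks, st.n_ages, st.n_areas))
        N[0, 5, 0] = 100.0
        for t in range(12):
            N, _, _, _, _ = step_quarter(N, t % 4 + 1, cfg, uni, derived)
        acc = st.accessible0("west")
        shares = N[0].sum(axis=0)[acc] / N[0].sum()
        np.testing.assert_allclose(shares, 0.25, rtol=1e-9)

    def test_never_fished_depletion_is_one(self, small_setup):
        cfg, derived, matrices = small_setup
        st = cfg.structure
        traj = run_model(cfg, derived, matrices)
        for s in st.stocks:
            depl = traj.ssb(s, st.last_year) / traj.ssb(s, st.first_year)
            assert depl == pytest.approx(1.0, abs=0.005)


class TestCatchConditioning:
    def test_realized_catch_matches_input(self, reduced_truth,
                                          reduced_dataset):
        catches, _, _ = reduced_dataset
        from mast.model import MASTModel

        model = MASTModel(catches, __import__("mast").ObservationBundle(),
                          reduced_truth.config)
        traj, _, _ = model.evaluate(reduced_truth.params)
        for t in range(traj.n_steps):
            observed = catches.at_quarter(t)
            m = observed > 1e-6
            if not m.any():
                continue
            realized = traj.realized_catch(t)
            np.testing.assert_allclose(realized[m], observed[m], rtol=1e-3)

    def test_spawning_biomass_units(self, small_setup):
        # 1000 (thousands) mature fish of 10 kg = 10 kt
        cfg, derived, matrices = small_setup
        st = cfg.structure
        cfg1 = default_config()
        for s in cfg1.biology:
            cfg1.biology[s].maturity[:] = 0.0
            cfg1.biology[s].weight[:] = 10.0
        cfg1.biology["west"].maturity[8] = 1.0
        N = np.zeros((8 + 1, st.n_stocks, st.n_ages, st.n_areas))
        N[:, 0, 8, 0] = 1000.0
        traj = Trajectory(cfg1, derived, N,
                          np.zeros((8, st.n_fleets, st.n_areas)),
                          np.zeros((8, st.n_stocks, st.n_ages, st.n_areas)),
                          np.zeros((8, st.n_stocks)))
        assert spawning_biomass(traj, "west", st.first_year) == pytest.approx(
            10_000.0)
        # zero maturity stock has zero SSB
        assert spawning_biomass(traj, "east", st.first_year) == 0.0
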