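"""Electronic-tag hidden-Markov likelihood: transitions, forward recursion
vs path enumeration, and track simulation."""

import numpy as np
import pytest

from mast.config import default_config
from mast.dynamics import Trajectory
from mast.io import TagTrack
from mast.movement import gravity_matrix
from mast.tag_hmm import (TagDynamics, TagError, build_transition,
                          simulate_track, track_loglik,
                          track_loglik_bruteforce)


class TestBuildTransition:
    def test_no_absorption_reduces_to_movement(self):
        mat = gravity_matrix(np.array([0.7, 0.6, 0.5, 0.8]), 4)
        T = build_transition(mat, np.zeros(4), np.zeros(4), 0.0)
        np.testing.assert_allclose(T[:4, :4], mat, rtol=1e-15)
        np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)

    def test_certain_shedding_absorbs_everything(self):
        mat = gravity_matrix(np.full(3, 0.5), 3)
        T = build_transition(mat, np.zeros(3), np.zeros(3), 1.0)
        np.testing.assert_allclose(T[:3, 5], 1.0)  # shed column
        np.testing.assert_allclose(T[:3, :5], 0.0, atol=1e-15)

    def test_row_arithmetic(self):
        # u=0.1, d=0.05, shed=0.02, movement row [0.7,0.1,0.1,0.1]:
        # alive part 0.83*row, captured 0.1, dead 0.05, shed 0.02
        mat = gravity_matrix(np.full(4, 0.7), 4)
        T = build_transition(mat, np.full(4, 0.1), np.full(4, 0.05), 0.02)
        np.testing.assert_allclose(T[0, :4], 0.83 * mat[0], rtol=1e-12)
        assert T[0, 4] == pytest.approx(0.1)
        assert T[0, 5] == pytest.approx(0.05)
        assert T[0, 6] == pytest.approx(0.02)
        np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)
        # absorbing rows are unit rows
        np.testing.assert_array_equal(T[4:, 4:], np.eye(3))

    def test_overcommitted_rates_rejected(self):
        mat = gravity_matrix(np.full(3, 0.5), 3)
        with pytest.raises(TagError):
            build_transition(mat, np.full(3, 0.6), np.full(3, 0.5), 0.1)


def make_tag_dynamics(u_level=0.0, shed=0.02, p_obs=0.9, n_years=6,
                      five_area_stock=False, zero_m=False):
    """Hand-built trajectory giving full control over exploitation.

    F and selectivity are chosen so each area's exploitation fraction is
    u_level for every age.
    """
    from mast.structure import FleetParams, ModelStructure

    kwargs = {"first_year": 2000, "last_year": 2000 + n_years - 1,
              "max_age": 10}
    if five_area_stock:
        kwargs["stock_area_sets"] = {"west": (1, 2, 3, 4, 5),
                                     "east": (3, 4, 5)}
    st = ModelStructure(**kwargs)
    cfg = default_config(structure=st)
    if zero_m:
        for s in cfg.biology:
            cfg.biology[s].M[:] = 0.0
    # flat selectivity = 1 for fleet 0 so u is age-independent
    cfg.fleet_params = FleetParams(a50=np.full(4, -50.0), slope=np.ones(4))
    T = st.n_quarters
    N = np.ones((T + 1, st.n_stocks, st.n_ages, st.n_areas))
    F = np.zeros((T, st.n_fleets, st.n_areas))
    Z = np.zeros((T, st.n_stocks, st.n_ages, st.n_areas))
    Mq = np.stack([cfg.biology[s].M for s in st.stocks]) / 4
    if u_level > 0:
        # solve F so that (F/Z)(1-e^-Z) = u with Z = Mq + F
        from scipy.optimize import brentq

        for si in range(st.n_stocks):
            for a in range(st.n_ages):
                m = Mq[si, a]
                f = brentq(
                    lambda f: f / (f + m) * (1 - np.exp(-(f + m))) - u_level,
                    1e-12, 10.0,
                )
                Z[:, si, a, :] = m + f
        F[:, 0, :] = Z[0, 0, 0, 0] - Mq[0, 0]
        # make both stocks' M equal so one F produces u for both
        for s in st.stocks:
            cfg.biology[s].M[:] = cfg.biology[st.stocks[0]].M[:]
    else:
        Z[:] = Mq[None, :, :, None]
        F[:] = 0.0
        Z[:] = Mq[None, :, :, None]
    traj = Trajectory(cfg, {}, N, F, Z, np.zeros((T, st.n_stocks)))
    from mast.movement import MovementParams, build_all_matrices

    mats = build_all_matrices(MovementParams.uniform(st, 0.7), cfg.biology, st)
    return TagDynamics(traj, mats, shed, p_obs)


class TestTrackLoglik:
    def test_single_step_psat_staying(self):
        dyn = make_tag_dynamics(u_level=0.0, shed=0.02, p_obs=0.9)
        T = dyn.transition("west", 5, 0, 0)
        stay = T[0, 0]
        track = TagTrack("t", "psat", "GoM", 2000, 1, 5, stock="west",
                         observations=["GoM", "GoM"])
        assert track_loglik(track, dyn) == pytest.approx(np.log(stay),
                                                         rel=1e-12)

    def test_forward_equals_bruteforce_random_tracks(self):
        dyn = make_tag_dynamics(u_level=0.05, shed=0.03, p_obs=0.8,
                                five_area_stock=True)
        st = dyn.st
        rng = np.random.default_rng(42)
        areas_west = [st.areas[j] for j in st.accessible0("west")]
        for _ in range(40):
            L = int(rng.integers(2, 5))
            a0 = str(rng.choice(areas_west))
            obs = [a0]
            for _ in range(L - 1):
                r = rng.random()
                if r < 0.3:
                    obs.append(None)
                else:
                    obs.append(str(rng.choice(areas_west)))
            tag_type = "archival" if any(o is None for o in obs) else (
                "psat" if rng.random() < 0.5 else "archival")
            stock = ["west", "east", "unknown"][int(rng.integers(0, 3))]
            if stock == "east" and not set(
                    o for o in obs if o) <= {"WAtl", "EAtl", "Med"}:
                stock = "west"
            track = TagTrack("t", tag_type, a0, 2001,
                             int(rng.integers(1, 5)), int(rng.integers(2, 10)),
                             stock=stock, observations=obs)
            ll_fwd = track_loglik(track, dyn)
            ll_bf = track_loglik_bruteforce(track, dyn)
            if np.isfinite(ll_fwd) or np.isfinite(ll_bf):
                assert ll_fwd == pytest.approx(ll_bf, rel=1e-10)

    def test_fully_observed_archival_with_pobs_one_equals_psat(self):
        dyn = make_tag_dynamics(u_level=0.05, shed=0.02, p_obs=1.0)
        obs = ["GoM", "WAtl", "WAtl", "GSL"]
        arch = TagTrack("a", "archival", "GoM", 2001, 2, 6, "west", obs)
        psat = TagTrack("p", "psat", "GoM", 2001, 2, 6, "west", list(obs))
        assert track_loglik(arch, dyn) == pytest.approx(
            track_loglik(psat, dyn), rel=1e-14)

    def test_inaccessible_area_forced_stock_is_impossible(self):
        dyn = make_tag_dynamics()
        track = TagTrack("t", "psat", "GoM", 2001, 1, 5, "east",
                         observations=["GoM", "GoM"])
        assert track_loglik(track, dyn) == -np.inf


class TestSimulateTrack:
    def test_certain_shedding_ends_after_one_quarter(self):
        dyn = make_tag_dynamics(shed=1.0, zero_m=True)
        rng = np.random.default_rng(0)
        for _ in range(20):
            tr = simulate_track("GoM", 2001, 1, 5, "west", "psat", dyn, rng,
                                horizon_quarters=8)
            assert tr.n_quarters == 1

    def test_capture_fraction_matches_exploitation(self):
        dyn = make_tag_dynamics(u_level=0.1, shed=0.0)
        rng = np.random.default_rng(7)
        T = dyn.transition("west", 5, 0, 0)
        n = len(dyn._acc["west"])
        assert T[0, n] == pytest.approx(0.1, rel=1e-6)
        captured = 0
        trials = 10_000
        state_draws = rng.choice(n + 3, size=trials, p=T[0])
        captured = int(np.sum(state_draws == n))
        assert captured / trials == pytest.approx(0.1, abs=0.01)

    def test_same_seed_identical_tracks(self):
        dyn = make_tag_dynamics(u_level=0.05, shed=0.02, p_obs=0.8)
        t1 = simulate_track("GoM", 2001, 1, 5, "west", "archival", dyn,
                            np.random.default_rng(99), horizon_quarters=10)
        t2 = simulate_track("GoM", 2001, 1, 5, "west", "archival", dyn,
                            np.random.default_rng(99), horizon_quarters=10)
        assert t1.observations == t2.observations

    def test_occupancy_matches_chain_marginals(self):
        # Monte-Carlo state frequencies vs transition-matrix powers
        dyn = make_tag_dynamics(u_level=0.0, shed=0.0, p_obs=1.0)
        rng = np.random.default_rng(5)
        n = len(dyn._acc["west"])
        counts = np.zeros(n)
        trials = 10_000
        for _ in range(trials):
            tr = simulate_track("GoM", 2001, 1, 5, "west", "psat", dyn, rng,
                                horizon_quarters=3)
            if tr.n_quarters >= 3:
                j = [dyn.st.areas[k] for k in dyn._acc["west"]].index(
                    tr.observations[2])
                counts[j] += 1
        T1 = dyn.transition("west", 5, 0, 0)
        T2 = dyn.transition("west", 5, 0, 1)
        marg = (np.eye(n + 3)[0] @ T1 @ T2)[:n]
        marg = marg / marg.sum()
        freq = counts / counts.sum()
        # chi-square sanity: large-sample frequencies close to marginals
        chi2 = trials * np.sum((freq - marg) ** 2 / marg)
        assert chi2 < 20.0
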