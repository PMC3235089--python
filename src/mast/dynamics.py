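"""Quarterly state dynamics conditioned on observed catches.

The central state is numbers-at-age (thousands of fish) by stock x age x
area, censused at the start of each calendar quarter.  Within a quarter the
update order is: fishing + natural mortality (with fleet fishing rates
solved from the observed catch via the Baranov equation), then movement,
then recruitment (in the spawning quarter, from spawning biomass at the
start-of-quarter census, discounted by one quarter of age-0 natural
mortality so that the quarterly discretization reproduces the annual
per-recruit survivorship used by the equilibrium derivation); ages
increment at the year boundary with plus-group accumulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ModelConfig
from .equilibrium import DerivedStock, beverton_holt
from .io import CatchArray
from .movement import check_row_stochastic

__all__ = ["Trajectory", "solve_fleet_F", "run_model", "spin_up",
           "step_quarter", "spawning_biomass", "recruit"]


class DynamicsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Baranov catch conditioning
# ---------------------------------------------------------------------------


def _pred_catch_and_slope(F, s_f, z_other, wN):
    """Baranov catch biomass for one fleet and its derivative wrt F.

    s_f: selectivity (flat); z_other: quarterly mortality from natural
    causes and the other fleets (flat); wN: weight * numbers (flat).
    Entries with zero total mortality contribute nothing (selectivity 0).
    """
    u = F * s_f
    Z = z_other + u
    Zs = np.maximum(Z, 1e-300)
    em = -np.expm1(-Z)
    pred = float(np.dot(wN, u / Zs * em))
    slope = float(np.dot(wN * s_f, (z_other / Zs**2) * em + (u / Zs) * np.exp(-Z)))
    return pred, slope


def solve_fleet_F(
    catch_tonnes: np.ndarray,
    N: np.ndarray,
    sel: np.ndarray,
    M_quarter: np.ndarray,
    weight: np.ndarray,
    f_cap: float = 2.0,
    tol: float = 1e-8,
    max_sweeps: int = 50,
    sel_tiled: np.ndarray = None,
):
    """Solve per-fleet quarterly fishing mortality from catch in one area.

    Parameters
    ----------
    catch_tonnes : array [fleet]
    N : array [stock, age] — numbers (thousands) present in the area
    sel : array [fleet, age]
    M_quarter : array [stock, age] — quarterly natural mortality M/4
    weight : array [stock, age] — kg

    Returns (F [fleet], shortfall [fleet]): F solves the Baranov equation
    sum_a w_a N_a (F s_a / Z_a)(1 - e^-Z_a) = catch per fleet, coupled
    across fleets through Z and resolved by Gauss-Seidel sweeps of
    safeguarded Newton steps.  F is capped at f_cap; any catch that cannot
    be taken even at the cap is returned as a shortfall (tonnes).
    """
    n_fleets = catch_tonnes.shape[0]
    F = np.zeros(n_fleets)
    shortfall = np.zeros(n_fleets)
    active = np.nonzero(catch_tonnes > 0)[0]
    if active.size == 0:
        return F, shortfall
    wN = (weight * N).ravel()
    if wN.sum() <= 0:
        return F, catch_tonnes.copy()
    n_stocks = N.shape[0]
    if sel_tiled is None:
        sel_tiled = np.tile(sel, (1, n_stocks))
    S = sel_tiled[active]  # [active fleet, stock*age]
    Mq_flat = M_quarter.ravel()
    target = catch_tonnes[active]

    # joint Newton over the active fleets (coupled through Z)
    vuln = S @ wN
    x = np.minimum(target / np.maximum(vuln, 1e-300), f_cap)
    k = active.size
    diag = np.arange(k)
    tol_vec = tol * np.maximum(target, 1.0)
    ok = False
    for _ in range(40):
        U = x[:, None] * S
        Z = Mq_flat + U.sum(axis=0)
        Zs = np.maximum(Z, 1e-300)
        em = -np.expm1(-Z)
        G = em / Zs
        wNG = wN * G
        pred = U @ wNG
        err = pred - target
        if float(np.max(np.abs(err) - tol_vec)) <= 0.0:
            ok = True
            break
        B = wN * (Z * np.exp(-Z) - em) / Zs**2
        J = (U * B[None, :]) @ S.T
        J[diag, diag] += S @ wNG
        try:
            step = np.linalg.solve(J, err)
        except np.linalg.LinAlgError:
            break
        x_new = x - step
        np.clip(x_new, 0.0, f_cap, out=x_new)
        if float(np.max(np.abs(x_new - x))) <= 1e-14:
            ok = bool(np.all(x_new < f_cap))
            x = x_new
            break
        x = x_new
    if ok:
        F[active] = x
        return F, shortfall

    # safeguarded per-fleet fallback (handles caps and hard cases)
    sel_flat = {f: sel_tiled[f] for f in active}
    vuln0 = {f: float(np.dot(wN, sel_flat[f])) for f in active}
    F[:] = 0.0
    for sweep in range(max_sweeps):
        max_delta = 0.0
        for f in active:
            s_f = sel_flat[f]
            z_other = Mq_flat.copy()
            for f2 in active:
                if f2 != f and F[f2] > 0:
                    z_other += F[f2] * sel_flat[f2]
            target = catch_tonnes[f]
            lo, hi = 0.0, f_cap
            x = F[f] if F[f] > 0 else min(target / max(vuln0[f], 1e-300), f_cap)
            x = min(max(x, 1e-12), f_cap)
            capped = False
            for _ in range(100):
                pred, slope = _pred_catch_and_slope(x, s_f, z_other, wN)
                err = pred - target
                if err < 0:
                    lo = x
                else:
                    hi = x
                if abs(err) <= tol * max(target, 1.0):
                    break
                step = err / slope if slope > 0 else 0.0
                x_new = x - step
                if x_new >= f_cap:
                    # check whether the catch is takeable at all
                    pred_cap, _ = _pred_catch_and_slope(f_cap, s_f, z_other, wN)
                    if pred_cap <= target:
                        x = f_cap
                        shortfall[f] = target - pred_cap
                        capped = True
                        break
                    hi = f_cap
                    x_new = 0.5 * (lo + hi)
                elif not lo < x_new < hi:
                    x_new = 0.5 * (lo + hi)
                if x_new == x:
                    break
                x = x_new
            if not capped:
                shortfall[f] = 0.0
            max_delta = max(max_delta, abs(x - F[f]))
            F[f] = x
        if max_delta < 1e-10 or active.size == 1:
            break
    return F, shortfall


# ---------------------------------------------------------------------------
# trajectory container
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Stored output of one model run.

    N is censused at the start of each quarter, with one extra slice for the
    state after the final quarter; F and Z are per step.
    """

    config: ModelConfig
    derived: dict  # stock -> DerivedStock
    N: np.ndarray  # [T+1, stock, age, area]
    F: np.ndarray  # [T, fleet, area] quarterly rates
    Z: np.ndarray  # [T, stock, age, area] quarterly total mortality
    recruits: np.ndarray  # [T, stock] thousands entering at age 0
    first_year: int = None
    shortfalls: list = field(default_factory=list)  # (t, fleet, area, tonnes)

    def __post_init__(self):
        if self.first_year is None:
            self.first_year = self.config.structure.first_year

    @property
    def n_steps(self) -> int:
        return self.F.shape[0]

    def t_index(self, year: int, quarter: int) -> int:
        t = 4 * (year - self.first_year) + quarter - 1
        if not 0 <= t < self.n_steps:
            raise DynamicsError(f"{year}Q{quarter} outside this run")
        return t

    def ssb(self, stock: str, year: int) -> float:
        """Spawning biomass (tonnes): mature biomass over all areas at the
        stock's spawning-quarter census."""
        return spawning_biomass(self, stock, year)

    def ssb_series(self, stock: str) -> np.ndarray:
        years = self.first_year + np.arange(self.n_steps // 4)
        return np.array([self.ssb(stock, y) for y in years])

    def total_numbers(self, stock: str, t: int) -> float:
        si = self.config.structure.stock_index(stock)
        return float(self.N[t, si].sum())

    def vulnerable_numbers(self, t: int, area_idx: int, sel_age: np.ndarray):
        """Per-stock selectivity-weighted numbers in one area at census t."""
        return np.einsum("sa,a->s", self.N[t, :, :, area_idx], sel_age)

    def catch_at_age_numbers(self, t: int) -> np.ndarray:
        """Predicted catch numbers [stock, age, area] at step t, all fleets."""
        cfg = self.config
        sel = cfg.selectivity_matrix()
        Ftot = np.einsum("fj,fa->aj", self.F[t], sel)  # [age, area]
        Z = self.Z[t]
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(Z > 0, -np.expm1(-Z) / Z, 0.0)
        return self.N[t] * Ftot[None, :, :] * frac

    def exploitation(self, t: int, age, fleet_idx=None) -> np.ndarray:
        """Exploitation fraction u [stock, area] at step t for one age.

        With fleet_idx None, all fleets combined.
        """
        cfg = self.config
        sel = cfg.selectivity_matrix()[:, age]  # [fleet]
        Z = self.Z[t][:, age, :]  # [stock, area]
        if fleet_idx is None:
            Fsel = np.einsum("f,fj->j", sel, self.F[t])  # [area]
        else:
            Fsel = self.F[t][fleet_idx] * sel[fleet_idx]
        return Fsel[None, :] / np.maximum(Z, 1e-300) * (-np.expm1(-Z))

    def realized_catch(self, t: int) -> np.ndarray:
        """Realized catch biomass [fleet, area] implied by the solved F."""
        cfg = self.config
        st = cfg.structure
        sel = cfg.selectivity_matrix()
        w = np.stack([cfg.biology[s].weight for s in st.stocks])
        Z = self.Z[t]
        with np.errstate(divide="ignore", invalid="ignore"):
            em = np.where(Z > 0, -np.expm1(-Z) / Z, 0.0)
        # catch_f = sum_{s,a} w N F s_f em
        return np.einsum(
            "fj,fa,saj->fj", self.F[t], sel, w[:, :, None] * self.N[t] * em
        )


def spawning_biomass(traj: Trajectory, stock: str, year: int) -> float:
    cfg = traj.config
    st = cfg.structure
    si = st.stock_index(stock)
    t = traj.t_index(year, st.spawning_quarter[stock])
    bio = cfg.biology[stock]
    return float(np.einsum("aj,a->", traj.N[t, si], bio.maturity * bio.weight))


def recruit(ssb: float, derived: DerivedStock, deviation: float = 0.0,
            sigma_r: float = 0.0) -> float:
    """Beverton-Holt recruits (thousands) with optional lognormal deviation.

    A non-zero deviation multiplies recruitment by exp(dev - sigma_r^2/2)
    (bias-corrected so deviations are mean-one on the natural scale).
    """
    r = float(beverton_holt(ssb, derived.kappa, derived.R0, derived.S0))
    if deviation != 0.0 or sigma_r > 0.0:
        r *= np.exp(deviation - 0.5 * sigma_r**2)
    return r


# ---------------------------------------------------------------------------
# the quarterly step and full runs
# ---------------------------------------------------------------------------


def _run_context(cfg: ModelConfig) -> dict:
    """Precomputed per-run quantities shared by every quarterly step."""
    st = cfg.structure
    return {
        "M_q": np.stack([cfg.biology[s].M for s in st.stocks]) / 4.0,
        "weight": np.stack([cfg.biology[s].weight for s in st.stocks]),
        "acc": {s: st.accessible0(s) for s in st.stocks},
        "sel": (sel := cfg.selectivity_matrix()),
        "sel_tiled": np.tile(sel, (1, len(st.stocks))),
        # age groups are contiguous by construction, so slices suffice
        "group_ages": [
            slice(lo, hi + 1) for lo, hi in st.movement_age_groups
        ],
        "acc_ix": {
            s: (slice(a[0], a[-1] + 1)
                if np.all(np.diff(a) == 1) else a)
            for s, a in ((s, st.accessible0(s)) for s in st.stocks)
        },
    }


def step_quarter(
    N: np.ndarray,
    quarter: int,
    cfg: ModelConfig,
    matrices: dict,
    derived: dict,
    catch_slice: np.ndarray = None,
    rec_dev: dict = None,
    sigma_r: float = 0.0,
    F_slice: np.ndarray = None,
    ctx: dict = None,
):
    """Advance the census one quarter.

    Fishing enters either through ``catch_slice`` [fleet, area] (tonnes;
    quarterly F solved by the Baranov conditioning) or directly through
    ``F_slice`` [fleet, area] (quarterly rates, used when simulating under
    an effort scenario).  Returns (N_next, F, Z, recruits, shortfalls);
    aging is applied when quarter == 4.
    """
    st = cfg.structure
    if ctx is None:
        ctx = _run_context(cfg)
    M_q, weight, acc, sel = (ctx["M_q"], ctx["weight"], ctx["acc"],
                             ctx["sel"])
    n_fleets, n_areas = st.n_fleets, st.n_areas

    if np.any(N < 0):
        raise DynamicsError("negative state entering step")

    F = np.zeros((n_fleets, n_areas))
    shortfalls = []
    if F_slice is not None:
        F = np.asarray(F_slice, float).copy()
    elif catch_slice is not None:
        for j in range(n_areas):
            if catch_slice[:, j].sum() <= 0:
                continue
            Fj, short = solve_fleet_F(
                catch_slice[:, j], N[:, :, j], sel, M_q, weight,
                f_cap=cfg.f_cap, sel_tiled=ctx.get("sel_tiled"),
            )
            F[:, j] = Fj
            for f in np.nonzero(short > 0)[0]:
                shortfalls.append((f, j, float(short[f])))

    Fsel = np.einsum("fj,fa->aj", F, sel)  # [age, area]
    Z = M_q[:, :, None] + Fsel[None, :, :]  # [stock, age, area]

    # spawning biomass from the start-of-quarter census
    recs = np.zeros(st.n_stocks)
    for si, stock in enumerate(st.stocks):
        if quarter == st.spawning_quarter[stock]:
            bio = cfg.biology[stock]
            ssb = float(np.einsum("aj,a->", N[si], bio.maturity * bio.weight))
            dev = 0.0 if rec_dev is None else rec_dev.get(stock, 0.0)
            recs[si] = recruit(ssb, derived[stock], dev, sigma_r)

    # survival, then movement
    N1 = N * np.exp(-Z)
    N2 = N1.copy()
    for si, stock in enumerate(st.stocks):
        ix = ctx["acc_ix"][stock]
        for g, ages in enumerate(ctx["group_ages"]):
            N2[si, ages, ix] = N1[si, ages, ix] @ matrices[stock][g, quarter - 1]

    # recruits enter at age 0 in the spawning area, discounted one quarter
    # of age-0 natural mortality (birth at the census of the spawning quarter)
    for si, stock in enumerate(st.stocks):
        if recs[si] > 0:
            sp = st.area_index(st.spawning_area[stock])
            N2[si, 0, sp] += recs[si] * np.exp(-M_q[si, 0])

    if quarter == 4:
        N3 = np.zeros_like(N2)
        N3[:, 1:, :] = N2[:, :-1, :]
        N3[:, -1, :] += N2[:, -1, :]  # plus-group accumulation
        N2 = N3

    if np.any(N2 < 0):
        raise DynamicsError("negative state produced by step")
    return N2, F, Z, recs, shortfalls


def run_model(
    cfg: ModelConfig,
    derived: dict,
    matrices: dict,
    catches: CatchArray = None,
    init_state: np.ndarray = None,
    n_quarters: int = None,
    first_year: int = None,
    rec_devs: dict = None,
    sigma_r: float = 0.0,
    F_given: np.ndarray = None,
) -> Trajectory:
    """Run the quarterly dynamics over a horizon, conditioned on catches.

    rec_devs maps stock -> array of per-year lognormal recruitment
    deviations (already on log scale).  ``F_given`` [T, fleet, area]
    bypasses the catch conditioning with specified quarterly rates.
    """
    st = cfg.structure
    for stock in st.stocks:
        for g in range(st.n_groups):
            for q in range(4):
                check_row_stochastic(matrices[stock][g, q])
    if n_quarters is None:
        if F_given is not None:
            n_quarters = F_given.shape[0]
        elif catches is not None:
            n_quarters = catches.tonnes.shape[2] * 4
        else:
            n_quarters = st.n_quarters
    if first_year is None:
        first_year = st.first_year
    if init_state is None:
        init_state = spin_up(cfg, derived, matrices)

    T = n_quarters
    N = np.zeros((T + 1, st.n_stocks, st.n_ages, st.n_areas))
    F = np.zeros((T, st.n_fleets, st.n_areas))
    Z = np.zeros((T, st.n_stocks, st.n_ages, st.n_areas))
    recs = np.zeros((T, st.n_stocks))
    N[0] = init_state
    traj = Trajectory(cfg, derived, N, F, Z, recs, first_year=first_year)

    ctx = _run_context(cfg)
    for t in range(T):
        q = t % 4 + 1
        catch_slice = catches.at_quarter(t) if catches is not None else None
        dev = None
        if rec_devs is not None:
            iy = t // 4
            dev = {s: rec_devs[s][iy] for s in rec_devs if iy < len(rec_devs[s])}
        N[t + 1], F[t], Z[t], recs[t], short = step_quarter(
            N[t], q, cfg, matrices, derived, catch_slice, dev, sigma_r,
            F_slice=None if F_given is None else F_given[t], ctx=ctx,
        )
        for f, j, tonnes in short:
            traj.shortfalls.append((t, f, j, tonnes))
    return traj


def spin_up(cfg: ModelConfig, derived: dict, matrices: dict,
            years: int = None) -> np.ndarray:
    """Unfished equilibration: seed each stock's spawning area with its
    unfished numbers-at-age and run the dynamics with no fishing until the
    spatial distribution has equilibrated (default 25 years).  Returns the
    quarter-1 census state [stock, age, area]."""
    st = cfg.structure
    if years is None:
        years = cfg.spinup_years
    N = np.zeros((st.n_stocks, st.n_ages, st.n_areas))
    for si, stock in enumerate(st.stocks):
        sp = st.area_index(st.spawning_area[stock])
        # translate the spawning-quarter-census unfished age structure to a
        # quarter-1 census: cohorts are (q_spawn - 1) quarters younger than
        # at their birth-quarter census, and the new cohort does not yet
        # exist at Q1 (ages increment at the year boundary)
        qs = st.spawning_quarter[stock]
        la = derived[stock].unfished_numbers()
        M = cfg.biology[stock].M
        N[si, 1:, sp] = la[1:] * np.exp(M[1:] * (qs - 1) / 4.0)
    ctx = _run_context(cfg)
    for t in range(4 * years):
        q = t % 4 + 1
        N, _, _, _, _ = step_quarter(N, q, cfg, matrices, derived, ctx=ctx)
    return N
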