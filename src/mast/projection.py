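"""Forward projection of posterior draws under management scenarios.

Five catch scenarios are predefined, mirroring the management alternatives
considered for Atlantic bluefin tuna: (i) complete fishery closure;
(ii) rebuilding quotas of 1750 t west / 12,900 t east of the 45 degree
meridian with no Gulf of Mexico closure; (iii) the same quotas with a Gulf
of Mexico closure and its catch redistributed to the western Atlantic;
(iv) doubled eastern quota (25,800 t); and (v) eastern overfishing at
60,000 t.  In the model's areas the western side is areas 1-3 and the
eastern side areas 4-5.  Future annual side totals are distributed over
fleet/area/quarter cells by the mean allocation of the last five data
years.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dynamics import run_model
from .inference import summarize_draws
from .io import CatchArray

__all__ = ["Scenario", "SCENARIOS", "scenario_catches", "project_draws",
           "ProjectionResults"]

WEST_SIDE = ("GoM", "GSL", "WAtl")
EAST_SIDE = ("EAtl", "Med")


@dataclass(frozen=True)
class Scenario:
    id: str
    west_catch: float  # tonnes / yr
    east_catch: float  # tonnes / yr
    gom_closure: bool = False
    horizon: int = 2025

    def __post_init__(self):
        if self.west_catch < 0 or self.east_catch < 0:
            raise ValueError("scenario catches must be non-negative")


SCENARIOS = {
    "i": Scenario("i", 0.0, 0.0),
    "ii": Scenario("ii", 1750.0, 12900.0),
    "iii": Scenario("iii", 1750.0, 12900.0, gom_closure=True),
    "iv": Scenario("iv", 1750.0, 25800.0),
    "v": Scenario("v", 1750.0, 60000.0),
}


def _allocation_shares(historical: CatchArray, side_areas, n_recent: int = 5):
    """Mean fleet/area/quarter allocation shares within one side."""
    st = historical.structure
    idx = [st.area_index(a) for a in side_areas]
    recent = historical.tonnes[:, idx, -n_recent:, :]  # [fleet, side, yr, q]
    mean = recent.mean(axis=2)
    total = mean.sum()
    if total <= 0:
        return None, idx
    return mean / total, idx


def scenario_catches(scenario: Scenario, historical: CatchArray):
    """Future CatchArray for a scenario, allocated by historical shares.

    Returns (catches, projection_structure); the structure spans the year
    after the data horizon through the scenario horizon.  With a Gulf of
    Mexico closure, area-1 shares move to the western Atlantic (area 3) so
    the western side total is preserved exactly.
    """
    st = historical.structure
    proj_structure = replace(st, first_year=st.last_year + 1,
                             last_year=scenario.horizon)
    if proj_structure.last_year < proj_structure.first_year:
        raise ValueError("scenario horizon does not extend past the data")
    out = CatchArray.zeros(proj_structure)
    for side_areas, annual in ((WEST_SIDE, scenario.west_catch),
                               (EAST_SIDE, scenario.east_catch)):
        if annual <= 0:
            continue
        shares, idx = _allocation_shares(historical, side_areas)
        if shares is None:
            warnings.warn(
                f"no historical catch on side {side_areas}; uniform allocation"
            )
            shares = np.full((st.n_fleets, len(idx), 4),
                             1.0 / (st.n_fleets * len(idx) * 4))
        if scenario.gom_closure and "GoM" in side_areas:
            gom = side_areas.index("GoM")
            watl = side_areas.index("WAtl")
            shares = shares.copy()
            shares[:, watl, :] += shares[:, gom, :]
            shares[:, gom, :] = 0.0
        for iy in range(proj_structure.n_years):
            out.tonnes[:, idx, iy, :] = annual * shares
    return out, proj_structure


def project_draws(runs, scenario: Scenario, historical: CatchArray,
                  seed: int = 0, sigma_r: float = 0.0) -> "ProjectionResults":
    """Project each posterior run forward under a scenario.

    ``runs`` is a list of (params, trajectory, matrices, derived) as
    returned by :meth:`PosteriorResults.derived_runs` (or a single MAP
    results object's components); ``historical`` is the conditioning catch
    series, used for the future allocation shares.  Each draw continues
    from its own terminal state (the census after the final data quarter)
    with catch-conditioned dynamics; recruitment deviations are off by
    default (median-deterministic projections), or lognormal with
    ``sigma_r``.
    """
    trajectories = []
    rng = np.random.default_rng(seed)
    catches, proj_structure = scenario_catches(scenario, historical)
    for params, traj, matrices, derived in runs:
        cfg0 = traj.config
        cfg = replace(cfg0, structure=proj_structure)
        rec_devs = None
        if sigma_r > 0:
            rec_devs = {
                s: rng.normal(0.0, sigma_r, proj_structure.n_years)
                for s in proj_structure.stocks
            }
        proj = run_model(cfg, derived, matrices, catches=catches,
                         init_state=traj.N[-1],
                         first_year=proj_structure.first_year,
                         rec_devs=rec_devs, sigma_r=sigma_r)
        trajectories.append(proj)
    return ProjectionResults(scenario=scenario, runs=runs,
                             trajectories=trajectories)


@dataclass
class ProjectionResults:
    """Per-draw projected trajectories plus stock-status summaries."""

    scenario: Scenario
    runs: list
    trajectories: list

    def _years(self):
        tr = self.trajectories[0]
        return tr.first_year + np.arange(tr.n_steps // 4)

    def ssb_matrix(self, stock: str) -> np.ndarray:
        """[draw, projection year] spawning biomass."""
        return np.stack([tr.ssb_series(stock) for tr in self.trajectories])

    def ssb_summary(self, stock: str) -> pd.DataFrame:
        return summarize_draws(self.ssb_matrix(stock), index=self._years())

    def depletion_summary(self, stock: str) -> pd.DataFrame:
        """SSB relative to each draw's first-data-year SSB."""
        first_year = self.runs[0][1].first_year
        base = np.array([tr.ssb(stock, first_year) for _, tr, _, _ in self.runs])
        mat = self.ssb_matrix(stock) / base[:, None]
        return summarize_draws(mat, index=self._years())

    def b_over_bmsy_summary(self, stock: str) -> pd.DataFrame:
        """SSB over each draw's own equilibrium spawning biomass at Fmsy."""
        smsy = np.array([d[stock].Smsy for _, _, _, d in self.runs])
        mat = self.ssb_matrix(stock) / smsy[:, None]
        return summarize_draws(mat, index=self._years())

    def status_tables(self) -> dict:
        st = self.trajectories[0].config.structure
        return {
            s: {
                "ssb": self.ssb_summary(s),
                "depletion": self.depletion_summary(s),
                "b_over_bmsy": self.b_over_bmsy_summary(s),
            }
            for s in st.stocks
        }
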