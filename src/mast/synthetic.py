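"""Synthetic-data generation: complete reduced-scale datasets from known truth.

The real conditioning data for this kind of assessment (official catch
tables, commercial CPUE series, conventional-tag databases, electronic-tag
tracks, otolith stock-composition samples) are not redistributable, so
every observation stream is emulated here with the statistical structure
the likelihoods assume: lognormal index errors, multinomial age
compositions, negative-binomial recapture counts, binomial composition
counts, and hidden-Markov tag tracks with capture/natural-death/shedding
absorption.  The generator runs the true dynamics under an explicit
two-phase effort history (effort rising then declining in the west, rising
late in the east, echoing the qualitative history of the fishery) and
records both the realized catches and the true trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .config import ModelConfig, default_config
from .dynamics import run_model
from .equilibrium import StockParams, derive_stock_recruit
from .inference import Params
from .io import (CAARecord, CatchArray, IndexSeries, ObservationBundle,
                 OtolithRecord, TagCohort)
from .likelihoods import (CAA_REGIONS, predict_caa, predict_otolith_fraction,
                          _predict_recaptures)
from .movement import MovementParams, build_all_matrices
from .structure import ModelStructure
from .tag_hmm import TagDynamics, simulate_track

__all__ = ["TruthSpec", "default_truth", "simulate_dataset"]

#: which fleets operate in which areas (1-based), for the effort history
FLEET_FOOTPRINT = {
    "LL": (1, 3, 4),
    "PS": (3, 4, 5),
    "BB": (2, 3),
    "OTH": (1, 2, 3, 4, 5),
}


@dataclass
class TruthSpec:
    """Generative truth: parameters, biology scale, effort and noise settings."""

    config: ModelConfig
    params: Params
    #: peak annual fully-recruited F by side during the effort history
    west_peak_F: float = 0.35
    east_peak_F: float = 0.4
    #: fraction of the horizon at which western effort peaks
    west_peak_at: float = 0.5
    cpue_sd: float = 0.2
    #: true catchability linking index series to vulnerable biomass
    cpue_q: float = 1e-4
    caa_effective_n: float = 100.0
    nb_dispersion: float = 2.0
    otolith_n: int = 25
    #: conventional-tag cohorts released per year per program
    cohorts_per_year: int = 1
    releases_per_cohort: int = 400
    #: electronic tags released in total (split archival/psat evenly)
    n_etags: int = 60
    etag_horizon_quarters: int = 8
    #: fraction of tag cohorts with unknown stock of origin
    frac_unknown: float = 0.85
    seed: int = 0

    def to_dict(self) -> dict:
        cfg = self.config
        st = cfg.structure
        d = {
            k: getattr(self, k)
            for k in (
                "west_peak_F", "east_peak_F", "west_peak_at", "cpue_sd",
                "cpue_q",
                "caa_effective_n", "nb_dispersion", "otolith_n",
                "cohorts_per_year", "releases_per_cohort", "n_etags",
                "etag_horizon_quarters", "frac_unknown", "seed",
            )
        }
        d["structure"] = {
            "first_year": st.first_year, "last_year": st.last_year,
            "max_age": st.max_age,
        }
        d["params"] = {
            "msy": dict(self.params.msy),
            "fmsy": dict(self.params.fmsy),
            "gravity": {s: g.tolist() for s, g in self.params.gravity.items()},
            "sel_a50": self.params.sel_a50.tolist(),
            "sel_slope": self.params.sel_slope.tolist(),
            "reporting": self.params.reporting.tolist(),
            "p_obs_archival": self.params.p_obs_archival,
            "nb_dispersion": self.params.nb_dispersion,
        }
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "TruthSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        sd = d.pop("structure")
        pd_ = d.pop("params")
        cfg = default_config(structure=ModelStructure(**sd))
        params = Params(
            msy=pd_["msy"], fmsy=pd_["fmsy"],
            gravity={s: np.array(g) for s, g in pd_["gravity"].items()},
            sel_a50=np.array(pd_["sel_a50"]),
            sel_slope=np.array(pd_["sel_slope"]),
            reporting=np.array(pd_["reporting"]),
            p_obs_archival=pd_["p_obs_archival"],
            nb_dispersion=pd_["nb_dispersion"],
        )
        return cls(config=cfg, params=params, **d)


def default_truth(scale: str = "reduced", seed: int = 0) -> TruthSpec:
    """Truth specifications at two scales.

    'paper-like': the 1950-2008 horizon with leading parameters at the
    reported magnitudes (western MSY 3.9 kt, eastern 25 kt).  'reduced': a
    20-year horizon with roughly 10x smaller tag programs so that full
    simulation-estimation experiments run quickly.
    """
    if scale == "paper-like":
        structure = ModelStructure()
        n_etags, cohorts = 600, 8
    elif scale == "reduced":
        structure = ModelStructure(first_year=1989, last_year=2008, max_age=12,
                                   movement_age_groups=((0, 7), (8, None)))
        n_etags, cohorts = 60, 2
    else:
        raise ValueError(f"unknown scale {scale!r}")
    cfg = default_config(structure=structure)
    st = structure
    gravity = {
        "west": np.broadcast_to(
            np.array([0.85, 0.7, 0.6, 0.7]), (st.n_groups, 4, 4)
        ).copy(),
        "east": np.broadcast_to(
            np.array([0.6, 0.55, 0.85]), (st.n_groups, 4, 3)
        ).copy(),
    }
    params = Params(
        msy={"west": 3900.0, "east": 25000.0},
        fmsy={"west": 0.15, "east": 0.2},
        gravity=gravity,
        sel_a50=cfg.fleet_params.a50.copy(),
        sel_slope=cfg.fleet_params.slope.copy(),
        reporting=np.full(st.n_fleets, 0.2),
        p_obs_archival=0.9,
        nb_dispersion=2.0,
    )
    return TruthSpec(config=cfg, params=params, n_etags=n_etags,
                     cohorts_per_year=cohorts, seed=seed)


# ---------------------------------------------------------------------------
# effort history and true run
# ---------------------------------------------------------------------------


def _effort_F(truth: TruthSpec) -> np.ndarray:
    """Quarterly F [T, fleet, area] under the two-phase effort history."""
    cfg = truth.config
    st = cfg.structure
    ny = st.n_years
    x = np.linspace(0.0, 1.0, ny)
    # west: rise to a peak then decline to 40% of peak
    peak = truth.west_peak_at
    west_shape = np.where(
        x <= peak, x / peak, 1.0 - 0.6 * (x - peak) / max(1.0 - peak, 1e-9)
    )
    # east: low early, steep late rise
    east_shape = 0.15 + 0.85 * np.clip((x - 0.5) / 0.5, 0.0, 1.0) ** 2
    west_areas = {1, 2, 3}
    F = np.zeros((st.n_quarters, st.n_fleets, st.n_areas))
    for f, fleet in enumerate(st.fleets):
        areas = FLEET_FOOTPRINT.get(fleet, tuple(range(1, st.n_areas + 1)))
        for j1 in areas:
            if j1 > st.n_areas:
                continue
            j = j1 - 1
            shape = west_shape if j1 in west_areas else east_shape
            peak_F = truth.west_peak_F if j1 in west_areas else truth.east_peak_F
            # split the area's annual peak F across the fleets present
            n_present = sum(
                1 for fl in st.fleets
                if j1 in FLEET_FOOTPRINT.get(fl, ())
            )
            annual = peak_F * shape / max(n_present, 1)
            for iy in range(ny):
                F[4 * iy:4 * iy + 4, f, j] = annual[iy] / 4.0
    return F


def true_run(truth: TruthSpec):
    """Run the dynamics at truth under the effort history.

    Returns (trajectory, matrices, derived, catches): catches are the
    realized removals, which become the conditioning data of the fitted
    model (the estimator re-solves F from them, closing the loop).
    """
    cfg = truth.config
    st = cfg.structure
    agg = cfg.aggregate_selectivity()
    derived = {}
    for s in st.stocks:
        bio = cfg.biology[s]
        derived[s] = derive_stock_recruit(
            StockParams(truth.params.msy[s], truth.params.fmsy[s], bio.M,
                        bio.weight, bio.maturity, agg)
        )
    matrices = build_all_matrices(
        MovementParams(gravity_diag=truth.params.gravity), cfg.biology, st
    )
    F = _effort_F(truth)
    traj = run_model(cfg, derived, matrices, F_given=F)
    arr = np.zeros((st.n_fleets, st.n_areas, st.n_years, 4))
    for t in range(traj.n_steps):
        arr[:, :, t // 4, t % 4] = traj.realized_catch(t)
    arr[arr < 1e-9] = 0.0
    catches = CatchArray(st, arr)
    if all(
        traj.vulnerable_numbers(t, j, agg).sum() <= 0
        for t in range(traj.n_steps)
        for j in range(st.n_areas)
        if F[t, :, j].sum() > 0
    ) and F.sum() > 0:
        raise ValueError("degenerate truth: positive effort on zero biomass")
    return traj, matrices, derived, catches


# ---------------------------------------------------------------------------
# observation streams
# ---------------------------------------------------------------------------

#: default CPUE series placement: (name, area, quarter, fleet)
CPUE_PLACEMENT = [
    ("gom_ll", "GoM", 2, "LL"),
    ("gsl_bb", "GSL", 3, "BB"),
    ("watl_ll_q1", "WAtl", 1, "LL"),
    ("watl_ps_q3", "WAtl", 3, "PS"),
    ("eatl_ll", "EAtl", 2, "LL"),
    ("med_ps", "Med", 3, "PS"),
]


def _simulate_cpue(truth, traj, rng):
    from .likelihoods import predict_index

    cfg = truth.config
    st = cfg.structure
    out = []
    years = np.arange(st.first_year, st.last_year + 1)
    for name, area, quarter, fleet in CPUE_PLACEMENT:
        series = IndexSeries(name, area, quarter, fleet, years,
                             np.ones(years.size))
        v = predict_index(traj, series)
        noise = rng.normal(0.0, truth.cpue_sd, years.size)
        series.values = truth.cpue_q * v * np.exp(noise - 0.5 * truth.cpue_sd**2)
        out.append(series)
    return out


def _simulate_caa(truth, traj, rng):
    cfg = truth.config
    st = cfg.structure
    out = []
    n_eff = int(truth.caa_effective_n)
    age_hi = min(10, st.max_age)
    for region in CAA_REGIONS:
        for year in range(st.first_year, st.last_year + 1):
            rec = CAARecord(region, year, np.full(age_hi, 1.0 / age_hi),
                            age_lo=1, age_hi=age_hi)
            p = predict_caa(traj, rec)
            if not np.all(np.isfinite(p)) or p.sum() <= 0:
                continue
            counts = rng.multinomial(n_eff, p / p.sum())
            if counts.sum() == 0:
                continue
            rec.props = counts / counts.sum()
            out.append(rec)
    return out


def _simulate_otolith(truth, traj, rng):
    """Binomial stock-composition samples in the mixed western Atlantic."""
    cfg = truth.config
    st = cfg.structure
    out = []
    for year in range(st.first_year + 2, st.last_year + 1, 3):
        for group in ("school", "medium", "giant"):
            rec = OtolithRecord("WAtl", group, year, 3, 0, truth.otolith_n)
            p = predict_otolith_fraction(traj, rec)
            rec.n_west = int(rng.binomial(truth.otolith_n, np.clip(p, 0, 1)))
            out.append(rec)
    return out


#: conventional-tag release programs: (program stock, areas, ages)
TAG_PROGRAMS = [
    ("west", ("GoM", "WAtl"), (3, 9)),
    ("east", ("Med",), (2, 6)),
]


def _simulate_cohorts(truth, traj, matrices, rng):
    cfg = truth.config
    st = cfg.structure
    out = []
    k = 0
    for year in range(st.first_year + 1, st.last_year - 2):
        for prog_stock, areas, ages in TAG_PROGRAMS:
            for i in range(truth.cohorts_per_year):
                area = areas[k % len(areas)]
                age = ages[k % len(ages)]
                quarter = 1 + (k % 4)
                k += 1
                cohort = TagCohort(
                    cohort_id=f"c{k:04d}", area=area, year=year,
                    quarter=quarter, age=age,
                    count=truth.releases_per_cohort, stock=prog_stock,
                )
                pred = _predict_recaptures(
                    cohort, traj, matrices, prog_stock,
                    truth.params.reporting, cfg.shed_rate,
                    cohort.horizon_quarters,
                )
                if pred is None:
                    continue
                r = truth.nb_dispersion
                recaps = []
                total = 0
                for (kk, f, j), m in np.ndenumerate(pred):
                    if m <= 0:
                        continue
                    p_nb = r / (r + m)
                    n_obs = int(rng.negative_binomial(r, p_nb))
                    if n_obs > 0:
                        t = 4 * cohort.year + (cohort.quarter - 1) + kk
                        recaps.append(
                            (st.areas[j], t // 4, t % 4 + 1, st.fleets[f],
                             n_obs)
                        )
                        total += n_obs
                if total > cohort.count:  # cap at releases (rare at this scale)
                    continue
                cohort.recaptures = recaps
                if rng.random() < truth.frac_unknown:
                    cohort.stock = "unknown"
                out.append(cohort)
    return out


def _simulate_etags(truth, traj, matrices, rng):
    cfg = truth.config
    st = cfg.structure
    dyn = TagDynamics(traj, matrices, cfg.shed_rate,
                      truth.params.p_obs_archival)
    out = []
    programs = [("west", "GoM", 8), ("west", "WAtl", 5), ("east", "Med", 4)]
    horizon = st.n_quarters
    for i in range(truth.n_etags):
        stock, area, age = programs[i % len(programs)]
        tag_type = "archival" if i % 2 == 0 else "psat"
        year = int(st.first_year + 2
                   + rng.integers(0, max(st.n_years - 4, 1)))
        quarter = int(1 + rng.integers(0, 4))
        track = simulate_track(
            area, year, quarter, age, stock, tag_type, dyn, rng,
            horizon_quarters=truth.etag_horizon_quarters,
            tag_id=f"e{i:04d}",
        )
        if track is None or track.n_quarters < 1:
            continue
        if rng.random() >= truth.frac_unknown:
            track.stock = stock
        out.append(track)
    return out


def simulate_dataset(truth: TruthSpec, seed: int = None):
    """Generate catches plus all five observation streams at known truth.

    Returns (catches, bundle, truth_traj); reproducible under the seed.
    """
    if seed is None:
        seed = truth.seed
    rng = np.random.default_rng(seed)
    traj, matrices, derived, catches = true_run(truth)
    bundle = ObservationBundle(
        cpue=_simulate_cpue(truth, traj, rng),
        caa=_simulate_caa(truth, traj, rng),
        otolith=_simulate_otolith(truth, traj, rng),
        tag_cohorts=_simulate_cohorts(truth, traj, matrices, rng),
        tag_tracks=_simulate_etags(truth, traj, matrices, rng),
    )
    bundle.validate(truth.config.structure)
    return catches, bundle, traj
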