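"""Model and results objects: the package's main user-facing surface.

:class:`MASTModel` couples a configuration, a catch series and an
observation bundle; ``fit()`` produces a :class:`MASTResults` carrying the
MAP estimates, the derived management quantities (kappa, R0, B0, Bmsy), the
fitted trajectory and an objective breakdown, with ``summary()`` giving a
readable table.  ``MASTResults.sample_posterior()`` runs the adaptive
Metropolis sampler and returns a :class:`PosteriorResults` holding the
draws, convergence diagnostics and per-draw derived trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import ModelConfig
from .dynamics import Trajectory, run_model
from .equilibrium import StockParams, derive_stock_recruit
from .inference import (ParameterSpace, Params, fit_map_objective,
                        multivariate_psrf, psrf, run_mcmc, summarize_draws)
from .io import CatchArray, ObservationBundle
from .likelihoods import total_objective
from .movement import MovementParams, build_all_matrices
from .structure import FleetParams

__all__ = ["MASTModel", "MASTResults", "PosteriorResults"]


class MASTModel:
    """Multistock age-structured tag-integrated assessment model.

    Parameters
    ----------
    catches : CatchArray
        Conditioning removals (apply any under-reporting adjustment first;
        see :func:`mast.io.inflate_east_catches`).
    observations : ObservationBundle
        Any subset of the five observation streams.
    config : ModelConfig
        Structure, biology and statistical settings.
    estimate : tuple
        Free parameter blocks (see :class:`mast.inference.ParameterSpace`).
    """

    def __init__(self, catches: CatchArray, observations: ObservationBundle,
                 config: ModelConfig = None, estimate=("msy", "fmsy", "gravity"),
                 gravity_sharing: str = "full"):
        self.config = config if config is not None else ModelConfig()
        self.catches = catches
        self.observations = observations
        self.observations.validate(self.config.structure)
        self.space = ParameterSpace(self.config.structure, tuple(estimate),
                                    gravity_sharing)
        self.n_evaluations = 0

    # -- parameter scaffolding ----------------------------------------
    def default_params(self) -> Params:
        """Neutral starting values: MSY from the catch magnitude, moderate
        Fmsy, retention 0.7, and the configured observation parameters."""
        st = self.config.structure
        mean_catch = {
            s: max(
                np.mean([
                    self.catches.year_total(y, areas=self.config.structure.stock_area_sets[s])
                    for y in range(st.first_year, st.last_year + 1)
                ]),
                100.0,
            )
            for s in st.stocks
        }
        return Params(
            msy={s: float(mean_catch[s]) for s in st.stocks},
            fmsy={s: 0.2 for s in st.stocks},
            gravity={
                s: np.full((st.n_groups, 4, st.n_stock_areas(s)), 0.7)
                for s in st.stocks
            },
            sel_a50=self.config.fleet_params.a50.copy(),
            sel_slope=self.config.fleet_params.slope.copy(),
            reporting=np.full(st.n_fleets, self.config.reporting_prior.mean),
            p_obs_archival=self.config.p_obs_archival,
            nb_dispersion=self.config.nb_dispersion,
        )

    # -- model evaluation ---------------------------------------------
    def _config_for(self, params: Params) -> ModelConfig:
        cfg = self.config
        if "selectivity" in self.space.estimate:
            cfg = replace(cfg, fleet_params=FleetParams(params.sel_a50,
                                                        params.sel_slope))
        return cfg

    def evaluate(self, params: Params):
        """Run the full model at given parameters.

        Returns (trajectory, matrices, derived) where derived maps stock ->
        DerivedStock (kappa, R0, S0, B0, Smsy).
        """
        cfg = self._config_for(params)
        st = cfg.structure
        agg_sel = cfg.aggregate_selectivity()
        derived = {}
        for s in st.stocks:
            bio = cfg.biology[s]
            derived[s] = derive_stock_recruit(
                StockParams(params.msy[s], params.fmsy[s], bio.M, bio.weight,
                            bio.maturity, agg_sel)
            )
        # estimation uses the gravity parameterization (the base case);
        # bulk-transfer matrices are available at the movement-module level
        # for simulation and sensitivity work
        matrices = build_all_matrices(
            MovementParams(gravity_diag=params.gravity), cfg.biology, st
        )
        traj = run_model(cfg, derived, matrices, catches=self.catches,
                         rec_devs=params.rec_devs, sigma_r=cfg.sigma_r)
        self.n_evaluations += 1
        return traj, matrices, derived

    def objective(self, params: Params):
        """Negative log-posterior and per-component breakdown."""
        traj, matrices, _ = self.evaluate(params)
        return total_objective(
            traj, matrices, self.observations, params.reporting,
            params.nb_dispersion, params.p_obs_archival,
            rec_devs=params.rec_devs,
        )

    def objective_theta(self, theta: np.ndarray, base: Params = None) -> float:
        if base is None:
            base = self.default_params()
        return self.objective(self.space.unpack(theta, base))[0]

    def logpost(self, theta: np.ndarray, base: Params = None) -> float:
        try:
            return -self.objective_theta(theta, base)
        except Exception:
            return -np.inf

    # -- fitting -------------------------------------------------------
    def fit(self, start: Params = None, maxiter: int = 200,
            ftol: float = 1e-9) -> "MASTResults":
        """MAP estimation by bounded quasi-Newton in transformed space."""
        base = start if start is not None else self.default_params()
        theta0 = self.space.pack(base)
        res = fit_map_objective(
            lambda th: self.objective_theta(th, base), theta0,
            maxiter=maxiter, ftol=ftol,
        )
        params = self.space.unpack(res.x, base)
        traj, matrices, derived = self.evaluate(params)
        value, breakdown = total_objective(
            traj, matrices, self.observations, params.reporting,
            params.nb_dispersion, params.p_obs_archival,
            rec_devs=params.rec_devs,
        )
        return MASTResults(
            model=self, params=params, theta=res.x.copy(), objective=value,
            breakdown=breakdown, converged=bool(res.success),
            n_iterations=int(res.nit), trajectory=traj, matrices=matrices,
            derived=derived, base=base,
        )


@dataclass
class MASTResults:
    """MAP fit results: estimates, derived quantities and diagnostics."""

    model: MASTModel
    params: Params
    theta: np.ndarray
    objective: float
    breakdown: dict
    converged: bool
    n_iterations: int
    trajectory: Trajectory
    matrices: dict
    derived: dict
    base: Params

    # -- reporting ------------------------------------------------------
    def ssb_table(self) -> pd.DataFrame:
        st = self.model.config.structure
        rows = []
        for s in st.stocks:
            series = self.trajectory.ssb_series(s)
            for y, v in zip(st.years, series):
                rows.append((s, int(y), v))
        return pd.DataFrame(rows, columns=["stock", "year", "ssb_tonnes"])

    def depletion(self) -> dict:
        st = self.model.config.structure
        return {
            s: self.trajectory.ssb(s, st.last_year)
            / self.trajectory.ssb(s, st.first_year)
            for s in st.stocks
        }

    def annual_F_table(self) -> pd.DataFrame:
        """Annualized fishing mortality (sum of quarterly rates) by
        fleet/area/year."""
        st = self.model.config.structure
        F = self.trajectory.F.reshape(st.n_years, 4, st.n_fleets, st.n_areas)
        annual = F.sum(axis=1)
        rows = []
        for iy, year in enumerate(st.years):
            for f, fleet in enumerate(st.fleets):
                for j, area in enumerate(st.areas):
                    if annual[iy, f, j] > 0:
                        rows.append((int(year), fleet, area, annual[iy, f, j]))
        return pd.DataFrame(rows, columns=["year", "fleet", "area", "F_per_yr"])

    def stock_composition_table(self, quarter: int = None) -> pd.DataFrame:
        """Western share of vulnerable numbers in the mixed areas by
        year/quarter (the mixed-stock ratio statistic)."""
        from .likelihoods import west_fraction

        st = self.model.config.structure
        mixed = [a for a in st.areas
                 if sum(st.area_index(a) in st.accessible0(s)
                        for s in st.stocks) > 1]
        ages = np.arange(st.n_ages)
        rows = []
        quarters = [quarter] if quarter else [1, 2, 3, 4]
        for area in mixed:
            for year in st.years:
                for q in quarters:
                    t = self.trajectory.t_index(int(year), q)
                    rows.append((area, int(year), q,
                                 west_fraction(self.trajectory, t, area,
                                               ages)))
        return pd.DataFrame(rows, columns=["area", "year", "quarter",
                                           "west_fraction"])

    def objective_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(k, n, v) for k, (n, v) in self.breakdown.items()],
            columns=["component", "n_data", "nll"],
        )

    def summary(self) -> str:
        st = self.model.config.structure
        lines = [
            "MAST model results (MAP)",
            "=" * 60,
            f"objective (neg. log posterior): {self.objective:.4f}"
            f"   converged: {self.converged}",
            "",
            f"{'stock':<8}{'MSY (t/yr)':>12}{'Fmsy (/yr)':>12}{'kappa':>10}"
            f"{'B0 (t)':>14}{'depletion':>11}",
        ]
        depl = self.depletion()
        for s in st.stocks:
            d = self.derived[s]
            lines.append(
                f"{s:<8}{self.params.msy[s]:>12.1f}{self.params.fmsy[s]:>12.4f}"
                f"{d.kappa:>10.2f}{d.B0:>14.0f}{depl[s]:>11.3f}"
            )
        lines.append("")
        lines.append("mean gravity retention by stock/quarter:")
        for s in st.stocks:
            g = self.params.gravity[s].mean(axis=(0, 2))
            lines.append("  " + s + "  " + "  ".join(
                f"Q{q + 1}={g[q]:.3f}" for q in range(4)))
        lines.append("")
        lines.append("objective components:")
        for k, (n, v) in self.breakdown.items():
            lines.append(f"  {k:<18} n={n:<5d} nll={v:.3f}")
        return "\n".join(lines)

    # -- posterior sampling --------------------------------------------
    def sample_posterior(self, n_iter: int = 2000, chains: int = 6,
                         thin: int = 10, seed: int = 0) -> "PosteriorResults":
        """Adaptive Metropolis around the MAP (chains jittered 5%)."""
        draws, accept = run_mcmc(
            lambda th: self.model.logpost(th, self.base), self.theta,
            n_iter=n_iter, chains=chains, thin=thin, seed=seed,
        )
        return PosteriorResults(results=self, draws=draws, accept=accept,
                                thin=thin)


@dataclass
class PosteriorResults:
    """MCMC posterior draws plus derived trajectories and diagnostics."""

    results: MASTResults
    draws: np.ndarray  # [chain, kept, dim]
    accept: np.ndarray
    thin: int
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def psrf(self) -> np.ndarray:
        return psrf(self.draws)

    def multivariate_psrf(self) -> float:
        return multivariate_psrf(self.draws)

    def converged(self, threshold: float = 1.05) -> bool:
        return self.multivariate_psrf() < threshold

    def params_for(self, draw_idx: int) -> Params:
        model = self.results.model
        return model.space.unpack(self.flat[draw_idx], self.results.base)

    def derived_runs(self, max_draws: int = 50, seed: int = 0):
        """Re-run the model for a subsample of draws.

        Returns a list of (params, trajectory, matrices, derived); cached.
        """
        key = (max_draws, seed)
        if key not in self._cache:
            rng = np.random.default_rng(seed)
            total = self.flat.shape[0]
            idx = (np.arange(total) if total <= max_draws
                   else rng.choice(total, max_draws, replace=False))
            runs = []
            model = self.results.model
            for i in sorted(idx):
                p = self.params_for(int(i))
                runs.append((p,) + model.evaluate(p))
            self._cache[key] = runs
        return self._cache[key]

    def ssb_summary(self, stock: str, max_draws: int = 50) -> pd.DataFrame:
        """Boxplot statistics of SSB per year across posterior draws."""
        runs = self.derived_runs(max_draws)
        st = self.results.model.config.structure
        series = np.stack([tr.ssb_series(stock) for _, tr, _, _ in runs])
        return summarize_draws(series, index=st.years)

    def parameter_summary(self) -> pd.DataFrame:
        df = summarize_draws(self.flat)
        df.insert(0, "parameter", self.results.model.space.names)
        df["psrf"] = self.psrf()
        return df
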