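"""Parameter packing, MAP estimation, MCMC and convergence diagnostics.

Estimation works in an unconstrained transformed space: log transforms for
positive parameters (MSY, Fmsy, selectivity, dispersion) and logit
transforms for probabilities (gravity retentions, reporting rates, the
archival observation probability).  The sampler is an adaptive random-walk
Metropolis with a joint Gaussian proposal scaled from a diagonal curvature
estimate at the mode; convergence is monitored with the Gelman-Rubin
potential scale reduction factor, including the multivariate (maximum-
eigenvalue) version with the < 1.05 stopping rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Params", "ParameterSpace", "fit_map_objective", "run_mcmc",
           "psrf", "multivariate_psrf", "psrf_satisfied", "summarize_draws"]

_LOGIT_EPS = 1e-9


def _logit(p):
    p = np.clip(p, _LOGIT_EPS, 1 - _LOGIT_EPS)
    return np.log(p / (1 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, float)))


@dataclass
class Params:
    """Structured parameter values for one model evaluation."""

    msy: dict  # stock -> tonnes/yr
    fmsy: dict  # stock -> /yr
    gravity: dict  # stock -> array [n_groups, 4, n_stock_areas]
    sel_a50: np.ndarray  # per fleet
    sel_slope: np.ndarray  # per fleet
    reporting: np.ndarray  # per fleet, in [0,1]
    p_obs_archival: float = 0.9
    nb_dispersion: float = 2.0
    rec_devs: dict = None  # stock -> per-year log deviations

    def copy(self) -> "Params":
        return Params(
            msy=dict(self.msy), fmsy=dict(self.fmsy),
            gravity={s: g.copy() for s, g in self.gravity.items()},
            sel_a50=self.sel_a50.copy(), sel_slope=self.sel_slope.copy(),
            reporting=self.reporting.copy(),
            p_obs_archival=self.p_obs_archival,
            nb_dispersion=self.nb_dispersion,
            rec_devs=None if self.rec_devs is None
            else {s: d.copy() for s, d in self.rec_devs.items()},
        )


@dataclass
class ParameterSpace:
    """Maps free parameters to/from an unconstrained vector.

    ``estimate`` selects the free blocks ('msy', 'fmsy', 'gravity',
    'selectivity', 'reporting', 'p_obs', 'dispersion'); gravity_sharing
    'full' frees one retention per (stock, group, quarter, area) while
    'area' shares one retention per (stock, area) across groups and
    quarters.
    """

    structure: object
    estimate: tuple = ("msy", "fmsy", "gravity")
    gravity_sharing: str = "full"

    def __post_init__(self):
        self.names = []
        st = self.structure
        if "msy" in self.estimate:
            self.names += [f"log_msy[{s}]" for s in st.stocks]
        if "fmsy" in self.estimate:
            self.names += [f"log_fmsy[{s}]" for s in st.stocks]
        if "gravity" in self.estimate:
            for s in st.stocks:
                n = st.n_stock_areas(s)
                if self.gravity_sharing == "area":
                    self.names += [f"logit_grav[{s},{j}]" for j in range(n)]
                else:
                    self.names += [
                        f"logit_grav[{s},g{g},q{q},{j}]"
                        for g in range(st.n_groups)
                        for q in range(1, 5)
                        for j in range(n)
                    ]
        if "selectivity" in self.estimate:
            self.names += [f"log_a50[{f}]" for f in st.fleets]
            self.names += [f"log_slope[{f}]" for f in st.fleets]
        if "reporting" in self.estimate:
            self.names += [f"logit_report[{f}]" for f in st.fleets]
        if "p_obs" in self.estimate:
            self.names += ["logit_p_obs"]
        if "dispersion" in self.estimate:
            self.names += ["log_nb_dispersion"]

    @property
    def n_free(self) -> int:
        return len(self.names)

    def pack(self, p: Params) -> np.ndarray:
        st = self.structure
        out = []
        if "msy" in self.estimate:
            out += [np.log(p.msy[s]) for s in st.stocks]
        if "fmsy" in self.estimate:
            out += [np.log(p.fmsy[s]) for s in st.stocks]
        if "gravity" in self.estimate:
            for s in st.stocks:
                g = p.gravity[s]
                if self.gravity_sharing == "area":
                    out += list(_logit(g[0, 0, :]))
                else:
                    out += list(_logit(g).ravel())
        if "selectivity" in self.estimate:
            out += list(np.log(p.sel_a50)) + list(np.log(p.sel_slope))
        if "reporting" in self.estimate:
            out += list(_logit(p.reporting))
        if "p_obs" in self.estimate:
            out.append(float(_logit(p.p_obs_archival)))
        if "dispersion" in self.estimate:
            out.append(np.log(p.nb_dispersion))
        return np.array(out)

    def unpack(self, theta: np.ndarray, base: Params) -> Params:
        st = self.structure
        p = base.copy()
        theta = np.asarray(theta, float)
        if theta.shape != (self.n_free,):
            raise ValueError(
                f"theta has {theta.shape}, expected ({self.n_free},)"
            )
        i = 0
        if "msy" in self.estimate:
            for s in st.stocks:
                p.msy[s] = float(np.exp(theta[i])); i += 1
        if "fmsy" in self.estimate:
            for s in st.stocks:
                p.fmsy[s] = float(np.exp(theta[i])); i += 1
        if "gravity" in self.estimate:
            for s in st.stocks:
                n = st.n_stock_areas(s)
                if self.gravity_sharing == "area":
                    vals = _expit(theta[i:i + n]); i += n
                    p.gravity[s] = np.broadcast_to(
                        vals, (st.n_groups, 4, n)
                    ).copy()
                else:
                    k = st.n_groups * 4 * n
                    p.gravity[s] = _expit(theta[i:i + k]).reshape(
                        st.n_groups, 4, n
                    )
                    i += k
        if "selectivity" in self.estimate:
            nf = st.n_fleets
            p.sel_a50 = np.exp(theta[i:i + nf]); i += nf
            p.sel_slope = np.exp(theta[i:i + nf]); i += nf
        if "reporting" in self.estimate:
            nf = st.n_fleets
            p.reporting = _expit(theta[i:i + nf]); i += nf
        if "p_obs" in self.estimate:
            p.p_obs_archival = float(_expit(theta[i])); i += 1
        if "dispersion" in self.estimate:
            p.nb_dispersion = float(np.exp(theta[i])); i += 1
        return p


# ---------------------------------------------------------------------------
# MAP optimization
# ---------------------------------------------------------------------------


def fit_map_objective(objective, theta0: np.ndarray, maxiter: int = 200,
                      ftol: float = 1e-9):
    """Bounded quasi-Newton minimization in the transformed space.

    Non-finite objective values during the line search are replaced with a
    large penalty (a logged retreat) rather than raising; failure to
    converge sets a flag on the result instead of raising.
    """
    from scipy.optimize import minimize

    def safe(theta):
        try:
            v = objective(theta)
        except Exception:
            return 1e12
        return v if np.isfinite(v) else 1e12

    res = minimize(safe, np.asarray(theta0, float), method="L-BFGS-B",
                   options={"maxiter": maxiter, "ftol": ftol})
    return res


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------


def _curvature_scales(logpost, theta, h: float = 1e-3) -> np.ndarray:
    """Per-parameter proposal SDs from a diagonal curvature estimate."""
    d = theta.size
    f0 = logpost(theta)
    scales = np.empty(d)
    for i in range(d):
        e = np.zeros(d)
        e[i] = h
        curv = -(logpost(theta + e) - 2 * f0 + logpost(theta - e)) / h**2
        scales[i] = 1.0 / np.sqrt(curv) if np.isfinite(curv) and curv > 0 else 0.1
    return np.clip(scales, 1e-4, 10.0)


def run_mcmc(
    logpost,
    theta0: np.ndarray,
    n_iter: int = 2000,
    chains: int = 6,
    thin: int = 10,
    seed: int = 0,
    scales: np.ndarray = None,
    jitter: float = 0.05,
    adapt: bool = True,
    target_accept: float = 0.3,
):
    """Adaptive random-walk Metropolis sampling of a log-posterior.

    Chains start over-dispersed around theta0 (multiplicative 5% jitter in
    the transformed space), one draw is retained per ``thin`` iterations,
    and the global proposal scale adapts toward the target acceptance rate
    during the first half of each chain.  Reproducible under ``seed``.

    Returns (draws [chain, kept, dim], accept_rate [chain]).
    """
    theta0 = np.asarray(theta0, float)
    d = theta0.size
    if scales is None:
        scales = _curvature_scales(logpost, theta0)
    rng = np.random.default_rng(seed)
    kept = n_iter // thin
    draws = np.empty((chains, kept, d))
    accept = np.zeros(chains)
    for c in range(chains):
        x = theta0 * (1.0 + jitter * rng.standard_normal(d))
        x += jitter * (np.abs(theta0) < 1e-8) * rng.standard_normal(d)
        lp = logpost(x)
        tries = 0
        while not np.isfinite(lp) and tries < 50:
            x = theta0 * (1.0 + jitter * rng.standard_normal(d))
            lp = logpost(x)
            tries += 1
        log_step = 0.0
        n_acc = 0
        window_acc, window_n = 0, 0
        k = 0
        for it in range(n_iter):
            prop = x + np.exp(log_step) * scales * rng.standard_normal(d)
            lp_prop = logpost(prop)
            if np.isfinite(lp_prop) and np.log(rng.random()) < lp_prop - lp:
                x, lp = prop, lp_prop
                n_acc += 1
                window_acc += 1
            window_n += 1
            if adapt and it < n_iter // 2 and window_n == 50:
                rate = window_acc / window_n
                log_step += 0.5 * (rate - target_accept)
                window_acc, window_n = 0, 0
            if (it + 1) % thin == 0:
                draws[c, k] = x
                k += 1
        accept[c] = n_acc / n_iter
    return draws, accept


# ---------------------------------------------------------------------------
# Gelman-Rubin diagnostics
# ---------------------------------------------------------------------------


def psrf(draws: np.ndarray) -> np.ndarray:
    """Classic Gelman-Rubin potential scale reduction factor per parameter.

    draws: [chain, iteration, parameter], >= 2 chains and >= 10 retained
    iterations.  Chains with zero within- and between-chain variance (all
    constant and identical) report 1 by convention.
    """
    draws = np.asarray(draws, float)
    m, n, d = draws.shape
    if m < 2 or n < 10:
        raise ValueError("psrf needs >= 2 chains and >= 10 draws per chain")
    chain_means = draws.mean(axis=1)  # [m, d]
    W = draws.var(axis=1, ddof=1).mean(axis=0)  # [d]
    B_over_n = chain_means.var(axis=0, ddof=1)  # [d]
    var_hat = (n - 1) / n * W + (1.0 + 1.0 / m) * B_over_n
    out = np.empty(d)
    for j in range(d):
        if W[j] <= 0:
            out[j] = 1.0 if B_over_n[j] <= 0 else np.inf
        else:
            out[j] = np.sqrt(var_hat[j] / W[j])
    return out


def multivariate_psrf(draws: np.ndarray) -> float:
    """Brooks-Gelman multivariate PSRF (maximum-eigenvalue version)."""
    draws = np.asarray(draws, float)
    m, n, d = draws.shape
    if m < 2 or n < 10:
        raise ValueError("psrf needs >= 2 chains and >= 10 draws per chain")
    chain_means = draws.mean(axis=1)
    grand = chain_means.mean(axis=0)
    W = np.zeros((d, d))
    for c in range(m):
        dev = draws[c] - chain_means[c]
        W += dev.T @ dev / (n - 1)
    W /= m
    dev_means = chain_means - grand
    B_over_n = dev_means.T @ dev_means / (m - 1)
    if np.allclose(W, 0):
        return 1.0 if np.allclose(B_over_n, 0) else np.inf
    lam = np.linalg.eigvalsh(np.linalg.pinv(W) @ B_over_n).max()
    return float(np.sqrt((n - 1) / n + (1.0 + 1.0 / m) * lam))


def psrf_satisfied(draws: np.ndarray, threshold: float = 1.05) -> bool:
    """Stopping rule: multivariate PSRF below the threshold (default 1.05)."""
    return multivariate_psrf(draws) < threshold


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------


def summarize_draws(values: np.ndarray, index=None,
                    index_name: str = "year") -> pd.DataFrame:
    """Boxplot statistics per column: median, quartiles, 1.5 IQR whiskers.

    Quantiles use linear interpolation between order statistics (type 7).
    """
    values = np.atleast_2d(np.asarray(values, float))
    q1, med, q3 = np.percentile(values, [25, 50, 75], axis=0)
    iqr = q3 - q1
    df = pd.DataFrame(
        {
            "median": med,
            "q1": q1,
            "q3": q3,
            "whisker_lo": q1 - 1.5 * iqr,
            "whisker_hi": q3 + 1.5 * iqr,
        }
    )
    if index is not None:
        df.insert(0, index_name, np.asarray(index))
    return df
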