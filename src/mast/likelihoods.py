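"""Observation likelihoods, priors and the total objective function.

Five data families are fitted: lognormal relative-abundance indices with
catchability (and error variance) concentrated out analytically; multinomial
catch-at-age proportions; binomial otolith stock-composition counts;
negative-binomial conventional-tag recaptures (with mixed-stock weighting
for cohorts of unknown origin); and the hidden-Markov electronic-tag
likelihood from :mod:`mast.tag_hmm`.  All proportion-type predictions are
clamped away from 0 and 1 so structural zeros penalize without producing
infinities during optimization.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import gammaln

from .io import CAARecord, IndexSeries, ObservationBundle, OtolithRecord, TagCohort
from .tag_hmm import TagDynamics, track_loglik

__all__ = [
    "cpue_loglik",
    "caa_loglik",
    "otolith_loglik",
    "stock_mixture_weights",
    "conventional_tag_loglik",
    "total_objective",
]

#: region aggregates for catch-at-age fitting (1-based area indices)
CAA_REGIONS = {"west": (1, 2, 3), "east": (4, 5)}


class LikelihoodError(ValueError):
    pass


def _clamp(p, lo=1e-6):
    return np.clip(p, lo, 1.0 - lo)


# ---------------------------------------------------------------------------
# CPUE
# ---------------------------------------------------------------------------


def cpue_loglik(series: IndexSeries, predicted: np.ndarray) -> float:
    """Concentrated lognormal NLL for one index series.

    With z_t = ln I_t - ln V_t and ln q_hat = mean(z), the concentrated
    negative log-likelihood is (n/2) * ln(sum of squared residuals), up to
    additive constants.  Invariant to rescaling the series (q absorbs it).
    """
    predicted = np.asarray(predicted, float)
    if predicted.shape != series.values.shape:
        raise LikelihoodError(
            f"series {series.name}: predicted length {predicted.shape} != "
            f"observations {series.values.shape}"
        )
    if np.any(predicted <= 0):
        raise LikelihoodError(
            f"series {series.name}: non-positive predicted vulnerable biomass"
        )
    z = np.log(series.values) - np.log(predicted)
    rss = float(np.sum((z - z.mean()) ** 2))
    n = z.size
    return 0.5 * n * np.log(max(rss, 1e-12))


def cpue_catchability(series: IndexSeries, predicted: np.ndarray) -> float:
    """Concentrated (analytic MLE) catchability for a series."""
    z = np.log(series.values) - np.log(np.asarray(predicted, float))
    return float(np.exp(z.mean()))


# ---------------------------------------------------------------------------
# catch-at-age
# ---------------------------------------------------------------------------


def caa_loglik(record: CAARecord, predicted: np.ndarray,
               effective_n: float = 50.0, clamp: float = 1e-6) -> float:
    """Multinomial NLL for one annual age-composition record.

    NLL = -N_eff * sum_a obs_a * ln(pred_a); the minimum over predictions
    is attained at pred = obs, where the NLL equals N_eff times the entropy
    of the observed composition.
    """
    obs = record.props
    predicted = np.asarray(predicted, float)
    if predicted.shape != obs.shape:
        raise LikelihoodError(
            f"CAA {record.region}/{record.year}: prediction shape mismatch"
        )
    if abs(predicted.sum() - 1.0) > 1e-3:
        predicted = predicted / predicted.sum()
    return float(-effective_n * np.sum(obs * np.log(_clamp(predicted, clamp))))


# ---------------------------------------------------------------------------
# otolith stock composition
# ---------------------------------------------------------------------------


def otolith_loglik(record: OtolithRecord, p_west: float,
                   clamp: float = 1e-6) -> float:
    """Binomial NLL of n_west western fish out of n_total sampled."""
    p = float(_clamp(p_west, clamp))
    k, n = record.n_west, record.n_total
    log_pmf = (
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + k * np.log(p) + (n - k) * np.log1p(-p)
    )
    return float(-log_pmf)


# ---------------------------------------------------------------------------
# mixed-stock weights
# ---------------------------------------------------------------------------


def stock_mixture_weights(traj, t: int, area, ages, sel_age: np.ndarray = None):
    """Per-stock weights: vulnerable numbers of each stock over the total.

    ``ages`` is an iterable of ages (or a single age); vulnerability uses
    the aggregate selectivity unless ``sel_age`` (a per-age vector) is
    given.  A zero total yields uniform weights with a warning.
    """
    cfg = traj.config
    st = cfg.structure
    if sel_age is None:
        sel_age = cfg.aggregate_selectivity()
    ages = np.atleast_1d(ages)
    j = st.area_index(area)
    V = np.einsum("sa,a->s", traj.N[t][:, ages, j], sel_age[ages])
    total = V.sum()
    if total <= 0:
        warnings.warn(
            f"zero vulnerable numbers in area {area} at t={t}; uniform weights"
        )
        return {s: 1.0 / st.n_stocks for s in st.stocks}
    return {s: float(V[i] / total) for i, s in enumerate(st.stocks)}


def west_fraction(traj, t: int, area, ages, sel_age: np.ndarray = None) -> float:
    """Western share of vulnerable numbers (the mixed-stock ratio statistic)."""
    return stock_mixture_weights(traj, t, area, ages, sel_age)["west"]


# ---------------------------------------------------------------------------
# conventional tags
# ---------------------------------------------------------------------------


def _nb_logpmf(k: np.ndarray, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial log-pmf, mean/dispersion parameterization.

    var = mean + mean^2 / dispersion; dispersion -> inf recovers Poisson.
    """
    r = dispersion
    m = np.maximum(mean, 1e-10)
    return (
        gammaln(k + r) - gammaln(r) - gammaln(k + 1)
        + r * (np.log(r) - np.log(r + m)) + k * (np.log(m) - np.log(r + m))
    )


def _predict_recaptures(cohort: TagCohort, traj, matrices, stock: str,
                        reporting_rates: np.ndarray, shed_rate: float,
                        n_quarters: int):
    """Expected recaptures [quarter, fleet, global area] for one stock.

    Tags are propagated with the same survival and movement as the stock;
    expected recaptures are tags-present x fleet exploitation x reporting
    rate.  Returns None when the release area is inaccessible to the stock.
    """
    cfg = traj.config
    st = cfg.structure
    si = st.stock_index(stock)
    acc = st.accessible0(stock)
    j_rel = st.area_index(cohort.area)
    if j_rel not in acc:
        return None
    local = list(acc)
    T0 = traj.t_index(cohort.year, cohort.quarter)
    sel = cfg.selectivity_matrix()
    Mq = cfg.biology[stock].M / 4.0
    tags = np.zeros(len(local))
    tags[local.index(j_rel)] = cohort.count
    pred = np.zeros((n_quarters, st.n_fleets, st.n_areas))
    for k in range(n_quarters):
        t = T0 + k
        if t >= traj.n_steps:
            break
        age = min(cohort.age + (t // 4 - T0 // 4), st.max_age)
        Z = traj.Z[t, si, age, acc]
        em = -np.expm1(-Z) / np.maximum(Z, 1e-300)
        Facc = traj.F[t][:, acc]  # [fleet, area]
        u_fj = Facc * sel[:, age, None] * em[None, :]
        pred[k, :, acc] = (tags[:, None] * u_fj.T
                           * reporting_rates[None, :])
        u_all = u_fj.sum(axis=0)
        d = Mq[age] * em
        stay = np.clip(1.0 - u_all - d - shed_rate, 0.0, 1.0)
        q = t % 4 + 1
        group = st.age_group_of(age)
        tags = (tags * stay) @ matrices[stock][group, q - 1]
    return pred


def conventional_tag_loglik(
    cohort: TagCohort,
    traj,
    matrices: dict,
    reporting_rates: np.ndarray,
    dispersion: float,
    shed_rate: float,
    mixture_weights: dict = None,
) -> float:
    """Negative-binomial NLL of a conventional-tag cohort's recaptures.

    Known-stock cohorts use that stock's dynamics; unknown-stock cohorts
    are likelihood-mixed across stocks with release-time vulnerable-numbers
    weights (held fixed within the cohort):
    NLL = -ln sum_i w_i exp(-NLL_i).
    """
    cfg = traj.config
    st = cfg.structure
    T0 = traj.t_index(cohort.year, cohort.quarter)
    n_quarters = cohort.horizon_quarters
    for area, year, quarter, fleet, n in cohort.recaptures:
        k = 4 * (year - cohort.year) + quarter - cohort.quarter
        n_quarters = max(n_quarters, k + 1)
    n_quarters = min(n_quarters, traj.n_steps - T0)

    obs = np.zeros((n_quarters, st.n_fleets, st.n_areas))
    for area, year, quarter, fleet, n in cohort.recaptures:
        k = 4 * (year - cohort.year) + quarter - cohort.quarter
        if k < n_quarters:
            obs[k, st.fleet_index(fleet), st.area_index(area)] += n

    stocks = [cohort.stock] if cohort.stock != "unknown" else list(st.stocks)
    if mixture_weights is None:
        if len(stocks) == 1:
            mixture_weights = {stocks[0]: 1.0}
        else:
            mixture_weights = stock_mixture_weights(
                traj, T0, cohort.area, min(cohort.age, st.max_age)
            )
    nlls = []
    for stock in stocks:
        pred = _predict_recaptures(
            cohort, traj, matrices, stock, reporting_rates, shed_rate,
            n_quarters,
        )
        if pred is None:
            nlls.append(np.inf)
            continue
        nlls.append(float(-np.sum(_nb_logpmf(obs, pred, dispersion))))
    if len(nlls) == 1:
        return nlls[0]
    ws = np.array([mixture_weights.get(s, 0.0) for s in stocks])
    ls = -np.array(nlls)
    finite = np.isfinite(ls) & (ws > 0)
    if not np.any(finite):
        return np.inf
    m = ls[finite].max()
    return float(-(m + np.log(np.sum(ws[finite] * np.exp(ls[finite] - m)))))


# ---------------------------------------------------------------------------
# predictions from a trajectory
# ---------------------------------------------------------------------------


def predict_index(traj, series: IndexSeries) -> np.ndarray:
    """Vulnerable biomass (both stocks) at the series' area/quarter censuses."""
    cfg = traj.config
    st = cfg.structure
    sel = cfg.selectivity_matrix()[st.fleet_index(series.fleet)]
    j = st.area_index(series.area)
    w = np.stack([cfg.biology[s].weight for s in st.stocks])
    out = np.empty(series.years.size)
    for i, year in enumerate(series.years):
        t = traj.t_index(year, series.quarter)
        out[i] = np.einsum("sa,sa,a->", traj.N[t][:, :, j], w, sel)
    return out


def predict_caa(traj, record: CAARecord) -> np.ndarray:
    """Predicted catch-at-age proportions for a region-aggregate year."""
    cfg = traj.config
    st = cfg.structure
    areas = [st.area_index(a) for a in CAA_REGIONS[record.region]]
    catch_age = np.zeros(st.n_ages)
    for q in range(1, 5):
        t = traj.t_index(record.year, q)
        caa = traj.catch_at_age_numbers(t)  # [stock, age, area]
        catch_age += caa[:, :, areas].sum(axis=(0, 2))
    lo, hi = record.age_lo, record.age_hi
    binned = np.zeros(hi - lo + 1)
    binned[:-1] = catch_age[lo:hi]
    binned[-1] = catch_age[hi:].sum()
    total = binned.sum()
    if total <= 0:
        return np.full(binned.shape, 1.0 / binned.size)
    return binned / total


def predict_otolith_fraction(traj, record: OtolithRecord) -> float:
    cfg = traj.config
    st = cfg.structure
    lo, hi = record.age_range
    hi = st.max_age if hi is None else min(hi, st.max_age)
    ages = np.arange(lo, hi + 1)
    t = traj.t_index(record.year, record.quarter)
    return west_fraction(traj, t, record.area, ages)


# ---------------------------------------------------------------------------
# the full objective
# ---------------------------------------------------------------------------


def reporting_rate_prior_nll(rates: np.ndarray, prior) -> float:
    """Negative log-prior for reporting rates (normal or beta family)."""
    rates = np.asarray(rates, float)
    if prior.family == "normal":
        return float(np.sum(0.5 * ((rates - prior.mean) / prior.sd) ** 2))
    r = _clamp(rates)
    return float(-np.sum((prior.alpha - 1) * np.log(r)
                         + (prior.beta - 1) * np.log1p(-r)))


def total_objective(
    traj,
    matrices: dict,
    bundle: ObservationBundle,
    reporting_rates: np.ndarray,
    nb_dispersion: float,
    p_obs_archival: float,
    rec_devs: dict = None,
) -> tuple:
    """Total negative log-posterior and its per-component breakdown.

    Returns (value, breakdown) where breakdown maps component name ->
    (datum count, NLL).  Components are additive and isolated: removing a
    data stream changes only its own term.
    """
    cfg = traj.config
    breakdown = {}

    nll = 0.0
    for series in bundle.cpue:
        v = cpue_loglik(series, predict_index(traj, series))
        nll += v
    breakdown["cpue"] = (len(bundle.cpue), nll)

    v_caa = 0.0
    for record in bundle.caa:
        v_caa += caa_loglik(record, predict_caa(traj, record),
                            cfg.caa_effective_n, cfg.prop_clamp)
    breakdown["caa"] = (len(bundle.caa), v_caa)

    v_oto = 0.0
    for record in bundle.otolith:
        v_oto += otolith_loglik(
            record, predict_otolith_fraction(traj, record), cfg.prop_clamp
        )
    breakdown["otolith"] = (len(bundle.otolith), v_oto)

    v_tag = 0.0
    for cohort in bundle.tag_cohorts:
        v_tag += conventional_tag_loglik(
            cohort, traj, matrices, reporting_rates, nb_dispersion,
            cfg.shed_rate,
        )
    breakdown["conventional_tags"] = (len(bundle.tag_cohorts), v_tag)

    v_etag = 0.0
    if bundle.tag_tracks:
        dyn = TagDynamics(traj, matrices, cfg.shed_rate, p_obs_archival)
        for track in bundle.tag_tracks:
            t0 = traj.t_index(track.year, track.quarter)
            if track.stock == "unknown":
                w = stock_mixture_weights(
                    traj, t0, track.area, min(track.age, cfg.structure.max_age)
                )
            else:
                w = None
            ll = track_loglik(track, dyn, w)
            if not np.isfinite(ll):
                warnings.warn(
                    f"track {track.tag_id}: impossible under both stocks"
                )
                ll = -1e6  # bounded penalty keeps the objective finite
            v_etag += -ll
    breakdown["electronic_tags"] = (len(bundle.tag_tracks), v_etag)

    v_prior = reporting_rate_prior_nll(reporting_rates, cfg.reporting_prior)
    if rec_devs is not None and cfg.sigma_r > 0:
        for devs in rec_devs.values():
            v_prior += float(np.sum(np.asarray(devs) ** 2)
                             / (2.0 * cfg.sigma_r**2))
    breakdown["priors"] = (0, v_prior)

    total = sum(v for _, v in breakdown.values())
    if not np.isfinite(total):
        bad = [k for k, (_, v) in breakdown.items() if not np.isfinite(v)]
        raise LikelihoodError(f"non-finite objective component(s): {bad}")
    return total, breakdown
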