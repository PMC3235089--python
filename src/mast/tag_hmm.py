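"""Discrete state-space (hidden-Markov) likelihood for electronic tag tracks.

A tag occupies one of n + 3 states each quarter: alive in one of the n
areas accessible to its stock, or absorbed as captured, dead of natural
causes, or shed.  Transitions combine the stock's quarterly movement matrix
with per-area exploitation (all fleets combined), the natural-death
fraction from the population mortality decomposition, and a quarterly
shedding probability.  Pop-up satellite tracks are observed every quarter
(observation probability 1); archival tags yield a usable geoposition with
a single estimated probability p_obs per quarter, and a missing quarter
contributes the Bernoulli failure factor (1 - p_obs) without restricting
the state marginal.
"""

from __future__ import annotations

import numpy as np

from .io import TagTrack

__all__ = ["build_transition", "track_loglik", "simulate_track", "TagDynamics"]


class TagError(ValueError):
    pass


def build_transition(movement: np.ndarray, u: np.ndarray, d: np.ndarray,
                     shed_rate: float) -> np.ndarray:
    """(n+3) x (n+3) transition matrix for one (stock, age-group, quarter).

    State order: alive in area 0..n-1 (local indices over the stock's
    accessible areas), then captured, natural-death, shed (absorbing).
    From alive in area j the tag is captured with u[j], dies naturally with
    d[j], is shed with shed_rate, and otherwise moves among areas by the
    movement row.
    """
    movement = np.asarray(movement, float)
    u = np.asarray(u, float)
    d = np.asarray(d, float)
    n = movement.shape[0]
    if movement.shape != (n, n) or u.shape != (n,) or d.shape != (n,):
        raise TagError("movement/u/d dimensions disagree")
    stay = 1.0 - u - d - shed_rate
    if np.any(stay < -1e-12):
        raise TagError(
            "capture + natural death + shedding exceed 1 in some area"
        )
    stay = np.clip(stay, 0.0, 1.0)
    T = np.zeros((n + 3, n + 3))
    T[:n, :n] = stay[:, None] * movement
    T[:n, n] = u
    T[:n, n + 1] = d
    T[:n, n + 2] = shed_rate
    T[n, n] = T[n + 1, n + 1] = T[n + 2, n + 2] = 1.0
    return T


class TagDynamics:
    """Adapter exposing per-quarter tag transition matrices from a model run.

    Couples the population trajectory (for exploitation and natural-death
    fractions), the movement matrices, and tag parameters.  Tag age
    advances across calendar year boundaries exactly as in the population
    dynamics, so a tag can cross the juvenile/adult movement boundary
    mid-track.
    """

    def __init__(self, traj, matrices: dict, shed_rate: float,
                 p_obs_archival: float):
        self.traj = traj
        self.matrices = matrices
        self.shed_rate = shed_rate
        self.p_obs_archival = p_obs_archival
        self.cfg = traj.config
        self.st = self.cfg.structure
        self._acc = {s: self.st.accessible0(s) for s in self.st.stocks}
        self._cache = {}

    def local_index(self, stock: str, area) -> int:
        j = self.st.area_index(area)
        acc = list(self._acc[stock])
        if j not in acc:
            raise TagError(
                f"area {area!r} not accessible to stock {stock!r}"
            )
        return acc.index(j)

    def age_at(self, release_age: int, release_t: int, t: int) -> int:
        """Calendar age of the tagged fish at quarter t (ages at year end)."""
        years_crossed = t // 4 - release_t // 4
        return min(release_age + years_crossed, self.st.max_age)

    def transition(self, stock: str, release_age: int, release_t: int,
                   t: int) -> np.ndarray:
        """Transition matrix for the step from quarter t to t + 1."""
        si = self.st.stock_index(stock)
        acc = self._acc[stock]
        age = self.age_at(release_age, release_t, t)
        key = (stock, age, t)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        q = t % 4 + 1
        group = self.st.age_group_of(age)
        mat = self.matrices[stock][group, q - 1]
        u = self.traj.exploitation(t, age)[si, acc]
        Z = self.traj.Z[t, si, age, acc]
        Mq = self.cfg.biology[stock].M[age] / 4.0
        d = Mq / np.maximum(Z, 1e-300) * (-np.expm1(-Z))
        T = build_transition(mat, u, d, self.shed_rate)
        self._cache[key] = T
        return T

    def p_obs(self, tag_type: str) -> float:
        return 1.0 if tag_type == "psat" else self.p_obs_archival


def _emission(dyn: TagDynamics, stock: str, tag_type: str, obs) -> np.ndarray:
    """Per-state observation probabilities for one quarter."""
    n = len(dyn._acc[stock])
    p = dyn.p_obs(tag_type)
    e = np.zeros(n + 3)
    if obs is None:
        e[:] = 1.0 - p
    else:
        e[dyn.local_index(stock, obs)] = p
    return e


def track_loglik(track: TagTrack, dyn: TagDynamics,
                 mixture_weights: dict = None) -> float:
    """Forward-recursion log-likelihood of one electronic-tag track.

    For unknown-stock tracks the per-stock likelihoods are mixed with
    ``mixture_weights`` (vulnerable-numbers ratios at release; uniform if
    not supplied).  An observed area outside a stock's accessible set
    yields likelihood zero for that stock (-inf if the stock is forced).
    """
    stocks = ([track.stock] if track.stock != "unknown"
              else list(dyn.st.stocks))
    if mixture_weights is None:
        mixture_weights = {s: 1.0 / len(stocks) for s in stocks}
    release_t = dyn.traj.t_index(track.year, track.quarter)
    logliks = []
    for stock in stocks:
        try:
            start = dyn.local_index(stock, track.area)
        except TagError:
            logliks.append(-np.inf)
            continue
        n = len(dyn._acc[stock])
        alpha = np.zeros(n + 3)
        alpha[start] = 1.0  # release state observed with probability 1
        log_scale = 0.0
        dead = False
        for k in range(1, track.n_quarters):
            t = release_t + k - 1
            T = dyn.transition(stock, track.age, release_t, t)
            alpha = alpha @ T
            try:
                e = _emission(dyn, stock, track.tag_type,
                              track.observations[k])
            except TagError:
                dead = True
                break
            alpha = alpha * e
            total = alpha.sum()
            if total <= 0.0:
                dead = True
                break
            log_scale += np.log(total)
            alpha = alpha / total
        logliks.append(-np.inf if dead else log_scale)
    if len(logliks) == 1:
        return float(logliks[0])
    ws = np.array([mixture_weights.get(s, 0.0) for s in stocks])
    ls = np.array(logliks)
    finite = np.isfinite(ls) & (ws > 0)
    if not np.any(finite):
        return -np.inf
    m = ls[finite].max()
    return float(m + np.log(np.sum(ws[finite] * np.exp(ls[finite] - m))))


def track_loglik_bruteforce(track: TagTrack, dyn: TagDynamics,
                            mixture_weights: dict = None) -> float:
    """Path-enumeration oracle for short tracks (exponential in length)."""
    from itertools import product

    stocks = ([track.stock] if track.stock != "unknown"
              else list(dyn.st.stocks))
    if mixture_weights is None:
        mixture_weights = {s: 1.0 / len(stocks) for s in stocks}
    release_t = dyn.traj.t_index(track.year, track.quarter)
    liks = []
    for stock in stocks:
        try:
            start = dyn.local_index(stock, track.area)
        except TagError:
            liks.append(0.0)
            continue
        n = len(dyn._acc[stock])
        n_states = n + 3
        K = track.n_quarters
        Ts = [dyn.transition(stock, track.age, release_t, release_t + k)
              for k in range(K - 1)]
        emis = []
        ok = True
        for k in range(1, K):
            try:
                emis.append(_emission(dyn, stock, track.tag_type,
                                      track.observations[k]))
            except TagError:
                ok = False
                break
        if not ok:
            liks.append(0.0)
            continue
        total = 0.0
        for path in product(range(n_states), repeat=K - 1):
            p = 1.0
            prev = start
            for k, s in enumerate(path):
                p *= Ts[k][prev, s] * emis[k][s]
                prev = s
                if p == 0.0:
                    break
            total += p
        liks.append(total)
    if len(liks) == 1:
        return float(np.log(liks[0])) if liks[0] > 0 else -np.inf
    mix = sum(mixture_weights.get(s, 0.0) * l for s, l in zip(stocks, liks))
    return float(np.log(mix)) if mix > 0 else -np.inf


def simulate_track(
    area,
    year: int,
    quarter: int,
    age: int,
    stock: str,
    tag_type: str,
    dyn: TagDynamics,
    rng: np.random.Generator,
    horizon_quarters: int = 8,
    tag_id: str = "sim",
):
    """Sample one electronic-tag track from the hidden-Markov process.

    The chain runs until absorption or the horizon; observations apply the
    tag-type observation model.  Returns a TagTrack (the reported stock is
    'unknown' — assignment is an input contract, not re-derived), or None
    when the sampled track has no usable post-release form (absorbed
    immediately with nothing observed is still a valid 1-quarter track).
    """
    release_t = dyn.traj.t_index(year, quarter)
    start = dyn.local_index(stock, area)
    n = len(dyn._acc[stock])
    p_obs = dyn.p_obs(tag_type)
    acc = dyn._acc[stock]
    areas = [dyn.st.areas[j] for j in acc]
    state = start
    observations = [areas[start]]
    for k in range(1, horizon_quarters):
        t = release_t + k - 1
        if t >= dyn.traj.n_steps - 1:
            break
        T = dyn.transition(stock, age, release_t, t)
        state = int(rng.choice(n + 3, p=T[state]))
        if state >= n:
            break  # absorbed: track ends (right-censored)
        if tag_type == "psat" or rng.random() < p_obs:
            observations.append(areas[state])
        else:
            observations.append(None)
    # archival tracks may end on a run of missing quarters; trim trailing
    # missings so serialized tracks stay well-formed
    while observations and observations[-1] is None:
        observations.pop()
    return TagTrack(
        tag_id=tag_id, tag_type=tag_type, area=areas[start], year=year,
        quarter=quarter, age=age, stock="unknown", observations=observations,
    )
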