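"""Management-oriented equilibrium parameterization.

The model is initialized from its leading parameters, maximum sustainable
yield (MSY) and the fishing mortality rate that produces it (Fmsy), rather
than from recruitment parameters directly.  Given a stock's life-history
schedules and an aggregate selectivity, per-recruit quantities

    phi_E(F)  spawning biomass per recruit (kg / recruit)
    phi_q(F)  equilibrium yield per recruit per unit F (kg / recruit)

are computed from survivorship under F * selectivity + M with a plus-group
closed form.  Under Beverton-Holt recruitment with compensation ratio kappa,
equilibrium recruitment at fishing rate F is

    R_eq(F) = R0 * (kappa - phi_E(0) / phi_E(F)) / (kappa - 1)

and equilibrium yield Y_eq(F) = F * phi_q(F) * R_eq(F).  kappa is chosen so
Y_eq is stationary at F = Fmsy, and R0 so that Y_eq(Fmsy) = MSY; unfished
spawning biomass and total biomass follow.  Units: weights in kg, numbers
in thousands of fish, so biomasses come out in tonnes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StockParams",
    "PerRecruit",
    "DerivedStock",
    "per_recruit",
    "derive_stock_recruit",
    "yield_curve",
    "equilibrium_yield",
    "beverton_holt",
]


class EquilibriumError(ValueError):
    """Raised when the leading-parameter pair admits no valid equilibrium."""


@dataclass
class StockParams:
    """Leading parameters plus the biology entering the equilibrium derivation."""

    MSY: float  # tonnes / yr
    Fmsy: float  # / yr
    M: np.ndarray  # / yr, per age
    weight: np.ndarray  # kg, per age
    maturity: np.ndarray  # [0,1], per age
    selectivity: np.ndarray  # [0,1], per age (aggregate)

    def __post_init__(self):
        self.M = np.asarray(self.M, float)
        self.weight = np.asarray(self.weight, float)
        self.maturity = np.asarray(self.maturity, float)
        self.selectivity = np.asarray(self.selectivity, float)
        if self.MSY <= 0 or self.Fmsy <= 0:
            raise EquilibriumError("MSY and Fmsy must be positive")
        if np.any((self.maturity < 0) | (self.maturity > 1)):
            raise EquilibriumError("maturity must lie in [0, 1]")
        if np.any((self.selectivity < 0) | (self.selectivity > 1)):
            raise EquilibriumError("selectivity must lie in [0, 1]")
        if np.any(self.weight <= 0):
            raise EquilibriumError("weight-at-age must be positive")


@dataclass
class PerRecruit:
    """Per-recruit quantities at one fishing rate."""

    F: float
    phi_E: float  # spawning biomass per recruit, kg
    phi_q: float  # yield per recruit per unit F, kg
    survivorship: np.ndarray  # l_a, recruit-relative numbers at age


def _survivorship(Z: np.ndarray, plus_group: bool) -> np.ndarray:
    """l_a = prod_{a'<a} exp(-Z_a'), with plus-group accumulation l_A /(1-e^-Z_A)."""
    n = Z.shape[0]
    l = np.ones(n)
    l[1:] = np.exp(-np.cumsum(Z[:-1]))
    if plus_group:
        denom = -np.expm1(-Z[-1])
        if denom <= 0.0:
            raise EquilibriumError(
                "plus group diverges: total mortality in the terminal age is zero"
            )
        l[-1] = l[-1] / denom
    return l


def per_recruit(F: float, stock: StockParams, plus_group: bool = True) -> PerRecruit:
    """Spawning biomass and yield per recruit at annual fishing rate F.

    Yield uses the Baranov exploitation fraction per age; with rates held
    constant within a year the four-quarter (M/4, F/4) discretization
    telescopes to the annual form used here.
    """
    if F < 0:
        raise EquilibriumError("F must be non-negative")
    Z = stock.M + F * stock.selectivity
    l = _survivorship(Z, plus_group)
    phi_E = float(np.sum(l * stock.maturity * stock.weight))
    # exploitation fraction u_a = (F s_a / Z_a)(1 - e^-Z_a); phi_q = YPR / F
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(Z > 0, -np.expm1(-Z) / Z, 1.0)
    phi_q = float(np.sum(l * stock.weight * stock.selectivity * frac))
    return PerRecruit(F=F, phi_E=phi_E, phi_q=phi_q, survivorship=l)


@dataclass
class DerivedStock:
    """Quantities derived from (MSY, Fmsy) and the biology."""

    kappa: float  # recruitment compensation ratio, > 1
    R0: float  # unfished recruits, thousands
    S0: float  # unfished spawning biomass, tonnes
    B0: float  # unfished total biomass, tonnes
    Smsy: float  # equilibrium spawning biomass at Fmsy, tonnes
    params: StockParams

    def unfished_numbers(self) -> np.ndarray:
        """Unfished equilibrium numbers at age (thousands), plus group closed."""
        return self.R0 * per_recruit(0.0, self.params).survivorship


def beverton_holt(S, kappa: float, R0: float, S0: float):
    """Beverton-Holt recruitment in compensation-ratio form.

    R = kappa * R0 * (S/S0) / (1 + (kappa - 1) * S/S0); R(S0) = R0.
    """
    x = np.asarray(S, float) / S0
    return kappa * R0 * x / (1.0 + (kappa - 1.0) * x)


def _requil_scale(F: float, kappa: float, stock: StockParams):
    """R_eq(F)/R0 = (kappa - phi_E(0)/phi_E(F)) / (kappa - 1); may be negative."""
    pr0 = per_recruit(0.0, stock)
    prF = per_recruit(F, stock)
    return (kappa - pr0.phi_E / prF.phi_E) / (kappa - 1.0), prF


def equilibrium_yield(F: float, kappa: float, R0: float, stock: StockParams) -> float:
    """Equilibrium yield (tonnes/yr) at F under Beverton-Holt recruitment.

    Clipped at zero where F exceeds the crash rate (R_eq would be negative).
    """
    scale, prF = _requil_scale(F, kappa, stock)
    return max(F * prF.phi_q * R0 * scale, 0.0)


def _dyield_dF(F: float, kappa: float, stock: StockParams, h: float) -> float:
    lo, hi = max(F - h, 0.0), F + h
    y_lo = equilibrium_yield(lo, kappa, 1.0, stock)
    y_hi = equilibrium_yield(hi, kappa, 1.0, stock)
    return (y_hi - y_lo) / (hi - lo)


def derive_stock_recruit(
    stock: StockParams, kappa_hi: float = 300.0, tol: float = 1e-12
) -> DerivedStock:
    """Derive kappa, R0, S0 and B0 from the leading parameters.

    kappa solves dY_eq/dF = 0 at F = Fmsy (central difference, bracketing
    bisection on (1, kappa_hi]); R0 then scales the yield curve so that
    Y_eq(Fmsy) = MSY.
    """
    F = stock.Fmsy
    h = 1e-5 * F

    def g(kappa):
        return _dyield_dF(F, kappa, stock, h)

    lo, hi = 1.0 + 1e-6, kappa_hi
    g_lo, g_hi = g(lo), g(hi)
    if g_lo > 0 or g_hi < 0:
        raise EquilibriumError(
            f"no compensation ratio in ({lo}, {hi}] makes the yield curve "
            f"stationary at Fmsy={F}: infeasible (MSY={stock.MSY}, Fmsy={F})"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if g(mid) < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(1.0, hi):
            break
    kappa = 0.5 * (lo + hi)

    scale, prF = _requil_scale(F, kappa, stock)
    y_unit = F * prF.phi_q * scale  # yield per unit R0
    if y_unit <= 0:
        raise EquilibriumError(
            f"equilibrium yield at Fmsy non-positive (MSY={stock.MSY}, Fmsy={F})"
        )
    R0 = stock.MSY / y_unit
    pr0 = per_recruit(0.0, stock)
    S0 = R0 * pr0.phi_E
    B0 = R0 * float(np.sum(pr0.survivorship * stock.weight))
    Smsy = R0 * scale * prF.phi_E
    return DerivedStock(kappa=kappa, R0=R0, S0=S0, B0=B0, Smsy=Smsy, params=stock)


def yield_curve(
    derived: DerivedStock, f_max: float = None, f_step: float = 0.002
) -> tuple:
    """Equilibrium yield over an F grid; returns (F_grid, yields)."""
    stock = derived.params
    if f_max is None:
        f_max = 4.0 * stock.Fmsy
    grid = np.arange(0.0, f_max + f_step / 2, f_step)
    ys = np.array(
        [equilibrium_yield(F, derived.kappa, derived.R0, stock) for F in grid]
    )
    return grid, ys
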