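"""Model structure: stocks, areas, fleets, ages, and the quarterly time grid.

The spatial skeleton of the assessment is categorical: five areas of the
North Atlantic (Gulf of Mexico, Gulf of St. Lawrence, western Atlantic,
eastern Atlantic, Mediterranean Sea), two stocks (western, spawning in the
Gulf of Mexico; eastern, spawning in the Mediterranean), and four gear
categories.  Western-stock fish occupy areas 1-4, eastern-stock fish areas
3-5; areas 3 and 4 are mixed-stock.  Time runs in calendar quarters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelStructure",
    "StockBiology",
    "FleetParams",
    "DEFAULT_AREAS",
    "DEFAULT_STOCKS",
    "DEFAULT_FLEETS",
]

DEFAULT_STOCKS = ("west", "east")
DEFAULT_AREAS = ("GoM", "GSL", "WAtl", "EAtl", "Med")
DEFAULT_FLEETS = ("LL", "PS", "BB", "OTH")


class StructureError(ValueError):
    """Raised when a model-structure definition violates an invariant."""


@dataclass(frozen=True)
class ModelStructure:
    """Immutable definition of the model's categorical and temporal axes.

    Parameters
    ----------
    stocks : tuple of str
        Ordered stock labels.
    areas : tuple of str
        Ordered area labels; 1-based integer indices follow this order.
    stock_area_sets : dict
        Accessible 1-based area indices per stock.
    spawning_area : dict
        1-based spawning-area index per stock.
    spawning_quarter : dict
        Spawning quarter (1-4) per stock.  Both default to Q2: the western
        stock spawns in the Gulf of Mexico in spring (April-June) and the
        eastern stock in the Mediterranean in early summer.
    first_year, last_year : int
        Calendar-year range of the conditioning data (inclusive).
    max_age : int
        Plus-group age A; ages run 0..A.
    movement_age_groups : tuple of (lo, hi)
        Contiguous, exhaustive age partition used for movement; default
        juveniles 0-7 and adults 8+.
    fleets : tuple of str
        Ordered gear labels.
    """

    stocks: tuple = DEFAULT_STOCKS
    areas: tuple = DEFAULT_AREAS
    stock_area_sets: dict = field(
        default_factory=lambda: {"west": (1, 2, 3, 4), "east": (3, 4, 5)}
    )
    spawning_area: dict = field(default_factory=lambda: {"west": 1, "east": 5})
    spawning_quarter: dict = field(default_factory=lambda: {"west": 2, "east": 2})
    first_year: int = 1950
    last_year: int = 2008
    max_age: int = 20
    movement_age_groups: tuple = ((0, 7), (8, None))
    fleets: tuple = DEFAULT_FLEETS

    def __post_init__(self):
        groups = []
        for lo, hi in self.movement_age_groups:
            groups.append((lo, self.max_age if hi is None else hi))
        object.__setattr__(self, "movement_age_groups", tuple(groups))
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        n_areas = len(self.areas)
        for stock in self.stocks:
            if stock not in self.stock_area_sets:
                raise StructureError(f"stock_area_sets missing stock {stock!r}")
            for j in self.stock_area_sets[stock]:
                if not 1 <= j <= n_areas:
                    raise StructureError(
                        f"area index {j} for stock {stock!r} outside 1..{n_areas}"
                    )
            sp = self.spawning_area[stock]
            if sp not in self.stock_area_sets[stock]:
                raise StructureError(
                    f"spawning_area {sp} for stock {stock!r} not in its area set "
                    f"{self.stock_area_sets[stock]}"
                )
            q = self.spawning_quarter[stock]
            if not 1 <= q <= 4:
                raise StructureError(f"spawning_quarter {q} for {stock!r} not in 1..4")
        if self.last_year < self.first_year:
            raise StructureError("last_year before first_year")
        # age partition must be contiguous and exhaustive over 0..max_age
        expected_lo = 0
        for lo, hi in self.movement_age_groups:
            if lo != expected_lo:
                raise StructureError(
                    f"movement_age_groups not contiguous at age {expected_lo}"
                )
            expected_lo = hi + 1
        if expected_lo != self.max_age + 1:
            raise StructureError(
                f"movement_age_groups do not cover ages 0..{self.max_age}"
            )

    # -- derived axes --------------------------------------------------
    @property
    def n_stocks(self) -> int:
        return len(self.stocks)

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    @property
    def n_fleets(self) -> int:
        return len(self.fleets)

    @property
    def n_ages(self) -> int:
        return self.max_age + 1

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.n_ages)

    @property
    def n_years(self) -> int:
        return self.last_year - self.first_year + 1

    @property
    def n_quarters(self) -> int:
        return 4 * self.n_years

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    @property
    def n_groups(self) -> int:
        return len(self.movement_age_groups)

    def stock_index(self, stock: str) -> int:
        return self.stocks.index(stock)

    def area_index(self, area) -> int:
        """0-based area index from a label or 1-based integer index."""
        if isinstance(area, str):
            if area not in self.areas:
                raise StructureError(f"unknown area label {area!r}")
            return self.areas.index(area)
        j = int(area)
        if not 1 <= j <= self.n_areas:
            raise StructureError(f"area index {j} outside 1..{self.n_areas}")
        return j - 1

    def fleet_index(self, fleet: str) -> int:
        if fleet not in self.fleets:
            raise StructureError(f"unknown fleet label {fleet!r}")
        return self.fleets.index(fleet)

    def accessible0(self, stock: str) -> np.ndarray:
        """0-based accessible area indices for a stock, in area order."""
        return np.array(sorted(j - 1 for j in self.stock_area_sets[stock]))

    def n_stock_areas(self, stock: str) -> int:
        """The symbol n of the gravity parameterization."""
        return len(self.stock_area_sets[stock])

    def area_mask(self, stock: str) -> np.ndarray:
        mask = np.zeros(self.n_areas, dtype=bool)
        mask[self.accessible0(stock)] = True
        return mask

    def age_group_of(self, age: int) -> int:
        for g, (lo, hi) in enumerate(self.movement_age_groups):
            if lo <= age <= hi:
                return g
        raise StructureError(f"age {age} outside 0..{self.max_age}")

    @property
    def age_group_index(self) -> np.ndarray:
        """Movement-group index per age (length n_ages)."""
        return np.array([self.age_group_of(a) for a in range(self.n_ages)])

    def group_mid_age(self, group: int) -> int:
        lo, hi = self.movement_age_groups[group]
        return (lo + hi) // 2

    def t_index(self, year: int, quarter: int) -> int:
        if not self.first_year <= year <= self.last_year:
            raise StructureError(f"year {year} outside {self.first_year}..{self.last_year}")
        if not 1 <= quarter <= 4:
            raise StructureError(f"quarter {quarter} not in 1..4")
        return 4 * (year - self.first_year) + (quarter - 1)

    def year_quarter(self, t: int) -> tuple:
        return self.first_year + t // 4, t % 4 + 1


@dataclass
class StockBiology:
    """Fixed life-history inputs for one stock.

    All schedules are indexed by age 0..A.  ``M`` is the instantaneous
    natural mortality rate (per year), ``weight`` mean mass (kg) and
    ``maturity`` the proportion mature.  Defaults elsewhere in the package
    are placeholder schedules with bluefin-like magnitudes, intended for
    synthetic-data work; real applications supply their own.
    """

    M: np.ndarray
    weight: np.ndarray
    maturity: np.ndarray

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=float)
        self.weight = np.asarray(self.weight, dtype=float)
        self.maturity = np.asarray(self.maturity, dtype=float)
        n = self.M.shape[0]
        if self.weight.shape[0] != n or self.maturity.shape[0] != n:
            raise StructureError("biology schedules must share one age axis")
        if np.any(self.M < 0) or not np.all(np.isfinite(self.M)):
            raise StructureError("M must be finite and non-negative")
        if np.any(self.weight <= 0):
            raise StructureError("weight-at-age must be strictly positive")
        if np.any(np.diff(self.weight) < -1e-12):
            raise StructureError("weight-at-age must be non-decreasing")
        if np.any((self.maturity < 0) | (self.maturity > 1)):
            raise StructureError("maturity must lie in [0, 1]")

    @property
    def n_ages(self) -> int:
        return self.M.shape[0]


def logistic_selectivity(ages: np.ndarray, a50: float, slope: float) -> np.ndarray:
    """Two-parameter logistic selectivity, in (0, 1], non-decreasing in age."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(ages, float) - a50) / slope))


@dataclass
class FleetParams:
    """Time-invariant logistic selectivity per fleet (age at 50%, slope)."""

    a50: np.ndarray  # per fleet
    slope: np.ndarray  # per fleet, > 0

    def __post_init__(self):
        self.a50 = np.atleast_1d(np.asarray(self.a50, dtype=float))
        self.slope = np.atleast_1d(np.asarray(self.slope, dtype=float))
        if self.a50.shape != self.slope.shape:
            raise StructureError("a50 and slope must align")
        if np.any(self.slope <= 0):
            raise StructureError("selectivity slope must be positive")

    def selectivity(self, ages: np.ndarray) -> np.ndarray:
        """Selectivity matrix [fleet, age]."""
        return logistic_selectivity(
            np.asarray(ages, float)[None, :], self.a50[:, None], self.slope[:, None]
        )
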