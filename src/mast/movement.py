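"""Row-stochastic quarterly movement matrices.

The base case is a gravity parameterization: for each (stock, age-group,
quarter, area) a single retention probability mu_jj is estimated, and the
off-diagonal entries of row j are spread uniformly as (1 - mu_jj)/(n - 1),
where n is the number of areas accessible to the stock.  The alternative
bulk-transfer mode parameterizes every row in full.  During a stock's
spawning quarter, movement into the spawning area is overridden by the
maturity schedule: each row sends probability m (the age-group
representative maturity) to the spawning area and reallocates the rest in
proportion to the base row restricted to non-spawning destinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import ModelStructure

__all__ = ["MovementParams", "gravity_matrix", "seasonal_matrix",
           "apply_movement", "build_all_matrices", "check_row_stochastic"]

ROW_TOL = 1e-12


class MovementError(ValueError):
    pass


def check_row_stochastic(matrix: np.ndarray, tol: float = ROW_TOL) -> None:
    m = np.asarray(matrix, float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise MovementError(f"movement matrix must be square, got {m.shape}")
    if np.any(m < -tol) or np.any(m > 1 + tol):
        raise MovementError("movement probabilities outside [0, 1]")
    rows = m.sum(axis=1)
    if np.any(np.abs(rows - 1.0) > 1e-9):
        raise MovementError(f"rows must sum to 1, got {rows}")


def gravity_matrix(diag, n: int) -> np.ndarray:
    """Gravity movement matrix from per-area retention probabilities.

    Row j has mu_jj = diag[j] and every off-diagonal (1 - diag[j])/(n - 1).
    """
    if n < 2:
        raise MovementError("gravity model needs at least 2 areas")
    diag = np.asarray(diag, float)
    if diag.shape != (n,):
        raise MovementError(f"need {n} retention probabilities, got {diag.shape}")
    if np.any((diag < 0) | (diag > 1)):
        raise MovementError("retention probabilities must lie in [0, 1]")
    off = (1.0 - diag) / (n - 1)
    m = np.tile(off[:, None], (1, n))
    np.fill_diagonal(m, diag)
    return m


def bulk_matrix(rows: np.ndarray) -> np.ndarray:
    """Bulk-transfer matrix from non-negative row weights (normalized)."""
    rows = np.asarray(rows, float)
    if np.any(rows < 0):
        raise MovementError("bulk weights must be non-negative")
    sums = rows.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise MovementError("bulk rows must be normalizable")
    return rows / sums


@dataclass
class MovementParams:
    """Movement parameters for all stocks, age groups and quarters.

    gravity_diag[stock][group, quarter, local_area] holds retention
    probabilities over the stock's accessible areas (local, sorted order).
    In bulk mode, bulk_rows[stock][group, quarter] is a full n x n weight
    matrix instead.
    """

    gravity_diag: dict  # stock -> array [n_groups, 4, n_stock_areas]
    mode: str = "gravity"
    bulk_rows: dict = field(default_factory=dict)

    def base_matrix(self, stock: str, group: int, quarter: int) -> np.ndarray:
        if self.mode == "bulk":
            return bulk_matrix(self.bulk_rows[stock][group, quarter - 1])
        diag = self.gravity_diag[stock][group, quarter - 1]
        return gravity_matrix(diag, diag.shape[0])

    @classmethod
    def uniform(cls, structure: ModelStructure, retention: float = 0.7):
        diag = {
            s: np.full((structure.n_groups, 4, structure.n_stock_areas(s)), retention)
            for s in structure.stocks
        }
        return cls(gravity_diag=diag)


def seasonal_matrix(
    stock: str,
    group: int,
    quarter: int,
    params: MovementParams,
    maturity_at_age: np.ndarray,
    structure: ModelStructure,
) -> np.ndarray:
    """Quarterly movement matrix with the spawning-quarter maturity override.

    Outside the spawning quarter this is the base (gravity or bulk) matrix.
    In the spawning quarter, each row moves to the spawning area with
    probability m = maturity at the age group's mid age, and distributes
    1 - m over the remaining areas in proportion to the base row restricted
    to non-spawning destinations.
    """
    if not 1 <= quarter <= 4:
        raise MovementError(f"quarter {quarter} not in 1..4")
    base = params.base_matrix(stock, group, quarter)
    if quarter != structure.spawning_quarter[stock]:
        return base
    m = float(maturity_at_age[structure.group_mid_age(group)])
    if not 0.0 <= m <= 1.0:
        raise MovementError(f"maturity {m} outside [0, 1]")
    local = list(structure.accessible0(stock))
    sp = local.index(structure.area_index(structure.spawning_area[stock]))
    n = base.shape[0]
    out = np.empty_like(base)
    for j in range(n):
        row = base[j].copy()
        rest = np.delete(row, sp)
        total = rest.sum()
        out[j] = 0.0
        out[j, sp] = m
        if total > 0:
            idx = [k for k in range(n) if k != sp]
            out[j, idx] = (1.0 - m) * rest / total
        else:
            # base row puts all mass on the spawning area already
            out[j, sp] = 1.0
    return out


def apply_movement(n_slice: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Transport numbers-by-area through a row-stochastic matrix.

    n_slice may be 1-D (areas) or 2-D (ages x areas); totals are conserved.
    """
    matrix = np.asarray(matrix, float)
    n_slice = np.asarray(n_slice, float)
    if n_slice.shape[-1] != matrix.shape[0]:
        raise MovementError(
            f"state has {n_slice.shape[-1]} areas, matrix is {matrix.shape}"
        )
    check_row_stochastic(matrix)
    if np.any(n_slice < 0):
        raise MovementError("numbers must be non-negative")
    return n_slice @ matrix


def build_all_matrices(
    params: MovementParams, biology: dict, structure: ModelStructure
) -> dict:
    """Precompute matrices[stock][group, quarter-1] -> n x n array."""
    out = {}
    for stock in structure.stocks:
        mats = np.empty(
            (structure.n_groups, 4, structure.n_stock_areas(stock),
             structure.n_stock_areas(stock))
        )
        for g in range(structure.n_groups):
            for q in range(1, 5):
                mats[g, q - 1] = seasonal_matrix(
                    stock, g, q, params, biology[stock].maturity, structure
                )
        out[stock] = mats
    return out
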