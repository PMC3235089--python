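"""Tabular input/output: catches and the five observation streams.

All files are UTF-8, comma-delimited, one header row, long (tidy) format.
Quarters are 1-based calendar quarters (Q1 = Jan-Mar).  The module also
implements the eastern-catch under-reporting adjustment, which rescales
Mediterranean catches so the summed eastern-Atlantic + Mediterranean total
matches an assumed annual level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure import ModelStructure

__all__ = [
    "CatchArray",
    "IndexSeries",
    "CAARecord",
    "OtolithRecord",
    "TagCohort",
    "TagTrack",
    "ObservationBundle",
    "read_catch_table",
    "inflate_east_catches",
    "read_observations",
    "write_observations",
]

#: otolith-microchemistry age groups: school (age <= 4), medium (5-9),
#: giant (10+)
OTOLITH_AGE_GROUPS = {"school": (0, 4), "medium": (5, 9), "giant": (10, None)}


class DataError(ValueError):
    """Raised when an input table violates its contract."""


# ---------------------------------------------------------------------------
# catches
# ---------------------------------------------------------------------------


@dataclass
class CatchArray:
    """Observed removals (tonnes) on a dense fleet x area x year x quarter grid."""

    structure: ModelStructure
    tonnes: np.ndarray  # [fleet, area, year, quarter]

    def __post_init__(self):
        st = self.structure
        expected = (st.n_fleets, st.n_areas, st.n_years, 4)
        self.tonnes = np.asarray(self.tonnes, dtype=float)
        if self.tonnes.shape != expected:
            raise DataError(
                f"catch array shape {self.tonnes.shape} != expected {expected}"
            )
        if not np.all(np.isfinite(self.tonnes)):
            raise DataError("catch array contains non-finite entries")
        if np.any(self.tonnes < 0):
            raise DataError("catch array contains negative entries")

    @classmethod
    def zeros(cls, structure: ModelStructure) -> "CatchArray":
        st = structure
        return cls(structure, np.zeros((st.n_fleets, st.n_areas, st.n_years, 4)))

    def copy(self) -> "CatchArray":
        return CatchArray(self.structure, self.tonnes.copy())

    def at_quarter(self, t: int) -> np.ndarray:
        """Catch slice [fleet, area] for flat quarter index t."""
        return self.tonnes[:, :, t // 4, t % 4]

    def year_total(self, year: int, areas=None) -> float:
        iy = year - self.structure.first_year
        sub = self.tonnes[:, :, iy, :]
        if areas is not None:
            idx = [self.structure.area_index(a) for a in areas]
            sub = sub[:, idx, :]
        return float(sub.sum())

    def to_frame(self) -> pd.DataFrame:
        st = self.structure
        fleets, areas, years, quarters = np.nonzero(self.tonnes)
        return pd.DataFrame(
            {
                "fleet": [st.fleets[f] for f in fleets],
                "area": [st.areas[a] for a in areas],
                "year": st.first_year + years,
                "quarter": quarters + 1,
                "tonnes": self.tonnes[fleets, areas, years, quarters],
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_catch_table(path_or_frame, structure: ModelStructure) -> CatchArray:
    """Read a tidy catch table (fleet, area, year, quarter, tonnes).

    Absent cells are zero; duplicate rows are summed.  Unknown labels,
    negative tonnage or out-of-range years are rejected with the offending
    row number.
    """
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame
    else:
        df = pd.read_csv(path_or_frame, float_precision="round_trip")
    required = {"fleet", "area", "year", "quarter", "tonnes"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"catch table missing columns {sorted(missing)}")
    out = CatchArray.zeros(structure)
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            f = structure.fleet_index(row.fleet)
            a = structure.area_index(row.area)
            iy = int(row.year) - structure.first_year
            if not 0 <= iy < structure.n_years:
                raise DataError(f"year {row.year} outside model horizon")
            q = int(row.quarter)
            if not 1 <= q <= 4:
                raise DataError(f"quarter {row.quarter} not in 1..4")
            tonnes = float(row.tonnes)
            if tonnes < 0:
                raise DataError(f"negative tonnes {tonnes}")
        except (ValueError, KeyError) as err:
            raise DataError(f"catch table row {row_no}: {err}") from err
        out.tonnes[f, a, iy, q - 1] += tonnes
    return out


def inflate_east_catches(
    catch: CatchArray, targets: dict, med_area="Med", east_areas=("EAtl", "Med")
) -> CatchArray:
    """Scale Mediterranean catches so eastern totals hit assumed levels.

    For each target year, all Mediterranean (area 5) cells of that year are
    multiplied by one factor chosen so that the summed eastern total (areas
    4 + 5) equals the target.  Eastern-Atlantic (area 4) cells and all other
    years are untouched.  Idempotent on already-adjusted years.
    """
    st = catch.structure
    med = st.area_index(med_area)
    east = [st.area_index(a) for a in east_areas]
    other_east = [a for a in east if a != med]
    out = catch.copy()
    for year, target in targets.items():
        iy = int(year) - st.first_year
        if not 0 <= iy < st.n_years:
            continue
        med_total = out.tonnes[:, med, iy, :].sum()
        rest = out.tonnes[:, other_east, iy, :].sum()
        needed = float(target) - rest
        if med_total <= 0.0:
            if needed > 1e-9:
                raise DataError(
                    f"year {year}: Mediterranean catch is zero but target "
                    f"{target} exceeds remaining eastern total {rest}"
                )
            continue
        factor = needed / med_total
        if factor < 0:
            raise DataError(
                f"year {year}: eastern-Atlantic catch alone exceeds target {target}"
            )
        out.tonnes[:, med, iy, :] *= factor
    return out


# ---------------------------------------------------------------------------
# observation streams
# ---------------------------------------------------------------------------


@dataclass
class IndexSeries:
    """One relative-abundance (CPUE) series.

    The series indexes vulnerable biomass in one area/quarter through the
    selectivity of a linked fleet; catchability is concentrated out of the
    likelihood, so only the observations themselves are stored.
    """

    name: str
    area: str
    quarter: int
    fleet: str
    years: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.shape != self.values.shape:
            raise DataError(f"series {self.name}: years/values misaligned")
        if self.years.size < 2:
            raise DataError(f"series {self.name}: needs at least 2 observations")
        if np.any(self.values <= 0):
            raise DataError(f"series {self.name}: index values must be positive")
        if not 1 <= self.quarter <= 4:
            raise DataError(f"series {self.name}: quarter not in 1..4")


@dataclass
class CAARecord:
    """Annual catch-at-age proportions for a region aggregate.

    region 'west' aggregates areas 1-3, 'east' areas 4-5; ages run from
    ``age_lo`` to a plus group at ``age_hi`` (default 1..10+).
    """

    region: str
    year: int
    props: np.ndarray
    age_lo: int = 1
    age_hi: int = 10

    def __post_init__(self):
        self.props = np.asarray(self.props, dtype=float)
        n = self.age_hi - self.age_lo + 1
        if self.props.shape != (n,):
            raise DataError(
                f"CAA record {self.region}/{self.year}: expected {n} proportions"
            )
        if np.any(self.props < 0):
            raise DataError(f"CAA record {self.region}/{self.year}: negative entry")
        if abs(self.props.sum() - 1.0) > 1e-6:
            raise DataError(
                f"CAA record {self.region}/{self.year}: proportions sum to "
                f"{self.props.sum():.8f}, not 1"
            )


@dataclass
class OtolithRecord:
    """Otolith-microchemistry stock-composition count for one area/age-group."""

    area: str
    age_group: str  # school | medium | giant
    year: int
    quarter: int
    n_west: int
    n_total: int

    def __post_init__(self):
        if self.age_group not in OTOLITH_AGE_GROUPS:
            raise DataError(f"unknown otolith age group {self.age_group!r}")
        if not 0 <= self.n_west <= self.n_total:
            raise DataError(
                f"otolith record {self.area}/{self.year}: n_west {self.n_west} "
                f"outside 0..{self.n_total}"
            )

    @property
    def age_range(self):
        return OTOLITH_AGE_GROUPS[self.age_group]


@dataclass
class TagCohort:
    """A conventional-tag release cohort with its recapture counts.

    Releases sharing an assigned age and release quarter form one cohort;
    recaptures are counts by (area, year, quarter, fleet).  ``stock`` may be
    'west', 'east' or 'unknown' (mixed-stock weighting applies).
    """

    cohort_id: str
    area: str
    year: int
    quarter: int
    age: int
    count: int
    stock: str = "unknown"
    recaptures: list = field(default_factory=list)  # (area, year, quarter, fleet, n)
    horizon_quarters: int = 12

    def __post_init__(self):
        if self.stock not in ("west", "east", "unknown"):
            raise DataError(f"cohort {self.cohort_id}: bad stock {self.stock!r}")
        if self.count <= 0:
            raise DataError(f"cohort {self.cohort_id}: release count must be positive")
        total_rec = 0
        t0 = 4 * self.year + self.quarter
        for area, year, quarter, fleet, n in self.recaptures:
            if n < 0 or int(n) != n:
                raise DataError(
                    f"cohort {self.cohort_id}: recapture counts must be "
                    "non-negative integers"
                )
            if 4 * year + quarter < t0:
                raise DataError(
                    f"cohort {self.cohort_id}: recapture at {year}Q{quarter} "
                    f"precedes release {self.year}Q{self.quarter}"
                )
            total_rec += n
        if total_rec > self.count:
            raise DataError(
                f"cohort {self.cohort_id}: {total_rec} recaptures exceed "
                f"{self.count} releases"
            )


@dataclass
class TagTrack:
    """A quarterly electronic-tag area track.

    ``observations`` holds one entry per quarter starting at release: an
    area label, or None for a quarter with no usable geoposition (archival
    tags only; pop-up satellite tracks are complete by construction).
    """

    tag_id: str
    tag_type: str  # archival | psat
    area: str
    year: int
    quarter: int
    age: int
    stock: str = "unknown"
    observations: list = field(default_factory=list)

    def __post_init__(self):
        if self.tag_type not in ("archival", "psat"):
            raise DataError(f"track {self.tag_id}: bad tag_type {self.tag_type!r}")
        if self.stock not in ("west", "east", "unknown"):
            raise DataError(f"track {self.tag_id}: bad stock {self.stock!r}")
        if not self.observations:
            raise DataError(f"track {self.tag_id}: empty track")
        if self.observations[0] != self.area:
            raise DataError(
                f"track {self.tag_id}: release area must be observed at t=0"
            )
        if sum(o is not None for o in self.observations) == 0:
            raise DataError(f"track {self.tag_id}: zero observed quarters")
        if self.tag_type == "psat" and any(o is None for o in self.observations):
            raise DataError(
                f"track {self.tag_id}: pop-up satellite tracks cannot have "
                "missing quarters"
            )

    @property
    def n_quarters(self) -> int:
        return len(self.observations)


@dataclass
class ObservationBundle:
    """All five observation streams; each stream individually optional."""

    cpue: list = field(default_factory=list)
    caa: list = field(default_factory=list)
    otolith: list = field(default_factory=list)
    tag_cohorts: list = field(default_factory=list)
    tag_tracks: list = field(default_factory=list)

    def validate(self, structure: ModelStructure) -> None:
        for s in self.cpue:
            structure.area_index(s.area)
            structure.fleet_index(s.fleet)
        for r in self.otolith:
            structure.area_index(r.area)
        for c in self.tag_cohorts:
            structure.area_index(c.area)
            for area, _, _, fleet, _ in c.recaptures:
                structure.area_index(area)
                structure.fleet_index(fleet)
        for tr in self.tag_tracks:
            for o in tr.observations:
                if o is not None:
                    structure.area_index(o)


# -- serialization ----------------------------------------------------------


def _cpue_frame(series_list):
    rows = []
    for s in series_list:
        for y, v in zip(s.years, s.values):
            rows.append((s.name, s.area, s.quarter, s.fleet, y, v))
    return pd.DataFrame(
        rows, columns=["series", "area", "quarter", "fleet", "year", "value"]
    )


def _caa_frame(records):
    rows = []
    for r in records:
        for age, p in zip(range(r.age_lo, r.age_hi + 1), r.props):
            rows.append((r.region, r.year, age, p))
    return pd.DataFrame(rows, columns=["region", "year", "age", "proportion"])


def _otolith_frame(records):
    return pd.DataFrame(
        [
            (r.area, r.age_group, r.year, r.quarter, r.n_west, r.n_total)
            for r in records
        ],
        columns=["area", "age_group", "year", "quarter", "n_west", "n_total"],
    )


def _cohort_frames(cohorts):
    rel = pd.DataFrame(
        [
            (c.cohort_id, c.area, c.year, c.quarter, c.age, c.count, c.stock,
             c.horizon_quarters)
            for c in cohorts
        ],
        columns=["cohort", "area", "year", "quarter", "age", "count", "stock",
                 "horizon_quarters"],
    )
    rec_rows = []
    for c in cohorts:
        for area, year, quarter, fleet, n in c.recaptures:
            rec_rows.append((c.cohort_id, area, year, quarter, fleet, n))
    rec = pd.DataFrame(
        rec_rows, columns=["cohort", "area", "year", "quarter", "fleet", "count"]
    )
    return rel, rec


def _track_frame(tracks):
    rows = []
    for tr in tracks:
        for k, obs in enumerate(tr.observations):
            t = 4 * tr.year + (tr.quarter - 1) + k
            rows.append(
                (tr.tag_id, tr.tag_type, tr.stock, tr.age, t // 4, t % 4 + 1,
                 "" if obs is None else obs)
            )
    return pd.DataFrame(
        rows, columns=["tag", "tag_type", "stock", "release_age", "year",
                       "quarter", "area"]
    )


def write_observations(bundle: ObservationBundle, paths: dict) -> None:
    """Write each stream to its CSV path; keys as in :func:`read_observations`."""
    if "cpue" in paths:
        _cpue_frame(bundle.cpue).to_csv(paths["cpue"], index=False)
    if "caa" in paths:
        _caa_frame(bundle.caa).to_csv(paths["caa"], index=False)
    if "otolith" in paths:
        _otolith_frame(bundle.otolith).to_csv(paths["otolith"], index=False)
    if "tag_releases" in paths:
        rel, rec = _cohort_frames(bundle.tag_cohorts)
        rel.to_csv(paths["tag_releases"], index=False)
        if "tag_recaptures" in paths:
            rec.to_csv(paths["tag_recaptures"], index=False)
    if "etag_tracks" in paths:
        _track_frame(bundle.tag_tracks).to_csv(paths["etag_tracks"], index=False)


def read_observations(paths: dict, structure: ModelStructure) -> ObservationBundle:
    """Assemble an ObservationBundle from per-stream CSV files.

    ``paths`` maps any subset of {'cpue', 'caa', 'otolith', 'tag_releases',
    'tag_recaptures', 'etag_tracks'} to file paths (or DataFrames).
    """

    def _load(key):
        src = paths.get(key)
        if src is None:
            return None
        if isinstance(src, pd.DataFrame):
            return src
        return pd.read_csv(src, float_precision="round_trip")

    bundle = ObservationBundle()

    df = _load("cpue")
    if df is not None and len(df):
        for (name, area, quarter, fleet), grp in df.groupby(
            ["series", "area", "quarter", "fleet"], sort=False
        ):
            grp = grp.sort_values("year")
            bundle.cpue.append(
                IndexSeries(str(name), area, int(quarter), fleet,
                            grp["year"].to_numpy(), grp["value"].to_numpy())
            )

    df = _load("caa")
    if df is not None and len(df):
        for (region, year), grp in df.groupby(["region", "year"], sort=False):
            grp = grp.sort_values("age")
            ages = grp["age"].to_numpy()
            bundle.caa.append(
                CAARecord(region, int(year), grp["proportion"].to_numpy(),
                          age_lo=int(ages[0]), age_hi=int(ages[-1]))
            )

    df = _load("otolith")
    if df is not None and len(df):
        for row in df.itertuples(index=False):
            bundle.otolith.append(
                OtolithRecord(row.area, row.age_group, int(row.year),
                              int(row.quarter), int(row.n_west), int(row.n_total))
            )

    rel = _load("tag_releases")
    if rel is not None and len(rel):
        rec = _load("tag_recaptures")
        rec_by_cohort = {}
        if rec is not None:
            for row in rec.itertuples(index=False):
                rec_by_cohort.setdefault(str(row.cohort), []).append(
                    (row.area, int(row.year), int(row.quarter), row.fleet,
                     int(row.count))
                )
        for row in rel.itertuples(index=False):
            bundle.tag_cohorts.append(
                TagCohort(
                    cohort_id=str(row.cohort), area=row.area, year=int(row.year),
                    quarter=int(row.quarter), age=int(row.age),
                    count=int(row.count), stock=row.stock,
                    recaptures=rec_by_cohort.get(str(row.cohort), []),
                    horizon_quarters=int(getattr(row, "horizon_quarters", 12)),
                )
            )

    df = _load("etag_tracks")
    if df is not None and len(df):
        for tag_id, grp in df.groupby("tag", sort=False):
            grp = grp.sort_values(["year", "quarter"])
            obs = [
                None if (pd.isna(a) or a == "") else a for a in grp["area"]
            ]
            first = grp.iloc[0]
            bundle.tag_tracks.append(
                TagTrack(
                    tag_id=str(tag_id), tag_type=first["tag_type"],
                    area=obs[0], year=int(first["year"]),
                    quarter=int(first["quarter"]),
                    age=int(first["release_age"]), stock=first["stock"],
                    observations=obs,
                )
            )

    bundle.validate(structure)
    return bundle
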