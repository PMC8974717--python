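"""Readers and writers for the pipeline's tabular and trajectory formats.

Daily airborne pollen concentrations and ground flowering observations travel
as plain CSV; back-trajectory footprints travel as HYSPLIT endpoint ("tdump")
text files.  Dates are ISO-8601 on disk and 1-based day-of-year integers in
memory; season arithmetic is always within a single calendar year.

A transcription of the published station x taxon x year table of differences
between pollen-season start and flowering start (Erlangen, Munich, Oberjoch,
1987-2017) ships with the package and is loaded with an integrity check.
"""

from __future__ import annotations

import hashlib
import io
import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STUDY_TAXA",
    "STUDY_WINDOWS",
    "DailyPollenSeries",
    "PhenoObservation",
    "TrajectoryPoint",
    "Trajectory",
    "Table2Record",
    "Table2Fixture",
    "read_pollen_table",
    "write_pollen_table",
    "read_pheno_table",
    "write_pheno_table",
    "parse_tdump",
    "write_tdump",
    "load_table2_fixture",
    "haversine_km",
    "ValidationError",
    "TableParseError",
    "FixtureIntegrityError",
]

#: The seven taxa monitored both aerobiologically and phenologically.
STUDY_TAXA = ("Corylus", "Alnus", "Betula", "Fraxinus", "Pinus", "Poaceae", "Artemisia")

#: Year windows of the transport study per station (trajectory-covered years).
STUDY_WINDOWS: Mapping[str, tuple[int, int]] = {
    "Erlangen": (2005, 2012),
    "Munich": (2005, 2015),
    "Oberjoch": (2005, 2015),
}

_TABLE2_RESOURCE = "table2_sos_differences.csv"
_TABLE2_SHA256 = "ca077ab31d3ea00097af2c29a0e3a89ac3f0084ad4bb2b552c344c75ee021ca0"

EARTH_RADIUS_KM = 6371.0088
KM_PER_DEG_LAT = 110.574
KM_PER_DEG_LON_EQUATOR = 111.320


def km_per_deg_lon(lat: float) -> float:
    """Kilometres per degree of longitude at a given latitude."""
    return KM_PER_DEG_LON_EQUATOR * math.cos(math.radians(lat))


class ValidationError(ValueError):
    """Input violates a domain invariant (range, sign, ordering)."""


class TableParseError(ValueError):
    """A tabular or trajectory file could not be parsed."""


class FixtureIntegrityError(RuntimeError):
    """The packaged reference table failed its checksum."""


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance between two points in kilometres."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def initial_bearing_deg(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Initial great-circle bearing from point 1 to point 2, degrees from north."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    y = math.sin(dl) * math.cos(p2)
    x = math.cos(p1) * math.sin(p2) - math.sin(p1) * math.cos(p2) * math.cos(dl)
    return math.degrees(math.atan2(y, x)) % 360.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DailyPollenSeries:
    """One station x taxon x year vector of daily pollen concentrations.

    ``values`` holds ``(doy, concentration)`` pairs with strictly increasing
    1-based day-of-year; missing days carry ``nan``.  ``first_operation_doy``
    is the day the trap started operating that year, needed for the
    late-start reliability checks.
    """

    station_id: str
    taxon: str
    year: int
    first_operation_doy: int
    values: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        doys = [d for d, _ in self.values]
        if any(not (1 <= d <= 366) for d in doys):
            raise ValidationError(f"{self.key()}: day-of-year outside 1..366")
        if any(b <= a for a, b in zip(doys, doys[1:])):
            raise ValidationError(f"{self.key()}: days not strictly increasing")
        concs = [c for _, c in self.values if not math.isnan(c)]
        if any(c < 0 for c in concs):
            raise ValidationError(f"{self.key()}: negative concentration")
        present = [d for d, c in self.values if not math.isnan(c)]
        if present and self.first_operation_doy > min(present):
            raise ValidationError(
                f"{self.key()}: first_operation_doy after first observed value"
            )

    def key(self) -> tuple[str, str, int]:
        return (self.station_id, self.taxon, self.year)

    @property
    def doys(self) -> np.ndarray:
        return np.array([d for d, _ in self.values], dtype=int)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for _, c in self.values], dtype=float)

    def with_values(self, doys: Iterable[int], concs: Iterable[float]) -> "DailyPollenSeries":
        return replace(self, values=tuple(zip([int(d) for d in doys],
                                              [float(c) for c in concs])))


@dataclass(frozen=True)
class PhenoObservation:
    """One flowering-onset observation: site, position, elevation, species, year."""

    site_id: str
    lat: float
    lon: float
    elevation_m: float
    species: str
    year: int
    onset_doy: float  # integer in observational files; fractional allowed in memory

    def __post_init__(self) -> None:
        if not -90 <= self.lat <= 90:
            raise ValidationError(f"site {self.site_id}: latitude {self.lat} out of range")
        if not -180 <= self.lon <= 180:
            raise ValidationError(f"site {self.site_id}: longitude {self.lon} out of range")
        if not 1 <= self.onset_doy <= 366:
            raise ValidationError(f"site {self.site_id}: onset day {self.onset_doy} out of range")
        if self.elevation_m is None or math.isnan(self.elevation_m):
            raise ValidationError(f"site {self.site_id}: elevation missing")


@dataclass(frozen=True)
class TrajectoryPoint:
    age_hours: float  # 0 at the receptor, negative backwards in time
    lat: float
    lon: float
    altitude_m: float


@dataclass(frozen=True)
class Trajectory:
    """One backward trajectory: start time/place plus its endpoint track.

    Ages are non-positive and decreasing (0, -3, -6, ...); points beyond the
    nominal 72 h window are retained but flagged via :attr:`exceeds_window`.
    """

    start_year: int
    start_month: int
    start_day: int
    start_hour: int
    start_lat: float
    start_lon: float
    start_altitude_m: float
    points: tuple[TrajectoryPoint, ...]
    window_hours: float = 72.0

    def __post_init__(self) -> None:
        ages = [p.age_hours for p in self.points]
        if any(a > 0 for a in ages):
            raise ValidationError("trajectory point with positive age")
        if any(b >= a for a, b in zip(ages, ages[1:])):
            raise ValidationError("trajectory ages not strictly decreasing")

    @property
    def exceeds_window(self) -> bool:
        return any(abs(p.age_hours) > self.window_hours for p in self.points)


@dataclass(frozen=True)
class Table2Record:
    station: str
    taxon: str
    year: int
    diff_days: float  # SOS_P - SOS_F; nan when missing
    missing_reason: str | None = None  # "n.a." (not measured) or "d." (discarded)

    @property
    def present(self) -> bool:
        return not math.isnan(self.diff_days)


@dataclass(frozen=True)
class Table2Fixture:
    """The packaged station x taxon x year table of SOS_P - SOS_F differences."""

    records: tuple[Table2Record, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "station": [r.station for r in self.records],
                "taxon": [r.taxon for r in self.records],
                "year": [r.year for r in self.records],
                "diff_days": [r.diff_days for r in self.records],
                "missing_reason": [r.missing_reason for r in self.records],
            }
        )

    def cell(self, station: str, taxon: str, year: int) -> Table2Record:
        for r in self.records:
            if (r.station, r.taxon, r.year) == (station, taxon, year):
                return r
        raise KeyError((station, taxon, year))

    def study_window(self) -> "Table2Fixture":
        """Restrict to the trajectory-study years per station."""
        recs = tuple(
            r
            for r in self.records
            if r.station in STUDY_WINDOWS
            and STUDY_WINDOWS[r.station][0] <= r.year <= STUDY_WINDOWS[r.station][1]
        )
        return Table2Fixture(records=recs)

    def present_records(self) -> tuple[Table2Record, ...]:
        return tuple(r for r in self.records if r.present)


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

#: Default column names for pollen tables; override any key to adapt headers.
POLLEN_DIALECT = {
    "station_id": "station_id",
    "date": "date",
    "taxon": "taxon",
    "concentration": "concentration",
}

#: Default column names for phenology tables.
PHENO_DIALECT = {
    "site_id": "site_id",
    "lat": "lat",
    "lon": "lon",
    "elevation_m": "elevation_m",
    "species": "species",
    "year": "year",
    "onset_doy": "onset_doy",
}


def _resolve_dialect(defaults: Mapping[str, str], dialect: Mapping[str, str] | None) -> dict:
    cols = dict(defaults)
    if dialect:
        unknown = set(dialect) - set(defaults)
        if unknown:
            raise ValueError(f"unknown dialect keys: {sorted(unknown)}")
        cols.update(dialect)
    return cols


def read_pollen_table(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> list[DailyPollenSeries]:
    """Read a daily pollen concentration CSV into per station x taxon x year series.

    Dates are parsed as ISO-8601 and converted to day-of-year.  Missing days
    may be encoded either as absent rows or as empty concentration cells; both
    become ``nan`` in the series.  Duplicate (station, date, taxon) rows are
    rejected.
    """
    cols = _resolve_dialect(POLLEN_DIALECT, dialect)
    df = pd.read_csv(path, float_precision="round_trip")
    required = [cols[k] for k in ("station_id", "date", "taxon", "concentration")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableParseError(f"{path}: missing columns {missing}")
    try:
        dates = pd.to_datetime(df[cols["date"]], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise TableParseError(f"{path}: malformed date ({exc})") from exc
    df = df.assign(_year=dates.dt.year, _doy=dates.dt.dayofyear)

    dup = df.duplicated(subset=[cols["station_id"], cols["date"], cols["taxon"]], keep=False)
    if dup.any():
        first = df.loc[dup].iloc[0]
        raise TableParseError(
            f"{path}: duplicate rows for key "
            f"({first[cols['station_id']]}, {first[cols['date']]}, {first[cols['taxon']]})"
        )
    conc = pd.to_numeric(df[cols["concentration"]], errors="coerce")
    if (conc.dropna() < 0).any():
        bad = df.loc[conc < 0].iloc[0]
        raise ValidationError(
            f"{path}: negative concentration for "
            f"({bad[cols['station_id']]}, {bad[cols['date']]}, {bad[cols['taxon']]})"
        )
    df = df.assign(_conc=conc.astype(float).where(conc.notna(), np.nan))

    out: list[DailyPollenSeries] = []
    for (station, taxon, year), grp in df.groupby(
        [cols["station_id"], cols["taxon"], "_year"], sort=True
    ):
        grp = grp.sort_values("_doy")
        values = tuple(zip(grp["_doy"].astype(int), grp["_conc"].astype(float)))
        present = grp.loc[grp["_conc"].notna(), "_doy"]
        first_op = int(grp["_doy"].min()) if present.empty else int(min(grp["_doy"].min(), present.min()))
        out.append(
            DailyPollenSeries(
                station_id=str(station),
                taxon=str(taxon),
                year=int(year),
                first_operation_doy=first_op,
                values=values,
            )
        )
    return out


def write_pollen_table(
    series: Iterable[DailyPollenSeries], path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> None:
    """Write series back to the pollen CSV layout (inverse of read_pollen_table)."""
    cols = _resolve_dialect(POLLEN_DIALECT, dialect)
    rows = []
    for s in series:
        base = pd.Timestamp(year=s.year, month=1, day=1)
        for doy, conc in s.values:
            rows.append(
                {
                    cols["station_id"]: s.station_id,
                    cols["date"]: (base + pd.Timedelta(days=doy - 1)).date().isoformat(),
                    cols["taxon"]: s.taxon,
                    cols["concentration"]: conc,  # NaN renders as an empty cell
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_pheno_table(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> list[PhenoObservation]:
    """Read a flowering-onset observation CSV (one row per site x species x year)."""
    cols = _resolve_dialect(PHENO_DIALECT, dialect)
    df = pd.read_csv(path, float_precision="round_trip")
    required = list(cols.values())
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableParseError(f"{path}: missing columns {missing}")
    dup = df.duplicated(subset=[cols["site_id"], cols["species"], cols["year"]], keep=False)
    if dup.any():
        first = df.loc[dup].iloc[0]
        raise TableParseError(
            f"{path}: duplicate observation for "
            f"({first[cols['site_id']]}, {first[cols['species']]}, {first[cols['year']]})"
        )
    out = []
    for _, row in df.iterrows():
        elev = row[cols["elevation_m"]]
        out.append(
            PhenoObservation(
                site_id=str(row[cols["site_id"]]),
                lat=float(row[cols["lat"]]),
                lon=float(row[cols["lon"]]),
                elevation_m=float(elev) if pd.notna(elev) else float("nan"),
                species=str(row[cols["species"]]),
                year=int(row[cols["year"]]),
                onset_doy=float(row[cols["onset_doy"]]),
            )
        )
    return out


def write_pheno_table(
    observations: Iterable[PhenoObservation], path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> None:
    cols = _resolve_dialect(PHENO_DIALECT, dialect)
    rows = [
        {
            cols["site_id"]: o.site_id,
            cols["lat"]: o.lat,
            cols["lon"]: o.lon,
            cols["elevation_m"]: o.elevation_m,
            cols["species"]: o.species,
            cols["year"]: o.year,
            cols["onset_doy"]: o.onset_doy,
        }
        for o in observations
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# HYSPLIT endpoint ("tdump") files
# ---------------------------------------------------------------------------
#
# Targeted layout (HYSPLIT >= v4 endpoint output, whitespace separated):
#
#   <n_met> [format-id]
#   n_met lines of meteorology-grid identification
#   <n_traj> <direction> <vertical-motion>
#   n_traj start lines:  yy mm dd hh  lat  lon  altitude
#   <n_vars> var-names...
#   endpoint records:
#     tnum grid yy mm dd hh mm fh age lat lon alt [diagnostics...]
#
# Only trajectory number, time, age, lat, lon and altitude are consumed;
# trailing diagnostic columns are tolerated and ignored.


def parse_tdump(path: str | Path) -> list[Trajectory]:
    """Parse a HYSPLIT trajectory endpoint file into :class:`Trajectory` objects.

    Raises :class:`TableParseError` with a line number on truncated records or
    endpoints referencing an undeclared trajectory index.  An empty endpoint
    section yields an empty list with a warning.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    pos = 0

    def next_fields(what: str) -> list[str]:
        nonlocal pos
        while pos < len(lines) and not lines[pos].strip():
            pos += 1
        if pos >= len(lines):
            raise TableParseError(f"{path}: unexpected end of file in {what}")
        fields = lines[pos].split()
        pos += 1
        return fields

    try:
        n_met = int(next_fields("header")[0])
    except (ValueError, IndexError) as exc:
        raise TableParseError(f"{path}: line 1: bad grid count") from exc
    for _ in range(n_met):
        next_fields("meteorology block")
    traj_hdr = next_fields("trajectory count line")
    n_traj = int(traj_hdr[0])

    starts = []
    for _ in range(n_traj):
        f = next_fields("trajectory start line")
        if len(f) < 7:
            raise TableParseError(f"{path}: line {pos}: truncated start line")
        yy, mm, dd, hh = (int(x) for x in f[:4])
        starts.append((yy, mm, dd, hh, float(f[4]), float(f[5]), float(f[6])))
    next_fields("variable count line")  # diagnostic variable names, ignored

    points: dict[int, list[TrajectoryPoint]] = {i + 1: [] for i in range(n_traj)}
    saw_endpoint = False
    while pos < len(lines):
        line = lines[pos]
        pos += 1
        if not line.strip():
            continue
        f = line.split()
        if len(f) < 12:
            raise TableParseError(f"{path}: line {pos}: truncated endpoint record")
        saw_endpoint = True
        tnum = int(f[0])
        if tnum not in points:
            raise TableParseError(f"{path}: line {pos}: unknown trajectory index {tnum}")
        age, lat, lon, alt = float(f[8]), float(f[9]), float(f[10]), float(f[11])
        points[tnum].append(TrajectoryPoint(age_hours=age, lat=lat, lon=lon, altitude_m=alt))

    if not saw_endpoint:
        warnings.warn(f"{path}: no endpoint records found", stacklevel=2)
        return []

    out = []
    for i, (yy, mm, dd, hh, lat, lon, alt) in enumerate(starts, start=1):
        pts = sorted(points[i], key=lambda p: -p.age_hours)
        year = yy if yy > 100 else (1900 + yy if yy >= 70 else 2000 + yy)
        traj = Trajectory(
            start_year=year, start_month=mm, start_day=dd, start_hour=hh,
            start_lat=lat, start_lon=lon, start_altitude_m=alt,
            points=tuple(pts),
        )
        if traj.exceeds_window:
            warnings.warn(
                f"{path}: trajectory {i} has endpoints older than "
                f"{traj.window_hours:.0f} h (retained)", stacklevel=2,
            )
        out.append(traj)
    return out


def write_tdump(trajectories: Sequence[Trajectory], path: str | Path) -> None:
    """Write trajectories in the endpoint layout accepted by :func:`parse_tdump`."""
    lines = ["     1     1", "    SYNTH    0    0    0    0"]
    lines.append(f"{len(trajectories):6d} BACKWARD OMEGA")
    for t in trajectories:
        yy = t.start_year % 100
        lines.append(
            f"{yy:6d}{t.start_month:6d}{t.start_day:6d}{t.start_hour:6d}"
            f" {t.start_lat:9.4f} {t.start_lon:9.4f} {t.start_altitude_m:8.1f}"
        )
    lines.append("     1 PRESSURE")
    for i, t in enumerate(trajectories, start=1):
        yy = t.start_year % 100
        for p in t.points:
            lines.append(
                f"{i:6d}{1:6d}{yy:6d}{t.start_month:6d}{t.start_day:6d}"
                f"{t.start_hour:6d}{0:6d}{0:6d}"
                f" {p.age_hours:8.1f} {p.lat:9.4f} {p.lon:9.4f} {p.altitude_m:9.1f}"
                f" {900.0:9.1f}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Packaged reference table
# ---------------------------------------------------------------------------


def load_table2_fixture() -> Table2Fixture:
    """Load the packaged SOS_P - SOS_F difference table (1987-2017, 3 stations).

    Missing cells carry ``nan`` with the transcribed reason: ``"n.a."`` for
    years without measurements and ``"d."`` for discarded seasons.  The file
    is checksummed; a mismatch raises :class:`FixtureIntegrityError`.
    """
    ref = resources.files("pollenwave").joinpath("data", _TABLE2_RESOURCE)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _TABLE2_SHA256:
        raise FixtureIntegrityError(
            f"packaged table checksum mismatch: {digest} != {_TABLE2_SHA256}"
        )
    df = pd.read_csv(io.BytesIO(raw), dtype=str)
    records = []
    for _, row in df.iterrows():
        cell = row["diff_days"]
        if cell in ("n.a.", "d."):
            diff, reason = float("nan"), cell
        else:
            diff, reason = float(int(cell)), None
            if not -100 <= diff <= 100:
                raise FixtureIntegrityError(f"out-of-range cell {row.to_dict()}")
        records.append(
            Table2Record(
                station=row["station"], taxon=row["taxon"], year=int(row["year"]),
                diff_days=diff, missing_reason=reason,
            )
        )
    return Table2Fixture(records=tuple(records))
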