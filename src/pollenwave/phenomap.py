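"""Spatial interpolation of flowering onset dates.

Ground flowering observations are regionalised with the overlapping-circle
scheme used by operational phenology services: within each circle the onset
day-of-year is regressed on elevation, longitude and latitude,

    DOY = a0 + a1*h + a2*lon + a3*lat,

the fitted coefficients are attached to the circle centre, interpolated to
any target point by inverse distance weighting (IDW) over the nearest two to
four circles, and evaluated on a regular pixel grid carrying elevation.  The
per-pixel onset surfaces feed two consumers: extraction of the flowering
start (SOS_F) at the pollen-station pixels, and per-pixel trend distributions
against which station trends are compared.

Circle membership is Euclidean in degree space (the circle radius is given in
degrees); IDW distances are great-circle kilometres between circle centres
and the target.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .aero_io import PhenoObservation, haversine_km
from .season import UndefinedTrendError, linear_trend

__all__ = [
    "Circle",
    "CircleModel",
    "FloweringSurface",
    "default_circle_lattice",
    "fit_circle_model",
    "interpolate_coefficients",
    "predict_doy_grid",
    "extract_site_sosf",
    "pixel_trend_distribution",
    "PixelTrendDistribution",
    "CoverageError",
]

DEFAULT_RADIUS_DEG = 1.95
DEFAULT_MIN_N = 10
DEFAULT_IDW_POWER = 2.0
IDW_K_MIN = 2
IDW_K_MAX = 4


class CoverageError(ValueError):
    """Not enough fitted circles to interpolate at a target location."""


@dataclass(frozen=True)
class Circle:
    """One regression region: centre plus radius in degrees."""

    center_lat: float
    center_lon: float
    radius_deg: float = DEFAULT_RADIUS_DEG

    def __post_init__(self) -> None:
        if self.radius_deg <= 0:
            raise ValueError("circle radius must be positive")

    def contains(self, lat: float, lon: float) -> bool:
        return math.hypot(lat - self.center_lat, lon - self.center_lon) <= self.radius_deg


@dataclass(frozen=True)
class CircleModel:
    """Fitted per-circle regression DOY = a0 + a1*h + a2*lon + a3*lat."""

    circle: Circle
    a0: float  # days
    a1: float  # days per metre of elevation
    a2: float  # days per degree longitude
    a3: float  # days per degree latitude
    n_obs: int
    rmse: float

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.a0, self.a1, self.a2, self.a3])

    def predict(self, h: float, lon: float, lat: float) -> float:
        return self.a0 + self.a1 * h + self.a2 * lon + self.a3 * lat


@dataclass(frozen=True)
class FloweringSurface:
    """Interpolated flowering onset on a regular lat/lon grid for one year.

    ``lats``/``lons`` are pixel-centre axes (strictly increasing, uniform
    step); ``elevation_m`` and ``sos_f`` are (n_lat, n_lon) arrays, the latter
    unrounded with ``nan`` outside circle coverage.
    """

    species: str
    year: int
    lats: np.ndarray
    lons: np.ndarray
    elevation_m: np.ndarray
    sos_f: np.ndarray

    def __post_init__(self) -> None:
        if self.sos_f.shape != (len(self.lats), len(self.lons)):
            raise ValueError("sos_f shape does not match grid axes")
        if self.elevation_m.shape != self.sos_f.shape:
            raise ValueError("elevation shape does not match grid axes")

    @property
    def sos_f_rounded(self) -> np.ndarray:
        """Integer-day surface for reporting (nearest day, half away from zero)."""
        out = np.full(self.sos_f.shape, np.nan)
        ok = np.isfinite(self.sos_f)
        out[ok] = np.floor(self.sos_f[ok] + 0.5)
        return out

    def pixel_index(self, lat: float, lon: float) -> tuple[int, int]:
        """Locate the pixel containing a point (half-open bins, lower edge inclusive)."""
        i = _locate(self.lats, lat)
        j = _locate(self.lons, lon)
        return i, j


def _locate(axis: np.ndarray, x: float) -> int:
    if len(axis) == 1:
        return 0
    step = float(axis[1] - axis[0])
    idx = int(math.floor((x - (axis[0] - step / 2)) / step))
    if not 0 <= idx < len(axis):
        raise CoverageError(f"coordinate {x} outside grid [{axis[0]}, {axis[-1]}]")
    return idx


def default_circle_lattice(
    observations: Iterable[PhenoObservation],
    n_circles: int = 30,
    radius_deg: float = DEFAULT_RADIUS_DEG,
) -> list[Circle]:
    """Lay a regular lattice of overlapping circles over the data bounding box.

    The lattice aspect follows the bounding box so that roughly ``n_circles``
    centres cover it; used when no operational circle geometry is supplied.
    """
    obs = list(observations)
    if not obs:
        raise ValueError("no observations to cover")
    lats = np.array([o.lat for o in obs])
    lons = np.array([o.lon for o in obs])
    lat_span = max(float(lats.max() - lats.min()), 1e-6)
    lon_span = max(float(lons.max() - lons.min()), 1e-6)
    ny = max(1, round(math.sqrt(n_circles * lat_span / lon_span)))
    nx = max(1, math.ceil(n_circles / ny))
    cy = np.linspace(lats.min(), lats.max(), ny)
    cx = np.linspace(lons.min(), lons.max(), nx)
    return [Circle(center_lat=float(a), center_lon=float(b), radius_deg=radius_deg)
            for a in cy for b in cx][:max(n_circles, 1)]


def fit_circle_model(
    observations: Iterable[PhenoObservation],
    circle: Circle,
    min_n: int = DEFAULT_MIN_N,
) -> CircleModel | None:
    """OLS fit of onset DOY on (elevation, lon, lat) within one circle.

    Returns ``None`` (skip-marker) when fewer than ``min_n`` member
    observations exist or the design matrix is rank deficient; degenerate
    circles are expected at the domain edge, not an error.
    """
    members = [o for o in observations if circle.contains(o.lat, o.lon)]
    if len(members) < max(min_n, 4):
        return None
    X = np.column_stack([
        np.ones(len(members)),
        [o.elevation_m for o in members],
        [o.lon for o in members],
        [o.lat for o in members],
    ])
    y = np.array([o.onset_doy for o in members], dtype=float)
    if np.linalg.matrix_rank(X) < 4:
        return None
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rmse = float(np.sqrt(np.mean(resid**2)))
    return CircleModel(
        circle=circle,
        a0=float(coef[0]), a1=float(coef[1]), a2=float(coef[2]), a3=float(coef[3]),
        n_obs=len(members), rmse=rmse,
    )


def interpolate_coefficients(
    models: Sequence[CircleModel | None],
    lat: float,
    lon: float,
    k_min: int = IDW_K_MIN,
    k_max: int = IDW_K_MAX,
    power: float = DEFAULT_IDW_POWER,
) -> np.ndarray:
    """IDW-interpolate the four regression coefficients to a target point.

    Uses the ``k`` nearest fitted circle centres with ``k = min(k_max,
    available)`` and weights ``1/d**power`` on great-circle distance.  A
    target coincident with a centre returns that circle's coefficients
    (distance-zero limit).  Fewer than ``k_min`` fitted circles raise
    :class:`CoverageError`.
    """
    fitted = [m for m in models if m is not None]
    if len(fitted) < k_min:
        raise CoverageError(
            f"need >= {k_min} fitted circles for interpolation, have {len(fitted)}"
        )
    dists = np.array([
        haversine_km(lat, lon, m.circle.center_lat, m.circle.center_lon) for m in fitted
    ])
    order = np.argsort(dists, kind="stable")
    k = min(k_max, len(fitted))
    sel = order[:k]
    d = dists[sel]
    if d[0] == 0.0:
        return fitted[int(sel[0])].coefficients.copy()
    w = 1.0 / d**power
    w /= w.sum()
    coefs = np.stack([fitted[int(i)].coefficients for i in sel])
    return w @ coefs


def predict_doy_grid(
    models: Sequence[CircleModel | None],
    lats: Sequence[float],
    lons: Sequence[float],
    elevation_m: np.ndarray,
    species: str = "",
    year: int = 0,
    k_min: int = IDW_K_MIN,
    k_max: int = IDW_K_MAX,
    power: float = DEFAULT_IDW_POWER,
) -> FloweringSurface:
    """Evaluate the interpolated regression on a regular pixel grid.

    Pixels outside all circle coverage get ``nan`` and are counted in a
    warning.  Coefficients are interpolated per pixel from circles covering
    it; when a pixel lies inside no circle but fitted circles exist nearby
    the nearest-circle coefficients would be extrapolation, so the pixel is
    left unpredicted.
    """
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    elevation_m = np.asarray(elevation_m, dtype=float)
    fitted = [m for m in models if m is not None]
    if len(fitted) < k_min:
        raise CoverageError(f"need >= {k_min} fitted circles, have {len(fitted)}")

    sos = np.full((len(lats), len(lons)), np.nan)
    n_uncovered = 0
    for i, la in enumerate(lats):
        for j, lo in enumerate(lons):
            covering = [m for m in fitted if m.circle.contains(la, lo)]
            if not covering:
                n_uncovered += 1
                continue
            if len(covering) < k_min:
                # inside coverage but too few local circles: fall back to the
                # global set so every covered pixel gets a prediction
                covering = fitted
            coef = interpolate_coefficients(covering, la, lo, k_min=k_min,
                                            k_max=k_max, power=power)
            h = elevation_m[i, j]
            sos[i, j] = coef[0] + coef[1] * h + coef[2] * lo + coef[3] * la
    if n_uncovered:
        warnings.warn(f"{n_uncovered} pixels outside circle coverage left unpredicted",
                      stacklevel=2)
    return FloweringSurface(species=species, year=year, lats=lats, lons=lons,
                            elevation_m=elevation_m, sos_f=sos)


def extract_site_sosf(surface: FloweringSurface, lat: float, lon: float) -> float:
    """SOS_F of the pixel containing a station (half-open bins, lower edge inclusive)."""
    i, j = surface.pixel_index(lat, lon)
    val = surface.sos_f[i, j]
    if not np.isfinite(val):
        raise CoverageError(f"station pixel ({lat}, {lon}) has no prediction")
    return float(val)


@dataclass(frozen=True)
class PixelTrendDistribution:
    """Distribution of per-pixel onset trends over a period of surfaces."""

    slopes: np.ndarray          # one slope per covered pixel, days/yr
    quantiles: dict[float, float]  # 2.5/25/50/75/97.5 percentiles

    def contains(self, station_slope: float) -> bool:
        """Is a station trend inside the central 95% of pixel trends?"""
        return self.quantiles[2.5] <= station_slope <= self.quantiles[97.5]


def pixel_trend_distribution(
    surfaces: Sequence[FloweringSurface],
    years: Sequence[int] | None = None,
) -> PixelTrendDistribution:
    """Per-pixel OLS slopes of SOS_F over years, summarised by quantiles.

    All surfaces must share the same grid.  Pixels missing in any year are
    dropped; at least three years are required.
    """
    if len(surfaces) < 3:
        raise UndefinedTrendError("need >= 3 yearly surfaces for pixel trends")
    ref = surfaces[0]
    for s in surfaces[1:]:
        if (len(s.lats) != len(ref.lats) or len(s.lons) != len(ref.lons)
                or not np.allclose(s.lats, ref.lats) or not np.allclose(s.lons, ref.lons)):
            raise ValueError("surfaces use inconsistent grids")
    if years is None:
        years = [s.year for s in surfaces]
    t = np.asarray(years, dtype=float)

    stack = np.stack([s.sos_f for s in surfaces])  # (n_years, n_lat, n_lon)
    ok = np.isfinite(stack).all(axis=0)
    vals = stack[:, ok]  # (n_years, n_pix)
    if vals.shape[1] == 0:
        raise CoverageError("no pixel covered in every year")
    tc = t - t.mean()
    denom = float((tc**2).sum())
    slopes = (tc @ (vals - vals.mean(axis=0))) / denom
    qs = {q: float(np.percentile(slopes, q)) for q in (2.5, 25, 50, 75, 97.5)}
    return PixelTrendDistribution(slopes=slopes, quantiles=qs)
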