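"""Pollen-season definition and quality control.

The season of one station x taxon x year is characterised by four parameters:
start (SOS_P) and end (EOS_P) by the percentage method — the first days at
which the cumulative daily concentration reaches alpha% and (100 - alpha)% of
the annual total, alpha = 2.5 by default — the peak day (PEAK_P, earliest day
of maximum concentration) and the annual pollen integral (SUM_P, the sum of
all daily concentrations).

Interior missing days are filled by linear interpolation ("lineal"
imputation) before the season is defined; the pre-imputation missing mask is
kept for the reliability checks.  Daily concentrations are mapped to clinical
intensity classes (nil / low / medium / high) by configurable per-taxon
cut-points, and multi-year series of season parameters get ordinary
least-squares trends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from .aero_io import DailyPollenSeries, ValidationError

__all__ = [
    "SeasonParams",
    "TrendResult",
    "DEFAULT_INTENSITY_CUTPOINTS",
    "INTENSITY_LABELS",
    "impute_lineal",
    "define_season_percentage",
    "classify_intensity",
    "check_sos_reliability",
    "linear_trend",
    "SEASON_METHODS",
    "register_season_method",
    "UndefinedSeasonError",
    "UndefinedTrendError",
]

# Reliability flags
LATE_START_CONC = "LATE_START_CONC"        # trap already caught >4 grains/m3 on day 1
LATE_START_PHENO = "LATE_START_PHENO"      # trap started <10 days before local flowering
HIGH_MISSING = "HIGH_MISSING"              # >20% of in-season days missing pre-imputation
OP_AFTER_FLOWERING = "OP_AFTER_FLOWERING"  # trap started after local flowering
LEADING_TRAILING_MISSING = "LEADING_TRAILING_MISSING"  # unimputable edge gaps

#: First-day concentration above which the season start is suspect (grains/m3).
LATE_START_CONC_THRESHOLD = 4.0
#: Minimum lead (days) of trap start before local flowering.
LATE_START_LEAD_DAYS = 10
#: Maximum tolerated fraction of missing days within the season.
MISSING_FRACTION_LIMIT = 0.20


class UndefinedSeasonError(ValueError):
    """Season parameters cannot be defined (zero or missing annual total)."""


class UndefinedTrendError(ValueError):
    """Too few paired observations for a trend."""


@dataclass(frozen=True)
class SeasonParams:
    """Percentage-method season parameters for one station x taxon x year."""

    station_id: str
    taxon: str
    year: int
    sos_p: int
    peak_p: int
    eos_p: int
    sum_p: float
    missing_fraction_in_season: float = 0.0
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.sos_p <= self.peak_p <= self.eos_p:
            raise ValidationError(
                f"season ordering violated: {self.sos_p} <= {self.peak_p} <= {self.eos_p}"
            )
        if self.sum_p < 0:
            raise ValidationError("negative annual pollen integral")
        if not 0 <= self.missing_fraction_in_season <= 1:
            raise ValidationError("missing fraction outside [0, 1]")


@dataclass(frozen=True)
class TrendResult:
    slope: float          # days/yr (or grains m-3 yr-1 for sums)
    p_value: float
    n_years: int
    intercept: float = float("nan")


def impute_lineal(series: DailyPollenSeries) -> DailyPollenSeries:
    """Fill interior missing days by linear interpolation between neighbours.

    Operates on the full day range spanned by the series: gaps between listed
    days are treated as missing days too.  Present values are never altered;
    leading/trailing missing days stay missing (they have no bracketing
    neighbour) and are reported via the LEADING_TRAILING_MISSING flag
    downstream.
    """
    conc = series.concentrations
    doys = series.doys
    present = ~np.isnan(conc)
    if present.sum() < 2:
        if present.sum() == 0:
            raise UndefinedSeasonError(f"{series.key()}: all values missing")
        return series  # single point: nothing to interpolate

    full_doys = np.arange(doys[0], doys[-1] + 1)
    full = np.full(full_doys.shape, np.nan)
    full[doys - doys[0]] = conc
    known = ~np.isnan(full)
    first, last = np.flatnonzero(known)[[0, -1]]
    interior = np.arange(first, last + 1)
    full[interior] = np.interp(
        full_doys[interior], full_doys[known], full[known]
    )
    return series.with_values(full_doys, full)


def define_season_percentage(series: DailyPollenSeries, alpha: float = 2.5) -> SeasonParams:
    """Define SOS_P / PEAK_P / EOS_P / SUM_P by the percentage method.

    SOS_P is the first day at which the cumulative concentration reaches
    alpha% of the annual total (closed bound: >=), EOS_P the first day at
    which it reaches (100 - alpha)%.  PEAK_P is the earliest day of maximum
    concentration within [SOS_P, EOS_P] (the trimmed tails cannot host the
    peak unless every day ties, in which case the earliest in-season tie
    wins); SUM_P is the total over all days.  Remaining missing days (edges
    not reachable by imputation) contribute zero to the sums and are reported
    in ``missing_fraction_in_season``.
    """
    if not 0 <= alpha < 50:
        raise ValueError("alpha must be in [0, 50)")
    doys = series.doys
    conc = series.concentrations
    mask = np.isnan(conc)
    vals = np.where(mask, 0.0, conc)
    total = float(vals.sum())
    if total <= 0:
        raise UndefinedSeasonError(f"{series.key()}: zero annual pollen total")

    csum = np.cumsum(vals)
    # strict > for the start threshold at alpha=0 so SOS is the first nonzero day
    lo = alpha / 100.0 * total
    hi = (100.0 - alpha) / 100.0 * total
    if alpha == 0:
        sos_idx = int(np.flatnonzero(vals > 0)[0])
        eos_idx = int(np.flatnonzero(vals > 0)[-1])
    else:
        sos_idx = int(np.flatnonzero(csum >= lo)[0])
        eos_idx = int(np.flatnonzero(csum >= hi)[0])
    # earliest in-season maximum (argmax returns the first of tied maxima)
    peak_idx = sos_idx + int(np.argmax(vals[sos_idx:eos_idx + 1]))

    in_season = (doys >= doys[sos_idx]) & (doys <= doys[eos_idx])
    missing_frac = float(mask[in_season].mean()) if in_season.any() else 0.0
    flags = set()
    if mask.any():
        # only edge gaps survive impute_lineal
        flags.add(LEADING_TRAILING_MISSING)
    return SeasonParams(
        station_id=series.station_id,
        taxon=series.taxon,
        year=series.year,
        sos_p=int(doys[sos_idx]),
        peak_p=int(doys[peak_idx]),
        eos_p=int(doys[eos_idx]),
        sum_p=total,
        missing_fraction_in_season=missing_frac,
        flags=frozenset(flags),
    )


#: Registry of season-definition methods; alternative definitions (logistic,
#: moving, clinical, grains) can be registered by users under their own names.
SEASON_METHODS: dict[str, Callable[..., SeasonParams]] = {
    "percentage": define_season_percentage,
}


def register_season_method(name: str, fn: Callable[..., SeasonParams]) -> None:
    if name in SEASON_METHODS:
        raise ValueError(f"season method {name!r} already registered")
    SEASON_METHODS[name] = fn


# ---------------------------------------------------------------------------
# Intensity classification
# ---------------------------------------------------------------------------

INTENSITY_LABELS = ("nil", "low", "medium", "high")

#: Default (low, medium, high) lower cut-points in grains/m3, closed from
#: below: a concentration equal to a cut-point belongs to the higher class.
#: Values follow the order of magnitude of published clinical scales for
#: tree, grass and herb pollen; they are configuration, not constants.
DEFAULT_INTENSITY_CUTPOINTS: Mapping[str, tuple[float, float, float]] = {
    "Corylus": (1.0, 11.0, 101.0),
    "Alnus": (1.0, 11.0, 101.0),
    "Betula": (1.0, 11.0, 101.0),
    "Fraxinus": (1.0, 11.0, 101.0),
    "Pinus": (1.0, 11.0, 101.0),
    "Poaceae": (1.0, 6.0, 51.0),
    "Artemisia": (1.0, 6.0, 31.0),
}


def classify_intensity(
    concentration: float,
    taxon: str,
    table: Mapping[str, tuple[float, float, float]] | None = None,
) -> str:
    """Map a daily concentration to nil / low / medium / high for one taxon."""
    if concentration < 0 or math.isnan(concentration):
        raise ValidationError(f"invalid concentration {concentration}")
    table = DEFAULT_INTENSITY_CUTPOINTS if table is None else table
    if taxon not in table:
        raise KeyError(
            f"taxon {taxon!r} has no intensity cut-points; configured: {sorted(table)}"
        )
    cuts = table[taxon]
    if not (cuts[0] < cuts[1] < cuts[2]):
        raise ValidationError(f"cut-points for {taxon} not strictly increasing: {cuts}")
    label = "nil"
    for cut, name in zip(cuts, INTENSITY_LABELS[1:]):
        if concentration >= cut:
            label = name
    return label


# ---------------------------------------------------------------------------
# Reliability checks and trends
# ---------------------------------------------------------------------------


def check_sos_reliability(
    series: DailyPollenSeries,
    season: SeasonParams,
    sos_f: float,
) -> frozenset[str]:
    """Flag season starts that may be artefacts of late trap operation or gaps.

    ``series`` must be the raw (pre-imputation) series: the in-season missing
    fraction is judged on the original mask.  ``sos_f`` is the interpolated
    local flowering onset at the station pixel.
    """
    flags: set[str] = set()
    doys = series.doys
    conc = series.concentrations
    op = series.first_operation_doy

    first_idx = np.flatnonzero(doys == op)
    if first_idx.size and not math.isnan(conc[first_idx[0]]):
        if conc[first_idx[0]] > LATE_START_CONC_THRESHOLD:
            flags.add(LATE_START_CONC)
    if op > sos_f - LATE_START_LEAD_DAYS:
        flags.add(LATE_START_PHENO)
    if op > sos_f:
        flags.add(OP_AFTER_FLOWERING)

    in_season = (doys >= season.sos_p) & (doys <= season.eos_p)
    season_days = season.eos_p - season.sos_p + 1
    n_missing = season_days - int((~np.isnan(conc[in_season])).sum())
    if season_days > 0 and n_missing / season_days > MISSING_FRACTION_LIMIT:
        flags.add(HIGH_MISSING)
    return frozenset(flags)


def linear_trend(years: Sequence[float], values: Sequence[float]) -> TrendResult:
    """OLS trend of a season parameter over years, with two-sided slope p-value.

    Pairs with a missing year or value are dropped; at least three finite
    pairs are required.
    """
    y = np.asarray(years, dtype=float)
    v = np.asarray(values, dtype=float)
    if y.shape != v.shape:
        raise ValueError("years and values must have equal length")
    keep = np.isfinite(y) & np.isfinite(v)
    y, v = y[keep], v[keep]
    if y.size < 3:
        raise UndefinedTrendError(f"need >= 3 paired values, got {y.size}")
    res = stats.linregress(y, v)
    p = float(res.pvalue)
    if math.isnan(p):  # zero-variance response: flat line, no evidence of trend
        p = 1.0 if res.slope == 0 else 0.0
    return TrendResult(slope=float(res.slope), p_value=p, n_years=int(y.size),
                       intercept=float(res.intercept))
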