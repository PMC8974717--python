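"""Green-wave extrapolation of flowering dates and trajectory-based confirmation.

Spring phenology sweeps across Europe as a "green wave" whose direction turns
through the season: in early spring it progresses from WSW toward ENE, then
from SW toward NE, from SSW toward NNE in late spring, and roughly south to
north in summer.  Given the flowering onset SOS_F at a receptor and a wave
segment (bearing the wave moves toward, speed in km/day), the flowering date
anywhere else is extrapolated by projecting the displacement from that point
to the receptor onto the wave bearing: points up-wave flower earlier, points
down-wave later, by projected-distance / speed days.

For each hypothesised transport case the earliest extrapolated flowering date
(SOS_T) under the 72 h back-trajectory footprint is computed for the season
start day and the two days before.  A day is scored high when SOS_T <= SOS_P
(sources were already flowering when the pollen arrived), medium when
SOS_P < SOS_T <= SOS_F, zero when SOS_T > SOS_F.  Transport is confirmed if
any of the three days scores high, partly confirmed if none is high but some
day is medium, and rejected otherwise.

Wave speeds are not bundled as scientific defaults: construct a
:class:`GreenWaveModel` with explicit per-segment speeds, or use
:func:`example_model` whose placeholder values only illustrate the expected
order of magnitude.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .aero_io import KM_PER_DEG_LAT, Trajectory, km_per_deg_lon

__all__ = [
    "WaveSegment",
    "GreenWaveModel",
    "DayLikelihood",
    "OverallAssessment",
    "TransportAssessment",
    "DEFAULT_SEGMENT_WINDOWS",
    "example_model",
    "wave_segment_for_doy",
    "extrapolate_sos_t",
    "earliest_sos_t",
    "assess_transport",
]


class DayLikelihood(enum.Enum):
    HIGH = "high"
    MEDIUM = "medium"
    ZERO = "zero"


class OverallAssessment(enum.Enum):
    CONFIRMED = "confirmed"
    PARTLY_CONFIRMED = "partly_confirmed"
    REJECTED = "rejected"


@dataclass(frozen=True)
class WaveSegment:
    """One seasonal segment of the green wave.

    ``doy_start``/``doy_end`` bound a half-open window [start, end); the
    bearing is the direction the wave moves toward, degrees clockwise from
    north; speed is km/day of onset-isoline progression.
    """

    doy_start: int
    doy_end: int  # exclusive
    bearing_deg: float
    speed_km_per_day: float

    def __post_init__(self) -> None:
        if self.speed_km_per_day <= 0:
            raise ValueError("wave speed must be positive")
        if not 1 <= self.doy_start < self.doy_end <= 367:
            raise ValueError("segment window must satisfy 1 <= start < end <= 367")


#: Seasonal windows and wave bearings (toward): early spring ENE, mid spring
#: NE, late spring NNE, summer N.  Window boundaries are configuration; these
#: defaults split the flowering year at conventional season edges.
DEFAULT_SEGMENT_WINDOWS: tuple[tuple[int, int, float], ...] = (
    (1, 91, 67.5),     # early spring: toward ENE
    (91, 136, 45.0),   # mid spring: toward NE
    (136, 167, 22.5),  # late spring: toward NNE
    (167, 367, 0.0),   # summer onward: toward N
)


@dataclass(frozen=True)
class GreenWaveModel:
    """Piecewise-seasonal green-wave direction/speed model covering DOY 1-366."""

    segments: tuple[WaveSegment, ...]

    def __post_init__(self) -> None:
        segs = sorted(self.segments, key=lambda s: s.doy_start)
        if not segs or segs[0].doy_start != 1 or segs[-1].doy_end < 367:
            raise ValueError("segments must cover day-of-year 1..366")
        for a, b in zip(segs, segs[1:]):
            if a.doy_end != b.doy_start:
                raise ValueError(
                    f"segments must tile without gap/overlap at doy {a.doy_end}"
                )

    @classmethod
    def from_speeds(
        cls,
        speeds: Sequence[float] | Mapping[int, float] | float,
        windows: Sequence[tuple[int, int, float]] = DEFAULT_SEGMENT_WINDOWS,
    ) -> "GreenWaveModel":
        """Build a model from the default seasonal windows and explicit speeds.

        ``speeds`` is one value per window (or a single value used for all).
        """
        if isinstance(speeds, (int, float)):
            speeds = [float(speeds)] * len(windows)
        if len(speeds) != len(windows):
            raise ValueError(f"need {len(windows)} speeds, got {len(speeds)}")
        segs = tuple(
            WaveSegment(doy_start=a, doy_end=b, bearing_deg=brg, speed_km_per_day=float(sp))
            for (a, b, brg), sp in zip(windows, speeds)
        )
        return cls(segments=segs)


def example_model() -> GreenWaveModel:
    """Placeholder-speed model for demonstrations and smoke tests.

    The 40/35/30/25 km/day values are literature-order magnitudes of spring
    onset progression across Europe, NOT fitted or published calibrations;
    reproduction runs must supply their own speeds.
    """
    return GreenWaveModel.from_speeds([40.0, 35.0, 30.0, 25.0])


def wave_segment_for_doy(model: GreenWaveModel, doy: int) -> WaveSegment:
    """The unique seasonal segment containing a day-of-year (half-open windows)."""
    if not 1 <= doy <= 366:
        raise ValueError(f"day-of-year {doy} outside 1..366")
    for seg in model.segments:
        if seg.doy_start <= doy < seg.doy_end:
            return seg
    raise AssertionError("validated model must cover 1..366")  # pragma: no cover


def extrapolate_sos_t(
    point_lat: float,
    point_lon: float,
    receptor_lat: float,
    receptor_lon: float,
    receptor_sos_f: float,
    model: GreenWaveModel,
) -> float:
    """Extrapolated flowering onset at a point, from the receptor's SOS_F.

    The displacement point -> receptor is projected onto the wave bearing of
    the segment containing the receptor's flowering day; SOS_T = SOS_F -
    projection_km / speed.  Up-wave points (the wave reaches them first) get
    earlier dates, down-wave points later, perpendicular displacement none.

    The projection uses a local equirectangular plane tangent at the receptor
    (metre-per-degree-longitude fixed at the receptor latitude).  This keeps
    the extrapolation exactly antisymmetric in the displacement sign and
    stays within ~1% of the great-circle projection at back-trajectory
    distances, which is far below the uncertainty of any wave-speed estimate.
    """
    seg = wave_segment_for_doy(model, int(max(1, min(366, round(receptor_sos_f)))))
    dy = (receptor_lat - point_lat) * KM_PER_DEG_LAT
    dx = (receptor_lon - point_lon) * km_per_deg_lon(receptor_lat)
    b = math.radians(seg.bearing_deg)
    projection = dx * math.sin(b) + dy * math.cos(b)
    return float(receptor_sos_f - projection / seg.speed_km_per_day)


def earliest_sos_t(
    trajectories: Sequence[Trajectory],
    receptor_lat: float,
    receptor_lon: float,
    receptor_sos_f: float,
    model: GreenWaveModel,
) -> float:
    """Earliest extrapolated flowering date under one day's trajectory footprint.

    Every endpoint of every trajectory is evaluated (the finest footprint);
    the minimum over points is returned.
    """
    points = [p for t in trajectories for p in t.points]
    if not points:
        raise ValueError("no trajectory points to evaluate")
    return min(
        extrapolate_sos_t(p.lat, p.lon, receptor_lat, receptor_lon,
                          receptor_sos_f, model)
        for p in points
    )


@dataclass(frozen=True)
class TransportAssessment:
    """Per-day SOS_T likelihoods and the overall confirmation verdict."""

    sos_p: float
    sos_f: float
    sos_t_by_day: tuple[float, ...]  # SOS_P day, -1 day, -2 days (nan = no data)
    day_likelihoods: tuple[DayLikelihood, ...]
    overall: OverallAssessment

    def __post_init__(self) -> None:
        likes = [l for l in self.day_likelihoods]
        has_high = DayLikelihood.HIGH in likes
        has_medium = DayLikelihood.MEDIUM in likes
        expected = (
            OverallAssessment.CONFIRMED if has_high
            else OverallAssessment.PARTLY_CONFIRMED if has_medium
            else OverallAssessment.REJECTED
        )
        if self.overall is not expected:
            raise ValueError("overall verdict inconsistent with day likelihoods")
        if self.overall is OverallAssessment.REJECTED:
            assert all(
                t > self.sos_f for t in self.sos_t_by_day if not math.isnan(t)
            ), "rejected verdict requires SOS_T > SOS_F on every assessed day"
        if self.overall is OverallAssessment.CONFIRMED:
            assert any(
                t <= self.sos_p for t in self.sos_t_by_day if not math.isnan(t)
            ), "confirmed verdict requires SOS_T <= SOS_P on some day"


def _day_likelihood(sos_t: float, sos_p: float, sos_f: float) -> DayLikelihood:
    if sos_t <= sos_p:
        return DayLikelihood.HIGH
    if sos_t <= sos_f:
        return DayLikelihood.MEDIUM
    return DayLikelihood.ZERO


def assess_transport(
    sos_t_per_day: Sequence[float],
    sos_p: float,
    sos_f: float,
) -> TransportAssessment:
    """Score the three assessment days and derive the overall verdict.

    ``sos_t_per_day`` holds SOS_T for the season-start day and the two days
    before it; ``nan`` marks a day without trajectory data (excluded).  All
    days missing is an error.  A day is high if SOS_T <= SOS_P, medium if
    SOS_P < SOS_T <= SOS_F, zero if SOS_T > SOS_F; overall: confirmed on any
    high day, partly confirmed on any medium (no high) day, else rejected.
    """
    ts = tuple(float(t) for t in sos_t_per_day)
    if len(ts) != 3:
        raise ValueError("expected three per-day SOS_T values (SOS_P day, -1, -2)")
    available = [t for t in ts if not math.isnan(t)]
    if not available:
        raise ValueError("no trajectory day available for assessment")
    likes = tuple(_day_likelihood(t, sos_p, sos_f) for t in available)
    has_high = DayLikelihood.HIGH in likes
    has_medium = DayLikelihood.MEDIUM in likes
    overall = (
        OverallAssessment.CONFIRMED if has_high
        else OverallAssessment.PARTLY_CONFIRMED if has_medium
        else OverallAssessment.REJECTED
    )
    return TransportAssessment(
        sos_p=float(sos_p), sos_f=float(sos_f), sos_t_by_day=ts,
        day_likelihoods=likes, overall=overall,
    )
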