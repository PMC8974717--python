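"""Synthetic inputs with known ground truth for every pipeline stage.

The monitoring data behind the method (pollen-trap series, volunteer
phenology networks, computed back trajectories) are restricted-access, so
this module generates labelled stand-ins:

* pollen years: a Gaussian-shaped unimodal season curve (centre, width,
  amplitude) plus truncated-at-zero Gaussian day noise, optional missing-day
  spells and an optional pre-season transport pulse; the truth record carries
  the percentage-method parameters of the noise-free curve;
* phenology networks: sites placed uniformly in a coordinate box with onset
  days generated from the plane DOY = a0 + a1*h + a2*lon + a3*lat plus noise;
* back trajectories: eight starts per day at 3 h intervals drifting toward a
  chosen origin bearing over 72 h, also written as endpoint text files for
  parser round-trips;
* full transport scenarios: consistent pollen year, flowering surface and
  trajectories whose end-to-end classification must equal the requested
  label.

Every generator takes a seed and is deterministic given it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .aero_io import (
    KM_PER_DEG_LAT,
    DailyPollenSeries,
    PhenoObservation,
    Trajectory,
    TrajectoryPoint,
    km_per_deg_lon,
    write_tdump,
)
from .greenwave import GreenWaveModel
from .phenomap import FloweringSurface
from .season import define_season_percentage

__all__ = [
    "PollenScenario",
    "NetworkScenario",
    "PollenTruth",
    "simulate_pollen_year",
    "simulate_pheno_network",
    "simulate_trajectories",
    "flat_surface",
    "TransportScenarioBundle",
    "build_transport_scenario",
]

_km_per_deg_lon = km_per_deg_lon


@dataclass(frozen=True)
class PollenScenario:
    """Generating parameters for one synthetic pollen year."""

    center_doy: float = 110.0
    width_days: float = 12.0        # Gaussian sigma of the season curve
    amplitude: float = 80.0         # peak concentration, grains/m3
    noise_sd: float = 0.0           # truncated-at-zero Gaussian day noise
    missing_spells: tuple[tuple[int, int], ...] = ()  # (start_doy, length) gaps
    pulse_offset_days: float = 0.0  # pre-season pulse lead before season centre
    pulse_magnitude: float = 0.0    # pulse peak concentration
    first_operation_doy: int = 1
    n_days: int = 365  # 366 for leap years; day 366 of a common year would
    # spill into the next calendar year on CSV round-trips
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_days <= 0 or self.amplitude <= 0:
            raise ValueError("width and amplitude must be positive")
        if self.pulse_offset_days < 0:
            raise ValueError("pulse offset must be >= 0")


@dataclass(frozen=True)
class PollenTruth:
    """Percentage-method parameters of the noise-free generating curve."""

    sos: int
    peak: int
    eos: int
    total: float
    pulse_doy: int | None = None


def _season_curve(scn: PollenScenario, doys: np.ndarray) -> np.ndarray:
    curve = scn.amplitude * np.exp(-0.5 * ((doys - scn.center_doy) / scn.width_days) ** 2)
    if scn.pulse_magnitude > 0:
        pulse_doy = scn.center_doy - scn.pulse_offset_days
        curve = curve + scn.pulse_magnitude * np.exp(-0.5 * ((doys - pulse_doy) / 1.5) ** 2)
    return curve


def simulate_pollen_year(
    scenario: PollenScenario,
    station_id: str = "SYN",
    taxon: str = "Betula",
    year: int = 2010,
    include_pulse_in_truth: bool = False,
) -> tuple[DailyPollenSeries, PollenTruth]:
    """Generate one pollen year plus the truth parameters of its clean curve.

    The truth SOS/PEAK/EOS are the percentage-method parameters of the
    noise-free base season curve (without the transport pulse unless
    ``include_pulse_in_truth``), so a pulse placed ahead of the season pulls
    the measured SOS_P forward relative to truth by construction.
    """
    scn = scenario
    rng = np.random.default_rng(scn.seed)
    doys = np.arange(scn.first_operation_doy, scn.n_days + 1)

    clean_base = scn.amplitude * np.exp(-0.5 * ((doys - scn.center_doy) / scn.width_days) ** 2)
    clean_full = _season_curve(scn, doys)
    truth_curve = clean_full if include_pulse_in_truth else clean_base
    truth_series = DailyPollenSeries(
        station_id=station_id, taxon=taxon, year=year,
        first_operation_doy=scn.first_operation_doy,
        values=tuple(zip(doys.tolist(), truth_curve.tolist())),
    )
    params = define_season_percentage(truth_series)
    truth = PollenTruth(
        sos=params.sos_p, peak=params.peak_p, eos=params.eos_p, total=params.sum_p,
        pulse_doy=(int(round(scn.center_doy - scn.pulse_offset_days))
                   if scn.pulse_magnitude > 0 else None),
    )

    values = clean_full.copy()
    if scn.noise_sd > 0:
        # counting noise perturbs days with airborne pollen; off-season days
        # stay zero as in real trap records (no spurious baseline mass)
        pollen_days = clean_full >= 0.5
        noise = rng.normal(0.0, scn.noise_sd, values.shape)
        values[pollen_days] = np.maximum(0.0, values[pollen_days] + noise[pollen_days])
    for start, length in scn.missing_spells:
        gap = (doys >= start) & (doys < start + length)
        values[gap] = np.nan

    series = DailyPollenSeries(
        station_id=station_id, taxon=taxon, year=year,
        first_operation_doy=scn.first_operation_doy,
        values=tuple(zip(doys.tolist(), values.tolist())),
    )
    return series, truth


@dataclass(frozen=True)
class NetworkScenario:
    """Generating parameters for a synthetic flowering observation network."""

    a0: float = 60.0
    a1: float = 0.03    # days per metre elevation
    a2: float = -2.0    # days per degree longitude
    a3: float = 4.0     # days per degree latitude
    n_sites: int = 80
    lat_range: tuple[float, float] = (47.0, 50.5)
    lon_range: tuple[float, float] = (9.0, 13.8)
    elevation_range: tuple[float, float] = (100.0, 1200.0)
    noise_sd_days: float = 0.0
    a0_trend_per_year: float = 0.0  # imposed shift of a0 per year
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 4:
            raise ValueError("need >= 4 sites for a rank-4 design")
        if self.noise_sd_days < 0:
            raise ValueError("noise sd must be >= 0")

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.a0, self.a1, self.a2, self.a3])


def simulate_pheno_network(
    scenario: NetworkScenario,
    years: Sequence[int] = (2010,),
    species: str = "Betula pendula",
    round_days: bool = True,
) -> tuple[list[PhenoObservation], np.ndarray]:
    """Generate observations from the regression plane plus noise.

    Site positions are fixed across years (a volunteer network revisits the
    same sites); the per-year intercept drifts by ``a0_trend_per_year``.
    Onset days are rounded to integer days as real observations are unless
    ``round_days=False`` (useful for exact-recovery checks).  Returns the
    observations and the year-0 truth coefficients (a0, a1, a2, a3).
    """
    scn = scenario
    rng = np.random.default_rng(scn.seed)
    lat = rng.uniform(*scn.lat_range, scn.n_sites)
    lon = rng.uniform(*scn.lon_range, scn.n_sites)
    h = rng.uniform(*scn.elevation_range, scn.n_sites)

    obs = []
    y0 = years[0]
    for yr in years:
        a0 = scn.a0 + scn.a0_trend_per_year * (yr - y0)
        doy = a0 + scn.a1 * h + scn.a2 * lon + scn.a3 * lat
        if scn.noise_sd_days > 0:
            doy = doy + rng.normal(0.0, scn.noise_sd_days, scn.n_sites)
        if round_days:
            doy = np.round(doy)
        doy = np.clip(doy, 1, 366)
        for i in range(scn.n_sites):
            obs.append(
                PhenoObservation(
                    site_id=f"S{i:03d}", lat=float(lat[i]), lon=float(lon[i]),
                    elevation_m=float(h[i]), species=species, year=int(yr),
                    onset_doy=float(doy[i]),
                )
            )
    return obs, scn.coefficients


def simulate_trajectories(
    origin_bearing_deg: float,
    distance_km: float,
    receptor_lat: float,
    receptor_lon: float,
    start_year: int = 2010,
    start_month: int = 4,
    start_day: int = 15,
    n_per_day: int = 8,
    jitter_km: float = 0.0,
    altitude_m: float = 500.0,
    seed: int = 0,
    tdump_path: str | Path | None = None,
) -> list[Trajectory]:
    """Eight 72 h back trajectories drifting toward an origin bearing.

    ``origin_bearing_deg`` is the bearing from the receptor toward the air-mass
    origin; endpoints move linearly along it up to ``distance_km`` at age
    -72 h, at 3 h resolution (25 points including the start), with optional
    isotropic position jitter.  When ``tdump_path`` is given the set is also
    written in the endpoint text layout for parser round-trips.

    ``distance_km`` of zero keeps every endpoint at the receptor.
    """
    if distance_km < 0:
        raise ValueError("distance must be >= 0")
    rng = np.random.default_rng(seed)
    ages = -np.arange(0.0, 73.0, 3.0)  # 0 .. -72 h
    brg = math.radians(origin_bearing_deg)
    trajs = []
    for k in range(n_per_day):
        frac = -ages / 72.0
        d = distance_km * frac
        dlat = d * math.cos(brg) / KM_PER_DEG_LAT
        dlon = d * math.sin(brg) / _km_per_deg_lon(receptor_lat)
        lats = receptor_lat + dlat
        lons = receptor_lon + dlon
        if jitter_km > 0:
            # start point stays exactly at the receptor
            jl = rng.normal(0.0, jitter_km, lats.shape) / KM_PER_DEG_LAT
            jo = rng.normal(0.0, jitter_km, lons.shape) / _km_per_deg_lon(receptor_lat)
            jl[0] = jo[0] = 0.0
            lats = lats + jl
            lons = lons + jo
        points = tuple(
            TrajectoryPoint(age_hours=float(a), lat=float(la), lon=float(lo),
                            altitude_m=altitude_m)
            for a, la, lo in zip(ages, lats, lons)
        )
        trajs.append(
            Trajectory(
                start_year=start_year, start_month=start_month, start_day=start_day,
                start_hour=3 * k, start_lat=receptor_lat, start_lon=receptor_lon,
                start_altitude_m=altitude_m, points=points,
            )
        )
    if tdump_path is not None:
        write_tdump(trajs, tdump_path)
    return trajs


def flat_surface(
    sos_f: float,
    species: str = "Betula pendula",
    year: int = 2010,
    lat_range: tuple[float, float] = (47.0, 50.5),
    lon_range: tuple[float, float] = (9.0, 13.8),
    n: int = 8,
) -> FloweringSurface:
    """A constant flowering surface, handy as a controlled scenario backdrop."""
    lats = np.linspace(*lat_range, n)
    lons = np.linspace(*lon_range, n)
    shape = (n, n)
    return FloweringSurface(
        species=species, year=year, lats=lats, lons=lons,
        elevation_m=np.zeros(shape), sos_f=np.full(shape, float(sos_f)),
    )


@dataclass(frozen=True)
class TransportScenarioBundle:
    """A consistent end-to-end input bundle with its expected outcomes."""

    label: str
    series: DailyPollenSeries
    truth: PollenTruth
    sos_f: float
    trajectories_by_day: tuple[list[Trajectory], ...]  # SOS_P day, -1, -2
    receptor_lat: float
    receptor_lon: float
    wave_model: GreenWaveModel
    expected_source_class: str
    expected_overall: str | None


def build_transport_scenario(
    label: str,
    seed: int = 0,
    receptor_lat: float = 48.1,
    receptor_lon: float = 11.6,
    noise_sd_days: float = 0.0,
) -> TransportScenarioBundle:
    """Construct a labelled scenario whose pipeline output is known.

    ``label`` is one of ``local``, ``preseason_transport`` or ``faulty``:

    * local — pollen season starts within the +-10 day band around flowering;
      trajectories stay at the receptor.
    * preseason_transport — a pre-season pulse pulls SOS_P >= 10 days ahead
      of flowering and trajectories reach 600 km up-wave, where extrapolated
      flowering leads by ~20 days at 30 km/day: classified transport and
      confirmed.
    * faulty — the pollen season starts >= 10 days after flowering;
      trajectories stay at the receptor (no transport signal).

    ``noise_sd_days`` jitters both the pollen-season timing (whole-curve day
    shift, affecting SOS_P) and the flowering date SOS_F by independent
    Gaussian draws of that sd; generating offsets sit ~>= 15 days from each
    decision boundary so labels remain recoverable under moderate noise.
    """
    wave = GreenWaveModel.from_speeds(30.0)
    rng = np.random.default_rng(seed)
    center = 110.0

    if label == "local":
        sos_f_offset = 0.0
        pulse = 0.0
        traj_distance = 0.0
        expected_source, expected_overall = "local", None
    elif label == "preseason_transport":
        # pulse ~25 days before the clean-season start -> diff ~ -25 days
        sos_f_offset = 0.0
        pulse = 60.0
        traj_distance = 1050.0  # up-wave: 35 days flowering lead at 30 km/day
        expected_source, expected_overall = "pre_season_transport", "confirmed"
    elif label == "faulty":
        # flowering 25 days before the pollen season: diff >= +10
        sos_f_offset = -25.0
        pulse = 0.0
        traj_distance = 0.0
        expected_source, expected_overall = "no_local_or_faulty", None
    else:
        raise ValueError(f"unknown scenario label {label!r}")

    # timing noise: shift the whole pollen curve (moves SOS_P) and the
    # flowering date independently
    p_shift = float(rng.normal(0.0, noise_sd_days)) if noise_sd_days > 0 else 0.0
    f_shift = float(rng.normal(0.0, noise_sd_days)) if noise_sd_days > 0 else 0.0

    # the clean Gaussian season (centre 110, sigma 10) starts at ~doy 90 by the
    # percentage method; an offset of 45 days from the centre places the pulse
    # ~25 days before that start
    scn = PollenScenario(
        center_doy=center + round(p_shift), width_days=10.0, amplitude=80.0,
        pulse_offset_days=45.0 if pulse else 0.0, pulse_magnitude=pulse,
        seed=int(rng.integers(2**31 - 1)),
    )
    series, truth = simulate_pollen_year(scn)
    # local flowering: aligned with the unshifted clean-season start (so
    # transport pulses shift diff negative), or shifted late for the faulty
    # label; the pollen-timing shift is NOT subtracted — it is the error
    sos_f = float((truth.sos - round(p_shift)) + sos_f_offset + f_shift)

    # up-wave origin: the early-spring/mid-spring wave moves toward NE-ish;
    # place the origin on the exact up-wave bearing of the receptor's segment
    from .greenwave import wave_segment_for_doy  # local import avoids cycle at module load

    seg = wave_segment_for_doy(wave, int(max(1, min(366, round(sos_f)))))
    origin_bearing = (seg.bearing_deg + 180.0) % 360.0
    trajectories_by_day = tuple(
        simulate_trajectories(
            origin_bearing_deg=origin_bearing, distance_km=traj_distance,
            receptor_lat=receptor_lat, receptor_lon=receptor_lon,
            start_day=10 + d, seed=seed * 10 + d,
        )
        for d in range(3)
    )
    return TransportScenarioBundle(
        label=label, series=series, truth=truth, sos_f=sos_f,
        trajectories_by_day=trajectories_by_day,
        receptor_lat=receptor_lat, receptor_lon=receptor_lon,
        wave_model=wave,
        expected_source_class=expected_source,
        expected_overall=expected_overall,
    )
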