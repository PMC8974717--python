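# Methods

This note documents the models and procedures implemented in `pollenwave`,
the conventions chosen where several were defensible, what the synthetic
generators do and do not emulate, and the package's known limitations.

## 1. Pollen season definition

**Model.** A station × taxon × year series of daily airborne concentrations
c(d) (pollen grains m⁻³, 1-based day-of-year d) is summarised by four
parameters. With C(d) the running cumulative sum and S the annual total:

* `SOS_P` — first d with C(d) ≥ (α/100)·S,
* `EOS_P` — first d with C(d) ≥ (1 − α/100)·S,
* `PEAK_P` — earliest day of maximum concentration within [SOS_P, EOS_P],
* `SUM_P` — S (the annual pollen integral).

α defaults to 2.5 (%). Both thresholds are closed (≥, "first crossing day").
The trimming operates on cumulative concentration mass, not on a count of
days — the standard aerobiological usage.

**Conventions.**
* α = 0 degenerates to the support bounds: SOS_P is the first and EOS_P the
  last non-zero day.
* Peak ties break to the earliest day. The peak is searched inside
  [SOS_P, EOS_P]; on flat series a global earliest-argmax could precede the
  season start, which would break the ordering SOS ≤ PEAK ≤ EOS.
* Season parameters are invariant under uniform scaling of the series
  (SUM_P scales linearly).

**Imputation.** Interior missing days (explicit NaNs or days absent from the
listing) are filled by linear interpolation between the nearest present
neighbours before season definition. Observed values are never altered, and
filled values always lie between their bracketing neighbours. Leading and
trailing gaps have no bracketing pair, stay missing (contributing zero mass),
and are flagged.

**Reliability flags.** Evaluated on the raw (pre-imputation) series:
* `LATE_START_CONC` — concentration on the first day of trap operation
  > 4 grains m⁻³ (the season may have started before the trap did);
* `LATE_START_PHENO` — trap operation began < 10 days before local
  flowering;
* `OP_AFTER_FLOWERING` — trap operation began after local flowering;
* `HIGH_MISSING` — more than 20 % of the days in [SOS_P, EOS_P] missing
  before imputation.

**Intensity classes.** Daily loads map to nil/low/medium/high by per-taxon
lower cut-points, closed from below (a value equal to a cut-point takes the
higher class). The shipped defaults (trees 1/11/101, grasses 1/6/51, mugwort
1/6/31 grains m⁻³) follow the order of magnitude of published clinical
scales; they are configuration, and any serious clinical use should supply
the locally applicable table.

**Trends.** Per-parameter multi-year trends are ordinary least squares of
value on year with the two-sided slope p-value; pairs with a missing member
are dropped and at least three pairs are required. A zero-variance response
is reported as slope 0 with p = 1.

## 2. Flowering surfaces

**Model.** Flowering onset observations are regionalised with an
overlapping-circle scheme. Inside each circle (default radius 1.95°,
membership Euclidean in degree space) the onset day is fit by OLS:

    DOY = a0 + a1·h + a2·lon + a3·lat

with h elevation (m). Circles with fewer than `min_n` = 10 member
observations or a rank-deficient design are skipped, not errored — edge
circles are expected to degenerate. The coefficient quadruple is attached to
the circle centre and interpolated to any target by inverse distance
weighting (IDW) over the k nearest fitted circles, k = min(4, available) and
at least 2, with weights 1/d² on great-circle (haversine) distance in km;
a target coincident with a centre takes that circle's coefficients. Each
coefficient is interpolated independently, so the result lies inside the
per-coefficient min/max envelope of the contributing circles.

The regression is evaluated per pixel of a regular lat/lon grid carrying
elevation. Pixels outside all circle coverage stay unpredicted (NaN, counted
in a warning); pixels inside coverage but with fewer than two covering
circles fall back to the global fitted set rather than extrapolating from a
single circle. Unrounded predictions are retained; a rounded (nearest-day)
surface is available for reporting. The flowering start `SOS_F` at a station
is the value of the pixel containing it, located by half-open binning (lower
edge inclusive).

**Circle geometry.** The default lattice lays ~30 circles over the data
bounding box, sized by the box aspect. Operational networks use fixed circle
sets; both centres and radius are configuration.

**Pixel trends.** Given yearly surfaces on a common grid, per-pixel OLS
slopes are computed for every pixel covered in all years and summarised by
the 2.5/25/50/75/97.5 percentiles; a station trend is "inside" the
distribution when it lies within the central 95 %. This mirrors the
violin-plot comparison of station pollen trends against the field of
interpolated flowering trends.

**Noisy recovery.** With 3-day observation noise, the intercept a0 is
recovered within ±1 day in ≥ 95 % of replicates when the network has ~200
sites and the coordinate box is centred on the origin. The centring matters:
a0 is the value at (h, lon, lat) = 0, so with a geographic box far from the
origin its sampling error is inflated by extrapolation even though the
fitted *surface* is accurate. The test suite therefore checks a0 on a
centred box and checks surface accuracy separately on the geographic box.

## 3. Transport classification

With `diff = SOS_P − SOS_F` (days), the source class partitions the line:

| interval | class |
|---|---|
| (−∞, −10] | pre-season transport (non-local sources) |
| (−10, +10) | local sources |
| [+10, +∞) | no local sources / faulty recording |

Both outer intervals are closed at ±10 — a 10-day lead *is* transport, a
10-day lag *is* suspect. The threshold absorbs interpolation uncertainty of
the flowering surface and micro/meso-climatic variation. At an alpine
station, taxa without local sources (default: all but pine and grasses)
cannot have a genuinely "local" match, so LOCAL is remapped to pre-season
transport when that interpretation is enabled.

Transport typing for classified transport cases: an alpine SOS_P at least
10 days before the lowland-reference flowering (default reference: mean of
the two lowland stations' SOS_F) is long-range from outside the region;
otherwise a season start within < 3 days of another station's SOS_P is
long-range; otherwise the range is undefined.

**Summaries.** Medians use the mean of the two central order statistics for
even n; values are rounded to reporting precision only at display. Source-
class percentages are computed over the summarised case set and sum to 100
(± 0.1 rounding). Unreliable cases — by default the mugwort cases (whose
interpolated flowering surfaces are weak) and any case with diff ≥ +10 —
are carried as flagged metadata and can be excluded by a switch, never
silently dropped. The published exclusion set mixed the numeric rule with
operational knowledge of individual trap failures, which is not derivable
from the difference table alone; the pure numeric rule reproduces the
reliable-case median exactly and the three-way breakdown to within two
percentage points.

**Group comparison.** Concentrations at season start for transport vs. local
years are compared by a two-sided Welch t-test; groups need n ≥ 2 and
non-degenerate variance.

## 4. Green-wave extrapolation and confirmation

**Wave model.** The green wave is piecewise-seasonal: half-open day-of-year
windows, each with a bearing the wave moves toward and a speed in km day⁻¹.
Default windows/bearings: days 1–90 toward ENE (67.5°), 91–135 toward NE
(45°), 136–166 toward NNE (22.5°), 167+ toward N (0°). The windows tile the
year without gap or overlap (validated at construction); the boundary day
belongs to the later window. **Speeds are not bundled as scientific
defaults** — published calibrations live in supplementary material not
packaged here — so reproduction runs must set them; `example_model()`
carries placeholder values (40/35/30/25 km day⁻¹) that only illustrate the
expected order of magnitude.

**Extrapolation.** For a trajectory point p and receptor r with flowering
onset SOS_F, the displacement p → r is projected onto the wave bearing of
the segment containing SOS_F, and

    SOS_T(p) = SOS_F − projection_km / speed.

Up-wave points flower earlier, down-wave later, perpendicular displacement
not at all. The projection uses a local equirectangular plane tangent at the
receptor (km-per-degree-longitude frozen at the receptor latitude). A
great-circle initial-bearing projection was considered and rejected: meridian
convergence makes it asymmetric under displacement sign by ~0.5 day at
500 km, whereas the tangent-plane form is exactly antisymmetric and differs
from the great-circle value by < 1 % at back-trajectory scale — far below
the uncertainty of any wave-speed estimate.

**Footprint and verdict.** SOS_T for one assessment day is the minimum of
the extrapolation over *every* endpoint of all eight of that day's 72 h back
trajectories (the finest footprint option). Days assessed: the SOS_P day and
the two days before. Scoring: high if SOS_T ≤ SOS_P, medium if
SOS_P < SOS_T ≤ SOS_F, zero if SOS_T > SOS_F. Overall: confirmed if any day
is high, partly confirmed if none is high and any is medium, rejected
otherwise. Days without trajectory data are excluded; all three missing is
an error. Trajectory altitude is carried but not filtered.

## 5. Synthetic data

The restricted-access inputs are emulated by seed-deterministic generators
that return their ground truth alongside the data:

* **Pollen years** — a Gaussian season curve (centre, σ, amplitude; default
  centre day 110, σ 12 d, peak 80 grains m⁻³ — a mid-spring tree season)
  with optional truncated-at-zero Gaussian counting noise applied to days
  carrying pollen, missing-day spells, and an optional narrow pre-season
  pulse (σ 1.5 d) for transport scenarios. Truth SOS/PEAK/EOS are the
  percentage-method parameters of the noise-free base curve, which for a
  Gaussian are its α-quantiles in closed form. Day-to-day autocorrelation
  and multi-modal seasons are *not* emulated — no decision rule depends on
  them.
* **Phenology networks** — sites uniform in a coordinate box (default: a
  Bavaria-sized box, 80 sites, elevations 100–1200 m), onset from the
  regression plane plus Gaussian noise, rounded to whole days unless the
  caller requests exact values for recovery tests. A linear drift on a0
  imposes a known flowering trend.
* **Trajectories** — eight starts per day at 3 h intervals, endpoints
  drifting linearly toward a chosen origin bearing over 72 h at 3 h
  resolution (25 points), optional isotropic jitter; also written as
  endpoint text files for parser round-trips. No meteorological realism is
  attempted.
* **Labelled scenarios** — consistent bundles (pollen year, flowering date,
  three days of trajectories) whose end-to-end pipeline output must equal
  the label: *local* (diff ≈ 0), *preseason_transport* (pulse ~25 days
  before flowering, trajectories from 1050 km up-wave at 30 km day⁻¹, so
  SOS_T leads SOS_P and the case must be confirmed), *faulty* (pollen ~25
  days after flowering). Offsets sit ≥ 15 days from every decision boundary,
  so with 2-day timing noise on both SOS_P and SOS_F the labels remain
  recoverable ≥ 90 % of the time; noise-free recovery is exact.

Passing these tests shows the rules and geometry are implemented correctly;
it does **not** validate the scientific assumptions (green-wave speeds, the
10-day threshold, trajectory realism) against real atmospheric transport.

## 6. File formats and fixtures

Pollen and phenology tables are plain CSV with configurable column mapping;
dates are ISO-8601 on disk and day-of-year in memory (comparisons always
within one calendar year). Trajectories use the HYSPLIT ≥ v4 endpoint
("tdump") whitespace layout; only trajectory number, time, age, lat, lon and
altitude are consumed, trailing diagnostics tolerated. The sub-version of
endpoint layout emitted by any particular HYSPLIT build varies; the parser
targets the common modern form and reports truncated records by line number.
Points older than 72 h are retained and flagged rather than dropped.

The packaged difference table (three stations, seven taxa, 1987–2017) is a
transcription of published values, checksummed at load; the two missing-cell
markers are kept distinct ("n.a." not measured, "d." discarded). Restricted
to the study window — Munich and Oberjoch 2005–2015, Erlangen 2005–2012 —
it contains exactly 209 present cells.

## 7. Problem sizes used by the test suite

Method-level oracles run on 1000 random series (percentage method), 10–50
random fits (OLS/IDW), 200 replicates (noisy a0 recovery) and 100 end-to-end
scenarios; the whole suite completes in a few seconds on one CPU. These
sizes give stable pass/fail behaviour for the properties checked; none of
the checked statements is asymptotic.

## 8. Known limitations

* Running HYSPLIT, retrieving reanalysis meteorology and converting it to
  ARL are out of scope; only the endpoint files are consumed. The published
  trajectory-scale confirmation rates therefore cannot be recomputed here.
* The flowering surface ships no digital elevation model; grids must carry
  elevation.
* Species-presence masking of the extrapolated flowering field (some taxa
  lack sources in parts of Iberia, Italy or SE Europe) is not applied; the
  published analysis used it qualitatively.
* Post-season transport is not classified — flowering *end* dates are not
  observed in the phenological network the method relies on.
* The alternative season definitions (logistic, moving, clinical, grains)
  are not implemented; a registry hook accepts user implementations.
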