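"""Circle regression, IDW coefficient interpolation, grid prediction, trends."""

import numpy as np
import pytest

from pollenwave.aero_io import PhenoObservation, haversine_km
from pollenwave.phenomap import (
    Circle,
    CoverageError,
    FloweringSurface,
    default_circle_lattice,
    extract_site_sosf,
    fit_circle_model,
    interpolate_coefficients,
    pixel_trend_distribution,
    predict_doy_grid,
)
from pollenwave.synthdata import NetworkScenario, simulate_pheno_network

TRUTH = NetworkScenario(a0=60.0, a1=0.03, a2=-2.0, a3=4.0, n_sites=80, seed=11)
BIG_CIRCLE = Circle(center_lat=48.75, center_lon=11.4, radius_deg=4.0)


def exact_network():
    obs, coef = simulate_pheno_network(TRUTH, round_days=False)
    return obs, coef


def normal_equations(obs):
    """Independent closed-form OLS via the normal equations."""
    X = np.column_stack([
        np.ones(len(obs)),
        [o.elevation_m for o in obs],
        [o.lon for o in obs],
        [o.lat for o in obs],
    ])
    y = np.array([o.onset_doy for o in obs], dtype=float)
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestFitCircleModel:
    def test_exact_recovery_noise_free(self):
        obs, coef = exact_network()
        m = fit_circle_model(obs, BIG_CIRCLE)
        assert np.allclose(m.coefficients, coef, atol=1e-8)
        assert m.rmse < 1e-8
        assert m.n_obs == 80

    def test_too_few_observations_skips(self):
        obs, _ = exact_network()
        m = fit_circle_model(obs[:3], BIG_CIRCLE, min_n=10)
        assert m is None

    def test_rank_deficient_design_skips(self):
        # all sites at identical position: lon/lat columns are constant multiples
        obs = [
            PhenoObservation(f"S{i}", 48.0, 11.0, 500.0, "x", 2010, 100 + i)
            for i in range(12)
        ]
        assert fit_circle_model(obs, BIG_CIRCLE) is None

    def test_matches_normal_equations_on_noisy_data(self):
        scn = NetworkScenario(noise_sd_days=5.0, n_sites=60, seed=5)
        obs, _ = simulate_pheno_network(scn, round_days=False)
        m = fit_circle_model(obs, BIG_CIRCLE)
        assert np.allclose(m.coefficients, normal_equations(obs), atol=1e-8)

    def test_observations_outside_circle_ignored(self):
        obs, _ = exact_network()
        small = Circle(center_lat=48.75, center_lon=11.4, radius_deg=1.5)
        inside_only = [o for o in obs if small.contains(o.lat, o.lon)]
        m_all = fit_circle_model(obs, small)
        m_inside = fit_circle_model(inside_only, small)
        assert np.allclose(m_all.coefficients, m_inside.coefficients, atol=0)
        assert m_all.n_obs == m_inside.n_obs


def models_at(centers, coefs, n_obs=30, rmse=1.0):
    from pollenwave.phenomap import CircleModel

    return [
        CircleModel(circle=Circle(center_lat=la, center_lon=lo), a0=c[0], a1=c[1],
                    a2=c[2], a3=c[3], n_obs=n_obs, rmse=rmse)
        for (la, lo), c in zip(centers, coefs)
    ]


class TestIDW:
    def test_identical_models_return_those_coefficients(self):
        coefs = [(60.0, 0.03, -2.0, 4.0)] * 3
        models = models_at([(47.5, 10.0), (48.5, 11.0), (49.5, 12.0)], coefs)
        out = interpolate_coefficients(models, 48.2, 11.3)
        assert np.allclose(out, coefs[0])

    def test_target_on_center_returns_that_circle(self):
        coefs = [(50.0, 0.0, 0.0, 0.0), (90.0, 1.0, 1.0, 1.0)]
        models = models_at([(48.0, 11.0), (49.0, 12.0)], coefs)
        out = interpolate_coefficients(models, 48.0, 11.0)
        assert np.allclose(out, coefs[0])

    def test_weights_match_hand_computation(self):
        centers = [(48.0, 11.0), (49.0, 11.0), (48.0, 12.5)]
        coefs = [(60.0, 0.0, 0.0, 0.0), (80.0, 0.0, 0.0, 0.0), (100.0, 0.0, 0.0, 0.0)]
        models = models_at(centers, coefs)
        target = (48.4, 11.4)
        d = np.array([haversine_km(*target, la, lo) for la, lo in centers])
        w = 1 / d**2
        w /= w.sum()
        expected_a0 = float(w @ [60.0, 80.0, 100.0])
        out = interpolate_coefficients(models, *target, power=2.0)
        assert out[0] == pytest.approx(expected_a0, abs=1e-12)

    def test_convex_hull_containment(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 7))
            centers = [(47 + 3 * rng.random(), 9 + 4 * rng.random()) for _ in range(k)]
            coefs = rng.normal(size=(k, 4))
            models = models_at(centers, [tuple(c) for c in coefs])
            out = interpolate_coefficients(models, 48.5, 11.0)
            used = min(4, k)
            # IDW is a convex combination, so within global min/max per coefficient
            assert np.all(out >= coefs.min(axis=0) - 1e-12)
            assert np.all(out <= coefs.max(axis=0) + 1e-12)

    def test_too_few_models_raises(self):
        models = models_at([(48.0, 11.0)], [(60.0, 0.0, 0.0, 0.0)])
        with pytest.raises(CoverageError):
            interpolate_coefficients(models, 48.5, 11.5)


def small_grid(n=6, elev=None):
    lats = np.linspace(47.2, 50.2, n)
    lons = np.linspace(9.2, 13.6, n)
    if elev is None:
        elev = np.zeros((n, n))
    return lats, lons, elev


class TestPredictGrid:
    def test_single_global_model_direct_evaluation(self):
        models = models_at([(48.0, 11.0)], [(60.0, 0.03, -2.0, 4.0)])
        big = Circle(center_lat=48.0, center_lon=11.0, radius_deg=50.0)
        models[0] = type(models[0])(circle=big, a0=60.0, a1=0.03, a2=-2.0, a3=4.0,
                                    n_obs=30, rmse=0.0)
        surface = predict_doy_grid(models, [48.0], [11.0],
                                   np.array([[500.0]]), k_min=1)
        assert surface.sos_f[0, 0] == pytest.approx(60 + 15 - 22 + 192)  # 245

    def test_elevation_monotonicity(self):
        obs, _ = exact_network()
        scn = NetworkScenario(a0=60.0, a1=0.05, a2=0.0, a3=0.0, n_sites=80, seed=3)
        obs, _ = simulate_pheno_network(scn, round_days=False)
        models = [fit_circle_model(obs, BIG_CIRCLE)]
        elev = np.linspace(0, 2000, 36).reshape(6, 6)
        lats, lons, _ = small_grid()
        surface = predict_doy_grid(models, lats, lons, elev, k_min=1)
        flat = surface.sos_f.ravel()
        assert np.all(np.diff(flat) > 0)  # elevation increases along ravel order

    def test_noise_free_network_recovers_truth_surface(self):
        obs, coef = exact_network()
        circles = default_circle_lattice(obs, n_circles=9, radius_deg=2.5)
        models = [fit_circle_model(obs, c) for c in circles]
        assert sum(m is not None for m in models) >= 2
        lats, lons, elev = small_grid(elev=np.full((6, 6), 400.0))
        surface = predict_doy_grid(models, lats, lons, elev)
        for i, la in enumerate(lats):
            for j, lo in enumerate(lons):
                if np.isfinite(surface.sos_f[i, j]):
                    truth = coef[0] + coef[1] * 400.0 + coef[2] * lo + coef[3] * la
                    assert abs(surface.sos_f[i, j] - truth) < 1e-6

    def test_rounded_surface_is_integer_days(self):
        models = models_at([(48.0, 11.0)], [(60.5, 0.0, 0.0, 0.0)])
        big = Circle(center_lat=48.0, center_lon=11.0, radius_deg=50.0)
        models[0] = type(models[0])(circle=big, a0=60.4, a1=0.0, a2=0.0, a3=0.0,
                                    n_obs=30, rmse=0.0)
        surface = predict_doy_grid(models, [48.0], [11.0], np.zeros((1, 1)), k_min=1)
        assert surface.sos_f[0, 0] == pytest.approx(60.4)
        assert surface.sos_f_rounded[0, 0] == 60.0


class TestExtractSiteSosf:
    def make_surface(self):
        lats = np.array([48.0, 48.5, 49.0])
        lons = np.array([11.0, 11.5])
        sos = np.arange(6, dtype=float).reshape(3, 2)
        return FloweringSurface("x", 2010, lats, lons, np.zeros((3, 2)), sos)

    def test_pixel_center(self):
        s = self.make_surface()
        assert extract_site_sosf(s, 48.5, 11.5) == 3.0

    def test_boundary_half_open_lower_inclusive(self):
        s = self.make_surface()
        # midpoint between rows 0 and 1 belongs to the upper pixel (floor rule)
        assert extract_site_sosf(s, 48.25, 11.0) == 2.0

    def test_consistent_with_direct_evaluation(self):
        obs, coef = exact_network()
        circles = default_circle_lattice(obs, n_circles=9, radius_deg=2.5)
        models = [fit_circle_model(obs, c) for c in circles]
        lats, lons, elev = small_grid(elev=np.full((6, 6), 300.0))
        surface = predict_doy_grid(models, lats, lons, elev)
        val = extract_site_sosf(surface, float(lats[2]), float(lons[3]))
        from pollenwave.phenomap import interpolate_coefficients as idw

        c = idw([m for m in models if m is not None], float(lats[2]), float(lons[3]))
        direct = c[0] + c[1] * 300.0 + c[2] * lons[3] + c[3] * lats[2]
        assert val == pytest.approx(direct, abs=1e-9)

    def test_outside_grid_errors(self):
        with pytest.raises(CoverageError):
            extract_site_sosf(self.make_surface(), 55.0, 11.0)


def shifted_surfaces(slope_per_year, years=range(2005, 2011), base=100.0):
    lats = np.linspace(47.5, 49.5, 5)
    lons = np.linspace(10.0, 13.0, 5)
    out = []
    for y in years:
        val = base + slope_per_year * (y - years[0])
        out.append(FloweringSurface("x", y, lats, lons, np.zeros((5, 5)),
                                    np.full((5, 5), val)))
    return out


class TestPixelTrends:
    def test_uniform_shift_recovers_slope_and_flags_station(self):
        surfaces = shifted_surfaces(-0.5)
        dist = pixel_trend_distribution(surfaces)
        assert np.allclose(dist.slopes, -0.5)
        assert not dist.contains(-2.0)
        assert dist.contains(-0.5)

    def test_constant_surfaces_zero_slopes(self):
        dist = pixel_trend_distribution(shifted_surfaces(0.0))
        assert np.allclose(dist.slopes, 0.0)

    def test_quantiles_match_sorting_oracle(self, rng):
        surfaces = shifted_surfaces(-0.3)
        # perturb each year's surface with noise so slopes vary across pixels
        noisy = []
        for s in surfaces:
            noisy.append(FloweringSurface(s.species, s.year, s.lats, s.lons,
                                          s.elevation_m,
                                          s.sos_f + rng.normal(0, 2, s.sos_f.shape)))
        dist = pixel_trend_distribution(noisy)
        srt = np.sort(dist.slopes)
        for q in (2.5, 25, 50, 75, 97.5):
            assert dist.quantiles[q] == pytest.approx(
                float(np.percentile(srt, q)), abs=1e-12
            )

    def test_inconsistent_grids_rejected(self):
        s1 = shifted_surfaces(0.0)[:3]
        bad = FloweringSurface("x", 2099, np.linspace(40, 42, 5),
                               s1[0].lons, np.zeros((5, 5)), np.zeros((5, 5)))
        with pytest.raises(ValueError, match="inconsistent"):
            pixel_trend_distribution([s1[0], s1[1], bad])

    def test_too_few_years_rejected(self):
        from pollenwave.season import UndefinedTrendError

        with pytest.raises(UndefinedTrendError):
            pixel_trend_distribution(shifted_surfaces(0.0)[:2])


def test_noisy_a0_recovery_rate():
    """With 3-day observation noise and 200 sites, the intercept is recovered
    within +-1 day in >= 95% of replicates (coordinate box centred on the
    origin so the intercept sits inside the data support)."""
    hits = 0
    n_rep = 200
    circle = Circle(center_lat=0.0, center_lon=0.0, radius_deg=5.0)
    for rep in range(n_rep):
        scn = NetworkScenario(
            a0=100.0, a1=0.02, a2=-1.0, a3=2.0, n_sites=200,
            lat_range=(-2.0, 2.0), lon_range=(-2.0, 2.0),
            elevation_range=(0.0, 1000.0), noise_sd_days=3.0, seed=rep,
        )
        obs, coef = simulate_pheno_network(scn, round_days=False)
        m = fit_circle_model(obs, circle)
        if abs(m.a0 - coef[0]) <= 1.0:
            hits += 1
    assert hits / n_rep >= 0.95
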