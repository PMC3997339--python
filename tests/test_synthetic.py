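"""Generators: determinism, ground-truth closure, trajectory and tidal
hydrochemistry, island DEMs, transects."""

from dataclasses import replace

import numpy as np
import pytest

from reefcarb.census import census_gnet
from reefcarb.production import PRODUCERS
from reefcarb.raster import GridSpec
from reefcarb.synthetic import (
    IslandParams,
    SceneParams,
    generate_hydrochem,
    generate_island_dem,
    generate_omega_trajectory,
    generate_scene,
    generate_transects,
    read_scene,
    sample_cover_points,
)


def _trapz_mean(v, t):
    return np.trapezoid(v, t) / (t[-1] - t[0])


class TestScene:
    def test_same_seed_bit_identical(self, default_grid, default_scene):
        again = generate_scene(default_grid, seed=0)
        for p in PRODUCERS:
            np.testing.assert_array_equal(
                again.true_cover[p].values, default_scene.true_cover[p].values
            )
        np.testing.assert_array_equal(again.dem.values, default_scene.dem.values)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            generate_scene(GridSpec(0, 10))

    def test_zero_noise_covers_equal_linear_predictor(self, default_grid):
        params = replace(SceneParams(), cover_noise_sd=0.0)
        scene = generate_scene(default_grid, params, seed=0)
        stack = np.stack([
            scene.reflectance_b1.values, scene.reflectance_b2.values,
            scene.dem.values, scene.slope.values, scene.rugosity.values,
        ])
        mask = scene.valid_mask()
        for p in PRODUCERS:
            beta = np.asarray(params.cover_betas[p])
            eta = np.clip(beta[0] + np.tensordot(beta[1:], stack, axes=1), 0, 1)
            np.testing.assert_array_equal(
                scene.true_cover[p].values[mask], eta[mask]
            )

    def test_flat_fraction_near_target(self, default_scene):
        frac = (default_scene.zone_mask.values == 1).mean()
        assert abs(frac - default_scene.params.flat_fraction) <= 0.05

    def test_cover_physicality(self, default_scene):
        mask = default_scene.valid_mask()
        total = sum(default_scene.true_cover[p].values[mask] for p in PRODUCERS)
        assert total.max() <= 1.0 + 1e-9
        for p in PRODUCERS:
            v = default_scene.true_cover[p].values[mask]
            assert v.min() >= 0.0 and v.max() <= 1.0

    def test_write_read_round_trip(self, default_scene, tmp_path):
        default_scene.write(tmp_path / "scene")
        back = read_scene(tmp_path / "scene")
        np.testing.assert_allclose(back.dem.values, default_scene.dem.values,
                                   rtol=1e-9, atol=1e-9)
        assert back.perimeter_length == default_scene.perimeter_length
        for p in PRODUCERS:
            m = np.isfinite(default_scene.true_cover[p].values)
            np.testing.assert_allclose(back.true_cover[p].values[m],
                                       default_scene.true_cover[p].values[m],
                                       rtol=1e-8, atol=1e-8)


class TestTrajectory:
    def test_default_end_century_values(self, default_trajectory):
        assert default_trajectory.annual_mean(2100) == pytest.approx(2.13)
        lower, upper = default_trajectory.diurnal_limits(2100)
        assert (lower, upper) == pytest.approx((0.85, 3.95))

    def test_constant_when_endpoints_equal(self):
        traj = generate_omega_trajectory(start_mean=3.0, end_mean=3.0,
                                         start_upper=4.0, end_upper=4.0,
                                         start_lower=2.0, end_lower=2.0)
        means = [traj.annual_mean(y) for y in traj.years]
        np.testing.assert_allclose(means, 3.0)

    def test_exponential_decrements_strictly_increasing(self, default_trajectory):
        means = np.array([default_trajectory.annual_mean(y)
                          for y in default_trajectory.years])
        decrements = -np.diff(means)
        assert (np.diff(decrements) > 0).all()

    def test_slope_zone_attenuated(self, default_trajectory):
        flat = default_trajectory.annual_mean(2100, "flat")
        slope = default_trajectory.annual_mean(2100, "slope")
        start = default_trajectory.annual_mean(2000, "flat")
        assert flat < slope < start

    def test_validation(self):
        with pytest.raises(ValueError):
            generate_omega_trajectory(start_year=2100, end_year=2000)
        with pytest.raises(ValueError):
            generate_omega_trajectory(end_mean=-1.0)
        with pytest.raises(ValueError):
            generate_omega_trajectory(shape="cubic")


class TestHydrochem:
    def test_zero_amplitude_zero_noise_is_constant(self, default_trajectory):
        series = generate_hydrochem("flat", "summer", 2050, default_trajectory,
                                    ponding_amplitude=0.0, noise_sd=0.0)
        expect = default_trajectory.seasonal_mean(2050, "summer", "flat")
        np.testing.assert_allclose(series.omega, expect)

    def test_trapezoid_mean_equals_seasonal_mean(self, default_trajectory):
        for zone in ("flat", "slope"):
            series = generate_hydrochem(zone, "winter", 2040, default_trajectory, seed=5)
            expect = default_trajectory.seasonal_mean(2040, "winter", zone)
            assert _trapz_mean(series.omega, series.times) == pytest.approx(expect)

    def test_flat_range_at_least_slope_range(self, default_trajectory):
        flat = generate_hydrochem("flat", "spring", 2080, default_trajectory, seed=2)
        slope = generate_hydrochem("slope", "spring", 2080, default_trajectory, seed=2)
        assert np.ptp(flat.omega) >= np.ptp(slope.omega)

    def test_end_century_series_within_diurnal_limits(self, default_trajectory):
        for season in ("summer", "autumn", "winter", "spring"):
            series = generate_hydrochem("flat", season, 2100, default_trajectory, seed=7)
            assert series.omega.min() >= 0.85 - 1e-9
            assert series.omega.max() <= 3.95 + 1e-9

    def test_unknown_zone_or_season_rejected(self, default_trajectory):
        with pytest.raises(ValueError):
            generate_hydrochem("lagoon", "summer", 2050, default_trajectory)
        with pytest.raises(ValueError):
            generate_hydrochem("flat", "monsoon", 2050, default_trajectory)

    def test_year_outside_trajectory_rejected(self, default_trajectory):
        with pytest.raises(ValueError):
            generate_hydrochem("flat", "summer", 2150, default_trajectory)


class TestIsland:
    def test_uniform_slab_volume(self):
        # degenerate "island": flat top via a huge radius and zero ridges
        spec = GridSpec(10, 10, 1.0)
        params = IslandParams(radius=1e6, height=2.0, ridge_amplitude_fraction=0.0)
        dem, _ = generate_island_dem(spec, params)
        np.testing.assert_allclose(dem.values, 2.0, rtol=1e-9)

    def test_dome_grid_volume_near_analytic(self):
        spec = GridSpec(200, 200, 4.0)
        dem, analytic = generate_island_dem(spec, IslandParams())
        grid_volume = dem.values.sum() * spec.cell_area
        assert grid_volume == pytest.approx(analytic, rel=0.01)

    def test_same_seed_identical(self):
        spec = GridSpec(60, 60, 10.0)
        params = IslandParams(noise_sd=0.2)
        a, _ = generate_island_dem(spec, params, seed=3)
        b, _ = generate_island_dem(spec, params, seed=3)
        np.testing.assert_array_equal(a.values, b.values)

    def test_ridges_do_not_change_volume(self):
        spec = GridSpec(200, 200, 4.0)
        plain, _ = generate_island_dem(spec, IslandParams(ridge_amplitude_fraction=0.0))
        ridged, _ = generate_island_dem(spec, IslandParams(ridge_amplitude_fraction=0.3))
        assert ridged.values.sum() == pytest.approx(plain.values.sum(), rel=1e-9)


class TestTransects:
    def test_conforming_length_and_segment_sums(self, default_scene):
        records = generate_transects(default_scene, seed=1)
        assert len(records) == 10
        for rec in records:
            assert rec.d1 >= rec.d2 > 0
            assert sum(s for _, s in rec.segments) == pytest.approx(rec.d1)

    def test_bare_scene_yields_pure_sand_and_zero_production(self):
        grid = GridSpec(40, 40, 12.0)
        params = replace(
            SceneParams(),
            cover_betas={p: [0.0] * 6 for p in PRODUCERS},
            cover_noise_sd=0.0,
        )
        scene = generate_scene(grid, params, seed=0)
        records = generate_transects(scene, n_sites=2, seed=0)
        for rec in records:
            assert {taxon for taxon, _ in rec.segments} == {"sand"}
            assert census_gnet(rec) == 0.0

    def test_values_bounded_and_overlap_field_range(self, default_scene):
        """Census production stays within the hard rugosity*K_max bound and
        overlaps the 0.21-4.58 kg m^-2 yr^-1 range observed in the field."""
        values = []
        for seed in (0, 1, 2):
            for rec in generate_transects(default_scene, seed=seed):
                v = census_gnet(rec)
                assert 0.0 <= v <= (rec.d1 / rec.d2) * 10.0 + 1e-9
                values.append(v)
        assert min(values) < 4.58  # overlap with the observed field range

    def test_rejects_bad_length(self, default_scene):
        with pytest.raises(ValueError):
            generate_transects(default_scene, length=0.0)


def test_sample_cover_points_deterministic_and_valid(default_scene):
    a = sample_cover_points(default_scene, 30, seed=9, cover_noise_sd=0.05)
    b = sample_cover_points(default_scene, 30, seed=9, cover_noise_sd=0.05)
    assert [(s.x, s.y) for s in a] == [(s.x, s.y) for s in b]
    for s in a:
        assert all(0.0 <= v <= 1.0 for v in s.covers.values())
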