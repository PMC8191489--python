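"""Wind interpolation, shoreline geometry, upwind windows, distances."""
import numpy as np
import pytest

from spindrift.attribution import (
    Shoreline,
    attribute_sample,
    distance_downwind,
    distance_inland,
    extract_window,
    interpolate_wind,
    mean_source_concentration,
    shoreline_at,
    shoreline_tangent,
    transit_time_s,
    upwind_intersection,
    SourceWindow,
)
from spindrift.core import DyeMap, WindSeries

T0 = np.datetime64("2015-09-23T12:00:00")
HOUR = np.timedelta64(1, "h")
HALF_HOUR = np.timedelta64(30, "m")


def make_winds(times, speeds, dirs):
    return WindSeries(np.array(times, dtype="datetime64[s]"), speeds, dirs)


def straight_shoreline(x=0.0, y0=-5000.0, y1=5000.0):
    return Shoreline(np.array([[x, y0], [x, y1]]), 0.0)


def uniform_map(value, nx=120, ny=120, origin=(-200.0, -120.0), time=T0):
    return DyeMap(time, np.full((ny, nx), float(value)), origin, 2.0)


class TestInterpolateWind:
    def test_station_timestamp_returned_unchanged(self):
        w = make_winds([T0, T0 + HOUR], [5.0, 7.0], [270.0, 290.0])
        speed, direction = interpolate_wind(w, T0 + HOUR)
        assert speed[0] == pytest.approx(7.0)
        assert direction[0] == pytest.approx(290.0)

    def test_midpoint_interpolates_components(self):
        # (u, v) = (0, -5) and (0, -3): wind from due north at 5 then 3 m/s
        w = make_winds([T0, T0 + HOUR], [5.0, 3.0], [0.0, 0.0])
        speed, direction = interpolate_wind(w, T0 + HALF_HOUR)
        assert speed[0] == pytest.approx(4.0)
        assert direction[0] == pytest.approx(0.0)

    def test_interpolation_across_north_wrap(self):
        w = make_winds([T0, T0 + HOUR], [5.0, 5.0], [350.0, 10.0])
        _, direction = interpolate_wind(w, T0 + HALF_HOUR)
        assert direction[0] == pytest.approx(0.0, abs=1e-9)

    def test_refuses_extrapolation(self):
        w = make_winds([T0, T0 + HOUR], [5.0, 5.0], [270.0, 270.0])
        with pytest.raises(ValueError):
            interpolate_wind(w, T0 + 2 * HOUR)


class TestShoreline:
    def test_planar_beach_contour_position(self):
        from conftest import small_config
        from spindrift.synthetic import make_terrain

        cfg = small_config(beach_slope=0.02)
        terrain = make_terrain(cfg)
        s = shoreline_at(terrain, 0.5)
        assert np.allclose(s.vertices[:, 0], 25.0, atol=1e-6)

    def test_higher_water_moves_shoreline_strictly_landward(self):
        from conftest import small_config
        from spindrift.synthetic import make_terrain

        terrain = make_terrain(small_config())
        x_low = shoreline_at(terrain, -0.3).vertices[:, 0].mean()
        x_high = shoreline_at(terrain, 0.3).vertices[:, 0].mean()
        assert x_high > x_low

    def test_fully_dry_domain_has_no_shoreline(self):
        from conftest import small_config
        from spindrift.synthetic import make_terrain

        terrain = make_terrain(small_config())
        with pytest.raises(ValueError):
            shoreline_at(terrain, 100.0)


class TestUpwindIntersection:
    def test_perpendicular_onshore_wind(self):
        hit = upwind_intersection((100.0, 0.0), 5.0, 270.0, straight_shoreline())
        assert hit == pytest.approx((0.0, 0.0), abs=1e-9)
        assert np.hypot(hit[0] - 100.0, hit[1]) == pytest.approx(100.0)

    def test_offshore_wind_finds_nothing(self):
        assert upwind_intersection((100.0, 0.0), 5.0, 90.0, straight_shoreline()) is None

    def test_45_degree_wind_hits_alongshore_offset(self):
        hit = upwind_intersection((100.0, 0.0), 5.0, 225.0, straight_shoreline())
        assert hit[0] == pytest.approx(0.0, abs=1e-9)
        assert abs(hit[1]) == pytest.approx(100.0)
        assert np.hypot(hit[0] - 100.0, hit[1]) == pytest.approx(100.0 * np.sqrt(2.0))

    def test_nearest_crossing_wins(self):
        # two parallel shorelines folded into one polyline: the ray must
        # stop at the first crossing
        zigzag = Shoreline(
            np.array([[0.0, -500.0], [0.0, 500.0], [-50.0, 500.0], [-50.0, -500.0]]), 0.0
        )
        hit = upwind_intersection((100.0, 0.0), 5.0, 270.0, zigzag)
        assert hit[0] == pytest.approx(0.0, abs=1e-9)

    def test_zero_wind_speed_rejected(self):
        with pytest.raises(ValueError):
            upwind_intersection((100.0, 0.0), 0.0, 270.0, straight_shoreline())

    def test_intersection_slides_continuously_with_direction(self):
        prev = None
        for d in np.linspace(225.0, 315.0, 19):
            hit = upwind_intersection((100.0, 0.0), 5.0, d, straight_shoreline())
            if prev is not None:
                assert abs(hit[1] - prev) < 30.0  # no jumps for 5 deg steps
            prev = hit[1]


class TestExtractWindow:
    def test_uniform_field_mean_is_the_constant(self):
        w = extract_window(uniform_map(3.3), (0.0, 0.0), (0.0, 1.0), (100.0, 0.0))
        assert w.mean_conc == pytest.approx(3.3)
        # 200 m x 100 m of 2 m cells on the seaward side
        assert w.n_cells == 100 * 50

    def test_mean_scales_linearly_with_field(self):
        m1 = uniform_map(1.0)
        m5 = DyeMap(T0, 5.0 * m1.conc_ppb, m1.origin, m1.cell_size)
        w1 = extract_window(m1, (0.0, 0.0), (0.0, 1.0), (100.0, 0.0))
        w5 = extract_window(m5, (0.0, 0.0), (0.0, 1.0), (100.0, 0.0))
        assert w5.mean_conc == pytest.approx(5.0 * w1.mean_conc)

    def test_half_window_split_averages_to_half(self):
        m = uniform_map(0.0)
        conc = m.conc_ppb.copy()
        conc[m.y_centers >= 0.0, :] = 2.0  # northern half of the window at 2
        m = DyeMap(T0, conc, m.origin, m.cell_size)
        w = extract_window(m, (0.0, 0.0), (0.0, 1.0), (100.0, 0.0))
        assert w.mean_conc == pytest.approx(1.0)

    def test_window_fully_outside_map_is_missing(self):
        w = extract_window(uniform_map(1.0), (10_000.0, 0.0), (0.0, 1.0), (10_100.0, 0.0))
        assert w.mean_conc is None
        assert w.n_cells == 0

    def test_matches_brute_force_cell_enumeration(self):
        """Production window means equal explicit per-cell enumeration on
        random maps, centres and orientations."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            nx, ny = rng.integers(30, 80, size=2)
            origin = rng.uniform(-100, 100, size=2)
            m = DyeMap(T0, rng.uniform(0, 5, size=(ny, nx)), tuple(origin), 2.0)
            center = (
                rng.uniform(origin[0], origin[0] + 2 * nx),
                rng.uniform(origin[1], origin[1] + 2 * ny),
            )
            ang = rng.uniform(0, 2 * np.pi)
            tangent = (np.cos(ang), np.sin(ang))
            land = (center[0] + 300 * np.sin(ang), center[1] - 300 * np.cos(ang))
            w = extract_window(m, center, tangent, land)

            normal = np.array([tangent[1], -tangent[0]])
            if np.dot(normal, np.asarray(land) - np.asarray(center)) > 0:
                normal = -normal
            vals = []
            for iy in range(ny):
                for ix in range(nx):
                    cx = origin[0] + 2.0 * (ix + 0.5) - center[0]
                    cy = origin[1] + 2.0 * (iy + 0.5) - center[1]
                    s = cx * tangent[0] + cy * tangent[1]
                    q = cx * normal[0] + cy * normal[1]
                    if abs(s) <= 100.0 and 0.0 <= q <= 100.0:
                        vals.append(m.conc_ppb[iy, ix])
            if vals:
                assert w.n_cells == len(vals)
                assert w.mean_conc == pytest.approx(float(np.mean(vals)), rel=1e-12)
            else:
                assert w.mean_conc is None


class TestAggregates:
    def test_mean_source_concentration(self):
        wins = [
            SourceWindow((0, 0), T0, mc) for mc in (1.0, 2.0, 3.0)
        ]
        assert mean_source_concentration(wins) == pytest.approx(2.0)
        assert mean_source_concentration([]) is None

    def test_distance_inland_basics(self):
        shore = straight_shoreline()
        assert distance_inland((0.0, 123.0), shore) == pytest.approx(0.0)
        assert distance_inland((668.0, 50.0), shore) == pytest.approx(668.0)

    def test_distance_inland_is_perpendicular_on_long_segment(self):
        # site offset (300, 400) from a vertex of a long straight segment:
        # the nearest point is the perpendicular foot, not the vertex
        shore = Shoreline(np.array([[0.0, 0.0], [0.0, 2000.0]]), 0.0)
        assert distance_inland((300.0, 400.0), shore) == pytest.approx(300.0)

    def test_distance_downwind(self):
        wins = [
            SourceWindow((0.0, 0.0), T0, 1.0),
            SourceWindow((0.0, 300.0), T0, 1.0),
        ]
        site = (100.0, 0.0)
        d1 = np.hypot(100.0, 0.0)
        d2 = np.hypot(100.0, 300.0)
        assert distance_downwind(site, wins) == pytest.approx((d1 + d2) / 2.0)
        assert distance_downwind(site, []) is None

    def test_single_window_at_site_distance_zero(self):
        wins = [SourceWindow((50.0, 20.0), T0, 1.0)]
        assert distance_downwind((50.0, 20.0), wins) == pytest.approx(0.0)

    def test_transit_time_sanity(self):
        assert transit_time_s(1500.0, 5.0) == pytest.approx(300.0)  # ~5 minutes


class TestAttributeSample:
    def test_translation_equivariance(self, campaign):
        """Shifting the whole scene (site, terrain, maps) leaves the
        attribution unchanged."""
        s = campaign.samples[0]
        base = attribute_sample(
            s.id, s.location, s.start, s.end, campaign.wind,
            campaign.dye_maps, campaign.terrain, campaign.water_level,
        )
        dx, dy = 1234.0, -567.0
        from spindrift.core import DyeMap as DM, Terrain as TR

        terrain2 = TR(
            campaign.terrain.elevation,
            (campaign.terrain.origin[0] + dx, campaign.terrain.origin[1] + dy),
            campaign.terrain.cell_size,
        )
        maps2 = [
            DM(m.time, m.conc_ppb, (m.origin[0] + dx, m.origin[1] + dy), m.cell_size)
            for m in campaign.dye_maps
        ]
        shifted = attribute_sample(
            s.id, (s.location[0] + dx, s.location[1] + dy), s.start, s.end,
            campaign.wind, maps2, terrain2, campaign.water_level,
        )
        assert shifted.dye_sea_ppb == pytest.approx(base.dye_sea_ppb, rel=1e-9)
        assert shifted.inland_m == pytest.approx(base.inland_m, rel=1e-9)
        assert shifted.downwind_m == pytest.approx(base.downwind_m, rel=1e-9)

    def test_night_interval_has_missing_source(self, campaign):
        night = [s for s in campaign.samples if (s.end - s.start) > np.timedelta64(10, "h")]
        assert night
        for s in night:
            att = attribute_sample(
                s.id, s.location, s.start, s.end, campaign.wind,
                campaign.dye_maps, campaign.terrain, campaign.water_level,
            )
            assert att.dye_sea_ppb is None
            assert att.downwind_m is None
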