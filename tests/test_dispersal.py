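import numpy as np
import pytest
from shapely.geometry import Polygon

from sandpop.dispersal import (
    ACTIVE,
    DEG2M,
    DispersalConfig,
    ParticleState,
    VelocityField,
    advect_diffuse_step,
    interpolate_velocity,
    make_synthetic_field,
    read_polygons_geojson,
    run_dispersal,
    seed_particles,
    settle,
    write_polygons_geojson,
)


def _particles(lon, lat):
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    n = lon.size
    return ParticleState(lon, lat, np.zeros(n), np.zeros(n, dtype=int),
                         np.full(n, ACTIVE), np.full(n, -1), np.zeros(n, dtype=int))


def _square(x0, y0, w=0.1):
    return Polygon([(x0, y0), (x0 + w, y0), (x0 + w, y0 + w), (x0, y0 + w)])


class TestSyntheticFields:
    def test_zero_and_uniform(self):
        z = make_synthetic_field("zero", days=2)
        assert not z.u.any() and not z.v.any()
        u = make_synthetic_field("uniform", days=2, u0=0.3, v0=-0.2)
        assert np.allclose(u.u, 0.3) and np.allclose(u.v, -0.2)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_synthetic_field("vortex")

    def test_double_gyre_divergence_free_as_grid_refines(self):
        divs = []
        for npts in (41, 81, 161):
            f = make_synthetic_field("double_gyre",
                                     lon=np.linspace(0, 2, npts),
                                     lat=np.linspace(0, 1, npts), days=1, amplitude=0.1)
            dx = (f.lon[1] - f.lon[0]) * DEG2M
            dy = (f.lat[1] - f.lat[0]) * DEG2M
            du_dx = np.gradient(f.u[0], axis=1) / dx
            dv_dy = np.gradient(f.v[0], axis=0) / dy
            divs.append(np.abs(du_dx + dv_dy).max())
        assert divs[2] < divs[0]

    def test_csv_round_trip(self, tmp_path):
        f = make_synthetic_field("rotation", lon=np.linspace(-1, 1, 5),
                                 lat=np.linspace(-1, 1, 5), days=2, omega=1e-5)
        p = tmp_path / "field.csv"
        f.to_csv(p)
        back = VelocityField.from_csv(p)
        np.testing.assert_allclose(back.u, f.u)
        np.testing.assert_allclose(back.lat, f.lat)


class TestSeeding:
    def test_points_inside_polygon_and_near_centroid(self):
        import shapely

        poly = {"sq": _square(0.0, 0.0, 1.0)}
        rng = np.random.default_rng(0)
        st = seed_particles(poly, 10_000, rng)
        assert st.n == 10_000
        assert shapely.contains_xy(poly["sq"], st.lon, st.lat).all()
        # mean within 3 SE of centroid (SD of U(0,1) = 1/sqrt(12))
        se = (1 / np.sqrt(12)) / np.sqrt(10_000)
        assert abs(st.lon.mean() - 0.5) < 3 * se
        assert abs(st.lat.mean() - 0.5) < 3 * se

    def test_zero_particles_empty_batch(self):
        st = seed_particles({"sq": _square(0, 0)}, 0, np.random.default_rng(0))
        assert st.n == 0

    def test_area_vs_equal_weighting(self):
        polys = {"small": _square(0, 0, 0.1), "big": _square(1, 1, 0.3)}
        rng = np.random.default_rng(1)
        by_area = seed_particles(polys, 1000, rng, weighting="area")
        assert (by_area.source == 1).sum() == 900  # 9:1 area ratio
        by_equal = seed_particles(polys, 1000, np.random.default_rng(1), weighting="equal")
        assert (by_equal.source == 0).sum() == 500

    def test_degenerate_polygon_rejected(self):
        line = Polygon([(0, 0), (1, 0), (0, 0)])
        with pytest.raises(ValueError, match="zero area"):
            seed_particles({"bad": line}, 10, np.random.default_rng(0))


class TestInterpolation:
    def test_exact_at_grid_nodes(self):
        rng = np.random.default_rng(3)
        lon = np.linspace(-1, 1, 9)
        lat = np.linspace(-1, 1, 7)
        u = rng.random((3, 7, 9))
        v = rng.random((3, 7, 9))
        f = VelocityField(lon, lat, np.arange(3.0), u, v)
        ui, vi, ok = interpolate_velocity(f, lon[4], lat[2], 1.0)
        assert ok
        assert ui == pytest.approx(u[1, 2, 4])
        assert vi == pytest.approx(v[1, 2, 4])

    def test_linear_field_reproduced_exactly(self):
        lon = np.linspace(0, 2, 11)
        lat = np.linspace(0, 2, 11)
        Y, X = np.meshgrid(lat, lon, indexing="ij")
        u = np.broadcast_to(0.3 * X, (2, 11, 11))
        f = VelocityField(lon, lat, np.array([0.0, 1.0]), u, np.zeros_like(u))
        ui, _, _ = interpolate_velocity(f, np.array([0.77]), np.array([1.33]), 0.0)
        assert ui[0] == pytest.approx(0.3 * 0.77, abs=1e-12)

    def test_time_interpolation_linear(self):
        lon = lat = np.linspace(-1, 1, 3)
        shape = (2, 3, 3)
        f = VelocityField(lon, lat, np.array([0.0, 1.0]),
                          np.stack([np.zeros((3, 3)), np.ones((3, 3))]),
                          np.zeros(shape))
        ui, _, _ = interpolate_velocity(f, 0.0, 0.0, 0.25)
        assert ui == pytest.approx(0.25)

    def test_out_of_domain_flagged(self):
        f = make_synthetic_field("uniform", days=1, u0=1.0)
        _, _, ok = interpolate_velocity(f, np.array([5.0]), np.array([0.0]), 0.0)
        assert not ok[0]


class TestAdvection:
    def test_uniform_flow_one_day_displacement_exact(self):
        f = make_synthetic_field("uniform", days=2, u0=0.1, v0=0.0)
        st = _particles(0.0, 0.0)
        rng = np.random.default_rng(0)
        for s in range(24):
            st = advect_diffuse_step(st, f, s / 24, 3600.0, 0.0, rng)
        metres = st.lon[0] * DEG2M * np.cos(np.radians(st.lat[0]))
        assert metres == pytest.approx(8640.0, rel=1e-9)
        assert st.age_days[0] == pytest.approx(1.0)

    def test_zero_field_zero_diffusivity_stationary(self):
        f = make_synthetic_field("zero", days=2)
        st = _particles([0.1, -0.2], [0.3, 0.0])
        st2 = advect_diffuse_step(st, f, 0.0, 86400.0, 0.0, np.random.default_rng(0))
        np.testing.assert_array_equal(st2.lon, [0.1, -0.2])

    def test_diffusion_msd_matches_4kt(self):
        f = make_synthetic_field("zero", days=4)
        n = 10_000
        st = _particles(np.zeros(n), np.zeros(n))
        rng = np.random.default_rng(1)
        K, T = 5.0, 2
        for day in range(T):
            for s in range(24):
                st = advect_diffuse_step(st, f, day + s / 24, 3600.0, K, rng)
        dx = st.lon * DEG2M * np.cos(np.radians(st.lat))
        dy = st.lat * DEG2M
        msd = np.mean(dx**2 + dy**2)
        assert msd == pytest.approx(4 * K * T * 86400, rel=0.05)

    def test_rotation_radius_drift_halves_with_substeps(self):
        omega = 2 * np.pi / (10 * 86400.0)
        f = make_synthetic_field("rotation", lon=np.linspace(-1, 1, 41),
                                 lat=np.linspace(-1, 1, 41), days=6,
                                 omega=omega, center=(0.0, 0.0))
        drifts = []
        for sub in (24, 48, 96):
            st = _particles(0.5, 0.0)
            rng = np.random.default_rng(0)
            for day in range(5):
                for s in range(sub):
                    st = advect_diffuse_step(st, f, day + s / sub, 86400.0 / sub, 0.0, rng)
            drifts.append(abs(np.hypot(st.lon[0], st.lat[0]) - 0.5))
        assert drifts[1] < drifts[0] * 0.7
        assert drifts[2] < drifts[1] * 0.7

    def test_invalid_dt_rejected(self):
        f = make_synthetic_field("zero", days=1)
        with pytest.raises(ValueError):
            advect_diffuse_step(_particles(0, 0), f, 0.0, -5.0, 0.0, np.random.default_rng(0))


class TestSettlement:
    def test_too_young_remains_active(self):
        st = _particles(0.05, 0.05)
        st.age_days[:] = 10.0
        st = settle(st, {"sq": _square(0, 0)}, pld_days=25, window_days=5)
        assert st.status[0] == ACTIVE

    def test_settles_during_window_first_polygon_wins(self):
        st = _particles(0.05, 0.05)
        st.age_days[:] = 25.0
        overlapping = {"first": _square(0, 0), "second": _square(0, 0, 0.2)}
        st = settle(st, overlapping, pld_days=25, window_days=5)
        assert st.status[0] == 1  # settled
        assert st.sink[0] == 0    # declaration order

    def test_expires_after_window(self):
        st = _particles(10.0, 10.0)  # outside any polygon
        st.age_days[:] = 31.0
        st = settle(st, {"sq": _square(0, 0)}, pld_days=25, window_days=5)
        assert st.status[0] == 3  # expired


class TestFullRun:
    def test_self_recruitment_with_zero_flow(self):
        f = make_synthetic_field("zero", days=31)
        polys = {"home": _square(-0.2, -0.2, 0.4)}
        cfg = DispersalConfig(particles_per_day=50, seeding_days=1, substeps_per_day=4,
                              eddy_diffusivity=0.0, seed=0)
        run = run_dispersal(f, polys, cfg)
        assert run.connectivity.loc["home", "home"] == pytest.approx(1.0)

    def test_constructed_source_sink_connectivity_one(self):
        # uniform eastward flow; sink centred on the 25-day advected image
        u0 = 0.1
        shift = u0 * 86400 * 25 / DEG2M
        f = make_synthetic_field("uniform", lon=np.linspace(-1, 3, 41),
                                 lat=np.linspace(-1, 1, 21), days=31, u0=u0)
        src = {"S": _square(-0.5, -0.05, 0.1)}
        snk = {"T": Polygon([(shift - 0.7, -0.3), (shift - 0.2, -0.3),
                             (shift - 0.2, 0.3), (shift - 0.7, 0.3)])}
        cfg = DispersalConfig(particles_per_day=100, seeding_days=1, substeps_per_day=24,
                              eddy_diffusivity=0.0, seed=1)
        run = run_dispersal(f, src, cfg, sink_polygons=snk)
        assert run.connectivity.loc["S", "T"] == pytest.approx(1.0)
        assert run.connectivity.loc["S", "unsettled"] == 0.0

    def test_particle_conservation_every_logged_day(self):
        f = make_synthetic_field("double_gyre", lon=np.linspace(0, 2, 41),
                                 lat=np.linspace(0, 1, 21), days=31, amplitude=0.05)
        polys = {"a": _square(0.3, 0.3), "b": _square(1.5, 0.6)}
        cfg = DispersalConfig(particles_per_day=60, seeding_days=3, substeps_per_day=6,
                              eddy_diffusivity=2.0, seed=2)
        run = run_dispersal(f, polys, cfg)
        per_day = run.trajectories.groupby("day").size()
        assert (per_day == 180).iloc[3:].all()
        rows = run.connectivity.drop(columns=[]).sum(axis=1)
        np.testing.assert_allclose(rows, 1.0, atol=1e-9)

    def test_westward_flow_sends_particles_west(self):
        f = make_synthetic_field("uniform", lon=np.linspace(-3, 1, 41),
                                 lat=np.linspace(-1, 1, 21), days=31, u0=-0.1)
        polys = {"src": _square(0.0, -0.05, 0.1)}
        cfg = DispersalConfig(particles_per_day=50, seeding_days=1, substeps_per_day=8,
                              eddy_diffusivity=0.0, seed=3)
        run = run_dispersal(f, polys, cfg)
        final = run.trajectories[run.trajectories.day == 30]
        assert (final.lon < 0.0).all()

    def test_reproducible_under_fixed_seed(self):
        f = make_synthetic_field("double_gyre", lon=np.linspace(0, 2, 21),
                                 lat=np.linspace(0, 1, 11), days=31, amplitude=0.05)
        polys = {"a": _square(0.3, 0.3)}
        cfg = DispersalConfig(particles_per_day=40, seeding_days=2, substeps_per_day=4,
                              eddy_diffusivity=2.0, seed=7)
        r1 = run_dispersal(f, polys, cfg)
        r2 = run_dispersal(f, polys, cfg)
        assert r1.trajectories.equals(r2.trajectories)
        assert r1.connectivity.equals(r2.connectivity)

    def test_short_field_rejected(self):
        f = make_synthetic_field("zero", days=10)
        with pytest.raises(ValueError, match="duration"):
            run_dispersal(f, {"a": _square(0, 0)}, DispersalConfig(particles_per_day=5))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            DispersalConfig(duration_days=20, pld_days=25, settlement_window_days=5)


class TestGeoJSON:
    def test_round_trip(self, tmp_path):
        polys = {"a": _square(0, 0), "b": _square(1, 1, 0.2)}
        p = tmp_path / "polys.geojson"
        write_polygons_geojson(polys, p)
        back = read_polygons_geojson(p)
        assert list(back) == ["a", "b"]
        assert back["a"].equals(polys["a"])

    def test_duplicate_names_rejected(self, tmp_path):
        import json

        polys = {"a": _square(0, 0)}
        p = tmp_path / "polys.geojson"
        write_polygons_geojson(polys, p)
        data = json.loads(p.read_text())
        data["features"].append(data["features"][0])
        p.write_text(json.dumps(data))
        with pytest.raises(ValueError, match="duplicate"):
            read_polygons_geojson(p)
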