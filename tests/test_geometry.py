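"""Unit and property tests for the closed-form sphere reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import urovol as uv
from conftest import random_configuration, solve_from_ranges


class TestChordLengths:
    def test_coincident_rays_are_degenerate(self):
        geom = uv.BeamGeometry(0.0, np.deg2rad(10), np.deg2rad(10))
        with pytest.raises(uv.DegenerateTriangleError):
            uv.chord_lengths((1.0, 1.0, 1.0), geom)

    def test_equilateral_symmetric_fan(self):
        d = 0.08
        geom = uv.BeamGeometry(*np.deg2rad([10.0, 10.0, 10.0]))
        tri = uv.chord_lengths((d, d, d), geom)
        side = 2 * d * np.sin(np.deg2rad(5.0))
        assert tri.l == pytest.approx(side, rel=1e-12)
        assert tri.m == pytest.approx(side, rel=1e-12)
        assert tri.n == pytest.approx(side, rel=1e-12)
        assert tri.theta == pytest.approx(np.pi / 3, rel=1e-12)
        assert tri.circumradius_r == pytest.approx(side / np.sqrt(3), rel=1e-12)

    @given(
        h1=st.floats(0.03, 0.2),
        h2=st.floats(0.03, 0.2),
        alpha_deg=st.floats(2.0, 85.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_first_chord_matches_law_of_cosines(self, h1, h2, alpha_deg):
        a = np.deg2rad(alpha_deg)
        geom = uv.BeamGeometry(a, a, a)  # symmetric fan is always realizable
        expected = np.sqrt(h1**2 + h2**2 - 2 * h1 * h2 * np.cos(a))
        try:
            tri = uv.chord_lengths((h1, h2, (h1 + h2) / 2), geom)
        except uv.DegenerateTriangleError:
            return  # some draws give flat triangles; the error path is tested above
        assert tri.l == pytest.approx(expected, rel=1e-12)

    def test_chord_increases_with_beam_angle(self):
        h1, h2, h3 = 0.08, 0.095, 0.085
        ls = []
        for a in np.deg2rad(np.linspace(5, 25, 11)):
            geom = uv.BeamGeometry(a, np.deg2rad(15), np.deg2rad(15))
            ls.append(uv.chord_lengths((h1, h2, h3), geom).l)
        assert np.all(np.diff(ls) > 0)

    def test_circumcenter_is_equidistant_from_vertices(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            _, geom, _, far = random_configuration(rng)
            tri = uv.chord_lengths(far, geom)
            dists = np.linalg.norm(tri.vertices - tri.circumcenter_O1, axis=1)
            assert np.allclose(dists, tri.circumradius_r, rtol=1e-10)


class TestApexPosition:
    def test_equilateral_apex_above_circumcenter(self):
        d = 0.08
        geom = uv.BeamGeometry(*np.deg2rad([10.0, 10.0, 10.0]))
        tri = uv.chord_lengths((d, d, d), geom)
        apex = uv.apex_position(tri, (d, d, d))
        assert apex.xp == pytest.approx(tri.l / 2, rel=1e-12)
        assert apex.yp == pytest.approx(tri.l / (2 * np.sqrt(3)), rel=1e-12)
        assert apex.zp > 0

    def test_right_angle_cancellation_gives_zero_xp(self):
        # forward-construct P on the x=0 plane: then h2^2 = h1^2 + l^2
        tri = uv.ChordTriangle(
            l=0.6, m=0.7211102550927979, n=0.8, theta=0.9,
            circumradius_r=0.0, circumcenter_O1=np.zeros(3),
        )
        p = np.array([0.0, 0.3, 0.7])
        h = [float(np.linalg.norm(p - v)) for v in tri.vertices]
        apex = uv.apex_position(tri, h)
        assert apex.xp == pytest.approx(0.0, abs=1e-12)

    def test_forward_backward_round_trip(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            a = np.zeros(3)
            b = np.array([rng.uniform(0.02, 0.1), 0, 0])
            theta = rng.uniform(0.3, 2.5)
            n = rng.uniform(0.02, 0.1)
            c = np.array([n * np.cos(theta), n * np.sin(theta), 0.0])
            p = np.array([rng.uniform(-0.05, 0.1), rng.uniform(-0.05, 0.1),
                          rng.uniform(0.02, 0.15)])
            tri = uv.ChordTriangle(
                l=float(np.linalg.norm(b - a)),
                m=float(np.linalg.norm(c - b)),
                n=float(np.linalg.norm(c - a)),
                theta=theta, circumradius_r=0.0, circumcenter_O1=np.zeros(3),
            )
            far = [float(np.linalg.norm(p - v)) for v in (a, b, c)]
            apex = uv.apex_position(tri, far)
            assert np.allclose(apex.position, p, atol=1e-12)

    def test_inconsistent_distances_raise(self):
        geom = uv.BeamGeometry(*np.deg2rad([10.0, 10.0, 10.0]))
        tri = uv.chord_lengths((0.08, 0.08, 0.08), geom)
        with pytest.raises(uv.InconsistentDistancesError):
            uv.apex_position(tri, (0.005, 0.08, 0.08))


class TestSolveSphere:
    def test_symmetric_fan_center_on_axis(self, fan10):
        ph = uv.phantom_for_volume(240.0)
        dirs = uv.beam_fan(fan10)
        pairs = [uv.ray_sphere_intersections(np.zeros(3), v, ph) for v in dirs]
        near = [p[0] for p in pairs]
        far = [p[1] for p in pairs]
        tri, apex, sph = solve_from_ranges(fan10, near, far, ph.standoff)
        # axisymmetric: apex sits directly above the circumcenter and the
        # reconstructed center lies on that vertical axis
        assert apex.xp == pytest.approx(tri.circumcenter_O1[0], rel=1e-9)
        assert apex.yp == pytest.approx(tri.circumcenter_O1[1], rel=1e-9)
        assert sph.center_O[:2] == pytest.approx([apex.xp, apex.yp], rel=1e-9)
        assert sph.R == pytest.approx(ph.radius, rel=1e-9)

    def test_oracle_ray_sphere_roundtrip_example(self, fan10):
        # sphere R = 30 mm centred 50 mm below the apex -> h = 20 mm
        ph = uv.PhantomSpec(center=(0.0, 0.0, 0.05), radius=0.03)
        dirs = uv.beam_fan(fan10)
        pairs = [uv.ray_sphere_intersections(np.zeros(3), v, ph) for v in dirs]
        _, _, sph = solve_from_ranges(
            fan10, [p[0] for p in pairs], [p[1] for p in pairs], 0.02
        )
        assert sph.R == pytest.approx(0.03, rel=1e-9)

    def test_matches_four_point_fit_on_random_configurations(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            ph, geom, near, far = random_configuration(rng)
            tri, apex, sph = solve_from_ranges(geom, near, far, geom.standoff_h)
            a_prime = apex.position + (tri.vertices[0] - apex.position) * (
                near[0] / far[0]
            )
            _, r_fit = uv.fit_sphere_four_points(*tri.vertices, a_prime)
            assert abs(sph.R - r_fit) / r_fit < 1e-8

    def test_vertices_equidistant_within_residual(self):
        rng = np.random.default_rng(29)
        for _ in range(50):
            ph, geom, near, far = random_configuration(rng)
            tri, apex, sph = solve_from_ranges(geom, near, far, geom.standoff_h)
            for v in tri.vertices:
                assert abs(np.linalg.norm(v - sph.center_O) - sph.R) <= sph.residual + 1e-15

    def test_scale_equivariance(self):
        rng = np.random.default_rng(31)
        ph, geom, near, far = random_configuration(rng)
        _, _, sph = solve_from_ranges(geom, near, far, geom.standoff_h)
        for k in (0.5, 2.0, 3.7):
            _, _, sph_k = solve_from_ranges(
                geom, [k * x for x in near], [k * x for x in far], k * geom.standoff_h
            )
            assert sph_k.R == pytest.approx(k * sph.R, rel=1e-9)
            assert uv.sphere_volume(sph_k.R) == pytest.approx(
                k**3 * uv.sphere_volume(sph.R), rel=1e-8
            )


class TestSphereVolume:
    @pytest.mark.parametrize(
        "radius_m, expected_ml",
        [
            (0.0, 0.0),
            (0.01, 4 * np.pi / 3),  # 1 cm sphere ~ 4.18879 mL
        ],
    )
    def test_known_values(self, radius_m, expected_ml):
        assert uv.sphere_volume(radius_m) == pytest.approx(expected_ml, abs=1e-9)

    def test_inverse_cube_root_gives_first_balloon(self):
        r = uv.radius_for_volume(120.0)
        assert r == pytest.approx((3 * 120 / (4 * np.pi)) ** (1 / 3) / 100, rel=1e-12)
        assert r == pytest.approx(0.0305983, abs=5e-7)
        assert uv.sphere_volume(r) == pytest.approx(120.0, rel=1e-12)

    def test_negative_radius_rejected(self):
        with pytest.raises(uv.ConfigError):
            uv.sphere_volume(-0.01)

    @given(st.floats(1e-4, 0.2), st.floats(1e-4, 0.2))
    @settings(max_examples=50, derandomize=True)
    def test_strictly_increasing(self, r1, r2):
        if r1 == r2:
            return
        lo, hi = sorted((r1, r2))
        assert uv.sphere_volume(lo) < uv.sphere_volume(hi)


class TestEstimateStandoff:
    def test_mean_and_min(self):
        assert uv.estimate_standoff((0.020, 0.020, 0.020), "mean") == pytest.approx(0.020)
        assert uv.estimate_standoff((0.021, 0.020, 0.022), "min") == pytest.approx(0.020)

    def test_fixed_requires_value(self):
        with pytest.raises(uv.ConfigError):
            uv.estimate_standoff((0.02, 0.02, 0.02), "fixed")
        assert uv.estimate_standoff(None, "fixed", 0.02) == 0.02

    def test_min_strategy_bias_bound_for_ten_degree_fan(self, fan10):
        # on-axis sphere: min first-echo range overestimates h by at most
        # (1 - cos 10 deg) * |OP|
        rng = np.random.default_rng(37)
        dirs = uv.beam_fan(fan10)
        for _ in range(50):
            r = rng.uniform(0.02, 0.06)
            h = rng.uniform(0.01, 0.04)
            ph = uv.PhantomSpec(center=(0.0, 0.0, h + r), radius=r)
            near = [uv.ray_sphere_intersections(np.zeros(3), v, ph)[0] for v in dirs]
            bias = uv.estimate_standoff(near, "min") - ph.standoff
            assert 0 <= bias <= (1 - np.cos(np.deg2rad(10))) * (h + r)


class TestRaySphere:
    def test_axial_ray(self):
        ph = uv.PhantomSpec(center=(0.0, 0.0, 5.0), radius=3.0)
        near, far = uv.ray_sphere_intersections((0, 0, 0), (0, 0, 1), ph)
        assert near == pytest.approx(2.0, abs=1e-12)
        assert far == pytest.approx(8.0, abs=1e-12)

    def test_tangent_ray_misses(self):
        ph = uv.PhantomSpec(center=(0.0, 0.0, 5.0), radius=3.0)
        with pytest.raises(uv.RayMissError):
            uv.ray_sphere_intersections((3.0, 0, 0), (0, 0, 1), ph)
        with pytest.raises(uv.RayMissError):
            uv.ray_sphere_intersections((10.0, 0, 0), (0, 0, 1), ph)

    def test_against_marching_oracle(self):
        rng = np.random.default_rng(41)
        ph = uv.PhantomSpec(center=(0.01, -0.005, 0.06), radius=0.025)
        for _ in range(20):
            d = rng.normal(size=3)
            d[2] = abs(d[2]) + 1.5  # aim roughly at the sphere
            d /= np.linalg.norm(d)
            try:
                near, far = uv.ray_sphere_intersections(np.zeros(3), d, ph)
            except uv.RayMissError:
                continue
            # brute-force marching: sign changes of |x(t) - c| - R
            t = np.linspace(0.0, 0.2, 2_000_001)
            f = np.linalg.norm(t[:, None] * d - ph.center_array, axis=1) - ph.radius
            crossings = t[np.nonzero(np.diff(np.sign(f)))[0]]
            assert abs(crossings[0] - near) < 1e-6
            assert abs(crossings[-1] - far) < 1e-6

    def test_non_unit_direction_rejected(self):
        ph = uv.PhantomSpec(center=(0.0, 0.0, 5.0), radius=3.0)
        with pytest.raises(uv.ConfigError):
            uv.ray_sphere_intersections((0, 0, 0), (0, 0, 2.0), ph)


class TestFitSphereFourPoints:
    def test_unit_sphere(self):
        c, r = uv.fit_sphere_four_points(
            (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, 0, 1)
        )
        assert np.allclose(c, 0.0, atol=1e-12)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_recovers_random_sphere(self):
        rng = np.random.default_rng(43)
        for _ in range(50):
            center = rng.uniform(-1, 1, 3)
            radius = rng.uniform(0.1, 2.0)
            pts = rng.normal(size=(4, 3))
            pts = center + radius * pts / np.linalg.norm(pts, axis=1)[:, None]
            if abs(np.linalg.det(pts[1:] - pts[0])) < 1e-6:
                continue
            c, r = uv.fit_sphere_four_points(*pts)
            assert np.allclose(c, center, atol=1e-10)
            assert r == pytest.approx(radius, abs=1e-10)

    def test_coplanar_points_rejected(self):
        with pytest.raises(uv.GeometryError):
            uv.fit_sphere_four_points((0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0))
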