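"""Domain geometry: membership, projections, normals, kinematics."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mobosim.geometry import (ShrinkingCircle, static_circle, Dumbbell,
                              DividingNucleus, StaticDomain,
                              synthetic_division_frames, read_frames,
                              write_frames)


class TestShrinkingCircle:
    @pytest.mark.parametrize("t, expected", [(0.0, 5.0), (5.0, 3.0), (2.5, 4.0),
                                             (7.0, 3.0)])
    def test_radius_linear_then_clamped(self, bench_circle, t, expected):
        assert bench_circle.radius_at(t) == pytest.approx(expected)

    def test_negative_time_rejected(self, bench_circle):
        with pytest.raises(ValueError):
            bench_circle.radius_at(-0.1)

    def test_membership_is_strict_interior(self, bench_circle):
        assert bench_circle.contains([4.9, 0.0], 0.0)
        assert not bench_circle.contains([5.0, 0.0], 0.0)
        assert not bench_circle.contains([5.1, 0.0], 0.0)

    @pytest.mark.parametrize("x", [[6.0, 0.0], [4.0, 0.0]])
    def test_projection_is_radial(self, bench_circle, x):
        np.testing.assert_allclose(
            bench_circle.closest_boundary_point(x, 0.0), [5.0, 0.0], atol=1e-12)

    def test_projection_tie_break_at_centre(self, bench_circle):
        # non-unique minimiser: smallest x, then smallest y
        np.testing.assert_allclose(
            bench_circle.closest_boundary_point([0.0, 0.0], 0.0), [-5.0, 0.0])

    def test_kinematics_radial_inward(self, bench_circle):
        n, v = bench_circle.boundary_kinematics([0.0, 4.0], 2.5)
        np.testing.assert_allclose(n, [0.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(v, [0.0, -0.4], atol=1e-12)

    def test_static_domain_zero_velocity(self):
        c = static_circle(5.0)
        _, v = c.boundary_kinematics([0.0, 5.0], 3.0)
        np.testing.assert_allclose(v, [0.0, 0.0], atol=1e-15)

    def test_numeric_velocity_converges_to_analytic(self, bench_circle):
        # finite-difference nearest-point velocity -> analytic r-dot as dt -> 0
        x = np.array([3.0, 4.0]) / 5.0 * bench_circle.radius_at(1.0)
        exact = bench_circle.boundary_velocity(x, 1.0)
        fd = super(ShrinkingCircle, bench_circle).boundary_velocity(x, 1.0, dt=1e-6)
        np.testing.assert_allclose(fd, exact, atol=1e-5)


class TestDumbbell:
    @pytest.mark.parametrize("t, expected", [(100000.0, 0.0), (201000.0, 10.0),
                                             (200500.0, 5.0), (999999.0, 10.0)])
    def test_bridge_length_schedule(self, dumbbell_full, t, expected):
        assert dumbbell_full.bridge_length(t) == pytest.approx(expected)

    def test_bridge_membership(self, dumbbell_open):
        t = 1000.0  # bridge length 10
        assert dumbbell_open.contains([0.0, 0.4, 0.0], t)
        assert not dumbbell_open.contains([0.0, 0.6, 0.0], t)

    def test_aperture_cross_section_equals_bridge_radius(self, dumbbell_open):
        # the sphere cross-section at x = +-l/2 has radius exactly d
        t = 1000.0
        l = dumbbell_open.bridge_length(t)
        c = dumbbell_open.centre_x(t)
        cross = np.sqrt(dumbbell_open.R ** 2 - (l / 2 - c) ** 2)
        assert cross == pytest.approx(dumbbell_open.d, abs=1e-10)

    @settings(max_examples=50, deadline=None)
    @given(x=st.floats(-8, 8), y=st.floats(-4, 4), z=st.floats(-4, 4),
           t=st.floats(0, 2000))
    def test_mirror_symmetry(self, dumbbell_open, x, y, z, t):
        assert (dumbbell_open.contains([x, y, z], t)
                == dumbbell_open.contains([-x, y, z], t))

    @pytest.mark.parametrize("pt", [[0.0, 0.45, 0.0], [2.0, 0.3, 0.2],
                                    [-6.5, 0.5, 0.0], [0.0, 2.0, 0.0],
                                    [4.9, 0.1, -0.1]])
    def test_projection_matches_brute_force(self, dumbbell_open, pt):
        t = 1000.0
        p = dumbbell_open.closest_boundary_point(pt, t)
        oracle_p, oracle_d = _brute_force_closest(dumbbell_open, t, np.asarray(pt))
        d = np.linalg.norm(np.asarray(pt) - p)
        assert d == pytest.approx(oracle_d, abs=1e-4)
        np.testing.assert_allclose(p, oracle_p, atol=5e-3)

    def test_projection_idempotent(self, dumbbell_open, rng):
        t = 500.0
        pts = rng.normal(0.0, 3.0, size=(100, 3))
        p, n = dumbbell_open.project_boundary(pts, t)
        p2, _ = dumbbell_open.project_boundary(p, t)
        np.testing.assert_allclose(p2, p, atol=1e-9)
        np.testing.assert_allclose(np.linalg.norm(n, axis=1), 1.0, atol=1e-12)

    def test_cap_velocity_matches_richardson_nearest_point(self, dumbbell_open):
        # mid-elongation, point on a sphere cap: the nearest-point velocity at
        # dt and dt/2 agree to first order
        t = 500.0
        c = dumbbell_open.centre_x(t)
        x = np.array([c + dumbbell_open.R / np.sqrt(2), dumbbell_open.R / np.sqrt(2), 0.0])
        v1 = dumbbell_open.boundary_velocity(x, t, dt=1e-3)
        v2 = dumbbell_open.boundary_velocity(x, t, dt=5e-4)
        np.testing.assert_allclose(v1, v2, atol=1e-4)


def _brute_force_closest(db, t, pt, n=200_000):
    """Dense sampling of the dumbbell surface profile (independent oracle)."""
    th_ap = np.arcsin(db.d / db.R)
    c = db.centre_x(t)
    l = db.bridge_length(t)
    th = np.linspace(th_ap, np.pi, n)
    arcs = [np.stack([-c + db.R * np.cos(th), db.R * np.sin(th)], axis=1),
            np.stack([c + db.R * np.cos(np.pi - th), db.R * np.sin(np.pi - th)], axis=1)]
    if l > 0:
        xs = np.linspace(-l / 2, l / 2, n)
        arcs.append(np.stack([xs, np.full(n, db.d)], axis=1))
    prof = np.vstack(arcs)
    prho = np.hypot(pt[1], pt[2])
    d = np.hypot(prof[:, 0] - pt[0], prof[:, 1] - prho)
    i = int(d.argmin())
    u = (np.array([pt[1], pt[2]]) / prho) if prho > 0 else np.array([-1.0, 0.0])
    best = np.array([prof[i, 0], prof[i, 1] * u[0], prof[i, 1] * u[1]])
    return best, float(d.min())


class TestDividingNucleus:
    def test_interpolation_midpoint_is_mean(self, nucleus):
        f = nucleus.frames
        t_mid = 0.5 * (f.loc[0, "time_s"] + f.loc[1, "time_s"])
        got = np.array(nucleus.params_at(t_mid))
        expected = 0.5 * (f.iloc[0, 1:].to_numpy(float) + f.iloc[1, 1:].to_numpy(float))
        np.testing.assert_allclose(got, expected)

    def test_bridge_axis_point_is_bridge_member(self, nucleus):
        t = 100.0
        _, _, _, _, l, w = nucleus.params_at(t)
        x_mid = nucleus.bridge_midplane(t)
        assert nucleus.region_of([x_mid, 0.5 * w, 0.0], t) == 1

    @pytest.mark.parametrize("t", [0.0, 75.0, 200.0])
    def test_recentred_centroid_is_zero(self, nucleus, t):
        # independent oracle: quadrature of the membership indicator in the
        # axisymmetric (x, rho) plane with weight 2 pi rho
        xs = np.linspace(-4.0, 4.0, 801)
        rhos = np.linspace(0.0, 1.2, 241)
        X, R = np.meshgrid(xs, rhos, indexing="ij")
        pts = np.stack([X.ravel(), R.ravel(), np.zeros(X.size)], axis=1)
        ind = nucleus.contains(pts, t).reshape(X.shape).astype(float)
        w = ind * R
        vol = np.trapezoid(np.trapezoid(w, rhos, axis=1), xs)
        mx = np.trapezoid(np.trapezoid(w * X, rhos, axis=1), xs)
        assert abs(mx / vol) < 2e-3

    def test_time_outside_frame_span_rejected(self, nucleus):
        with pytest.raises(ValueError):
            nucleus.params_at(1000.0)

    def test_projection_idempotent_and_consistent(self, nucleus, rng):
        t = 60.0
        pts = rng.normal(0.0, 1.5, size=(80, 3))
        p, n = nucleus.project_boundary(pts, t)
        p2, _ = nucleus.project_boundary(p, t)
        np.testing.assert_allclose(p2, p, atol=1e-8)
        eps = 1e-6
        assert nucleus.contains(p - eps * n, t).all()
        assert not nucleus.contains(p + eps * n, t).any()

    def test_frame_table_validation(self):
        f = synthetic_division_frames()
        bad = f.copy()
        bad.loc[1, "time_s"] = bad.loc[0, "time_s"]
        with pytest.raises(ValueError):
            DividingNucleus(bad)

    def test_frame_table_round_trip(self, tmp_path):
        f = synthetic_division_frames()
        path = tmp_path / "frames.tsv"
        write_frames(f, path)
        back = read_frames(path)
        np.testing.assert_allclose(back.to_numpy(float), f.to_numpy(float))


class TestStaticWrapper:
    def test_frozen_membership_and_projection(self, nucleus):
        s = StaticDomain(nucleus, 0.0)
        pt = [0.5, 0.2, 0.0]
        assert s.contains(pt, 123.0) == nucleus.contains(pt, 0.0)
        np.testing.assert_allclose(s.project_boundary([0, 2, 0], 99.0)[0],
                                   nucleus.project_boundary([0, 2, 0], 0.0)[0])
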