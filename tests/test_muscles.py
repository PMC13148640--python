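"""Muscle routing, wrapping geometry and tendon-excursion moment arms."""

import numpy as np
import pytest

from paleolimb import muscles as M
from paleolimb.joints import Bone, FrameACS, JointSpec, KinematicChain


def hinge_chain(rom=(-90.0, 90.0)):
    """Hinge at the origin, axis = world +y (JCS z)."""
    axes = np.column_stack([(1.0, 0, 0), (0, 0, -1.0), (0, 1.0, 0)])
    joint = JointSpec("hinge", "parent", "child", FrameACS(np.zeros(3), axes),
                      dof_mask=("z",), rom_limits={"z": rom})
    return KinematicChain([Bone("parent"), Bone("child")], [joint])


def cyl_frame(origin=(0.0, 0.0, 0.0)):
    # cylinder local z along world +y (the hinge axis)
    T = np.eye(4)
    T[:3, :3] = np.column_stack([(1.0, 0, 0), (0, 0, -1.0), (0, 1.0, 0)])
    T[:3, 3] = origin
    return T


def numeric_geodesic_length(p, s, radius, n=100):
    """Independent oracle: shortest tangent-arc-tangent path around an
    infinite cylinder about z, by brute-force search over the two surface
    contact angles (tangency enforced by penalty) with local refinement.
    The blocked straight chord is NOT a candidate."""
    from scipy.optimize import minimize

    p, s = np.asarray(p, float), np.asarray(s, float)
    thetas = np.linspace(-np.pi, np.pi, n, endpoint=False)
    best = np.inf
    best_x = (0.0, 0.0)
    for th1 in thetas:
        for th2 in thetas:
            v = _path_via(p, s, radius, th1, th2)
            if v < best:
                best, best_x = v, (th1, th2)
    res = minimize(lambda x: _path_via(p, s, radius, x[0], x[1]),
                   x0=list(best_x), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12})
    return min(best, res.fun)


def _segment_min_dist_to_origin(a, b):
    d = b - a
    L2 = d @ d
    if L2 == 0:
        return np.linalg.norm(a)
    t = np.clip(-(a @ d) / L2, 0.0, 1.0)
    return np.linalg.norm(a + t * d)


def _path_via(p, s, r, th1, th2):
    q2 = r * np.array([np.cos(th1), np.sin(th1)])
    t2 = r * np.array([np.cos(th2), np.sin(th2)])
    # straight segments must not cut the obstacle's projected disc
    if _segment_min_dist_to_origin(p[:2], q2) < r * (1 - 1e-9):
        return np.inf
    if _segment_min_dist_to_origin(t2, s[:2]) < r * (1 - 1e-9):
        return np.inf
    arc = abs((th2 - th1 + np.pi) % (2 * np.pi) - np.pi)
    l1 = np.linalg.norm(q2 - p[:2])
    l2 = np.linalg.norm(s[:2] - t2)
    L2 = l1 + r * arc + l2
    dz = s[2] - p[2]
    return np.hypot(L2, dz)


class TestRouting:
    def test_straight_line_length(self):
        chain = hinge_chain()
        mus = M.MusclePath("m", [("parent", (0, 0, 0.05)),
                                 ("child", (0, 0, -0.05))])
        L, poly = M.route_path(mus, chain)
        assert L == pytest.approx(0.1)
        assert len(poly) == 2

    def test_path_length_at_least_chord(self, toy_chain, toy_muscles):
        mus, _ = toy_muscles
        from paleolimb.joints import pose

        transforms = pose(toy_chain, {})
        for m in mus:
            L, _ = M.route_path(m, toy_chain)
            pts = []
            for b, xyz in m.points:
                T = transforms[b]
                pts.append(T[:3, :3] @ np.asarray(xyz) + T[:3, 3])
            chord = np.linalg.norm(pts[-1] - pts[0])
            assert L >= chord - 1e-12

    def test_cylinder_wrap_matches_closed_form_and_oracle(self):
        d, r = 0.05, 0.02
        p, s = np.array([-d, 0, 0.0]), np.array([d, 0, 0.0])
        L, wrapped, _ = M.cylinder_wrap_length(p, s, r, +1)
        closed = 2 * np.sqrt(d**2 - r**2) + r * (np.pi - 2 * np.arccos(r / d))
        assert wrapped
        assert L == pytest.approx(closed, abs=1e-12)
        assert L == pytest.approx(numeric_geodesic_length(p, s, r), abs=1e-5)

    def test_cylinder_wrap_with_axial_drop_vs_oracle(self):
        r = 0.015
        p = np.array([-0.04, -0.03, 0.00])
        s = np.array([0.05, 0.025, 0.07])
        L, wrapped, _ = M.cylinder_wrap_length(p, s, r, +1)
        Lm, wrappedm, _ = M.cylinder_wrap_length(p, s, r, -1)
        assert wrapped and wrappedm
        oracle = numeric_geodesic_length(p, s, r)
        assert min(L, Lm) == pytest.approx(oracle, abs=1e-4)

    def test_tangency_continuity_at_engagement(self):
        # slide the endpoint across the graze limit: the path length varies
        # continuously from the free chord into the engaged wrap
        r = 0.02
        p = np.array([-0.1, r + 1e-9, 0.0])
        L_free, wrapped_free, _ = M.cylinder_wrap_length(
            p, np.array([0.1, r + 1e-9, 0.0]), r, -1)
        assert not wrapped_free and L_free == pytest.approx(0.2, abs=1e-6)
        L_graze, _, _ = M.cylinder_wrap_length(
            p, np.array([0.1, r - 1e-7, 0.0]), r, -1)
        assert L_graze == pytest.approx(L_free, abs=1e-5)
        L_deep, wrapped, _ = M.cylinder_wrap_length(
            p, np.array([0.1, r - 1e-3, 0.0]), r, -1)
        assert wrapped
        assert L_free < L_deep < L_free + 1e-3

    def test_sphere_wrap_in_plane_closed_form(self):
        d, r = 0.06, 0.025
        p, s = np.array([-d, 0, 0.0]), np.array([d, 0, 0.0])
        L, wrapped, _ = M.sphere_wrap_length(p, s, r)
        closed = 2 * np.sqrt(d**2 - r**2) + r * (np.pi - 2 * np.arccos(r / d))
        assert wrapped
        assert L == pytest.approx(closed, abs=1e-12)

    def test_point_inside_wrap_rejected(self):
        with pytest.raises(M.PathRoutingError, match="inside"):
            M.cylinder_wrap_length((0.001, 0, 0), (0.1, 0, 0), 0.02)


class TestMomentArm:
    def test_axis_parallel_muscle_zero(self):
        chain = hinge_chain()
        mus = M.MusclePath("m", [("parent", (0.03, -0.02, 0)),
                                 ("child", (0.03, 0.02, 0))])
        assert M.moment_arm(mus, chain, "hinge", "z", 0.0) == pytest.approx(
            0.0, abs=1e-12)

    def test_hinge_perpendicular_distance_and_virtual_work(self):
        d = 0.02
        chain = hinge_chain()
        mus = M.MusclePath("m", [("parent", (-d, 0, 0.05)),
                                 ("child", (-d, 0, -0.05))])
        ma = M.moment_arm(mus, chain, "hinge", "z", 0.0)
        assert abs(ma) == pytest.approx(d, abs=1e-6)
        # virtual-work oracle: unit tension along the straight path; torque
        # about the hinge axis = (r x F) . axis at the child attachment
        attach = np.array([-d, 0, -0.05])
        direction = np.array([0.0, 0.0, 1.0])  # toward the parent point
        torque = np.cross(attach, direction) @ np.array([0.0, 1.0, 0.0])
        assert ma == pytest.approx(torque, abs=1e-6)

    def test_coaxial_wrap_moment_arm_equals_radius(self, toy_chain, toy_muscles):
        mus, registry = toy_muscles
        m = next(x for x in mus if x.name == "knee_coaxial_wrap")
        r = registry["knee_coaxial_wrap"]["mma_abs"]
        for deg in (0.0, -5.0, -10.0):
            ma = M.moment_arm(m, toy_chain, "knee", "z", np.deg2rad(deg))
            assert abs(ma) == pytest.approx(r, abs=1e-9)

    def test_finite_difference_converges_quadratically(self):
        chain = hinge_chain()
        mus = M.MusclePath("m", [("parent", (-0.02, 0, 0.05)),
                                 ("child", (-0.015, 0, -0.06))])
        a = np.deg2rad(10.0)
        coarse = M.moment_arm(mus, chain, "hinge", "z", a, h_deg=0.5)
        fine = M.moment_arm(mus, chain, "hinge", "z", a, h_deg=0.25)
        finest = M.moment_arm(mus, chain, "hinge", "z", a, h_deg=0.125)
        # successive halvings shrink the error ~4x; smooth path, tiny changes
        assert abs(fine - finest) < abs(coarse - fine)
        assert abs(fine - finest) < 5e-8

    def test_sign_convention_factor(self):
        chain = hinge_chain()
        mus = M.MusclePath("m", [("parent", (-0.02, 0, 0.05)),
                                 ("child", (-0.02, 0, -0.05))])
        raw = M.moment_arm(mus, chain, "hinge", "z", 0.0)
        flipped = M.moment_arm(mus, chain, "hinge", "z", 0.0, sign=-1.0)
        assert flipped == pytest.approx(-raw)


class TestCurvesAndReport:
    def test_coaxial_wrap_curve_plateau_and_grid(self):
        chain = hinge_chain(rom=(-30.0, 30.0))
        # a cylinder coaxial with the hinge pins the moment arm to its
        # radius wherever the wrap is engaged (the mid-range plateau)
        mus = M.MusclePath(
            "m", [("parent", (-0.04, 0.0, 0.05)), ("child", (0.04, 0.0, -0.05))],
            wraps=[M.WrapSurface("cylinder", "parent", cyl_frame(),
                                 radius=0.004, active_side=-1)])
        curve = M.mma_curve(mus, chain, "hinge", "z", grid_step_deg=5.0)
        assert curve.angles_deg[0] == -30.0 and curve.angles_deg[-1] == 30.0
        mid = np.abs(curve.angles_deg) <= 5.0
        assert np.allclose(np.abs(curve.moment_arms[mid]), 0.004, atol=1e-9)
        # continuity: no step-to-step jump beyond 10% of segment length
        assert np.max(np.abs(np.diff(curve.moment_arms))) < 0.1 * 0.1
        assert M.mean_dimensionless_mma(curve, 0.080) == pytest.approx(
            np.mean(curve.moment_arms) / 0.080)

    def test_flat_mean_dimensionless_value(self):
        curve = M.MomentArmCurve("m", "hip", "z", np.arange(5.0),
                                 np.full(5, 0.004))
        assert M.mean_dimensionless_mma(curve, 0.080) == pytest.approx(0.05)

    def test_mean_dimensionless_mma_scale_invariant(self, toy_spec):
        from paleolimb import synthetic

        k = 2.0
        spec0 = toy_spec
        chain0 = synthetic.make_toy_chain(spec0)
        mus0, _ = synthetic.make_toy_muscles(spec0)
        m0 = next(x for x in mus0 if x.name == "hip_extensor_strap")
        c0 = M.mma_curve(m0, chain0, "hip", "z")
        v0 = M.mean_dimensionless_mma(c0, spec0.femur_length)
        # uniform x2 scaling of every geometric quantity
        spec1 = synthetic.ToyTaxonSpec(
            femur_length=spec0.femur_length * k,
            limb_segments={n: (a * k, b * k, r * k)
                           for n, (a, b, r) in spec0.limb_segments.items()})
        chain1 = synthetic.make_toy_chain(spec1)
        m1 = M.MusclePath(m0.name, [(b, tuple(np.asarray(xyz) * k))
                                    for b, xyz in m0.points])
        c1 = M.mma_curve(m1, chain1, "hip", "z")
        v1 = M.mean_dimensionless_mma(c1, spec1.femur_length)
        assert v1 == pytest.approx(v0, abs=1e-12)

    def test_sphere_wrapped_hip_muscle_plateau_and_continuity(self, toy_chain,
                                                              toy_muscles):
        # while the sphere is engaged the moment arm is pinned to the wrap
        # radius (mid-range plateau); the curve stays continuous through
        # engagement and disengagement
        mus, _ = toy_muscles
        m = next(x for x in mus if x.name == "hip_sphere_abductor")
        curve = M.mma_curve(m, toy_chain, "hip", "z")
        mags = np.abs(curve.moment_arms)
        # plateau away from the symmetric pose (at exactly 0 deg the chord
        # passes through the sphere centre and the lever genuinely flips sign)
        mid = (np.abs(curve.angles_deg) >= 5.0) & (np.abs(curve.angles_deg) <= 30.0)
        assert np.allclose(mags[mid], m.wraps[0].radius, atol=1e-9)
        assert np.max(np.abs(np.diff(curve.moment_arms))) < 0.02

    def test_report_shape_and_determinism(self, toy_chain, toy_muscles, toy_spec):
        mus, _ = toy_muscles
        lengths = {"hip": toy_spec.femur_length, "knee": 0.068}
        r1 = M.mma_report(toy_chain, mus, [("hip", "z"), ("knee", "z")], lengths)
        r2 = M.mma_report(toy_chain, mus, [("hip", "z"), ("knee", "z")], lengths)
        assert len(r1) == len(mus) * 2
        assert r1.equals(r2)

    def test_missing_normalizer_rejected(self, toy_chain, toy_muscles):
        mus, _ = toy_muscles
        with pytest.raises(ValueError, match="normalizing"):
            M.mma_report(toy_chain, mus, [("ankle", "z")], {"hip": 0.08})

    def test_empty_curve_rejected(self):
        curve = M.MomentArmCurve("m", "hip", "z", np.array([]), np.array([]))
        with pytest.raises(ValueError, match="empty"):
            M.mean_dimensionless_mma(curve, 0.08)
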