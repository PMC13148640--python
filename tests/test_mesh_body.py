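"""Mass-property engine: closed-form solids, cavity bookkeeping, lofting,
caudal-series regression and whole-body summaries."""

import numpy as np
import pytest
import trimesh

from paleolimb import mesh_body as mb


def octagon_prism(radius, length, n_hoops=2):
    from paleolimb.synthetic import _prism_stack

    return _prism_stack(0.0, length, radius, axis="z", n_hoops=n_hoops)


class TestMeshMassProperties:
    def test_unit_cube(self):
        cube = trimesh.creation.box(extents=(1, 1, 1))
        cube.apply_translation((0.5, 0.5, 0.5))
        p = mb.mesh_mass_properties(cube, density=1060.0)
        assert p.mass == pytest.approx(1060.0)
        assert p.com == pytest.approx([0.5, 0.5, 0.5])
        assert p.volume == pytest.approx(1.0)

    def test_icosphere_matches_closed_form(self):
        r = 0.1
        sph = trimesh.creation.icosphere(subdivisions=4, radius=r)
        p = mb.mesh_mass_properties(sph, density=1000.0)
        assert p.volume == pytest.approx(4 / 3 * np.pi * r**3, rel=5e-3)
        assert np.linalg.norm(p.com) < 1e-9
        # inertia of a solid sphere: 2/5 m r^2 on the diagonal
        expected = 0.4 * p.mass * r**2
        assert np.diag(p.inertia) == pytest.approx([expected] * 3, rel=1e-2)

    def test_rigid_motion_invariance(self, rng):
        mesh = trimesh.creation.icosphere(subdivisions=2, radius=0.05)
        mesh.apply_translation((0.02, -0.01, 0.03))
        p0 = mb.mesh_mass_properties(mesh, 900.0)
        angle = rng.uniform(0, np.pi)
        axis = rng.normal(size=3)
        T = trimesh.transformations.rotation_matrix(angle, axis)
        T[:3, 3] = rng.uniform(-1, 1, 3)
        moved = mesh.copy()
        moved.apply_transform(T)
        p1 = mb.mesh_mass_properties(moved, 900.0)
        assert p1.mass == pytest.approx(p0.mass)
        assert np.sort(np.linalg.eigvalsh(p1.inertia)) == pytest.approx(
            np.sort(np.linalg.eigvalsh(p0.inertia)), rel=1e-9, abs=1e-15)
        com_mapped = T[:3, :3] @ p0.com + T[:3, 3]
        assert p1.com == pytest.approx(com_mapped, abs=1e-12)

    def test_open_mesh_rejected_with_edge_report(self):
        cube = trimesh.creation.box(extents=(1, 1, 1))
        open_mesh = trimesh.Trimesh(cube.vertices, cube.faces[:-2], process=False)
        with pytest.raises(mb.MeshError, match="open edge"):
            mb.mesh_mass_properties(open_mesh)

    def test_degenerate_and_bad_density(self):
        with pytest.raises(mb.MeshError):
            mb.mesh_mass_properties(trimesh.Trimesh(), 1000.0)
        with pytest.raises(ValueError, match="density"):
            mb.mesh_mass_properties(trimesh.creation.box(), -1.0)

    def test_inverted_orientation_repaired(self):
        cube = trimesh.creation.box(extents=(1, 1, 1))
        flipped = trimesh.Trimesh(cube.vertices, cube.faces[:, ::-1], process=False)
        p = mb.mesh_mass_properties(flipped, 500.0)
        assert p.volume == pytest.approx(1.0)


class TestCompositeSegments:
    def test_no_cavity_trivial(self):
        box = trimesh.creation.box(extents=(0.1, 0.1, 0.1))
        seg = mb.BodySegment("trunk", box, density=1060.0)
        p = mb.composite_segment_properties(seg)
        assert p.mass == pytest.approx(1060.0 * 1e-3)
        assert p.net_density == pytest.approx(1060.0)

    def test_head_neck_cavity_fraction_gives_95_percent_density(self):
        # an air space of 5.47% of segment volume cuts 1060 kg/m^3 to ~1002
        outer = trimesh.creation.box(extents=(0.1, 0.1, 0.1))
        k = 0.0547 ** (1 / 3)
        inner = trimesh.creation.box(extents=(0.1 * k,) * 3)
        seg = mb.BodySegment("head_neck", outer, [inner], density=1060.0)
        p = mb.composite_segment_properties(seg)
        assert p.net_density == pytest.approx(1002.0, abs=0.5)
        assert round(100 * p.net_density / 1060.0) == 95

    def test_concentric_sphere_shell_closed_form(self):
        R, r = 0.1, 0.05
        outer = trimesh.creation.icosphere(subdivisions=4, radius=R)
        inner = trimesh.creation.icosphere(subdivisions=4, radius=r)
        seg = mb.BodySegment("shell", outer, [inner], density=1000.0)
        p = mb.composite_segment_properties(seg)
        expected = 1000.0 * 4 / 3 * np.pi * (R**3 - r**3)
        assert p.mass == pytest.approx(expected, rel=5e-3)
        assert np.linalg.norm(p.com) < 1e-9

    def test_mass_conservation_exact(self):
        outer = trimesh.creation.box(extents=(0.2, 0.1, 0.1))
        inner = trimesh.creation.box(extents=(0.05, 0.05, 0.05))
        seg = mb.BodySegment("s", outer, [inner], density=1060.0)
        p = mb.composite_segment_properties(seg)
        solid = mb.mesh_mass_properties(outer, 1060.0)
        cavity = mb.mesh_mass_properties(inner, 1060.0)
        assert p.mass + cavity.mass == pytest.approx(solid.mass, abs=1e-12)

    def test_cavity_larger_than_solid_rejected(self):
        small = trimesh.creation.box(extents=(0.01, 0.01, 0.01))
        big = trimesh.creation.box(extents=(1, 1, 1))
        with pytest.raises(ValueError, match="cavity"):
            mb.composite_segment_properties(mb.BodySegment("x", small, [big]))


class TestHoops:
    def test_loft_octagonal_prism_closed_form(self):
        R, L = 0.05, 1.0
        mesh = mb.loft_hoops(octagon_prism(R, L))
        s = 2 * R * np.sin(np.pi / 8)  # octagon side from circumradius
        expected = 2 * (1 + np.sqrt(2)) * s**2 * L
        assert mesh.is_watertight
        assert mesh.volume == pytest.approx(expected, abs=1e-9)

    def test_frustum_volume_between_prisms(self):
        R, L = 0.05, 0.3
        stack = octagon_prism(R, L)
        scaled = mb.inflate_hoops(stack, [1.0, 0.5])
        frustum = mb.loft_hoops(scaled)
        v_big = mb.loft_hoops(octagon_prism(R, L)).volume
        v_small = mb.loft_hoops(octagon_prism(R / 2, L)).volume
        assert v_small < frustum.volume < v_big

    def test_single_hoop_rejected(self):
        from paleolimb.mesh_body import HoopStack, regular_octagon

        stack = HoopStack(regular_octagon(0.05, (0, 0, 0))[None])
        with pytest.raises(ValueError, match="2 hoops"):
            mb.loft_hoops(stack)

    def test_inflation_identity_and_area_scaling(self):
        R, L, k = 0.04, 0.2, 1.7
        stack = octagon_prism(R, L)
        same = mb.inflate_hoops(stack, 1.0)
        assert np.allclose(same.hoops, stack.hoops)
        inflated = mb.inflate_hoops(stack, k)
        v0 = mb.loft_hoops(stack).volume
        v1 = mb.loft_hoops(inflated).volume
        assert v1 == pytest.approx(k**2 * v0, rel=1e-12)

    def test_per_hoop_multiplier_scales_about_centroid(self):
        stack = octagon_prism(0.05, 1.0)
        out = mb.inflate_hoops(stack, [1.0, 2.0])
        c0 = stack.hoops[1].mean(axis=0)
        c1 = out.hoops[1].mean(axis=0)
        assert np.allclose(c0, c1)
        r1 = np.linalg.norm(out.hoops[1] - c1, axis=1)
        assert np.allclose(r1, 0.10)

    def test_nonpositive_multiplier_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            mb.inflate_hoops(octagon_prism(0.05, 1.0), 0.0)


class TestCaudalSeries:
    @staticmethod
    def exact_spec(n_measured=10, n_total=30):
        nums = np.arange(1, n_measured + 1)
        lengths = 10.0 - 0.2 * nums
        heights = 6.0 - 0.1 * nums
        return mb.CaudalSeriesSpec(np.c_[nums, lengths * 1e-3, heights * 1e-3],
                                   n_total=n_total)

    def test_perfect_line_recovered(self):
        res = mb.reconstruct_caudal_series(self.exact_spec())
        assert res.length_fit[2] == pytest.approx(1.0)
        assert res.height_fit[2] == pytest.approx(1.0)
        # vertebra 25 (unmeasured) follows the line exactly
        n, length, radius, _ = res.segments[24]
        assert n == 25
        assert length == pytest.approx((10.0 - 0.2 * 25) * 1e-3)
        assert radius == pytest.approx((6.0 - 0.1 * 25) * 1e-3 / 2)

    def test_noisy_slopes_recovered_within_2_se(self, rng):
        nums = np.arange(1.0, 19.0)
        true_slope = -0.25e-3
        lengths = 8e-3 + true_slope * nums + rng.normal(0, 0.1e-3, len(nums))
        heights = 5e-3 - 0.1e-3 * nums + rng.normal(0, 0.05e-3, len(nums))
        spec = mb.CaudalSeriesSpec(np.c_[nums, lengths, heights], n_total=30)
        res = mb.reconstruct_caudal_series(spec)
        # standard error of an OLS slope
        resid = lengths - (res.length_fit[0] * nums + res.length_fit[1])
        se = np.sqrt(np.sum(resid**2) / (len(nums) - 2)
                     / np.sum((nums - nums.mean()) ** 2))
        assert abs(res.length_fit[0] - true_slope) < 2 * se

    def test_ten_percent_gaps_total_extent(self):
        res = mb.reconstruct_caudal_series(self.exact_spec(n_total=30))
        lengths = [s[1] for s in res.segments]
        expected = sum(lengths) * 1.10 - 0.10 * lengths[-1]
        assert res.total_extent == pytest.approx(expected)

    def test_too_few_points_rejected(self):
        spec = mb.CaudalSeriesSpec(np.array([[1, 1e-2, 5e-3], [2, 9e-3, 4e-3],
                                             [3, 8e-3, 3e-3]]), n_total=5)
        mb.reconstruct_caudal_series(spec)  # 3 is the minimum
        with pytest.raises(ValueError):
            mb.reconstruct_caudal_series(
                mb.CaudalSeriesSpec(np.array([[1, 1e-2, 5e-3], [2, 9e-3, 4e-3]]),
                                    n_total=5))


class TestScaleAndSummary:
    def test_scale_factor_cubes_volume(self):
        cube = trimesh.creation.box(extents=(1, 1, 1))
        assert mb.scale_mesh(cube, 1.11).volume == pytest.approx(1.367631)
        assert mb.scale_mesh(cube, 1.0).volume == pytest.approx(1.0)
        assert mb.scale_mesh(cube, 0.15).volume == pytest.approx(0.15**3)

    def test_two_point_segments_com(self):
        a = trimesh.creation.box(extents=(0.01, 0.01, 0.01))
        b = a.copy()
        b.apply_translation((1.0, 0, 0))
        model = mb.BodyModel([mb.BodySegment("a", a), mb.BodySegment("b", b)],
                             hip_midpoint=(0, 0, 0), femur_length=0.08)
        s = mb.whole_body_summary(model)
        assert s.com[0] == pytest.approx(0.5)
        assert sum(s.mass_fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_printed_bipedality_ratio(self):
        # offset 0.053 m over a 0.080 m femur rounds to 66%
        a = trimesh.creation.box(extents=(0.01, 0.01, 0.01))
        a.apply_translation((0.053, 0, 0))
        model = mb.BodyModel([mb.BodySegment("a", a)], hip_midpoint=(0, 0, 0),
                             femur_length=0.080)
        s = mb.whole_body_summary(model)
        assert round(100 * s.bipedality_ratio) == 66

    def test_summary_independent_of_segment_order(self, toy_skeleton):
        model, _, _ = toy_skeleton
        s1 = mb.whole_body_summary(model)
        reordered = mb.BodyModel(list(reversed(model.segments)),
                                 model.hip_midpoint, model.femur_length,
                                 model.craniocaudal_axis)
        s2 = mb.whole_body_summary(reordered)
        assert s1.total_mass == pytest.approx(s2.total_mass)
        assert s1.com == pytest.approx(s2.com)

    def test_uniform_scaling_preserves_bipedality_ratio(self, toy_skeleton):
        model, _, _ = toy_skeleton
        s0 = mb.whole_body_summary(model)
        k = 2.0
        scaled = mb.BodyModel(
            [mb.BodySegment(s.name, mb.scale_mesh(s.solid, k),
                            [mb.scale_mesh(c, k) for c in s.cavities], s.density)
             for s in model.segments],
            hip_midpoint=np.asarray(model.hip_midpoint) * k,
            femur_length=model.femur_length * k,
            craniocaudal_axis=model.craniocaudal_axis)
        s1 = mb.whole_body_summary(scaled)
        assert s1.total_mass == pytest.approx(k**3 * s0.total_mass, rel=1e-9)
        assert s1.bipedality_ratio == pytest.approx(s0.bipedality_ratio, abs=1e-12)
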