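"""Joint coordinate systems, kinematic chains and range-of-motion scanning.

The workflow mirrors standard "digital marionette" modelling of fossil
limbs: geometric primitives (plane / sphere / cylinder / ellipsoid) are
least-squares fitted to isolated articular surfaces; anatomical and joint
coordinate systems (ACS/JCS) are built from the fitted primitives; joints
rotate in a fixed z-y-x Euler order (z = flexion/extension, y =
abduction/adduction, x = long-axis rotation); and joint limits are found by
sweeping one degree of freedom at a time in 5-degree steps until the bones
either collide or disarticulate.

Per-joint sign conventions differ anatomically (e.g. positive z is
*extension* at the hip but *flexion* at the elbow); they are data, carried
on each :class:`JointSpec`, not baked into code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree


# ---------------------------------------------------------------------------
# Primitive fitting
# ---------------------------------------------------------------------------

@dataclass
class ArticularSurface:
    points: np.ndarray  # (n, 3)
    bone_name: str = ""

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)


@dataclass
class GeometricPrimitive:
    kind: str  # plane | sphere | cylinder | ellipsoid
    center: np.ndarray = None  # type: ignore[assignment]
    normal: np.ndarray = None  # plane normal, type: ignore[assignment]
    axis: np.ndarray = None  # cylinder axis / ellipsoid principal axes (3x3), type: ignore
    radius: float = None  # sphere/cylinder, type: ignore[assignment]
    radii: np.ndarray = None  # ellipsoid semi-axes, type: ignore[assignment]
    rms_residual: float = 0.0


class DegenerateFitError(ValueError):
    pass


_MIN_POINTS = {"plane": 3, "sphere": 4, "cylinder": 6, "ellipsoid": 9}


def fit_primitive(surface: ArticularSurface, kind: str) -> GeometricPrimitive:
    """Least-squares fit of a geometric primitive to articular-surface points.

    plane: total least squares (SVD). sphere: algebraic (linear) fit refined
    geometrically. cylinder: nonlinear refinement seeded by the covariance
    direction of least surface-normal variation. ellipsoid: algebraic
    constrained fit. ``rms_residual`` is the RMS orthogonal distance of the
    points to the fitted surface.
    """
    pts = np.asarray(surface.points, float)
    need = _MIN_POINTS.get(kind)
    if need is None:
        raise ValueError(f"unknown primitive kind {kind!r}")
    if len(pts) < need:
        raise DegenerateFitError(f"{kind} fit needs >= {need} points, got {len(pts)}")
    return {"plane": _fit_plane, "sphere": _fit_sphere,
            "cylinder": _fit_cylinder, "ellipsoid": _fit_ellipsoid}[kind](pts)


def _fit_plane(pts):
    c = pts.mean(axis=0)
    u, s, vt = np.linalg.svd(pts - c, full_matrices=False)
    if s[1] < 1e-12 * max(s[0], 1e-30):
        raise DegenerateFitError("plane fit: points are collinear")
    n = vt[2]
    res = (pts - c) @ n
    return GeometricPrimitive("plane", center=c, normal=n,
                              rms_residual=float(np.sqrt(np.mean(res ** 2))))


def _sphere_algebraic(pts):
    # |p|^2 = 2 c.p + (r^2 - |c|^2): linear in (c, k)
    A = np.hstack([2 * pts, np.ones((len(pts), 1))])
    b = np.sum(pts ** 2, axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    c = sol[:3]
    r2 = sol[3] + c @ c
    if r2 <= 0:
        raise DegenerateFitError("sphere fit: degenerate (non-positive radius^2)")
    return c, np.sqrt(r2)


def _fit_sphere(pts):
    c0 = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(c0, tol=1e-10 * max(np.abs(c0).max(), 1e-30)) < 2:
        raise DegenerateFitError("sphere fit: points are collinear")
    c, r = _sphere_algebraic(pts)

    def resid(x):
        return np.linalg.norm(pts - x[:3], axis=1) - x[3]

    sol = least_squares(resid, np.r_[c, r], method="lm")
    c, r = sol.x[:3], sol.x[3]
    return GeometricPrimitive("sphere", center=c, radius=float(abs(r)),
                              rms_residual=float(np.sqrt(np.mean(sol.fun ** 2))))


def _fit_cylinder(pts):
    c = pts.mean(axis=0)
    # seed: for points sampled on a cylinder wall, spread is largest along
    # the axis only for long cylinders; try all three covariance axes and
    # keep the best refined fit
    _, _, vt = np.linalg.svd(pts - c, full_matrices=False)
    best = None
    for seed_axis in vt:
        theta0 = np.arccos(np.clip(seed_axis[2], -1, 1))
        phi0 = np.arctan2(seed_axis[1], seed_axis[0])

        def resid(x):
            theta, phi, cx, cy, cz, r = x
            a = np.array([np.sin(theta) * np.cos(phi),
                          np.sin(theta) * np.sin(phi),
                          np.cos(theta)])
            d = pts - np.array([cx, cy, cz])
            radial = d - np.outer(d @ a, a)
            return np.linalg.norm(radial, axis=1) - r

        d0 = pts - c
        rad0 = d0 - np.outer(d0 @ seed_axis, seed_axis)
        r0 = float(np.mean(np.linalg.norm(rad0, axis=1)))
        try:
            sol = least_squares(resid, np.r_[theta0, phi0, c, max(r0, 1e-9)], method="lm")
        except Exception:
            continue
        rms = float(np.sqrt(np.mean(sol.fun ** 2)))
        if best is None or rms < best[0]:
            best = (rms, sol.x)
    if best is None:
        raise DegenerateFitError("cylinder fit failed from all seeds")
    rms, x = best
    theta, phi = x[0], x[1]
    axis = np.array([np.sin(theta) * np.cos(phi),
                     np.sin(theta) * np.sin(phi), np.cos(theta)])
    center = x[2:5]
    # canonical axis sign: positive sum of components, tie-break on z
    if axis.sum() < 0 or (abs(axis.sum()) < 1e-12 and axis[2] < 0):
        axis = -axis
    center = center - (center @ axis) * 0  # center is any point on the axis
    return GeometricPrimitive("cylinder", center=np.asarray(center), axis=axis,
                              radius=float(abs(x[5])), rms_residual=rms)


def _fit_ellipsoid(pts):
    # Algebraic fit: x^T A x + b^T x + c = 0 with trace normalisation.
    x, y, z = pts.T
    D = np.column_stack([x * x, y * y, z * z, 2 * x * y, 2 * x * z, 2 * y * z,
                         x, y, z, np.ones_like(x)])
    # minimise |D v| with |v| = 1 -> smallest right singular vector
    _, _, vt = np.linalg.svd(D, full_matrices=False)
    v = vt[-1]
    A = np.array([[v[0], v[3], v[4]],
                  [v[3], v[1], v[5]],
                  [v[4], v[5], v[2]]])
    b = v[6:9]
    c = v[9]
    try:
        center = np.linalg.solve(-2 * A, b)
    except np.linalg.LinAlgError as e:
        raise DegenerateFitError(f"ellipsoid fit: singular quadric ({e})")
    k = center @ A @ center - c
    evals, evecs = np.linalg.eigh(A / k)
    if np.any(evals <= 0):
        raise DegenerateFitError("ellipsoid fit: quadric is not an ellipsoid")
    radii = 1.0 / np.sqrt(evals)
    # residual: algebraic proxy -> normalised radial distance
    d = (pts - center) @ evecs / radii
    res = (np.linalg.norm(d, axis=1) - 1.0) * radii.mean()
    return GeometricPrimitive("ellipsoid", center=center, axis=evecs, radii=radii,
                              rms_residual=float(np.sqrt(np.mean(res ** 2))))


# ---------------------------------------------------------------------------
# Frames and joints
# ---------------------------------------------------------------------------

@dataclass
class FrameACS:
    """A right-handed orthonormal frame: origin plus x, y, z axis columns."""

    origin: np.ndarray
    axes: np.ndarray  # 3x3, columns x, y, z

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-9):
            raise ValueError("frame axes are not orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise ValueError("frame is left-handed")

    def as_matrix(self) -> np.ndarray:
        T = np.eye(4)
        T[:3, :3] = self.axes
        T[:3, 3] = self.origin
        return T


def _orthonormal_from_z(z, sagittal_hint):
    """Right-handed frame with the given z; x chosen as close as possible to
    the sagittal hint direction (projected off z)."""
    z = np.asarray(z, float)
    z = z / np.linalg.norm(z)
    hint = np.asarray(sagittal_hint, float)
    x = hint - (hint @ z) * z
    nx = np.linalg.norm(x)
    if nx < 1e-8:
        warnings.warn("sagittal hint parallel to hinge axis; using fallback x")
        fallback = np.array([1.0, 0, 0]) if abs(z[0]) < 0.9 else np.array([0, 1.0, 0])
        x = fallback - (fallback @ z) * z
        nx = np.linalg.norm(x)
    x = x / nx
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def build_jcs(parent_primitive: GeometricPrimitive,
              child_primitive: GeometricPrimitive,
              sagittal_hint=(1.0, 0.0, 0.0),
              mediolateral_hint=(0.0, 1.0, 0.0)) -> FrameACS:
    """Joint coordinate system from a pair of fitted primitives.

    Hinge-like joints (a cylinder on either side) put z along the cylinder
    axis with the origin at the fitted axis point; ball-and-socket pairs
    (sphere/sphere, e.g. head in acetabulum) put the origin at the *socket*
    (parent) sphere centre and orient z mediolaterally so that
    flexion/extension lies in the sagittal plane. Axis sign is canonicalised
    (flipping a fitted primitive's axis leaves the JCS unchanged).
    """
    kinds = (parent_primitive.kind, child_primitive.kind)
    if "cylinder" in kinds:
        cyl = parent_primitive if parent_primitive.kind == "cylinder" else child_primitive
        z = np.asarray(cyl.axis, float)
        if z @ np.asarray(mediolateral_hint, float) < 0:
            z = -z
        origin = np.asarray(cyl.center, float)
        axes = _orthonormal_from_z(z, sagittal_hint)
        return FrameACS(origin, axes)
    if kinds == ("sphere", "sphere") or "sphere" in kinds:
        socket = parent_primitive if parent_primitive.kind == "sphere" else child_primitive
        origin = np.asarray(socket.center, float)
        z = np.asarray(mediolateral_hint, float)
        axes = _orthonormal_from_z(z, sagittal_hint)
        return FrameACS(origin, axes)
    raise ValueError(f"unsupported primitive pairing: {kinds}")


DOF_NAMES = ("x", "y", "z")  # x = LAR, y = ab/adduction, z = flexion/extension


@dataclass
class JointSpec:
    """One joint: its JCS, allowed DOFs, per-axis anatomical sign labels,
    ROM limits in degrees, and the fixed z-y-x rotation order."""

    name: str
    parent_bone: str
    child_bone: str
    jcs: FrameACS
    dof_mask: tuple = ("z",)
    sign_convention: dict = field(default_factory=dict)  # axis -> (pos label, neg label)
    rom_limits: dict = field(default_factory=dict)  # axis -> (min_deg, max_deg)
    rotation_order: str = "zyx"

    def __post_init__(self):
        if not self.dof_mask:
            raise ValueError(f"joint {self.name}: empty dof_mask")
        for ax, (lo, hi) in self.rom_limits.items():
            if lo >= hi:
                raise ValueError(f"joint {self.name} {ax}: limits {lo} >= {hi}")


def _rot(axis: str, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def euler_zyx_matrix(angles) -> np.ndarray:
    """Rz(az) @ Ry(ay) @ Rx(ax) for angles = (ax, ay, az) in radians."""
    ax, ay, az = angles
    return _rot("z", az) @ _rot("y", ay) @ _rot("x", ax)


def euler_zyx_decompose(R: np.ndarray):
    """Recover (ax, ay, az) from Rz @ Ry @ Rx. Near gimbal lock (|ay| -> 90
    degrees) ay is clamped just inside and a warning is emitted."""
    sy = -R[2, 0]
    if abs(sy) >= 1.0 - 1e-9:
        warnings.warn("z-y-x decomposition near gimbal lock; clamping pitch")
        sy = np.clip(sy, -np.sin(np.deg2rad(89.999)), np.sin(np.deg2rad(89.999)))
    ay = np.arcsin(sy)
    ax = np.arctan2(R[2, 1], R[2, 2])
    az = np.arctan2(R[1, 0], R[0, 0])
    return np.array([ax, ay, az])


@dataclass
class Bone:
    name: str
    mesh: object = None  # trimesh.Trimesh or None for frame-only bones
    rest_transform: np.ndarray = field(default_factory=lambda: np.eye(4))
    articular_points: dict = field(default_factory=dict)  # joint name -> (n,3) points


class KinematicChain:
    """Bones linked by joints in a tree; the all-zeros pose is the reference
    ("parasagittally straight") pose and reproduces rest transforms exactly."""

    def __init__(self, bones, joints):
        self.bones = {b.name: b for b in bones}
        self.joints = {j.name: j for j in joints}
        self._children = {}
        self._parent_joint = {}
        for j in joints:
            if j.parent_bone not in self.bones or j.child_bone not in self.bones:
                raise ValueError(f"joint {j.name}: unknown bone")
            if j.child_bone in self._parent_joint:
                raise ValueError(f"bone {j.child_bone} has two parent joints")
            self._parent_joint[j.child_bone] = j
            self._children.setdefault(j.parent_bone, []).append(j)
        roots = [b for b in self.bones if b not in self._parent_joint]
        if len(roots) != 1:
            raise ValueError(f"chain must have exactly one root bone, got {roots}")
        self.root = roots[0]

    def joint_path(self, bone_name: str):
        """Joints from the root down to (and including) the bone's parent joint."""
        path = []
        b = bone_name
        while b in self._parent_joint:
            j = self._parent_joint[b]
            path.append(j)
            b = j.parent_bone
        return list(reversed(path))

    def descendants(self, bone_name: str):
        out = [bone_name]
        stack = [bone_name]
        while stack:
            for j in self._children.get(stack.pop(), []):
                out.append(j.child_bone)
                stack.append(j.child_bone)
        return out


def joint_delta(joint: JointSpec, angles_rad) -> np.ndarray:
    """World-space incremental transform of one posed joint:
    T_jcs @ Rz Ry Rx @ T_jcs^-1 (rotation about the JCS, expressed at rest)."""
    R = euler_zyx_matrix(angles_rad)
    T = joint.jcs.as_matrix()
    M = np.eye(4)
    M[:3, :3] = R
    return T @ M @ np.linalg.inv(T)


def pose(chain: KinematicChain, joint_angles: dict, check_rom: bool = True) -> dict:
    """Posed world transform per bone.

    ``joint_angles`` maps joint name -> (ax, ay, az) radians (missing joints
    are at 0). Deltas accumulate down the tree; the child's posed transform
    is the composition of every ancestor joint's delta applied to its rest
    transform. Raises when an angle lies outside the declared ROM unless
    ``check_rom`` is False.
    """
    if check_rom:
        bad = []
        for name, ang in joint_angles.items():
            j = chain.joints[name]
            for ax, val in zip(DOF_NAMES, ang):
                lim = j.rom_limits.get(ax)
                if lim is not None and not (np.deg2rad(lim[0]) - 1e-12 <= val <= np.deg2rad(lim[1]) + 1e-12):
                    bad.append((name, ax, np.rad2deg(val), lim))
                if abs(val) > 1e-12 and ax not in j.dof_mask:
                    bad.append((name, ax, np.rad2deg(val), "locked DOF"))
        if bad:
            raise ValueError(f"pose outside ROM: {bad}")
    out = {}
    for bone_name, bone in chain.bones.items():
        M = np.eye(4)
        for j in chain.joint_path(bone_name):
            ang = joint_angles.get(j.name, (0.0, 0.0, 0.0))
            if any(abs(a) > 0 for a in ang):
                M = M @ joint_delta(j, ang)
        out[bone_name] = M @ bone.rest_transform
    return out


def apply_cartilage_offset(chain: KinematicChain, segment_name: str,
                           fraction: float, reference_bone_length: float,
                           direction=None) -> KinematicChain:
    """Translate a segment and all its distal descendants distally by
    ``fraction * reference_bone_length`` to stand in for missing articular
    cartilage. ``direction`` defaults to the parent bone's long (local x)
    axis mapped through its rest transform; JCS origins of the moved joints
    move with their bones.
    """
    if not (0 <= fraction < 1):
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    if segment_name not in chain.bones:
        raise ValueError(f"unknown segment {segment_name!r}")
    if fraction == 0:
        return chain
    parent_joint = chain._parent_joint.get(segment_name)
    if direction is None:
        # distal = direction from the parent joint's JCS origin toward the
        # segment's rest origin
        if parent_joint is None:
            raise ValueError("root segment needs an explicit direction")
        seg_origin = chain.bones[segment_name].rest_transform[:3, 3]
        d = seg_origin - parent_joint.jcs.origin
        n = np.linalg.norm(d)
        direction = d / n if n > 1e-12 else np.array([0.0, 0.0, -1.0])
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    shift = fraction * reference_bone_length * direction
    moved = set(chain.descendants(segment_name))
    new_bones = []
    for name, b in chain.bones.items():
        T = b.rest_transform.copy()
        mesh = b.mesh
        if name in moved:
            T[:3, 3] = T[:3, 3] + shift
            if mesh is not None:
                mesh = mesh.copy()
                mesh.apply_translation(shift)
        new_bones.append(Bone(name, mesh, T,
                              {k: np.asarray(v) + (shift if name in moved else 0)
                               for k, v in b.articular_points.items()}))
    new_joints = []
    for j in chain.joints.values():
        jcs = j.jcs
        if j.child_bone in moved:
            jcs = FrameACS(jcs.origin + shift, jcs.axes)
        new_joints.append(JointSpec(j.name, j.parent_bone, j.child_bone, jcs,
                                    j.dof_mask, j.sign_convention, j.rom_limits,
                                    j.rotation_order))
    return KinematicChain(new_bones, new_joints)


# ---------------------------------------------------------------------------
# ROM scanning
# ---------------------------------------------------------------------------

def _points_in_mesh(mesh, points) -> np.ndarray:
    """Ray-cast containment test (vectorised Moller-Trumbore over all
    triangles; no spatial index needed at the mesh sizes used here)."""
    tri = mesh.triangles  # (m, 3, 3)
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1, e2 = v1 - v0, v2 - v0
    # irrational-ish direction to dodge edge/vertex grazing
    d = np.array([0.57735027, 0.51449576, 0.63339887])
    h = np.cross(d, e2)
    a = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(a) > 1e-14
    inside = np.zeros(len(points), dtype=bool)
    for i, p in enumerate(np.asarray(points, float)):
        s = p - v0
        u = np.einsum("ij,ij->i", s, h) / np.where(ok, a, 1.0)
        q = np.cross(s, e1)
        v = (q @ d) / np.where(ok, a, 1.0)
        t = np.einsum("ij,ij->i", e2, q) / np.where(ok, a, 1.0)
        hits = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 1e-12)
        inside[i] = hits.sum() % 2 == 1
    return inside


def _point_surface_distance(mesh, points) -> np.ndarray:
    """Distance from each point to the mesh surface (exact point-triangle
    distance, brute force over triangles)."""
    tri = mesh.triangles
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e0, e1 = v1 - v0, v2 - v0
    a = np.einsum("ij,ij->i", e0, e0)
    b = np.einsum("ij,ij->i", e0, e1)
    c = np.einsum("ij,ij->i", e1, e1)
    out = np.empty(len(points))
    for i, p in enumerate(np.asarray(points, float)):
        w = v0 - p
        d = np.einsum("ij,ij->i", e0, w)
        e = np.einsum("ij,ij->i", e1, w)
        # clamped barycentric minimisation (Eberly's algorithm, vectorised
        # via candidate projections)
        det = a * c - b * b
        s = np.clip((b * e - c * d) / np.where(det > 1e-30, det, 1.0), 0, 1)
        t = np.clip((b * d - a * e) / np.where(det > 1e-30, det, 1.0), 0, 1)
        cands = [(s, t)]
        # edge projections cover the clamped cases
        s0 = np.clip(-d / np.where(a > 1e-30, a, 1.0), 0, 1)
        cands.append((s0, np.zeros_like(s0)))
        t0 = np.clip(-e / np.where(c > 1e-30, c, 1.0), 0, 1)
        cands.append((np.zeros_like(t0), t0))
        s1 = np.clip((c + e - b - d) / np.where(a - 2 * b + c > 1e-30,
                                                a - 2 * b + c, 1.0), 0, 1)
        cands.append((s1, 1.0 - s1))
        best = np.full(len(tri), np.inf)
        for ss, tt in cands:
            valid = ss + tt <= 1.0 + 1e-12
            pt = v0 + ss[:, None] * e0 + tt[:, None] * e1
            dd = np.linalg.norm(pt - p, axis=1)
            best = np.where(valid, np.minimum(best, dd), best)
        out[i] = best.min()
    return out


def _penetration_depth(mesh_a, mesh_b) -> float:
    """Max depth of one watertight mesh's vertices inside the other (m)."""
    depth = 0.0
    for m, other in ((mesh_a, mesh_b), (mesh_b, mesh_a)):
        verts = other.vertices
        inside = _points_in_mesh(m, verts)
        if inside.any():
            depth = max(depth, float(_point_surface_distance(m, verts[inside]).max()))
    return depth


def _transformed(mesh, T):
    out = mesh.copy()
    out.apply_transform(T)
    return out


def rom_scan(chain: KinematicChain, joint_name: str, dof: str,
             step_deg: float = 5.0, collision_tol: float = 1e-4,
             disarticulation_tol: float = None,
             max_angle_deg: float = 180.0) -> tuple:
    """Sweep one DOF of one joint outward from 0 in +/- ``step_deg``
    increments until the bone meshes interpenetrate beyond ``collision_tol``
    or the articular point sets separate beyond ``disarticulation_tol``.

    Returns (min_deg, max_deg, total_deg). The default disarticulation
    tolerance is 150% of the rest articular gap. The paper's limits were set
    by eye; this scan is the package's automated proxy for that judgement.
    """
    joint = chain.joints[joint_name]
    if dof not in joint.dof_mask:
        raise ValueError(f"joint {joint_name} has no DOF {dof!r}")
    if collision_tol <= 0:
        raise ValueError("collision_tol must be positive")
    parent = chain.bones[joint.parent_bone]
    child = chain.bones[joint.child_bone]
    art_p = parent.articular_points.get(joint_name)
    art_c = child.articular_points.get(joint_name)

    def stats(angle_deg):
        ang = [0.0, 0.0, 0.0]
        ang[DOF_NAMES.index(dof)] = np.deg2rad(angle_deg)
        transforms = pose(chain, {joint_name: tuple(ang)}, check_rom=False)
        pen = gap = None
        if parent.mesh is not None and child.mesh is not None:
            pen = _penetration_depth(_transformed(parent.mesh, transforms[parent.name]),
                                     _transformed(child.mesh, transforms[child.name]))
        if art_p is not None and art_c is not None:
            Tp, Tc = transforms[parent.name] @ np.linalg.inv(parent.rest_transform), \
                     transforms[child.name] @ np.linalg.inv(child.rest_transform)
            pp = art_p @ Tp[:3, :3].T + Tp[:3, 3]
            pc = art_c @ Tc[:3, :3].T + Tc[:3, 3]
            gap = float(cKDTree(pp).query(pc)[0].min())
        return pen, gap

    pen0, gap0 = stats(0.0)
    if pen0 is not None and pen0 > collision_tol:
        raise ValueError(
            f"joint {joint_name}: bones already collide at 0 deg "
            f"(penetration {pen0:.2e} m) -- bad reference pose")
    if disarticulation_tol is None:
        disarticulation_tol = 1.5 * gap0 if gap0 else np.inf
    if disarticulation_tol <= 0:
        raise ValueError("disarticulation_tol must be positive")

    limits = []
    for sign in (-1.0, +1.0):
        last_ok = 0.0
        a = step_deg
        while a <= max_angle_deg + 1e-9:
            pen, gap = stats(sign * a)
            stop = (pen is not None and pen > collision_tol) or \
                   (gap is not None and gap > disarticulation_tol)
            if stop:
                break
            last_ok = sign * a
            a += step_deg
        limits.append(last_ok)
    lo, hi = limits
    return float(lo), float(hi), float(hi - lo)


def rom_table(chain: KinematicChain):
    """Per-joint, per-DOF min/max/total table from the limits stored on the
    chain's joints (scanned or configured). Returns a pandas DataFrame."""
    import pandas as pd

    rows = []
    for j in chain.joints.values():
        for ax in j.dof_mask:
            lim = j.rom_limits.get(ax)
            if lim is None:
                continue
            pos, neg = j.sign_convention.get(ax, ("+", "-"))
            rows.append({"joint": j.name, "dof": ax,
                         "positive_sense": pos, "negative_sense": neg,
                         "min_deg": lim[0], "max_deg": lim[1],
                         "total_deg": lim[1] - lim[0]})
    return pd.DataFrame(rows)
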