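"""Muscle paths, wrapping surfaces and tendon-excursion moment arms.

Muscles are modelled as single lines of action from origin to insertion,
optionally deflected by via points (fixed to bones) and by analytic
wrapping obstacles (cylinders and spheres, the classic obstacle-set
method). The moment arm about a joint degree of freedom is computed by
tendon excursion, MMA = -dL/d(theta), with a central finite difference;
on a frictionless path this equals the virtual-work moment arm exactly.

For cross-taxon comparison, moment arms are made dimensionless by dividing
by a reference bone length (femur for the hip, tibia for the knee,
metatarsal III for the ankle) and averaged over the joint's range of
motion on the scanning grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .joints import DOF_NAMES, KinematicChain, pose


class PathRoutingError(ValueError):
    pass


@dataclass
class WrapSurface:
    """An analytic wrapping obstacle fixed to a bone.

    ``frame`` is a 4x4 local transform in the bone's frame; the cylinder
    axis is the local z. ``active_side`` (+1/-1) selects which tangent
    family the path may take when it engages the surface -- side flips are
    a classic silent error, so the side is explicit and never auto-flipped.
    ``chord_index`` says which straight segment of the path (0 = the chord
    leaving the origin) the obstacle acts on.
    """

    kind: str  # "cylinder" | "sphere"
    bone: str
    frame: np.ndarray
    radius: float
    half_length: float = None  # cylinders only, informational  # type: ignore
    active_side: int = +1
    chord_index: int = 0
    name: str = ""

    def __post_init__(self):
        if self.kind not in ("cylinder", "sphere"):
            raise ValueError(f"unknown wrap kind {self.kind!r}")
        if self.radius <= 0:
            raise ValueError("wrap radius must be positive")
        self.frame = np.asarray(self.frame, dtype=float)


@dataclass
class MusclePath:
    """Ordered attachment points (origin, vias, insertion), each a
    (bone_name, local_xyz) pair, plus wrapping obstacles."""

    name: str
    points: list  # [(bone, (x, y, z)), ...] length >= 2
    wraps: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.points) < 2:
            raise ValueError(f"muscle {self.name}: needs >= 2 path points")


# ---------------------------------------------------------------------------
# Wrapping geometry
# ---------------------------------------------------------------------------

def _tangent_angles(p2, r, sigma):
    """Angle of the tangent point on the circle of radius r reached from the
    external 2D point p2, leaving in wrap direction sigma (+1 = CCW)."""
    d = np.linalg.norm(p2)
    alpha = np.arctan2(p2[1], p2[0])
    beta = np.arccos(np.clip(r / d, -1.0, 1.0))
    return alpha, beta


def _segment_circle_hit(p2, s2, r):
    """Does the 2D segment p2->s2 pass within radius r of the origin?"""
    d = s2 - p2
    L2 = d @ d
    if L2 == 0:
        return np.linalg.norm(p2) < r
    t = np.clip(-(p2 @ d) / L2, 0.0, 1.0)
    closest = p2 + t * d
    return np.linalg.norm(closest) < r


def cylinder_wrap_length(p_local, s_local, radius, sigma=+1):
    """Shortest path from p to s around an infinite cylinder of given
    radius about the local z axis (obstacle-set method).

    Returns (length, wrapped, waypoints_local). The geodesic on the cylinder
    is a helix; unrolling the cylinder makes the in-plane path length L2 and
    the axial drop dz combine as sqrt(L2^2 + dz^2) piecewise. If the
    projected chord misses the circle the chord itself is returned.
    """
    p = np.asarray(p_local, float)
    s = np.asarray(s_local, float)
    p2, s2 = p[:2], s[:2]
    rp, rs = np.linalg.norm(p2), np.linalg.norm(s2)
    if rp < radius - 1e-12 or rs < radius - 1e-12:
        raise PathRoutingError("path point lies inside wrapping cylinder")
    if not _segment_circle_hit(p2, s2, radius):
        return float(np.linalg.norm(s - p)), False, [p, s]
    a_p, b_p = _tangent_angles(p2, radius, sigma)
    a_s, b_s = _tangent_angles(s2, radius, sigma)
    # departing tangent point for traversal direction sigma (+1 = CCW):
    # touching at a_p + b_p continues counterclockwise, a_p - b_p clockwise
    th_q = a_p + sigma * b_p
    th_t = a_s - sigma * b_s   # arriving tangent point
    # signed arc in (-pi, pi]: non-positive means the tangent points have
    # inverted -- the path lifts off the surface on this side (continuity
    # at the graze limit); the chord is returned and, if it still cuts the
    # obstacle, the side mismatch is logged rather than auto-flipped
    arc = ((sigma * (th_t - th_q) + np.pi) % (2 * np.pi)) - np.pi
    if arc <= 1e-12:
        import warnings

        if _segment_circle_hit(p2, s2, radius * (1 - 1e-9)):
            warnings.warn("chord penetrates wrap surface but the active-side "
                          "tangents invert; returning chord (check active_side)")
        return float(np.linalg.norm(s - p)), False, [p, s]
    q2 = radius * np.array([np.cos(th_q), np.sin(th_q)])
    t2 = radius * np.array([np.cos(th_t), np.sin(th_t)])
    l1 = np.linalg.norm(q2 - p2)
    l2 = np.linalg.norm(s2 - t2)
    L2 = l1 + radius * arc + l2
    dz = s[2] - p[2]
    length = float(np.hypot(L2, dz))
    # axial positions of the tangent points follow the unrolled straight line
    zq = p[2] + dz * (l1 / L2) if L2 > 0 else p[2]
    zt = p[2] + dz * ((l1 + radius * arc) / L2) if L2 > 0 else s[2]
    q = np.array([q2[0], q2[1], zq])
    t = np.array([t2[0], t2[1], zt])
    return length, True, [p, q, t, s]


def sphere_wrap_length(p_local, s_local, radius):
    """Shortest path from p to s around a sphere at the local origin.

    The geodesic lies in the plane containing both points and the centre;
    within that plane this is the 2D circle-wrap problem, and the shorter
    of the two tangent families is taken.
    """
    p = np.asarray(p_local, float)
    s = np.asarray(s_local, float)
    rp, rs = np.linalg.norm(p), np.linalg.norm(s)
    if rp < radius - 1e-12 or rs < radius - 1e-12:
        raise PathRoutingError("path point lies inside wrapping sphere")
    if not _segment_circle_hit3(p, s, radius):
        return float(np.linalg.norm(s - p)), False, [p, s]
    n = np.cross(p, s)
    nn = np.linalg.norm(n)
    if nn < 1e-15:
        # p, s and centre collinear: any plane; pick one
        ref = np.array([1.0, 0, 0]) if abs(p[0]) < 0.9 * rp else np.array([0, 1.0, 0])
        n = np.cross(p, ref)
        nn = np.linalg.norm(n)
    n = n / nn
    u = p / rp
    v = np.cross(n, u)
    p2 = np.array([rp, 0.0])
    s2 = np.array([s @ u, s @ v])
    best = None
    for sigma in (+1, -1):
        a_p, b_p = _tangent_angles(p2, radius, sigma)
        a_s, b_s = _tangent_angles(s2, radius, sigma)
        th_q = a_p + sigma * b_p
        th_t = a_s - sigma * b_s
        arc = ((sigma * (th_t - th_q) + np.pi) % (2 * np.pi)) - np.pi
        if arc <= 1e-12:
            continue
        q2 = radius * np.array([np.cos(th_q), np.sin(th_q)])
        t2 = radius * np.array([np.cos(th_t), np.sin(th_t)])
        L = np.linalg.norm(q2 - p2) + radius * arc + np.linalg.norm(s2 - t2)
        if best is None or L < best[0]:
            q = q2[0] * u + q2[1] * v
            t = t2[0] * u + t2[1] * v
            best = (float(L), [p, q, t, s])
    if best is None:  # graze limit: tangents inverted on both sides
        return float(np.linalg.norm(s - p)), False, [p, s]
    return best[0], True, best[1]


def _segment_circle_hit3(p, s, r):
    d = s - p
    L2 = d @ d
    if L2 == 0:
        return np.linalg.norm(p) < r
    t = np.clip(-(p @ d) / L2, 0.0, 1.0)
    return np.linalg.norm(p + t * d) < r


# ---------------------------------------------------------------------------
# Path routing
# ---------------------------------------------------------------------------

def route_path(muscle: MusclePath, chain: KinematicChain,
               joint_angles: dict = None, check_rom: bool = False):
    """Route a muscle through the posed chain.

    Returns (length_m, polyline_world). Straight segments join consecutive
    attachment points; a wrap obstacle assigned to a chord replaces it by
    the tangent-geodesic-tangent path whenever the chord engages the
    obstacle on its active side.
    """
    transforms = pose(chain, joint_angles or {}, check_rom=check_rom)

    def world_point(bone, local):
        T = transforms[bone]
        local = np.asarray(local, float)
        return T[:3, :3] @ local + T[:3, 3]

    pts = [world_point(b, xyz) for b, xyz in muscle.points]
    wraps_by_chord = {}
    for w in muscle.wraps:
        wraps_by_chord.setdefault(w.chord_index, []).append(w)

    total = 0.0
    polyline = [pts[0]]
    for i in range(len(pts) - 1):
        p, s = pts[i], pts[i + 1]
        wraps = wraps_by_chord.get(i, [])
        if not wraps:
            total += float(np.linalg.norm(s - p))
            polyline.append(s)
            continue
        if len(wraps) > 1:
            raise PathRoutingError(
                f"muscle {muscle.name}: multiple wraps on one chord unsupported")
        w = wraps[0]
        Tw = transforms[w.bone] @ w.frame
        Rw, tw = Tw[:3, :3], Tw[:3, 3]
        p_l = Rw.T @ (p - tw)
        s_l = Rw.T @ (s - tw)
        try:
            if w.kind == "cylinder":
                L, wrapped, way = cylinder_wrap_length(p_l, s_l, w.radius, w.active_side)
            else:
                L, wrapped, way = sphere_wrap_length(p_l, s_l, w.radius)
        except PathRoutingError as e:
            raise PathRoutingError(f"muscle {muscle.name}, wrap {w.name or w.kind}: {e}")
        total += L
        for wp in way[1:]:
            polyline.append(Rw @ wp + tw)
    return float(total), polyline


def path_length(muscle, chain, joint_angles=None):
    return route_path(muscle, chain, joint_angles)[0]


# ---------------------------------------------------------------------------
# Moment arms
# ---------------------------------------------------------------------------

def moment_arm(muscle: MusclePath, chain: KinematicChain, joint_name: str,
               dof: str, angle_rad: float, h_deg: float = 0.25,
               base_angles: dict = None, sign: float = 1.0) -> float:
    """Tendon-excursion moment arm, -dL/d(theta), at one joint angle.

    Central finite difference with half-width ``h_deg`` (degrees; theta in
    radians in the derivative). ``sign`` maps the raw geometric value onto
    the joint's anatomical convention (e.g. +1 if positive angle =
    extension and extensor moment arms are to be reported positive).
    """
    h = np.deg2rad(h_deg)
    idx = DOF_NAMES.index(dof)

    def L(theta):
        angles = {k: list(v) for k, v in (base_angles or {}).items()}
        a = angles.setdefault(joint_name, [0.0, 0.0, 0.0])
        a[idx] = theta
        try:
            return path_length(muscle, chain, {k: tuple(v) for k, v in angles.items()})
        except PathRoutingError as e:
            raise PathRoutingError(
                f"{muscle.name} at {joint_name}/{dof} = "
                f"{np.rad2deg(theta):.2f} deg: {e}")

    return float(sign * -(L(angle_rad + h) - L(angle_rad - h)) / (2 * h))


@dataclass
class MomentArmCurve:
    muscle: str
    joint: str
    dof: str
    angles_deg: np.ndarray
    moment_arms: np.ndarray  # metres

    def mean(self) -> float:
        return float(np.mean(self.moment_arms))


def mma_curve(muscle: MusclePath, chain: KinematicChain, joint_name: str,
              dof: str, grid_step_deg: float = 5.0, sign: float = 1.0,
              base_angles: dict = None) -> MomentArmCurve:
    """Moment-arm curve on an inclusive grid across the joint's declared ROM."""
    joint = chain.joints[joint_name]
    lim = joint.rom_limits.get(dof)
    if lim is None:
        raise ValueError(f"joint {joint_name} has no ROM limits for DOF {dof!r}")
    lo, hi = lim
    n = int(round((hi - lo) / grid_step_deg))
    grid = np.linspace(lo, hi, n + 1)
    arms = np.array([
        moment_arm(muscle, chain, joint_name, dof, np.deg2rad(a),
                   base_angles=base_angles, sign=sign)
        for a in grid
    ])
    return MomentArmCurve(muscle.name, joint_name, dof, grid, arms)


def mean_dimensionless_mma(curve: MomentArmCurve, bone_length: float) -> float:
    """Unweighted grid mean of the curve, divided by the normalising bone
    length (femur / tibia / metatarsal III depending on the joint)."""
    if bone_length <= 0:
        raise ValueError("bone_length must be positive")
    if len(curve.moment_arms) == 0:
        raise ValueError("empty moment-arm curve")
    return curve.mean() / bone_length


def mma_report(chain: KinematicChain, muscles: list, joint_dofs: list,
               normalizing_lengths: dict, groups: dict = None,
               grid_step_deg: float = 5.0, signs: dict = None):
    """Mean dimensionless moment arms, one row per muscle x (joint, dof).

    ``joint_dofs``: [(joint_name, dof), ...]; ``normalizing_lengths``:
    joint_name -> bone length (m); ``groups``: muscle -> "uniarticular" /
    "biarticular" label for Table-style grouping; ``signs``: (joint, dof) ->
    +1/-1 anatomical sign factor.
    """
    import pandas as pd

    rows = []
    for m in muscles:
        for joint_name, dof in joint_dofs:
            if joint_name not in normalizing_lengths:
                raise ValueError(f"no normalizing length for joint {joint_name!r}")
            sign = (signs or {}).get((joint_name, dof), 1.0)
            curve = mma_curve(m, chain, joint_name, dof, grid_step_deg, sign=sign)
            rows.append({
                "muscle": m.name,
                "group": (groups or {}).get(m.name, ""),
                "joint": joint_name,
                "dof": dof,
                "mean_mma_m": curve.mean(),
                "mean_dimensionless_mma": mean_dimensionless_mma(
                    curve, normalizing_lengths[joint_name]),
            })
    return pd.DataFrame(rows)
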