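"""Body-segment parameter (BSP) engine.

Mass, centre of mass and inertia of watertight triangle meshes; composite
segments with zero-density air cavities; octagonal-hoop lofting and inflation
of "fleshed-out" segment shapes; regression-based reconstruction of an
incompletely preserved caudal vertebral series; and whole-body summaries
(total mass, COM position relative to the hips, per-segment mass fractions).

All lengths are metres, masses kilograms, densities kg m^-3. The default
tissue density is 1060 kg m^-3; air cavities (pharynx, trachea, lungs)
subtract volume at zero density, lowering a segment's *net* density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

DEFAULT_TISSUE_DENSITY = 1060.0  # kg m^-3, vertebrate soft-tissue bulk density


class MeshError(ValueError):
    """Raised for non-watertight or degenerate input meshes."""


@dataclass
class MassProperties:
    """Mass properties of a (possibly composite) solid.

    ``inertia`` is about the centre of mass; ``inertia_origin`` about the
    world origin (parallel-axis transfer). Both are symmetric 3x3 tensors in
    kg m^2.
    """

    mass: float
    com: np.ndarray
    inertia: np.ndarray
    volume: float
    inertia_origin: np.ndarray = None  # type: ignore[assignment]
    net_density: float = None  # type: ignore[assignment]

    def __post_init__(self):
        self.com = np.asarray(self.com, dtype=float)
        self.inertia = np.asarray(self.inertia, dtype=float)
        if self.inertia_origin is None:
            self.inertia_origin = _parallel_axis(self.inertia, self.mass, self.com)
        if self.net_density is None and self.volume > 0:
            self.net_density = self.mass / self.volume


def _parallel_axis(inertia_com: np.ndarray, mass: float, com: np.ndarray) -> np.ndarray:
    c = np.asarray(com, float)
    d2 = c @ c
    return inertia_com + mass * (d2 * np.eye(3) - np.outer(c, c))


def ensure_watertight(mesh: trimesh.Trimesh, repair: bool = True) -> trimesh.Trimesh:
    """Validate (and lightly repair) a mesh for volumetric integration.

    Checks edge-manifoldness/closedness; repairs winding consistency and
    flips orientation if the signed volume is negative. Raises
    :class:`MeshError` naming the open edges when the surface is not closed.
    """
    mesh = mesh.copy()
    if len(mesh.faces) == 0 or mesh.area == 0:
        raise MeshError("degenerate mesh: no faces or zero surface area")
    if repair:
        trimesh.repair.fix_winding(mesh)
    if not mesh.is_watertight:
        boundary = mesh.edges[trimesh.grouping.group_rows(mesh.edges_sorted, require_count=1)]
        raise MeshError(
            f"mesh is not watertight: {len(boundary)} open edge(s), "
            f"e.g. {boundary[:5].tolist()}"
        )
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def mesh_mass_properties(
    mesh: trimesh.Trimesh, density: float = DEFAULT_TISSUE_DENSITY
) -> MassProperties:
    """Exact mass properties of a watertight mesh by divergence-theorem
    integration over its triangles (signed-tetrahedron accumulation).

    Orientation is auto-repaired so that volume is positive.
    """
    if density <= 0:
        raise ValueError(f"density must be positive, got {density}")
    mesh = ensure_watertight(mesh)
    mesh.density = density
    # trimesh's moment_inertia is about the centre of mass, world-aligned
    inertia_com = mesh.moment_inertia
    return MassProperties(
        mass=float(mesh.mass),
        com=np.array(mesh.center_mass, float),
        inertia=np.array(inertia_com, float),
        volume=float(mesh.volume),
        net_density=density,
    )


@dataclass
class BodySegment:
    """A named body segment: a solid outer shape, optional zero-density
    cavities carved out of it, and a base tissue density."""

    name: str
    solid: trimesh.Trimesh
    cavities: list = field(default_factory=list)
    density: float = DEFAULT_TISSUE_DENSITY


def composite_segment_properties(segment: BodySegment) -> MassProperties:
    """Mass properties of a segment with zero-density cavities subtracted.

    mass = rho * (V_solid - sum V_cavity); the COM is the signed
    volume-weighted combination (cavities enter with negative mass). The
    reported ``net_density`` = mass / V_solid is what the air spaces reduce
    the bulk density to.
    """
    solid = mesh_mass_properties(segment.solid, segment.density)
    cavs = [mesh_mass_properties(c, segment.density) for c in segment.cavities]
    v_cav = sum(c.volume for c in cavs)
    if v_cav >= solid.volume:
        raise ValueError(
            f"segment {segment.name!r}: cavity volume {v_cav:.3e} >= "
            f"solid volume {solid.volume:.3e}"
        )
    mass = segment.density * (solid.volume - v_cav)
    moment = segment.density * solid.volume * solid.com
    inertia = solid.inertia_origin.copy()
    for c in cavs:
        moment -= segment.density * c.volume * c.com
        inertia -= c.inertia_origin
    com = moment / mass
    inertia_com = inertia - _parallel_axis(np.zeros((3, 3)), mass, com)
    return MassProperties(
        mass=float(mass),
        com=com,
        inertia=inertia_com,
        volume=float(solid.volume - v_cav),
        inertia_origin=inertia,
        net_density=float(mass / solid.volume),
    )


# ---------------------------------------------------------------------------
# Octagonal hoops and lofting
# ---------------------------------------------------------------------------

@dataclass
class HoopStack:
    """An ordered stack of octagonal cross-sections along a segment's long
    axis, to be lofted into a watertight segment shape."""

    hoops: np.ndarray  # (n_hoops, 8, 3)
    segment_name: str = ""
    inflation_multipliers: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.hoops = np.asarray(self.hoops, dtype=float)
        if self.hoops.ndim != 3 or self.hoops.shape[1] != 8 or self.hoops.shape[2] != 3:
            raise ValueError(f"hoops must have shape (n, 8, 3), got {self.hoops.shape}")
        if self.inflation_multipliers is None:
            self.inflation_multipliers = np.ones(len(self.hoops))
        else:
            self.inflation_multipliers = np.broadcast_to(
                np.asarray(self.inflation_multipliers, float), (len(self.hoops),)
            ).copy()

    @property
    def n_hoops(self) -> int:
        return len(self.hoops)


def regular_octagon(circumradius: float, center, normal=(0, 0, 1), phase: float = 0.0) -> np.ndarray:
    """Vertices of a regular octagon of given circumradius in the plane
    through ``center`` with the given ``normal``."""
    center = np.asarray(center, float)
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    # build an in-plane orthonormal basis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    ang = phase + np.arange(8) * (2 * np.pi / 8)
    return center + circumradius * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))


def inflate_hoops(stack: HoopStack, multipliers) -> HoopStack:
    """Scale each octagon about its own centroid, in its own plane.

    ``multipliers`` is a scalar or one value per hoop; centroids are
    unchanged, so the segment's skeleton-fitted midline is preserved while
    the cross-sections grow to represent missing soft tissue.
    """
    mult = np.broadcast_to(np.asarray(multipliers, float), (stack.n_hoops,))
    if np.any(mult <= 0):
        raise ValueError(f"multipliers must be positive, got {mult}")
    out = stack.hoops.copy()
    for i, k in enumerate(mult):
        c = out[i].mean(axis=0)
        out[i] = c + k * (out[i] - c)
    return HoopStack(out, stack.segment_name, mult * stack.inflation_multipliers)


def loft_hoops(stack: HoopStack, cap_ends: bool = True) -> trimesh.Trimesh:
    """Loft a hoop stack into a watertight triangle mesh.

    Octagon vertex i of each hoop joins vertex i of the next (no twist
    minimisation); each quad strip is split into two triangles and the end
    octagons are fan-triangulated about their centroids. A warning is issued
    when consecutive hoops cross (self-intersecting loft).
    """
    n = stack.n_hoops
    if n < 2:
        raise ValueError(f"need at least 2 hoops to loft, got {n}")
    verts = [stack.hoops.reshape(-1, 3)]
    faces = []
    for i in range(n - 1):
        a, b = 8 * i, 8 * (i + 1)
        for j in range(8):
            j2 = (j + 1) % 8
            # outward winding for counter-clockwise octagons stacked along +axis
            faces.append([a + j, b + j, b + j2])
            faces.append([a + j, b + j2, a + j2])
    nv = 8 * n
    if cap_ends:
        c0 = stack.hoops[0].mean(axis=0)
        c1 = stack.hoops[-1].mean(axis=0)
        verts.append(c0[None, :])
        verts.append(c1[None, :])
        i0, i1 = nv, nv + 1
        for j in range(8):
            j2 = (j + 1) % 8
            faces.append([i0, j2, j])                       # start cap faces backwards
            faces.append([i1, 8 * (n - 1) + j, 8 * (n - 1) + j2])  # end cap
    mesh = trimesh.Trimesh(
        vertices=np.vstack(verts), faces=np.asarray(faces), process=False
    )
    trimesh.repair.fix_winding(mesh)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


# ---------------------------------------------------------------------------
# Caudal series reconstruction
# ---------------------------------------------------------------------------

@dataclass
class CaudalSeriesSpec:
    """Measured caudal vertebral dimensions and reconstruction settings.

    ``measured`` is a sequence of (vertebra_number, length_m, height_m).
    Missing vertebrae up to ``n_total`` are predicted from ordinary
    least-squares regressions of length and height on vertebral number;
    axial gaps of ``gap_fraction`` x length stand in for intervertebral
    soft tissue.
    """

    measured: np.ndarray
    n_total: int = 30
    gap_fraction: float = 0.10

    def __post_init__(self):
        self.measured = np.asarray(self.measured, dtype=float)
        nums = self.measured[:, 0]
        if len(np.unique(nums)) != len(nums):
            raise ValueError("measured vertebra numbers must be unique")
        if self.n_total < nums.max():
            raise ValueError("n_total must be >= the largest measured number")


@dataclass
class CaudalSeriesResult:
    segments: list  # (number, length, radius, axial_start) tuples
    length_fit: tuple  # (slope, intercept, r2)
    height_fit: tuple
    total_extent: float


def _ols_line(x, y):
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = np.sum((y - pred) ** 2)
    ss_tot = np.sum((y - np.mean(y)) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), float(r2)


def reconstruct_caudal_series(spec: CaudalSeriesSpec) -> CaudalSeriesResult:
    """Predict the full caudal series from the preserved vertebrae.

    Returns cylinder segments for vertebrae 1..n_total: measured dimensions
    where preserved, OLS predictions elsewhere. Cylinder radius = height / 2
    (vertebral "height" is the dorsoventral extent, taken as the cylinder
    diameter). Negative predictions are clamped to the smallest measured
    value with a warning.
    """
    import warnings

    m = spec.measured
    if len(m) < 3:
        raise ValueError(f"need >= 3 measured vertebrae, got {len(m)}")
    nums, lengths, heights = m[:, 0], m[:, 1], m[:, 2]
    lfit = _ols_line(nums, lengths)
    hfit = _ols_line(nums, heights)
    measured_map = {int(n): (l, h) for n, l, h in m}
    segments = []
    x = 0.0
    for n in range(1, spec.n_total + 1):
        if n in measured_map:
            length, height = measured_map[n]
        else:
            length = lfit[0] * n + lfit[1]
            height = hfit[0] * n + hfit[1]
            if length <= 0:
                warnings.warn(f"predicted length for vertebra {n} non-positive; clamped")
                length = float(lengths.min())
            if height <= 0:
                warnings.warn(f"predicted height for vertebra {n} non-positive; clamped")
                height = float(heights.min())
        segments.append((n, float(length), float(height) / 2.0, x))
        x += length * (1.0 + spec.gap_fraction)
    total_extent = x - segments[-1][1] * spec.gap_fraction  # no trailing gap
    return CaudalSeriesResult(segments, lfit, hfit, float(total_extent))


# ---------------------------------------------------------------------------
# Whole-body model
# ---------------------------------------------------------------------------

def scale_mesh(mesh: trimesh.Trimesh, factor: float) -> trimesh.Trimesh:
    """Uniform scaling about the origin; volume scales by factor cubed."""
    if factor <= 0:
        raise ValueError(f"scale factor must be positive, got {factor}")
    out = mesh.copy()
    out.apply_scale(factor)
    return out


@dataclass
class BodyModel:
    """Named body segments plus the landmarks needed to judge bipedal
    potential: the hip midpoint, femur length and craniocaudal axis (a unit
    vector pointing cranially, conventionally defined by the sacrum)."""

    segments: list  # of BodySegment
    hip_midpoint: np.ndarray
    femur_length: float
    craniocaudal_axis: np.ndarray = (1.0, 0.0, 0.0)

    def __post_init__(self):
        self.hip_midpoint = np.asarray(self.hip_midpoint, dtype=float)
        ax = np.asarray(self.craniocaudal_axis, dtype=float)
        self.craniocaudal_axis = ax / np.linalg.norm(ax)


@dataclass
class WholeBodySummary:
    total_mass: float
    com: np.ndarray
    mass_fractions: dict
    com_cranial_offset: float
    bipedality_ratio: float  # offset / femur_length
    segment_properties: dict


def whole_body_summary(model: BodyModel) -> WholeBodySummary:
    """Total mass, whole-body COM, per-segment mass fractions, and the COM's
    cranial offset from the hips (absolute, and as a fraction of femur
    length -- the static-bipedalism yardstick)."""
    if not model.segments:
        raise ValueError("model has no segments")
    if model.femur_length <= 0:
        raise ValueError("femur_length must be positive")
    props = {s.name: composite_segment_properties(s) for s in model.segments}
    total = sum(p.mass for p in props.values())
    if total <= 0:
        raise ValueError("zero total mass")
    com = sum(p.mass * p.com for p in props.values()) / total
    fractions = {name: p.mass / total for name, p in props.items()}
    offset = float((com - model.hip_midpoint) @ model.craniocaudal_axis)
    return WholeBodySummary(
        total_mass=float(total),
        com=com,
        mass_fractions=fractions,
        com_cranial_offset=offset,
        bipedality_ratio=offset / model.femur_length,
        segment_properties=props,
    )
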