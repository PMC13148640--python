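"""Synthetic fixtures with closed-form or brute-force oracle answers.

Everything the pipeline consumes can be generated here at desk scale, with
the correct answer carried alongside: primitive-solid body segments
(octagonal-prism lofts with closed-form volumes and centroids), a small
jointed hindlimb chain with known axes, muscles whose moment arms are known
analytically, random trees and character matrices whose parsimony solutions
are recomputed by exhaustive enumeration, and two-class Gaussian
morphometric datasets with stated means and covariances.

Scale matches a roughly 1-kg, 0.3-m-torso animal (segment lengths of order
0.05-0.3 m) so tolerances carry over to real fossil-model workflows. All
randomness flows from a single integer seed; same seed, same bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .joints import Bone, FrameACS, JointSpec, KinematicChain
from .mesh_body import (BodyModel, BodySegment, HoopStack, loft_hoops,
                        regular_octagon)
from .muscles import MusclePath, WrapSurface

OCTAGON_AREA_FACTOR = 2.0 * np.sqrt(2.0)  # area of a regular octagon = 2*sqrt(2)*R^2


@dataclass
class ToyTaxonSpec:
    """Parameters of the synthetic taxon. Defaults emulate a small
    quadrupedal pseudosuchian: ~1 kg, 0.08 m femur, 1060 kg/m^3 tissue with
    air cavities in the head-neck and trunk."""

    seed: int = 0
    density: float = 1060.0
    femur_length: float = 0.080
    # axial segments: name -> (x_start, x_end, octagon circumradius, cavity fraction)
    axial_segments: dict = field(default_factory=lambda: {
        "head_neck": (0.18, 0.30, 0.024, 0.0547),
        "trunk": (0.06, 0.18, 0.038, 0.08),
        "body": (-0.02, 0.06, 0.038, 0.0),
        "proximal_tail": (-0.14, -0.02, 0.024, 0.0),
        "distal_tail": (-0.34, -0.14, 0.016, 0.0),
    })
    # limb segments hang from the hip at x=0: name -> (z_top, z_bottom, radius)
    limb_segments: dict = field(default_factory=lambda: {
        "thigh": (0.0, -0.080, 0.020),
        "crus": (-0.080, -0.148, 0.012),
        "pes": (-0.148, -0.178, 0.009),
    })
    hip_midpoint: tuple = (0.0, 0.0, 0.0)
    rom_limits: dict = field(default_factory=lambda: {
        "hip": {"z": (-65.0, 65.0), "y": (-10.0, 90.0), "x": (-60.0, 60.0)},
        "knee": {"z": (-130.0, 0.0)},
        "ankle": {"z": (-40.0, 60.0)},
        "mtp3": {"z": (-50.0, 115.0)},
    })
    # morphometric classes: 3-sigma separation, 40 per class
    class_separation_sigma: float = 3.0
    n_per_class: int = 40


def _prism_stack(x0, x1, radius, axis="x", n_hoops=2, center_yz=(0.0, 0.0)):
    """A hoop stack for a straight regular-octagonal prism along one axis."""
    ts = np.linspace(x0, x1, n_hoops)
    hoops = []
    for t in ts:
        if axis == "x":
            center = (t, center_yz[0], center_yz[1])
            normal = (1, 0, 0)
        else:
            center = (center_yz[0], center_yz[1], t)
            normal = (0, 0, 1)
        hoops.append(regular_octagon(radius, center, normal))
    return HoopStack(np.array(hoops))


def octagonal_prism_volume(radius: float, length: float) -> float:
    """Closed-form volume of a regular-octagonal prism of given
    circumradius and length."""
    return OCTAGON_AREA_FACTOR * radius ** 2 * abs(length)


def make_toy_skeleton(spec: ToyTaxonSpec = None):
    """Build the toy body model and hindlimb chain.

    Returns (BodyModel, KinematicChain, oracle) where ``oracle`` holds the
    closed-form masses, volumes and COM coordinates of every segment plus
    whole-body totals, for use as an independent check on the mesh
    integrals.
    """
    spec = spec or ToyTaxonSpec()
    segments = []
    oracle = {"segments": {}}
    total_mass = 0.0
    moment = np.zeros(3)
    for name, (x0, x1, radius, cav_frac) in spec.axial_segments.items():
        solid = loft_hoops(_prism_stack(x0, x1, radius, axis="x"))
        cavities = []
        v = octagonal_prism_volume(radius, x1 - x0)
        if cav_frac > 0:
            # a coaxial prism with the same length and scaled radius
            r_c = radius * np.sqrt(cav_frac)
            cavities = [loft_hoops(_prism_stack(x0, x1, r_c, axis="x"))]
        segments.append(BodySegment(name, solid, cavities, spec.density))
        mass = spec.density * v * (1.0 - cav_frac)
        com = np.array([(x0 + x1) / 2.0, 0.0, 0.0])
        oracle["segments"][name] = {
            "volume": v * (1.0 - cav_frac), "mass": mass, "com": com,
            "net_density": spec.density * (1.0 - cav_frac),
        }
        total_mass += mass
        moment += mass * com
    for name, (z0, z1, radius) in spec.limb_segments.items():
        solid = loft_hoops(_prism_stack(z0, z1, radius, axis="z"))
        segments.append(BodySegment(name, solid, [], spec.density))
        v = octagonal_prism_volume(radius, z1 - z0)
        mass = spec.density * v
        com = np.array([0.0, 0.0, (z0 + z1) / 2.0])
        oracle["segments"][name] = {"volume": v, "mass": mass, "com": com,
                                    "net_density": spec.density}
        total_mass += mass
        moment += mass * com
    oracle["total_mass"] = total_mass
    oracle["com"] = moment / total_mass
    model = BodyModel(segments, spec.hip_midpoint, spec.femur_length,
                      craniocaudal_axis=(1.0, 0.0, 0.0))
    chain = make_toy_chain(spec)
    return model, chain, oracle


def make_toy_chain(spec: ToyTaxonSpec = None) -> KinematicChain:
    """A hindlimb chain: pelvis -> femur -> crus -> pes -> toe.

    World axes: x cranial, y left-lateral, z up; the limb hangs straight
    down (reference pose). Every flexion/extension axis (JCS z) points
    along +y, so positive z-rotations swing segments cranially in the
    sagittal plane. Sign conventions follow the packaged convention table
    (positive = extension at hip/ankle/MTP3, knee positive = extension,
    capped at 0).
    """
    spec = spec or ToyTaxonSpec()
    fl = spec.femur_length
    z_knee = -fl
    z_ankle = spec.limb_segments["crus"][1]
    z_mtp = spec.limb_segments["pes"][1]
    # JCS: x cranial, z mediolateral (world +y) so Rz = sagittal swing
    axes = np.column_stack([np.array([1.0, 0, 0]), np.cross((0, 1.0, 0), (1.0, 0, 0)), (0, 1.0, 0)])

    def frame(origin):
        return FrameACS(np.asarray(origin, float), axes)

    sign_limb = {"z": ("extension", "flexion"), "y": ("abduction", "adduction"),
                 "x": ("external LAR", "internal LAR")}
    bones = [
        Bone("pelvis"),
        Bone("femur", rest_transform=_translate((0, 0, 0))),
        Bone("crus", rest_transform=_translate((0, 0, z_knee))),
        Bone("pes", rest_transform=_translate((0, 0, z_ankle))),
        Bone("toe", rest_transform=_translate((0, 0, z_mtp))),
    ]
    joints = [
        JointSpec("hip", "pelvis", "femur", frame((0, 0, 0)),
                  dof_mask=("x", "y", "z"), sign_convention=sign_limb,
                  rom_limits=spec.rom_limits["hip"]),
        JointSpec("knee", "femur", "crus", frame((0, 0, z_knee)),
                  dof_mask=("z",),
                  sign_convention={"z": ("extension", "flexion")},
                  rom_limits=spec.rom_limits["knee"]),
        JointSpec("ankle", "crus", "pes", frame((0, 0, z_ankle)),
                  dof_mask=("z",),
                  sign_convention={"z": ("extension", "flexion")},
                  rom_limits=spec.rom_limits["ankle"]),
        JointSpec("mtp3", "pes", "toe", frame((0, 0, z_mtp)),
                  dof_mask=("z",),
                  sign_convention={"z": ("dorsiflexion", "plantarflexion")},
                  rom_limits=spec.rom_limits["mtp3"]),
    ]
    return KinematicChain(bones, joints)


def _translate(xyz):
    T = np.eye(4)
    T[:3, 3] = xyz
    return T


def make_toy_muscles(spec: ToyTaxonSpec = None):
    """Muscles with analytically known moment arms.

    Returns (muscles, registry); ``registry[name]`` holds the joint, DOF
    and the exact moment-arm magnitude at the reference pose (or, for the
    coaxial wrap, throughout the wrapped range).
    """
    spec = spec or ToyTaxonSpec()
    fl = spec.femur_length
    z_knee = -fl
    d = 0.020  # hip strap's perpendicular distance from the hip axis
    r_wrap = 0.015  # coaxial knee wrap radius
    muscles = [
        # straight strap crossing the hip axis at perpendicular distance d
        # (caudal to the joint: an extensor-like lever)
        MusclePath("hip_extensor_strap",
                   [("pelvis", (-d, 0.0, 0.05)), ("femur", (-d, 0.0, -0.05))]),
        # path wrapped on a cylinder coaxial with the knee axis: the moment
        # arm equals the wrap radius while the wrap is engaged
        MusclePath("knee_coaxial_wrap",
                   [("femur", (-0.04, 0.0, z_knee + 0.05)),
                    ("crus", (0.04, 0.0, -0.05))],  # crus-local: 0.05 below the knee
                   wraps=[WrapSurface("cylinder", "femur",
                                      _cyl_frame_at((0, 0, z_knee)),
                                      radius=r_wrap, active_side=-1,
                                      name="knee_wrap")]),
        # line parallel to the hip axis: zero moment arm about it
        MusclePath("axis_parallel_line",
                   [("pelvis", (0.03, -0.02, 0.0)), ("femur", (0.03, 0.02, 0.0))]),
        # abductor deflected by a sphere at the hip (qualitative fixture)
        MusclePath("hip_sphere_abductor",
                   [("pelvis", (0.0, 0.0, 0.035)), ("femur", (0.0, 0.0, -0.05))],
                   wraps=[WrapSurface("sphere", "pelvis", np.eye(4),
                                      radius=0.018, name="hip_wrap")]),
    ]
    registry = {
        "hip_extensor_strap": {"joint": "hip", "dof": "z", "mma_abs": d},
        "knee_coaxial_wrap": {"joint": "knee", "dof": "z", "mma_abs": r_wrap},
        "axis_parallel_line": {"joint": "hip", "dof": "z", "mma_abs": 0.0},
    }
    return muscles, registry


def _cyl_frame_at(origin):
    # cylinder local z must align with the hinge axis (world +y)
    T = np.eye(4)
    T[:3, :3] = np.column_stack([(1, 0, 0), (0, 0, -1), (0, 1, 0)])
    T[:3, 3] = origin
    return T


# ---------------------------------------------------------------------------
# Trees and character matrices
# ---------------------------------------------------------------------------

def make_toy_characters(seed: int = 7, n_tips: int = 6, n_chars: int = 20,
                        n_states: int = 3, p_missing: float = 0.05):
    """A random rooted bifurcating tree plus a character matrix, with the
    exhaustive-enumeration parsimony solution stored alongside.

    Returns (tree, matrix, oracle) where oracle[char_index] =
    {"min_changes": int, "root_states": frozenset}.
    """
    from .epb import CharacterMatrix, brute_force_min_changes

    if n_tips > 8:
        raise ValueError("brute-force oracle limited to <= 8 tips")
    rng = np.random.default_rng(seed)
    labels = [f"T{i + 1}" for i in range(n_tips)]
    newick = _random_topology(labels, rng)
    tree = dendropy.Tree.get(data=newick, schema="newick")
    cells = {}
    for t in labels:
        row = []
        for _ in range(n_chars):
            if rng.random() < p_missing:
                row.append("?")
            else:
                row.append(str(int(rng.integers(0, n_states))))
        cells[t] = row
    matrix = CharacterMatrix(cells, n_chars=n_chars)
    oracle = {}
    for ci in range(n_chars):
        observed = matrix.states_for(ci)
        if not observed:
            continue
        tip_sets = {t: matrix.cell_state_set(t, ci, observed) for t in labels}
        best, mpr = brute_force_min_changes(tree, tip_sets, observed)
        oracle[ci] = {"min_changes": best,
                      "root_states": mpr[id(tree.seed_node)]}
    return tree, matrix, oracle


def _random_topology(labels, rng) -> str:
    nodes = list(labels)
    nodes = [str(n) for n in nodes]
    order = rng.permutation(len(nodes))
    nodes = [nodes[i] for i in order]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0] + ";"


# ---------------------------------------------------------------------------
# Morphometrics
# ---------------------------------------------------------------------------

def make_toy_morphometrics(seed: int = 0, separation_sigma: float = None,
                           n_per_class: int = None,
                           focal_displacement: float = 0.0) -> pd.DataFrame:
    """Two labelled Gaussian classes in the four stance predictors plus one
    "unknown" focal row displaced from the quadruped centroid by
    ``focal_displacement`` (in units of the class separation vector).

    Class means are separated by ``separation_sigma`` standard deviations
    along every predictor (isotropic unit-free scales).
    """
    spec = ToyTaxonSpec()
    sep = spec.class_separation_sigma if separation_sigma is None else separation_sigma
    n = spec.n_per_class if n_per_class is None else n_per_class
    rng = np.random.default_rng(seed)
    cols = ["body_mass", "com_dimensionless", "forelimb_length", "hindlimb_length"]
    sd = np.array([0.3, 0.05, 0.02, 0.03])
    quad_mean = np.array([1.2, 0.45, 0.12, 0.18])
    biped_mean = quad_mean + sep * sd * np.array([1, 1, -1, 1])
    rows = []
    for label, mean in (("quadruped", quad_mean), ("biped", biped_mean)):
        draws = rng.normal(mean, sd, size=(n, 4))
        for i, x in enumerate(draws):
            rows.append({"taxon": f"{label}_{i + 1}", "stance": label,
                         **dict(zip(cols, x))})
    focal = quad_mean + focal_displacement * (biped_mean - quad_mean)
    rows.append({"taxon": "Focalus", "stance": "unknown",
                 **dict(zip(cols, focal))})
    return pd.DataFrame(rows)
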