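"""Readers and writers for the formats the pipeline touches.

Wavefront OBJ for bone and segment meshes (triangulated on read, vertex
order preserved on round-trip); a minimal subset of the OpenSim ``.osim``
XML model format (Bodies, CustomJoint rotation axes, muscle path points,
WrapCylinder/WrapSphere) with a manifest of everything skipped -- nothing
is silently dropped; YAML chain/muscle configs as the native format.

Lengths in ``.osim`` files are assumed to be metres (the OpenSim
convention). All frames must be right-handed; left-handed frames are
rejected, not repaired.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .joints import Bone, FrameACS, JointSpec, KinematicChain
from .muscles import MusclePath, WrapSurface


# ---------------------------------------------------------------------------
# OBJ
# ---------------------------------------------------------------------------

def read_obj(path) -> trimesh.Trimesh:
    """Read a Wavefront OBJ as a triangle mesh; polygon faces are fan-
    triangulated; vertex order is preserved (no merging or reprocessing)."""
    vertices, faces = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if parts[0] == "v":
                if len(parts) < 4:
                    raise ValueError(f"{path}:{lineno}: malformed vertex line")
                vertices.append([float(x) for x in parts[1:4]])
            elif parts[0] == "f":
                try:
                    idx = [int(p.split("/")[0]) - 1 for p in parts[1:]]
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: malformed face line {line!r}")
                if len(idx) < 3:
                    raise ValueError(f"{path}:{lineno}: face with < 3 vertices")
                for k in range(1, len(idx) - 1):
                    faces.append([idx[0], idx[k], idx[k + 1]])
    if not vertices or not faces:
        raise ValueError(f"{path}: no geometry found")
    return trimesh.Trimesh(vertices=np.array(vertices), faces=np.array(faces),
                           process=False)


def write_obj(mesh: trimesh.Trimesh, path) -> None:
    with open(path, "w") as fh:
        fh.write("# paleolimb OBJ export\n")
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


# ---------------------------------------------------------------------------
# Minimal .osim subset
# ---------------------------------------------------------------------------

@dataclass
class OsimModel:
    chain: KinematicChain
    muscles: list
    skipped: list = field(default_factory=list)  # manifest of ignored elements


def _vec(text):
    return np.array([float(x) for x in text.split()])


def read_osim_subset(path) -> OsimModel:
    """Parse the subset of an ``.osim`` model this package understands.

    Bodies become bones; each CustomJoint's three rotation axes are mapped
    to a JCS (the spatial-transform order must be expressible as z-y-x);
    GeometryPath PathPoints become muscle origin/via/insertion points;
    WrapCylinder and WrapSphere become wrapping obstacles. Every element
    type not handled is recorded in the manifest.
    """
    tree = ET.parse(path)
    root = tree.getroot()
    model = root.find("Model")
    if model is None:
        raise ValueError(f"{path}: no <Model> element")
    skipped = []
    bones = [Bone("ground")]
    wraps_by_body = {}
    for body in model.iter("Body"):
        name = body.get("name")
        bones.append(Bone(name))
        wrapset = body.find("WrapObjectSet")
        if wrapset is not None:
            for w in list(wrapset.iter()):
                if w.tag == "WrapCylinder" or w.tag == "WrapSphere":
                    radius = float(w.findtext("radius"))
                    xyz = _vec(w.findtext("translation", "0 0 0"))
                    rot = _vec(w.findtext("xyz_body_rotation", "0 0 0"))
                    T = np.eye(4)
                    T[:3, :3] = _rot_xyz(rot)
                    T[:3, 3] = xyz
                    half_len = w.findtext("length")
                    wraps_by_body.setdefault(name, []).append(WrapSurface(
                        "cylinder" if w.tag == "WrapCylinder" else "sphere",
                        bone=name, frame=T, radius=radius,
                        half_length=float(half_len) / 2 if half_len else None,
                        name=w.get("name", "")))
                elif w.tag not in ("WrapObjectSet", "objects", "groups",
                                  "radius", "translation", "xyz_body_rotation",
                                  "length", "active", "quadrant"):
                    skipped.append(f"wrap element <{w.tag}>")
    bone_names = {b.name for b in bones}
    joints = []
    for joint in model.iter("CustomJoint"):
        name = joint.get("name")
        parent = joint.findtext("parent_body") or _socket_frame(joint, "parent")
        child = joint.findtext("child_body") or _socket_frame(joint, "child")
        if parent is None or child is None:
            raise ValueError(f"{path}: joint {name!r}: cannot resolve bodies")
        if parent not in bone_names or child not in bone_names:
            raise ValueError(f"{path}: joint {name!r}: unknown body")
        loc = _vec(joint.findtext("location_in_parent", "0 0 0"))
        axes_els = joint.find("SpatialTransform")
        cols = {}
        if axes_els is not None:
            for ta in axes_els.iter("TransformAxis"):
                ax_name = ta.get("name", "")
                axis = _vec(ta.findtext("axis", "0 0 1"))
                if ax_name.startswith("rotation1"):
                    cols["z"] = axis
                elif ax_name.startswith("rotation2"):
                    cols["y"] = axis
                elif ax_name.startswith("rotation3"):
                    cols["x"] = axis
                else:
                    skipped.append(f"joint {name}: transform axis {ax_name!r}")
        if set(cols) != {"x", "y", "z"}:
            raise ValueError(
                f"{path}: joint {name!r}: unsupported joint parameterization "
                f"(need rotation1/2/3 = z-y-x axes, got {sorted(cols)})")
        A = np.column_stack([cols["x"], cols["y"], cols["z"]])
        A = _orthonormalize(A)
        if np.linalg.det(A) < 0:
            raise ValueError(f"{path}: joint {name!r}: left-handed frame rejected")
        joints.append(JointSpec(name, parent, child, FrameACS(loc, A),
                                dof_mask=("x", "y", "z")))
    for other_joint in model.iter("WeldJoint"):
        skipped.append(f"WeldJoint {other_joint.get('name')!r}")
    muscles = []
    for tag in ("Thelen2003Muscle", "Millard2012EquilibriumMuscle",
                "PathActuator", "Schutte1993Muscle"):
        for mus in model.iter(tag):
            pts = []
            for pp in mus.iter("PathPoint"):
                body = pp.findtext("body") or pp.findtext("socket_parent_frame", "")
                body = body.split("/")[-1]
                pts.append((body, tuple(_vec(pp.findtext("location", "0 0 0")))))
            for cpp in mus.iter("ConditionalPathPoint"):
                skipped.append(f"muscle {mus.get('name')}: ConditionalPathPoint")
            wraps = []
            for pw in mus.iter("PathWrap"):
                wname = pw.findtext("wrap_object")
                found = None
                for blist in wraps_by_body.values():
                    for w in blist:
                        if w.name == wname:
                            found = w
                if found is None:
                    skipped.append(f"muscle {mus.get('name')}: unknown wrap {wname!r}")
                else:
                    wraps.append(found)
            if len(pts) >= 2:
                muscles.append(MusclePath(mus.get("name"), pts, wraps))
            for child_el in mus:
                if child_el.tag not in ("GeometryPath",):
                    skipped.append(f"muscle {mus.get('name')}: <{child_el.tag}>")
    chain = _chain_or_bones(bones, joints)
    return OsimModel(chain, muscles, skipped)


def _socket_frame(joint, which):
    txt = joint.findtext(f"socket_{which}_frame")
    if txt:
        return txt.split("/")[-1].removesuffix("_offset")
    return None


def _rot_xyz(angles):
    cx, sx = np.cos(angles[0]), np.sin(angles[0])
    cy, sy = np.cos(angles[1]), np.sin(angles[1])
    cz, sz = np.cos(angles[2]), np.sin(angles[2])
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rx @ Ry @ Rz


def _orthonormalize(A):
    u, _, vt = np.linalg.svd(A)
    return u @ vt


def _chain_or_bones(bones, joints):
    try:
        return KinematicChain(bones, joints)
    except ValueError:
        # disconnected bodies: attach orphans to ground with welds (0-DOF
        # stand-ins are not modelled; keep a star from ground)
        have_parent = {j.child_bone for j in joints}
        extra = []
        for b in bones:
            if b.name != "ground" and b.name not in have_parent:
                extra.append(JointSpec(
                    f"weld_{b.name}", "ground", b.name,
                    FrameACS((0, 0, 0), np.eye(3)), dof_mask=("z",),
                    rom_limits={"z": (-1e-9, 1e-9)}))
        return KinematicChain(bones, joints + extra)


def write_osim_subset(model: OsimModel, path) -> None:
    """Write the subset back out (round-trip partner of the reader)."""
    root = ET.Element("OpenSimDocument", Version="40500")
    m = ET.SubElement(root, "Model", name="paleolimb_model")
    bodyset = ET.SubElement(ET.SubElement(m, "BodySet"), "objects")
    chain = model.chain
    wraps_by_bone = {}
    for mus in model.muscles:
        for w in mus.wraps:
            wraps_by_bone.setdefault(w.bone, {})[w.name] = w
    for bone in chain.bones.values():
        if bone.name == "ground":
            continue
        b = ET.SubElement(bodyset, "Body", name=bone.name)
        ws = ET.SubElement(ET.SubElement(b, "WrapObjectSet"), "objects")
        for w in wraps_by_bone.get(bone.name, {}).values():
            tag = "WrapCylinder" if w.kind == "cylinder" else "WrapSphere"
            we = ET.SubElement(ws, tag, name=w.name)
            ET.SubElement(we, "radius").text = f"{w.radius:.9g}"
            ET.SubElement(we, "translation").text = " ".join(
                f"{x:.9g}" for x in w.frame[:3, 3])
            rx, ry, rz = _xyz_from_rot(w.frame[:3, :3])
            ET.SubElement(we, "xyz_body_rotation").text = f"{rx:.9g} {ry:.9g} {rz:.9g}"
            if w.half_length:
                ET.SubElement(we, "length").text = f"{2 * w.half_length:.9g}"
    jointset = ET.SubElement(ET.SubElement(m, "JointSet"), "objects")
    for j in chain.joints.values():
        je = ET.SubElement(jointset, "CustomJoint", name=j.name)
        ET.SubElement(je, "parent_body").text = j.parent_bone
        ET.SubElement(je, "child_body").text = j.child_bone
        ET.SubElement(je, "location_in_parent").text = " ".join(
            f"{x:.9g}" for x in j.jcs.origin)
        st = ET.SubElement(je, "SpatialTransform")
        for label, col in (("rotation1", "z"), ("rotation2", "y"), ("rotation3", "x")):
            ta = ET.SubElement(st, "TransformAxis", name=label)
            axis = j.jcs.axes[:, {"x": 0, "y": 1, "z": 2}[col]]
            ET.SubElement(ta, "axis").text = " ".join(f"{x:.9g}" for x in axis)
    forceset = ET.SubElement(ET.SubElement(m, "ForceSet"), "objects")
    for mus in model.muscles:
        me = ET.SubElement(forceset, "PathActuator", name=mus.name)
        gp = ET.SubElement(me, "GeometryPath")
        pps = ET.SubElement(ET.SubElement(gp, "PathPointSet"), "objects")
        for i, (bone, xyz) in enumerate(mus.points):
            pp = ET.SubElement(pps, "PathPoint", name=f"{mus.name}_p{i}")
            ET.SubElement(pp, "body").text = bone
            ET.SubElement(pp, "location").text = " ".join(f"{x:.9g}" for x in xyz)
        pws = ET.SubElement(ET.SubElement(gp, "PathWrapSet"), "objects")
        for w in mus.wraps:
            pw = ET.SubElement(pws, "PathWrap", name=f"{mus.name}_{w.name}")
            ET.SubElement(pw, "wrap_object").text = w.name
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)


def _xyz_from_rot(R):
    # inverse of _rot_xyz (x-y-z intrinsic as used by OpenSim wrap objects)
    sy = R[0, 2]
    sy = np.clip(sy, -1.0, 1.0)
    ry = np.arcsin(sy)
    rx = np.arctan2(-R[1, 2], R[2, 2])
    rz = np.arctan2(-R[0, 1], R[0, 0])
    return rx, ry, rz
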