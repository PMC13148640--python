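"""Packaged model configuration: the *Gracilisuchus* joint table.

The published joint limits, per-joint sign conventions and DOF assignments
are data, not code; they live in ``data/gracilisuchus_joints.yaml`` and are
turned into a frame-only kinematic chain here (identity joint frames -- the
chain carries the bookkeeping even when no meshes are loaded).
"""

from __future__ import annotations

from importlib.resources import files

import numpy as np
import yaml

from .joints import Bone, FrameACS, JointSpec, KinematicChain


def load_gracilisuchus_joints(path=None) -> dict:
    if path is None:
        text = (files("paleolimb") / "data" / "gracilisuchus_joints.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


_TOPOLOGY = [
    # joint, parent bone, child bone
    ("hip", "trunk", "femur"),
    ("knee", "femur", "crus"),
    ("ankle", "crus", "pes"),
    ("mtp3", "pes", "pedal_digit3"),
    ("shoulder", "trunk", "humerus"),
    ("elbow", "humerus", "forearm"),
    ("wrist", "forearm", "manus"),
    ("mcp3", "manus", "manual_digit3"),
]


def gracilisuchus_chain(config: dict = None) -> KinematicChain:
    """A frame-only limb chain carrying the packaged DOF masks, sign
    conventions and ROM limits (identity JCS frames; no meshes)."""
    cfg = config or load_gracilisuchus_joints()
    bones = {"trunk"}
    joints = []
    for joint_name, parent, child in _TOPOLOGY:
        jc = cfg["joints"].get(joint_name)
        if jc is None:
            continue
        bones.add(parent)
        bones.add(child)
        signs = {ax: tuple(v) for ax, v in jc.get("signs", {}).items()}
        limits = {ax: tuple(v) for ax, v in jc.get("limits", {}).items()}
        joints.append(JointSpec(joint_name, parent, child,
                                FrameACS(np.zeros(3), np.eye(3)),
                                dof_mask=tuple(jc["dof"]),
                                sign_convention=signs, rom_limits=limits))
    return KinematicChain([Bone(b) for b in sorted(bones)], joints)


def gracilisuchus_rom_table():
    """The packaged joint-limit table (min/max/total per joint DOF)."""
    from .joints import rom_table

    return rom_table(gracilisuchus_chain())
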