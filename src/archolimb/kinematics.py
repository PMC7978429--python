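"""Forward kinematics of the limb chain.

Joint rotations compose in the fixed order FLEXEX - ABAD - LAR with no
translations.  In the segment-frame convention (+x cranial, +y dorsal,
+z right-lateral, limb hanging along -y in the reference pose):

* FLEXEX is a rotation about +z (the right-lateral axis).  Positive FLEXEX
  flexes (protracts) the hip, extends the knee and dorsiflexes the ankle.
* ABAD (hip only) is a rotation about +x (cranial axis); positive adducts.
* LAR (hip only) is a rotation about +y (the femoral long axis in the
  reference pose); positive is medial/internal rotation of the right limb.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import JOINT_CHILD, JOINT_PARENT, LimbModel


def _rx(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _ry(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


def _rz(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def joint_rotation(flexex_deg: float = 0.0, abad_deg: float = 0.0,
                   lar_deg: float = 0.0) -> np.ndarray:
    """Rotation of a child segment relative to its parent, composed in the
    order FLEXEX (about z), then ABAD (about x), then LAR (about y)."""
    return (
        _rz(math.radians(flexex_deg))
        @ _rx(math.radians(abad_deg))
        @ _ry(math.radians(lar_deg))
    )


@dataclass
class Pose:
    """Joint angles in degrees: ``angles[joint][dof]``.  DoFs not given take
    the joint's locked defaults.  Angles outside the joint's range of motion
    are permitted but warned about."""

    angles: dict[str, dict[str, float]] = field(default_factory=dict)

    def angle(self, model: LimbModel, joint: str, dof: str) -> float:
        v = self.angles.get(joint, {}).get(dof)
        if v is None:
            return model.joints[joint].locked_defaults_deg[dof]
        return float(v)

    def replace(self, joint: str, dof: str, value: float) -> "Pose":
        new = {j: dict(d) for j, d in self.angles.items()}
        new.setdefault(joint, {})[dof] = value
        return Pose(new)


@dataclass
class FramePlacement:
    rotation: np.ndarray  # (3,3) segment -> world
    origin: np.ndarray  # (3,) world

    def transform(self, point: np.ndarray) -> np.ndarray:
        return self.origin + self.rotation @ np.asarray(point, dtype=float)


def segment_frames(model: LimbModel, pose: Pose,
                   warn_out_of_rom: bool = True) -> dict[str, FramePlacement]:
    """World placement of every segment frame, composed root to leaf.

    The pelvis frame is the world frame.  A child frame's origin sits at the
    joint centre (cartilage spacing already folded into the centre), and its
    rotation is the parent rotation composed with the joint rotation.
    """
    frames = {"pelvis": FramePlacement(np.eye(3), np.zeros(3))}
    for joint_name in ("hip", "knee", "ankle", "mtp"):
        if joint_name not in model.joints:
            continue
        joint = model.joints[joint_name]
        parent = JOINT_PARENT[joint_name]
        child = JOINT_CHILD[joint_name]
        if child not in model.segments:
            continue
        ang = {dof: pose.angle(model, joint_name, dof) for dof in joint.dofs}
        if warn_out_of_rom:
            for dof, v in ang.items():
                lo, hi = joint.rom_deg[dof]
                if not (min(lo, hi) - 1e-9 <= v <= max(lo, hi) + 1e-9):
                    warnings.warn(
                        f"{joint_name} {dof} = {v:g} deg outside RoM [{lo:g}, {hi:g}]",
                        stacklevel=2,
                    )
        rot = joint_rotation(
            ang.get("FLEXEX", 0.0), ang.get("ABAD", 0.0), ang.get("LAR", 0.0)
        )
        pf = frames[parent]
        frames[child] = FramePlacement(
            rotation=pf.rotation @ rot,
            origin=pf.transform(joint.center),
        )
    return frames


def forward_kinematics(model: LimbModel, pose: Pose,
                       warn_out_of_rom: bool = True) -> dict:
    """World-frame coordinates of all MTU attachments, via points and wrap
    surfaces for a pose.

    Returns a dict with ``frames`` (per segment), ``attachments`` (per MTU:
    ordered fixed-point world coordinates) and ``wraps`` (per wrap surface:
    world translation, rotation and wrap-side vector).
    """
    frames = segment_frames(model, pose, warn_out_of_rom=warn_out_of_rom)
    attachments = {
        name: np.array([frames[s].transform(p) for s, p in mtu.fixed_points])
        for name, mtu in model.mtus.items()
    }
    wraps = {}
    for name, w in model.wrap_surfaces.items():
        f = frames[w.segment]
        wraps[name] = {
            "translation": f.transform(w.translation),
            "rotation": f.rotation @ w.rotation,
            "wrap_side": None if w.wrap_side is None else f.rotation @ w.rotation @ w.wrap_side,
        }
    return {"frames": frames, "attachments": attachments, "wraps": wraps}
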