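"""Moment arms by the virtual-work method.

An MTU's moment arm about a joint degree of freedom is the negative
derivative of its path length with respect to the joint angle,
``r = -dL/dtheta`` (theta in radians).  Path length is evaluated by routing
the MTU polyline through its via points and around any engaged wrapping
surfaces; the derivative is taken by a central finite difference (5-point
stencil by default, step 0.25 deg).

Sign convention (inherited from the positive joint-rotation senses): a
positive moment arm means tension drives positive rotation - hip flexion,
hip adduction, hip medial long-axis rotation, knee extension, ankle
dorsiflexion.  Negative values are the antagonistic actions (hip extension,
abduction, lateral rotation; knee flexion; ankle plantarflexion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import Pose, forward_kinematics
from .model import NORMALIZING_SEGMENT, LimbModel
from .wrapping import WrapError, wrap_cylinder, wrap_ellipsoid, wrap_sphere

DEFAULT_FD_STEP_DEG = 0.25
DEFAULT_GRID_STEP_DEG = 1.0


@dataclass
class PathPolyline:
    mtu: str
    points: np.ndarray  # (n, 3) world coordinates
    length: float  # mm
    wrapped_surfaces: tuple[str, ...] = ()


@dataclass
class MomentArmCurve:
    mtu: str
    joint: str
    dof: str
    angles_deg: np.ndarray
    moment_arms_mm: np.ndarray

    def mean(self) -> float:
        return float(np.mean(self.moment_arms_mm))


def route_path(model: LimbModel, pose: Pose, mtu_name: str,
               warn_out_of_rom: bool = False) -> PathPolyline:
    """Route one MTU through its via points and wrapping surfaces for a pose.

    Straight segments between consecutive fixed points are tested against the
    MTU's assigned surfaces (in declaration order); the first surface that
    engages replaces the segment by its tangent-geodesic-tangent route.
    """
    mtu = model.mtus[mtu_name]
    fk = forward_kinematics(model, pose, warn_out_of_rom=warn_out_of_rom)
    fixed = fk["attachments"][mtu_name]
    pieces: list[np.ndarray] = []
    total = 0.0
    wrapped: list[str] = []
    for a, b in zip(fixed[:-1], fixed[1:]):
        result = None
        for wname in mtu.wrap_surfaces:
            surf = model.wrap_surfaces[wname]
            wp = fk["wraps"][wname]
            try:
                if surf.shape == "cylinder":
                    axis = wp["rotation"][:, 2]  # local +z is the cylinder axis
                    res = wrap_cylinder(
                        a, b, wp["translation"], axis, surf.radius,
                        side=wp["wrap_side"],
                    )
                elif surf.shape == "sphere":
                    res = wrap_sphere(a, b, wp["translation"], surf.radius)
                else:
                    res = wrap_ellipsoid(
                        a, b, wp["translation"], surf.radii, wp["rotation"]
                    )
            except WrapError as err:
                raise WrapError(f"MTU {mtu_name!r} on surface {wname!r}: {err}")
            if res.wrapped:
                result = res
                wrapped.append(wname)
                break
        if result is None:
            seg = np.array([a, b])
            result_points, seg_len = seg, float(np.linalg.norm(b - a))
        else:
            result_points, seg_len = result.points, result.length
        if pieces:
            result_points = result_points[1:]  # avoid duplicating the joint point
        pieces.append(result_points)
        total += seg_len
    return PathPolyline(
        mtu=mtu_name,
        points=np.vstack(pieces),
        length=total,
        wrapped_surfaces=tuple(wrapped),
    )


def path_length(model: LimbModel, pose: Pose, mtu_name: str) -> float:
    return route_path(model, pose, mtu_name).length


_STENCILS = {
    2: ((-1.0, 1.0), (-0.5, 0.5)),
    4: ((-2.0, -1.0, 1.0, 2.0), (1.0 / 12.0, -8.0 / 12.0, 8.0 / 12.0, -1.0 / 12.0)),
}


def moment_arm(model: LimbModel, mtu_name: str, joint: str, dof: str,
               pose: Pose | None = None, h_deg: float = DEFAULT_FD_STEP_DEG,
               order: int = 4) -> float:
    """Signed moment arm (mm) of an MTU about one joint DoF at a pose.

    ``order`` selects the central-difference stencil (2 = 3-point,
    4 = 5-point; default 4).  Wrap failures at the probe angles are
    propagated with the MTU and angle in the message.
    """
    if joint not in model.joints:
        raise ValueError(f"model has no joint {joint!r}")
    if dof not in model.joints[joint].dofs:
        raise ValueError(f"joint {joint!r} has no DoF {dof!r}")
    pose = pose or Pose()
    theta0 = pose.angle(model, joint, dof)
    offsets, weights = _STENCILS[order]
    h_rad = math.radians(h_deg)
    acc = 0.0
    for off, wgt in zip(offsets, weights):
        probe = pose.replace(joint, dof, theta0 + off * h_deg)
        try:
            L = path_length(model, probe, mtu_name)
        except WrapError as err:
            raise WrapError(
                f"wrap failure for {mtu_name!r} at {joint} {dof} = "
                f"{theta0 + off * h_deg:g} deg: {err}"
            )
        acc += wgt * L
    return -acc / h_rad


def sweep_rom(model: LimbModel, mtu_name: str, joint: str, dof: str,
              grid_step_deg: float = DEFAULT_GRID_STEP_DEG,
              h_deg: float = DEFAULT_FD_STEP_DEG,
              locked_overrides: dict | None = None) -> MomentArmCurve:
    """Moment-arm curve over the joint's full range of motion.

    The grid runs at ``grid_step_deg`` (default 1 deg) from the lower to the
    upper RoM bound inclusive.  All non-swept DoFs are held at the joints'
    locked defaults (hip: -15 deg ABAD, 0 deg LAR, femur vertical at 0 deg
    FLEXEX), unless overridden.
    """
    lo, hi = model.joints[joint].rom_deg[dof]
    n = int(round((hi - lo) / grid_step_deg)) + 1
    grid = lo + grid_step_deg * np.arange(n)
    base = Pose({j: dict(d) for j, d in (locked_overrides or {}).items()})
    values = np.array(
        [
            moment_arm(
                model, mtu_name, joint, dof,
                pose=base.replace(joint, dof, float(theta)), h_deg=h_deg,
            )
            for theta in grid
        ]
    )
    return MomentArmCurve(
        mtu=mtu_name, joint=joint, dof=dof,
        angles_deg=grid, moment_arms_mm=values,
    )


def mean_normalized(curve: MomentArmCurve, model: LimbModel) -> dict:
    """Reduce a moment-arm curve to one table row: the unweighted grid mean,
    normalized by the joint's reference segment length (femur for the hip,
    tibiotarsus for the knee, tarsometatarsus for the ankle)."""
    if curve.moment_arms_mm.size == 0:
        raise ValueError("cannot average an empty moment-arm curve")
    seg_name = NORMALIZING_SEGMENT[curve.joint]
    seg_len = model.segments[seg_name].reference_length
    mean_mm = curve.mean()
    return {
        "taxon": model.taxon,
        "mtu": curve.mtu,
        "joint": curve.joint,
        "dof": curve.dof,
        "mean_mm": mean_mm,
        "segment_length_mm": seg_len,
        "mean_normalized": mean_mm / seg_len,
    }


def average_subheads(values) -> float:
    """Collapse the mean moment arms of a muscle's sub-heads into one value
    (plain arithmetic mean)."""
    vals = list(values)
    if not vals:
        raise ValueError("no sub-head values to average")
    return float(np.mean(vals))


def sweep_model(model: LimbModel, mtus: list[str] | None = None,
                joints: list[str] | None = None,
                grid_step_deg: float = DEFAULT_GRID_STEP_DEG,
                h_deg: float = DEFAULT_FD_STEP_DEG) -> pd.DataFrame:
    """Mean normalized moment arms for every (MTU, joint, DoF) combination
    the model supports; the long-format table one taxon contributes.

    MTUs recorded in the anatomical roster but absent from this taxon's model
    (lost muscles) appear with value 0 and ``lost = True``.
    """
    from . import muscles as _m

    rows = []
    joints = joints or [j for j in ("hip", "knee", "ankle") if j in model.joints]
    for joint in joints:
        crossing = {
            "hip": _m.HIP_MTUS, "knee": _m.KNEE_MTUS, "ankle": _m.ANKLE_MTUS
        }[joint]
        for dof in model.joints[joint].dofs:
            for mtu in crossing:
                if mtus is not None and mtu not in mtus:
                    continue
                heads = [
                    n for n in model.mtus
                    if n == mtu or (n.rstrip("ab") == mtu and n != mtu)
                ]
                if not heads:
                    seg = model.segments[NORMALIZING_SEGMENT[joint]]
                    rows.append({
                        "taxon": model.taxon, "mtu": mtu, "joint": joint,
                        "dof": dof, "mean_mm": 0.0,
                        "segment_length_mm": seg.reference_length,
                        "mean_normalized": 0.0, "lost": True,
                    })
                    continue
                head_rows = [
                    mean_normalized(
                        sweep_rom(model, h, joint, dof,
                                  grid_step_deg=grid_step_deg, h_deg=h_deg),
                        model,
                    )
                    for h in heads
                ]
                row = dict(head_rows[0])
                row["mtu"] = mtu
                row["mean_mm"] = average_subheads(r["mean_mm"] for r in head_rows)
                row["mean_normalized"] = average_subheads(
                    r["mean_normalized"] for r in head_rows
                )
                row["lost"] = False
                rows.append(row)
    return pd.DataFrame(rows)
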