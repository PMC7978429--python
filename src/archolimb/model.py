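"""Posable hindlimb models: segments, joints, muscle paths, wrap surfaces.

A model is a single kinematic chain rooted at the pelvis
(pelvis - hip - femur - knee - tibiotarsus - ankle - tarsometatarsus - mtp -
pes).  The hip is a ball-and-socket joint with three rotational degrees of
freedom (flexion/extension, abduction/adduction, long-axis rotation); knee,
ankle and metatarsophalangeal joints are single-axis hinges.  There are no
joint translations.  Joint centres come from primitives fitted to articular
surfaces; the knee and ankle centres are additionally spaced apart along the
proximal segment's long axis by a fixed fraction of its length to represent
articular cartilage (5% at the knee, 7.5% at the ankle).

Frame convention (right-handed, every segment frame): +x cranial, +y dorsal,
+z right-lateral.  In the reference pose (all angles zero) the limb hangs
fully extended ventrally, i.e. each segment's long axis points along local
-y and all joint centres are vertically aligned.  Coordinates are in mm,
angles in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import muscles as _muscles
from .primitives import CylinderPrimitive, EllipsoidPrimitive, SpherePrimitive

SEGMENT_ORDER = ("pelvis", "femur", "tibiotarsus", "tarsometatarsus", "pes")
JOINT_ORDER = ("hip", "knee", "ankle", "mtp")
JOINT_PARENT = {"hip": "pelvis", "knee": "femur", "ankle": "tibiotarsus", "mtp": "tarsometatarsus"}
JOINT_CHILD = {"hip": "femur", "knee": "tibiotarsus", "ankle": "tarsometatarsus", "mtp": "pes"}

#: fraction of the proximal segment length by which the child segment is
#: translated distally to represent joint cartilage
CARTILAGE_FRACTION = {"hip": 0.0, "knee": 0.05, "ankle": 0.075, "mtp": 0.0}

JOINT_DOFS = {
    "hip": ("FLEXEX", "ABAD", "LAR"),
    "knee": ("FLEXEX",),
    "ankle": ("FLEXEX",),
    "mtp": ("FLEXEX",),
}

#: study ranges of motion, degrees (lower, upper) per joint and DoF
DEFAULT_ROM_DEG = {
    ("hip", "FLEXEX"): (-45.0, 65.0),
    ("hip", "ABAD"): (-45.0, 0.0),
    ("hip", "LAR"): (-30.0, 30.0),
    ("knee", "FLEXEX"): (-90.0, 10.0),
    ("ankle", "FLEXEX"): (0.0, 90.0),
    ("mtp", "FLEXEX"): (0.0, 0.0),  # fixed
}

#: angles taken by DoFs that are not being swept; the hip is held at -15 deg
#: of abduction (limb clearance of the abdomen) and 0 deg LAR, femur vertical
DEFAULT_LOCKED_DEG = {
    ("hip", "FLEXEX"): 0.0,
    ("hip", "ABAD"): -15.0,
    ("hip", "LAR"): 0.0,
    ("knee", "FLEXEX"): 0.0,
    ("ankle", "FLEXEX"): 0.0,
    ("mtp", "FLEXEX"): 0.0,
}

#: segment whose length normalizes moment arms at each joint
NORMALIZING_SEGMENT = {"hip": "femur", "knee": "tibiotarsus", "ankle": "tarsometatarsus"}


class ModelValidationError(ValueError):
    """Raised when a model description is internally inconsistent."""


@dataclass
class Segment:
    name: str
    reference_length: float  # mm; used for normalization and cartilage gaps
    parent_joint: str | None = None  # None only for the pelvis root

    def __post_init__(self):
        if self.reference_length <= 0:
            raise ModelValidationError(
                f"segment {self.name!r}: reference_length must be > 0"
            )


@dataclass
class JointSpec:
    name: str
    center: np.ndarray  # (3,) mm, in the parent segment frame (pre-cartilage)
    rom_deg: dict[str, tuple[float, float]] = field(default_factory=dict)
    locked_defaults_deg: dict[str, float] = field(default_factory=dict)
    cartilage_fraction: float | None = None
    center_discrepancy: float = 0.0  # |sphere-centre mismatch| at the hip, mm

    def __post_init__(self):
        if self.name not in JOINT_ORDER:
            raise ModelValidationError(f"unknown joint name {self.name!r}")
        self.center = np.asarray(self.center, dtype=float)
        if self.cartilage_fraction is None:
            self.cartilage_fraction = CARTILAGE_FRACTION[self.name]
        for dof in self.dofs:
            self.rom_deg.setdefault(dof, DEFAULT_ROM_DEG[(self.name, dof)])
            self.locked_defaults_deg.setdefault(
                dof, DEFAULT_LOCKED_DEG[(self.name, dof)]
            )
        for dof, (lo, hi) in self.rom_deg.items():
            if not lo < hi and (self.name, dof) != ("mtp", "FLEXEX"):
                raise ModelValidationError(
                    f"{self.name} {dof}: RoM lower bound must be < upper bound"
                )
            d = self.locked_defaults_deg[dof]
            if not (min(lo, hi) <= d <= max(lo, hi)):
                raise ModelValidationError(
                    f"{self.name} {dof}: locked default {d} outside RoM [{lo}, {hi}]"
                )

    @property
    def dofs(self) -> tuple[str, ...]:
        return JOINT_DOFS[self.name]


@dataclass
class WrapSurface:
    """A wrapping obstacle fixed in a segment frame.

    ``shape`` is "cylinder" (local axis = +z of the surface frame), "sphere"
    or "ellipsoid".  ``wrap_side``, if given, is a unit vector in the surface
    frame: the muscle path is forced to pass the obstacle on that side.
    """

    name: str
    shape: str
    segment: str
    translation: np.ndarray  # (3,) in segment frame
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    radius: float | None = None
    radii: np.ndarray | None = None  # ellipsoid semi-axes
    half_length: float | None = None  # cylinder
    wrap_side: np.ndarray | None = None

    def __post_init__(self):
        if self.shape not in ("cylinder", "sphere", "ellipsoid"):
            raise ModelValidationError(f"unknown wrap shape {self.shape!r}")
        self.translation = np.asarray(self.translation, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        if self.shape in ("cylinder", "sphere"):
            if self.radius is None or self.radius <= 0:
                raise ModelValidationError(
                    f"wrap surface {self.name!r}: radius must be > 0"
                )
        if self.shape == "ellipsoid":
            self.radii = np.asarray(self.radii, dtype=float)
            if self.radii is None or np.any(self.radii <= 0):
                raise ModelValidationError(
                    f"wrap surface {self.name!r}: all radii must be > 0"
                )
        if self.wrap_side is not None:
            s = np.asarray(self.wrap_side, dtype=float)
            n = np.linalg.norm(s)
            if n == 0:
                raise ModelValidationError(
                    f"wrap surface {self.name!r}: wrap_side must be nonzero"
                )
            self.wrap_side = s / n


@dataclass
class MTUPath:
    """Muscle-tendon unit path: origin, ordered via points, insertion, and
    the wrap surfaces (by name) that may deflect it."""

    name: str
    origin: tuple[str, np.ndarray]
    insertion: tuple[str, np.ndarray]
    via_points: list[tuple[str, np.ndarray]] = field(default_factory=list)
    wrap_surfaces: list[str] = field(default_factory=list)
    present: bool = True
    custom: bool = False  # synthetic muscle outside the anatomical roster

    def __post_init__(self):
        self.origin = (self.origin[0], np.asarray(self.origin[1], dtype=float))
        self.insertion = (self.insertion[0], np.asarray(self.insertion[1], dtype=float))
        self.via_points = [
            (s, np.asarray(p, dtype=float)) for s, p in self.via_points
        ]

    @property
    def fixed_points(self) -> list[tuple[str, np.ndarray]]:
        return [self.origin, *self.via_points, self.insertion]


@dataclass
class LimbModel:
    taxon: str
    segments: dict[str, Segment]
    joints: dict[str, JointSpec]
    mtus: dict[str, MTUPath]
    wrap_surfaces: dict[str, WrapSurface] = field(default_factory=dict)
    clade_path: tuple[str, ...] = ()
    metadata: dict = field(default_factory=dict)

    def segment_chain(self) -> list[str]:
        return [s for s in SEGMENT_ORDER if s in self.segments]

    def joint_for_child(self, segment: str) -> str | None:
        for j, c in JOINT_CHILD.items():
            if c == segment and j in self.joints:
                return j
        return None


def place_joint(joint: JointSpec, proximal: Segment,
                primitives: dict | None = None) -> JointSpec:
    """Place a joint centre from fitted primitives and apply cartilage spacing.

    The hip centre is the superposition of the femoral-head and acetabular
    sphere centres; when the two fitted centres differ, their mean is used
    and the discrepancy recorded.  Knee/ankle centres come from the fitted
    cylinder's long-axis midpoint.  The effective centre is then translated
    distally (local -y of the parent frame) by
    ``cartilage_fraction x proximal.reference_length``.
    """
    primitives = primitives or {}
    center = joint.center
    discrepancy = 0.0
    if joint.name == "hip" and primitives:
        spheres = [p for p in primitives.values() if isinstance(p, SpherePrimitive)]
        if not spheres:
            raise ModelValidationError("hip placement needs fitted sphere primitives")
        centers = np.array([s.center for s in spheres])
        center = centers.mean(axis=0)
        if len(spheres) == 2:
            discrepancy = float(np.linalg.norm(centers[0] - centers[1]))
    elif joint.name in ("knee", "ankle") and primitives:
        cyls = [p for p in primitives.values() if isinstance(p, CylinderPrimitive)]
        if not cyls:
            raise ModelValidationError(
                f"{joint.name} placement needs a fitted cylinder primitive"
            )
        center = cyls[0].axis_point
    gap = joint.cartilage_fraction * proximal.reference_length
    effective = np.asarray(center, dtype=float) + gap * np.array([0.0, -1.0, 0.0])
    return JointSpec(
        name=joint.name,
        center=effective,
        rom_deg=dict(joint.rom_deg),
        locked_defaults_deg=dict(joint.locked_defaults_deg),
        cartilage_fraction=joint.cartilage_fraction,
        center_discrepancy=discrepancy,
    )


def validate_model(model: LimbModel) -> LimbModel:
    chain = model.segment_chain()
    if not chain or chain[0] != "pelvis":
        raise ModelValidationError("segments must form a chain rooted at the pelvis")
    for i, seg in enumerate(chain[1:], start=1):
        joint = model.joint_for_child(seg)
        if joint is None:
            raise ModelValidationError(f"segment {seg!r} has no connecting joint")
        if JOINT_PARENT[joint] != chain[i - 1]:
            raise ModelValidationError(
                f"joint {joint!r} does not connect {chain[i - 1]!r} to {seg!r}"
            )
    for name, mtu in model.mtus.items():
        if not mtu.custom and not _muscles.is_known(name):
            raise ModelValidationError(f"unknown MTU acronym {name!r}")
        for seg, _pt in mtu.fixed_points:
            if seg not in model.segments:
                raise ModelValidationError(
                    f"MTU {name!r} attaches to undeclared segment {seg!r}"
                )
        o_idx = SEGMENT_ORDER.index(mtu.origin[0])
        i_idx = SEGMENT_ORDER.index(mtu.insertion[0])
        if o_idx > i_idx:
            raise ModelValidationError(
                f"MTU {name!r}: origin must be proximal to insertion"
            )
        for w in mtu.wrap_surfaces:
            if w not in model.wrap_surfaces:
                raise ModelValidationError(
                    f"MTU {name!r} references undeclared wrap surface {w!r}"
                )
    for w in model.wrap_surfaces.values():
        if w.segment not in model.segments:
            raise ModelValidationError(
                f"wrap surface {w.name!r} attached to undeclared segment {w.segment!r}"
            )
    return model


def assemble_model(spec: dict) -> LimbModel:
    """Build and validate a :class:`LimbModel` from a structured description.

    Muscles that the roster marks absent for the taxon's clade membership
    (e.g. FTI1 and PIFE3 in Phasianidae, ITC outside Dinosauromorpha) are
    dropped from the assembled model.
    """
    taxon = spec.get("taxon", "unnamed")
    clade_path = tuple(spec.get("clade_path", ()))
    segments: dict[str, Segment] = {}
    for s in spec["segments"]:
        seg = Segment(
            name=s["name"],
            reference_length=float(s["reference_length"]),
            parent_joint=s.get("parent_joint"),
        )
        if seg.name not in SEGMENT_ORDER:
            raise ModelValidationError(f"unknown segment name {seg.name!r}")
        segments[seg.name] = seg

    joints: dict[str, JointSpec] = {}
    for j in spec["joints"]:
        name = j["name"]
        raw = JointSpec(
            name=name,
            center=j["center"],
            rom_deg={k: tuple(v) for k, v in j.get("rom_deg", {}).items()},
            locked_defaults_deg=dict(j.get("locked_defaults_deg", {})),
            cartilage_fraction=j.get("cartilage_fraction"),
        )
        if j.get("apply_cartilage", True):
            joints[name] = place_joint(raw, segments[JOINT_PARENT[name]])
        else:
            joints[name] = raw

    wraps: dict[str, WrapSurface] = {}
    for w in spec.get("wrap_surfaces", []):
        surf = WrapSurface(
            name=w["name"],
            shape=w["shape"],
            segment=w["segment"],
            translation=w["translation"],
            rotation=np.asarray(w.get("rotation", np.eye(3)), dtype=float),
            radius=w.get("radius"),
            radii=w.get("radii"),
            half_length=w.get("half_length"),
            wrap_side=w.get("wrap_side"),
        )
        wraps[surf.name] = surf

    mtus: dict[str, MTUPath] = {}
    for m in spec.get("mtus", []):
        name = m["name"]
        base = name.rstrip("ab") if name not in _muscles.ROSTER else name
        custom = bool(m.get("custom", False))
        if not custom and base in _muscles.ROSTER:
            if clade_path and not _muscles.present_in(base, clade_path):
                continue  # lost in this taxon: excluded from the model
        mtus[name] = MTUPath(
            name=name,
            origin=(m["origin"]["segment"], m["origin"]["point"]),
            insertion=(m["insertion"]["segment"], m["insertion"]["point"]),
            via_points=[(v["segment"], v["point"]) for v in m.get("via_points", [])],
            wrap_surfaces=list(m.get("wraps", [])),
            custom=custom,
        )

    model = LimbModel(
        taxon=taxon,
        segments=segments,
        joints=joints,
        mtus=mtus,
        wrap_surfaces=wraps,
        clade_path=clade_path,
        metadata=dict(spec.get("metadata", {})),
    )
    return validate_model(model)


# ---------------------------------------------------------------------------
# model spec files (YAML) and point-cloud input
# ---------------------------------------------------------------------------

def load_model(path: str | Path) -> LimbModel:
    """Read a model spec file (YAML; mm, degrees, right-handed frames)."""
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    return assemble_model(spec)


def save_model_spec(spec: dict, path: str | Path) -> None:
    def _clean(obj):
        if isinstance(obj, np.ndarray):
            return [float(v) for v in obj.ravel()]
        if isinstance(obj, (np.floating, np.integer)):
            return float(obj)
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(_clean(spec), fh, sort_keys=False)


def read_point_cloud(path: str | Path) -> np.ndarray:
    """Read bone geometry as an (n, 3) array of mm coordinates.

    STL (binary or ASCII) and OBJ go through trimesh; ``.asc``/``.xyz``/
    ``.txt`` are whitespace-delimited XYZ lists.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".stl", ".obj"):
        import trimesh

        mesh = trimesh.load(str(path), force="mesh")
        return np.asarray(mesh.vertices, dtype=float)
    if suffix in (".asc", ".xyz", ".txt"):
        pts = np.loadtxt(path, dtype=float)
        if pts.ndim == 1:
            pts = pts.reshape(1, -1)
        return pts[:, :3]
    raise ValueError(f"unsupported point-cloud format: {path.suffix!r}")
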