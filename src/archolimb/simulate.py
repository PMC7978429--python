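"""Synthetic inputs with analytically known answers.

The generators produce every input the pipeline needs without any external
download: parametric limb models whose pulley and straight-line muscles
have closed-form moment arms (recorded as sidecar ground truth, never
derived from the engine under test), whole mock clades whose true leverage
follows a programmed trend, and Brownian-motion trait evolution on the
study tree with the true internal-node states retained.

Default geometry loosely follows theropod limb proportions
(femur : tibiotarsus : tarsometatarsus = 1 : 1.1 : 0.6) and the default
wrap-cylinder radius is 0.1421 x femur length, the proportion the knee
wrap surfaces follow across the study's models.  Realism is cosmetic: all
ground truth comes from the recorded recipes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import LimbModel, assemble_model
from .phylo import TimeTree

DEFAULT_WRAP_RADIUS_FRACTION = 0.1421
SEGMENT_PROPORTIONS = {
    "pelvis": 0.6, "femur": 1.0, "tibiotarsus": 1.1,
    "tarsometatarsus": 0.6, "pes": 0.35,
}


@dataclass(frozen=True)
class MuscleRecipe:
    """One synthetic muscle: how to build it and how to know its truth.

    ``style``: "pulley" (fully wrapped on a joint-coaxial cylinder; true
    |moment arm| = wrap radius at every angle), "straight" (direct
    origin-insertion line; true moment arm from the perpendicular-distance
    formula), or "via" (straight with an interposed via point).
    Attachment offsets are fractions of the owning segment's length in the
    segment frame (+x cranial, +y dorsal, +z lateral).
    """

    name: str
    style: str
    joint: str
    origin_offset: tuple[float, float, float]
    insertion_offset: tuple[float, float, float]
    via_offset: tuple[float, float, float] | None = None
    wrap_radius_fraction: float | None = None  # pulley only
    wrap_sign: float = 1.0  # +1 wraps cranially (flexor-like), -1 caudally


@dataclass(frozen=True)
class LimbGenParams:
    taxon: str = "synthetic"
    femur_length: float = 300.0  # mm
    recipes: tuple[MuscleRecipe, ...] = ()
    wrap_radius_fraction: float = DEFAULT_WRAP_RADIUS_FRACTION
    clade_path: tuple[str, ...] = ()
    seed: int = 0

    def segment_lengths(self) -> dict[str, float]:
        return {
            s: p * self.femur_length for s, p in SEGMENT_PROPORTIONS.items()
        }


# Pulley attachments sit on the joint's sagittal axis plane (x = z = 0) so
# the chord pierces the wrap cylinder near mid-range and lands on the wrong
# side of the forced wrap at the range extremes: the tendon stays fully
# wrapped across the whole range of motion and |r| = wrap radius exactly.
DEFAULT_RECIPES = (
    # hip pulley extensor (caudofemoral-like): wraps the hip cylinder caudally
    MuscleRecipe("CFL", "pulley", "hip", (0.0, 0.35, 0.0), (0.0, -0.45, 0.0),
                 wrap_sign=-1.0),
    # hip straight flexor from the preacetabular ilium (iliotibial-like)
    MuscleRecipe("IT1", "straight", "hip", (0.45, 0.15, 0.0), (0.12, -0.35, 0.0)),
    # hip straight extensor from the ischium (adductor-like)
    MuscleRecipe("ADD1", "straight", "hip", (-0.35, -0.25, 0.0), (0.0, -0.6, -0.05)),
    # knee pulley extensor (femorotibial-like over the condylar cylinder)
    MuscleRecipe("FMTE", "pulley", "knee", (0.0, -0.5, 0.0), (0.0, -0.3, 0.0),
                 wrap_sign=1.0),
    # knee straight flexor (flexor cruris-like)
    MuscleRecipe("FTE", "straight", "knee", (-0.3, -0.05, 0.0), (-0.08, -0.3, 0.0)),
    # ankle pulley plantarflexor (gastrocnemius-like behind the ankle)
    MuscleRecipe("GM", "pulley", "ankle", (0.0, -0.5, 0.0), (0.0, -0.4, 0.0),
                 wrap_sign=-1.0),
    # ankle straight dorsiflexor (tibialis-like)
    MuscleRecipe("TA", "straight", "ankle", (0.12, -0.35, 0.0), (0.1, -0.25, 0.0)),
)

_JOINT_PARENT = {"hip": "pelvis", "knee": "femur", "ankle": "tibiotarsus"}
_JOINT_CHILD = {"hip": "femur", "knee": "tibiotarsus", "ankle": "tarsometatarsus"}


def _build_spec(params: LimbGenParams) -> tuple[dict, dict]:
    """Model spec dict + sidecar ground-truth dict for the recipes."""
    L = params.segment_lengths()
    spec: dict = {
        "taxon": params.taxon,
        "clade_path": list(params.clade_path),
        "segments": [
            {"name": "pelvis", "reference_length": L["pelvis"]},
            {"name": "femur", "reference_length": L["femur"], "parent_joint": "hip"},
            {"name": "tibiotarsus", "reference_length": L["tibiotarsus"],
             "parent_joint": "knee"},
            {"name": "tarsometatarsus", "reference_length": L["tarsometatarsus"],
             "parent_joint": "ankle"},
            {"name": "pes", "reference_length": L["pes"], "parent_joint": "mtp"},
        ],
        "joints": [
            {"name": "hip", "center": [0.0, 0.0, 0.0]},
            {"name": "knee", "center": [0.0, -L["femur"], 0.0]},
            {"name": "ankle", "center": [0.0, -L["tibiotarsus"], 0.0]},
            {"name": "mtp", "center": [0.0, -L["tarsometatarsus"], 0.0]},
        ],
        "wrap_surfaces": [],
        "mtus": [],
    }
    truth: dict = {"taxon": params.taxon, "muscles": {}}
    for rec in params.recipes:
        parent = _JOINT_PARENT[rec.joint]
        child = _JOINT_CHILD[rec.joint]
        Lp, Lc = L[parent], L[child]
        origin = [c * Lp for c in rec.origin_offset]
        insertion = [c * Lc for c in rec.insertion_offset]
        mtu = {
            "name": rec.name,
            "origin": {"segment": parent, "point": origin},
            "insertion": {"segment": child, "point": insertion},
        }
        entry = {"style": rec.style, "joint": rec.joint,
                 "origin": origin, "insertion": insertion}
        if rec.style == "pulley":
            frac = (
                rec.wrap_radius_fraction
                if rec.wrap_radius_fraction is not None
                else params.wrap_radius_fraction
            )
            radius = frac * params.femur_length
            wname = f"{rec.name}_wrap"
            spec["wrap_surfaces"].append({
                "name": wname,
                "shape": "cylinder",
                "segment": parent,
                # coaxial with the joint's FLEXEX axis (local +z)
                "translation": list(_joint_center_in_parent(spec, rec.joint)),
                "radius": radius,
                "half_length": 0.5 * Lp,
                "wrap_side": [rec.wrap_sign, 0.0, 0.0],
            })
            mtu["wraps"] = [wname]
            # tension drives the rotation that shortens the wrapped path:
            # a cranial (+x) wrap side makes the MTU act like a flexor at
            # the hip (positive), extensor sign conventions follow
            entry["true_abs_moment_arm_mm"] = radius
            entry["true_sign"] = _pulley_sign(rec)
        elif rec.style == "via":
            via = [c * Lp for c in rec.via_offset]
            mtu["via_points"] = [{"segment": parent, "point": via}]
            entry["via"] = via
        spec["mtus"].append(mtu)
        truth["muscles"][rec.name] = entry
    return spec, truth


def _joint_center_in_parent(spec: dict, joint: str) -> np.ndarray:
    for j in spec["joints"]:
        if j["name"] == joint:
            center = np.asarray(j["center"], dtype=float)
            break
    # cartilage spacing shifts the effective centre distally at assembly
    from .model import CARTILAGE_FRACTION, JOINT_PARENT as _JP

    parent = _JP[joint]
    for s in spec["segments"]:
        if s["name"] == parent:
            gap = CARTILAGE_FRACTION[joint] * s["reference_length"]
            return center + gap * np.array([0.0, -1.0, 0.0])
    raise KeyError(joint)


def _pulley_sign(rec: MuscleRecipe) -> float:
    """Sign of the pulley's constant moment arm under the study convention.

    Wrapping on the cranial side (+x) means tension shortens the path when
    the child rotates cranially, i.e. drives positive FLEXEX; caudal
    wrapping drives negative FLEXEX.
    """
    return 1.0 if rec.wrap_sign > 0 else -1.0


def generate_limb(params: LimbGenParams) -> tuple[LimbModel, dict]:
    """Build a synthetic limb model plus its sidecar ground truth.

    Deterministic: the same params give an identical model (the generator
    draws nothing at random; ``seed`` exists for schedule-level jitter in
    clade generation).
    """
    spec, truth = _build_spec(params)
    return assemble_model(spec), truth


def straight_line_moment_arm(joint_center, axis, fixed_point, moving_point) -> float:
    """Closed-form moment arm of a straight-line muscle about a revolute
    axis: r = -axis . ((B - c) x (B - A)) / |B - A| for fixed attachment A
    and moving attachment B.  Positive r drives positive rotation about
    ``axis`` (the independent oracle for the virtual-work engine)."""
    c = np.asarray(joint_center, float)
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    A = np.asarray(fixed_point, float)
    B = np.asarray(moving_point, float)
    line = B - A
    L = np.linalg.norm(line)
    return float(-a @ np.cross(B - c, line) / L)


# ---------------------------------------------------------------------------
# clade series with programmed trends
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CladeSchedule:
    """Smooth per-tip deformation of the base geometry.

    ``leverage_scale`` maps tip label -> multiplier on the pulley muscles'
    wrap radius (their true normalized leverage scales identically).
    ``sign_flip`` lists (tip, muscle) pairs whose pulley wrap side (hence
    moment-arm sign) is mirrored.
    """

    leverage_scale: dict[str, float] = field(default_factory=dict)
    sign_flip: tuple[tuple[str, str], ...] = ()


def linear_decline_schedule(tip_order: list[str], total_change: float = -0.5
                            ) -> CladeSchedule:
    """Leverage multipliers declining linearly from 1 to 1 + total_change
    across the given tip order (default a 50% decline)."""
    n = len(tip_order)
    scales = {
        t: 1.0 + total_change * (i / (n - 1)) for i, t in enumerate(tip_order)
    }
    return CladeSchedule(leverage_scale=scales)


def clade_params(base: LimbGenParams, tree: TimeTree,
                 schedule: CladeSchedule) -> dict[str, LimbGenParams]:
    """Per-tip generator parameters after applying the schedule."""
    out = {}
    flips = set(schedule.sign_flip)
    for tip in tree.tip_labels:
        scale = schedule.leverage_scale.get(tip, 1.0)
        recipes = []
        for rec in base.recipes:
            if rec.style == "pulley":
                frac = (
                    rec.wrap_radius_fraction
                    if rec.wrap_radius_fraction is not None
                    else base.wrap_radius_fraction
                )
                new = replace(rec, wrap_radius_fraction=frac * scale)
                if (tip, rec.name) in flips:
                    new = replace(new, wrap_sign=-new.wrap_sign)
                recipes.append(new)
            else:
                recipes.append(rec)
        out[tip] = replace(base, taxon=tip, recipes=tuple(recipes))
    return out


def generate_clade_series(base: LimbGenParams, tree: TimeTree,
                          schedule: CladeSchedule) -> dict[str, tuple[LimbModel, dict]]:
    """One limb model per tree tip, deformed per the schedule.

    True mean normalized moment arms of the pulley muscles follow the
    programmed multipliers exactly (|r| = scale x wrap fraction x femur
    length at every angle), so downstream ancestral estimates can be
    checked against a known trend.
    """
    return {
        tip: generate_limb(params)
        for tip, params in clade_params(base, tree, schedule).items()
    }


# ---------------------------------------------------------------------------
# Brownian motion on the tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BMSimParams:
    sigma2: float = 1.0  # trait variance per Ma
    root_state: float = 0.0
    seed: int = 0
    replicates: int = 1

    def __post_init__(self):
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")


def simulate_bm(timetree: TimeTree, params: BMSimParams
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate Brownian trait evolution root -> tips.

    Each branch adds a Gaussian increment with variance sigma2 x branch
    length.  Returns ``(tips, nodes)`` DataFrames (rows = replicates,
    columns = tip labels / internal-node labels); the true internal states
    support estimator-recovery tests.
    """
    rng = np.random.default_rng(params.seed)
    tree = timetree.tree
    nodes = list(tree.preorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    R = params.replicates
    states = np.zeros((len(nodes), R))
    for n in nodes:
        i = index[id(n)]
        if n.parent_node is None:
            states[i] = params.root_state
        else:
            p = index[id(n.parent_node)]
            sd = math.sqrt(params.sigma2 * n.edge.length)
            states[i] = states[p] + rng.normal(0.0, sd, size=R)
    tip_cols, tip_vals, node_cols, node_vals = [], [], [], []
    for n in nodes:
        i = index[id(n)]
        if n.is_leaf():
            tip_cols.append(n.taxon.label)
            tip_vals.append(states[i])
        else:
            node_cols.append(n.label if n.label else f"node{i}")
            node_vals.append(states[i])
    tips = pd.DataFrame(dict(zip(tip_cols, tip_vals)))
    internals = pd.DataFrame(dict(zip(node_cols, node_vals)))
    return tips, internals
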