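"""Geometric primitives used for joint centres and muscle-path wrapping.

Joints in the limb models are located by fitting simple primitives to the
articular surfaces of the digitised bones: spheres for the hip (femoral head
and acetabulum), cylinders for the knee and ankle condyles.  The same
primitive types double as wrapping surfaces that deflect muscle paths.
All coordinates are millimetres in a right-handed frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares


class DegenerateGeometryError(ValueError):
    """Raised when a primitive fit is underdetermined by the input points."""


@dataclass(frozen=True)
class SpherePrimitive:
    center: np.ndarray  # (3,) mm
    radius: float  # mm
    rms_residual: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.radius <= 0:
            raise ValueError(f"sphere radius must be positive, got {self.radius}")


@dataclass(frozen=True)
class CylinderPrimitive:
    axis_point: np.ndarray  # (3,) mm, long-axis midpoint of the fitted points
    axis_dir: np.ndarray  # (3,) unit vector
    radius: float  # mm
    half_length: float  # mm
    rms_residual: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "axis_point", np.asarray(self.axis_point, dtype=float))
        d = np.asarray(self.axis_dir, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("cylinder axis direction must be nonzero")
        object.__setattr__(self, "axis_dir", d / n)
        if self.radius <= 0:
            raise ValueError(f"cylinder radius must be positive, got {self.radius}")


@dataclass(frozen=True)
class EllipsoidPrimitive:
    center: np.ndarray  # (3,) mm
    radii: np.ndarray  # (3,) mm, semi-axes along `axes` rows
    axes: np.ndarray = field(default=None)  # (3,3) rotation, rows = axis dirs

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        r = np.asarray(self.radii, dtype=float)
        if np.any(r <= 0):
            raise ValueError("ellipsoid radii must all be positive")
        object.__setattr__(self, "radii", r)
        a = np.eye(3) if self.axes is None else np.asarray(self.axes, dtype=float)
        object.__setattr__(self, "axes", a)


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected an (n, 3) point array, got shape {pts.shape}")
    return pts


def fit_sphere(points) -> SpherePrimitive:
    """Least-squares sphere through a point cloud.

    Algebraic (Coope) linear fit followed by one geometric Gauss-Newton
    refinement pass, so noiseless samples are recovered exactly and noisy
    samples get the true geometric least-squares optimum.

    Raises
    ------
    DegenerateGeometryError
        For < 4 points or (near-)coplanar input, where the sphere is
        underdetermined.
    """
    pts = _as_points(points)
    if len(pts) < 4:
        raise DegenerateGeometryError(
            f"sphere fit needs >= 4 points, got {len(pts)}"
        )
    centered = pts - pts.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    scale = max(svals[0], 1e-12)
    if svals[2] / scale < 1e-8:
        raise DegenerateGeometryError(
            "sphere fit is underdetermined: points are coplanar"
        )
    # Algebraic fit: |p|^2 = 2 c.p + (r^2 - |c|^2), linear in (c, k).
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = np.einsum("ij,ij->i", pts, pts)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    radius = float(np.sqrt(max(sol[3] + center @ center, 0.0)))

    def resid(x):
        return np.linalg.norm(pts - x[:3], axis=1) - x[3]

    out = least_squares(resid, np.append(center, radius), method="lm")
    center, radius = out.x[:3], float(out.x[3])
    rms = float(np.sqrt(np.mean(resid(out.x) ** 2)))
    return SpherePrimitive(center=center, radius=abs(radius), rms_residual=rms)


def _cylinder_residuals(x, pts):
    # x = (px, py, pz, theta, phi, r): axis point, axis spherical angles, radius
    theta, phi = x[3], x[4]
    d = np.array(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )
    rel = pts - x[:3]
    radial = rel - np.outer(rel @ d, d)
    return np.linalg.norm(radial, axis=1) - x[5]


def fit_cylinder(points) -> CylinderPrimitive:
    """Least-squares circular cylinder through a point cloud.

    The axis is initialised from the principal directions of the cloud (each
    of the three PCA axes is tried; the best nonlinear refinement wins).  The
    returned ``axis_point`` is the midpoint of the points' axial extent, which
    is where the revolute joint centre is placed when a cylinder is fitted to
    condyles.

    Raises
    ------
    DegenerateGeometryError
        For < 6 points, collinear input, or points confined to a single
        axial station (a ring), where the cylinder is underdetermined.
    """
    pts = _as_points(points)
    if len(pts) < 6:
        raise DegenerateGeometryError(
            f"cylinder fit needs >= 6 points, got {len(pts)}"
        )
    mean = pts.mean(axis=0)
    centered = pts - mean
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    scale = max(svals[0], 1e-12)
    if svals[1] / scale < 1e-8:
        raise DegenerateGeometryError(
            "cylinder fit is underdetermined: points are collinear"
        )

    best = None
    for axis in vt:  # try each principal direction as the axis seed
        theta = float(np.arccos(np.clip(axis[2], -1.0, 1.0)))
        phi = float(np.arctan2(axis[1], axis[0]))
        rel = centered - np.outer(centered @ axis, axis)
        r0 = max(float(np.mean(np.linalg.norm(rel, axis=1))), 1e-6)
        x0 = np.array([*mean, theta, phi, r0])
        try:
            out = least_squares(_cylinder_residuals, x0, args=(pts,), method="lm")
        except Exception:  # pragma: no cover - LM rarely fails here
            continue
        if best is None or out.cost < best.cost:
            best = out
    if best is None:
        raise DegenerateGeometryError("cylinder fit failed to converge")

    x = best.x
    theta, phi = x[3], x[4]
    axis_dir = np.array(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )
    # polarity: hinge axes face right-laterally (+z); fall back to making
    # the dominant component positive when the axis is near the x-y plane
    if abs(axis_dir[2]) > 1e-6:
        if axis_dir[2] < 0:
            axis_dir = -axis_dir
    elif axis_dir[np.argmax(np.abs(axis_dir))] < 0:
        axis_dir = -axis_dir
    stations = (pts - x[:3]) @ axis_dir
    span = float(stations.max() - stations.min())
    radius = abs(float(x[5]))
    if span < max(1e-6, 1e-6 * radius) or span < 1e-8 * scale:
        raise DegenerateGeometryError(
            "cylinder fit is underdetermined: points lie on a single axial ring"
        )
    axis_point = x[:3] + axis_dir * float(stations.min() + stations.max()) / 2.0
    rms = float(np.sqrt(np.mean(_cylinder_residuals(x, pts) ** 2)))
    return CylinderPrimitive(
        axis_point=axis_point,
        axis_dir=axis_dir,
        radius=radius,
        half_length=span / 2.0,
        rms_residual=rms,
    )
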