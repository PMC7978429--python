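"""Muscle-path wrapping over geometric obstacles.

Straight path segments that contact a wrapping surface are replaced by the
shortest tangent - surface-geodesic - tangent route on the prescribed side:

* **cylinder** - the classic obstacle-set construction: tangents and arc are
  solved in the cross-section plane and the axial coordinate is distributed
  linearly along the unrolled path, which is the exact geodesic solution
  (unrolling a cylinder is an isometry).
* **sphere** - tangent lines plus a great-circle arc in the plane through
  the two endpoints and the centre.
* **ellipsoid** - the endpoints are affinely mapped to a unit sphere
  (tangency of a line to a quadric is affine-invariant), the sphere solution
  seeds an on-surface polyline, and the interior points are iteratively
  relaxed on the ellipsoid surface until the length change per pass drops
  below a tolerance (1e-4 x mean radius by default).

All solvers raise :class:`WrapError` when an endpoint lies inside the
obstacle or no valid tangent exists on the required side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

_ARC_POINTS = 24  # polyline resolution of an arc


class WrapError(RuntimeError):
    """Wrapping failed: endpoint inside the obstacle or no valid tangent."""


@dataclass
class WrapResult:
    points: np.ndarray  # (n, 3) full polyline including the two endpoints
    length: float
    wrapped: bool


def _perp_basis(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(w @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(ref, w)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return u, v


def _seg_point_min(q1: np.ndarray, q2: np.ndarray) -> tuple[float, np.ndarray]:
    """Minimum distance from the origin to the segment q1-q2 (any dim)."""
    d = q2 - q1
    denom = float(d @ d)
    t = 0.0 if denom == 0 else float(np.clip(-(q1 @ d) / denom, 0.0, 1.0))
    closest = q1 + t * d
    return float(np.linalg.norm(closest)), closest


def _tangent_point_2d(q: np.ndarray, R: float, eps: int) -> tuple[np.ndarray, float]:
    """Tangent point on the circle |t| = R from external 2D point q, for wrap
    direction ``eps`` (+1 counterclockwise travel along the arc, -1 clockwise),
    such that travel q -> t -> (eps direction along circle) is smooth."""
    d2 = float(q @ q)
    if d2 <= R * R:
        raise WrapError("path endpoint lies inside the wrap surface")
    l = math.sqrt(d2 - R * R)
    qp = np.array([-q[1], q[0]])
    t = (R * R * q + eps * R * l * qp) / d2
    return t, l


def _arc_sweep(phi1: float, phi2: float, eps: int) -> float:
    """Arc angle travelled from phi1 to phi2 moving in direction eps."""
    sweep = (eps * (phi2 - phi1)) % (2.0 * math.pi)
    return sweep


def _solve_circle_2d(q1, q2, R, eps):
    """Tangent-arc-tangent route around the circle |x| = R, direction eps.
    Returns (t1, t2, l1, l2, sweep, planar_length)."""
    t1, l1 = _tangent_point_2d(q1, R, eps)
    # leaving the circle toward q2 reverses the role of the tangent sign
    t2, l2 = _tangent_point_2d(q2, R, -eps)
    sweep = _arc_sweep(math.atan2(t1[1], t1[0]), math.atan2(t2[1], t2[0]), eps)
    return t1, t2, l1, l2, sweep, l1 + R * sweep + l2


def wrap_cylinder(p1, p2, center, axis, radius, side=None) -> WrapResult:
    """Shortest path from p1 to p2 around an infinite circular cylinder.

    ``side``, if given, is a world vector: the path must pass the cylinder
    with the arc on that side of the axis; wrapping then engages even when
    the straight segment clears the surface on the wrong side.  Without a
    side, wrapping engages only on penetration and the shorter of the two
    wrap directions wins.
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    center = np.asarray(center, float)
    w = np.asarray(axis, float)
    w = w / np.linalg.norm(w)
    u, v = _perp_basis(w)

    def to2d(p):
        rel = p - center
        return np.array([rel @ u, rel @ v]), float(rel @ w)

    q1, z1 = to2d(p1)
    q2, z2 = to2d(p2)
    for q in (q1, q2):
        if q @ q < radius * radius * (1 - 1e-12):
            raise WrapError("attachment point lies inside the wrap cylinder")

    dmin, closest = _seg_point_min(q1, q2)
    straight = WrapResult(
        points=np.array([p1, p2]),
        length=float(np.linalg.norm(p2 - p1)),
        wrapped=False,
    )
    side2 = None
    if side is not None:
        s = np.asarray(side, float)
        s2 = np.array([s @ u, s @ v])
        n = np.linalg.norm(s2)
        side2 = s2 / n if n > 1e-12 else None

    if side2 is None:
        if dmin >= radius:
            return straight
        candidates = [+1, -1]
    else:
        wrong_side = (closest @ side2) < 0 and dmin > 0
        if dmin >= radius and not wrong_side:
            return straight
        candidates = [+1, -1]

    best = None
    for eps in candidates:
        try:
            t1, t2, l1, l2, sweep, planar = _solve_circle_2d(q1, q2, radius, eps)
        except WrapError:
            continue
        if sweep > 2.0 * math.pi - 1e-9:
            continue
        if side2 is not None:
            mid_phi = math.atan2(t1[1], t1[0]) + eps * sweep / 2.0
            mid = np.array([math.cos(mid_phi), math.sin(mid_phi)])
            if (mid @ side2) < 0:
                continue
        if best is None or planar < best[-1]:
            best = (eps, t1, t2, l1, l2, sweep, planar)
    if best is None:
        raise WrapError("no valid tangent path on the required side of the cylinder")

    eps, t1, t2, l1, l2, sweep, planar = best
    dz = z2 - z1
    length = math.hypot(planar, dz)
    # axial coordinate varies linearly with unrolled path length
    phi1 = math.atan2(t1[1], t1[0])
    arc_pts = []
    for k in range(_ARC_POINTS + 1):
        f = k / _ARC_POINTS
        phi = phi1 + eps * sweep * f
        s_here = l1 + radius * sweep * f
        z = z1 + dz * s_here / planar if planar > 0 else z1
        arc_pts.append(
            center + radius * (math.cos(phi) * u + math.sin(phi) * v) + z * w
        )
    points = np.vstack([p1, np.array(arc_pts), p2])
    return WrapResult(points=points, length=length, wrapped=True)


def wrap_sphere(p1, p2, center, radius) -> WrapResult:
    """Shortest path from p1 to p2 around a sphere: tangents plus a
    great-circle arc in the plane of p1, p2 and the centre.  Engages only
    when the straight segment penetrates the sphere (for which the shortest
    route is unique, so no side is needed)."""
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    center = np.asarray(center, float)
    r1 = p1 - center
    r2 = p2 - center
    for r in (r1, r2):
        if r @ r < radius * radius * (1 - 1e-12):
            raise WrapError("attachment point lies inside the wrap sphere")
    dmin, _ = _seg_point_min(r1, r2)
    if dmin >= radius:
        return WrapResult(
            points=np.array([p1, p2]),
            length=float(np.linalg.norm(p2 - p1)),
            wrapped=False,
        )
    # plane basis: e1 along r1, e2 completing it within span(r1, r2)
    e1 = r1 / np.linalg.norm(r1)
    r2_perp = r2 - (r2 @ e1) * e1
    n = np.linalg.norm(r2_perp)
    if n < 1e-12:  # collinear with the centre: wrap plane is degenerate
        raise WrapError("endpoints are collinear with the sphere centre")
    e2 = r2_perp / n
    q1 = np.array([r1 @ e1, r1 @ e2])
    q2 = np.array([r2 @ e1, r2 @ e2])
    best = None
    for eps in (+1, -1):
        try:
            sol = _solve_circle_2d(q1, q2, radius, eps)
        except WrapError:
            continue
        if sol[4] > 2.0 * math.pi - 1e-9:
            continue
        if best is None or sol[-1] < best[1][-1]:
            best = (eps, sol)
    if best is None:
        raise WrapError("no valid tangent path around the wrap sphere")
    eps, (t1, t2, l1, l2, sweep, planar) = best
    phi1 = math.atan2(t1[1], t1[0])
    arc_pts = []
    for k in range(_ARC_POINTS + 1):
        phi = phi1 + eps * sweep * (k / _ARC_POINTS)
        arc_pts.append(center + radius * (math.cos(phi) * e1 + math.sin(phi) * e2))
    points = np.vstack([p1, np.array(arc_pts), p2])
    return WrapResult(points=points, length=planar, wrapped=True)


def _project_unit(y: np.ndarray) -> np.ndarray:
    return y / np.linalg.norm(y)


def wrap_ellipsoid(p1, p2, center, radii, rotation=None,
                   tol_factor: float = 1e-4, max_iter: int = 500) -> WrapResult:
    """Approximate shortest path from p1 to p2 around a triaxial ellipsoid.

    The problem is mapped affinely onto the unit sphere, the spherical
    tangent-arc solution (a valid tangent path, since tangency survives the
    affine map) seeds an on-surface polyline, and the interior points are
    relaxed iteratively (neighbour averaging + reprojection to the surface)
    until the length improvement per pass is below
    ``tol_factor x mean(radii)``.
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    center = np.asarray(center, float)
    radii = np.asarray(radii, float)
    rot = np.eye(3) if rotation is None else np.asarray(rotation, float)

    def to_unit(p):  # world -> unit-sphere space
        return (rot.T @ (p - center)) / radii

    def to_world(y):
        return center + rot @ (y * radii)

    y1, y2 = to_unit(p1), to_unit(p2)
    for y in (y1, y2):
        if y @ y < 1.0 - 1e-12:
            raise WrapError("attachment point lies inside the wrap ellipsoid")
    dmin, _ = _seg_point_min(y1, y2)
    if dmin >= 1.0:
        return WrapResult(
            points=np.array([p1, p2]),
            length=float(np.linalg.norm(p2 - p1)),
            wrapped=False,
        )
    seed = wrap_sphere(y1, y2, np.zeros(3), 1.0)
    ys = [to_unit(to_world(y)) for y in seed.points[1:-1]]  # arc points, unit space
    # relax on the ellipsoid surface, in world space
    pts = [to_world(_project_unit(y)) for y in ys]

    def total_len(interior):
        chain = [p1, *interior, p2]
        return float(
            sum(np.linalg.norm(b - a) for a, b in zip(chain[:-1], chain[1:]))
        )

    tol = tol_factor * float(np.mean(radii))
    prev = total_len(pts)
    for _ in range(max_iter):
        new = list(pts)
        for i in range(len(pts)):
            left = p1 if i == 0 else new[i - 1]
            right = p2 if i == len(pts) - 1 else pts[i + 1]
            target = 0.5 * (left + right)
            y = to_unit(target)
            ny = np.linalg.norm(y)
            if ny >= 1.0:  # midpoint already clear of the surface
                new[i] = target
            else:
                new[i] = to_world(y / ny)
        pts = new
        cur = total_len(pts)
        if prev - cur < tol:
            break
        prev = cur
    points = np.vstack([p1, np.array(pts), p2])
    return WrapResult(points=points, length=total_len(pts), wrapped=True)
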