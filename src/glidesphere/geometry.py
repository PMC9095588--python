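"""Sphere geometry: coordinate conventions, metric quantities, trajectories.

Conventions shared by every other module:

* colatitude ``theta`` is measured from the +z pole, ``theta in [0, pi]``;
  the equator is ``theta = pi/2``;
* azimuth ``phi in [0, 2*pi)``, measured from +x toward +y;
* at the poles the azimuth is undefined mathematically and returned as 0;
* Cartesian positions are in micrometres, in the laboratory frame; the
  vesicle-centred frame is obtained by subtracting ``SphereGeometry.center``.

The central kinematic quantity is the arc-length speed

    v = R * acos(r_i . r_{i+1} / R^2) / dt

of a structure between two consecutive on-sphere positions.  The central
angle itself is evaluated with the numerically stable
``atan2(|r1 x r2|, r1 . r2)`` form, which keeps full precision for the
nanometre-scale steps (micro-radian separations on an ~18 um sphere) that
slow, jammed structures exhibit; for well-separated points it agrees with
the plain arccos form to better than 1e-10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: default relative tolerance for declaring a point "on sphere"
ON_SPHERE_RTOL = 1e-6


class OffSphereError(ValueError):
    """A point declared on-sphere lies beyond the allowed radial tolerance."""


@dataclass(frozen=True)
class SphereGeometry:
    """Centre (um, lab frame) and radius R (um) of a fitted vesicle sphere."""

    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        center = np.asarray(self.center, dtype=float)
        if center.shape != (3,):
            raise ValueError(f"center must be a 3-vector, got shape {center.shape}")
        if not np.all(np.isfinite(center)):
            raise ValueError("center must be finite")
        object.__setattr__(self, "center", center)
        if not np.isfinite(self.radius) or self.radius <= 0:
            raise ValueError(f"radius must be positive and finite, got {self.radius}")

    def to_centered(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) - self.center

    def from_centered(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) + self.center


def _check_on_sphere(points: np.ndarray, geometry: SphereGeometry,
                     rtol: float = ON_SPHERE_RTOL) -> None:
    r = np.linalg.norm(geometry.to_centered(points), axis=-1)
    err = np.abs(r - geometry.radius)
    if np.any(err > rtol * geometry.radius):
        raise OffSphereError(
            f"point(s) off sphere by up to {float(np.max(err)):.3g} um "
            f"(tolerance {rtol * geometry.radius:.3g} um)")


def spherical_to_cartesian(theta, phi, geometry: SphereGeometry) -> np.ndarray:
    """Map angular position(s) to lab-frame Cartesian positions on the sphere.

    r = center + R (cos(phi) sin(theta), sin(phi) sin(theta), cos(theta)).
    Accepts scalars or arrays; returns shape (..., 3).
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any((theta < 0) | (theta > np.pi)):
        raise ValueError("theta must lie in [0, pi]")
    st = np.sin(theta)
    xyz = np.stack([np.cos(phi) * st, np.sin(phi) * st, np.cos(theta)], axis=-1)
    return geometry.from_centered(geometry.radius * xyz)


def cartesian_to_spherical(points, geometry: SphereGeometry,
                           rtol: float = ON_SPHERE_RTOL):
    """Inverse map; returns (theta, phi) with phi := 0 at the poles.

    Raises :class:`OffSphereError` for points off the sphere beyond ``rtol``.
    """
    points = np.asarray(points, dtype=float)
    _check_on_sphere(points, geometry, rtol)
    c = geometry.to_centered(points)
    r = np.linalg.norm(c, axis=-1)
    theta = np.arccos(np.clip(c[..., 2] / r, -1.0, 1.0))
    phi = np.mod(np.arctan2(c[..., 1], c[..., 0]), 2 * np.pi)
    # pole convention: azimuth pinned to zero where sin(theta) vanishes
    at_pole = np.sin(theta) * r < 1e-12 * geometry.radius
    phi = np.where(at_pole, 0.0, phi)
    if points.ndim == 1:
        return float(theta), float(phi)
    return theta, phi


def project_to_sphere(points, geometry: SphereGeometry) -> np.ndarray:
    """Radially project nearly-on-sphere points exactly onto the sphere."""
    c = geometry.to_centered(np.asarray(points, dtype=float))
    r = np.linalg.norm(c, axis=-1, keepdims=True)
    if np.any(r == 0):
        raise ValueError("cannot radially project the sphere centre")
    return geometry.from_centered(c * (geometry.radius / r))


def confocal_to_sphere(x, y, geometry: SphereGeometry,
                       hemisphere: str = "upper") -> np.ndarray:
    """Lift a confocal in-plane click (x, y), relative to the sphere centre,
    onto the sphere: r = (x, y, +-sqrt(R^2 - x^2 - y^2)).

    ``hemisphere`` selects the sign of z ("upper" -> +, "lower" -> -).
    """
    if hemisphere not in ("upper", "lower"):
        raise ValueError(f"hemisphere must be 'upper' or 'lower', got {hemisphere!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho2 = x * x + y * y
    R2 = geometry.radius ** 2
    if np.any(rho2 > R2 * (1 + 4 * ON_SPHERE_RTOL)):
        raise ValueError(
            f"point outside projected disk: x^2+y^2 = {float(np.max(rho2)):.4g} "
            f"> R^2 = {R2:.4g}")
    z = np.sqrt(np.maximum(R2 - rho2, 0.0))
    if hemisphere == "lower":
        z = -z
    return geometry.from_centered(np.stack([x, y, z], axis=-1))


def central_angle(p1, p2, geometry: SphereGeometry, *, check: bool = True,
                  rtol: float = ON_SPHERE_RTOL) -> np.ndarray | float:
    """Angle (rad) subtended at the sphere centre by two on-sphere points.

    Uses atan2(|r1 x r2|, r1 . r2): exact at 0 and pi, and precise for the
    tiny separations where arccos of the dot product loses digits.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if check:
        _check_on_sphere(p1, geometry, rtol)
        _check_on_sphere(p2, geometry, rtol)
    a = geometry.to_centered(p1)
    b = geometry.to_centered(p2)
    cross = np.linalg.norm(np.cross(a, b), axis=-1)
    dot = np.sum(a * b, axis=-1)
    ang = np.arctan2(cross, dot)
    return float(ang) if np.ndim(ang) == 0 else ang


def arc_speed(p_i, p_next, dt, geometry: SphereGeometry, *,
              check: bool = True) -> np.ndarray | float:
    """Arc-length speed (um/s) between consecutive on-sphere positions."""
    dt = np.asarray(dt, dtype=float)
    if np.any(dt <= 0):
        raise ValueError("dt must be positive")
    ang = central_angle(p_i, p_next, geometry, check=check)
    return geometry.radius * ang / dt


def unwrap_azimuth(phis) -> np.ndarray:
    """Remove 2*pi jumps from an azimuth series (first element unchanged).

    After unwrapping, successive differences have magnitude <= pi and the
    series re-wrapped mod 2*pi recovers the input.
    """
    phis = np.asarray(phis, dtype=float)
    if phis.size == 0:
        raise ValueError("empty azimuth sequence")
    return np.unwrap(phis)


def rotate_points(points, rotation, *, center=None, atol: float = 1e-10) -> np.ndarray:
    """Apply a proper rotation matrix to points (about ``center`` if given)."""
    R = np.asarray(rotation, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=atol):
        raise ValueError("rotation must be a 3x3 orthogonal matrix")
    if np.linalg.det(R) < 0:
        raise ValueError("rotation must be proper (det = +1)")
    pts = np.asarray(points, dtype=float)
    if center is None:
        return pts @ R.T
    center = np.asarray(center, dtype=float)
    return (pts - center) @ R.T + center


def rotation_about_axis(axis, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about ``axis`` by ``angle`` (rad)."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("axis must be nonzero")
    k = axis / n
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped positions of one structure constrained to a sphere.

    ``positions`` are lab-frame Cartesian (n, 3) um; ``times`` (n,) s,
    strictly increasing.  Points further than the on-sphere tolerance are
    radially projected with a logged warning (manual clicks are never
    exactly on-sphere); use ``strict=True`` to make that an error instead.
    """

    times: np.ndarray
    positions: np.ndarray
    geometry: SphereGeometry
    strict: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.positions, dtype=float)
        if t.ndim != 1 or t.size < 1:
            raise ValueError("times must be a nonempty 1-D array")
        if p.shape != (t.size, 3):
            raise ValueError(f"positions must have shape ({t.size}, 3), got {p.shape}")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        r = np.linalg.norm(self.geometry.to_centered(p), axis=-1)
        err = np.abs(r - self.geometry.radius)
        tol = ON_SPHERE_RTOL * self.geometry.radius
        if np.any(err > tol):
            if self.strict:
                raise OffSphereError(
                    f"trajectory point off sphere by {float(np.max(err)):.3g} um")
            logger.warning(
                "projecting %d trajectory point(s) onto the sphere "
                "(max radial error %.3g um)", int(np.sum(err > tol)), float(np.max(err)))
            p = project_to_sphere(p, self.geometry)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", p)

    def __len__(self) -> int:
        return self.times.size

    @classmethod
    def from_angles(cls, times, theta, phi, geometry: SphereGeometry) -> "Trajectory":
        theta = np.broadcast_to(np.asarray(theta, dtype=float), np.shape(times))
        phi = np.broadcast_to(np.asarray(phi, dtype=float), np.shape(times))
        return cls(np.asarray(times, dtype=float),
                   spherical_to_cartesian(theta, phi, geometry), geometry)

    def angles(self):
        """(theta, phi) arrays of the trajectory."""
        return cartesian_to_spherical(self.positions, self.geometry)

    @property
    def dt(self) -> float:
        """Uniform frame interval (s); raises if sampling is irregular."""
        if len(self) < 2:
            raise ValueError("trajectory has fewer than 2 points")
        d = np.diff(self.times)
        if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
            raise ValueError("trajectory is not regularly sampled")
        return float(d[0])
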