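"""Continuous-domain geometric primitives used to describe phantom scenes.

Each primitive supports a vectorized point-membership test, a conservative
"near surface" band test (used to decide which voxels need subvoxel
supersampling), rigid transformation, and an axis-aligned bounding box.
All lengths are millimetres; world coordinates are RAS-like axis-aligned mm.

Membership tests take three broadcastable coordinate arrays ``(x, y, z)``
rather than packed ``(N, 3)`` points, so a regular grid can be evaluated
from its 1-D axis vectors without materializing the full coordinate cube.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Sphere", "Ellipsoid", "EllipticCylinder", "Box", "primitive_from_dict"]


def _as_vec3(x) -> np.ndarray:
    return np.asarray(x, dtype=float).reshape(3)


def _identity_rot() -> np.ndarray:
    return np.eye(3)


def _local_coords(x, y, z, center: np.ndarray, rotation: np.ndarray):
    """Coordinates in the primitive's frame: R^T (p - c), broadcast-friendly."""
    dx, dy, dz = x - center[0], y - center[1], z - center[2]
    if rotation is None or np.array_equal(rotation, np.eye(3)):
        return dx, dy, dz
    r = rotation
    return (
        dx * r[0, 0] + dy * r[1, 0] + dz * r[2, 0],
        dx * r[0, 1] + dy * r[1, 1] + dz * r[2, 1],
        dx * r[0, 2] + dy * r[1, 2] + dz * r[2, 2],
    )


@dataclass(frozen=True)
class Sphere:
    center: np.ndarray
    radius: float

    def __post_init__(self):
        object.__setattr__(self, "center", _as_vec3(self.center))
        if not self.radius > 0:
            raise ValueError(f"sphere radius must be > 0, got {self.radius}")

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    def _d2(self, x, y, z):
        c = self.center
        return (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2

    def contains(self, x, y, z) -> np.ndarray:
        return self._d2(x, y, z) <= self.radius**2

    def near_surface(self, x, y, z, band: float) -> np.ndarray:
        d2 = self._d2(x, y, z)
        lo = max(self.radius - band, 0.0)
        return (d2 >= lo**2) & (d2 <= (self.radius + band) ** 2)

    def transformed(self, rot: np.ndarray, trans: np.ndarray) -> "Sphere":
        return Sphere(rot @ self.center + trans, self.radius)

    def aabb(self):
        return self.center - self.radius, self.center + self.radius

    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius**3

    def to_dict(self) -> dict:
        return {"type": "sphere", "center": self.center.tolist(), "radius": self.radius}


@dataclass(frozen=True)
class Ellipsoid:
    center: np.ndarray
    semi_axes: np.ndarray
    rotation: np.ndarray = field(default_factory=_identity_rot)

    def __post_init__(self):
        object.__setattr__(self, "center", _as_vec3(self.center))
        object.__setattr__(self, "semi_axes", _as_vec3(self.semi_axes))
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float).reshape(3, 3))
        if not np.all(self.semi_axes > 0):
            raise ValueError("ellipsoid semi-axes must be > 0")

    def _rho2(self, x, y, z):
        px, py, pz = _local_coords(x, y, z, self.center, self.rotation)
        a = self.semi_axes
        return (px / a[0]) ** 2 + (py / a[1]) ** 2 + (pz / a[2]) ** 2

    def contains(self, x, y, z) -> np.ndarray:
        return self._rho2(x, y, z) <= 1.0

    def near_surface(self, x, y, z, band: float) -> np.ndarray:
        # |rho - 1| * min_axis under-estimates the surface distance by at
        # most max_axis/min_axis near the surface; widen conservatively.
        rho = np.sqrt(self._rho2(x, y, z))
        amin = float(np.min(self.semi_axes))
        amax = float(np.max(self.semi_axes))
        eff = band * (amax / amin) / amin
        return np.abs(rho - 1.0) <= eff

    def transformed(self, rot: np.ndarray, trans: np.ndarray) -> "Ellipsoid":
        return Ellipsoid(rot @ self.center + trans, self.semi_axes, rot @ self.rotation)

    def aabb(self):
        ext = np.sqrt(np.sum((self.rotation * self.semi_axes) ** 2, axis=1))
        return self.center - ext, self.center + ext

    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * float(np.prod(self.semi_axes))

    def to_dict(self) -> dict:
        return {
            "type": "ellipsoid",
            "center": self.center.tolist(),
            "semi_axes": self.semi_axes.tolist(),
            "rotation": self.rotation.tolist(),
        }


@dataclass(frozen=True)
class EllipticCylinder:
    """Cylinder with an elliptical cross-section in the local xy plane."""

    center: np.ndarray
    semi_axis_x: float
    semi_axis_y: float
    half_height: float
    rotation: np.ndarray = field(default_factory=_identity_rot)

    def __post_init__(self):
        object.__setattr__(self, "center", _as_vec3(self.center))
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float).reshape(3, 3))
        if not (self.semi_axis_x > 0 and self.semi_axis_y > 0 and self.half_height > 0):
            raise ValueError("cylinder dimensions must be > 0")

    def contains(self, x, y, z) -> np.ndarray:
        px, py, pz = _local_coords(x, y, z, self.center, self.rotation)
        r2 = (px / self.semi_axis_x) ** 2 + (py / self.semi_axis_y) ** 2
        return (r2 <= 1.0) & (np.abs(pz) <= self.half_height)

    def near_surface(self, x, y, z, band: float) -> np.ndarray:
        px, py, pz = _local_coords(x, y, z, self.center, self.rotation)
        amin = min(self.semi_axis_x, self.semi_axis_y)
        amax = max(self.semi_axis_x, self.semi_axis_y)
        rho = np.sqrt((px / self.semi_axis_x) ** 2 + (py / self.semi_axis_y) ** 2)
        az = np.abs(pz)
        lateral = (np.abs(rho - 1.0) <= band * (amax / amin) / amin) & (
            az <= self.half_height + band
        )
        caps = (np.abs(az - self.half_height) <= band) & (rho <= 1.0 + band / amin)
        return lateral | caps

    def transformed(self, rot: np.ndarray, trans: np.ndarray) -> "EllipticCylinder":
        return EllipticCylinder(
            rot @ self.center + trans,
            self.semi_axis_x,
            self.semi_axis_y,
            self.half_height,
            rot @ self.rotation,
        )

    def aabb(self):
        half = np.array([self.semi_axis_x, self.semi_axis_y, self.half_height])
        ext = np.abs(self.rotation) @ half
        return self.center - ext, self.center + ext

    def volume(self) -> float:
        return np.pi * self.semi_axis_x * self.semi_axis_y * 2.0 * self.half_height

    def to_dict(self) -> dict:
        return {
            "type": "elliptic_cylinder",
            "center": self.center.tolist(),
            "semi_axis_x": self.semi_axis_x,
            "semi_axis_y": self.semi_axis_y,
            "half_height": self.half_height,
            "rotation": self.rotation.tolist(),
        }


@dataclass(frozen=True)
class Box:
    center: np.ndarray
    half_sizes: np.ndarray
    rotation: np.ndarray = field(default_factory=_identity_rot)

    def __post_init__(self):
        object.__setattr__(self, "center", _as_vec3(self.center))
        object.__setattr__(self, "half_sizes", _as_vec3(self.half_sizes))
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float).reshape(3, 3))
        if not np.all(self.half_sizes > 0):
            raise ValueError("box half sizes must be > 0")

    def contains(self, x, y, z) -> np.ndarray:
        px, py, pz = _local_coords(x, y, z, self.center, self.rotation)
        h = self.half_sizes
        return (np.abs(px) <= h[0]) & (np.abs(py) <= h[1]) & (np.abs(pz) <= h[2])

    def near_surface(self, x, y, z, band: float) -> np.ndarray:
        px, py, pz = _local_coords(x, y, z, self.center, self.rotation)
        h = self.half_sizes
        ax, ay, az = np.abs(px), np.abs(py), np.abs(pz)
        expanded = (ax <= h[0] + band) & (ay <= h[1] + band) & (az <= h[2] + band)
        shrunk = (ax <= h[0] - band) & (ay <= h[1] - band) & (az <= h[2] - band)
        return expanded & ~shrunk

    def transformed(self, rot: np.ndarray, trans: np.ndarray) -> "Box":
        return Box(rot @ self.center + trans, self.half_sizes, rot @ self.rotation)

    def aabb(self):
        ext = np.abs(self.rotation) @ self.half_sizes
        return self.center - ext, self.center + ext

    def volume(self) -> float:
        return float(np.prod(2.0 * self.half_sizes))

    def to_dict(self) -> dict:
        return {
            "type": "box",
            "center": self.center.tolist(),
            "half_sizes": self.half_sizes.tolist(),
            "rotation": self.rotation.tolist(),
        }


_PRIMITIVES = {
    "sphere": lambda d: Sphere(d["center"], d["radius"]),
    "ellipsoid": lambda d: Ellipsoid(d["center"], d["semi_axes"], d.get("rotation", np.eye(3))),
    "elliptic_cylinder": lambda d: EllipticCylinder(
        d["center"],
        d["semi_axis_x"],
        d["semi_axis_y"],
        d["half_height"],
        d.get("rotation", np.eye(3)),
    ),
    "box": lambda d: Box(d["center"], d["half_sizes"], d.get("rotation", np.eye(3))),
}


def primitive_from_dict(d: dict):
    try:
        factory = _PRIMITIVES[d["type"]]
    except KeyError as exc:
        raise ValueError(f"unknown primitive type {d.get('type')!r}") from exc
    return factory(d)
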