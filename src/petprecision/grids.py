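"""Voxel grid geometry and the in-memory activity image container.

Conventions: voxel indices are 0-based; ``origin`` is the world (mm)
coordinate of the centre of voxel (0, 0, 0); each voxel owns the half-open
extent ``[centre - voxel/2, centre + voxel/2)``; axes are world axis-aligned
(RAS order x, y, z matching array axes 0, 1, 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "ActivityImage"]


@dataclass(frozen=True)
class GridSpec:
    voxel_size: tuple  # mm per axis
    shape: tuple  # number of voxels per axis
    origin: tuple = (0.0, 0.0, 0.0)  # mm, centre of voxel (0,0,0)

    def __post_init__(self):
        vs = tuple(float(v) for v in np.asarray(self.voxel_size).reshape(3))
        sh = tuple(int(n) for n in np.asarray(self.shape).reshape(3))
        og = tuple(float(o) for o in np.asarray(self.origin).reshape(3))
        if not all(v > 0 for v in vs):
            raise ValueError(f"voxel sizes must be > 0, got {vs}")
        if not all(n > 0 for n in sh):
            raise ValueError(f"grid dimensions must be > 0, got {sh}")
        object.__setattr__(self, "voxel_size", vs)
        object.__setattr__(self, "shape", sh)
        object.__setattr__(self, "origin", og)

    # -- geometry -----------------------------------------------------------
    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def voxel_volume_mL(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def axis_centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.voxel_size[axis] * np.arange(self.shape[axis])

    def world_bounds(self):
        """(lo, hi) mm corners of the full grid extent (voxel edges)."""
        o = np.asarray(self.origin)
        v = np.asarray(self.voxel_size)
        n = np.asarray(self.shape)
        lo = o - v / 2.0
        hi = o + (n - 1) * v + v / 2.0
        return lo, hi

    def covers(self, lo, hi, tol: float = 1e-9) -> bool:
        glo, ghi = self.world_bounds()
        return bool(np.all(glo <= np.asarray(lo) + tol) and np.all(ghi >= np.asarray(hi) - tol))

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(idx) * np.asarray(self.voxel_size)

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel indices for world points."""
        return (np.asarray(pts) - np.asarray(self.origin)) / np.asarray(self.voxel_size)

    def affine(self) -> np.ndarray:
        """4x4 RAS affine suitable for NIfTI-1 headers."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size)
        aff[:3, 3] = self.origin
        return aff

    @classmethod
    def cover(cls, lo, hi, voxel_size, margin: float = 0.0) -> "GridSpec":
        """Smallest grid with the given voxel size covering [lo, hi] + margin.

        The grid is centred on the midpoint of the requested bounds so that
        symmetric scenes land symmetrically on the lattice.
        """
        lo = np.asarray(lo, dtype=float) - margin
        hi = np.asarray(hi, dtype=float) + margin
        vs = np.asarray(voxel_size, dtype=float).reshape(3)
        n = np.maximum(1, np.ceil((hi - lo) / vs - 1e-9).astype(int))
        mid = (lo + hi) / 2.0
        origin = mid - (n - 1) * vs / 2.0
        return cls(tuple(vs), tuple(int(i) for i in n), tuple(origin))

    def refine(self, factors) -> "GridSpec":
        """Subdivide each voxel by integer factors (for fine-grid simulation)."""
        f = np.asarray(factors, dtype=int).reshape(3)
        if np.any(f < 1):
            raise ValueError("refinement factors must be >= 1")
        vs = np.asarray(self.voxel_size) / f
        origin = np.asarray(self.origin) - np.asarray(self.voxel_size) / 2.0 + vs / 2.0
        return GridSpec(tuple(vs), tuple(np.asarray(self.shape) * f), tuple(origin))


@dataclass
class ActivityImage:
    """A voxelized activity-concentration volume (kBq/mL) with provenance."""

    values: np.ndarray
    grid: GridSpec
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if tuple(self.values.shape) != tuple(self.grid.shape):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("activity image contains non-finite values")

    @property
    def total_activity_kBq(self) -> float:
        return float(self.values.sum()) * self.grid.voxel_volume_mL

    def with_values(self, values: np.ndarray, step: dict | None = None) -> "ActivityImage":
        prov = list(self.provenance)
        if step is not None:
            prov.append(step)
        return ActivityImage(values, self.grid, prov)

    def copy(self) -> "ActivityImage":
        return ActivityImage(self.values.copy(), self.grid, list(self.provenance))

    def find_step(self, op: str):
        """Most recent provenance record with the given ``op`` name, or None."""
        for step in reversed(self.provenance):
            if step.get("op") == op:
                return step
        return None
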