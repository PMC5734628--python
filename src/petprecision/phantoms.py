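"""Digital phantom scenes and their voxelization.

A :class:`Scene` is a continuous-domain description of activity
compartments: an ordered list of geometric primitives, each carrying a true
activity concentration in kBq/mL. Later compartments override earlier ones
(paint order), and points outside every compartment read zero (air). This
representation stands in for the physical phantoms used in quantitative PET
harmonization work:

* the NEMA NU-2 image-quality (IQ) body phantom — six fillable spheres of
  10–37 mm inner diameter on a 114.4 mm ring inside a ~9400 mL background
  compartment, filled at roughly 10:1 sphere-to-background contrast;
* a procedural gray/white brain scene standing in for an anthropomorphic
  brain phantom: an ellipsoidal cortical gray shell around white matter,
  plus deep gray nuclei (caudate and putamen analogs), with a matching
  20-region VOI template (ten gray, ten white, five per tissue per
  hemisphere).

Voxelization computes, per voxel, the volume-weighted average concentration
using subvoxel supersampling; voxels far from any compartment surface are
resolved with a single centre sample, so only boundary voxels pay the
supersampling cost. This is the tissue-fraction (voxel sampling) effect in
its pure form, before any resolution blur is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from ._primitives import Box, Ellipsoid, EllipticCylinder, Sphere, primitive_from_dict
from .grids import ActivityImage, GridSpec

__all__ = [
    "Compartment",
    "Scene",
    "BrainTemplate",
    "NEMA_SPHERE_DIAMETERS_MM",
    "build_iq_scene",
    "build_mini_iq_scene",
    "build_brain_scene",
    "voxelize_scene",
]

#: Inner diameters (mm) of the six fillable spheres of the NEMA NU-2 IQ phantom.
NEMA_SPHERE_DIAMETERS_MM = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)

#: Radius (mm) of the ring on which the sphere centres sit (114.4 mm diameter).
NEMA_RING_RADIUS_MM = 57.2

#: Background compartment volume (mL) of the IQ phantom.
NEMA_BACKGROUND_VOLUME_ML = 9400.0


@dataclass(frozen=True)
class Compartment:
    primitive: object
    concentration: float  # kBq/mL
    name: str = ""

    def __post_init__(self):
        if self.concentration < 0:
            raise ValueError(
                f"compartment {self.name!r}: concentration must be >= 0, "
                f"got {self.concentration}"
            )


@dataclass(frozen=True)
class Scene:
    """Ordered compartments painted over an empty (zero-activity) domain."""

    compartments: tuple
    background_concentration: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "compartments", tuple(self.compartments))
        if self.background_concentration < 0:
            raise ValueError("background concentration must be >= 0")

    # -- evaluation ---------------------------------------------------------
    def evaluate(self, x, y, z) -> np.ndarray:
        """Concentration (kBq/mL) at world points (broadcastable coordinate
        arrays), paint-order override."""
        shape = np.broadcast_shapes(np.shape(x), np.shape(y), np.shape(z))
        out = np.zeros(shape, dtype=float)
        for comp in self.compartments:
            mask = comp.primitive.contains(x, y, z)
            out[np.broadcast_to(mask, shape)] = comp.concentration
        return out

    def compartment_index(self, x, y, z) -> np.ndarray:
        """Index of the winning compartment per point (-1 where outside all)."""
        shape = np.broadcast_shapes(np.shape(x), np.shape(y), np.shape(z))
        out = np.full(shape, -1, dtype=np.int32)
        for i, comp in enumerate(self.compartments):
            out[np.broadcast_to(comp.primitive.contains(x, y, z), shape)] = i
        return out

    def near_any_surface(self, x, y, z, band: float) -> np.ndarray:
        shape = np.broadcast_shapes(np.shape(x), np.shape(y), np.shape(z))
        out = np.zeros(shape, dtype=bool)
        for comp in self.compartments:
            out |= np.broadcast_to(comp.primitive.near_surface(x, y, z, band), shape)
        return out

    # -- geometry -----------------------------------------------------------
    def bounds(self):
        los, his = zip(*(c.primitive.aabb() for c in self.compartments))
        return np.min(los, axis=0), np.max(his, axis=0)

    def transformed(self, rot: np.ndarray, trans: np.ndarray) -> "Scene":
        comps = tuple(
            Compartment(c.primitive.transformed(rot, trans), c.concentration, c.name)
            for c in self.compartments
        )
        return Scene(comps, self.background_concentration)

    # -- convenience --------------------------------------------------------
    def spheres(self):
        """(name, Sphere, concentration) for every spherical compartment."""
        return [
            (c.name, c.primitive, c.concentration)
            for c in self.compartments
            if isinstance(c.primitive, Sphere)
        ]

    def __getitem__(self, name: str) -> Compartment:
        for c in self.compartments:
            if c.name == name:
                return c
        raise KeyError(name)

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "background_concentration": self.background_concentration,
                "compartments": [
                    {
                        "name": c.name,
                        "concentration": c.concentration,
                        "primitive": c.primitive.to_dict(),
                    }
                    for c in self.compartments
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "Scene":
        data = json.loads(text)
        comps = tuple(
            Compartment(primitive_from_dict(c["primitive"]), c["concentration"], c["name"])
            for c in data["compartments"]
        )
        return cls(comps, data["background_concentration"])


# ---------------------------------------------------------------------------
# NEMA IQ phantom
# ---------------------------------------------------------------------------


def build_iq_scene(
    sphere_concentration: float,
    background_concentration: float,
    *,
    sphere_diameters=NEMA_SPHERE_DIAMETERS_MM,
    ring_radius_mm: float = NEMA_RING_RADIUS_MM,
    background_volume_mL: float = NEMA_BACKGROUND_VOLUME_ML,
    background_semi_axes=(150.0, 105.0),
) -> Scene:
    """NEMA IQ phantom analog: six spheres on a ring in a 9400 mL background.

    The spheres sit coplanarly (z = 0) on a ring of 57.2 mm radius, the
    standard NEMA arrangement. The background is an elliptical cylinder
    scaled to the requested volume; only its bulk statistics near the
    spheres matter for recovery-coefficient analysis.
    """
    if sphere_concentration <= 0 or background_concentration <= 0:
        raise ValueError("sphere and background concentrations must be > 0")
    ax, ay = background_semi_axes
    half_height = background_volume_mL * 1000.0 / (np.pi * ax * ay) / 2.0
    comps = [
        Compartment(
            EllipticCylinder((0.0, 0.0, 0.0), ax, ay, half_height),
            background_concentration,
            "background",
        )
    ]
    angles = np.deg2rad(np.arange(len(sphere_diameters)) * 360.0 / len(sphere_diameters))
    for d, ang in zip(sphere_diameters, angles):
        if d <= 0:
            raise ValueError(f"sphere diameter must be > 0, got {d}")
        center = (ring_radius_mm * np.cos(ang), ring_radius_mm * np.sin(ang), 0.0)
        comps.append(
            Compartment(Sphere(center, d / 2.0), sphere_concentration, f"sphere_{d:g}mm")
        )
    return Scene(tuple(comps), background_concentration)


def build_mini_iq_scene(
    sphere_concentration: float,
    background_concentration: float,
    *,
    sphere_diameters=(10.0, 13.0),
    box_half_mm: float = 36.0,
    spacing_mm: float = 36.0,
) -> Scene:
    """Compact variant of the IQ scene for replicate-heavy precision studies.

    Same sphere-in-warm-background construction as :func:`build_iq_scene`
    but with only the requested spheres inside a small background box, so a
    fine-grid simulation of hundreds of replicates stays cheap. Sphere
    centres are spread along x, centred on the origin.
    """
    if sphere_concentration <= 0 or background_concentration <= 0:
        raise ValueError("sphere and background concentrations must be > 0")
    n = len(sphere_diameters)
    xs = (np.arange(n) - (n - 1) / 2.0) * spacing_mm
    comps = [
        Compartment(
            Box((0.0, 0.0, 0.0), (box_half_mm, box_half_mm, box_half_mm)),
            background_concentration,
            "background",
        )
    ]
    for d, x in zip(sphere_diameters, xs):
        comps.append(
            Compartment(Sphere((x, 0.0, 0.0), d / 2.0), sphere_concentration, f"sphere_{d:g}mm")
        )
    return Scene(tuple(comps), background_concentration)


# ---------------------------------------------------------------------------
# Procedural brain scene
# ---------------------------------------------------------------------------


@dataclass
class BrainTemplate:
    """Gray/white label image plus 20 named VOIs on the same grid.

    ``labels``: 0 outside, 1 gray, 2 white. ``voi_ids``: 0 where no VOI,
    otherwise 1-based index into ``voi_names``. VOIs are disjoint by
    construction (a single id volume cannot overlap).
    """

    labels: np.ndarray
    grid: GridSpec
    voi_ids: np.ndarray
    voi_names: list
    voi_class: dict  # name -> "gray" | "white"

    GRAY, WHITE = 1, 2

    def __post_init__(self):
        if self.labels.shape != self.voi_ids.shape:
            raise ValueError("labels and voi_ids shapes differ")
        for i, name in enumerate(self.voi_names, start=1):
            sel = self.voi_ids == i
            if not sel.any():
                raise ValueError(f"VOI {name!r} is empty")
            want = self.GRAY if self.voi_class[name] == "gray" else self.WHITE
            if not np.all(self.labels[sel] == want):
                raise ValueError(f"VOI {name!r} leaks outside its tissue class")

    @property
    def vois(self) -> dict:
        """Mapping VOI name -> (N, 3) array of voxel indices."""
        return {
            name: np.argwhere(self.voi_ids == i)
            for i, name in enumerate(self.voi_names, start=1)
        }

    def voi_volumes_mL(self) -> dict:
        v = self.grid.voxel_volume_mL
        return {
            name: float((self.voi_ids == i).sum()) * v
            for i, name in enumerate(self.voi_names, start=1)
        }


def build_brain_scene(
    solution_concentration: float,
    gray_white_ratio: float = 4.0,
    *,
    template_voxel_mm: float = 2.0,
):
    """Procedural gray/white brain scene plus its 20-region VOI template.

    Gray structures (cortical shell, caudate and putamen analogs) hold the
    full solution concentration; white matter holds ``solution / ratio``,
    emulating how a single-fill anthropomorphic brain phantom produces
    apparent gray:white contrast (nominally ~4:1 by design). Returns
    ``(scene, template)``; the template carries five gray and five white
    VOIs per hemisphere, spanning large cortical patches down to small deep
    nuclei.
    """
    if solution_concentration <= 0:
        raise ValueError("solution concentration must be > 0")
    if gray_white_ratio <= 1:
        raise ValueError(f"gray:white ratio must be > 1, got {gray_white_ratio}")
    gray = solution_concentration
    white = solution_concentration / gray_white_ratio

    outer = Ellipsoid((0.0, 0.0, 0.0), (66.0, 84.0, 58.0))
    inner = Ellipsoid((0.0, 0.0, 0.0), (54.0, 72.0, 46.0))
    nuclei = {}
    for side, s in (("l", 1.0), ("r", -1.0)):
        nuclei[f"caudate_{side}"] = Ellipsoid((s * 14.0, 14.0, 6.0), (5.0, 14.0, 7.0))
        nuclei[f"putamen_{side}"] = Ellipsoid((s * 27.0, 2.0, 0.0), (8.0, 17.0, 9.0))

    comps = [
        Compartment(outer, gray, "cortex"),
        Compartment(inner, white, "white_matter"),
    ]
    comps += [Compartment(prim, gray, name) for name, prim in nuclei.items()]
    scene = Scene(tuple(comps), background_concentration=0.0)

    # --- template on its own grid -----------------------------------------
    lo, hi = scene.bounds()
    grid = GridSpec.cover(lo, hi, (template_voxel_mm,) * 3, margin=2.0)
    xs, ys, zs = (grid.axis_centers(a) for a in range(3))
    x = xs[:, None, None]
    y = ys[None, :, None]
    z = zs[None, None, :]
    comp_idx = scene.compartment_index(x, y, z)

    labels = np.zeros(grid.shape, dtype=np.uint8)
    is_gray = np.zeros(grid.shape, dtype=bool)
    for i, comp in enumerate(scene.compartments):
        sel = comp_idx == i
        if comp.concentration == gray:
            labels[sel] = BrainTemplate.GRAY
            is_gray |= sel
        else:
            labels[sel] = BrainTemplate.WHITE

    # VOIs are drawn interior to their structures (one-voxel 26-neighbour
    # erosion), as manual templates are, so boundary voxels with partial
    # tissue fill never enter a regional mean.
    from scipy import ndimage as _ndi

    _struct = np.ones((3, 3, 3), dtype=bool)

    def _interior(sel):
        return _ndi.binary_erosion(sel, structure=_struct)

    shell = _interior(comp_idx == 0)  # cortical shell (outer minus later paint)
    in_white = _interior(comp_idx == 1)

    voi_ids = np.zeros(grid.shape, dtype=np.int16)
    voi_names: list = []
    voi_class: dict = {}

    def add(name: str, cls: str, sel: np.ndarray):
        sel = np.broadcast_to(sel, grid.shape) & (voi_ids == 0)
        idx = len(voi_names) + 1
        voi_ids[sel] = idx
        voi_names.append(name)
        voi_class[name] = cls

    for side, s in (("l", 1.0), ("r", -1.0)):
        hx = s * x
        add(f"frontal_cortex_{side}", "gray", shell & (hx > 8) & (y > 40))
        add(f"occipital_cortex_{side}", "gray", shell & (hx > 8) & (y < -40))
        add(f"temporal_cortex_{side}", "gray", shell & (hx > 30) & (np.abs(y) <= 30) & (z < 10))
        for nuc in (f"caudate_{side}", f"putamen_{side}"):
            i = next(i for i, c in enumerate(scene.compartments) if c.name == nuc)
            add(nuc, "gray", _interior(comp_idx == i))
        add(f"frontal_white_{side}", "white", in_white & (hx > 10) & (y > 30))
        add(f"occipital_white_{side}", "white", in_white & (hx > 10) & (y < -35))
        add(
            f"centrum_semiovale_{side}",
            "white",
            in_white & (hx > 6) & (np.abs(y) <= 25) & (z > 18),
        )
        add(
            f"temporal_white_{side}",
            "white",
            in_white & (hx > 29) & (np.abs(y) <= 25) & (z < -8),
        )
        deep = (x - s * 18.0) ** 2 + (y + 12.0) ** 2 + (z + 8.0) ** 2 <= 7.0**2
        add(f"deep_white_{side}", "white", in_white & deep & (hx > 0))

    template = BrainTemplate(labels, grid, voi_ids, voi_names, voi_class)
    return scene, template


# ---------------------------------------------------------------------------
# Voxelization
# ---------------------------------------------------------------------------


def voxelize_scene(
    scene: Scene,
    grid: GridSpec,
    supersampling: int = 4,
    *,
    dtype=np.float64,
    chunk_voxels: int = 2_000_000,
) -> ActivityImage:
    """Rasterize a scene onto a grid with fractional voxel coverage.

    Each voxel straddling a compartment surface is resolved as the mean
    concentration over ``supersampling**3`` subvoxel sample points; voxels
    away from every surface use a single centre sample. Deterministic.
    """
    s = int(supersampling)
    if s < 1:
        raise ValueError(f"supersampling must be >= 1, got {supersampling}")
    lo, hi = scene.bounds()
    if not grid.covers(lo, hi):
        raise ValueError(
            f"grid extent {grid.world_bounds()} does not cover scene bounds ({lo}, {hi})"
        )

    vs = np.asarray(grid.voxel_size)
    band = float(np.linalg.norm(vs / 2.0)) * 1.05  # conservative half-diagonal
    values = np.zeros(grid.shape, dtype=dtype)
    comps = scene.compartments
    bands = [np.zeros(grid.shape, dtype=bool) for _ in comps]

    xs, ys, zs = (grid.axis_centers(a) for a in range(3))

    def _aabb_slices(primitive, pad):
        lo_w, hi_w = primitive.aabb()
        lo_i = np.floor(grid.world_to_index(np.asarray(lo_w) - pad)).astype(int)
        hi_i = np.ceil(grid.world_to_index(np.asarray(hi_w) + pad)).astype(int) + 1
        lo_i = np.clip(lo_i, 0, grid.shape)
        hi_i = np.clip(hi_i, 0, grid.shape)
        return tuple(slice(a, b) for a, b in zip(lo_i, hi_i))

    # Paint-order centre pass and per-compartment surface bands, each
    # evaluated only inside the compartment's (padded) bounding subgrid.
    for comp, b in zip(comps, bands):
        slc = _aabb_slices(comp.primitive, band + float(np.max(vs)))
        x = xs[slc[0]][:, None, None]
        y = ys[slc[1]][None, :, None]
        z = zs[slc[2]][None, None, :]
        sub_shape = tuple(s.stop - s.start for s in slc)
        inside = np.broadcast_to(comp.primitive.contains(x, y, z), sub_shape)
        values[slc][inside] = comp.concentration
        b[slc] = np.broadcast_to(comp.primitive.near_surface(x, y, z, band), sub_shape)

    if s > 1:
        offs = (np.arange(s) + 0.5) / s - 0.5
        shifts = (
            np.stack(np.meshgrid(offs, offs, offs, indexing="ij"), axis=-1).reshape(-1, 3) * vs
        )
        n_bands = np.zeros(grid.shape, dtype=np.int8)
        for b in bands:
            n_bands += b

        # Voxels straddling exactly one compartment surface: composite that
        # compartment's subvoxel coverage over the (constant) underlying value.
        for i, (comp, b) in enumerate(zip(comps, bands)):
            sel = b & (n_bands == 1)
            idx = np.argwhere(sel)
            if not idx.size:
                continue
            centers = grid.index_to_world(idx)
            cx, cy, cz = centers[:, 0], centers[:, 1], centers[:, 2]
            jmax = np.full(len(idx), -1, dtype=np.int32)
            for j, other in enumerate(comps):
                if j != i:
                    jmax[other.primitive.contains(cx, cy, cz)] = j
            need = jmax < i  # otherwise a later compartment overpaints this one
            if not need.any():
                continue
            sx = cx[need][:, None] + shifts[None, :, 0]
            sy = cy[need][:, None] + shifts[None, :, 1]
            sz = cz[need][:, None] + shifts[None, :, 2]
            frac = comp.primitive.contains(sx, sy, sz).mean(axis=1)
            under = np.zeros(len(centers), dtype=float)
            covered = jmax >= 0
            if covered.any():
                concs = np.array([c.concentration for c in comps])
                under[covered] = concs[jmax[covered]]
            vals = frac * comp.concentration + (1.0 - frac) * under[need]
            values[tuple(idx[need].T)] = vals

        # Voxels near several surfaces at once: full paint-order supersampling.
        idx = np.argwhere(n_bands >= 2)
        if idx.size:
            centers = grid.index_to_world(idx)
            sx = centers[:, 0][:, None] + shifts[None, :, 0]
            sy = centers[:, 1][:, None] + shifts[None, :, 1]
            sz = centers[:, 2][:, None] + shifts[None, :, 2]
            values[tuple(idx.T)] = scene.evaluate(sx, sy, sz).mean(axis=1)

    prov = [{"op": "voxelize", "supersampling": s, "voxel_size": tuple(grid.voxel_size)}]
    return ActivityImage(values, grid, prov)
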