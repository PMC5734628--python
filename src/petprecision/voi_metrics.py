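"""Quantitative uptake metrics: SUV_max, SUV_peak, A50 SUV_mean, RCs.

Implements the standard harmonized sphere analysis used for quantitative
PET accreditation work:

* ``SUV_max`` — maximum voxel value in a search region;
* ``SUV_peak`` — highest mean over a 1 mL spherical VOI, positioned
  exhaustively over voxel-centre candidates, with fractional voxel weights
  at the VOI edge so the kernel volume is exactly 1 mL on any grid;
* ``SUV_mean`` — unweighted mean over a background-corrected 50% isocontour
  (A50) segmentation: threshold ``T = B + 0.5 (SUVmax_local - B)``, largest
  26-connected component containing the local maximum;
* recovery coefficients RC = observed / true concentration.

For the brain scene, regional means are computed by rigidly realigning the
gray/white VOI template onto each replicate (nearest-neighbour label
resampling) and averaging per region.

In phantom terms SUV is simply the measured activity concentration
(kBq/mL); normalisation to injected dose and mass cancels in the recovery
coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._primitives import Sphere
from .grids import ActivityImage, GridSpec
from .imaging import RigidTransform
from .phantoms import BrainTemplate, Scene

__all__ = [
    "PeakKernel",
    "SphereMeasurement",
    "RegionMeasurement",
    "make_peak_kernel",
    "suv_max",
    "suv_peak",
    "segment_a50",
    "suv_mean",
    "recovery_coefficient",
    "region_means",
    "estimate_background",
    "measure_iq_replicate",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# Peak kernel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeakKernel:
    """Fractional-coverage weights of a fixed-volume sphere on a voxel grid."""

    weights: np.ndarray  # odd-shaped, centred weight array with values in [0, 1]
    voxel_size: tuple
    radius_mm: float
    volume_mL: float

    @property
    def volume_error(self) -> float:
        """Relative error of sum(weights) * voxel volume vs the nominal volume."""
        vol = float(self.weights.sum()) * float(np.prod(self.voxel_size)) / 1000.0
        return vol / self.volume_mL - 1.0

    def normalized(self) -> np.ndarray:
        return self.weights / self.weights.sum()


def make_peak_kernel(
    grid: GridSpec, volume_mL: float = 1.0, supersampling: int = 8
) -> PeakKernel:
    """Weight array for a sphere of the given volume centred on a voxel centre.

    The sphere radius is ``(3V / 4 pi)^(1/3)`` (6.2035 mm for 1 mL). Edge
    voxels get fractional weights by subvoxel counting so that
    ``sum(w) * voxel_volume`` reproduces the nominal volume closely on any
    of the clinical voxel sizes. Centre offsets other than voxel centres are
    not searched (documented simplification).
    """
    if volume_mL <= 0:
        raise ValueError("peak VOI volume must be > 0")
    radius = (3.0 * volume_mL * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    vs = np.asarray(grid.voxel_size)
    if np.any(vs > 2.0 * radius):
        raise ValueError(
            f"voxel size {tuple(vs)} exceeds peak-VOI diameter {2 * radius:.2f} mm; "
            "kernel would be degenerate"
        )
    half = np.ceil((radius + vs / 2.0) / vs).astype(int)
    shape = 2 * half + 1
    sphere = Sphere((0.0, 0.0, 0.0), radius)
    s = int(supersampling)
    offs = (np.arange(s) + 0.5) / s - 0.5
    ax, ay, az = ((np.arange(n) - h) * v for n, h, v in zip(shape, half, vs))
    acc = np.zeros(tuple(shape), dtype=np.float64)
    for ox in offs:
        for oy in offs:
            for oz in offs:
                acc += sphere.contains(
                    (ax + ox * vs[0])[:, None, None],
                    (ay + oy * vs[1])[None, :, None],
                    (az + oz * vs[2])[None, None, :],
                )
    weights = acc / s**3
    return PeakKernel(weights, tuple(grid.voxel_size), radius, volume_mL)


# ---------------------------------------------------------------------------
# Scalar metrics
# ---------------------------------------------------------------------------


def suv_max(image: ActivityImage, region: np.ndarray | None = None):
    """Maximum voxel value (and its index) within a boolean region.

    Ties break to the lowest linear index. ``region=None`` searches the
    whole volume.
    """
    values = image.values
    if region is None:
        region = np.ones(values.shape, dtype=bool)
    if not region.any():
        raise ValueError("suv_max: empty search region")
    masked = np.where(region, values, -np.inf)
    flat = int(np.argmax(masked))
    idx = np.unravel_index(flat, values.shape)
    return float(values[idx]), idx


def suv_peak(image: ActivityImage, kernel: PeakKernel, region: np.ndarray | None = None):
    """Highest kernel-weighted mean over candidate centres in the region.

    The search is exhaustive over voxel-centre positions whose full kernel
    support lies inside the image; the weighted mean uses the fractional
    edge weights, so the VOI volume is exactly the kernel's nominal volume
    everywhere.
    """
    if tuple(kernel.voxel_size) != tuple(image.grid.voxel_size):
        raise ValueError("peak kernel voxel size does not match image grid")
    values = image.values
    kshape = np.asarray(kernel.weights.shape)
    half = kshape // 2
    if np.any(np.asarray(values.shape) < kshape):
        raise ValueError("peak kernel larger than image")
    if region is None:
        region = np.ones(values.shape, dtype=bool)
    fits = np.zeros(values.shape, dtype=bool)
    fits[
        half[0] : values.shape[0] - half[0],
        half[1] : values.shape[1] - half[1],
        half[2] : values.shape[2] - half[2],
    ] = True
    candidates = region & fits
    if not candidates.any():
        raise ValueError("suv_peak: no candidate centre with the kernel fully inside")
    # Restrict the convolution to the candidate bounding box for speed.
    idx = np.argwhere(candidates)
    lo = np.maximum(idx.min(axis=0) - half, 0)
    hi = np.minimum(idx.max(axis=0) + half + 1, values.shape)
    sub = values[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    conv = ndimage.correlate(
        sub.astype(np.float64), kernel.normalized(), mode="constant", cval=0.0
    )
    cand_sub = candidates[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    masked = np.where(cand_sub, conv, -np.inf)
    flat = int(np.argmax(masked))
    sub_idx = np.unravel_index(flat, sub.shape)
    idx_full = tuple(int(a + b) for a, b in zip(sub_idx, lo))
    return float(conv[sub_idx]), idx_full


def segment_a50(
    image: ActivityImage,
    seed_region: np.ndarray,
    background_estimate: float,
) -> np.ndarray:
    """Background-corrected 50% isocontour around a local maximum.

    The local maximum is taken within ``seed_region``; the threshold is
    ``T = B + 0.5 (SUVmax_local - B)`` and the mask is the largest
    26-connected component of ``{values >= T}`` that contains the local
    maximum voxel.
    """
    if background_estimate < 0:
        raise ValueError("background estimate must be >= 0")
    local_max, idx = suv_max(image, seed_region)
    if local_max <= background_estimate:
        raise ValueError(
            f"no object: local max {local_max:.3g} <= background {background_estimate:.3g}"
        )
    threshold = background_estimate + 0.5 * (local_max - background_estimate)
    above = image.values >= threshold
    labels, _ = ndimage.label(above, structure=_CONN26)
    mask = labels == labels[idx]
    return mask


def suv_mean(image: ActivityImage, mask: np.ndarray) -> float:
    """Unweighted mean voxel value over a boolean mask."""
    if not mask.any():
        raise ValueError("suv_mean: empty mask")
    return float(image.values[mask].mean())


def recovery_coefficient(observed: float, true_concentration: float) -> float:
    """RC = observed / true activity concentration."""
    if true_concentration <= 0:
        raise ValueError(f"true concentration must be > 0, got {true_concentration}")
    return observed / true_concentration


# ---------------------------------------------------------------------------
# Brain template regional means
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionMeasurement:
    region: str
    tissue_class: str  # "gray" | "white"
    mean_concentration: float  # kBq/mL
    rc_mean: float  # mean / solution concentration
    n_voxels: int
    replicate: int = 0
    recon_label: str = ""
    condition: str = ""


def region_means(
    image: ActivityImage,
    template: BrainTemplate,
    realignment: RigidTransform | None = None,
    *,
    solution_concentration: float = 1.0,
    replicate: int = 0,
    recon_label: str = "",
    condition: str = "",
) -> list:
    """Mean concentration per template VOI after rigid template realignment.

    The VOI template lives in the original (untransformed) phantom frame;
    ``realignment`` maps template coordinates onto the replicate image (the
    acquisition's repositioning transform, taken from provenance or
    perturbed to emulate registration error). Labels are resampled to the
    image grid by nearest neighbour. Raises if any VOI ends up empty,
    naming the VOI.
    """
    realignment = realignment or RigidTransform.identity()
    grid = image.grid
    xs, ys, zs = (grid.axis_centers(a) for a in range(3))
    pts = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
    # image voxel at world p samples the template at T^-1(p)
    tpts = realignment.inverse_apply_points(pts.reshape(-1, 3))
    tidx = np.rint(template.grid.world_to_index(tpts)).astype(int)
    valid = np.all((tidx >= 0) & (tidx < np.asarray(template.grid.shape)), axis=1)
    voi_at = np.zeros(len(tidx), dtype=np.int16)
    voi_at[valid] = template.voi_ids[tuple(tidx[valid].T)]
    voi_at = voi_at.reshape(grid.shape)

    out = []
    flat_vals = image.values
    for i, name in enumerate(template.voi_names, start=1):
        sel = voi_at == i
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"VOI {name!r} is empty after realignment")
        mean = float(flat_vals[sel].mean())
        out.append(
            RegionMeasurement(
                region=name,
                tissue_class=template.voi_class[name],
                mean_concentration=mean,
                rc_mean=recovery_coefficient(mean, solution_concentration),
                n_voxels=n,
                replicate=replicate,
                recon_label=recon_label,
                condition=condition,
            )
        )
    return out


# ---------------------------------------------------------------------------
# IQ sphere measurement
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SphereMeasurement:
    sphere: str
    diameter_mm: float
    suv_max: float
    suv_peak: float
    suv_mean: float
    rc_max: float
    rc_peak: float
    rc_mean: float
    segmented_volume_mL: float
    replicate: int = 0
    recon_label: str = ""
    frame_duration_min: float = float("nan")
    condition: str = ""
    flag: str = ""  # non-empty marks a failed/degenerate measurement

    def __post_init__(self):
        if self.flag:
            return
        if not (self.suv_peak <= self.suv_max + 1e-9):
            raise ValueError("SUV_peak must not exceed SUV_max")


def _ball_mask(grid: GridSpec, center_world, radius_mm: float) -> np.ndarray:
    xs, ys, zs = (grid.axis_centers(a) for a in range(3))
    c = np.asarray(center_world)
    d2 = (
        (xs - c[0])[:, None, None] ** 2
        + (ys - c[1])[None, :, None] ** 2
        + (zs - c[2])[None, None, :] ** 2
    )
    return d2 <= radius_mm**2


def estimate_background(
    image: ActivityImage,
    scene: Scene,
    transform: RigidTransform | None = None,
    *,
    margin_mm: float = 20.0,
) -> float:
    """Mean over a fixed background region of the phantom.

    Uses the simulation's known geometry: voxels whose world position maps
    (through the inverse of the applied transform) well inside the
    background compartment and at least ``margin_mm`` beyond every sphere
    surface. For real scans, pass an explicit background value or mask to
    the measurement functions instead.
    """
    transform = transform or RigidTransform.identity()
    grid = image.grid
    xs, ys, zs = (grid.axis_centers(a) for a in range(3))
    pts = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
    local = transform.inverse_apply_points(pts.reshape(-1, 3))
    lx, ly, lz = local[:, 0], local[:, 1], local[:, 2]
    bg = scene["background"]
    sel = bg.primitive.contains(lx, ly, lz)
    # stay away from the compartment wall and from every sphere
    sel &= ~bg.primitive.near_surface(lx, ly, lz, margin_mm / 2.0)
    for _, sph, _ in scene.spheres():
        d = np.linalg.norm(local - sph.center, axis=-1)
        sel &= d > sph.radius + margin_mm
    sel = sel.reshape(grid.shape)
    if not sel.any():
        raise ValueError("background region empty; reduce margin_mm")
    return float(image.values[sel].mean())


def measure_iq_replicate(
    image: ActivityImage,
    scene: Scene,
    *,
    transform: RigidTransform | None = None,
    kernel: PeakKernel | None = None,
    background_estimate: float | None = None,
    replicate: int = 0,
    recon_label: str = "",
    frame_duration_min: float = float("nan"),
    condition: str = "",
) -> list:
    """Per-sphere SUV_max / SUV_peak / A50 SUV_mean and RCs for one replicate.

    Spheres are located from the simulation's ground-truth geometry
    (transform from image provenance if not given), so no image
    registration is involved. Search regions: SUV_max over a ball of
    ``radius + 15 mm`` around the transformed centre; SUV_peak candidate
    centres within ``radius + 5 mm`` (the kernel's non-zero support then
    stays inside the max region, preserving peak <= max); the A50 seed within
    ``radius + 8 mm``. A failed segmentation yields a flagged record
    rather than a silent drop.
    """
    if transform is None:
        step = image.find_step("transform")
        transform = (
            RigidTransform(tuple(step["rotation_deg"]), tuple(step["translation_mm"]))
            if step
            else RigidTransform.identity()
        )
    if kernel is None:
        kernel = make_peak_kernel(image.grid)
    if background_estimate is None:
        background_estimate = estimate_background(image, scene, transform)

    out = []
    for name, sph, true_conc in scene.spheres():
        center_t = transform.apply_points(sph.center[None, :])[0]
        try:
            max_region = _ball_mask(image.grid, center_t, sph.radius + 15.0)
            peak_region = _ball_mask(image.grid, center_t, sph.radius + 5.0)
            seed_region = _ball_mask(image.grid, center_t, sph.radius + 8.0)
            vmax, _ = suv_max(image, max_region)
            vpeak, _ = suv_peak(image, kernel, peak_region)
            mask = segment_a50(image, seed_region, background_estimate)
            vmean = suv_mean(image, mask)
            out.append(
                SphereMeasurement(
                    sphere=name,
                    diameter_mm=sph.diameter,
                    suv_max=vmax,
                    suv_peak=vpeak,
                    suv_mean=vmean,
                    rc_max=recovery_coefficient(vmax, true_conc),
                    rc_peak=recovery_coefficient(vpeak, true_conc),
                    rc_mean=recovery_coefficient(vmean, true_conc),
                    segmented_volume_mL=float(mask.sum()) * image.grid.voxel_volume_mL,
                    replicate=replicate,
                    recon_label=recon_label,
                    frame_duration_min=frame_duration_min,
                    condition=condition,
                )
            )
        except ValueError as exc:
            out.append(
                SphereMeasurement(
                    sphere=name,
                    diameter_mm=sph.diameter,
                    suv_max=float("nan"),
                    suv_peak=float("nan"),
                    suv_mean=float("nan"),
                    rc_max=float("nan"),
                    rc_peak=float("nan"),
                    rc_mean=float("nan"),
                    segmented_volume_mL=float("nan"),
                    replicate=replicate,
                    recon_label=recon_label,
                    frame_duration_min=frame_duration_min,
                    condition=condition,
                    flag=str(exc),
                )
            )
    return out
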