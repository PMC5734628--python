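"""Replicate image formation: repositioning, blur, PSF emulation, noise.

A "reconstructed" replicate is produced by composing, in order:

1. rigid repositioning of the continuous scene (no interpolation error);
2. voxelization onto a fine internal grid (voxels <= ~1 mm) with fractional
   coverage, so resolution and voxel-sampling effects stay separable;
3. isotropic Gaussian blur emulating the effective reconstructed
   resolution (FWHM in mm);
4. optional Richardson-Lucy deconvolution emulating post-reconstruction
   resolution modelling ("PSF" reconstruction), including its Gibbs-type
   edge overshoot;
5. block-mean downsampling to the reconstruction voxel grid;
6. count-statistics-scaled Poisson noise under a decay-compensated frame
   schedule, returned in concentration units.

Noise is a post-reconstruction voxel-level Poisson surrogate, not a
sinogram-domain simulation: expected voxel counts are
``concentration x voxel volume x frame duration x counts scale x decay``,
so relative noise falls as one over the square root of frame duration and
grows as voxels shrink — the two count-statistics relationships the
precision analysis depends on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .grids import ActivityImage, GridSpec
from .phantoms import Scene, voxelize_scene

__all__ = [
    "FWHM_TO_SIGMA",
    "F18_HALF_LIFE_MIN",
    "RigidTransform",
    "PsfEmulation",
    "ReconProfile",
    "FrameSchedule",
    "NoiseModel",
    "sample_transform",
    "apply_transform",
    "blur",
    "psf_enhance",
    "equal_counts_schedule",
    "add_noise",
    "downsample",
    "simulate_replicate",
    "simulate_clean_fine",
    "blurred_sphere_center_value",
]

#: FWHM = FWHM_TO_SIGMA * sigma for a Gaussian.
FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...

#: Physical half-life of 18F in minutes.
F18_HALF_LIFE_MIN = 109.77


# ---------------------------------------------------------------------------
# Rigid repositioning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RigidTransform:
    """Rigid motion: intrinsic xyz Euler rotation (degrees) then translation (mm)."""

    rotation_deg: tuple = (0.0, 0.0, 0.0)
    translation_mm: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(
            self, "rotation_deg", tuple(float(a) for a in np.asarray(self.rotation_deg).reshape(3))
        )
        object.__setattr__(
            self,
            "translation_mm",
            tuple(float(t) for t in np.asarray(self.translation_mm).reshape(3)),
        )

    @property
    def matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotation_deg, degrees=True).as_matrix()

    @property
    def displacement_mm(self) -> float:
        return float(np.linalg.norm(self.translation_mm))

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        return pts @ self.matrix.T + np.asarray(self.translation_mm)

    def inverse_apply_points(self, pts: np.ndarray) -> np.ndarray:
        return (pts - np.asarray(self.translation_mm)) @ self.matrix

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def to_dict(self) -> dict:
        return {"rotation_deg": self.rotation_deg, "translation_mm": self.translation_mm}


def sample_transform(
    max_rotation_deg: float, max_displacement_mm: float, rng
) -> RigidTransform:
    """Random repositioning: per-axis angles uniform on [-max, +max] degrees,
    translation uniform in the closed ball of the given radius (mm)."""
    if max_rotation_deg < 0 or max_displacement_mm < 0:
        raise ValueError("repositioning bounds must be >= 0")
    rng = np.random.default_rng(rng)
    angles = rng.uniform(-max_rotation_deg, max_rotation_deg, size=3)
    if max_displacement_mm == 0:
        trans = np.zeros(3)
    else:
        direction = rng.normal(size=3)
        norm = np.linalg.norm(direction)
        while norm == 0.0:  # pragma: no cover - probability zero
            direction = rng.normal(size=3)
            norm = np.linalg.norm(direction)
        radius = max_displacement_mm * rng.uniform() ** (1.0 / 3.0)
        trans = direction / norm * radius
    return RigidTransform(tuple(angles), tuple(trans))


def apply_transform(scene: Scene, t: RigidTransform) -> Scene:
    """Rigidly move every compartment; concentrations are untouched."""
    return scene.transformed(t.matrix, np.asarray(t.translation_mm))


# ---------------------------------------------------------------------------
# Resolution
# ---------------------------------------------------------------------------


def blur(image: ActivityImage, fwhm_mm: float) -> ActivityImage:
    """Isotropic Gaussian blur; sigma = fwhm / 2.3548 per axis in mm.

    Convolution uses zero padding outside the grid, which conserves total
    activity exactly for scenes interior to the grid.
    """
    if fwhm_mm < 0:
        raise ValueError(f"blur FWHM must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return image.with_values(image.values.copy(), {"op": "blur", "fwhm_mm": 0.0})
    sigma_vox = [fwhm_mm / FWHM_TO_SIGMA / v for v in image.grid.voxel_size]
    out = ndimage.gaussian_filter(image.values, sigma=sigma_vox, mode="constant", cval=0.0)
    return image.with_values(out, {"op": "blur", "fwhm_mm": float(fwhm_mm)})


def blurred_sphere_center_value(
    sphere_radius_mm: float, fwhm_mm: float, inside: float, outside: float
) -> float:
    """Closed-form centre value of a uniform sphere after Gaussian blur.

    For a sphere of radius R and concentrations S inside / B outside,
    the blurred value at the centre is
    ``B + (S - B) * [erf(R / (sigma sqrt 2)) - sqrt(2/pi) (R/sigma) exp(-R^2 / 2 sigma^2)]``.
    Used as the analytic oracle for recovery-coefficient checks.
    """
    if fwhm_mm == 0:
        return inside
    sigma = fwhm_mm / FWHM_TO_SIGMA
    r = sphere_radius_mm
    g = math.erf(r / (sigma * math.sqrt(2.0))) - math.sqrt(2.0 / math.pi) * (
        r / sigma
    ) * math.exp(-(r**2) / (2.0 * sigma**2))
    return outside + (inside - outside) * g


def psf_enhance(image: ActivityImage, kernel_fwhm_mm: float, iterations: int) -> ActivityImage:
    """Richardson-Lucy iterative deconvolution with a Gaussian kernel.

    Emulates post-reconstruction resolution modelling: edges sharpen and a
    Gibbs-type overshoot can appear near sharp boundaries. Zero iterations
    is the identity; the output is non-negative and renormalized to the
    input's total activity.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return image.with_values(image.values.copy(), {"op": "psf_enhance", "iterations": 0})
    if kernel_fwhm_mm <= 0:
        raise ValueError("kernel FWHM must be > 0 when iterations > 0")
    sigma_vox = [kernel_fwhm_mm / FWHM_TO_SIGMA / v for v in image.grid.voxel_size]

    def k(a):
        return ndimage.gaussian_filter(a, sigma=sigma_vox, mode="constant", cval=0.0)

    data = np.clip(image.values.astype(np.float64), 0.0, None)
    eps = 1e-12 * max(1.0, float(data.max()))
    x = data.copy()
    for _ in range(int(iterations)):
        conv = k(x)
        ratio = data / np.maximum(conv, eps)
        x *= k(ratio)
    x = np.clip(x, 0.0, None)
    total_in, total_out = float(data.sum()), float(x.sum())
    if total_out > 0:
        x *= total_in / total_out
    return image.with_values(
        x,
        {"op": "psf_enhance", "kernel_fwhm_mm": float(kernel_fwhm_mm), "iterations": int(iterations)},
    )


@dataclass(frozen=True)
class PsfEmulation:
    kernel_fwhm_mm: float = 7.0
    iterations: int = 10


@dataclass(frozen=True)
class ReconProfile:
    """One "reconstruction": output grid, effective resolution, PSF setting.

    ``fwhm_mm`` is the effective reconstructed resolution applied on the
    fine simulation grid; ``psf`` (if set) adds Richardson-Lucy resolution
    modelling before downsampling. ``fine_max_voxel_mm`` bounds the internal
    simulation voxel size; the fine grid subdivides each output voxel by an
    integer factor so downsampling is an exact block mean.
    """

    grid: GridSpec
    fwhm_mm: float = 7.0
    psf: PsfEmulation | None = None
    label: str = ""
    fine_max_voxel_mm: float = 1.0
    supersampling: int = 4

    def __post_init__(self):
        if not self.fwhm_mm >= 0:
            raise ValueError("effective resolution FWHM must be >= 0")
        if self.psf is not None and self.psf.iterations < 0:
            raise ValueError("PSF iteration count must be >= 0")

    def fine_factors(self) -> tuple:
        return tuple(
            max(1, int(math.ceil(v / self.fine_max_voxel_mm - 1e-9)))
            for v in self.grid.voxel_size
        )


# ---------------------------------------------------------------------------
# Frame schedule and noise
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous frames (minutes) with decay-compensated equal counts."""

    start_times_min: tuple
    durations_min: tuple
    half_life_min: float = F18_HALF_LIFE_MIN

    def __post_init__(self):
        st = tuple(float(t) for t in self.start_times_min)
        du = tuple(float(d) for d in self.durations_min)
        if len(st) != len(du) or not st:
            raise ValueError("schedule needs matching, non-empty starts and durations")
        if any(d <= 0 for d in du):
            raise ValueError("frame durations must be > 0")
        for k in range(1, len(st)):
            if not math.isclose(st[k], st[k - 1] + du[k - 1], rel_tol=0, abs_tol=1e-9):
                raise ValueError("frames must be contiguous and non-overlapping")
        object.__setattr__(self, "start_times_min", st)
        object.__setattr__(self, "durations_min", du)

    def __len__(self):
        return len(self.durations_min)

    @property
    def decay_constant(self) -> float:
        if math.isinf(self.half_life_min):
            return 0.0
        return math.log(2.0) / self.half_life_min

    def midpoint_decay_factor(self, frame: int) -> float:
        t_mid = self.start_times_min[frame] + self.durations_min[frame] / 2.0
        return math.exp(-self.decay_constant * t_mid)

    def expected_counts_integral(self, frame: int) -> float:
        """Exact integral of the unit-activity decay curve over the frame."""
        lam = self.decay_constant
        t0 = self.start_times_min[frame]
        d = self.durations_min[frame]
        if lam == 0.0:
            return d
        return math.exp(-lam * t0) * (1.0 - math.exp(-lam * d)) / lam


def equal_counts_schedule(
    first_duration_min: float, n_frames: int, half_life_min: float = F18_HALF_LIFE_MIN
) -> FrameSchedule:
    """Frames from t=0 whose decay-weighted integrals all equal frame 1's.

    With decay constant lambda = ln2 / half_life, frame boundaries satisfy
    ``exp(-lam t_k) - exp(-lam t_{k+1}) = 1 - exp(-lam d_1)`` so frame
    durations grow to compensate radioactive decay; for an infinite
    half-life all frames share the first duration.
    """
    if first_duration_min <= 0:
        raise ValueError("first frame duration must be > 0")
    if n_frames < 1:
        raise ValueError("need at least one frame")
    if half_life_min <= 0:
        raise ValueError("half-life must be > 0 (use math.inf for no decay)")
    if math.isinf(half_life_min):
        starts = tuple(first_duration_min * k for k in range(n_frames))
        return FrameSchedule(starts, (first_duration_min,) * n_frames, half_life_min)
    lam = math.log(2.0) / half_life_min
    target = 1.0 - math.exp(-lam * first_duration_min)
    starts, durations = [0.0], []
    e_t = 1.0  # exp(-lam * t_k)
    for _ in range(n_frames):
        e_next = e_t - target
        if e_next <= 0.0:
            raise ValueError(
                f"equal-count schedule infeasible: {n_frames} frames of "
                f"{first_duration_min} min starting counts exceed remaining activity"
            )
        t_next = -math.log(e_next) / lam
        durations.append(t_next - starts[-1])
        starts.append(t_next)
        e_t = e_next
    return FrameSchedule(tuple(starts[:-1]), tuple(durations), half_life_min)


@dataclass(frozen=True)
class NoiseModel:
    """Voxel-level Poisson surrogate for reconstruction noise.

    ``counts_per_mL_per_min`` converts concentration (kBq/mL) x voxel
    volume (mL) x frame duration (min) into expected detected counts per
    voxel. ``post_filter_fwhm_mm`` optionally smooths the noise residual to
    emulate spatially correlated reconstruction noise (the noiseless signal
    is untouched, so resolution stays defined by the blur step);
    ``white_fraction`` keeps that share of the residual unfiltered, giving
    colored noise — correlated at the filter scale with a sub-resolution
    white component, as reconstructed PET noise is. Seeded, reproducible.
    """

    counts_per_mL_per_min: float
    post_filter_fwhm_mm: float = 0.0
    white_fraction: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if not self.counts_per_mL_per_min > 0:
            raise ValueError("counts scale must be > 0")
        if self.post_filter_fwhm_mm < 0:
            raise ValueError("post-filter FWHM must be >= 0")
        if not 0.0 <= self.white_fraction <= 1.0:
            raise ValueError("white fraction must be within [0, 1]")


def add_noise(
    image: ActivityImage,
    noise: NoiseModel,
    schedule: FrameSchedule,
    frame: int,
    rng=None,
) -> ActivityImage:
    """Poisson count noise for one frame, returned in concentration units.

    Expected voxel counts are value x voxel volume (mL) x frame duration x
    counts scale x frame-midpoint decay factor; sampled counts are rescaled
    back to kBq/mL so the output is an unbiased noisy concentration image.
    """
    if not 0 <= frame < len(schedule):
        raise IndexError(f"frame {frame} outside schedule of {len(schedule)} frames")
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    else:
        rng = np.random.default_rng(rng)
    scale = (
        image.grid.voxel_volume_mL
        * schedule.durations_min[frame]
        * noise.counts_per_mL_per_min
        * schedule.midpoint_decay_factor(frame)
    )
    clean = np.clip(image.values.astype(np.float64), 0.0, None)
    counts = rng.poisson(clean * scale)
    noisy = counts / scale
    if noise.post_filter_fwhm_mm > 0:
        sigma_vox = [
            noise.post_filter_fwhm_mm / FWHM_TO_SIGMA / v for v in image.grid.voxel_size
        ]
        residual = noisy - clean
        filtered = ndimage.gaussian_filter(residual, sigma=sigma_vox, mode="constant")
        w = noise.white_fraction
        noisy = clean + w * residual + (1.0 - w) * filtered
    return image.with_values(
        noisy,
        {
            "op": "add_noise",
            "frame": int(frame),
            "duration_min": schedule.durations_min[frame],
            "counts_per_mL_per_min": noise.counts_per_mL_per_min,
            "post_filter_fwhm_mm": noise.post_filter_fwhm_mm,
            "white_fraction": noise.white_fraction,
        },
    )


# ---------------------------------------------------------------------------
# Downsampling and full replicate pipeline
# ---------------------------------------------------------------------------


def downsample(image: ActivityImage, factors) -> ActivityImage:
    """Block-mean downsampling by integer factors per axis (activity-exact)."""
    f = np.asarray(factors, dtype=int).reshape(3)
    if np.any(f < 1):
        raise ValueError("downsampling factors must be >= 1")
    shape = np.asarray(image.grid.shape)
    if np.any(shape % f != 0):
        raise ValueError(f"grid shape {tuple(shape)} not divisible by factors {tuple(f)}")
    n = shape // f
    v = image.values.reshape(n[0], f[0], n[1], f[1], n[2], f[2])
    out = v.mean(axis=(1, 3, 5))
    vs = np.asarray(image.grid.voxel_size) * f
    origin = (
        np.asarray(image.grid.origin)
        - np.asarray(image.grid.voxel_size) / 2.0
        + vs / 2.0
    )
    grid = GridSpec(tuple(vs), tuple(int(i) for i in n), tuple(origin))
    prov = list(image.provenance) + [{"op": "downsample", "factors": tuple(int(i) for i in f)}]
    return ActivityImage(out, grid, prov)


def simulate_replicate(
    scene: Scene,
    profile: ReconProfile,
    schedule: FrameSchedule,
    frame: int,
    transform: RigidTransform | None = None,
    noise: NoiseModel | None = None,
    *,
    noise_rng=None,
    clean_fine: ActivityImage | None = None,
) -> ActivityImage:
    """One replicate: transform -> voxelize fine -> blur -> PSF -> downsample -> noise.

    ``clean_fine`` lets callers reuse the deterministic part of the pipeline
    (everything before noise, on the fine grid) across frames of a
    stationary series; it must have been produced by this function for the
    same scene/profile/transform.
    """
    transform = transform or RigidTransform.identity()
    fine = clean_fine if clean_fine is not None else simulate_clean_fine(scene, profile, transform)
    out = downsample(fine, profile.fine_factors())
    out.provenance.append({"op": "recon_profile", "label": profile.label})
    if noise is not None:
        out = add_noise(out, noise, schedule, frame, rng=noise_rng)
    return out


def simulate_clean_fine(
    scene: Scene, profile: ReconProfile, transform: RigidTransform | None = None
) -> ActivityImage:
    """Deterministic fine-grid part of :func:`simulate_replicate` (pre-noise)."""
    transform = transform or RigidTransform.identity()
    moved = apply_transform(scene, transform)
    fine_grid = profile.grid.refine(profile.fine_factors())
    fine = voxelize_scene(moved, fine_grid, profile.supersampling)
    fine.provenance.insert(0, {"op": "transform", **transform.to_dict()})
    fine = blur(fine, profile.fwhm_mm)
    if profile.psf is not None and profile.psf.iterations > 0:
        fine = psf_enhance(fine, profile.psf.kernel_fwhm_mm, profile.psf.iterations)
    return fine
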