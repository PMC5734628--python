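"""Config-driven orchestration of replicate precision experiments.

One experiment = phantom x reconstruction profiles x frame plans x
{stationary, repositioned}. The stationary series is a single positioning
imaged as successive decay-compensated equal-count frames; the repositioned
series draws a fresh rigid transform (per-axis rotations below a bound,
translation uniform in a displacement ball) for every replicate while
keeping per-frame count statistics identical. Replicates are measured
(sphere RCs or brain regional RCs), aggregated, and compared between
conditions with variance F-tests.

Everything is deterministic for a fixed master seed: per-replicate seeds
are derived as ``SeedSequence([master, profile, frame_plan, condition,
replicate])``, transform and noise drawing from separate children.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .grids import GridSpec
from .imaging import (
    F18_HALF_LIFE_MIN,
    NoiseModel,
    PsfEmulation,
    ReconProfile,
    RigidTransform,
    equal_counts_schedule,
    sample_transform,
    simulate_clean_fine,
    simulate_replicate,
)
from .phantoms import (
    NEMA_SPHERE_DIAMETERS_MM,
    build_brain_scene,
    build_iq_scene,
    build_mini_iq_scene,
)
from .precision_stats import format_precision_table, precision_table
from .voi_metrics import make_peak_kernel, measure_iq_replicate, region_means

__all__ = [
    "ProfileSpec",
    "ExperimentConfig",
    "ExperimentResult",
    "ConfigError",
    "PAPER_PROFILE_SPECS",
    "validate_config",
    "load_config",
    "run_experiment",
    "measurements_to_long",
]


class ConfigError(ValueError):
    """Aggregated, human-readable configuration problems."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid experiment config:\n- " + "\n- ".join(self.errors))


@dataclass(frozen=True)
class ProfileSpec:
    """Reconstruction profile settings independent of the output grid."""

    label: str
    voxel_size: tuple
    fwhm_mm: float = 7.0
    psf_kernel_fwhm_mm: float = 0.0  # > 0 with iterations > 0 enables deconvolution
    psf_iterations: int = 0
    fine_max_voxel_mm: float = 1.0

    def build(self, grid: GridSpec, supersampling: int = 4) -> ReconProfile:
        psf = (
            PsfEmulation(self.psf_kernel_fwhm_mm, self.psf_iterations)
            if self.psf_iterations > 0
            else None
        )
        return ReconProfile(
            grid=grid,
            fwhm_mm=self.fwhm_mm,
            psf=psf,
            label=self.label,
            fine_max_voxel_mm=self.fine_max_voxel_mm,
            supersampling=supersampling,
        )


#: The four clinical voxel-size/PSF combinations emulated by default.
#: "TOF" profiles are plain 7 mm effective resolution; "TOF+PSF" either adds
#: post-reconstruction Richardson-Lucy deconvolution (Philips-style, large
#: body voxels) or uses a sharper 5 mm effective resolution (Siemens-style
#: in-reconstruction resolution modelling).
PAPER_PROFILE_SPECS = {
    "TOF-4mm": ProfileSpec("TOF-4mm", (4.0, 4.0, 4.0)),
    "TOF+PSF-4mm": ProfileSpec(
        "TOF+PSF-4mm", (4.0, 4.0, 4.0), psf_kernel_fwhm_mm=7.0, psf_iterations=10
    ),
    "TOF-2mm": ProfileSpec("TOF-2mm", (2.0, 2.0, 2.0)),
    "TOF+PSF-2mm": ProfileSpec(
        "TOF+PSF-2mm", (2.0, 2.0, 2.0), psf_kernel_fwhm_mm=7.0, psf_iterations=10
    ),
    "TOF-3.18mm": ProfileSpec("TOF-3.18mm", (3.1819, 3.1819, 2.0)),
    "TOF+PSF-3.18mm": ProfileSpec("TOF+PSF-3.18mm", (3.1819, 3.1819, 2.0), fwhm_mm=5.0),
    "TOF-2.04mm": ProfileSpec("TOF-2.04mm", (2.0364, 2.0364, 2.0)),
    "TOF+PSF-2.04mm": ProfileSpec("TOF+PSF-2.04mm", (2.0364, 2.0364, 2.0), fwhm_mm=5.0),
}


@dataclass
class ExperimentConfig:
    phantom: str = "iq"  # "iq" | "iq-mini" | "brain"
    sphere_concentration: float = 20.0  # kBq/mL (iq)
    background_concentration: float = 2.0  # kBq/mL (iq)
    sphere_diameters: tuple | None = None  # default: full NEMA set / (10, 13) mini
    solution_concentration: float = 10.0  # kBq/mL (brain)
    gray_white_ratio: float = 4.0
    replicates: int = 12
    conditions: tuple = ("stationary", "repositioned")
    max_rotation_deg: float = 5.0
    max_displacement_mm: float = 20.0
    first_frame_durations_min: tuple = (5.0,)
    half_life_min: float = F18_HALF_LIFE_MIN
    profiles: tuple = ("TOF-4mm", "TOF+PSF-4mm")
    noise_scale: float = 40.0  # counts per (kBq/mL * mL * min); 0 disables noise
    post_filter_fwhm_mm: float = 7.0  # noise-correlation scale (resolution-like)
    white_fraction: float = 0.15  # unfiltered share of the noise residual
    supersampling: int = 4
    master_seed: int = 0
    alpha: float = 0.05
    output_dir: str | None = None
    save_images: bool = False

    def profile_specs(self) -> list:
        out = []
        for p in self.profiles:
            if isinstance(p, ProfileSpec):
                out.append(p)
            else:
                out.append(PAPER_PROFILE_SPECS[p])
        return out


def validate_config(raw: dict) -> ExperimentConfig:
    """Check a raw mapping, fill defaults, reject unknown keys.

    All problems are collected and raised together as :class:`ConfigError`
    before any computation starts.
    """
    errors = []
    if not isinstance(raw, dict):
        raise ConfigError([f"config must be a mapping, got {type(raw).__name__}"])
    unknown = set(raw) - set(ExperimentConfig.__dataclass_fields__)
    for key in sorted(unknown):
        errors.append(f"unknown key {key!r}")
    merged = {**{k: v for k, v in raw.items() if k not in unknown}}
    cfg = ExperimentConfig(**merged)

    if cfg.phantom not in ("iq", "iq-mini", "brain"):
        errors.append(f"phantom must be one of iq, iq-mini, brain; got {cfg.phantom!r}")
    if cfg.replicates < 2:
        errors.append(f"replicate count must be >= 2, got {cfg.replicates}")
    if not cfg.conditions:
        errors.append("at least one condition required")
    for c in cfg.conditions:
        if c not in ("stationary", "repositioned"):
            errors.append(f"unknown condition {c!r}")
    if cfg.max_rotation_deg < 0 or cfg.max_displacement_mm < 0:
        errors.append("repositioning bounds must be >= 0")
    if not cfg.first_frame_durations_min:
        errors.append("at least one first-frame duration required")
    for d in cfg.first_frame_durations_min:
        if not d > 0:
            errors.append(f"frame duration must be > 0, got {d}")
    if not cfg.half_life_min > 0:
        errors.append("half-life must be > 0")
    if not cfg.profiles:
        errors.append("at least one reconstruction profile required")
    for p in cfg.profiles:
        if not isinstance(p, ProfileSpec) and p not in PAPER_PROFILE_SPECS:
            errors.append(
                f"unknown recon profile {p!r}; valid labels: "
                + ", ".join(sorted(PAPER_PROFILE_SPECS))
            )
    if cfg.noise_scale < 0:
        errors.append("noise scale must be >= 0 (0 disables noise)")
    if not 0.0 <= cfg.white_fraction <= 1.0:
        errors.append("white_fraction must be within [0, 1]")
    if cfg.phantom in ("iq", "iq-mini"):
        if cfg.sphere_concentration <= 0 or cfg.background_concentration <= 0:
            errors.append("sphere and background concentrations must be > 0")
    else:
        if cfg.solution_concentration <= 0:
            errors.append("solution concentration must be > 0")
        if cfg.gray_white_ratio <= 1:
            errors.append("gray:white ratio must be > 1")
    if cfg.supersampling < 1:
        errors.append("supersampling must be >= 1")
    if errors:
        raise ConfigError(errors)
    return cfg


def load_config(source) -> ExperimentConfig:
    """Load a YAML/JSON config from text or a file path and validate it."""
    import yaml

    path = Path(source)
    text = path.read_text() if path.exists() else str(source)
    raw = yaml.safe_load(text)
    return validate_config(raw if raw is not None else {})


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    measurements: pd.DataFrame  # wide, one row per (replicate, target)
    long: pd.DataFrame  # tidy, one row per (replicate, target, metric)
    summaries: pd.DataFrame
    ftests: pd.DataFrame
    manifest: dict


def measurements_to_long(df: pd.DataFrame, phantom: str) -> pd.DataFrame:
    """Tidy (target, metric, rc) rows from the wide measurement table."""
    keys = ["condition", "recon_label", "first_frame_min", "replicate", "target"]
    if phantom in ("iq", "iq-mini"):
        long = df.melt(
            id_vars=keys + ["diameter_mm"],
            value_vars=["rc_max", "rc_peak", "rc_mean"],
            var_name="metric",
            value_name="rc",
        )
        long["metric"] = long["metric"].str.replace("rc_", "", regex=False)
    else:
        long = df.rename(columns={"rc_mean": "rc"})[keys + ["tissue_class", "rc"]].copy()
        long["metric"] = "mean"
    return long


def _build_scene(cfg: ExperimentConfig):
    if cfg.phantom == "iq":
        diameters = cfg.sphere_diameters or NEMA_SPHERE_DIAMETERS_MM
        return (
            build_iq_scene(
                cfg.sphere_concentration,
                cfg.background_concentration,
                sphere_diameters=diameters,
            ),
            None,
        )
    if cfg.phantom == "iq-mini":
        diameters = cfg.sphere_diameters or (10.0, 13.0)
        return (
            build_mini_iq_scene(
                cfg.sphere_concentration,
                cfg.background_concentration,
                sphere_diameters=diameters,
            ),
            None,
        )
    return build_brain_scene(cfg.solution_concentration, cfg.gray_white_ratio)


def _experiment_grid(scene, spec: ProfileSpec, cfg: ExperimentConfig) -> GridSpec:
    lo, hi = scene.bounds()
    corner = float(np.max(np.abs(np.stack([lo, hi]))))
    rot_slack = 2.0 * corner * np.sin(np.deg2rad(cfg.max_rotation_deg) / 2.0)
    margin = cfg.max_displacement_mm + rot_slack + 2.0
    return GridSpec.cover(lo, hi, spec.voxel_size, margin=margin)


def _derive_seeds(master: int, *path) -> tuple:
    ss = np.random.SeedSequence([int(master), *[int(p) for p in path]])
    a, b = ss.generate_state(2)
    return int(a % 2**31), int(b % 2**31)


def run_experiment(config: ExperimentConfig | dict) -> ExperimentResult:
    """Run the full replicate design and return measurements + statistics.

    Output row counts are exactly determined by the configuration:
    ``replicates x n_targets`` wide rows per (condition, profile, frame
    plan), where n_targets is the number of spheres (IQ) or 20 brain VOIs.
    Deterministic for a fixed master seed.
    """
    cfg = validate_config(config) if isinstance(config, dict) else config
    scene, template = _build_scene(cfg)
    noise = (
        NoiseModel(cfg.noise_scale, cfg.post_filter_fwhm_mm, cfg.white_fraction)
        if cfg.noise_scale > 0
        else None
    )

    rows = []
    flagged = []
    for pi, spec in enumerate(cfg.profile_specs()):
        grid = _experiment_grid(scene, spec, cfg)
        profile = spec.build(grid, cfg.supersampling)
        kernel = (
            make_peak_kernel(grid) if cfg.phantom in ("iq", "iq-mini") else None
        )
        stationary_fine = None
        for fi, first in enumerate(cfg.first_frame_durations_min):
            schedule = equal_counts_schedule(first, cfg.replicates, cfg.half_life_min)
            for ci, condition in enumerate(cfg.conditions):
                for rep in range(cfg.replicates):
                    t_seed, n_seed = _derive_seeds(cfg.master_seed, pi, fi, ci, rep)
                    if condition == "stationary":
                        transform = RigidTransform.identity()
                        if stationary_fine is None:
                            stationary_fine = simulate_clean_fine(scene, profile, transform)
                        img = simulate_replicate(
                            scene,
                            profile,
                            schedule,
                            rep,
                            transform,
                            noise,
                            noise_rng=n_seed,
                            clean_fine=stationary_fine,
                        )
                    else:
                        transform = sample_transform(
                            cfg.max_rotation_deg, cfg.max_displacement_mm, t_seed
                        )
                        img = simulate_replicate(
                            scene, profile, schedule, rep, transform, noise, noise_rng=n_seed
                        )
                    meta = {
                        "condition": condition,
                        "recon_label": spec.label,
                        "first_frame_min": first,
                        "replicate": rep,
                    }
                    if cfg.phantom in ("iq", "iq-mini"):
                        records = measure_iq_replicate(
                            img,
                            scene,
                            transform=transform,
                            kernel=kernel,
                            replicate=rep,
                            recon_label=spec.label,
                            frame_duration_min=schedule.durations_min[rep],
                            condition=condition,
                        )
                        for r in records:
                            row = {**meta, "target": r.sphere, "diameter_mm": r.diameter_mm}
                            row.update(
                                suv_max=r.suv_max,
                                suv_peak=r.suv_peak,
                                suv_mean=r.suv_mean,
                                rc_max=r.rc_max,
                                rc_peak=r.rc_peak,
                                rc_mean=r.rc_mean,
                                segmented_volume_mL=r.segmented_volume_mL,
                                flag=r.flag,
                            )
                            rows.append(row)
                            if r.flag:
                                flagged.append(row)
                    else:
                        records = region_means(
                            img,
                            template,
                            realignment=transform,
                            solution_concentration=cfg.solution_concentration,
                            replicate=rep,
                            recon_label=spec.label,
                            condition=condition,
                        )
                        for r in records:
                            rows.append(
                                {
                                    **meta,
                                    "target": r.region,
                                    "tissue_class": r.tissue_class,
                                    "mean_concentration": r.mean_concentration,
                                    "rc_mean": r.rc_mean,
                                    "n_voxels": r.n_voxels,
                                }
                            )
                    if cfg.save_images and cfg.output_dir:
                        from .io import write_nifti

                        out = Path(cfg.output_dir) / "images"
                        out.mkdir(parents=True, exist_ok=True)
                        name = f"{spec.label}_{condition}_f{first:g}_r{rep:02d}.nii"
                        write_nifti(img, out / name)

    measurements = pd.DataFrame(rows)
    long = measurements_to_long(measurements, cfg.phantom)
    summaries = (
        long.groupby(["condition", "recon_label", "first_frame_min", "target", "metric"])
        .agg(n=("rc", "size"), mean=("rc", "mean"), sd=("rc", lambda v: v.std(ddof=1)))
        .reset_index()
    )
    summaries["cv"] = summaries["sd"] / summaries["mean"]

    ftest_frames = []
    if {"stationary", "repositioned"} <= set(cfg.conditions):
        for (first,), g in long.groupby([("first_frame_min")], sort=True):
            tab = precision_table(g, alpha=cfg.alpha)
            tab.insert(0, "first_frame_min", first)
            ftest_frames.append(tab)
    ftests = (
        pd.concat(ftest_frames, ignore_index=True)
        if ftest_frames
        else pd.DataFrame(
            columns=["first_frame_min", "target", "recon", "metric", "f", "p",
                     "variance_ratio", "significant", "status"]
        )
    )

    manifest = {
        "package_version": _pkg_version,
        "numpy_version": np.__version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cfg).items()
            if not isinstance(v, ProfileSpec)
        },
        "profiles": [asdict(s) for s in cfg.profile_specs()],
        "n_measurement_rows": len(measurements),
        "n_flagged": len(flagged),
    }

    result = ExperimentResult(cfg, measurements, long, summaries, ftests, manifest)
    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        measurements.to_csv(out / "measurements.csv", index=False)
        long.to_csv(out / "measurements_long.csv", index=False)
        summaries.to_csv(out / "summaries.csv", index=False)
        ftests.to_csv(out / "ftests.csv", index=False)
        (out / "precision_table.md").write_text(
            format_precision_table(ftests, cfg.alpha) if len(ftests) else "(no tests)\n"
        )
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return result
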