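# Methods

## Model overview

The package treats a quantitative PET acquisition as a chain of explicit,
separable effects applied to a continuous-domain activity scene:

```
scene  →  rigid repositioning  →  voxelization (tissue fraction)
       →  Gaussian blur (resolution)  →  optional RL deconvolution (PSF)
       →  block-mean downsampling to the clinical grid
       →  colored Poisson noise (count statistics)
```

Scenes are ordered lists of geometric primitives (spheres, ellipsoids,
boxes, elliptical cylinders), each with a true activity concentration in
kBq/mL; later compartments overpaint earlier ones and points outside all
compartments read zero. Because repositioning acts on the continuous
scene, it is exact — no interpolation error — and the only discretization
happens once, at voxelization. That separation is the point of the design:
the *tissue-fraction effect* (how a fixed object is sampled by a voxel
lattice) and the *resolution effect* (blur) can be varied independently,
which is exactly the contrast the precision analysis needs.

## Phantom scenes

**IQ analog.** Six spheres (10, 13, 17, 22, 28, 37 mm inner diameter)
coplanar on a 57.2 mm-radius ring, the standard arrangement of the NEMA
NU-2 image-quality phantom. The background is an elliptical cylinder
(semi-axes 150 × 105 mm) scaled to 9400 mL; a body-contoured shell would
change nothing that the analysis measures, which is only the background
level and noise near the spheres. Default fill 20 kBq/mL spheres over
2 kBq/mL background (10:1, the harmonization-protocol contrast; measured
fills in practice range roughly 17.8–28.6 over 1.75–3.08 kBq/mL).

**Compact variant** (`build_mini_iq_scene`): the same sphere-in-warm-
background construction with only the spheres under study inside a small
box, used for replicate-heavy precision studies where simulating 9.4 L of
background per replicate would buy nothing.

**Brain scene.** Procedural stand-in for an anthropomorphic gray/white
brain phantom: an ellipsoidal cortical shell (outer semi-axes 66/84/58 mm,
inner 54/72/46 mm) of gray matter around white matter, plus four deep gray
nuclei (caudate analogs 5/14/7 mm, putamen analogs 8/17/9 mm semi-axes,
one pair per hemisphere). Gray holds the fill solution concentration,
white holds `solution / ratio` with a default gray:white ratio of 4:1 —
the nominal design value of single-fill brain phantoms; the ratio is a
parameter because the physical value is nowhere printed. The VOI template
defines five gray and five white regions per hemisphere (cortical patches,
nuclei, white-matter blocks from ~1 mL to ~55 mL), each eroded one voxel
(26-neighbourhood) into its tissue so that regional means never include
partially filled boundary voxels — as manually drawn templates are.

## Voxelization

Each voxel's value is the volume-weighted mean concentration, computed by
subvoxel supersampling (default 4³ sample points). Voxels away from every
compartment surface are resolved with a single centre sample; voxels
straddling exactly one surface composite that compartment's subvoxel
coverage fraction over the (constant) underlying value; voxels near two or
more surfaces fall back to full paint-order supersampling. This is exact
with respect to the all-points definition (verified bit-for-bit against
brute force) and makes the cost scale with surface area rather than
volume. Volume conservation holds to ~(1/supersampling) relative
tolerance; with supersampling 4 a 10 mm sphere's volume is recovered to
0.13%.

## Image formation

* **Blur**: isotropic Gaussian, σ = FWHM/2.3548, applied on an internal
  fine grid whose voxels subdivide the output voxels to ≤ 1 mm, so the
  effective resolution is independent of the output voxel size. Default
  effective FWHM 7.0 mm for "TOF" profiles; Siemens-style in-recon
  resolution modelling is emulated as a direct 5.0 mm blur, Philips-style
  post-reconstruction resolution modelling as 7.0 mm blur followed by
  Richardson–Lucy deconvolution (Gaussian kernel 7.0 mm, 10 iterations).
  No vendor publishes these figures; they are configurable labels, not
  scanner clones. The analytic centre value of a blurred uniform sphere,
  `B + (S−B)[erf(R/σ√2) − √(2/π)(R/σ)e^(−R²/2σ²)]`, is the oracle used
  throughout testing (e.g. 6.23 for a 10 mm sphere, S=10, B=1, FWHM 7 mm).
* **RL deconvolution**: multiplicative Richardson–Lucy with a symmetric
  Gaussian kernel; output clipped non-negative and renormalized to the
  input total. It sharpens edges and produces the characteristic
  Gibbs-type overshoot (max value increases), which is the behaviour the
  PSF-reconstruction comparisons probe.
* **Downsampling**: exact block means over integer subdivision factors;
  conserves total activity identically and keeps nested grids (4 mm and
  2 mm) on one lattice so voxel-size comparisons share positions and
  noise seeds.
* **Frame schedules**: `equal_counts_schedule` solves
  `exp(−λt_k) − exp(−λt_{k+1}) = 1 − exp(−λd₁)` in closed form so every
  frame collects the same expected counts under decay (λ = ln2/109.77 min
  for ¹⁸F); the λ→0 limit returns equal durations. Infeasible requests
  (counts exceeding remaining activity) raise.

## Noise model

Noise is applied post-reconstruction, per voxel: expected counts =
concentration × voxel volume (mL) × frame duration (min) × counts scale ×
frame-midpoint decay factor; sampled counts are Poisson and rescaled back
to concentration, so the image is unbiased and its relative SD falls as
1/√(duration) and 1/√(voxel volume). A sinogram-domain simulation would
add fidelity the analysis does not use; this surrogate reproduces the two
relationships the precision comparisons rest on and is a documented
limitation.

The residual can be *colored*: a fraction `white_fraction` is kept
unfiltered and the rest is smoothed with a Gaussian `post_filter_fwhm_mm`.
Reconstructed PET noise is spatially correlated at roughly the resolution
scale but retains sub-resolution power; a purely white model makes the
1 mL peak VOI's noise floor implausibly small (it averages ~15 independent
voxels), while a purely band-limited model erases the voxel-size
dependence of noise that smaller reconstruction voxels show in practice.
The replicate-study defaults — correlation FWHM 7 mm (the effective
resolution), white fraction 0.15, counts scale 40 counts/(kBq/mL·mL·min),
giving ~6% background CV at 4 mm voxels and ~10% at 2 mm for a 5-min
frame — were chosen to reproduce those two stationary-noise facts (peak
replicate SD roughly a third to half of max's; 2 mm noisier than 4 mm)
and then held fixed for all repositioning comparisons, whose
voxel-sampling variances do not depend on the noise settings at all.

For the noise-bias study, count images at different frame durations are
coupled by Poisson superposition (the 2-min image is a sub-frame of the
5-min acquisition), which is both how reframing list-mode data actually
behaves and what makes the bias comparison a genuinely paired test.

## Quantification

* `suv_max`: maximum voxel in a search region; ties break to the lowest
  linear index.
* `suv_peak`: 1 mL sphere (radius 6.2035 mm) rasterized once per grid with
  fractional edge weights (volume correct to <0.5% on all clinical voxel
  sizes), then an exhaustive search over voxel-centre positions for the
  highest weighted mean. Subvoxel centre offsets are deliberately not
  searched — standard practice and bounded compute; the residual
  position-sampling sensitivity this leaves in SUV_peak is part of what
  the repositioning study measures.
* `segment_a50`: background-corrected 50% isocontour. Threshold
  `T = B + 0.5(SUVmax_local − B)` with the local maximum taken near the
  known (transformed) sphere centre; mask = the 26-connected component of
  `{v ≥ T}` containing that maximum. The background estimate B is the mean
  over phantom background voxels ≥20 mm from every sphere and away from
  the compartment wall (known geometry in simulation; for real volumes the
  caller supplies B or a mask).
* `measure_iq_replicate` locates spheres from the simulation's ground-truth
  transform (no image registration, mirroring analysis on original images);
  search regions are nested so that the peak kernel's support lies inside
  the max-search ball, making SUV_peak ≤ SUV_max structural. Failed
  segmentations yield flagged records, never silent drops.
* `region_means` resamples the brain VOI template onto a replicate by
  nearest neighbour under the acquisition's rigid transform (or a
  perturbed one, to emulate registration error).

## Statistics

Sample SDs use n−1; CV = SD/mean. The precision comparison is a two-sided
variance F-test, `p = 2·min(P(F′≤F), P(F′≥F))` with (n₁−1, n₂−1) degrees
of freedom, reported uncorrected for multiple comparisons (a Holm column
is available but off by default). Degenerate cases: both variances zero →
p = 1; one zero → p = 0, flagged. Normality of replicate RCs is assumed.
Type-I error at α = 0.05 calibrates to [0.040, 0.060] over 10⁴ null
simulations and null p-values pass a KS uniformity check.

## Experiment designs and problem sizes

`run_experiment` realizes the replicate design: the stationary series is
one positioning imaged as successive equal-count frames (12 for the IQ
scene, 10 for the brain scene by convention); the repositioned series
draws a fresh transform per replicate (per-axis rotations uniform within
±5°, translation uniform in a 20 mm ball). Seeds derive from a single
master seed via `SeedSequence([master, profile, frame_plan, condition,
replicate])`; outputs (tidy CSVs, a markdown precision table, a JSON
manifest) are byte-identical across runs with the same master seed.

The replicate-heavy studies (`petprecision.studies`) use the compact
two-sphere scene, a 1 mm fine grid with supersampling 2 (under a 7 mm
blur, further subvoxel refinement changes voxel values by ≪0.1%), and
frames of equal duration (matched counts realized directly; the
decay-compensated schedule is used where decay is in scope). The shipped
study sizes — 100 stationary + 100 repositioned replicates × 20
meta-repeats for the repositioning ordering, 200 paired replicates for
the noise bias — run in minutes on one CPU; `scripts/acceptance.py` uses
a reduced meta-study (40 × 5) for its summary numbers.

## What the generator does and does not emulate

Captured: partial-volume and tissue-fraction effects, resolution
differences with and without PSF modelling (including overshoot),
count-statistics scaling with frame duration and voxel volume, matched
counts across frames, rigid repositioning within clinical bounds.
Not captured: attenuation/scatter/randoms and their corrections, TOF
weighting, sinogram-domain noise propagation and reconstruction
non-linearities (OSEM noise is signal-dependent and non-Gaussian in ways a
post-hoc Poisson surrogate only approximates), CT-based registration
error, fill/calibration uncertainty, and anatomical texture within gray or
white matter (uniform compartments make regional means less variable than
in patients). Passing tests therefore demonstrate the *mechanisms* —
which metric is most sensitive to repositioning and why, how voxel size
trades sampling variance against noise — not scanner-specific magnitudes.

## Known limitations and open choices

* The A50 mean over a voxelized object is structurally below 1 even
  without blur or noise (boundary voxels with ≥50% fill enter at partial
  values: ~0.95–0.97 across the sphere set on a 2 mm grid), and the
  fractional-weight peak of a just-larger-than-1-mL sphere is ~0.89, not
  ~1: fixed-threshold isocontour means and discrete peak kernels have
  voxel-level floors that continuum reasoning misses.
* Whether the <5° rotation bound applies per axis or to the total rotation
  is ambiguous in common protocol descriptions; per-axis is implemented
  and configurable.
* The background-region definition for A50 correction follows the fixed
  margin rule above; accreditation tools do not publish theirs.
* The rotation centre is the scene origin (phantom centre), an adequate
  stand-in for couch/gantry geometry at these bounds.
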