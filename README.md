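# petprecision

Digital-phantom analysis of the **test–retest precision of quantitative PET
uptake metrics**. In longitudinal oncology and brain PET, a change in SUV is
only meaningful if it exceeds the measurement's own variability — which
depends on the reconstruction protocol, the voxel size, the scan duration
(count statistics), the analysis metric, and on the fact that a patient is
never repositioned identically between scans. `petprecision` reproduces
this experimental design in silico:

* **Phantoms as continuous scenes** — a NEMA NU-2 image-quality analog
  (six spheres of 10–37 mm inner diameter on a 114.4 mm ring inside a
  9400 mL background, ~10:1 sphere:background contrast) and a procedural
  gray/white brain scene with a 20-region VOI template (ten gray, ten
  white, five per tissue per hemisphere, from large cortical patches down
  to caudate/putamen-sized nuclei).
* **Replicate image formation** — rigid repositioning (per-axis rotations
  < 5°, displacements ≤ 20 mm), fractional-coverage voxelization on a
  ≤ 1 mm internal grid, Gaussian resolution blur, optional Richardson–Lucy
  "PSF" resolution modelling, block-mean downsampling to clinical voxel
  grids (4×4×4, 2×2×2, 3.1819×3.1819×2, 2.0364×2.0364×2 mm³), and
  count-statistics-scaled colored Poisson noise under decay-compensated
  equal-count frame schedules.
* **Quantification** — SUV_max; SUV_peak as the highest mean of a 1 mL
  spherical VOI with exact fractional voxel weights, searched exhaustively
  over voxel centres; SUV_mean over a background-corrected 50% isocontour
  (A50: threshold `T = B + 0.5·(SUVmax − B)`, largest 26-connected
  component); recovery coefficients `RC = measured / true concentration`;
  brain regional means via rigid template realignment.
* **Statistics** — per-condition replicate summaries and two-sided
  variance F-tests `F = s²_repositioned / s²_stationary` against
  F(n₁−1, n₂−1), reported uncorrected for multiple comparisons, arranged
  as a sphere × (reconstruction × metric) precision table.

The metrics module also accepts real axis-aligned NIfTI-1 volumes
(`petprecision.io.read_nifti`), so the same analysis can run on physical
phantom scans.

## Worked example

```bash
python examples/recovery_curve.py
```

```
    sphere  RC_max  RC_peak  RC_mean  analytic max
      10mm   0.608    0.355    0.438         0.623
      13mm   0.814    0.545    0.593         0.830
      17mm   0.955    0.778    0.706         0.962
      22mm   0.996    0.945    0.776         0.997
      28mm   1.000    0.995    0.810         1.000
      37mm   1.000    1.000    0.854         1.000
```

One noiseless reconstruction at 7 mm effective resolution on a 2 mm grid:
RC_max follows the closed-form Gaussian-blurred-sphere centre value
(partial-volume loss grows as spheres shrink); RC_peak collapses for
spheres smaller than the 12.4 mm peak VOI because background enters the
1 mL average; RC_mean sits below 1 since the 50% isocontour includes
partially filled boundary voxels.

Other examples: `repositioning_precision.py` (stationary vs repositioned
replicate series and the F-test table), `brain_regions.py` (gray/white
regional recovery with and without PSF emulation),
`equal_count_frames.py` (decay-compensated framing).

A full experiment is driven by a config mapping (or YAML):

```python
from petprecision import run_experiment, validate_config
cfg = validate_config({"phantom": "iq", "replicates": 12,
                       "profiles": ["TOF-4mm", "TOF+PSF-4mm"],
                       "master_seed": 1, "output_dir": "out"})
result = run_experiment(cfg)   # measurements.csv, ftests.csv, manifest.json …
```

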