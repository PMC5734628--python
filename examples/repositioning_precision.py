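"""Does repositioning the phantom between scans degrade SUV precision?

Runs a compact replicate experiment (two small spheres in a warm
background, 12 stationary vs 12 randomly repositioned replicates at equal
count statistics) and prints the per-metric variance F-tests. SUV_max is
the most sensitive metric to repositioning at 4 mm voxels; the 1 mL
SUV_peak, with fractional voxel weighting, is the least.
"""

from petprecision import format_precision_table, run_experiment, validate_config

config = validate_config(
    {
        "phantom": "iq-mini",
        "sphere_diameters": [10.0, 13.0],
        "replicates": 12,
        "profiles": ["TOF-4mm"],
        "first_frame_durations_min": [5.0],
        "master_seed": 7,
    }
)
result = run_experiment(config)

print("Replicate SD of the recovery coefficient by condition:\n")
print(
    result.summaries.pivot_table(
        index=["target", "metric"], columns="condition", values="sd"
    ).round(4)
)
print("\nTwo-sided variance F-tests (repositioned vs stationary):\n")
print(format_precision_table(result.ftests))
print(
    "\nCells with p < 0.05 mark metrics whose test-retest precision is\n"
    "significantly degraded by repositioning; dashes are non-significant."
)
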