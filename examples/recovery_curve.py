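"""Recovery-coefficient curve of the digital NEMA IQ phantom.

Builds the six-sphere scene at 10:1 contrast, simulates one noiseless
reconstruction at 7 mm effective resolution on a 2 mm grid, measures each
sphere, and compares RC_max with the analytic Gaussian-blurred-sphere
centre value. RCs rise with sphere diameter (partial-volume effect); the
37 mm sphere recovers fully, the 10 mm sphere only ~60%.
"""

import math

from petprecision import (
    FrameSchedule,
    GridSpec,
    ReconProfile,
    blurred_sphere_center_value,
    build_iq_scene,
    measure_iq_replicate,
    simulate_replicate,
)

scene = build_iq_scene(sphere_concentration=20.0, background_concentration=2.0)
grid = GridSpec.cover(*scene.bounds(), (2.0, 2.0, 2.0), margin=4)
profile = ReconProfile(grid=grid, fwhm_mm=7.0, label="TOF-2mm", supersampling=2)
schedule = FrameSchedule((0.0,), (5.0,), math.inf)

image = simulate_replicate(scene, profile, schedule, frame=0)  # noiseless
records = measure_iq_replicate(image, scene, recon_label=profile.label)

print(f"{'sphere':>10} {'RC_max':>7} {'RC_peak':>8} {'RC_mean':>8} {'analytic max':>13}")
for r in sorted(records, key=lambda r: r.diameter_mm):
    analytic = blurred_sphere_center_value(r.diameter_mm / 2, 7.0, 20.0, 2.0) / 20.0
    print(
        f"{r.diameter_mm:>8.0f}mm {r.rc_max:7.3f} {r.rc_peak:8.3f} "
        f"{r.rc_mean:8.3f} {analytic:13.3f}"
    )
print(
    "\nRC_max tracks the analytic blurred-centre value; RC_peak drops for\n"
    "spheres smaller than the 12.4 mm peak VOI; RC_mean sits below 1 because\n"
    "the 50% isocontour includes partially filled boundary voxels."
)
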