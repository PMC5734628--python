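"""Gray/white regional recovery in the procedural brain phantom.

Simulates the brain scene noiselessly at 7 mm resolution with and without
PSF emulation (Richardson-Lucy resolution modelling) and prints the
regional mean recovery for all 20 template VOIs. Blur spills gray-matter
activity out (gray RC < 1) and into white matter (white RC above its 0.25
truth); resolution modelling pushes both back toward truth.
"""

from petprecision.studies import brain_psf_contrast_study

df = brain_psf_contrast_study(solution_concentration=10.0, gray_white_ratio=4.0)
wide = df.pivot_table(index=["tissue_class", "region"], columns="profile", values="rc_mean")
wide["delta_%"] = (wide["TOF+PSF"] / wide["TOF"] - 1.0) * 100.0
print(wide.round(3))
truth = {"gray": 1.0, "white": 0.25}
for cls in ("gray", "white"):
    sub = wide.loc[cls]
    print(
        f"\n{cls}: truth RC {truth[cls]:.2f}; TOF mean {sub['TOF'].mean():.3f}; "
        f"PSF shifts regions by {sub['delta_%'].mean():+.1f}% on average"
    )
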