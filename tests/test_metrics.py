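"""SUV metrics: peak kernel, max/peak/mean, A50 segmentation, RCs, regions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petprecision.grids import ActivityImage, GridSpec
from petprecision.imaging import RigidTransform, blur, simulate_clean_fine, downsample, ReconProfile
from petprecision.phantoms import (
    build_brain_scene,
    build_mini_iq_scene,
    voxelize_scene,
)
from petprecision.voi_metrics import (
    estimate_background,
    make_peak_kernel,
    measure_iq_replicate,
    recovery_coefficient,
    region_means,
    segment_a50,
    suv_max,
    suv_mean,
    suv_peak,
)

PAPER_VOXELS = [(4.0, 4.0, 4.0), (2.0, 2.0, 2.0), (3.1819, 3.1819, 2.0), (2.0364, 2.0364, 2.0)]


def grid_for(voxel, shape=(32, 32, 32)):
    return GridSpec(voxel, shape)


class TestPeakKernel:
    @pytest.mark.parametrize("voxel", PAPER_VOXELS, ids=str)
    def test_volume_normalized_on_clinical_grids(self, voxel):
        k = make_peak_kernel(grid_for(voxel))
        assert abs(k.volume_error) <= 0.005
        assert k.radius_mm == pytest.approx(6.2035, abs=1e-3)
        assert k.weights.min() >= 0.0 and k.weights.max() <= 1.0

    def test_weights_symmetric_under_axis_permutation(self):
        k = make_peak_kernel(grid_for((4.0, 4.0, 4.0)))
        assert np.array_equal(k.weights, k.weights.transpose(1, 2, 0))
        assert np.array_equal(k.weights, k.weights[::-1])

    def test_oversized_voxel_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            make_peak_kernel(grid_for((15.0, 15.0, 15.0)))


class TestSuvMaxPeak:
    def test_constant_image_returns_constant(self):
        img = ActivityImage(np.full((20, 20, 20), 3.5), grid_for((4.0, 4.0, 4.0), (20, 20, 20)))
        k = make_peak_kernel(img.grid)
        vmax, _ = suv_max(img)
        vpeak, _ = suv_peak(img, k)
        assert vmax == 3.5
        assert vpeak == pytest.approx(3.5, rel=1e-12)

    def test_tie_breaks_to_lowest_linear_index(self):
        vals = np.zeros((4, 4, 4))
        vals[1, 2, 3] = vals[2, 0, 0] = 7.0
        img = ActivityImage(vals, GridSpec((1, 1, 1), (4, 4, 4)))
        _, idx = suv_max(img)
        assert idx == (1, 2, 3)

    def test_empty_region_rejected(self):
        img = ActivityImage(np.ones((4, 4, 4)), GridSpec((1, 1, 1), (4, 4, 4)))
        with pytest.raises(ValueError):
            suv_max(img, np.zeros((4, 4, 4), bool))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_peak_never_exceeds_max(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.lognormal(0.0, 1.0, size=(14, 14, 14))
        img = ActivityImage(vals, grid_for((4.0, 4.0, 4.0), (14, 14, 14)))
        k = make_peak_kernel(img.grid)
        vpeak, _ = suv_peak(img, k)
        vmax, _ = suv_max(img)
        assert vpeak <= vmax + 1e-12

    def test_small_sphere_peak_dilution(self, blurred_sphere_image):
        # 1 mL VOI (12.4 mm across) larger than the 10 mm sphere: peak
        # includes background and must fall below the analytic centre value.
        _, b = blurred_sphere_image
        k = make_peak_kernel(b.grid)
        vpeak, _ = suv_peak(b, k)
        vmax, _ = suv_max(b)
        assert vpeak < 6.23 < 10.0
        assert vpeak <= vmax

    def test_kernel_must_fit_somewhere(self):
        img = ActivityImage(np.ones((20, 20, 20)), grid_for((2.0, 2.0, 2.0), (20, 20, 20)))
        k = make_peak_kernel(img.grid)
        edge_only = np.zeros(img.values.shape, bool)
        edge_only[0, 0, 0] = True
        with pytest.raises(ValueError, match="candidate"):
            suv_peak(img, k, edge_only)


class TestSegmentA50:
    def test_threshold_arithmetic(self):
        # B=1, local max 10 -> T=5.5: voxels at 5.5 included, 5.49 not
        vals = np.ones((9, 9, 9))
        vals[4, 4, 4] = 10.0
        vals[4, 4, 5] = 5.5
        vals[4, 4, 3] = 5.49
        img = ActivityImage(vals, GridSpec((1, 1, 1), (9, 9, 9)))
        mask = segment_a50(img, np.ones(vals.shape, bool), 1.0)
        assert mask[4, 4, 4] and mask[4, 4, 5] and not mask[4, 4, 3]

    def test_unblurred_large_sphere_volume(self):
        scene = build_mini_iq_scene(10.0, 1.0, sphere_diameters=(37.0,), box_half_mm=32.0)
        grid = GridSpec((2.0, 2.0, 2.0), (33, 33, 33), (-32.0, -32.0, -32.0))
        img = voxelize_scene(scene, grid, 4)
        mask = segment_a50(img, np.ones(img.values.shape, bool), 1.0)
        vol = mask.sum() * grid.voxel_volume_mL
        assert vol == pytest.approx(26.52, rel=0.05)

    def test_blurred_large_sphere_volume_within_15_percent(self):
        scene = build_mini_iq_scene(10.0, 1.0, sphere_diameters=(37.0,), box_half_mm=34.0)
        grid = GridSpec.cover(*scene.bounds(), (2.0, 2.0, 2.0), margin=2)
        img = blur(voxelize_scene(scene, grid, 4), 7.0)
        mask = segment_a50(img, np.ones(img.values.shape, bool), 1.0)
        vol = mask.sum() * grid.voxel_volume_mL
        assert vol == pytest.approx(26.52, rel=0.15)

    def test_no_object_above_background_rejected(self):
        img = ActivityImage(np.ones((6, 6, 6)), GridSpec((1, 1, 1), (6, 6, 6)))
        with pytest.raises(ValueError, match="no object"):
            segment_a50(img, np.ones((6, 6, 6), bool), 2.0)


class TestSuvMeanAndRC:
    def test_constant_mean_and_linearity(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(1, 5, size=(8, 8, 8))
        img = ActivityImage(vals, GridSpec((2, 2, 2), (8, 8, 8)))
        m1 = np.zeros(vals.shape, bool)
        m2 = np.zeros(vals.shape, bool)
        m1[:4], m2[5:] = True, True
        merged = m1 | m2
        expect = (
            suv_mean(img, m1) * m1.sum() + suv_mean(img, m2) * m2.sum()
        ) / merged.sum()
        assert suv_mean(img, merged) == pytest.approx(expect, rel=1e-12)
        with pytest.raises(ValueError):
            suv_mean(img, np.zeros(vals.shape, bool))

    @pytest.mark.parametrize(
        "obs, true, rc", [(10.0, 10.0, 1.0), (6.23, 10.0, 0.623), (0.0, 10.0, 0.0)]
    )
    def test_recovery_coefficient_definition(self, obs, true, rc):
        assert recovery_coefficient(obs, true) == pytest.approx(rc)

    def test_recovery_requires_positive_truth(self):
        with pytest.raises(ValueError):
            recovery_coefficient(1.0, 0.0)


@pytest.fixture(scope="module")
def brain():
    return build_brain_scene(10.0, 4.0)


class TestRegionMeans:
    def test_blurred_scene_shows_spill_out_and_spill_in(self, brain):
        scene, template = brain
        img = blur(voxelize_scene(scene, template.grid, 2), 7.0)
        for r in region_means(img, template, solution_concentration=10.0):
            if r.tissue_class == "gray":
                assert r.rc_mean < 1.0
            else:
                assert r.rc_mean > 0.25  # spill-in raises white above truth

    def test_true_realignment_beats_identity_on_shifted_replicate(self, brain):
        scene, template = brain
        grid = GridSpec.cover(*scene.bounds(), (2.0,) * 3, margin=20)
        profile = ReconProfile(grid=grid, fwhm_mm=7.0, supersampling=2)
        stationary = downsample(simulate_clean_fine(scene, profile), profile.fine_factors())
        t = RigidTransform((0.0, 0.0, 0.0), (15.0, 0.0, 0.0))
        moved = downsample(simulate_clean_fine(scene, profile, t), profile.fine_factors())
        ref = {r.region: r.mean_concentration for r in region_means(stationary, template)}
        aligned = {r.region: r.mean_concentration for r in region_means(moved, template, t)}
        naive = {r.region: r.mean_concentration for r in region_means(moved, template)}
        better = sum(
            abs(aligned[k] - ref[k]) < abs(naive[k] - ref[k]) for k in ref
        )
        assert better == len(ref)

    def test_empty_voi_after_realignment_names_the_region(self, brain):
        scene, template = brain
        img = voxelize_scene(scene, template.grid, 1)
        bad = RigidTransform((0, 0, 0), (500.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="frontal_cortex_l"):
            region_means(img, template, bad)


@pytest.fixture(scope="module")
def measured(iq_scene):
    grid = GridSpec.cover(*iq_scene.bounds(), (4.0,) * 3, margin=4)
    img = voxelize_scene(iq_scene, grid, 2)
    return measure_iq_replicate(img, iq_scene)


class TestMeasureIQReplicate:
    def test_six_records_per_image(self, measured):
        assert len(measured) == 6
        assert {r.sphere for r in measured} == {
            f"sphere_{d:g}mm" for d in (10, 13, 17, 22, 28, 37)
        }

    def test_max_dominates_peak_everywhere(self, measured):
        for r in measured:
            assert r.rc_max >= r.rc_peak
            assert not r.flag

    def test_background_estimate_matches_fill(self, iq_scene):
        grid = GridSpec.cover(*iq_scene.bounds(), (4.0,) * 3, margin=4)
        img = voxelize_scene(iq_scene, grid, 2)
        assert estimate_background(img, iq_scene) == pytest.approx(2.0, rel=1e-3)

    def test_segmentation_failure_yields_flagged_record(self, iq_scene):
        grid = GridSpec.cover(*iq_scene.bounds(), (4.0,) * 3, margin=4)
        img = voxelize_scene(iq_scene, grid, 2)
        recs = measure_iq_replicate(img, iq_scene, background_estimate=25.0)
        assert len(recs) == 6
        assert all(r.flag for r in recs)
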