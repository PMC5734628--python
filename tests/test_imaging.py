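"""Image-formation chain: transforms, blur, deconvolution, framing, noise."""

import math

import numpy as np
import pytest
from scipy import integrate, optimize

from petprecision.grids import ActivityImage, GridSpec
from petprecision.imaging import (
    F18_HALF_LIFE_MIN,
    FrameSchedule,
    NoiseModel,
    PsfEmulation,
    ReconProfile,
    RigidTransform,
    add_noise,
    apply_transform,
    blur,
    blurred_sphere_center_value,
    downsample,
    equal_counts_schedule,
    psf_enhance,
    sample_transform,
    simulate_clean_fine,
    simulate_replicate,
)
from petprecision.phantoms import build_mini_iq_scene, voxelize_scene


class TestSampleTransform:
    def test_bounds_hold_over_many_seeds(self):
        for seed in range(300):
            t = sample_transform(5.0, 20.0, seed)
            assert all(abs(a) <= 5.0 for a in t.rotation_deg)
            assert t.displacement_mm <= 20.0 + 1e-12

    def test_zero_bounds_give_identity(self):
        t = sample_transform(0.0, 0.0, 123)
        assert t.rotation_deg == (0.0, 0.0, 0.0)
        assert t.translation_mm == (0.0, 0.0, 0.0)

    def test_negative_bounds_rejected(self):
        with pytest.raises(ValueError):
            sample_transform(-1.0, 20.0, 0)

    def test_translations_are_centred(self):
        rng = np.random.default_rng(7)
        draws = np.array(
            [sample_transform(5.0, 20.0, rng).translation_mm for _ in range(10_000)]
        )
        se = draws.std(axis=0) / math.sqrt(len(draws))
        assert np.all(np.abs(draws.mean(axis=0)) < 3.0 * se)


class TestApplyTransform:
    def test_identity_leaves_scene_unchanged(self):
        scene = build_mini_iq_scene(10.0, 1.0)
        moved = apply_transform(scene, RigidTransform.identity())
        for a, b in zip(scene.compartments, moved.compartments):
            assert np.allclose(a.primitive.aabb(), b.primitive.aabb())

    def test_translation_moves_sphere_rigidly(self):
        scene = build_mini_iq_scene(10.0, 1.0, sphere_diameters=(10.0,))
        t = RigidTransform((0, 0, 0), (20.0, 0.0, 0.0))
        moved = apply_transform(scene, t)
        _, sph0, _ = scene.spheres()[0]
        _, sph1, _ = moved.spheres()[0]
        assert np.allclose(sph1.center, sph0.center + [20, 0, 0])
        assert sph1.volume() == sph0.volume()

    def test_roundtrip_restores_parameters(self):
        scene = build_mini_iq_scene(10.0, 1.0)
        t = sample_transform(5.0, 20.0, 42)
        rot = t.matrix
        back = apply_transform(scene, t).transformed(rot.T, -rot.T @ np.asarray(t.translation_mm))
        for a, b in zip(scene.compartments, back.compartments):
            lo_a, hi_a = a.primitive.aabb()
            lo_b, hi_b = b.primitive.aabb()
            assert np.allclose(lo_a, lo_b, atol=1e-10) and np.allclose(hi_a, hi_b, atol=1e-10)


class TestBlur:
    def test_zero_fwhm_is_identity(self, single_sphere_image):
        _, img = single_sphere_image
        assert np.array_equal(blur(img, 0.0).values, img.values)

    def test_negative_fwhm_rejected(self, single_sphere_image):
        _, img = single_sphere_image
        with pytest.raises(ValueError):
            blur(img, -1.0)

    def test_uniform_interior_unchanged(self):
        img = ActivityImage(np.full((40, 40, 40), 3.0), GridSpec((1, 1, 1), (40, 40, 40)))
        out = blur(img, 7.0)
        assert np.allclose(out.values[15:25, 15:25, 15:25], 3.0, rtol=1e-6)

    def test_total_activity_conserved(self):
        # scene well inside the grid (margin > 3 sigma) so no spill leaves it
        scene = build_mini_iq_scene(10.0, 1.0, sphere_diameters=(10.0,), box_half_mm=18.0)
        grid = GridSpec.cover(*scene.bounds(), (1.0, 1.0, 1.0), margin=12.0)
        img = voxelize_scene(scene, grid, 2)
        out = blur(img, 7.0)
        assert out.total_activity_kBq == pytest.approx(img.total_activity_kBq, rel=1e-3)

    def test_matches_closed_form_centre_value(self, blurred_sphere_image):
        _, b = blurred_sphere_image
        pred = blurred_sphere_center_value(5.0, 7.0, 10.0, 1.0)
        assert pred == pytest.approx(6.2315, abs=5e-4)  # frozen closed-form value
        assert b.values.max() == pytest.approx(pred, rel=0.02)


class TestPsfEnhance:
    def test_zero_iterations_is_identity(self, blurred_sphere_image):
        _, b = blurred_sphere_image
        assert np.array_equal(psf_enhance(b, 7.0, 0).values, b.values)

    def test_requires_positive_kernel(self, blurred_sphere_image):
        _, b = blurred_sphere_image
        with pytest.raises(ValueError):
            psf_enhance(b, 0.0, 5)

    def test_sharpens_blurred_sphere_with_overshoot(self):
        scene = build_mini_iq_scene(10.0, 1.0, sphere_diameters=(22.0,), box_half_mm=36.0)
        grid = GridSpec.cover(*scene.bounds(), (1.0, 1.0, 1.0))
        b = blur(voxelize_scene(scene, grid, 2), 7.0)
        e = psf_enhance(b, 7.0, 10)
        assert e.values.max() > b.values.max()
        assert e.values.min() >= 0.0
        assert e.values.sum() == pytest.approx(b.values.sum(), rel=1e-6)


class TestEqualCountsSchedule:
    def test_second_duration_matches_root_finding_oracle(self):
        sched = equal_counts_schedule(5.0, 12, F18_HALF_LIFE_MIN)
        lam = math.log(2) / F18_HALF_LIFE_MIN
        target = 1 - math.exp(-lam * 5.0)
        d2 = optimize.brentq(
            lambda d: math.exp(-lam * 5.0) * (1 - math.exp(-lam * d)) - target, 1.0, 20.0
        )
        assert sched.durations_min[1] == pytest.approx(d2, abs=1e-9)
        assert sched.durations_min[1] == pytest.approx(5.163, abs=2e-3)

    def test_counts_equal_by_quadrature(self):
        sched = equal_counts_schedule(5.0, 12, F18_HALF_LIFE_MIN)
        lam = sched.decay_constant
        counts = [
            integrate.quad(lambda t: math.exp(-lam * t), t0, t0 + d)[0]
            for t0, d in zip(sched.start_times_min, sched.durations_min)
        ]
        assert (max(counts) - min(counts)) / counts[0] < 1e-3
        assert all(b > a for a, b in zip(sched.durations_min, sched.durations_min[1:]))

    def test_no_decay_limit_gives_equal_durations(self):
        sched = equal_counts_schedule(5.0, 12, math.inf)
        assert set(sched.durations_min) == {5.0}

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            equal_counts_schedule(0.0, 12)
        with pytest.raises(ValueError):
            equal_counts_schedule(5.0, 12, -3.0)
        with pytest.raises(ValueError, match="infeasible"):
            equal_counts_schedule(60.0, 12, 10.0)


@pytest.fixture(scope="module")
def flat_image():
    return ActivityImage(np.full((24, 24, 24), 2.0), GridSpec((4, 4, 4), (24, 24, 24)))


class TestAddNoise:
    def test_same_seed_reproduces_exactly(self, flat_image):
        sched = FrameSchedule((0.0,), (5.0,), math.inf)
        nm = NoiseModel(40.0, seed=7)
        a = add_noise(flat_image, nm, sched, 0)
        b = add_noise(flat_image, nm, sched, 0)
        assert np.array_equal(a.values, b.values)

    def test_sd_halves_when_counts_quadruple(self, flat_image, rng):
        sched = FrameSchedule((0.0,), (5.0,), math.inf)
        sds = {}
        for scale in (40.0, 160.0):
            vals = [
                add_noise(
                    flat_image, NoiseModel(scale), sched, 0, rng=int(rng.integers(2**31))
                ).values.std()
                for _ in range(100)
            ]
            sds[scale] = np.mean(vals)
        assert sds[160.0] / sds[40.0] == pytest.approx(0.5, rel=0.05)

    def test_equal_count_frames_have_equal_background_cv(self, flat_image, rng):
        sched = equal_counts_schedule(5.0, 12, F18_HALF_LIFE_MIN)
        nm = NoiseModel(40.0)
        cvs = []
        for frame in (0, 11):
            vals = [
                add_noise(flat_image, nm, sched, frame, rng=int(rng.integers(2**31))).values.std()
                for _ in range(200)
            ]
            cvs.append(np.mean(vals) / 2.0)
        assert cvs[0] == pytest.approx(cvs[1], rel=0.05)

    def test_unbiased_in_the_mean(self, flat_image, rng):
        sched = FrameSchedule((0.0,), (5.0,), math.inf)
        nm = NoiseModel(40.0, post_filter_fwhm_mm=7.0, white_fraction=0.15)
        means = [
            add_noise(flat_image, nm, sched, 0, rng=int(rng.integers(2**31))).values.mean()
            for _ in range(50)
        ]
        assert np.mean(means) == pytest.approx(2.0, rel=2e-3)

    def test_invalid_inputs_rejected(self, flat_image):
        sched = FrameSchedule((0.0,), (5.0,), math.inf)
        with pytest.raises(ValueError):
            NoiseModel(0.0)
        with pytest.raises(ValueError):
            NoiseModel(10.0, white_fraction=1.5)
        with pytest.raises(IndexError):
            add_noise(flat_image, NoiseModel(10.0), sched, 3)


@pytest.fixture(scope="module")
def scene():
    return build_mini_iq_scene(20.0, 2.0, sphere_diameters=(13.0,), box_half_mm=28.0)


class TestSimulateReplicate:
    def test_identity_composition_matches_direct_voxelization(self, scene):
        grid = GridSpec.cover(*scene.bounds(), (4.0, 4.0, 4.0), margin=4)
        profile = ReconProfile(grid=grid, fwhm_mm=0.0, supersampling=2)
        sched = FrameSchedule((0.0,), (5.0,), math.inf)
        out = simulate_replicate(scene, profile, sched, 0)
        # fine voxelization + exact block mean == coarse voxelization whose
        # supersampling refines each axis by the same total factor
        direct = voxelize_scene(scene, grid, 2 * profile.fine_factors()[0])
        assert np.allclose(out.values, direct.values, rtol=1e-12, atol=1e-12)

    def test_downsampling_conserves_activity(self, scene):
        grid = GridSpec.cover(*scene.bounds(), (4.0, 4.0, 4.0), margin=4)
        profile = ReconProfile(grid=grid, fwhm_mm=7.0, supersampling=2)
        fine = simulate_clean_fine(scene, profile)
        for f in ((4, 4, 4), (2, 2, 2)):
            coarse = downsample(fine, f)
            assert coarse.total_activity_kBq == pytest.approx(
                fine.total_activity_kBq, rel=1e-3
            )

    def test_series_is_bit_reproducible(self, scene):
        grid = GridSpec.cover(*scene.bounds(), (4.0, 4.0, 4.0), margin=24)
        profile = ReconProfile(grid=grid, fwhm_mm=7.0, supersampling=2)
        sched = FrameSchedule((0.0,), (5.0,), math.inf)
        noise = NoiseModel(40.0, 7.0, 0.15)

        def series():
            out = []
            for rep in range(3):
                t = sample_transform(5.0, 20.0, 100 + rep)
                out.append(
                    simulate_replicate(scene, profile, sched, 0, t, noise, noise_rng=200 + rep)
                )
            return out

        for a, b in zip(series(), series()):
            assert np.array_equal(a.values, b.values)

    def test_provenance_records_each_step(self, scene):
        grid = GridSpec.cover(*scene.bounds(), (4.0, 4.0, 4.0), margin=24)
        profile = ReconProfile(
            grid=grid, fwhm_mm=7.0, psf=PsfEmulation(7.0, 2), supersampling=2
        )
        sched = FrameSchedule((0.0,), (5.0,), math.inf)
        t = sample_transform(5.0, 20.0, 3)
        img = simulate_replicate(scene, profile, sched, 0, t, NoiseModel(40.0), noise_rng=1)
        ops = [step["op"] for step in img.provenance]
        assert ops == [
            "transform",
            "voxelize",
            "blur",
            "psf_enhance",
            "downsample",
            "recon_profile",
            "add_noise",
        ]
        step = img.find_step("transform")
        assert tuple(step["rotation_deg"]) == t.rotation_deg
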