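import math

import numpy as np
import pytest

from cardiopet import (
    PhantomSpec,
    generate_dynamic_series,
    generate_gated_series,
    generate_static_phantom,
    misalign_labels,
    randomize_heart_interior,
)
from cardiopet.synthetic_phantom import blood_input_curve, myocardial_uptake_curve
from cardiopet.volumetric_io import GeometryError, LabelMap, Task, Unit, VolumeGrid, LM
from cardiopet.metrics import overlap_metrics


class TestSpecValidation:
    def test_endo_must_be_inside_epi(self):
        with pytest.raises(ValueError):
            PhantomSpec(lv_endo_axes_mm=(31.0, 22.0, 32.0))

    def test_ef_range(self):
        with pytest.raises(ValueError):
            PhantomSpec(ef_target_pct=95.0)

    def test_gate_count(self):
        with pytest.raises(ValueError):
            PhantomSpec(n_gates=1)


class TestStaticPhantom:
    def test_compartments_disjoint_and_inside_heart(self, clean_phantom):
        t = clean_phantom
        heart = t.whole_heart.foreground()
        for code in (1, 2, 3):
            assert (t.truth_labels.mask(code) & ~heart).sum() == 0

    def test_true_volumes_equal_voxel_counting(self, clean_phantom):
        t = clean_phantom
        vv = t.truth_labels.voxel_volume_mm3 / 1000.0
        assert t.true_volumes_ml["LM"] == pytest.approx(t.truth_labels.mask(1).sum() * vv)
        assert t.true_volumes_ml["LV_cavity"] == pytest.approx(
            t.truth_labels.mask(2).sum() * vv
        )

    def test_zero_noise_zero_blur_pet_is_piecewise_constant(self, clean_phantom):
        t = clean_phantom
        spec = t.spec
        assert np.all(t.pet.values[t.truth_labels.mask(1)] == spec.uptake_lm)
        assert np.all(t.pet.values[t.truth_labels.mask(2)] == spec.uptake_lv_cavity)

    def test_zero_misalignment_gives_identical_ct_labels(self, clean_phantom):
        t = clean_phantom
        assert np.array_equal(t.ct_labels.labels, t.truth_labels.labels)

    def test_no_defect_limit(self):
        base = PhantomSpec(psf_fwhm_mm=0, noise_scale=0, seed=2)
        with_null_defect = PhantomSpec(
            psf_fwhm_mm=0, noise_scale=0, seed=2,
            defect_extent_deg=60.0, defect_reduction=1.0,
        )
        a = generate_static_phantom(base)
        b = generate_static_phantom(with_null_defect)
        np.testing.assert_array_equal(a.pet.values, b.pet.values)

    def test_defect_reduces_pet_only_not_truth(self):
        spec = PhantomSpec(psf_fwhm_mm=0, noise_scale=0, seed=2,
                           defect_extent_deg=60.0, defect_reduction=0.5)
        t = generate_static_phantom(spec)
        base = generate_static_phantom(PhantomSpec(psf_fwhm_mm=0, noise_scale=0, seed=2))
        assert np.array_equal(t.truth_labels.labels, base.truth_labels.labels)
        lm = t.truth_labels.mask(LM)
        assert t.pet.values[lm].min() == pytest.approx(spec.uptake_lm * 0.5)
        assert t.pet.values[lm].max() == pytest.approx(spec.uptake_lm)

    def test_lm_volume_approaches_analytic_shell(self):
        # voxelized shell volume converges on (4/3)π(a1b1c1 − a2b2c2)
        spec = PhantomSpec(shape=(96, 96, 96), spacing=(1.5, 1.5, 1.5),
                           psf_fwhm_mm=0, noise_scale=0)
        t = generate_static_phantom(spec)
        analytic = spec.analytic_lm_shell_ml()
        assert t.true_volumes_ml["LM"] == pytest.approx(analytic, rel=0.02)

    def test_bit_reproducible_under_seed(self):
        a = generate_static_phantom(PhantomSpec(seed=9))
        b = generate_static_phantom(PhantomSpec(seed=9))
        np.testing.assert_array_equal(a.pet.values, b.pet.values)
        c = generate_static_phantom(PhantomSpec(seed=10))
        assert not np.array_equal(a.pet.values, c.pet.values)


class TestMisalignLabels:
    def test_zero_shift_identity(self, clean_phantom):
        out = misalign_labels(clean_phantom.truth_labels, (0, 0, 0))
        assert np.array_equal(out.labels, clean_phantom.truth_labels.labels)

    def test_one_voxel_shift_is_index_shift(self):
        labels = np.zeros((6, 6, 6), np.int16)
        labels[2, 3, 3] = 1
        lmap = LabelMap(labels, (2.0, 2.0, 2.0))
        out = misalign_labels(lmap, (2.0, 0.0, 0.0))
        expected = np.zeros_like(labels)
        expected[3, 3, 3] = 1
        assert np.array_equal(out.labels, expected)

    def test_codes_preserved(self, clean_phantom):
        out = misalign_labels(clean_phantom.truth_labels, (3.0, -5.0, 2.0))
        assert set(np.unique(out.labels)) <= {0, 1, 2, 3}

    def test_opposite_shifts_recover_overlap(self):
        # for a convex mask, shifting out and back beats the single shift
        labels = np.zeros((16, 16, 16), np.int16)
        labels[5:11, 5:11, 5:11] = 1
        lmap = LabelMap(labels, (1.0, 1.0, 1.0))
        once = misalign_labels(lmap, (3.0, 0.0, 0.0))
        back = misalign_labels(once, (-3.0, 0.0, 0.0))
        d_once = overlap_metrics(once.labels > 0, labels > 0)[0]
        d_back = overlap_metrics(back.labels > 0, labels > 0)[0]
        assert d_back >= d_once


class TestGatedSeries:
    def test_zero_ef_gives_identical_gates(self):
        spec = PhantomSpec(ef_target_pct=0.0, psf_fwhm_mm=0, noise_scale=0)
        t = generate_gated_series(spec)
        for g in t.gates[1:]:
            assert np.array_equal(g.truth_labels.labels, t.gates[0].truth_labels.labels)

    def test_analytic_curve_ef_exact(self):
        spec = PhantomSpec(ef_target_pct=60.0, n_gates=8)
        t = generate_gated_series(spec)
        c = t.analytic_volume_curve_ml
        assert (max(c) - min(c)) / max(c) == pytest.approx(0.60, abs=1e-12)

    def test_voxelized_curve_tracks_analytic(self):
        spec = PhantomSpec(ef_target_pct=55.0, psf_fwhm_mm=0, noise_scale=0)
        t = generate_gated_series(spec)
        vox = [g.true_volumes_ml["LV_cavity"] for g in t.gates]
        for v, a in zip(vox, t.analytic_volume_curve_ml):
            assert v == pytest.approx(a, rel=0.04)  # voxelization error at 2 mm


class TestDynamicSeries:
    def test_pre_arrival_frame_is_background(self):
        spec = PhantomSpec(psf_fwhm_mm=0, noise_scale=0, blood_onset_s=4.0)
        t = generate_dynamic_series(spec)
        cavity = t.truth_labels.mask(2)
        assert t.frames[0].values[cavity].max() < 0.1

    def test_late_frame_myocardium_dominant(self):
        spec = PhantomSpec(psf_fwhm_mm=0, noise_scale=0, n_frames=30)
        t = generate_dynamic_series(spec)
        last = t.frames[-1]
        lm_mean = last.values[t.truth_labels.mask(1)].mean()
        cav_mean = last.values[t.truth_labels.mask(2)].mean()
        assert lm_mean > cav_mean

    def test_frame_values_integrate_input_function(self):
        # frame amplitude x duration must match the numeric integral of the
        # blood curve over the frame window
        spec = PhantomSpec(psf_fwhm_mm=0, noise_scale=0, n_frames=20)
        t = generate_dynamic_series(spec)
        cavity = t.truth_labels.mask(2)
        for i in (5, 8, 12):
            t0, t1 = i * spec.frame_duration_s, (i + 1) * spec.frame_duration_s
            ts = np.linspace(t0, t1, 2001)
            integral = np.trapezoid(blood_input_curve(spec, ts), ts)
            frame_val = t.frames[i].values[cavity].max()
            assert frame_val * spec.frame_duration_s == pytest.approx(integral, rel=0.02)


class TestRandomizeHeartInterior:
    def test_outside_mask_bit_identical(self, clean_phantom):
        t = clean_phantom
        out = randomize_heart_interior(t.ct, t.whole_heart, seed=5)
        outside = ~t.whole_heart.foreground()
        assert np.array_equal(out.values[outside], t.ct.values[outside])

    def test_in_mask_range(self, clean_phantom):
        t = clean_phantom
        out = randomize_heart_interior(t.ct, t.whole_heart, seed=5)
        inside = t.whole_heart.foreground()
        assert out.values[inside].min() >= -100.0
        assert out.values[inside].max() <= 100.0

    def test_seeded_determinism(self, clean_phantom):
        t = clean_phantom
        a = randomize_heart_interior(t.ct, t.whole_heart, seed=5)
        b = randomize_heart_interior(t.ct, t.whole_heart, seed=5)
        c = randomize_heart_interior(t.ct, t.whole_heart, seed=6)
        assert np.array_equal(a.values, b.values)
        inside = t.whole_heart.foreground()
        assert not np.array_equal(a.values[inside], c.values[inside])

    def test_empty_mask_identity(self, clean_phantom):
        t = clean_phantom
        empty = t.whole_heart.with_labels(np.zeros_like(t.whole_heart.labels))
        out = randomize_heart_interior(t.ct, empty, seed=5)
        assert np.array_equal(out.values, t.ct.values)

    def test_geometry_mismatch(self, clean_phantom):
        t = clean_phantom
        other = LabelMap(np.zeros((10, 10, 10), np.int16), (2, 2, 2))
        with pytest.raises(GeometryError):
            randomize_heart_interior(t.ct, other, seed=0)

    def test_requires_hu_unit(self, clean_phantom):
        t = clean_phantom
        with pytest.raises(ValueError):
            randomize_heart_interior(t.pet, t.whole_heart, seed=0)
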