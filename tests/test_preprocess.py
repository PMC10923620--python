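"""Slice selection, resampling, normalization, and registration contracts."""

import dataclasses

import numpy as np
import pytest

from hccseg.phantom import generate_phantom
from hccseg.preprocess import (RegistrationParams, SlicePair,
                               normalize_intensity, prepare_case_slices,
                               register_phase2_to_phase1, resample_slice,
                               select_tumor_slices)


class TestSelectTumorSlices:
    def test_empty_mask_yields_empty_list(self, rng):
        v = rng.random((8, 8, 4))
        assert select_tumor_slices(v, v, np.zeros((8, 8, 4))) == []

    def test_exactly_the_foreground_slices_ascending(self, rng):
        v = rng.random((8, 8, 8))
        mask = np.zeros((8, 8, 8), dtype=np.uint8)
        mask[3, 4, [3, 4, 5]] = 1
        pairs = select_tumor_slices(v, v, mask, case_id="c")
        assert [p.slice_index for p in pairs] == [3, 4, 5]
        np.testing.assert_array_equal(pairs[0].phase1_slice, v[:, :, 3])

    def test_count_matches_brute_force_on_phantom(self, tiny_case):
        pairs = select_tumor_slices(tiny_case.phase1, tiny_case.phase2,
                                    tiny_case.gt_mask)
        brute = sum(1 for z in range(tiny_case.gt_mask.shape[2])
                    if tiny_case.gt_mask[:, :, z].sum() > 0)
        assert len(pairs) == brute

    def test_grid_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            select_tumor_slices(rng.random((8, 8, 4)), rng.random((8, 8, 5)),
                                np.zeros((8, 8, 4)))


class TestResampleSlice:
    def test_identity_when_already_target_size(self, rng):
        img = rng.random((16, 16))
        np.testing.assert_array_equal(resample_slice(img, (16, 16)), img)

    def test_halving_a_512_grid_to_256(self, rng):
        img = rng.random((512, 512)).astype(np.float32)
        out = resample_slice(img, (256, 256))
        assert out.shape == (256, 256)
        assert abs(float(out.mean()) - float(img.mean())) < 0.01

    def test_mask_resampling_stays_binary(self, rng):
        mask = (rng.random((20, 20)) > 0.5).astype(np.uint8)
        out = resample_slice(mask, (16, 16), is_mask=True)
        assert set(np.unique(out)) <= {0, 1}

    @pytest.mark.parametrize("target", [(100, 100), (8, 12), (4, 8)])
    def test_targets_not_divisible_by_eight_rejected(self, target, rng):
        with pytest.raises(ValueError, match="divisible by 8"):
            resample_slice(rng.random((32, 32)), target)


class TestNormalizeIntensity:
    def test_constant_slice_maps_to_zeros(self):
        out = normalize_intensity(np.full((8, 8), 3.5))
        assert np.all(out == 0.0)

    def test_affine_rescaling(self):
        img = np.array([[10.0, 15.0], [20.0, 12.5]])
        np.testing.assert_allclose(normalize_intensity(img), (img - 10) / 10)

    def test_output_spans_unit_interval(self, rng):
        out = normalize_intensity(rng.random((8, 8)) * 100 - 50)
        assert out.min() == 0.0 and out.max() == 1.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            normalize_intensity(np.array([[np.nan, 1.0]]))


class TestRegistration:
    def test_identity_inputs_give_null_field(self, tiny_case):
        fast = RegistrationParams(levels=2, iterations=5, grid_spacing=12)
        reg, field = register_phase2_to_phase1(tiny_case.phase1, tiny_case.phase1, fast)
        assert np.linalg.norm(field, axis=-1).mean() < 0.1

    def test_registration_does_not_worsen_alignment(self, tiny_case):
        fast = RegistrationParams(levels=2, iterations=8, grid_spacing=12)
        reg, _ = register_phase2_to_phase1(tiny_case.phase2, tiny_case.phase1, fast)
        pre = float(((np.float64(tiny_case.phase2) - tiny_case.phase1) ** 2).mean())
        post = float(((reg - tiny_case.phase1) ** 2).mean())
        assert post <= pre

    def test_residual_not_worse_than_misalignment(self, tiny_spec, tiny_case):
        # recovered field should reduce the displacement error inside the
        # liver, where intensity structure actually constrains it
        fast = RegistrationParams(levels=2, iterations=8, grid_spacing=12)
        _, field = register_phase2_to_phase1(tiny_case.phase2, tiny_case.phase1, fast)
        liver = tiny_case.liver_mask.astype(bool)
        resid = np.linalg.norm(field - tiny_case.true_deformation, axis=-1)[liver].mean()
        uncorrected = np.linalg.norm(tiny_case.true_deformation, axis=-1)[liver].mean()
        assert resid < uncorrected

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            register_phase2_to_phase1(rng.random((8, 8, 4)), rng.random((8, 8, 5)))


class TestPrepareCaseSlices:
    def test_slices_on_network_grid_and_binary(self, tiny_case):
        pairs = prepare_case_slices(tiny_case.phase1, tiny_case.phase2,
                                    tiny_case.gt_mask, (24, 24), "c")
        assert pairs
        for sp in pairs:
            assert sp.phase1_slice.shape == (24, 24)
            assert 0.0 <= sp.phase1_slice.min() and sp.phase1_slice.max() <= 1.0
            assert set(np.unique(sp.mask_slice)) <= {0, 1}

    def test_slice_pair_shape_validation(self, rng):
        with pytest.raises(ValueError):
            SlicePair(phase1_slice=rng.random((8, 8)),
                      phase2_slice=rng.random((8, 9)),
                      mask_slice=np.zeros((8, 8)))
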