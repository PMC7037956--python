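"""Similarity measures, rigid search curves, slice matching and warp selection."""

import numpy as np
import pytest

from patchent import (
    DeflectionSummary,
    DeformationField,
    IntensityImage,
    PatchSpec,
    SimilarityCurve,
    compute_descriptor_image,
    deformation_residual,
    mad_similarity,
    match_slices,
    mutual_information,
    normalized_convergence_rate,
    random_smooth_deformation,
    rigid_transform,
    select_best_deformation,
    similarity_curve,
    similarity_curves,
    standard_pair,
    standard_stack,
    warp_image,
)

from conftest import make_random_image


class TestMadSimilarity:
    def test_identity_is_zero(self, random_image_8bit):
        assert mad_similarity(random_image_8bit, random_image_8bit) == 0.0

    def test_hand_sum(self):
        a = np.array([[0.0, 1.0], [2.0, 3.0]])
        b = np.array([[1.0, 1.0], [2.0, 1.0]])
        assert mad_similarity(a, b) == pytest.approx(0.75)

    def test_constant_offset(self, rng):
        a = rng.normal(size=(8, 8))
        assert mad_similarity(a, a + 2.5) == pytest.approx(2.5)

    def test_symmetry(self, rng):
        a, b = rng.normal(size=(8, 8)), rng.normal(size=(8, 8))
        assert mad_similarity(a, b) == pytest.approx(mad_similarity(b, a), abs=1e-12)

    def test_l2_option(self):
        a = np.zeros((2, 2))
        b = np.full((2, 2), 3.0)
        assert mad_similarity(a, b, norm="l2") == pytest.approx(3.0)

    def test_errors(self, rng):
        with pytest.raises(ValueError):
            mad_similarity(np.zeros((2, 2)), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            mad_similarity(np.zeros((2, 2)), np.zeros((2, 2)), mask=np.zeros((2, 2), bool))


class TestMutualInformation:
    def test_self_information_equals_entropy(self, rng):
        img = make_random_image(rng, (64, 64), 8)
        from patchent import ProbabilityVector, measure

        h = np.bincount((img.pixels.ravel() * 16) >> 8, minlength=16)
        entropy = measure("m1", ProbabilityVector(h / h.sum()))
        assert mutual_information(img, img, bins=16) == pytest.approx(entropy, rel=1e-10)

    def test_independent_images_near_zero(self, rng):
        a = make_random_image(rng, (256, 256), 8)
        b = make_random_image(rng, (256, 256), 8)
        assert mutual_information(a, b, bins=16) < 0.02

    def test_bijective_remap_preserves_information(self, rng):
        a = make_random_image(rng, (64, 64), 8)
        perm = rng.permutation(256)
        b = IntensityImage(perm[a.pixels].astype(np.int32), 8)
        assert mutual_information(a, b, bins=256) == pytest.approx(
            mutual_information(a, a, bins=256), rel=1e-10
        )

    def test_symmetry(self, rng):
        a, b = standard_pair(3, size=32)
        assert mutual_information(a, b) == pytest.approx(
            mutual_information(b, a), abs=1e-12
        )


class TestRigidTransform:
    def test_identity_transform(self, random_image_8bit):
        out, mask = rigid_transform(random_image_8bit, 0.0)
        np.testing.assert_array_equal(out.pixels, random_image_8bit.pixels)
        assert mask.all()

    def test_quarter_turn_is_exact(self, rng):
        img = make_random_image(rng, (9, 9), 8)
        out, mask = rigid_transform(img, 90.0)
        np.testing.assert_array_equal(out.pixels, np.rot90(img.pixels, 1))
        assert mask.all()

    def test_shift_round_trip(self, rng):
        img = make_random_image(rng, (16, 16), 8)
        fwd, m1 = rigid_transform(img, 0.0, shift=(5.0, 0.0))
        back, m2 = rigid_transform(fwd, 0.0, shift=(-5.0, 0.0))
        both = m2 & np.roll(m1, -5, axis=1)
        np.testing.assert_array_equal(back.pixels[both], img.pixels[both])

    def test_rejects_wild_angle(self, random_image_8bit):
        with pytest.raises(ValueError):
            rigid_transform(random_image_8bit, 200.0)


class TestSimilarityCurve:
    def test_self_curve_minimum_at_identity(self, rng):
        img = make_random_image(rng, (24, 24), 8)
        curve = similarity_curve(img, img, "m1", PatchSpec(l=3), [-10, -5, 0, 5, 10])
        assert curve.best_parameter == 0.0
        assert curve.values[2] == pytest.approx(0.0, abs=1e-12)
        assert np.all(curve.values >= 0)

    def test_multimodal_pair_recovers_alignment(self):
        fixed, moving = standard_pair(4, size=64)
        curve = similarity_curve(
            fixed, moving, "m2", PatchSpec(l=5), list(range(-15, 16, 3))
        )
        assert abs(curve.best_parameter) <= 3.0

    def test_raw_mad_misled_by_contrast_inversion(self):
        fixed, moving = standard_pair(4, size=64)
        curve = similarity_curve(
            fixed, moving, "mad_raw", PatchSpec(l=5), list(range(-15, 16, 3))
        )
        assert curve.best_parameter != 0.0

    def test_batch_matches_individual(self, rng):
        fixed, moving = standard_pair(6, size=32)
        params = [-10, 0, 10]
        spec = PatchSpec(l=3)
        batch = similarity_curves(fixed, moving, ["m1", "m2", "mad_raw"], spec, params)
        for m in ("m1", "m2", "mad_raw"):
            single = similarity_curve(fixed, moving, m, spec, params)
            np.testing.assert_allclose(batch[m].values, single.values, atol=1e-12)

    def test_empty_parameters_rejected(self, random_image_8bit):
        with pytest.raises(ValueError):
            similarity_curve(random_image_8bit, random_image_8bit, "m1", PatchSpec(l=3), [])


class TestConvergenceRate:
    def _curve(self, values, params=None):
        params = params if params is not None else np.arange(-5, 6, dtype=float)
        return SimilarityCurve(
            parameters=np.asarray(params, float),
            values=np.asarray(values, float),
            method="m2",
            overlap=np.ones(len(values)),
        )

    def test_v_shape_is_one(self):
        p = np.arange(-5, 6, dtype=float)
        assert normalized_convergence_rate(self._curve(np.abs(p) / 5), 5.0) == 1.0

    def test_flat_curve_is_zero(self):
        assert normalized_convergence_rate(self._curve(np.ones(11)), 5.0) == 0.0

    def test_steeper_curve_scores_higher(self):
        p = np.arange(-5, 6, dtype=float)
        shallow = normalized_convergence_rate(self._curve((np.abs(p) / 5) ** 2), 2.0)
        steep = normalized_convergence_rate(self._curve(np.sqrt(np.abs(p) / 5)), 2.0)
        assert steep > shallow

    def test_radius_outside_range_rejected(self):
        p = np.arange(-5, 6, dtype=float)
        with pytest.raises(ValueError):
            normalized_convergence_rate(self._curve(np.abs(p)), 50.0)


class TestMatchSlices:
    def test_identical_stacks_match_exactly(self):
        stack = standard_stack(7, n_slices=5, size=32)
        ref = stack.modalities["t1"]
        summary = match_slices(ref, ref, "m1", PatchSpec(l=5, bins=16))
        assert summary.zdn == summary.total == 5
        assert summary.zdp == 100.0 and summary.failures == 0

    def test_shifted_stack_counts_one_slice_deflections(self):
        stack = standard_stack(7, n_slices=6, size=32)
        ref = stack.modalities["t1"]
        shifted = ref[1:] + [ref[-1]]  # each reference slice now shows the next anatomy
        summary = match_slices(shifted, ref, "m1", PatchSpec(l=5, bins=16))
        # found - reference = +1: deflections land on the inferior neighbour
        assert summary.rdn >= 4 and summary.failures == 0

    def test_summary_invariants(self):
        s = DeflectionSummary(rdn=2, ldn=3, zdn=20, failures=5, total=30)
        assert s.sum == 25
        assert s.zdp == pytest.approx(100 * 20 / 30)
        assert s.sum_probability == pytest.approx(100 * 25 / 30)
        with pytest.raises(ValueError):
            DeflectionSummary(rdn=1, ldn=1, zdn=1, failures=1, total=30)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            match_slices([], [], "m1", PatchSpec(l=3))


class TestDeformation:
    def test_zero_residual_for_identical_fields(self, rng):
        f = random_smooth_deformation(0, 16, 16, 2.0, 8.0)
        assert deformation_residual(f, f) == 0.0

    def test_constant_offset_pythagoras(self):
        d = np.zeros((4, 4, 2))
        g = d.copy()
        g[..., 0] += 3.0
        g[..., 1] += 4.0
        assert deformation_residual(DeformationField(g), DeformationField(d)) == pytest.approx(5.0)

    def test_matches_naive_double_loop(self, rng):
        dc = DeformationField(rng.normal(size=(6, 6, 2)))
        dg = DeformationField(rng.normal(size=(6, 6, 2)))
        acc = 0.0
        for i in range(6):
            for j in range(6):
                acc += np.sqrt(
                    (dc.d[i, j, 0] - dg.d[i, j, 0]) ** 2
                    + (dc.d[i, j, 1] - dg.d[i, j, 1]) ** 2
                )
        assert deformation_residual(dc, dg) == pytest.approx(acc / 36, abs=1e-12)

    def test_domain_mismatch_rejected(self):
        with pytest.raises(ValueError):
            deformation_residual(
                DeformationField(np.zeros((4, 4, 2))), DeformationField(np.zeros((5, 5, 2)))
            )

    def test_zero_amplitude_warp_is_identity(self, rng):
        img = make_random_image(rng, (16, 16), 8)
        fld = random_smooth_deformation(1, 16, 16, amplitude=0.0)
        np.testing.assert_array_equal(warp_image(img, fld).pixels, img.pixels)


class TestSelectBestDeformation:
    def test_single_candidate_returns_it(self, rng):
        img = make_random_image(rng, (16, 16), 8)
        truth = random_smooth_deformation(0, 16, 16, 2.0, 8.0)
        idx, tau = select_best_deformation(
            img, [(img, truth)], "mad_raw", PatchSpec(l=3), truth
        )
        assert idx == 0 and tau == 0.0

    def test_true_warp_selected_on_clean_pair(self):
        fixed_src, moving = standard_pair(8, size=32)
        truth = random_smooth_deformation(11, 32, 32, 2.0, 16.0)
        fixed = warp_image(fixed_src, truth)
        cands = [(warp_image(moving, truth), truth)]
        for i in range(5):
            f = random_smooth_deformation(50 + i, 32, 32, 2.0, 16.0)
            cands.append((warp_image(moving, f), f))
        idx, tau = select_best_deformation(fixed, cands, "m2", PatchSpec(l=5, bins=16), truth)
        assert idx == 0 and tau == 0.0

    def test_empty_candidates_rejected(self, random_image_8bit):
        truth = random_smooth_deformation(0, 16, 16, 1.0)
        with pytest.raises(ValueError):
            select_best_deformation(random_image_8bit, [], "m1", PatchSpec(l=3), truth)


class TestModalityInvariance:
    def test_descriptors_ignore_bijective_remaps(self, rng):
        img = make_random_image(rng, (32, 32), 4)
        perm = rng.permutation(16)
        remap = IntensityImage(perm[img.pixels].astype(np.int32), 4)
        spec = PatchSpec(l=5, bins=16)  # bins aligned with the remapped levels
        for kind in ("m1", "m2", "m3", "m4"):
            da = compute_descriptor_image(img, spec, kind)
            db = compute_descriptor_image(remap, spec, kind)
            assert mad_similarity(da, db) < 1e-9
        assert mad_similarity(img, remap) > 0.1 * 15
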