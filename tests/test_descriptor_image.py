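"""Descriptor images: engine correctness, range bounds, and scale behaviour."""

import numpy as np
import pytest
from scipy.ndimage import laplace

from patchent import (
    CoreFunctionKind,
    Estimator,
    IntensityImage,
    PatchSpec,
    Weighting,
    compress_bit_depth,
    compute_descriptor_image,
    compute_descriptor_images,
    extract_patch,
    measure,
    normalize_descriptor,
    parzen_estimate,
    standard_pair,
    upper_bound,
    variety_degree,
    weighted_histogram,
)
from patchent.patch_statistics import weight_map_for

from conftest import make_random_image

KINDS = list(CoreFunctionKind)


def naive_descriptor(image, spec, kind):
    """Independent per-pixel loop oracle built from the patch-level operations."""
    bins = spec.resolve_bins(image.bit_depth)
    wm = weight_map_for(spec)
    out = np.zeros(image.shape)
    for r in range(image.shape[0]):
        for c in range(image.shape[1]):
            patch = extract_patch(image, (r, c), spec.l)
            if spec.estimator is Estimator.PARZEN:
                pv = parzen_estimate(patch, wm, bins, image.bit_depth, spec.bandwidth)
            else:
                pv = weighted_histogram(patch, wm, bins, image.bit_depth)
            out[r, c] = measure(kind, pv)
    return out


class TestVarietyDegree:
    @pytest.mark.parametrize(
        "l,n,bins,expected",
        [(7, 13, None, 49), (65, 8, None, 256), (1, 8, None, 1), (9, 8, 16, 16)],
    )
    def test_min_rule(self, l, n, bins, expected):
        assert variety_degree(l, n, bins) == expected

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            variety_degree(0, 8)
        with pytest.raises(ValueError):
            variety_degree(3, 17)


class TestComputeDescriptorImage:
    @pytest.mark.parametrize("kind", KINDS)
    def test_monochrome_image_gives_zero_descriptor(self, kind):
        img = IntensityImage(np.full((12, 12), 100, dtype=np.int32), 8)
        d = compute_descriptor_image(img, PatchSpec(l=3), kind)
        np.testing.assert_array_equal(d.values, 0.0)

    @pytest.mark.parametrize("kind", KINDS)
    def test_tiled_ramp_attains_bound_in_interior(self, kind):
        # every interior 3x3 window holds the 9 values exactly once
        tile = np.arange(9, dtype=np.int32).reshape(3, 3)
        img = IntensityImage(np.tile(tile, (4, 4)), 4)
        spec = PatchSpec(l=3, bins=16)
        d = compute_descriptor_image(img, spec, kind)
        expected = upper_bound(kind, 9)
        np.testing.assert_allclose(d.values[1:-1, 1:-1], expected, atol=1e-9)

    @pytest.mark.parametrize(
        "spec",
        [
            PatchSpec(l=3),
            PatchSpec(l=5, weighting=Weighting.GAUSSIAN),
            PatchSpec(l=5, weighting=Weighting.MODIFIED, alpha=0.3),
            PatchSpec(l=5, bins=16, estimator=Estimator.PARZEN, bandwidth=1.5),
        ],
    )
    @pytest.mark.parametrize("kind", ["m1", "m2"])
    def test_matches_naive_loop(self, rng, spec, kind):
        img = make_random_image(rng, (12, 12), 8)
        d = compute_descriptor_image(img, spec, kind)
        np.testing.assert_allclose(d.values, naive_descriptor(img, spec, kind), atol=1e-12)

    @pytest.mark.parametrize("kind", KINDS)
    def test_values_within_bound(self, rng, kind):
        img = make_random_image(rng, (20, 20), 8)
        spec = PatchSpec(l=5)
        d = compute_descriptor_image(img, spec, kind)
        assert d.values.min() >= 0.0
        assert d.values.max() <= upper_bound(kind, d.r) + 1e-9

    def test_shared_pass_matches_single_kind(self, rng):
        img = make_random_image(rng, (16, 16), 8)
        spec = PatchSpec(l=5)
        joint = compute_descriptor_images(img, spec, ["m1", "m2"])
        for tag in ("m1", "m2"):
            single = compute_descriptor_image(img, spec, tag)
            np.testing.assert_array_equal(
                joint[CoreFunctionKind.from_tag(tag)].values, single.values
            )

    def test_patch_larger_than_image_rejected(self, rng):
        img = make_random_image(rng, (4, 4), 8)
        with pytest.raises(ValueError, match="exceeds"):
            compute_descriptor_image(img, PatchSpec(l=5), "m1")

    def test_bins_exceeding_levels_rejected(self, rng):
        img = make_random_image(rng, (8, 8), 2)
        with pytest.raises(ValueError, match="bins"):
            compute_descriptor_image(img, PatchSpec(l=3, bins=16), "m1")


class TestScaleBehaviour:
    def test_blur_increases_with_patch_size(self):
        # descriptor sets smooth out as l grows, like a widening blur
        img, _ = standard_pair(5, size=64)
        rough = []
        for l in (3, 7, 11, 15, 19):
            d = compute_descriptor_image(img, PatchSpec(l=l), "m2")
            rough.append(np.abs(laplace(d.values)).mean())
        assert all(np.diff(rough) < 0)

    def test_small_patches_duplicate_descriptor_values(self):
        img, _ = standard_pair(5, size=64)
        def duplicates(l):
            v = compute_descriptor_image(img, PatchSpec(l=l), "m2").values
            return v.size - np.unique(v).size
        assert duplicates(3) > duplicates(19)

    def test_descriptor_range_shrinks_with_bit_depth(self, rng):
        img = make_random_image(rng, (32, 32), 6)
        maxima = []
        for n in (6, 5, 4, 3, 2):
            comp = compress_bit_depth(img, n)
            d = compute_descriptor_image(comp, PatchSpec(l=9), "m2")
            maxima.append(d.values.max())
            assert d.values.max() <= upper_bound("m2", 1 << n) + 1e-9
        assert all(np.diff(maxima) < 0)


class TestCompressBitDepth:
    def test_identity_at_same_depth(self, rng):
        img = make_random_image(rng, (8, 8), 8)
        np.testing.assert_array_equal(compress_bit_depth(img, 8).pixels, img.pixels)

    def test_13_to_7_divides_by_64(self):
        img = IntensityImage(np.array([[8191, 64], [63, 0]], dtype=np.int32), 13)
        out = compress_bit_depth(img, 7)
        np.testing.assert_array_equal(out.pixels, [[127, 1], [0, 0]])
        assert out.bit_depth == 7

    def test_deepening_rejected(self, rng):
        with pytest.raises(ValueError):
            compress_bit_depth(make_random_image(rng, (4, 4), 8), 9)


class TestNormalizeDescriptor:
    def test_none_is_identity(self, rng):
        img = make_random_image(rng, (10, 10), 8)
        d = compute_descriptor_image(img, PatchSpec(l=3), "m1")
        assert normalize_descriptor(d, "none") is d

    def test_global_minmax_and_degenerate_rule(self, rng):
        img = make_random_image(rng, (10, 10), 8)
        d = compute_descriptor_image(img, PatchSpec(l=3), "m1")
        out = normalize_descriptor(d, "global_minmax")
        assert out.values.min() == 0.0 and out.values.max() == 1.0
        mono = IntensityImage(np.full((8, 8), 3, dtype=np.int32), 8)
        dm = compute_descriptor_image(mono, PatchSpec(l=3), "m1")
        np.testing.assert_array_equal(
            normalize_descriptor(dm, "global_minmax").values, 0.0
        )

    def test_two_value_affine_map(self):
        from patchent import DescriptorImage

        d = DescriptorImage(
            np.array([[0.0, 4.0], [4.0, 0.0]]), CoreFunctionKind.SHANNON, PatchSpec(l=3), 9
        )
        out = normalize_descriptor(d, "global_minmax")
        np.testing.assert_array_equal(out.values, [[0.0, 1.0], [1.0, 0.0]])

    def test_local_zscore_centres_values(self, rng):
        img = make_random_image(rng, (16, 16), 8)
        d = compute_descriptor_image(img, PatchSpec(l=3), "m1")
        out = normalize_descriptor(d, "local_zscore", window=5)
        assert abs(out.values.mean()) < 0.5

    def test_invalid_window_and_mode_rejected(self, rng):
        img = make_random_image(rng, (8, 8), 8)
        d = compute_descriptor_image(img, PatchSpec(l=3), "m1")
        with pytest.raises(ValueError):
            normalize_descriptor(d, "local_zscore", window=4)
        with pytest.raises(ValueError):
            normalize_descriptor(d, "sigmoid")
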