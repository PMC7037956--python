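"""Per-pixel uncertainty descriptor images — the shared "third modality".

Every pixel of the source image is replaced by the uncertainty of the
intensity distribution of its ``l x l`` neighbourhood, measured by one of the
four concave core functions.  The resulting real-valued image depends on local
structure and intensity *richness* but not on the particular grey values, so
two modalities of the same anatomy map to near-identical descriptor images and
can be compared with a mono-modal criterion.

The sliding-window computation is vectorized per intensity bin: the bin
indicator image is box-summed (uniform weighting, exact integer arithmetic) or
correlated with the separable weight kernel, which is algebraically identical
to accumulating each sample's weight into its bin patch by patch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional

import numpy as np
from scipy.ndimage import correlate1d, gaussian_filter1d, uniform_filter

from .core_functions import CoreFunctionKind, core_term, upper_bound
from .patch_statistics import (
    Estimator,
    IntensityImage,
    PatchSpec,
    Weighting,
    bin_intensities,
    _gaussian_profile,
)

__all__ = [
    "DescriptorImage",
    "variety_degree",
    "compute_descriptor_image",
    "compute_descriptor_images",
    "compress_bit_depth",
    "normalize_descriptor",
]

_BIN_CHUNK = 64  # bins processed per pass; bounds peak memory at ~chunk * H * W


def variety_degree(l: int, n: int, bins: Optional[int] = None) -> int:
    """Maximum number of distinguishable levels in a patch: min(l², 2^n, bins)."""
    if l < 1:
        raise ValueError(f"side length must be >= 1, got {l}")
    if not 1 <= n <= 16:
        raise ValueError(f"bit depth must be in 1..16, got {n}")
    r = min(l * l, 1 << n)
    if bins is not None:
        r = min(r, int(bins))
    return r


@dataclass(frozen=True)
class DescriptorImage:
    """A descriptor image: per-pixel patch uncertainty values in nats.

    ``values`` has the shape of the source image (mirror padding preserves
    size) and lies in ``[0, upper_bound(kind, r)]`` where ``r`` is the variety
    degree of the configuration.
    """

    values: np.ndarray = field(repr=False)
    kind: CoreFunctionKind
    spec: PatchSpec
    r: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def bound(self) -> float:
        return upper_bound(self.kind, self.r)


def compute_descriptor_image(
    image: IntensityImage, spec: PatchSpec, kind: "CoreFunctionKind | str"
) -> DescriptorImage:
    """Descriptor image of ``image`` under one core function.

    For each pixel the patch intensity distribution is estimated with the
    spec's weighting and estimator and reduced by the core-function measure.
    Deterministic for fixed inputs.
    """
    kind = CoreFunctionKind.from_tag(kind)
    return compute_descriptor_images(image, spec, [kind])[kind]


def compute_descriptor_images(
    image: IntensityImage, spec: PatchSpec, kinds: Iterable["CoreFunctionKind | str"]
) -> Dict[CoreFunctionKind, DescriptorImage]:
    """Descriptor images for several core functions in one sliding-window pass.

    The patch distribution estimate is shared across kinds, so asking for M1
    and M2 together costs barely more than one of them.
    """
    kinds = [CoreFunctionKind.from_tag(k) for k in kinds]
    n = image.bit_depth
    bins = spec.resolve_bins(n)
    l = spec.l
    if l > min(image.shape):
        raise ValueError(f"patch side {l} exceeds image extent {image.shape}")
    maps = _measure_maps(image.pixels, n, bins, spec, kinds)
    if spec.estimator is Estimator.PARZEN:
        r = bins  # smoothing can spread mass over more bins than l^2 samples
    else:
        r = variety_degree(l, n, bins)
    return {
        k: DescriptorImage(values=maps[k], kind=k, spec=spec, r=r) for k in kinds
    }


def _measure_maps(pixels, n, bins, spec, kinds):
    l = spec.l
    pad = l // 2
    binimg = bin_intensities(pixels, bins, n)
    padded = np.pad(binimg, pad, mode="symmetric")
    H, W = binimg.shape
    out = {k: np.zeros((H, W)) for k in kinds}

    uniform_hist = (
        spec.weighting is Weighting.UNIFORM and spec.estimator is Estimator.HISTOGRAM
    )
    if uniform_hist:
        # Integer counts + lookup table: p_i = c_i / l^2 with c_i in 0..l^2.
        samples = l * l
        tables = {k: core_term(k, np.arange(samples + 1) / samples) for k in kinds}
        for lo in range(0, bins, _BIN_CHUNK):
            ids = np.arange(lo, min(lo + _BIN_CHUNK, bins))
            onehot = padded[None, :, :] == ids[:, None, None]
            c = _box_counts(onehot, l)
            for k in kinds:
                out[k] += tables[k][c].sum(axis=0)
        return out

    if spec.estimator is Estimator.HISTOGRAM:
        for lo in range(0, bins, _BIN_CHUNK):
            ids = np.arange(lo, min(lo + _BIN_CHUNK, bins))
            p = _weighted_fractions(padded, ids, l, spec, H, W)
            for k in kinds:
                out[k] += core_term(k, p).sum(axis=0)
        return out

    # Parzen: the smoothing couples neighbouring bins, so build the full stack.
    ids = np.arange(bins)
    p = _weighted_fractions(padded, ids, l, spec, H, W)
    p = gaussian_filter1d(p, sigma=spec.bandwidth, axis=0, mode="reflect")
    np.clip(p, 0.0, None, out=p)
    p /= p.sum(axis=0, keepdims=True)
    for k in kinds:
        out[k] = core_term(k, p).sum(axis=0)
    return out


def _box_counts(onehot: np.ndarray, l: int) -> np.ndarray:
    """Sliding l x l sums of a (bins, H+l-1, W+l-1) indicator stack, exactly."""
    b, hp, wp = onehot.shape
    ii = np.zeros((b, hp + 1, wp + 1), dtype=np.int32)
    ii[:, 1:, 1:] = onehot.astype(np.int32).cumsum(axis=1).cumsum(axis=2)
    return ii[:, l:, l:] - ii[:, :-l, l:] - ii[:, l:, :-l] + ii[:, :-l, :-l]


def _weighted_fractions(padded, ids, l, spec, H, W):
    """Per-bin weighted histogram mass for every pixel, shape (len(ids), H, W)."""
    pad = l // 2
    if spec.weighting is Weighting.UNIFORM:
        c = _box_counts(padded[None, :, :] == ids[:, None, None], l).astype(float)
        return c / (l * l)
    onehot = (padded[None, :, :] == ids[:, None, None]).astype(float)
    g = _gaussian_profile(l, spec.effective_sigma)
    g = g / g.sum()
    c = correlate1d(onehot, g, axis=1, mode="constant")
    c = correlate1d(c, g, axis=2, mode="constant")
    c = c[:, pad : pad + H, pad : pad + W]
    if spec.weighting is Weighting.MODIFIED:
        centre = onehot[:, pad : pad + H, pad : pad + W]
        c = (1.0 - spec.alpha) * c + spec.alpha * centre
    np.clip(c, 0.0, 1.0, out=c)
    return c


def compress_bit_depth(image: IntensityImage, n_target: int) -> IntensityImage:
    """Reduce effective bit depth: each pixel becomes ``floor(v / 2^(n - n_target))``."""
    if not 1 <= n_target <= image.bit_depth:
        raise ValueError(
            f"target bit depth {n_target} must be in 1..{image.bit_depth}"
        )
    shift = image.bit_depth - n_target
    return IntensityImage(pixels=image.pixels >> shift, bit_depth=n_target)


def normalize_descriptor(
    desc: DescriptorImage, mode: str = "none", window: int = 9
) -> DescriptorImage:
    """Normalize descriptor values.

    ``none``: identity.  ``global_minmax``: affine map onto [0, 1] (a constant
    image maps to all zeros).  ``local_zscore``: per-pixel
    ``(D - local mean) / (local sd + 1e-8)`` over an odd square window.
    """
    v = desc.values
    if mode == "none":
        return desc
    if mode == "global_minmax":
        lo, hi = float(v.min()), float(v.max())
        out = np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)
    elif mode == "local_zscore":
        if window < 3 or window % 2 == 0:
            raise ValueError(f"window must be odd and >= 3, got {window}")
        mean = uniform_filter(v, size=window, mode="reflect")
        sq = uniform_filter(v * v, size=window, mode="reflect")
        sd = np.sqrt(np.clip(sq - mean * mean, 0.0, None))
        out = (v - mean) / (sd + 1e-8)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return DescriptorImage(values=out, kind=desc.kind, spec=desc.spec, r=desc.r)
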