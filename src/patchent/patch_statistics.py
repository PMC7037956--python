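"""Patch extraction, spatial weighting and patch intensity-distribution estimation.

A descriptor is computed from the intensity distribution of a square ``l x l``
neighbourhood.  Two patches with mirrored structure share a histogram, so a
non-uniform spatial weight over the patch (Gaussian, or a centre-boosted
"modified" Gaussian) is used to break that tie: each sample contributes its
weight, not 1, to its intensity bin.  The binned histogram may additionally be
smoothed along the bin axis by a discrete Gaussian kernel (Parzen-window
estimation) before the uncertainty measure is applied.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core_functions import ProbabilityVector

__all__ = [
    "IntensityImage",
    "as_pixels",
    "Weighting",
    "Estimator",
    "PatchSpec",
    "WeightMap",
    "extract_patch",
    "uniform_weight_map",
    "gaussian_weight_map",
    "modified_weight_map",
    "weight_map_for",
    "weighted_histogram",
    "parzen_estimate",
    "bin_intensities",
]


MAX_IMAGE_SIDE = 4096


@dataclass(frozen=True)
class IntensityImage:
    """A 2-D single-channel integer image with a declared bit depth ``n <= 16``.

    All pixel values must lie in ``[0, 2^n - 1]``.  The bit depth is the
    *effective* depth: a 13-bit MRI slice stored in a 16-bit container is
    declared with ``bit_depth=13``.
    """

    pixels: np.ndarray = field(repr=False)
    bit_depth: int

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"image must be 2-D, got shape {px.shape}")
        if not np.issubdtype(px.dtype, np.integer):
            raise TypeError(f"pixels must be integers, got dtype {px.dtype}")
        if not 1 <= self.bit_depth <= 16:
            raise ValueError(f"bit depth must be in 1..16, got {self.bit_depth}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        if max(px.shape) > MAX_IMAGE_SIDE:
            raise ValueError(f"image side exceeds {MAX_IMAGE_SIDE} pixels")
        lo, hi = int(px.min()), int(px.max())
        if lo < 0 or hi > (1 << self.bit_depth) - 1:
            raise ValueError(
                f"pixel range [{lo}, {hi}] outside [0, {(1 << self.bit_depth) - 1}] "
                f"for bit depth {self.bit_depth}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


def as_pixels(image) -> np.ndarray:
    """Pixel array of an :class:`IntensityImage` or a bare array."""
    return image.pixels if isinstance(image, IntensityImage) else np.asarray(image)


class Weighting(enum.Enum):
    UNIFORM = "uniform"
    GAUSSIAN = "gaussian"
    MODIFIED = "modified"


class Estimator(enum.Enum):
    HISTOGRAM = "histogram"
    PARZEN = "parzen"


@dataclass(frozen=True)
class PatchSpec:
    """Configuration of patch-based distribution estimation.

    Parameters
    ----------
    l:
        Odd patch side length in pixels (>= 3) so a unique centre exists.
    bins:
        Number of histogram bins; ``None`` resolves to ``min(l², 2^n, 256)``
        for an image of bit depth ``n``.
    weighting:
        Spatial weighting of the samples within the patch.
    sigma:
        Gaussian weight spread in pixels; ``None`` defaults to ``l / 4`` so
        that ±2σ stays inside the patch.
    estimator:
        ``HISTOGRAM`` for the raw weighted histogram, ``PARZEN`` for the
        kernel-smoothed variant.
    bandwidth:
        Parzen kernel standard deviation in bins.
    alpha:
        Centre point-mass fraction of the modified weighting, in [0, 1).
    """

    l: int = 7
    bins: Optional[int] = None
    weighting: Weighting = Weighting.UNIFORM
    sigma: Optional[float] = None
    estimator: Estimator = Estimator.HISTOGRAM
    bandwidth: float = 1.0
    alpha: float = 0.5

    def __post_init__(self) -> None:
        if self.l < 3 or self.l % 2 == 0:
            raise ValueError(f"patch side length must be odd and >= 3, got {self.l}")
        if self.bins is not None and self.bins < 2:
            raise ValueError(f"bins must be >= 2, got {self.bins}")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.bandwidth <= 0:
            raise ValueError(f"Parzen bandwidth must be positive, got {self.bandwidth}")
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError(f"alpha must be in [0, 1), got {self.alpha}")

    @property
    def effective_sigma(self) -> float:
        return self.sigma if self.sigma is not None else self.l / 4.0

    def resolve_bins(self, bit_depth: int) -> int:
        """Bins to use on an image of the given bit depth."""
        if self.bins is not None:
            if self.bins > 2 ** bit_depth:
                raise ValueError(
                    f"bins={self.bins} exceeds the 2^{bit_depth} intensity levels of the image"
                )
            return self.bins
        return min(self.l * self.l, 2 ** bit_depth, 256)


@dataclass(frozen=True)
class WeightMap:
    """An ``l x l`` non-negative spatial weight map with its centre index."""

    w: np.ndarray = field(repr=False)
    centre: tuple

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight map must be square")
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be non-negative and not all zero")
        object.__setattr__(self, "w", w)


def extract_patch(image, x: tuple, l: int) -> np.ndarray:
    """The ``l x l`` neighbourhood centred at ``x``, mirror-padded at borders.

    ``x`` is a (row, col) index that must lie inside the image; out-of-bounds
    samples are filled by symmetric (mirror) reflection, which never introduces
    intensity values absent from the image.
    """
    pixels = as_pixels(image)
    r, c = int(x[0]), int(x[1])
    if not (0 <= r < pixels.shape[0] and 0 <= c < pixels.shape[1]):
        raise IndexError(f"patch centre {x} outside image of shape {pixels.shape}")
    if l < 1 or l % 2 == 0:
        raise ValueError(f"side length must be odd and >= 1, got {l}")
    pad = l // 2
    padded = np.pad(pixels, pad, mode="symmetric")
    return padded[r : r + l, c : c + l].copy()


def uniform_weight_map(l: int) -> WeightMap:
    _check_l(l)
    return WeightMap(np.full((l, l), 1.0 / (l * l)), (l // 2, l // 2))


def gaussian_weight_map(l: int, sigma: float) -> WeightMap:
    """Isotropic Gaussian weights ``∝ exp(-‖d‖²/2σ²)``, normalized to sum 1.

    Point-symmetric about the centre, which carries the strict maximum.
    """
    _check_l(l)
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    g = _gaussian_profile(l, sigma)
    w = np.outer(g, g)
    return WeightMap(w / w.sum(), (l // 2, l // 2))


def modified_weight_map(l: int, sigma: float, alpha: float = 0.5) -> WeightMap:
    """Centre-boosted Gaussian: ``(1-α)·Gaussian + α·point mass at centre``.

    For ``α > 0`` the centre weight strictly exceeds the plain Gaussian centre
    weight, emphasising the pixel whose descriptor is being computed.
    """
    if not 0.0 <= alpha < 1.0:
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    base = gaussian_weight_map(l, sigma)
    w = (1.0 - alpha) * base.w
    w[base.centre] += alpha
    return WeightMap(w, base.centre)


def weight_map_for(spec: PatchSpec) -> WeightMap:
    """The weight map a :class:`PatchSpec` implies."""
    if spec.weighting is Weighting.UNIFORM:
        return uniform_weight_map(spec.l)
    if spec.weighting is Weighting.GAUSSIAN:
        return gaussian_weight_map(spec.l, spec.effective_sigma)
    return modified_weight_map(spec.l, spec.effective_sigma, spec.alpha)


def bin_intensities(values: np.ndarray, bins: int, bit_depth: int) -> np.ndarray:
    """Map intensity ``v`` to bin ``floor(v · bins / 2^n)`` (integer arithmetic)."""
    v = np.asarray(values)
    if not np.issubdtype(v.dtype, np.integer):
        raise TypeError("intensities must be integers")
    return (v.astype(np.int64) * bins) // (1 << bit_depth)


def weighted_histogram(
    patch: np.ndarray, weights: WeightMap, bins: int, bit_depth: int
) -> ProbabilityVector:
    """Weighted patch histogram, normalized to a probability vector.

    Each sample adds its spatial weight to its intensity bin; the result is
    normalized to sum 1 and has variety degree ``bins``.
    """
    patch = np.asarray(patch)
    if patch.shape != weights.w.shape:
        raise ValueError(f"patch shape {patch.shape} != weight shape {weights.w.shape}")
    if bins > 1 << bit_depth:
        raise ValueError(f"bins={bins} exceeds 2^{bit_depth} intensity levels")
    idx = bin_intensities(patch, bins, bit_depth)
    h = np.bincount(idx.ravel(), weights=weights.w.ravel(), minlength=bins)
    return ProbabilityVector(h / h.sum())


def parzen_estimate(
    patch: np.ndarray,
    weights: WeightMap,
    bins: int,
    bit_depth: int,
    bandwidth: float,
) -> ProbabilityVector:
    """Parzen-window estimate: the weighted histogram smoothed along the bin axis.

    The smoothing kernel is a discrete Gaussian of standard deviation
    ``bandwidth`` bins, reflected at the bin edges, and the result is
    renormalized to sum 1.
    """
    if bandwidth <= 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")
    raw = weighted_histogram(patch, weights, bins, bit_depth)
    sm = gaussian_filter1d(raw.p, sigma=bandwidth, mode="reflect")
    sm = np.clip(sm, 0.0, None)
    return ProbabilityVector(sm / sm.sum())


def _check_l(l: int) -> None:
    if l < 1 or l % 2 == 0:
        raise ValueError(f"side length must be odd and >= 1, got {l}")


def _gaussian_profile(l: int, sigma: float) -> np.ndarray:
    d = np.arange(l) - l // 2
    return np.exp(-(d * d) / (2.0 * sigma * sigma))
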