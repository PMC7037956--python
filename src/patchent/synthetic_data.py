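"""Synthetic multimodal phantoms with known ground truth.

Real multimodal MR data (T1/T2/PD renderings of one anatomy) share tissue
geometry but map tissues to very different — often reversed — intensity
levels.  The generators here emulate exactly that statistical structure:

* a smooth label volume of blob-shaped "tissues" that evolves gradually from
  slice to slice (thresholded smoothed noise on top of a nested radial field);
* modality renderings that assign each tissue a mean intensity, modulate it by
  a smooth multiplicative bias field (intensity nonuniformity, INU) and add
  Gaussian read-out noise, with a declared effective bit depth;
* band-limited random displacement fields for nonrigid experiments.

Defaults follow the study conditions the descriptors are meant for: 13-bit
intensities, 3% noise, 20% INU amplitude, and reversed tissue-contrast
orderings between the two modalities of a pair.  Every generator is a pure
function of its seed and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .patch_statistics import IntensityImage
from .similarity_registration import DeformationField

__all__ = [
    "PhantomStack",
    "make_label_volume",
    "render_modality",
    "standard_pair",
    "standard_stack",
    "random_smooth_deformation",
    "min_jacobian_determinant",
]

DEFAULT_BIT_DEPTH = 13
DEFAULT_NOISE_PCT = 3.0
DEFAULT_INU_PCT = 20.0
DEFAULT_N_TISSUES = 5
MIN_SLICE_CHANGE = 0.005  # fraction of labels that must change between slices


@dataclass(frozen=True)
class PhantomStack:
    """An aligned multimodal stack: one label volume, several renderings.

    Slice correspondence across modalities is index identity by construction.
    For multi-slice stacks adjacent label slices must differ in at least 0.5%
    of pixels, so slice matching is a non-degenerate problem.
    """

    labels: np.ndarray = field(repr=False)
    modalities: Dict[str, List[IntensityImage]]
    bit_depth: int
    seed: int

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 3:
            raise ValueError(f"label volume must be 3-D, got shape {lab.shape}")
        for name, stack in self.modalities.items():
            if len(stack) != lab.shape[0]:
                raise ValueError(f"modality {name!r} has {len(stack)} slices, labels {lab.shape[0]}")
            for img in stack:
                if img.shape != lab.shape[1:]:
                    raise ValueError(f"modality {name!r} slice shape mismatch")
        if lab.shape[0] > 1:
            changes = np.mean(lab[1:] != lab[:-1], axis=(1, 2))
            if np.any(changes < MIN_SLICE_CHANGE):
                raise ValueError(
                    f"adjacent label slices change by {changes.min():.4%} < {MIN_SLICE_CHANGE:.1%}"
                )
        object.__setattr__(self, "labels", lab)

    @property
    def n_slices(self) -> int:
        return self.labels.shape[0]


def make_label_volume(
    seed: int,
    n_slices: int,
    rows: int,
    cols: int,
    n_tissues: int = DEFAULT_N_TISSUES,
) -> np.ndarray:
    """Smooth blob-shaped tissue labels evolving gradually across slices.

    A nested radial field plus smoothed 3-D noise is split at its global
    quantiles into ``n_tissues`` level sets, so every tissue occupies roughly
    an equal share (and always at least 1%) of the volume.
    """
    if n_tissues < 3:
        raise ValueError(f"need at least 3 tissues, got {n_tissues}")
    if n_slices < 1 or rows < 8 or cols < 8:
        raise ValueError("degenerate volume size")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_slices, rows, cols))
    slice_sigma = 1.5 if n_slices > 1 else 0.0
    smooth = gaussian_filter(noise, sigma=(slice_sigma, rows / 16.0, cols / 16.0))
    smooth /= smooth.std() or 1.0
    rr = (np.arange(rows) - (rows - 1) / 2.0) / (rows / 2.0)
    cc = (np.arange(cols) - (cols - 1) / 2.0) / (cols / 2.0)
    radial = 1.0 - np.sqrt((rr[:, None] / 0.85) ** 2 + (cc[None, :] / 0.75) ** 2)
    fieldv = radial[None, :, :] + 0.9 * smooth
    edges = np.quantile(fieldv, np.linspace(0, 1, n_tissues + 1)[1:-1])
    return np.digitize(fieldv, edges).astype(np.int32)


def render_modality(
    labels: np.ndarray,
    lut: Sequence[float],
    noise_pct: float = DEFAULT_NOISE_PCT,
    inu_pct: float = DEFAULT_INU_PCT,
    n: int = DEFAULT_BIT_DEPTH,
    seed: int = 0,
) -> List[IntensityImage]:
    """Render a label volume into one intensity modality.

    Each pixel becomes ``clip(round(lut[label] * bias + ε))`` where ``bias`` is
    a smooth per-slice multiplicative field of amplitude ``±inu_pct/100`` and
    ``ε`` is zero-mean Gaussian noise with sd ``noise_pct/100`` of the full
    intensity range ``2^n - 1``.
    """
    lab = np.asarray(labels)
    if lab.ndim == 2:
        lab = lab[None]
    lut_arr = np.asarray(lut, dtype=float)
    if lab.max() >= lut_arr.size:
        raise ValueError(f"lut of size {lut_arr.size} does not cover label {lab.max()}")
    if not (0 <= noise_pct <= 100 and 0 <= inu_pct <= 100):
        raise ValueError("noise_pct and inu_pct must be in [0, 100]")
    top = (1 << n) - 1
    if lut_arr.min() < 0 or lut_arr.max() > top:
        raise ValueError(f"lut values must lie in [0, {top}]")
    rng = np.random.default_rng(seed)
    out: List[IntensityImage] = []
    h, w = lab.shape[1:]
    for s in range(lab.shape[0]):
        base = lut_arr[lab[s]]
        if inu_pct > 0:
            b = gaussian_filter(rng.standard_normal((h, w)), sigma=(h / 6.0, w / 6.0))
            peak = np.abs(b).max()
            if peak > 0:
                b /= peak
            base = base * (1.0 + inu_pct / 100.0 * b)
        if noise_pct > 0:
            base = base + rng.normal(0.0, noise_pct / 100.0 * top, size=(h, w))
        px = np.clip(np.rint(base), 0, top).astype(np.int32)
        out.append(IntensityImage(px, n))
    return out


def _tissue_means(n_tissues: int, n: int) -> np.ndarray:
    top = (1 << n) - 1
    return np.round(np.linspace(0.08, 0.92, n_tissues) * top)


def standard_pair(
    seed: int, size: int = 128, n_tissues: int = DEFAULT_N_TISSUES
) -> Tuple[IntensityImage, IntensityImage]:
    """The canonical aligned multimodal pair for curve experiments.

    One anatomy slice rendered twice at 13 bits with 3% noise and 20% INU,
    once with ascending tissue means ("T1-like") and once with the reversed
    ordering ("T2-like"), so raw intensities anti-correlate while structure
    is shared.
    """
    labels = make_label_volume(seed, 1, size, size, n_tissues)
    means = _tissue_means(n_tissues, DEFAULT_BIT_DEPTH)
    a = render_modality(labels, means, seed=_derive(seed, 1))[0]
    b = render_modality(labels, means[::-1], seed=_derive(seed, 2))[0]
    return a, b


def standard_stack(
    seed: int,
    n_slices: int = 30,
    size: int = 64,
    n_tissues: int = DEFAULT_N_TISSUES,
) -> PhantomStack:
    """An aligned bimodal multi-slice stack for slice-matching experiments."""
    labels = make_label_volume(seed, n_slices, size, size, n_tissues)
    means = _tissue_means(n_tissues, DEFAULT_BIT_DEPTH)
    return PhantomStack(
        labels=labels,
        modalities={
            "t1": render_modality(labels, means, seed=_derive(seed, 1)),
            "t2": render_modality(labels, means[::-1], seed=_derive(seed, 2)),
        },
        bit_depth=DEFAULT_BIT_DEPTH,
        seed=seed,
    )


def random_smooth_deformation(
    seed: int, rows: int, cols: int, amplitude: float = 3.0, scale: float = 32.0
) -> DeformationField:
    """A band-limited random displacement field with max norm ``amplitude``.

    White noise smoothed at correlation length ``scale/4`` pixels and rescaled
    so the largest displacement vector has length ``amplitude``.  Fields with
    ``amplitude < scale/2`` stay diffeomorphic (positive Jacobian), which
    :func:`min_jacobian_determinant` can verify.
    """
    if amplitude < 0:
        raise ValueError(f"amplitude must be >= 0, got {amplitude}")
    if amplitude == 0:
        return DeformationField(np.zeros((rows, cols, 2)))
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((rows, cols, 2))
    sm = gaussian_filter(raw, sigma=(scale / 4.0, scale / 4.0, 0.0))
    norms = np.sqrt(sm[..., 0] ** 2 + sm[..., 1] ** 2)
    peak = norms.max()
    if peak == 0:
        return DeformationField(np.zeros((rows, cols, 2)))
    return DeformationField(sm * (amplitude / peak))


def min_jacobian_determinant(fld: DeformationField) -> float:
    """Minimum determinant of ``I + ∇d`` over the field (positivity ⇒ invertible)."""
    d = fld.d
    d0r, d0c = np.gradient(d[..., 0])
    d1r, d1c = np.gradient(d[..., 1])
    det = (1.0 + d0r) * (1.0 + d1c) - d0c * d1r
    return float(det.min())


def _derive(seed: int, salt: int) -> int:
    """A derived sub-seed, kept below 2^31."""
    return int((seed * 1000003 + salt) % (2**31 - 1))
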