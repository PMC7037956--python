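"""Similarity measures and the registration-style experiments built on them.

The working criterion is the mean absolute difference (MAD, an L1 norm) of two
descriptor images; raw-intensity MAD and mutual information (MI) serve as
baselines.  On top of the measures sit the experiment drivers: rigid rotation
and translation similarity curves, stack slice-matching with deflection
bookkeeping, and selection of the best candidate among pre-generated
deformations scored by the residual ``τ`` against the ground-truth field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import map_coordinates, minimum_filter

from .core_functions import CoreFunctionKind
from .descriptor_image import (
    DescriptorImage,
    compute_descriptor_image,
    compute_descriptor_images,
)
from .patch_statistics import IntensityImage, PatchSpec

__all__ = [
    "DESCRIPTOR_METHODS",
    "SimilarityCurve",
    "DeflectionSummary",
    "DeformationField",
    "mad_similarity",
    "mutual_information",
    "rigid_transform",
    "warp_image",
    "similarity_curve",
    "similarity_curves",
    "average_curves",
    "normalized_convergence_rate",
    "match_slices",
    "deformation_residual",
    "select_best_deformation",
]

DESCRIPTOR_METHODS = ("m1", "m2", "m3", "m4")
ALL_METHODS = DESCRIPTOR_METHODS + ("mi", "mad_raw")


def _check_method(method: str) -> str:
    method = str(method).lower()
    if method not in ALL_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {ALL_METHODS}")
    return method


def _values(img) -> np.ndarray:
    if isinstance(img, DescriptorImage):
        return img.values
    if isinstance(img, IntensityImage):
        return img.pixels.astype(float)
    return np.asarray(img, dtype=float)


def mad_similarity(a, b, mask: Optional[np.ndarray] = None, norm: str = "l1") -> float:
    """Mean absolute difference of two images over an optional mask.

    Lower is more similar; 0 iff the images agree on the mask.  ``norm="l2"``
    returns the root-mean-square difference instead (some slice-matching
    baselines are reported with an L2 criterion).
    """
    va, vb = _values(a), _values(b)
    if va.shape != vb.shape:
        raise ValueError(f"shape mismatch {va.shape} vs {vb.shape}")
    if mask is None:
        mask = np.ones(va.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != va.shape:
            raise ValueError("mask shape must match the images")
    if not mask.any():
        raise ValueError("empty mask")
    diff = va[mask] - vb[mask]
    if norm == "l1":
        return float(np.mean(np.abs(diff)))
    if norm == "l2":
        return float(np.sqrt(np.mean(diff * diff)))
    raise ValueError(f"norm must be 'l1' or 'l2', got {norm!r}")


def mutual_information(
    a: IntensityImage,
    b: IntensityImage,
    bins: int = 64,
    mask: Optional[np.ndarray] = None,
) -> float:
    """Mutual information I(A, B) = H(A) + H(B) - H(A, B) in nats.

    Estimated from the joint ``bins x bins`` histogram of the two intensity
    images (unweighted).  Symmetric; ``MI(a, a)`` equals the marginal entropy.
    """
    pa, pb = a.pixels, b.pixels
    if pa.shape != pb.shape:
        raise ValueError(f"shape mismatch {pa.shape} vs {pb.shape}")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        pa, pb = pa[mask], pb[mask]
        if pa.size == 0:
            raise ValueError("empty mask")
    ia = (pa.astype(np.int64).ravel() * bins) >> a.bit_depth
    ib = (pb.astype(np.int64).ravel() * bins) >> b.bit_depth
    joint = np.bincount(ia * bins + ib, minlength=bins * bins).reshape(bins, bins)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])))


def rigid_transform(
    image: IntensityImage, angle: float, shift: Tuple[float, float] = (0.0, 0.0)
) -> Tuple[IntensityImage, np.ndarray]:
    """Rotate about the image centre and translate, with bilinear interpolation.

    ``shift`` is ``(dx, dy)`` in pixels (columns, rows).  Returns the
    transformed image and a boolean mask of pixels whose pre-image lies inside
    the source frame; pixels outside are set to 0 and masked out.
    """
    if abs(angle) > 180:
        raise ValueError(f"|angle| must be <= 180 degrees, got {angle}")
    px = image.pixels.astype(float)
    h, w = px.shape
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    dx, dy = float(shift[0]), float(shift[1])
    th = np.deg2rad(angle)
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    r0 = rows - dy - cr
    c0 = cols - dx - cc
    qr = np.cos(th) * r0 + np.sin(th) * c0 + cr
    qc = -np.sin(th) * r0 + np.cos(th) * c0 + cc
    vals = map_coordinates(px, [qr, qc], order=1, mode="constant", cval=0.0)
    mask = (qr >= 0) & (qr <= h - 1) & (qc >= 0) & (qc <= w - 1)
    top = (1 << image.bit_depth) - 1
    out = np.clip(np.rint(vals), 0, top).astype(image.pixels.dtype)
    out[~mask] = 0
    return IntensityImage(out, image.bit_depth), mask


@dataclass(frozen=True)
class DeformationField:
    """Per-pixel displacement vectors ``d(x)`` with an optional domain mask Ω.

    ``d`` has shape (rows, cols, 2) ordered (dr, dc); a warped image samples
    the source at ``x + d(x)``.
    """

    d: np.ndarray = field(repr=False)
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 3 or d.shape[2] != 2:
            raise ValueError(f"field must have shape (rows, cols, 2), got {d.shape}")
        if not np.all(np.isfinite(d)):
            raise ValueError("deformation field contains non-finite entries")
        object.__setattr__(self, "d", d)
        if self.mask is not None:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != d.shape[:2]:
                raise ValueError("mask shape must match the field")
            object.__setattr__(self, "mask", m)

    @property
    def shape(self) -> tuple:
        return self.d.shape[:2]


def warp_image(image: IntensityImage, fld: DeformationField) -> IntensityImage:
    """Warp an image by a displacement field (bilinear, edge-clamped)."""
    if fld.shape != image.shape:
        raise ValueError(f"field shape {fld.shape} != image shape {image.shape}")
    h, w = image.shape
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    vals = map_coordinates(
        image.pixels.astype(float),
        [rows + fld.d[..., 0], cols + fld.d[..., 1]],
        order=1,
        mode="nearest",
    )
    top = (1 << image.bit_depth) - 1
    return IntensityImage(
        np.clip(np.rint(vals), 0, top).astype(image.pixels.dtype), image.bit_depth
    )


def deformation_residual(d_c: DeformationField, d_g: DeformationField) -> float:
    """Registration residual τ: mean Euclidean norm of ``d_c - d_g`` over Ω."""
    if d_c.shape != d_g.shape:
        raise ValueError(f"domain mismatch {d_c.shape} vs {d_g.shape}")
    mask = d_c.mask if d_c.mask is not None else np.ones(d_c.shape, dtype=bool)
    if d_g.mask is not None and not np.array_equal(
        mask, d_g.mask
    ):
        raise ValueError("deformation fields have different domains")
    diff = d_c.d - d_g.d
    norms = np.sqrt(diff[..., 0] ** 2 + diff[..., 1] ** 2)
    return float(norms[mask].mean())


@dataclass(frozen=True)
class SimilarityCurve:
    """Similarity as a function of a rigid-transform parameter.

    ``parameters`` (degrees or pixels) is strictly increasing; ``values`` are
    dissimilarities for descriptor/raw-MAD methods (lower = better) and
    similarities for MI (higher = better).  ``overlap`` records the valid
    overlap fraction at each point.
    """

    parameters: np.ndarray
    values: np.ndarray
    method: str
    overlap: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.parameters, dtype=float)
        v = np.asarray(self.values, dtype=float)
        o = np.asarray(self.overlap, dtype=float)
        if not (len(p) == len(v) == len(o)):
            raise ValueError("parameter/value/overlap lengths differ")
        if len(p) == 0:
            raise ValueError("empty similarity curve")
        if np.any(np.diff(p) <= 0):
            raise ValueError("parameters must be strictly increasing")
        object.__setattr__(self, "parameters", p)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "overlap", o)

    @property
    def best_parameter(self) -> float:
        v = -self.values if self.method == "mi" else self.values
        return float(self.parameters[int(np.argmin(v))])


class _Scorer:
    """Evaluates one method's similarity against a fixed image, caching its descriptor."""

    def __init__(self, fixed: IntensityImage, method: str, spec: PatchSpec):
        self.method = _check_method(method)
        self.spec = spec
        self.fixed = fixed
        self._fixed_desc = None
        if self.method in DESCRIPTOR_METHODS:
            self._fixed_desc = compute_descriptor_image(
                fixed, spec, CoreFunctionKind.from_tag(self.method)
            )

    @property
    def higher_is_better(self) -> bool:
        return self.method == "mi"

    def score(self, moving: IntensityImage, mask: Optional[np.ndarray] = None) -> float:
        if self.method in DESCRIPTOR_METHODS:
            desc = compute_descriptor_image(
                moving, self.spec, CoreFunctionKind.from_tag(self.method)
            )
            m = mask
            if m is not None:
                # patches touching invalid pixels see fill values; shrink the mask
                m = minimum_filter(m.astype(np.uint8), size=self.spec.l, mode="constant", cval=0).astype(bool)
                if not m.any():
                    raise ValueError("valid overlap vanished after patch erosion")
            return mad_similarity(self._fixed_desc, desc, mask=m)
        if self.method == "mi":
            return mutual_information(self.fixed, moving, mask=mask)
        return mad_similarity(self.fixed, moving, mask=mask)


def similarity_curve(
    fixed: IntensityImage,
    moving: IntensityImage,
    method: str,
    spec: PatchSpec,
    parameters: Sequence[float],
    mode: str = "rotation",
) -> SimilarityCurve:
    """Similarity of ``fixed`` vs rigidly transformed ``moving`` over a parameter sweep.

    ``mode`` is ``"rotation"`` (degrees about the centre), ``"shift-x"`` or
    ``"shift-y"`` (pixels).  The moving image is transformed first and its
    descriptor recomputed on the transformed frame, so the descriptor sees the
    same resampling the intensities do.
    """
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving images must share a shape")
    params = list(parameters)
    if not params:
        raise ValueError("parameter list is empty")
    if mode not in ("rotation", "shift-x", "shift-y"):
        raise ValueError(f"unknown mode {mode!r}")
    scorer = _Scorer(fixed, method, spec)
    values, overlaps = [], []
    for p in params:
        if mode == "rotation":
            timg, mask = rigid_transform(moving, angle=p)
        elif mode == "shift-x":
            timg, mask = rigid_transform(moving, angle=0.0, shift=(p, 0.0))
        else:
            timg, mask = rigid_transform(moving, angle=0.0, shift=(0.0, p))
        values.append(scorer.score(timg, mask=mask))
        overlaps.append(float(mask.mean()))
    return SimilarityCurve(
        parameters=np.asarray(params, dtype=float),
        values=np.asarray(values),
        method=scorer.method,
        overlap=np.asarray(overlaps),
    )


def similarity_curves(
    fixed: IntensityImage,
    moving: IntensityImage,
    methods: Sequence[str],
    spec: PatchSpec,
    parameters: Sequence[float],
    mode: str = "rotation",
) -> Dict[str, SimilarityCurve]:
    """Similarity curves for several methods over one shared transform sweep.

    Descriptor methods share the patch-distribution pass at every transform
    position, so sweeping M1 and M2 together costs barely more than one of
    them.  Results are identical to calling :func:`similarity_curve` per
    method.
    """
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving images must share a shape")
    methods = [_check_method(m) for m in methods]
    params = list(parameters)
    if not params:
        raise ValueError("parameter list is empty")
    if mode not in ("rotation", "shift-x", "shift-y"):
        raise ValueError(f"unknown mode {mode!r}")
    desc_kinds = [CoreFunctionKind.from_tag(m) for m in methods if m in DESCRIPTOR_METHODS]
    fixed_desc = (
        compute_descriptor_images(fixed, spec, desc_kinds) if desc_kinds else {}
    )
    values: Dict[str, list] = {m: [] for m in methods}
    overlaps = []
    for p in params:
        if mode == "rotation":
            timg, mask = rigid_transform(moving, angle=p)
        elif mode == "shift-x":
            timg, mask = rigid_transform(moving, angle=0.0, shift=(p, 0.0))
        else:
            timg, mask = rigid_transform(moving, angle=0.0, shift=(0.0, p))
        overlaps.append(float(mask.mean()))
        if desc_kinds:
            mov_desc = compute_descriptor_images(timg, spec, desc_kinds)
            dmask = minimum_filter(mask.astype(np.uint8), size=spec.l, mode="constant", cval=0).astype(bool)
            if not dmask.any():
                raise ValueError("valid overlap vanished after patch erosion")
        for m in methods:
            if m in DESCRIPTOR_METHODS:
                kind = CoreFunctionKind.from_tag(m)
                values[m].append(
                    mad_similarity(fixed_desc[kind], mov_desc[kind], mask=dmask)
                )
            elif m == "mi":
                values[m].append(mutual_information(fixed, timg, mask=mask))
            else:
                values[m].append(mad_similarity(fixed, timg, mask=mask))
    p_arr = np.asarray(params, dtype=float)
    o_arr = np.asarray(overlaps)
    return {
        m: SimilarityCurve(
            parameters=p_arr, values=np.asarray(values[m]), method=m, overlap=o_arr
        )
        for m in methods
    }


def average_curves(curves: Iterable[SimilarityCurve]) -> SimilarityCurve:
    """Point-wise mean of raw similarity curves sampled on the same grid.

    Averaging happens before any normalization, mirroring how multi-layer
    similarity curves are pooled before their shape is compared.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("no curves to average")
    p0 = curves[0].parameters
    method = curves[0].method
    for c in curves[1:]:
        if not np.array_equal(c.parameters, p0) or c.method != method:
            raise ValueError("curves must share parameter grid and method")
    return SimilarityCurve(
        parameters=p0,
        values=np.mean([c.values for c in curves], axis=0),
        method=method,
        overlap=np.mean([c.overlap for c in curves], axis=0),
    )


def normalized_convergence_rate(curve: SimilarityCurve, radius: float) -> float:
    """Steepness of a similarity curve around its extremum, scale-free.

    The curve is oriented so lower = better, min-max normalized to [0, 1], and
    the mean normalized value at the two points ``extremum ± radius`` is
    returned (linear interpolation between samples).  A flat curve returns 0.
    Higher values mean the curve rises faster away from the optimum.
    """
    v = -curve.values if curve.method == "mi" else curve.values.copy()
    p = curve.parameters
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        return 0.0  # flat curve: no extremum to converge to
    i0 = int(np.argmin(v))
    centre = p[i0]
    if centre - radius < p[0] - 1e-9 or centre + radius > p[-1] + 1e-9:
        raise ValueError(
            f"radius {radius} around extremum at {centre} exceeds the sampled range"
        )
    vn = (v - lo) / (hi - lo)
    left = float(np.interp(centre - radius, p, vn))
    right = float(np.interp(centre + radius, p, vn))
    return 0.5 * (left + right)


@dataclass(frozen=True)
class DeflectionSummary:
    """Slice-matching outcome counts over a stack.

    Right/left deflection: the best match is one slice after/before the true
    one; zero deflection: exact; failure: off by more than one slice.
    """

    rdn: int
    ldn: int
    zdn: int
    failures: int
    total: int

    def __post_init__(self) -> None:
        if self.rdn + self.ldn + self.zdn + self.failures != self.total:
            raise ValueError("deflection counts do not sum to the trial total")

    @property
    def sum(self) -> int:
        return self.rdn + self.ldn + self.zdn

    @property
    def zdp(self) -> float:
        """Zero-deflection percentage."""
        return 100.0 * self.zdn / self.total

    @property
    def sum_probability(self) -> float:
        """Percentage of matches within one slice of the truth."""
        return 100.0 * self.sum / self.total

    def as_dict(self) -> dict:
        return {
            "RDN": self.rdn,
            "LDN": self.ldn,
            "ZDN": self.zdn,
            "SUM": self.sum,
            "ZDP": self.zdp,
            "SUM_probability": self.sum_probability,
            "failures": self.failures,
            "total": self.total,
        }


def match_slices(
    reference: Sequence[IntensityImage],
    search: Sequence[IntensityImage],
    method: str,
    spec: PatchSpec,
) -> DeflectionSummary:
    """Match every reference slice to its most similar search slice.

    Ground truth is index identity: reference slice ``i`` corresponds to search
    slice ``i``.  The signed index difference (found - true) is classified as
    left (-1), zero (0), right (+1) deflection or failure (|diff| > 1).  Ties
    on the optimum are broken toward the lowest index.
    """
    reference, search = list(reference), list(search)
    if not reference or not search:
        raise ValueError("empty stack")
    method = _check_method(method)
    if method in DESCRIPTOR_METHODS:
        kind = CoreFunctionKind.from_tag(method)
        ref_desc = [compute_descriptor_image(s, spec, kind) for s in reference]
        sea_desc = [compute_descriptor_image(s, spec, kind) for s in search]

        def sim(i: int, j: int) -> float:
            return mad_similarity(ref_desc[i], sea_desc[j])

        better = min
    elif method == "mi":

        def sim(i: int, j: int) -> float:
            return mutual_information(reference[i], search[j])

        better = max
    else:

        def sim(i: int, j: int) -> float:
            return mad_similarity(reference[i], search[j])

        better = min

    rdn = ldn = zdn = failures = 0
    for i in range(len(reference)):
        scores = np.array([sim(i, j) for j in range(len(search))])
        j = int(np.argmax(scores)) if better is max else int(np.argmin(scores))
        diff = j - i
        if diff == 0:
            zdn += 1
        elif diff == 1:
            rdn += 1
        elif diff == -1:
            ldn += 1
        else:
            failures += 1
    return DeflectionSummary(
        rdn=rdn, ldn=ldn, zdn=zdn, failures=failures, total=len(reference)
    )


def select_best_deformation(
    fixed: IntensityImage,
    candidates: Sequence[Tuple[IntensityImage, DeformationField]],
    method: str,
    spec: PatchSpec,
    ground_truth: DeformationField,
) -> Tuple[int, float]:
    """Pick the candidate warp most similar to ``fixed``; score it against truth.

    ``candidates`` are (warped image, deformation field) pairs, one of which
    should stem from the ground-truth field.  Returns the selected index and
    the residual ``τ`` of its field against ``ground_truth``.  Ties broken
    toward the lowest index.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate list")
    scorer = _Scorer(fixed, method, spec)
    scores = np.array([scorer.score(img) for img, _ in candidates])
    idx = int(np.argmax(scores)) if scorer.higher_is_better else int(np.argmin(scores))
    tau = deformation_residual(candidates[idx][1], ground_truth)
    return idx, tau
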