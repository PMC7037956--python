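"""Reading and writing images and descriptor sets.

Intensity images are single-channel 8- or 16-bit PNG/TIFF rasters; the
*effective* bit depth (e.g. 13 bits stored in a 16-bit container) can be
declared explicitly.  Descriptor images are written as 32-bit float TIFF with
an 8-bit min-max preview PNG and a JSON sidecar recording the configuration.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import tifffile

from .core_functions import CoreFunctionKind
from .descriptor_image import DescriptorImage
from .patch_statistics import IntensityImage

__all__ = ["read_image", "write_image", "write_descriptor", "read_descriptor"]


def read_image(path, bit_depth: Optional[int] = None) -> IntensityImage:
    """Load a single-channel integer image.

    The bit depth is taken from the container dtype (uint8 → 8, uint16 → 16)
    unless ``bit_depth`` overrides it; values are validated against the
    declared range.  Multi-channel or floating-point rasters are rejected.
    """
    path = Path(path)
    arr = iio.imread(path)
    if arr.ndim == 3:
        raise ValueError(
            f"{path}: multi-channel image ({arr.shape[-1]} channels); "
            "convert to single-channel grayscale first"
        )
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D image, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(
            f"{path}: floating-point pixel data is unsupported; "
            "store intensities as 8- or 16-bit integers"
        )
    if bit_depth is None:
        bit_depth = 8 * arr.dtype.itemsize
        if bit_depth not in (8, 16):
            raise ValueError(f"{path}: unsupported container dtype {arr.dtype}")
    return IntensityImage(pixels=arr.astype(np.int32), bit_depth=bit_depth)


def write_image(image: IntensityImage, path) -> None:
    """Write an intensity image as PNG or TIFF (8-bit or 16-bit container)."""
    path = Path(path)
    dtype = np.uint8 if image.bit_depth <= 8 else np.uint16
    iio.imwrite(path, image.pixels.astype(dtype))


def write_descriptor(desc: DescriptorImage, path) -> None:
    """Write a descriptor image: float32 TIFF + 8-bit preview PNG + JSON sidecar.

    A read back with :func:`read_descriptor` reproduces the values to float32
    precision.  The preview is min-max scaled; a constant descriptor yields an
    all-zero preview.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, desc.values.astype(np.float32))
    v = desc.values
    lo, hi = float(v.min()), float(v.max())
    preview = (
        np.zeros(v.shape, dtype=np.uint8)
        if hi == lo
        else np.round(255.0 * (v - lo) / (hi - lo)).astype(np.uint8)
    )
    iio.imwrite(path.with_suffix(".preview.png"), preview)
    sidecar = {
        "kind": desc.kind.value,
        "l": desc.spec.l,
        "bins": desc.spec.bins,
        "r": desc.r,
        "weighting": desc.spec.weighting.value,
        "estimator": desc.spec.estimator.value,
        "bandwidth": desc.spec.bandwidth,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_descriptor(path) -> np.ndarray:
    """Read back the float32 values of a stored descriptor image."""
    return tifffile.imread(Path(path))
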