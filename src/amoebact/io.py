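"""Reading and writing images and sinograms.

Grayscale images round-trip either as 16-bit PNG (values quantized on
``[0, 1]``) or as 32-bit float TIFF (lossless).  Sinograms persist as float
TIFF plus a YAML sidecar carrying the acquisition geometry.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .ct import FanBeamGeometry, Sinogram

__all__ = ["read_image", "write_image", "read_sinogram", "write_sinogram"]


def write_image(path, image: np.ndarray) -> None:
    """Write a [0, 1] grayscale image as 16-bit PNG or 32-bit float TIFF."""
    path = Path(path)
    image = np.asarray(image, dtype=np.float64)
    if path.suffix.lower() == ".png":
        q = np.clip(np.round(image * 65535.0), 0, 65535).astype(np.uint16)
        iio.imwrite(path, q)
    elif path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.astype(np.float32))
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")


def read_image(path) -> np.ndarray:
    """Read an image back to a float array on [0, 1] (integer formats are
    rescaled by their bit depth; float TIFFs are taken as-is)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse RGB(A) to luminance
        arr = arr[..., :3].mean(axis=-1)
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float64) / np.iinfo(arr.dtype).max
    return arr.astype(np.float64)


def write_sinogram(path, sinogram: Sinogram) -> None:
    """Float TIFF of the projection values plus a ``.yaml`` geometry sidecar."""
    path = Path(path)
    tifffile.imwrite(path, sinogram.values.astype(np.float32))
    geom = sinogram.geometry
    sidecar = {
        "source_to_center": float(geom.source_to_center),
        "detector_spacing": float(geom.detector_spacing),
        "detector_count": int(geom.detector_count),
        "angles_deg": [float(a) for a in geom.angles_deg],
    }
    path.with_suffix(path.suffix + ".yaml").write_text(
        yaml.safe_dump(sidecar))


def read_sinogram(path) -> Sinogram:
    path = Path(path)
    values = tifffile.imread(path).astype(np.float64)
    sidecar = yaml.safe_load(path.with_suffix(path.suffix + ".yaml").read_text())
    geom = FanBeamGeometry(
        source_to_center=sidecar["source_to_center"],
        detector_spacing=sidecar["detector_spacing"],
        detector_count=sidecar["detector_count"],
        angles_deg=np.asarray(sidecar["angles_deg"], dtype=np.float64),
    )
    return Sinogram(values, geom)
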