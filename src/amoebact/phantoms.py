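"""Synthetic phantoms and piecewise-constant test images.

All images in this package share one convention: a 2-D float array indexed
``(row, col)``, row 0 at the top, values nominally in ``[0, 1]``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["shepp_logan", "piecewise_test_image", "roi_crop",
           "SHEPP_LOGAN_ELLIPSES", "MODIFIED_SHEPP_LOGAN_ELLIPSES"]

# Each row: (intensity, semi-axis a, semi-axis b, x0, y0, rotation phi in deg)
# on the unit square [-1, 1]^2, x to the right, y up.
SHEPP_LOGAN_ELLIPSES = [
    (2.00, 0.69, 0.92, 0.0, 0.0, 0.0),
    (-0.98, 0.6624, 0.8740, 0.0, -0.0184, 0.0),
    (-0.02, 0.1100, 0.3100, 0.22, 0.0, -18.0),
    (-0.02, 0.1600, 0.4100, -0.22, 0.0, 18.0),
    (0.01, 0.2100, 0.2500, 0.0, 0.35, 0.0),
    (0.01, 0.0460, 0.0460, 0.0, 0.10, 0.0),
    (0.01, 0.0460, 0.0460, 0.0, -0.10, 0.0),
    (0.01, 0.0460, 0.0230, -0.08, -0.605, 0.0),
    (0.01, 0.0230, 0.0230, 0.0, -0.606, 0.0),
    (0.01, 0.0230, 0.0460, 0.06, -0.605, 0.0),
]

# Same geometry, higher-contrast gray levels (the variant MATLAB's
# ``phantom`` uses by default; interior features become visible).
MODIFIED_SHEPP_LOGAN_ELLIPSES = [
    (1.00,) + e[1:] for e in SHEPP_LOGAN_ELLIPSES[:1]
] + [
    (-0.80,) + SHEPP_LOGAN_ELLIPSES[1][1:],
    (-0.20,) + SHEPP_LOGAN_ELLIPSES[2][1:],
    (-0.20,) + SHEPP_LOGAN_ELLIPSES[3][1:],
] + [(0.10,) + e[1:] for e in SHEPP_LOGAN_ELLIPSES[4:]]


def _render_ellipses(size: int, ellipses) -> np.ndarray:
    # pixel centers on [-1, 1]^2; row 0 maps to y = +1 edge
    axis = (np.arange(size) + 0.5) * 2.0 / size - 1.0
    x = axis[np.newaxis, :]
    y = -axis[:, np.newaxis]
    img = np.zeros((size, size), dtype=np.float64)
    for val, a, b, x0, y0, phi in ellipses:
        c, s = np.cos(np.deg2rad(phi)), np.sin(np.deg2rad(phi))
        xr = (x - x0) * c + (y - y0) * s
        yr = -(x - x0) * s + (y - y0) * c
        img[(xr / a) ** 2 + (yr / b) ** 2 <= 1.0] += val
    return img


def shepp_logan(size: int, *, modified: bool = False) -> np.ndarray:
    """Render the Shepp-Logan head phantom on a ``size x size`` grid.

    Parameters
    ----------
    size : int
        Output edge length in pixels, at least 16.
    modified : bool
        If True use the high-contrast gray-level variant (soft tissue at
        ~0.2-0.4 instead of ~0.01-0.04); geometry is identical.

    Returns
    -------
    ndarray
        Float image with values clipped to ``[0, 1]``.
    """
    if size < 16:
        raise ValueError(f"size must be >= 16, got {size}")
    table = MODIFIED_SHEPP_LOGAN_ELLIPSES if modified else SHEPP_LOGAN_ELLIPSES
    return np.clip(_render_ellipses(int(size), table), 0.0, 1.0)


def piecewise_test_image(size: int, levels, layout: str = "nested") -> np.ndarray:
    """Piecewise-constant image of nested regions at the given gray levels.

    Emulates the canonical multi-level test image used to illustrate kernel
    shaping: a handful of intensity plateaus separated by straight edges,
    each region several filter windows wide.

    Parameters
    ----------
    size : int
        Edge length in pixels.
    levels : sequence of float
        Strictly increasing intensities in [0, 1], outermost region first.
        A single level yields a constant image.
    layout : {"nested", "bands"}
        "nested" draws concentric squares; "bands" draws vertical stripes.
    """
    levels = list(levels)
    if size < 1:
        raise ValueError("size must be positive")
    if not (1 <= len(levels) <= 8):
        raise ValueError("need between 1 and 8 levels")
    if any(not (0.0 <= v <= 1.0) for v in levels):
        raise ValueError("levels must lie in [0, 1]")
    if any(b <= a for a, b in zip(levels, levels[1:])):
        raise ValueError("levels must be strictly increasing")

    img = np.full((size, size), levels[0], dtype=np.float64)
    k = len(levels)
    if k == 1:
        return img
    if layout == "nested":
        # region n is a centered square inset by n rings of width size/(2k)
        for n in range(1, k):
            inset = int(round(n * size / (2 * k)))
            img[inset:size - inset, inset:size - inset] = levels[n]
    elif layout == "bands":
        edges = np.linspace(0, size, k + 1).round().astype(int)
        for n in range(1, k):
            img[:, edges[n]:] = levels[n]
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return img


def roi_crop(image: np.ndarray, top: int, left: int, h: int, w: int) -> np.ndarray:
    """Return the ``h x w`` sub-image with corner at ``(top, left)``; no resampling."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a 2-D image")
    if h < 1 or w < 1:
        raise ValueError("crop extent must be positive")
    if top < 0 or left < 0 or top + h > image.shape[0] or left + w > image.shape[1]:
        raise ValueError(
            f"crop ({top},{left})+({h},{w}) outside image {image.shape}")
    return image[top:top + h, left:left + w].copy()
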