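"""Spatially variant ("amoeba") kernel shaping and mean filtering.

At every pixel a kernel is shaped inside the sliding window of a pilot image
and the degraded image is averaged over that kernel.  Two shaping rules:

* ``rbs`` (proposed): segment the window by multilevel Otsu thresholding of
  its own histogram, keep the intensity bin containing the center pixel, and
  restrict to the connected component containing the center.  The kernel
  follows the region around the center and never crosses a contour.
* ``classical``: the geodesic amoeba-distance rule — a pixel belongs to the
  kernel when the cheapest path from the center costs no more than ``radius``,
  each step costing ``1 + lambda * |pilot difference|``.

Windows are truncated (never padded) at image borders, so no fabricated
intensities enter any kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import _kernels
from ._kernels import NBINS
from .pilots import WindowSpec

__all__ = ["ThresholdSet", "KernelMask", "ShapingConfig",
           "DegenerateWindowError", "multilevel_otsu", "select_n_classes",
           "bin_of_interest_mask", "central_connected_component",
           "rbs_kernel", "classical_amoeba_kernel", "amoeba_mean_filter"]

#: relative between-class-variance gain below which adding a class stops
REL_GAIN = 0.05


class DegenerateWindowError(ValueError):
    """Raised when a window cannot support the requested class count."""


@dataclass(frozen=True)
class ThresholdSet:
    """Ordered intensity thresholds splitting a gray range into ``n_classes`` bins."""

    levels: tuple
    n_classes: int

    def __post_init__(self):
        levels = tuple(float(t) for t in self.levels)
        object.__setattr__(self, "levels", levels)
        if self.n_classes < 1 or len(levels) != self.n_classes - 1:
            raise ValueError("need exactly n_classes - 1 levels")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("levels must be strictly increasing")


@dataclass
class KernelMask:
    """Binary amoeba shape inside one window, anchored at the center pixel."""

    mask: np.ndarray
    center: tuple

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.mask[self.center]:
            raise ValueError("kernel must contain its center pixel")

    @property
    def size(self) -> int:
        return int(self.mask.sum())

    def is_connected(self, connectivity: int = 8) -> bool:
        structure = np.ones((3, 3)) if connectivity == 8 else None
        _, n = ndimage.label(self.mask, structure=structure)
        return n == 1


@dataclass
class ShapingConfig:
    """Parameters of the kernel-shaping stage.

    Attributes
    ----------
    method : {"rbs", "classical"}
        Region-based segmentation (proposed) or amoeba distance (baseline).
    window : WindowSpec
        Sliding window, default 9x9.
    max_classes : int
        Upper bound on the per-window Otsu class count (rbs only).
    uniformity_tolerance : float
        Intensity span at or below which a window counts as flat.
    lam : float
        Gradient weight of the amoeba distance (classical only).
    radius : float
        Amoeba distance budget (classical only).
    connectivity : {4, 8}
        Pixel adjacency used for components and paths.
    """

    method: str = "rbs"
    window: WindowSpec = field(default_factory=WindowSpec)
    max_classes: int = 4
    uniformity_tolerance: float = 0.02
    lam: float = 10.0
    radius: float = 4.0
    connectivity: int = 8

    def __post_init__(self):
        if self.method not in ("rbs", "classical"):
            raise ValueError("method must be 'rbs' or 'classical'")
        if not (2 <= self.max_classes <= 8):
            raise ValueError("max_classes must lie in [2, 8]")
        if self.lam < 0 or self.radius <= 0:
            raise ValueError("need lam >= 0 and radius > 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


def _quantize(values: np.ndarray):
    vmin = float(values.min())
    vmax = float(values.max())
    span = vmax - vmin
    bins = np.zeros(values.size, dtype=np.int64)
    cnt = np.zeros(NBINS, dtype=np.int64)
    s1 = np.zeros(NBINS, dtype=np.float64)
    if span > 0:
        _kernels.quantize_window(values.astype(np.float64).ravel(),
                                 values.size, vmin, span, bins, cnt, s1)
    else:
        cnt[0] = values.size
        s1[0] = float(values.sum())
    return vmin, span, bins, cnt, s1


def multilevel_otsu(values, n_classes: int) -> ThresholdSet:
    """Optimal multilevel Otsu thresholds of a sample of window intensities.

    The sample is quantized to 64 uniform bins over its own range and the
    ``n_classes - 1`` cut positions maximizing the between-class variance are
    found exactly by dynamic programming.  Thresholds are returned as the
    upper bin-edge intensities of each class (ties broken toward the lowest
    thresholds).
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValueError("values must be non-empty")
    distinct = np.unique(values).size
    if not 1 <= n_classes <= 8:
        raise ValueError("n_classes must lie in [1, 8]")
    if n_classes > distinct:
        raise DegenerateWindowError(
            f"{n_classes} classes requested but only {distinct} distinct values")
    if n_classes == 1:
        return ThresholdSet((), 1)
    vmin, span, _, cnt, s1 = _quantize(values)
    f = np.empty((n_classes, NBINS), dtype=np.float64)
    arg = np.empty((n_classes, NBINS), dtype=np.int64)
    _kernels.otsu_dp(cnt, s1, n_classes, f, arg)
    cuts = np.empty(n_classes, dtype=np.int64)
    _kernels.recover_cuts(arg, n_classes, cuts)
    levels = tuple(vmin + (cuts[k] + 1) * span / NBINS
                   for k in range(n_classes - 1))
    return ThresholdSet(levels, n_classes)


def select_n_classes(values, max_classes: int = 4,
                     tolerance: float = 0.02) -> int:
    """Adaptive per-window class count.

    Returns 1 for flat windows (intensity span at or below ``tolerance``);
    otherwise walks N = 2, 3, ... and stops when the relative gain in
    between-class variance drops below 5% (or at ``max_classes`` / the
    number of distinct quantized levels).
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValueError("values must be non-empty")
    span = float(values.max() - values.min())
    if span <= tolerance:
        return 1
    _, _, _, cnt, s1 = _quantize(values)
    distinct = int(np.count_nonzero(cnt))
    n_max = max(2, min(max_classes, distinct))
    f = np.empty((n_max, NBINS), dtype=np.float64)
    arg = np.empty((n_max, NBINS), dtype=np.int64)
    return int(_kernels.pick_n_classes(cnt, s1, values.size, n_max, f, arg,
                                       REL_GAIN))


def bin_of_interest_mask(window: np.ndarray, thresholds: ThresholdSet,
                         center: tuple) -> np.ndarray:
    """Binary mask of the threshold bin containing the window center.

    Bin ``k`` is the half-open interval ``(T_{k-1}, T_k]`` with sentinels
    ``-inf`` and ``+inf`` at the ends, so a center sitting exactly on a
    threshold belongs to the lower bin.
    """
    window = np.asarray(window, dtype=np.float64)
    levels = np.asarray(thresholds.levels, dtype=np.float64)
    if levels.size == 0:
        return np.ones(window.shape, dtype=bool)
    v = window[center]
    k = int(np.searchsorted(levels, v, side="left"))
    lo = levels[k - 1] if k > 0 else -np.inf
    hi = levels[k] if k < levels.size else np.inf
    mask = (window > lo) & (window <= hi)
    mask[center] = True
    return mask


def central_connected_component(mask: np.ndarray, center: tuple,
                                connectivity: int = 8) -> KernelMask:
    """Keep only the connected component of True pixels containing ``center``."""
    mask = np.asarray(mask, dtype=bool)
    if not mask[center]:
        raise ValueError("mask must be True at the center pixel")
    structure = np.ones((3, 3)) if connectivity == 8 else None
    labels, _ = ndimage.label(mask, structure=structure)
    return KernelMask(labels == labels[center], center)


def rbs_kernel(pilot_window: np.ndarray, config: ShapingConfig,
               center: tuple | None = None) -> KernelMask:
    """Region-based amoeba kernel for one window of the pilot image.

    Composition: adaptive class count -> multilevel Otsu -> bin of interest
    -> central connected component.  Flat windows keep the full square.
    ``center`` defaults to the geometric window center; border-truncated
    windows pass the anchor pixel's offset position explicitly.
    """
    pw = np.asarray(pilot_window, dtype=np.float64)
    if center is None:
        center = (pw.shape[0] // 2, pw.shape[1] // 2)
    n = select_n_classes(pw, config.max_classes, config.uniformity_tolerance)
    if n == 1:
        return KernelMask(np.ones(pw.shape, dtype=bool), center)
    thresholds = multilevel_otsu(pw, n)
    mask = bin_of_interest_mask(pw, thresholds, center)
    return central_connected_component(mask, center, config.connectivity)


def classical_amoeba_kernel(pilot_window: np.ndarray,
                            config: ShapingConfig,
                            center: tuple | None = None) -> KernelMask:
    """Amoeba-distance kernel: pixels whose cheapest path from the center
    costs at most ``config.radius`` (step cost ``1 + lam * |pilot diff|``)."""
    pw = np.asarray(pilot_window, dtype=np.float64)
    wh, ww = pw.shape
    if center is None:
        center = (wh // 2, ww // 2)
    dist = np.empty(wh * ww, dtype=np.float64)
    _kernels.amoeba_distances(pw.ravel(), wh, ww, center[0], center[1],
                              float(config.lam), config.connectivity == 8,
                              dist)
    return KernelMask(dist.reshape(wh, ww) <= config.radius, center)


def amoeba_mean_filter(image: np.ndarray, pilot: np.ndarray,
                       config: ShapingConfig | None = None) -> np.ndarray:
    """Amoeba mean filter of ``image`` with kernels shaped on ``pilot``.

    For every pixel the kernel is shaped inside the pilot's (border-truncated)
    window and the output is the arithmetic mean of ``image`` over the
    kernel's pixels.

    Parameters
    ----------
    image : ndarray
        Degraded image to be averaged.
    pilot : ndarray
        Pilot image guiding the kernel shapes; same shape as ``image``.
    config : ShapingConfig
        Shaping method and parameters (default: 9x9 RBS).
    """
    if config is None:
        config = ShapingConfig()
    image = np.asarray(image, dtype=np.float64)
    pilot = np.asarray(pilot, dtype=np.float64)
    if image.shape != pilot.shape or image.ndim != 2:
        raise ValueError("image and pilot must be 2-D and share a shape")
    out = np.empty_like(image)
    U, V = config.window.shape
    if config.method == "rbs":
        _kernels.rbs_filter(image, pilot, U, V, config.max_classes,
                            config.uniformity_tolerance,
                            config.connectivity == 8, REL_GAIN, out)
    else:
        _kernels.classical_filter(image, pilot, U, V, float(config.lam),
                                  float(config.radius),
                                  config.connectivity == 8, out)
    return out
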