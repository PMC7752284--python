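"""Full- and no-reference image quality metrics.

The seven metrics reported by the experiment tables, in column order:
RMSE, PSNR, SSIM, EPI, SI, SC, NAE.  ``A`` is always the distortion-free
reference and ``B`` the test image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.fft import fft2, ifft2
from scipy.stats import norm

__all__ = ["MetricConfig", "QualityReport", "UndefinedMetricError",
           "rmse", "psnr", "ssim", "epi", "sharpness_index",
           "structural_content", "nae", "quality_report",
           "PSNR_CAP", "LAPLACIAN_HP"]

#: sentinel PSNR (dB) reported for identical images (RMSE = 0)
PSNR_CAP = 99.0

#: 3x3 Laplacian high-pass used by the edge preservation index:
#: all ones with the center set to minus the sum of its neighbors.
LAPLACIAN_HP = np.array([[1.0, 1.0, 1.0],
                         [1.0, -8.0, 1.0],
                         [1.0, 1.0, 1.0]])


class UndefinedMetricError(ValueError):
    """A metric is undefined for this input (e.g. constant image for SI)."""


@dataclass(frozen=True)
class MetricConfig:
    """Shared metric parameters.

    ``c1``/``c2`` default to the universal SSIM stabilizers
    ``(0.01 * i_max)**2`` and ``(0.03 * i_max)**2``; ``ssim_window`` is the
    side of the sliding window for mean-SSIM (``None`` selects a single
    global window); the sharpness index is estimated from
    ``si_mc_samples`` Fourier phase randomizations seeded by ``si_seed``.
    """

    i_max: float = 1.0
    c1: float | None = None
    c2: float | None = None
    ssim_window: int | None = 8
    si_mc_samples: int = 100
    si_seed: int = 0

    def __post_init__(self):
        if self.i_max <= 0:
            raise ValueError("i_max must be positive")
        if self.c1 is None:
            object.__setattr__(self, "c1", (0.01 * self.i_max) ** 2)
        if self.c2 is None:
            object.__setattr__(self, "c2", (0.03 * self.i_max) ** 2)
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("stabilizers must be positive")
        if self.si_mc_samples < 2:
            raise ValueError("need at least 2 Monte-Carlo samples")


@dataclass
class QualityReport:
    """One table row of the seven metrics for a (reference, test) pair."""

    rmse: float
    psnr: float
    ssim: float
    epi: float
    si: float
    sc: float
    nae: float
    flags: dict = field(default_factory=dict)

    COLUMNS = ("RMSE", "PSNR", "SSIM", "EPI", "SI", "SC", "NAE")

    def as_row(self) -> dict:
        return {"RMSE": self.rmse, "PSNR": self.psnr, "SSIM": self.ssim,
                "EPI": self.epi, "SI": self.si, "SC": self.sc,
                "NAE": self.nae}


def _pair(A, B):
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    if A.shape != B.shape or A.ndim != 2:
        raise ValueError("images must be 2-D and share a shape")
    return A, B


def rmse(A, B) -> float:
    """Root mean square error ``sqrt(mean((A - B)**2))``."""
    A, B = _pair(A, B)
    return float(np.sqrt(np.mean((A - B) ** 2)))


def psnr(A, B, config: MetricConfig = MetricConfig()) -> float:
    """Peak signal-to-noise ratio ``20 log10(i_max / rmse)`` in dB.

    Identical images are reported at the ``PSNR_CAP`` sentinel.
    """
    e = rmse(A, B)
    if e == 0.0:
        return PSNR_CAP
    return float(20.0 * np.log10(config.i_max / e))


def _ssim_field(A, B, config: MetricConfig, win: int | None):
    c1, c2 = config.c1, config.c2
    if win is None:
        mx, my = A.mean(), B.mean()
        vx, vy = A.var(), B.var()
        cov = ((A - mx) * (B - my)).mean()
    else:
        size = (win, win)
        mx = ndimage.uniform_filter(A, size, mode="reflect")
        my = ndimage.uniform_filter(B, size, mode="reflect")
        vx = np.clip(ndimage.uniform_filter(A * A, size, mode="reflect")
                     - mx * mx, 0.0, None)
        vy = np.clip(ndimage.uniform_filter(B * B, size, mode="reflect")
                     - my * my, 0.0, None)
        cov = ndimage.uniform_filter(A * B, size, mode="reflect") - mx * my
    lum = (2 * mx * my + c1) / (mx * mx + my * my + c1)
    cs = (2 * cov + c2) / (vx + vy + c2)
    return lum * cs


def ssim(A, B, config: MetricConfig = MetricConfig()) -> float:
    """Structural similarity index (luminance x contrast x structure).

    With unit exponents and the stabilizer convention ``C3 = C2/2`` the
    contrast and structure terms merge, giving
    ``(2 mu_x mu_y + C1)(2 sigma_xy + C2) /
    ((mu_x^2 + mu_y^2 + C1)(sigma_x^2 + sigma_y^2 + C2))``.
    Computed per sliding window and averaged over the valid interior
    (mean SSIM); pass ``ssim_window=None`` for a single global window.
    """
    A, B = _pair(A, B)
    win = config.ssim_window
    s = _ssim_field(A, B, config, win)
    if win is None:
        return float(s)
    pad = win // 2
    interior = s[pad:s.shape[0] - pad, pad:s.shape[1] - pad]
    return float(interior.mean() if interior.size else s.mean())


def epi(A, B) -> float:
    """Edge preservation index: correlation of Laplacian high-pass responses.

    Both images are filtered with the 3x3 Laplacian ``LAPLACIAN_HP`` and the
    Pearson correlation of the mean-removed responses is returned (1 means
    edges perfectly preserved).  Constant inputs have no edges; the
    documented sentinel 0 is returned.
    """
    A, B = _pair(A, B)
    dA = ndimage.convolve(A, LAPLACIAN_HP, mode="reflect")
    dB = ndimage.convolve(B, LAPLACIAN_HP, mode="reflect")
    dA = dA - dA.mean()
    dB = dB - dB.mean()
    denom = np.sqrt((dA * dA).sum() * (dB * dB).sum())
    if denom == 0.0:
        return 0.0
    return float((dA * dB).sum() / denom)


def total_variation(B) -> float:
    """Anisotropic discrete total variation (sum of |forward differences|)."""
    B = np.asarray(B, dtype=np.float64)
    return float(np.abs(np.diff(B, axis=0)).sum()
                 + np.abs(np.diff(B, axis=1)).sum())


def sharpness_index(B, config: MetricConfig = MetricConfig()) -> float:
    """No-reference sharpness index from the Fourier phase spectrum.

    Compares the total variation of ``B`` with its distribution under random
    phase scrambling (power spectrum preserved):
    ``SI = -log10 Phi((mu - TV(B)) / sigma)`` with ``Phi`` the upper Gaussian
    tail and ``mu``, ``sigma`` the Monte-Carlo mean and standard deviation of
    the scrambled total variations.  Sharp structure has far lower TV than
    any of its phase randomizations, giving a large SI; pure textures score
    near ``-log10(1/2) ~ 0.3``.
    """
    B = np.asarray(B, dtype=np.float64)
    if B.ndim != 2:
        raise ValueError("expected a 2-D image")
    if B.max() == B.min():
        raise UndefinedMetricError("sharpness index undefined for a constant image")
    rng = np.random.default_rng(config.si_seed)
    mag = np.abs(fft2(B))
    tvs = np.empty(config.si_mc_samples)
    for i in range(config.si_mc_samples):
        w = rng.standard_normal(B.shape)
        Fw = fft2(w)
        phase = Fw / np.maximum(np.abs(Fw), 1e-300)
        tvs[i] = total_variation(ifft2(mag * phase).real)
    mu = tvs.mean()
    sigma = tvs.std()
    if sigma == 0.0:
        raise UndefinedMetricError("degenerate phase-randomized ensemble")
    t = (mu - total_variation(B)) / sigma
    # -log10 of the upper tail, via logsf for numerical range
    return float(-norm.logsf(t) / np.log(10.0))


def structural_content(A, B) -> float:
    """Energy ratio ``sum(A**2) / sum(B**2)`` (1 for identical images)."""
    A, B = _pair(A, B)
    eb = float((B * B).sum())
    if eb == 0.0:
        raise UndefinedMetricError("structural content undefined for zero-energy B")
    return float((A * A).sum() / eb)


def nae(A, B) -> float:
    """Normalized absolute error ``sum|A - B| / sum|A|``."""
    A, B = _pair(A, B)
    ea = float(np.abs(A).sum())
    if ea == 0.0:
        raise UndefinedMetricError("NAE undefined for a zero reference")
    return float(np.abs(A - B).sum() / ea)


def quality_report(A, B, config: MetricConfig = MetricConfig()) -> QualityReport:
    """All seven metrics for one (reference, test) pair, table-row order.

    Metrics that are undefined for the given pair are recorded as ``nan``
    with an entry in ``flags`` instead of raising.
    """
    A, B = _pair(A, B)
    flags: dict = {}

    def guarded(name, fn):
        try:
            return fn()
        except UndefinedMetricError as exc:
            flags[name] = str(exc)
            return float("nan")

    r = rmse(A, B)
    if r == 0.0:
        flags["psnr"] = f"identical images; capped at {PSNR_CAP} dB"
    return QualityReport(
        rmse=r,
        psnr=psnr(A, B, config),
        ssim=ssim(A, B, config),
        epi=epi(A, B),
        si=guarded("si", lambda: sharpness_index(B, config)),
        sc=guarded("sc", lambda: structural_content(A, B)),
        nae=guarded("nae", lambda: nae(A, B)),
        flags=flags,
    )
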