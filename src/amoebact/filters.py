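"""scikit-learn style transformer interfaces to the pilot and amoeba filters.

Each transformer consumes and produces a single 2-D grayscale image (the
package's universal currency), validates it in ``fit``/``transform``, and
follows the estimator contract (``get_params``/``set_params``, fitted
attributes with a trailing underscore, ``clone``-ability), so the denoisers
compose with :class:`sklearn.pipeline.Pipeline` and the model-selection
utilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .amoeba import ShapingConfig, amoeba_mean_filter
from .pilots import (WindowSpec, estimate_noise_variance, gaussian_pilot,
                     wiener_pilot)

__all__ = ["WienerPilot", "GaussianPilot", "AmoebaFilter"]


def _check_image(X) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 1:
        raise ValueError("expected a single 2-D grayscale image")
    if not np.all(np.isfinite(X)):
        raise ValueError("image values must be finite")
    return X


class WienerPilot(TransformerMixin, BaseEstimator):
    """Locally adaptive Wiener filter as a transformer.

    Parameters
    ----------
    window : int
        Side of the (square, odd) local moment window.
    noise_variance : float or None
        Known noise variance sigma_n^2; estimated from the image seen by
        ``fit`` when None.

    Attributes
    ----------
    noise_variance_ : float
        Variance actually used by ``transform``.
    """

    def __init__(self, window: int = 9, noise_variance: float | None = None):
        self.window = window
        self.noise_variance = noise_variance

    def fit(self, X, y=None):
        X = _check_image(X)
        spec = WindowSpec(self.window, self.window)
        self.noise_variance_ = estimate_noise_variance(
            X, spec, override=self.noise_variance).sigma_n_sq
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = _check_image(X)
        return wiener_pilot(X, WindowSpec(self.window, self.window),
                            self.noise_variance_)


class GaussianPilot(TransformerMixin, BaseEstimator):
    """Gaussian blur (the classical pilot) as a transformer."""

    def __init__(self, sigma: float = 2.0, truncate: float = 3.0):
        self.sigma = sigma
        self.truncate = truncate

    def fit(self, X, y=None):
        _check_image(X)
        self.fitted_ = True
        return self

    def transform(self, X):
        X = _check_image(X)
        return gaussian_pilot(X, self.sigma, self.truncate)


class AmoebaFilter(TransformerMixin, BaseEstimator):
    """Spatially variant amoeba mean filter as a transformer.

    ``transform`` builds a pilot image from the input (adaptive Wiener,
    Gaussian, or none), shapes a kernel in every sliding window of the pilot
    — by region-based segmentation (``method="rbs"``) or the classical
    amoeba distance (``method="classical"``) — and averages the input over
    each kernel.

    Parameters
    ----------
    method : {"rbs", "classical"}
        Kernel shaping rule.
    pilot : {"wiener", "gaussian", "none"}
        Pilot image type guiding the shaping.
    window : int
        Side of the (square, odd) sliding window for both pilot and shaping.
    max_classes : int
        Cap on the adaptive per-window Otsu class count (rbs).
    uniformity_tolerance : float
        Intensity span below which a window counts as flat.
    lam, radius : float
        Amoeba-distance gradient weight and budget (classical).
    connectivity : {4, 8}
        Pixel adjacency.
    noise_variance : float or None
        Known sigma_n^2 for the Wiener pilot; estimated in ``fit`` when None.
    sigma : float
        Gaussian pilot width in pixels.
    """

    def __init__(self, method: str = "rbs", pilot: str = "wiener",
                 window: int = 9, max_classes: int = 4,
                 uniformity_tolerance: float = 0.02, lam: float = 10.0,
                 radius: float = 4.0, connectivity: int = 8,
                 noise_variance: float | None = None, sigma: float = 2.0):
        self.method = method
        self.pilot = pilot
        self.window = window
        self.max_classes = max_classes
        self.uniformity_tolerance = uniformity_tolerance
        self.lam = lam
        self.radius = radius
        self.connectivity = connectivity
        self.noise_variance = noise_variance
        self.sigma = sigma

    def _shaping_config(self) -> ShapingConfig:
        return ShapingConfig(
            method=self.method,
            window=WindowSpec(self.window, self.window),
            max_classes=self.max_classes,
            uniformity_tolerance=self.uniformity_tolerance,
            lam=self.lam, radius=self.radius,
            connectivity=self.connectivity)

    def fit(self, X, y=None):
        X = _check_image(X)
        self._shaping_config()  # validate parameters eagerly
        if self.pilot not in ("wiener", "gaussian", "none"):
            raise ValueError("pilot must be 'wiener', 'gaussian' or 'none'")
        if self.pilot == "wiener":
            self.noise_variance_ = estimate_noise_variance(
                X, WindowSpec(self.window, self.window),
                override=self.noise_variance).sigma_n_sq
        else:
            self.noise_variance_ = None
        return self

    def make_pilot(self, X) -> np.ndarray:
        """The pilot image ``transform`` would shape kernels on."""
        check_is_fitted(self)
        X = _check_image(X)
        if self.pilot == "wiener":
            return wiener_pilot(X, WindowSpec(self.window, self.window),
                                self.noise_variance_)
        if self.pilot == "gaussian":
            return gaussian_pilot(X, self.sigma)
        return X

    def transform(self, X):
        X = _check_image(X)
        return amoeba_mean_filter(X, self.make_pilot(X),
                                  self._shaping_config())

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)
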