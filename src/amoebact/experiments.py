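"""End-to-end experiment orchestration.

Pipelines reproduce the simulation studies: phantom -> sparse-view fan-beam
projection -> projection noise -> FBP -> {no filter | classical amoeba |
region-based amoeba} -> seven quality metrics against the phantom; plus the
interior-ROI comparison and the noise-level and view-sampling sweeps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .amoeba import ShapingConfig
from .ct import (NoiseSpec, default_geometry, fanbeam_project,
                 add_projection_noise, fbp_reconstruct)
from .filters import AmoebaFilter
from .metrics import MetricConfig, QualityReport, quality_report, rmse, ssim
from .phantoms import shepp_logan, roi_crop
from .pilots import WindowSpec

__all__ = ["ExperimentConfig", "PipelineResult", "run_denoise_pipeline",
           "run_roi_comparison", "noise_robustness_sweep",
           "view_sampling_sweep", "write_report", "SCHEMES"]

log = logging.getLogger("amoebact")

#: scheme key -> table label, in the row order of the experiment tables
SCHEMES = {
    "fbp": "Sparse-view FBP",
    "classical": "Classical amoeba",
    "rbs": "Proposed RBS amoeba",
}


@dataclass
class ExperimentConfig:
    """Everything one pipeline run needs; defaults are the reference study
    conditions (512 phantom, 2-degree views over a half rotation, detector
    spacing 0.25 px, 3 dB projection SNR, 9x9 windows)."""

    phantom_size: int = 512
    modified_phantom: bool = True
    angle_increment_deg: float = 2.0
    detector_spacing: float = 0.25
    source_to_center: float | None = None
    fbp_filter: str = "ramp"
    snr_db: float = 3.0
    noise_reference: str = "unit"
    seed: int = 0
    window: int = 9
    pilot_sigma: float = 2.0
    noise_variance: float | None = None
    max_classes: int = 4
    uniformity_tolerance: float = 0.02
    lam: float = 10.0
    radius: float = 4.0
    connectivity: int = 8
    metrics: MetricConfig = field(default_factory=MetricConfig)
    roi: tuple | None = None
    schemes: tuple = ("fbp", "classical", "rbs")
    output_dir: str | None = None

    def make_filter(self, scheme: str) -> AmoebaFilter | None:
        """The denoiser for a scheme key ('fbp' means no filtering)."""
        if scheme == "fbp":
            return None
        if scheme == "classical":
            return AmoebaFilter(method="classical", pilot="gaussian",
                                window=self.window, lam=self.lam,
                                radius=self.radius, sigma=self.pilot_sigma,
                                connectivity=self.connectivity)
        if scheme == "rbs":
            return AmoebaFilter(method="rbs", pilot="wiener",
                                window=self.window,
                                max_classes=self.max_classes,
                                uniformity_tolerance=self.uniformity_tolerance,
                                noise_variance=self.noise_variance,
                                connectivity=self.connectivity)
        raise ValueError(f"unknown scheme {scheme!r}")


@dataclass
class PipelineResult:
    phantom: np.ndarray
    images: dict        # scheme -> reconstructed/denoised image
    reports: pd.DataFrame


@lru_cache(maxsize=8)
def _cached_projection(size, modified, increment, spacing, source):
    phantom = shepp_logan(size, modified=modified)
    geom = default_geometry(size, increment, spacing, source)
    return phantom, fanbeam_project(phantom, geom)


def simulate_fbp(config: ExperimentConfig, seed: int | None = None,
                 angle_increment: float | None = None,
                 snr_db: float | None = None):
    """Phantom and its noisy sparse-view FBP reconstruction.

    The (deterministic) forward projection is cached across calls so that
    multi-seed replications only redraw the noise.
    """
    seed = config.seed if seed is None else seed
    snr = config.snr_db if snr_db is None else snr_db
    inc = config.angle_increment_deg if angle_increment is None else angle_increment
    phantom, sino = _cached_projection(
        config.phantom_size, config.modified_phantom, inc,
        config.detector_spacing, config.source_to_center)
    noisy = add_projection_noise(
        sino, NoiseSpec(snr, seed, reference=config.noise_reference))
    fbp = fbp_reconstruct(noisy, config.phantom_size, config.fbp_filter)
    return phantom, fbp


def run_denoise_pipeline(config: ExperimentConfig,
                         roi: tuple | None = None) -> PipelineResult:
    """One full run: reconstruct once, denoise per scheme, score vs phantom.

    All schemes share the same noise realization (paired comparison).  With
    ``roi`` set, metrics are computed on the cropped reference and outputs
    only (the images returned stay full size).
    """
    log.info("pipeline config: %s", asdict(config))
    phantom, fbp = simulate_fbp(config)
    images: dict = {}
    rows = []
    reference = phantom if roi is None else roi_crop(phantom, *roi)
    for scheme in config.schemes:
        filt = config.make_filter(scheme)
        out = fbp if filt is None else filt.fit_transform(fbp)
        images[scheme] = out
        scored = out if roi is None else roi_crop(out, *roi)
        rep = quality_report(reference, scored, config.metrics)
        rows.append({"Scheme": SCHEMES[scheme], **rep.as_row()})
        log.info("%s: %s", SCHEMES[scheme], rep.as_row())
    reports = pd.DataFrame(rows)
    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .io import write_image
        write_image(outdir / "phantom.tif", phantom)
        for scheme, img in images.items():
            write_image(outdir / f"{scheme}.tif", img)
        reports.to_csv(outdir / "report.csv", index=False)
    return PipelineResult(phantom, images, reports)


def default_roi(size: int) -> tuple:
    """Central crop of half the image side: interior to the skull boundary,
    excluding the streak artifacts outside the phantom."""
    return (size // 4, size // 4, size // 2, size // 2)


def run_roi_comparison(config: ExperimentConfig,
                       roi: tuple | None = None) -> PipelineResult:
    """The enlarged-ROI comparison: identical pipeline, metrics on the crop."""
    if roi is None:
        roi = config.roi if config.roi is not None else default_roi(
            config.phantom_size)
    return run_denoise_pipeline(config, roi=roi)


def _point_seed(base: int, index: int) -> int:
    """Fresh (deterministic) seed per sweep point, shared across schemes."""
    return int(np.random.SeedSequence([base, index]).generate_state(1)[0]
               % (2 ** 31))


def noise_robustness_sweep(config: ExperimentConfig, snr_values,
                           n_seeds: int = 5) -> pd.DataFrame:
    """SSIM and RMSE of every scheme at each projection SNR level.

    Within one (SNR, replicate) point all schemes share the noise seed
    (paired comparison); seeds are fresh across points.  Returns a
    long-format table with columns snr_db, seed, Scheme, SSIM, RMSE.
    """
    snr_values = list(snr_values)
    if len(snr_values) < 2:
        raise ValueError("need at least 2 SNR values")
    rows = []
    for i, snr in enumerate(snr_values):
        for rep in range(n_seeds):
            seed = _point_seed(config.seed, 1000 * i + rep)
            phantom, fbp = simulate_fbp(config, seed=seed, snr_db=snr)
            for scheme in config.schemes:
                filt = config.make_filter(scheme)
                out = fbp if filt is None else filt.fit_transform(fbp)
                rows.append({
                    "snr_db": snr, "seed": seed, "Scheme": SCHEMES[scheme],
                    "SSIM": ssim(phantom, out, config.metrics),
                    "RMSE": rmse(phantom, out),
                })
    return pd.DataFrame(rows)


def view_sampling_sweep(config: ExperimentConfig, increments_deg,
                        n_seeds: int = 5) -> pd.DataFrame:
    """SSIM of every scheme at each angular sampling increment."""
    increments = list(increments_deg)
    if any(not (0 < inc <= 8) for inc in increments):
        raise ValueError("increments must lie in (0, 8] degrees")
    rows = []
    for i, inc in enumerate(increments):
        for rep in range(n_seeds):
            seed = _point_seed(config.seed, 2000 * i + rep)
            phantom, fbp = simulate_fbp(config, seed=seed,
                                        angle_increment=inc)
            for scheme in config.schemes:
                filt = config.make_filter(scheme)
                out = fbp if filt is None else filt.fit_transform(fbp)
                rows.append({
                    "increment_deg": inc, "seed": seed,
                    "Scheme": SCHEMES[scheme],
                    "SSIM": ssim(phantom, out, config.metrics),
                    "RMSE": rmse(phantom, out),
                })
    return pd.DataFrame(rows)


def write_report(rows, path) -> None:
    """Write quality reports as CSV (header Scheme,RMSE,...,NAE).

    ``rows`` may be a DataFrame or a mapping of scheme label ->
    :class:`QualityReport`.  Values round-trip through ``read_csv`` to 1e-9.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame([{"Scheme": k, **v.as_row()} for k, v in rows.items()])
    if df.empty:
        raise ValueError("no rows to write")
    cols = ["Scheme", *QualityReport.COLUMNS]
    df = df[[c for c in cols if c in df.columns]]
    df.to_csv(path, index=False, float_format="%.12g")
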