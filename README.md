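# amoebact

Adaptive **amoeba** (spatially variant kernel) denoising for sparse-view CT,
with the full simulation harness needed to study it: fan-beam projection of
synthetic head phantoms, projection-domain Gaussian noise, filtered back
projection (FBP), and a seven-metric image-quality evaluation.

## The problem

Sparse-view CT lowers the radiation dose by acquiring far fewer projection
angles (here 90 views at 2° increments instead of hundreds), at the price of
severe streak artifacts and noise in the FBP reconstruction.  Post-processing
with a *spatially variant* mean filter can smooth those artifacts without
blurring anatomy: at every pixel the averaging kernel — the "amoeba" —
reshapes itself inside a sliding window so that it never crosses a tissue
contour.

Two design choices define an amoeba filter:

1. **The pilot image** the kernel shapes are read from (shaping on the noisy
   image itself would wrap kernels around noise spikes).  The classical
   choice is a Gaussian blur; this package's primary scheme uses the locally
   adaptive **Wiener filter**

   $$W(p) = \mu_L(p) + \frac{\max(\sigma_L^2(p) - \sigma_n^2,\,0)}{\sigma_L^2(p)}\,\bigl(D(p) - \mu_L(p)\bigr),$$

   where $\mu_L,\sigma_L^2$ are the 9×9 sliding-window mean and variance of
   the degraded image $D$ and $\sigma_n^2$ its (estimated) noise variance —
   smooth regions collapse to the local mean while edges pass through.

2. **The shaping rule.**
   * *Region-based segmentation (RBS, the proposed scheme)*: each 9×9 pilot
     window is segmented by multilevel **Otsu thresholding** (thresholds
     maximizing between-class variance, class count chosen adaptively); the
     kernel is the connected component, containing the window center, of the
     intensity bin the center falls in.  CT anatomy is piecewise-homogeneous,
     so kernels naturally fill the local tissue region.
   * *Classical amoeba distance* (baseline, Lerallut-style): the kernel is
     every pixel whose cheapest path from the center costs at most $r$, each
     step costing $1 + \lambda\,|\Delta \text{pilot}|$.

   The output pixel is the arithmetic mean of the degraded image over the
   kernel.

The package evaluates reconstructions with RMSE, PSNR, SSIM, EPI (edge
preservation index: correlation of Laplacian high-pass responses), SI
(sharpness index from the Fourier phase spectrum), SC (structural content)
and NAE (normalized absolute error).

## Worked example

```python
from amoebact.experiments import ExperimentConfig, run_denoise_pipeline

cfg = ExperimentConfig(phantom_size=256, seed=0)   # 2° views, 3 dB noise
result = run_denoise_pipeline(cfg)
print(result.reports.round(3).to_string(index=False))
```

```
             Scheme  RMSE   PSNR  SSIM   EPI         SI    SC   NAE
    Sparse-view FBP 0.058 24.805 0.335 0.626  29968.489 1.053 0.280
   Classical amoeba 0.072 22.898 0.533 0.408  53149.053 1.164 0.278
Proposed RBS amoeba 0.036 28.805 0.566 0.957 214744.326 1.090 0.194
```

One row per scheme, scored against the noise-free phantom.  The unfiltered
sparse-view FBP is streaky (SSIM 0.34); the proposed Wiener-pilot RBS amoeba
roughly halves the RMSE (0.058 → 0.036), raises structural similarity to
0.57, and keeps the Laplacian edge response almost perfectly correlated with
the phantom (EPI 0.96) — the filter smooths *within* regions only.

The denoiser is also available as a scikit-learn transformer:

```python
from amoebact import AmoebaFilter
denoised = AmoebaFilter(method="rbs", pilot="wiener", window=9).fit_transform(image)
```

and from the shell:

```bash
amoebact run --size 512 --views-deg 2 --snr-db 3 --seed 0 --out results/
amoebact denoise noisy.png clean.png --method rbs --pilot wiener
amoebact metrics phantom.tif recon.tif
amoebact sweep-noise --snr-db 0 --snr-db 3 --snr-db 6
```

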