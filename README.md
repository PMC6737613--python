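# nvca — edge-preserving spatio-temporal denoising for low-dose fluoroscopy

Low-dose X-ray fluoroscopy is limited by quantum noise: the detected
photon count per pixel is Poisson distributed, so the lower the dose, the
noisier the image. Simple temporal or spatial averaging suppresses that
noise but smears static edges and produces motion blur, which is
unacceptable when a clinician is steering a needle or catheter in real
time. This package implements the **Noise Variance Conditioned Average
(NVCA)** filter — a conditioned spatio-temporal mean designed for
real-time quantum-noise suppression with edge preservation — together
with the noise model it relies on, estimators for the noise parameters,
synthetic phantoms with ground truth, and the image-quality metrics used
to evaluate denoisers. It is intended for researchers and engineers
working on fluoroscopy image chains and for anyone who needs a fast,
transparent baseline denoiser for Poisson–Gaussian video data.

## The model and the filter

Detector gain and additive electronic noise turn the Poisson photon
statistics into a mixed Poissonian–Gaussian model whose expected
value–variance relationship is affine:

```
σ²(h) = A·h + B
```

with `h` the noise-free pixel value (a.u.), `A` (a.u.) set by the
detector gain and `B` (a.u.²) by the electronics. Given `(A, B)`, the
NVCA filter replaces each pixel `I(x, y, t)` by the mean of those
neighbours in an `N × N × K` mask (`K` counts the current plus `K − 1`
past frames — the window is strictly causal, enabling streaming use)
that plausibly share its noise distribution:

```
          Σ C_ijh · I(x−h, y−j, t−i)
I_f = ─────────────────────────────────,   C_ijh = 1  iff  |I(x−h, y−j, t−i) − I(x,y,t)| ≤ T
                  Σ C_ijh

T = F · σ(I(x, y, t))
```

Neighbours across an edge differ from the centre by more than a few
noise standard deviations and are excluded, so edges — including the
edges of moving objects — survive the averaging; the threshold factor
`F` trades noise suppression against resolution. A lookup-table variant
precomputes `T` over the gray-level range, as hardware implementations
do, and a plain moving average (all neighbours admitted) serves as the
baseline.

Around the filter the package provides:

* `estimate_temporal` — per-pixel temporal mean/variance regression
  recovering `(A, B)` from a motionless sequence, plus spatial/temporal
  autocovariance diagnostics for the "uncorrelated pixels" assumption;
* the generalized Anscombe transform pair (`gat_forward`,
  `gat_inverse_algebraic`) for variance stabilization;
* phantom generators: a motionless nested-squares step phantom and a
  digital moving-insert phantom (motionless discs plus a 46%-contrast
  rectangle translating at an integer number of px/frame, all ideal
  edges);
* metrics: line-spread-function FWHM via erf edge fitting
  (`ψ(x) = 0.5·(1 − erf((x−c)/(√2·d)))`, `FWHM = 2.355·d`), CNR
  (`√2·(μ_A − μ_B)/√(σ_A² + σ_B²)`), and FSIM (phase congruency +
  gradient similarity).

## Worked example

```python
from nvca import (FilterConfig, MaskSpec, NoiseParams, ROISpec,
                  StepPhantomSpec, cnr, estimate_temporal,
                  make_step_sequence, moving_average, nvca_filter)

# a motionless step phantom at the noise level of a real C-arm sequence
noise = NoiseParams(a_gain=43.90e-4, b_offset=0.0)
spec = StepPhantomSpec(frame_height=160, frame_width=160, n_frames=120)
clean, noisy, regions = make_step_sequence(spec, noise, seed=42)

# recover (A, B) from the noisy sequence alone
fit = estimate_temporal(noisy)
print(f"estimated A = {fit.a_hat:.3e} a.u.   (true 4.390e-03)")
print(f"estimated B = {fit.b_hat:+.3e} a.u.^2 (true 0)")
print(f"R^2 = {fit.r_squared:.4f} over {fit.n_points} pixels")

# denoise and compare detail visibility
config = FilterConfig(mask=MaskSpec(n_spatial=5, k_temporal=5),
                      threshold_factor=2.0, noise=noise)
denoised = nvca_filter(noisy, config)
averaged = moving_average(noisy, config.mask)

roi_bg = ROISpec(top=8, left=8, height=12, width=12)
inner = spec.side_px()[-1]
roi_in = ROISpec(80 - inner // 2 + 2, 80 - inner // 2 + 2, inner - 4, inner - 4)
for name, seq in [("raw", noisy), ("nvca", denoised), ("moving avg", averaged)]:
    print(f"CNR {name:10s} {cnr(seq.frames[-1], roi_bg, roi_in).cnr:6.2f}")
```

prints

```
estimated A = 4.398e-03 a.u.   (true 4.390e-03)
estimated B = -3.647e-06 a.u.^2 (true 0)
R^2 = 0.9244 over 25600 pixels
CNR raw         11.30
CNR nvca        19.35
CNR moving avg  19.06
```

The regression recovers the generating slope to 0.2% from the noisy data
alone, and the 5×5×5 NVCA filter with `F = 2` raises the
background-vs-innermost-step CNR by ~70% over the raw frame, slightly
ahead of the moving average at the same mask size — while, unlike the
moving average, leaving edges essentially intact (the acceptance script
below quantifies the edge comparison).

A command-line interface mirrors the library (`nvca simulate`,
`estimate-noise`, `denoise`, `anscombe`, `evaluate`); every command
writes a JSON manifest sufficient to reproduce its outputs.

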