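"""Noise Variance Conditioned Average (NVCA) spatio-temporal filter.

The NVCA filter replaces each pixel with the mean of those neighbours in
an N x N x K spatio-temporal mask (K past frames, including the current
one) whose absolute difference from the centre pixel does not exceed
T = F * sigma(I(x, y, t)), the local noise standard deviation scaled by a
threshold factor F. Neighbours that plausibly share the centre's noise
distribution are averaged; pixels across an edge are excluded, so edges
— including those of moving objects — survive the averaging. The mean of
the admitted neighbours is

    I_f(x,y,t) = sum(C_ijh * I(x-h, y-j, t-i)) / sum(C_ijh)

with C_ijh in {0, 1} the admission indicator. The centre always admits
itself, so the denominator is >= 1.

The moving-average baseline is the same geometry with every in-bounds
neighbour admitted. A lookup-table (LUT) threshold variant mirrors the
hardware implementations that precompute T over the gray-level range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .noise_model import FrameSequence, NoiseParams, threshold_at


@dataclass(frozen=True)
class MaskSpec:
    """N x N x K neighbourhood geometry.

    ``n_spatial`` (N) must be odd for symmetry about the centre pixel;
    ``k_temporal`` (K) counts frames (current + K-1 past). K = 1 gives a
    purely spatial filter.
    """

    n_spatial: int = 5
    k_temporal: int = 5

    def __post_init__(self) -> None:
        if self.n_spatial < 1 or self.n_spatial % 2 == 0:
            raise ValueError(f"n_spatial must be an odd integer >= 1, got {self.n_spatial}")
        if self.k_temporal < 1:
            raise ValueError(f"k_temporal must be >= 1, got {self.k_temporal}")


@dataclass(frozen=True)
class ThresholdLUT:
    """Precomputed thresholds on a uniform gray-level grid."""

    levels: np.ndarray
    thresholds: np.ndarray

    @property
    def quantization(self) -> float:
        return float(self.levels[1] - self.levels[0])

    def lookup(self, values: np.ndarray) -> np.ndarray:
        """Map values to the threshold of the nearest grid level (ties round half up)."""
        lo = float(self.levels[0])
        idx = np.floor((np.asarray(values) - lo) / self.quantization + 0.5).astype(int)
        idx = np.clip(idx, 0, len(self.levels) - 1)
        return self.thresholds[idx]


def build_threshold_lut(
    noise: NoiseParams,
    factor: float,
    n_levels: int = 2 ** 16,
    level_range: Optional[tuple[float, float]] = None,
) -> ThresholdLUT:
    """Tabulate T = F * sigma(level) on a uniform grid over the data range."""
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    lo, hi = level_range if level_range is not None else (noise.level_min, noise.level_max)
    if not (lo < hi):
        raise ValueError(f"invalid level range [{lo}, {hi}]")
    levels = np.linspace(lo, hi, n_levels)
    thresholds = threshold_at(noise, factor, levels)
    return ThresholdLUT(levels=levels, thresholds=np.asarray(thresholds))


@dataclass(frozen=True)
class FilterConfig:
    """Complete NVCA configuration: mask geometry, F, and the threshold source.

    Exactly one of ``noise`` (direct per-pixel evaluation of T) or ``lut``
    drives thresholding.
    """

    mask: MaskSpec
    threshold_factor: float
    noise: Optional[NoiseParams] = None
    lut: Optional[ThresholdLUT] = None

    def __post_init__(self) -> None:
        if self.threshold_factor < 0:
            raise ValueError("threshold_factor must be >= 0")
        if (self.noise is None) == (self.lut is None):
            raise ValueError("exactly one of noise or lut must be provided")

    def thresholds_for(self, frames: np.ndarray) -> np.ndarray:
        if self.lut is not None:
            return self.lut.lookup(frames)
        return threshold_at(self.noise, self.threshold_factor, frames)


# ---------------------------------------------------------------------------
# Core conditioned average
# ---------------------------------------------------------------------------

def _conditioned_average(
    frames: np.ndarray, mask: MaskSpec, thr: Optional[np.ndarray]
) -> np.ndarray:
    """Shared kernel for NVCA (thr given) and the moving average (thr None).

    Iterates over the K*N*N offsets, shifting the stack so that
    ``shifted[t, y, x] = I(t-i, y-j, x-h)``; out-of-bounds neighbours are
    skipped (C = 0), which truncates the window at borders and at the
    first K-1 frames without inventing data.

    The admitted mean is accumulated as centre + sum(neighbour - centre)/count,
    which is algebraically Eq.-style sum/count but keeps flat regions (and the
    F = 0 identity) exact in floating point.
    """
    t_len, height, width = frames.shape
    n, k = mask.n_spatial, mask.k_temporal
    if n > height or n > width:
        raise ValueError(
            f"spatial mask {n}x{n} exceeds frame size {height}x{width}"
        )
    r = (n - 1) // 2
    num = np.zeros_like(frames)
    den = np.zeros(frames.shape, dtype=np.float64)

    for i in range(min(k, t_len)):
        for j in range(-r, r + 1):
            for h in range(-r, r + 1):
                # destination region of centres for which (t-i, y-j, x-h) exists
                ty0, ty1 = i, t_len
                yy0, yy1 = max(j, 0), height + min(j, 0)
                xx0, xx1 = max(h, 0), width + min(h, 0)
                if yy0 >= yy1 or xx0 >= xx1:
                    continue
                centre = frames[ty0:ty1, yy0:yy1, xx0:xx1]
                neighbour = frames[ty0 - i:t_len - i, yy0 - j:yy1 - j, xx0 - h:xx1 - h]
                delta = neighbour - centre
                if thr is None:
                    num[ty0:ty1, yy0:yy1, xx0:xx1] += delta
                    den[ty0:ty1, yy0:yy1, xx0:xx1] += 1.0
                else:
                    c = np.abs(delta) <= thr[ty0:ty1, yy0:yy1, xx0:xx1]
                    num[ty0:ty1, yy0:yy1, xx0:xx1] += np.where(c, delta, 0.0)
                    den[ty0:ty1, yy0:yy1, xx0:xx1] += c
    return frames + num / den


def nvca_filter(seq: FrameSequence, config: FilterConfig) -> FrameSequence:
    """Apply the NVCA conditioned spatio-temporal average to a sequence.

    The temporal window is strictly causal (current + K-1 past frames);
    early frames and borders use the truncated window, the denominator
    adapting through the admission count. The threshold is evaluated at
    the centre pixel's observed value, which stands proxy for its expected
    value. Every output pixel is a convex combination of admitted input
    pixels, so the sequence min/max are never exceeded.
    """
    thr = np.asarray(config.thresholds_for(seq.frames), dtype=np.float64)
    out = _conditioned_average(seq.frames, config.mask, thr)
    return seq.copy_with(
        out,
        filter="nvca",
        mask=(config.mask.n_spatial, config.mask.n_spatial, config.mask.k_temporal),
        threshold_factor=config.threshold_factor,
        used_lut=config.lut is not None,
    )


def moving_average(seq: FrameSequence, mask: MaskSpec) -> FrameSequence:
    """Spatio-temporal moving average over the same causal, truncated window.

    Identical to NVCA with an unconditionally admitted neighbourhood
    (the F -> infinity limit).
    """
    out = _conditioned_average(seq.frames, mask, None)
    return seq.copy_with(
        out,
        filter="moving_average",
        mask=(mask.n_spatial, mask.n_spatial, mask.k_temporal),
    )
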