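"""Temporal noise-parameter estimation and pixel-correlation analysis.

On a motionless sequence each pixel's time series consists of independent
draws around its noise-free level, so the per-pixel temporal mean and
variance trace out the EV-variance line sigma^2(h) = A*h + B. Ordinary
least squares over the per-pixel (mean, variance) cloud recovers (A, B).
Spatial and temporal autocovariance of a flat region quantify how well the
"uncorrelated pixels" assumption of that model holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .noise_model import FrameSequence


@dataclass(frozen=True)
class ROISpec:
    """Rectangular region of interest: 0-based, half-open pixel intervals."""

    top: int
    left: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("ROI height and width must be positive")
        if self.top < 0 or self.left < 0:
            raise ValueError("ROI top/left must be >= 0")

    def validate_in(self, seq: FrameSequence) -> None:
        if self.top + self.height > seq.height or self.left + self.width > seq.width:
            raise ValueError(
                f"ROI {self} exceeds frame bounds {seq.height}x{seq.width}"
            )

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.top, self.top + self.height),
                slice(self.left, self.left + self.width))

    def to_dict(self) -> dict:
        return {"top": self.top, "left": self.left,
                "height": self.height, "width": self.width}


@dataclass(frozen=True)
class EVVarFit:
    """Result of the EV-variance linear regression.

    ``a_hat`` (a.u.) and ``b_hat`` (a.u.^2) estimate the slope A and
    intercept B; ``r_squared`` is the ordinary coefficient of
    determination of the fit over ``n_points`` retained pixels.
    """

    a_hat: float
    b_hat: float
    r_squared: float
    n_points: int
    excluded_clipped: int = 0


@dataclass(frozen=True)
class AutocorrResult:
    """Radial/temporal autocovariance estimates for a flat-region ROI.

    Values are unnormalized autocovariances in a.u.^2 (the lag-0 value is
    the sample variance); ``normalized()`` gives the lag-0 = 1 view.
    """

    lags: np.ndarray
    values: np.ndarray
    axis: str  # "spatial" (radial, pixels) or "temporal" (frames)
    roi: ROISpec

    def normalized(self) -> np.ndarray:
        v0 = self.values[0]
        if v0 == 0:
            return np.zeros_like(self.values)
        return self.values / v0


# ---------------------------------------------------------------------------
# EV-variance regression
# ---------------------------------------------------------------------------

def estimate_temporal(
    seq: FrameSequence,
    exclude_clipped: bool = False,
    clip_margin: float = 0.0,
    n_bins: int | None = None,
) -> EVVarFit:
    """Estimate (A, B) from a motionless sequence via per-pixel statistics.

    For every pixel the temporal mean ``m`` and unbiased temporal variance
    ``v`` are computed over all frames; OLS of ``v`` on ``m`` over the
    retained pixels yields ``(a_hat, b_hat)``. With ``exclude_clipped``
    set, pixels whose mean lies within ``clip_margin`` of the global
    min/max mean are dropped (crude guard against saturated regions).
    ``n_bins`` optionally replaces the raw pixel cloud with equal-count
    bin means before regressing (an optional variant; the default is the
    plain per-pixel fit).
    """
    if seq.n_frames < 2:
        raise ValueError("temporal estimation needs at least 2 frames")
    m = seq.frames.mean(axis=0).ravel()
    v = seq.frames.var(axis=0, ddof=1).ravel()

    excluded = 0
    if exclude_clipped:
        lo, hi = m.min(), m.max()
        keep = (m > lo + clip_margin) & (m < hi - clip_margin)
        excluded = int(np.count_nonzero(~keep))
        m, v = m[keep], v[keep]

    scale = max(1.0, float(np.abs(m).max()))
    if m.size < 2 or np.ptp(m) <= 1e-12 * scale:
        raise ValueError(
            "degenerate regression: pixel means span a single level; use a "
            "multi-level (step) phantom so the EV-variance line is identifiable"
        )
    if v.max() <= 1e-15 * scale ** 2:
        raise ValueError("all temporal variances are zero (noiseless sequence); "
                         "the EV-variance regression is undefined")

    if n_bins is not None and n_bins >= 2:
        order = np.argsort(m)
        splits = np.array_split(order, n_bins)
        m = np.array([m[s].mean() for s in splits if s.size])
        v = np.array([v[s].mean() for s in splits if s.size])

    design = np.column_stack([m, np.ones_like(m)])
    (a_hat, b_hat), *_ = np.linalg.lstsq(design, v, rcond=None)
    pred = design @ np.array([a_hat, b_hat])
    ss_res = float(np.sum((v - pred) ** 2))
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else -np.inf
    return EVVarFit(float(a_hat), float(b_hat), r2, int(m.size), excluded)


# ---------------------------------------------------------------------------
# Autocovariance
# ---------------------------------------------------------------------------

def spatial_autocorrelation(seq: FrameSequence, roi: ROISpec) -> AutocorrResult:
    """Radial spatial autocovariance of a flat ROI, averaged over frames.

    Per frame the ROI mean is subtracted and the biased 2-D autocovariance
    is computed (divisor = ROI pixel count, so lag 0 is the sample
    variance and dominates every other lag). The 1-D curve is the radial
    profile of the frame-averaged 2-D matrix using integer-rounded
    Euclidean radii.
    """
    roi.validate_in(seq)
    sy, sx = roi.slices()
    patch = seq.frames[:, sy, sx]
    n_pix = roi.height * roi.width

    acc = None
    for f in range(seq.n_frames):
        x = patch[f] - patch[f].mean()
        c = signal.fftconvolve(x, x[::-1, ::-1], mode="full") / n_pix
        acc = c if acc is None else acc + c
    acf2d = acc / seq.n_frames

    cy, cx = roi.height - 1, roi.width - 1
    yy, xx = np.indices(acf2d.shape)
    radii = np.rint(np.hypot(yy - cy, xx - cx)).astype(int)
    max_lag = min(roi.height, roi.width) - 1
    lags = np.arange(max_lag + 1)
    values = np.array([acf2d[radii == r].mean() for r in lags])
    return AutocorrResult(lags=lags, values=values, axis="spatial", roi=roi)


def temporal_autocorrelation(
    seq: FrameSequence, roi: ROISpec, max_lag: int | None = None
) -> AutocorrResult:
    """Per-pixel temporal autocovariance averaged over the ROI.

    Each pixel's time series is mean-subtracted; the biased autocovariance
    (divisor = n_frames) is averaged over all ROI pixels, so the lag-0
    value equals the ROI-averaged temporal variance.
    """
    if seq.n_frames < 2:
        raise ValueError("temporal autocorrelation needs at least 2 frames")
    roi.validate_in(seq)
    sy, sx = roi.slices()
    patch = seq.frames[:, sy, sx].reshape(seq.n_frames, -1)
    x = patch - patch.mean(axis=0)
    n = seq.n_frames
    if max_lag is None:
        max_lag = min(n - 1, 50)
    lags = np.arange(max_lag + 1)
    values = np.array([
        (x[: n - k] * x[k:]).sum(axis=0).mean() / n for k in lags
    ])
    return AutocorrResult(lags=lags, values=values, axis="temporal", roi=roi)
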