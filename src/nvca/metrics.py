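"""Image-quality readouts: LSF FWHM via erf edge fitting, CNR, FSIM.

Spatial resolution is read off an edge: the edge spread function (ESF)
across an ideal edge blurred by a Gaussian-like kernel follows

    psi(x) = 0.5 * (1 - erf((x - c) / (sqrt(2) * d)))

whose derivative (the line spread function, LSF) is a Gaussian of
standard deviation ``d``, hence FWHM = 2.355 * d. Profiles are fitted
with the 4-parameter extension ``offset + amplitude * psi`` since real
profiles are not normalized.

Detail visibility is the contrast-to-noise ratio between two ROIs,

    CNR = sqrt(2) * (meanA - meanB) / sqrt(stdA^2 + stdB^2),

and global quality is the feature-similarity index FSIM, which compares
phase-congruency and gradient-magnitude maps of a test frame against a
reference (for motionless scenes, the temporal average of the raw
sequence).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy import ndimage, optimize, special

from .noise_estimation import ROISpec
from .noise_model import FrameSequence

#: FWHM of a Gaussian in units of its standard deviation (2*sqrt(2*ln 2)).
FWHM_PER_SIGMA = 2.355


# ---------------------------------------------------------------------------
# Edge fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EdgeProfile:
    """1-D profile across an edge: unit-spaced positions and pixel values."""

    positions: np.ndarray
    values: np.ndarray
    orientation: str = "horizontal"

    def __post_init__(self) -> None:
        p = np.asarray(self.positions, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if p.ndim != 1 or p.shape != v.shape or p.size < 5:
            raise ValueError("profile needs matching 1-D positions/values, >= 5 samples")
        if not np.allclose(np.diff(p), 1.0):
            raise ValueError("profile positions must be strictly increasing with unit spacing")
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class EdgeFit:
    """Fitted erf-edge parameters; ``fwhm`` is stored as 2.355 * d."""

    c: float
    d: float
    offset: float
    amplitude: float
    r_squared: float
    fwhm: float
    flagged: bool = False
    message: str = ""


@dataclass(frozen=True)
class FWHMSummary:
    """Mean +/- std of per-profile FWHM estimates over an edge ROI."""

    mean_fwhm: float
    std_fwhm: float
    n_profiles: int
    n_flagged: int = 0


def _edge_model(x, c, d, offset, amplitude):
    psi = 0.5 * (1.0 - special.erf((x - c) / (np.sqrt(2.0) * d)))
    return offset + amplitude * psi


def fit_edge(profile: EdgeProfile, r2_floor: float = 0.5) -> EdgeFit:
    """Nonlinear least-squares fit of ``offset + amplitude * psi(x; c, d)``.

    The edge centre is initialized at the maximum-|gradient| sample, the
    spread at 1 px, offset/amplitude from the plateau medians. A fit that
    fails to converge or scores ``r_squared`` below ``r2_floor`` is
    returned flagged (with diagnostics) rather than raised.
    """
    x, y = profile.positions, profile.values
    if np.ptp(y) == 0:
        raise ValueError("flat profile: no edge to fit")
    grad = np.abs(np.diff(y))
    c0 = float(x[np.argmax(grad)]) + 0.5
    tail = max(3, x.size // 8)
    left = float(np.median(y[:tail]))
    right = float(np.median(y[-tail:]))
    p0 = (c0, 1.0, right, left - right)
    lo = (x[0] - 1.0, 1e-6, -np.inf, -np.inf)
    hi = (x[-1] + 1.0, float(x[-1] - x[0]), np.inf, np.inf)
    try:
        popt, _ = optimize.curve_fit(
            _edge_model, x, y, p0=p0, bounds=(lo, hi), maxfev=20000
        )
    except (RuntimeError, ValueError) as exc:
        return EdgeFit(np.nan, np.nan, np.nan, np.nan, -np.inf, np.nan,
                       flagged=True, message=f"fit failed: {exc}")
    c, d, offset, amplitude = (float(v) for v in popt)
    resid = y - _edge_model(x, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else -np.inf
    flagged = r2 < r2_floor
    return EdgeFit(c, d, offset, amplitude, r2, FWHM_PER_SIGMA * d,
                   flagged=flagged,
                   message="low r_squared" if flagged else "")


def _as_frame(seq_or_frame: Union[FrameSequence, np.ndarray], frame_index: int) -> np.ndarray:
    if isinstance(seq_or_frame, FrameSequence):
        return seq_or_frame.frames[frame_index]
    arr = np.asarray(seq_or_frame, dtype=float)
    if arr.ndim == 3:
        return arr[frame_index]
    if arr.ndim != 2:
        raise ValueError("expected a 2-D frame or a FrameSequence")
    return arr


def fwhm_over_profiles(
    seq_or_frame: Union[FrameSequence, np.ndarray],
    roi: ROISpec,
    n_profiles: int = 10,
    direction: str = "horizontal",
    frame_index: int = -1,
    r2_floor: float = 0.5,
) -> FWHMSummary:
    """FWHM mean +/- std over consecutive parallel profiles in an ROI.

    ``direction="horizontal"`` samples profiles along rows (across a
    vertical edge); ``"vertical"`` samples along columns (across a
    horizontal edge). Profiles are 1 px apart; flagged fits are excluded
    from the summary and counted.
    """
    frame = _as_frame(seq_or_frame, frame_index)
    sy, sx = roi.slices()
    patch = frame[sy, sx]
    if direction == "vertical":
        patch = patch.T
        origin = roi.top
    elif direction == "horizontal":
        origin = roi.left
    else:
        raise ValueError("direction must be 'horizontal' or 'vertical'")
    n_avail = patch.shape[0]
    if n_profiles > n_avail:
        raise ValueError(f"ROI provides {n_avail} profiles, {n_profiles} requested")
    start = (n_avail - n_profiles) // 2
    positions = np.arange(patch.shape[1], dtype=float) + origin

    fwhms = []
    flagged = 0
    for k in range(start, start + n_profiles):
        fit = fit_edge(EdgeProfile(positions, patch[k], orientation=direction),
                       r2_floor=r2_floor)
        if fit.flagged:
            flagged += 1
        else:
            fwhms.append(fit.fwhm)
    if not fwhms:
        raise RuntimeError(
            f"no successful edge fits in ROI ({flagged} flagged of {n_profiles})"
        )
    arr = np.asarray(fwhms)
    return FWHMSummary(float(arr.mean()),
                       float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                       len(fwhms), flagged)


# ---------------------------------------------------------------------------
# CNR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CNRResult:
    cnr: float
    roiA_mean: float
    roiB_mean: float
    roiA_std: float
    roiB_std: float
    per_frame: np.ndarray | None = None  # populated for sequence input


def cnr(
    frame_or_seq: Union[FrameSequence, np.ndarray],
    roiA: ROISpec,
    roiB: ROISpec,
) -> CNRResult:
    """Contrast-to-noise ratio between two disjoint ROIs.

    ``CNR = sqrt(2) * (meanA - meanB) / sqrt(stdA^2 + stdB^2)`` with
    sample standard deviations. For a sequence the per-frame values are
    returned alongside their mean.
    """
    if roiA.height * roiA.width < 4 or roiB.height * roiB.width < 4:
        raise ValueError("each ROI must contain at least 4 pixels")
    ya, xa = roiA.slices()
    yb, xb = roiB.slices()
    if (max(roiA.top, roiB.top) < min(roiA.top + roiA.height, roiB.top + roiB.height)
            and max(roiA.left, roiB.left) < min(roiA.left + roiA.width, roiB.left + roiB.width)):
        raise ValueError("ROIs must be disjoint")

    def one(frame: np.ndarray) -> tuple[float, float, float, float, float]:
        a, b = frame[ya, xa].ravel(), frame[yb, xb].ravel()
        ma, mb = float(a.mean()), float(b.mean())
        sa, sb = float(a.std(ddof=1)), float(b.std(ddof=1))
        pooled = sa * sa + sb * sb
        if pooled == 0:
            raise ValueError("zero pooled variance: CNR undefined")
        return np.sqrt(2.0) * (ma - mb) / np.sqrt(pooled), ma, mb, sa, sb

    if isinstance(frame_or_seq, FrameSequence) or np.asarray(frame_or_seq).ndim == 3:
        frames = frame_or_seq.frames if isinstance(frame_or_seq, FrameSequence) \
            else np.asarray(frame_or_seq, dtype=float)
        vals = [one(f) for f in frames]
        per = np.array([v[0] for v in vals])
        mid = vals[len(vals) // 2]
        return CNRResult(float(per.mean()), mid[1], mid[2], mid[3], mid[4], per)
    c, ma, mb, sa, sb = one(_as_frame(frame_or_seq, -1))
    return CNRResult(float(c), ma, mb, sa, sb)


# ---------------------------------------------------------------------------
# FSIM (feature similarity index)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FSIMResult:
    fsim: float
    parameters: dict = field(default_factory=dict)


_FSIM_DEFAULTS = dict(
    nscale=4, norient=4, min_wavelength=6, mult=2.0, sigma_onf=0.55,
    d_theta_on_sigma=1.2, k_noise=2.0, epsilon=1e-4, t1=0.85, t2=160.0,
)


def _lowpass_filter(shape: tuple[int, int], cutoff: float = 0.45, order: int = 15) -> np.ndarray:
    rows, cols = shape
    fy = np.fft.ifftshift((np.arange(rows) - rows // 2) / rows)
    fx = np.fft.ifftshift((np.arange(cols) - cols // 2) / cols)
    radius = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    return 1.0 / (1.0 + (radius / cutoff) ** (2 * order))


def phase_congruency(img: np.ndarray, **kwargs) -> np.ndarray:
    """Phase-congruency map via a multi-scale log-Gabor filter bank.

    Moment-free variant used by the feature-similarity index: per
    orientation, scale responses are combined into a noise-compensated
    local energy and normalized by the summed amplitudes; orientations
    are pooled by summing energies and amplitudes.
    """
    p = {**_FSIM_DEFAULTS, **kwargs}
    img = np.asarray(img, dtype=float)
    rows, cols = img.shape
    imgfft = np.fft.fft2(img)

    fy = np.fft.ifftshift((np.arange(rows) - rows // 2) / rows)
    fx = np.fft.ifftshift((np.arange(cols) - cols // 2) / cols)
    radius = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    radius[0, 0] = 1.0
    theta = np.arctan2(-fy[:, None], fx[None, :])
    sintheta, costheta = np.sin(theta), np.cos(theta)
    lp = _lowpass_filter((rows, cols))

    log_gabors = []
    for s in range(p["nscale"]):
        fo = 1.0 / (p["min_wavelength"] * p["mult"] ** s)
        lg = np.exp(-(np.log(radius / fo)) ** 2 / (2 * np.log(p["sigma_onf"]) ** 2))
        lg *= lp
        lg[0, 0] = 0.0
        log_gabors.append(lg)

    theta_sigma = np.pi / p["norient"] / p["d_theta_on_sigma"]
    energy_all = np.zeros_like(img)
    an_all = np.zeros_like(img)

    for o in range(p["norient"]):
        angl = o * np.pi / p["norient"]
        ds = sintheta * np.cos(angl) - costheta * np.sin(angl)
        dc = costheta * np.cos(angl) + sintheta * np.sin(angl)
        dtheta = np.abs(np.arctan2(ds, dc))
        spread = np.exp(-dtheta ** 2 / (2 * theta_sigma ** 2))

        sum_e = np.zeros_like(img)
        sum_o = np.zeros_like(img)
        sum_an = np.zeros_like(img)
        eo = []
        tau = 0.0
        for s in range(p["nscale"]):
            resp = np.fft.ifft2(imgfft * log_gabors[s] * spread)
            e, od = resp.real, resp.imag
            an = np.abs(resp)
            sum_e += e
            sum_o += od
            sum_an += an
            eo.append((e, od))
            if s == 0:
                tau = np.median(an) / np.sqrt(np.log(4.0))
        x_energy = np.sqrt(sum_e ** 2 + sum_o ** 2) + p["epsilon"]
        mean_e, mean_o = sum_e / x_energy, sum_o / x_energy
        energy = np.zeros_like(img)
        for e, od in eo:
            energy += e * mean_e + od * mean_o - np.abs(e * mean_o - od * mean_e)
        # Rayleigh-statistics noise threshold from the smallest-scale response
        total_tau = tau * (1 - (1 / p["mult"]) ** p["nscale"]) / (1 - 1 / p["mult"])
        noise_mean = total_tau * np.sqrt(np.pi / 2.0)
        noise_sigma = total_tau * np.sqrt((4 - np.pi) / 2.0)
        t_noise = (noise_mean + p["k_noise"] * noise_sigma) / 1.7
        energy = np.maximum(energy - t_noise, 0.0)
        energy_all += energy
        an_all += sum_an
    return energy_all / (an_all + p["epsilon"])


_SCHARR_X = np.array([[3.0, 0.0, -3.0], [10.0, 0.0, -10.0], [3.0, 0.0, -3.0]]) / 16.0


def _gradient_magnitude(img: np.ndarray) -> np.ndarray:
    gx = ndimage.convolve(img, _SCHARR_X, mode="nearest")
    gy = ndimage.convolve(img, _SCHARR_X.T, mode="nearest")
    return np.sqrt(gx * gx + gy * gy)


def fsim(
    test: Union[FrameSequence, np.ndarray],
    reference: Union[FrameSequence, np.ndarray],
    frame_index: int = -1,
    **pc_kwargs,
) -> FSIMResult:
    """Feature-similarity index of a test frame against a reference frame.

    Both images are jointly rescaled to a 0-255 dynamic range (so a
    common affine gray transformation cancels), smoothed and downsampled
    by round(min(shape)/256) as prescribed, and compared through their
    phase-congruency and Scharr gradient-magnitude maps; the similarity
    map is pooled with the pointwise-max phase congruency as weight.
    """
    t = _as_frame(test, frame_index)
    r = _as_frame(reference, frame_index)
    if t.shape != r.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {r.shape}")
    lo = min(t.min(), r.min())
    hi = max(t.max(), r.max())
    if hi == lo:
        raise ValueError("reference and test are jointly constant; FSIM undefined")
    t = (t - lo) * (255.0 / (hi - lo))
    r = (r - lo) * (255.0 / (hi - lo))

    p = {**_FSIM_DEFAULTS, **pc_kwargs}
    f = max(1, int(round(min(t.shape) / 256.0)))
    if f > 1:
        kern = np.full((f, f), 1.0 / (f * f))
        t = ndimage.convolve(t, kern, mode="nearest")[::f, ::f]
        r = ndimage.convolve(r, kern, mode="nearest")[::f, ::f]

    pc1 = phase_congruency(t, **pc_kwargs)
    pc2 = phase_congruency(r, **pc_kwargs)
    g1 = _gradient_magnitude(t)
    g2 = _gradient_magnitude(r)

    s_pc = (2 * pc1 * pc2 + p["t1"]) / (pc1 ** 2 + pc2 ** 2 + p["t1"])
    s_g = (2 * g1 * g2 + p["t2"]) / (g1 ** 2 + g2 ** 2 + p["t2"])
    pcm = np.maximum(pc1, pc2)
    value = float(np.sum(s_pc * s_g * pcm) / np.sum(pcm))
    return FSIMResult(value, parameters={**p, "downsample": f})


def reference_from_time_average(seq: FrameSequence) -> np.ndarray:
    """Pixel-wise temporal mean of a motionless sequence (FSIM reference)."""
    return seq.frames.mean(axis=0)
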