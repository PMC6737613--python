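"""Mixed Poissonian-Gaussian noise model for low-dose fluoroscopy.

X-ray quantum noise is Poisson distributed; detector gain and additive
electronic noise turn the per-pixel expected-value/variance relationship
into the affine law

    sigma^2(h) = A * h + B

where ``h`` is the noise-free pixel value in arbitrary units (a.u.),
``A`` (a.u.) is set by the detector gain and ``B`` (a.u.^2) by the
signal-independent Gaussian noise of the detector and electronics.
This module defines the parameter container, samples noisy sequences
from the model, evaluates local variance/threshold, and provides the
generalized Anscombe transform (GAT) pair used for variance
stabilization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

logger = logging.getLogger("nvca")

#: Positive floor applied to the affine variance so that thresholds stay
#: defined when a fitted B is slightly negative (as temporal estimation on
#: real data can produce).
VARIANCE_FLOOR = 1e-12

SampleMode = Literal["gaussian_approx", "poisson_gaussian"]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseParams:
    """Parameters (A, B) of the affine expected-value/variance law.

    Parameters
    ----------
    a_gain : float
        Slope A of the EV-variance line, in a.u. Set by the detector gain.
    b_offset : float
        Intercept B, in a.u.^2. Variance of the additive Gaussian
        detector/electronics noise; a fitted value may be slightly negative.
    level_min, level_max : float
        Declared valid pixel-value range; the variance must stay positive
        over it (up to the floor).
    """

    a_gain: float
    b_offset: float
    level_min: float = 0.0
    level_max: float = 1.0

    def __post_init__(self) -> None:
        for name in ("a_gain", "b_offset", "level_min", "level_max"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"NoiseParams.{name} must be finite, got {v!r}")
        if self.level_min >= self.level_max:
            raise ValueError("level_min must be < level_max")
        lo = self.a_gain * self.level_min + self.b_offset
        hi = self.a_gain * self.level_max + self.b_offset
        if max(lo, hi) < 0:
            raise ValueError(
                "sigma^2(h) = A*h + B is negative over the whole declared "
                f"range [{self.level_min}, {self.level_max}]"
            )
        if min(lo, hi) < 0:
            warnings.warn(
                "sigma^2(h) = A*h + B is non-positive for part of "
                f"[{self.level_min}, {self.level_max}]; the variance floor "
                f"{VARIANCE_FLOOR} a.u.^2 applies there",
                RuntimeWarning,
                stacklevel=2,
            )

    def to_dict(self) -> dict:
        return {
            "a_gain": self.a_gain,
            "b_offset": self.b_offset,
            "level_min": self.level_min,
            "level_max": self.level_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseParams":
        return cls(**{k: float(v) for k, v in d.items()})


#: Temporal per-pixel estimates reported for a GE 9900 Elite C-arm at
#: 57 kVp / 1 mA on 16-bit data normalized to [0, 1] a.u. The slightly
#: negative fitted B makes the variance floor apply near level 0; the
#: construction-time warning is silenced for this packaged constant only.
with warnings.catch_warnings():
    warnings.simplefilter("ignore", RuntimeWarning)
    FLUORO_TEMPORAL = NoiseParams(a_gain=43.90e-4, b_offset=-0.99e-4)
#: Median per-frame estimates from the spatial (segmentation-based) method
#: on the same sequence.
FLUORO_SPATIAL = NoiseParams(a_gain=37.91e-4, b_offset=0.05e-4)


class FrameSequence:
    """Ordered stack of equally sized grayscale frames.

    ``frames`` is a float array indexed ``(t, row, col)`` in a.u.; this is
    the universal input/output of every filter and metric in the package.
    """

    __slots__ = ("frames", "bit_depth_hint", "meta")

    def __init__(
        self,
        frames: np.ndarray,
        bit_depth_hint: Optional[int] = None,
        meta: Optional[dict] = None,
    ) -> None:
        frames = np.asarray(frames, dtype=np.float64)
        if frames.ndim == 2:
            frames = frames[None]
        if frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (t, row, col), got shape {frames.shape}")
        if frames.size == 0:
            raise ValueError("empty frame sequence")
        if not np.all(np.isfinite(frames)):
            raise ValueError("frame pixel values must be finite")
        self.frames = frames
        self.bit_depth_hint = bit_depth_hint
        self.meta = dict(meta or {})

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def shape(self) -> tuple:
        return self.frames.shape

    def copy_with(self, frames: np.ndarray, **meta) -> "FrameSequence":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return FrameSequence(frames, bit_depth_hint=self.bit_depth_hint, meta=new_meta)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"FrameSequence(n_frames={self.n_frames}, "
            f"height={self.height}, width={self.width})"
        )


@dataclass(frozen=True)
class AnscombeParams:
    """Parameters of the generalized Anscombe transform.

    ``pedestal`` is an optional additive acquisition baseline (a.u.)
    subtracted inside the transform argument.
    """

    noise: NoiseParams
    pedestal: float = 0.0

    def __post_init__(self) -> None:
        if self.noise.a_gain <= 0:
            raise ValueError("generalized Anscombe transform requires a_gain > 0")
        if not np.isfinite(self.pedestal):
            raise ValueError("pedestal must be finite")


# ---------------------------------------------------------------------------
# Variance and threshold
# ---------------------------------------------------------------------------

def variance_at(params: NoiseParams, level) -> np.ndarray | float:
    """Noise variance ``max(A*level + B, floor)`` at a pixel level (a.u.^2).

    Accepts scalars or arrays; the floor keeps the result positive when a
    fitted ``B`` is slightly negative.
    """
    level = np.asarray(level, dtype=np.float64)
    if not np.all(np.isfinite(level)):
        bad = np.asarray(level)[~np.isfinite(level)]
        raise ValueError(f"non-finite pixel level(s) passed to variance_at: {bad[:5]!r}")
    var = np.maximum(params.a_gain * level + params.b_offset, VARIANCE_FLOOR)
    return float(var) if var.ndim == 0 else var


def threshold_at(params: NoiseParams, factor: float, level) -> np.ndarray | float:
    """NVCA threshold ``T = F * sigma(level)`` in a.u.

    ``factor`` is the dimensionless multiple F of the local noise standard
    deviation.
    """
    if factor < 0:
        raise ValueError(f"threshold factor must be >= 0, got {factor}")
    t = factor * np.sqrt(variance_at(params, level))
    return float(t) if np.ndim(t) == 0 else t


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def sample_noisy(
    clean: FrameSequence,
    params: NoiseParams,
    mode: SampleMode = "poisson_gaussian",
    seed: int | None = None,
) -> FrameSequence:
    """Corrupt a clean sequence with signal-dependent mixed noise.

    Two equivalent-moment modes are provided:

    ``gaussian_approx``
        ``g = h + N(0, A*h + B)`` — the Gaussian approximation, valid when
        the underlying photon count ``h/A`` is large (>= ~10).
    ``poisson_gaussian``
        ``g = A * P + n`` with ``P ~ Poisson(h/A)`` and ``n ~ N(0, B)`` —
        the physical Poisson-Gaussian mixture (requires ``A > 0``,
        ``B >= 0`` and non-negative clean values).

    Both have mean ``h`` and variance ``A*h + B``. A fixed ``seed`` makes
    the output reproducible; the seed is recorded in the output metadata.
    """
    h = clean.frames
    rng = np.random.default_rng(seed)
    if mode == "gaussian_approx":
        sigma = np.sqrt(variance_at(params, h))
        noisy = h + rng.standard_normal(h.shape) * sigma
    elif mode == "poisson_gaussian":
        if params.a_gain <= 0:
            raise ValueError("poisson_gaussian sampling requires a_gain > 0 "
                             "(the Poisson branch scales photon counts by A)")
        if params.b_offset < 0:
            raise ValueError("poisson_gaussian sampling requires b_offset >= 0 "
                             "(B is the Gaussian branch variance)")
        if np.any(h < 0):
            raise ValueError("poisson_gaussian sampling requires clean values >= 0")
        counts = rng.poisson(h / params.a_gain)
        noisy = params.a_gain * counts
        if params.b_offset > 0:
            noisy = noisy + rng.standard_normal(h.shape) * np.sqrt(params.b_offset)
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")
    return clean.copy_with(noisy, noise=params.to_dict(), sample_mode=mode, seed=seed)


# ---------------------------------------------------------------------------
# Generalized Anscombe transform
# ---------------------------------------------------------------------------

def _gat_argument(z: np.ndarray, p: AnscombeParams) -> np.ndarray:
    a, b = p.noise.a_gain, p.noise.b_offset
    return a * z + 0.375 * a * a + b - a * p.pedestal


def gat_forward(seq: FrameSequence, params: AnscombeParams) -> FrameSequence:
    """Generalized Anscombe transform, stabilizing the variance to ~1.

    Pixel-wise ``f(z) = (2/A) * sqrt(A*z + (3/8)A^2 + B - A*pedestal)``;
    the argument is clamped at zero before the square root and the number
    of clamped pixels is recorded in the output metadata (key
    ``gat_clamped``) and logged.
    """
    z = seq.frames
    arg = _gat_argument(z, params)
    clamped = int(np.count_nonzero(arg < 0))
    if clamped:
        logger.warning("gat_forward clamped %d negative argument(s) to zero", clamped)
    out = (2.0 / params.noise.a_gain) * np.sqrt(np.maximum(arg, 0.0))
    return seq.copy_with(out, gat_clamped=clamped)


def gat_inverse_algebraic(seq: FrameSequence, params: AnscombeParams) -> FrameSequence:
    """Algebraic (exact functional) inverse of :func:`gat_forward`.

    ``z = ((A*f/2)^2 - (3/8)A^2 - B + A*pedestal) / A``. On the non-clamped
    domain ``gat_inverse_algebraic(gat_forward(x)) == x`` to floating-point
    tolerance. The exact-unbiased inverse is deliberately not provided: the
    algebraic form is the one used for fluoroscopy post-filter inversion.
    """
    a, b = params.noise.a_gain, params.noise.b_offset
    f = seq.frames
    z = ((a * f / 2.0) ** 2 - 0.375 * a * a - b + a * params.pedestal) / a
    return seq.copy_with(z)
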