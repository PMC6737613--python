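import numpy as np
import pytest

from nvca import FrameSequence, NoiseParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fluoro_noise():
    """Poisson-dominant noise at the level estimated on real fluoroscopy."""
    return NoiseParams(a_gain=43.90e-4, b_offset=0.0)


@pytest.fixture
def random_seq(rng):
    return FrameSequence(rng.random((6, 12, 12)))


def brute_force_nvca(frames, n_spatial, k_temporal, thresholds):
    """Literal per-pixel transliteration of the conditioned-average rule.

    Enumerates the N x N x K neighbourhood of every pixel, applies
    |neighbour - centre| <= T(centre) with out-of-bounds neighbours
    skipped, and averages the admitted values as
    centre + sum(neighbour - centre) / count (the same centred form of the
    admitted mean the filter uses, so the comparison is bit-for-bit).
    Deliberately loop-based and independent of the vectorized
    implementation.
    """
    t_len, height, width = frames.shape
    r = (n_spatial - 1) // 2
    out = np.empty_like(frames)
    for t in range(t_len):
        for y in range(height):
            for x in range(width):
                centre = frames[t, y, x]
                total, count = 0.0, 0
                for i in range(k_temporal):
                    if t - i < 0:
                        continue
                    for j in range(-r, r + 1):
                        for h in range(-r, r + 1):
                            yy, xx = y - j, x - h
                            if 0 <= yy < height and 0 <= xx < width:
                                v = frames[t - i, yy, xx]
                                if abs(v - centre) <= thresholds[t, y, x]:
                                    total += v - centre
                                    count += 1
                out[t, y, x] = centre + total / count
    return out
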