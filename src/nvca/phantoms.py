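"""Synthetic fluoroscopy scenes with ground truth.

Two phantoms drive the evaluation:

* a motionless **step phantom** — nested concentric squares emulating a
  stack of aluminium sheets, giving flat regions at several gray levels;
  the workhorse for noise characterization (EV-variance regression) and
  static image-quality readouts;
* a **moving-insert phantom** — motionless discs of various sizes and
  contrasts plus a darker rectangle translating horizontally at an
  integer number of pixels per frame, all with ideal (single-pixel)
  edges; the motion-blur test bench.

Both return the clean sequence, a noisy copy corrupted by the mixed
Poisson-Gaussian model, and ground-truth geometry (region labels or the
per-frame position of the insert's leading edge).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .noise_estimation import ROISpec
from .noise_model import FrameSequence, NoiseParams, SampleMode, sample_noisy

#: Sheet edge lengths of the emulated aluminium step stack, in cm,
#: outermost to innermost; used as relative side lengths.
DEFAULT_SHEET_EDGES_CM = (30.0, 26.0, 22.0, 18.0, 14.0, 10.0, 6.0)


def _default_step_levels() -> tuple[float, ...]:
    # 8 flat levels (background + 7 steps), geometrically spaced: each
    # added sheet attenuates the beam by a constant factor, so levels
    # decay geometrically from the bright background to the darkest
    # innermost region.
    return tuple(np.geomspace(0.8, 0.1, 8)[1:])


@dataclass(frozen=True)
class StepPhantomSpec:
    """Motionless nested-squares step phantom.

    ``step_levels`` are the clean gray levels of the nested squares,
    outermost to innermost (a.u.); ``step_edge_fractions`` their side
    lengths relative to the largest square, which itself spans
    ``outer_side_fraction`` of the smaller frame dimension. Every pixel
    of the clean frame belongs to exactly one flat region.
    """

    frame_height: int = 328
    frame_width: int = 333
    step_levels: tuple[float, ...] = field(default_factory=_default_step_levels)
    step_edge_fractions: tuple[float, ...] = tuple(
        e / DEFAULT_SHEET_EDGES_CM[0] for e in DEFAULT_SHEET_EDGES_CM
    )
    background_level: float = 0.8
    outer_side_fraction: float = 0.9
    include_screws: bool = False
    n_frames: int = 712

    def __post_init__(self) -> None:
        if len(self.step_levels) != len(self.step_edge_fractions):
            raise ValueError("one gray level per nested square is required")
        if self.n_frames < 1 or self.frame_height < 8 or self.frame_width < 8:
            raise ValueError("degenerate phantom dimensions")
        fr = self.step_edge_fractions
        if any(f2 >= f1 for f1, f2 in zip(fr, fr[1:])) or fr[0] > 1.0:
            raise ValueError("step_edge_fractions must be strictly decreasing and <= 1")

    def side_px(self) -> list[int]:
        base = self.outer_side_fraction * min(self.frame_height, self.frame_width)
        return [max(2, int(round(f * base))) for f in self.step_edge_fractions]


def _render_step_frame(spec: StepPhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Clean frame plus integer region map (0 = background, 1..n = squares,
    -1 = screws when present)."""
    frame = np.full((spec.frame_height, spec.frame_width), spec.background_level)
    region = np.zeros(frame.shape, dtype=np.int32)
    cy, cx = spec.frame_height // 2, spec.frame_width // 2
    for idx, (side, level) in enumerate(zip(spec.side_px(), spec.step_levels), start=1):
        half = side // 2
        y0, y1 = cy - half, cy - half + side
        x0, x1 = cx - half, cx - half + side
        frame[y0:y1, x0:x1] = level
        region[y0:y1, x0:x1] = idx
    if spec.include_screws:
        # two dark discs flanking the centre, excluded from region stats
        inner = spec.side_px()[-1]
        r = max(2, inner // 6)
        for dx in (-inner // 4, inner // 4):
            yy, xx = np.indices(frame.shape)
            disc = (yy - cy) ** 2 + (xx - (cx + dx)) ** 2 <= r * r
            frame[disc] = 0.05
            region[disc] = -1
    return frame, region


def make_step_sequence(
    spec: StepPhantomSpec,
    noise: NoiseParams,
    mode: SampleMode = "poisson_gaussian",
    seed: int | None = None,
) -> tuple[FrameSequence, FrameSequence, np.ndarray]:
    """Render the step phantom and corrupt it with the given noise model.

    Returns ``(clean, noisy, region_map)``; the clean frames are identical
    across time and ``region_map`` labels each flat region for ROI
    selection downstream.
    """
    levels = (spec.background_level,) + tuple(spec.step_levels)
    for lv in levels:
        if not (noise.level_min <= lv <= noise.level_max):
            raise ValueError(
                f"step level {lv} outside the noise model's valid range "
                f"[{noise.level_min}, {noise.level_max}]"
            )
    frame, region = _render_step_frame(spec)
    clean = FrameSequence(
        np.broadcast_to(frame, (spec.n_frames,) + frame.shape).copy(),
        meta={"phantom": "step", "seed": seed},
    )
    if noise.a_gain == 0 and noise.b_offset == 0:
        noisy = clean.copy_with(clean.frames.copy())
    else:
        noisy = sample_noisy(clean, noise, mode=mode, seed=seed)
    return clean, noisy, region


# ---------------------------------------------------------------------------
# Moving insert
# ---------------------------------------------------------------------------

def _default_circles() -> tuple:
    return (
        ((60, 58), 22, 0.72),
        ((196, 62), 15, 0.33),
        ((62, 196), 10, 0.60),
        ((190, 188), 27, 0.40),
    )


@dataclass(frozen=True)
class MovingInsertSpec:
    """Digital phantom: motionless discs + a rectangle moving left to right.

    The insert is radiopaque (darker than the background): its clean mean
    over background mean equals ``insert_contrast_ratio`` (default 0.46,
    i.e. a 46% contrast). ``speed`` must be an integer number of pixels
    per frame so that every edge stays ideal; the insert column position
    at frame ``f`` is ``start_col + speed * f``.
    """

    frame_height: int = 256
    frame_width: int = 256
    background_level: float = 0.5
    circles: tuple = field(default_factory=_default_circles)
    insert_size: tuple[int, int] = (60, 80)
    insert_contrast_ratio: float = 0.46
    speed: int = 1
    start_col: int = 8
    insert_top: int | None = None
    n_frames: int = 60
    edge_halfwidth: int = 25
    corner_exclusion: int = 10

    def __post_init__(self) -> None:
        if not float(self.speed).is_integer() or self.speed < 0:
            raise ValueError(
                "only integer insert speeds are supported: fractional motion "
                "would anti-alias the edges, breaking the ideal-edge invariant"
            )
        if self.insert_contrast_ratio <= 0:
            raise ValueError("insert_contrast_ratio must be positive")
        h, w = self.insert_size
        if h < 2 * self.corner_exclusion + 10:
            raise ValueError("insert too short for 10 corner-free edge profiles")

    @property
    def insert_level(self) -> float:
        return self.insert_contrast_ratio * self.background_level

    def insert_row0(self) -> int:
        if self.insert_top is not None:
            return self.insert_top
        return (self.frame_height - self.insert_size[0]) // 2

    def leading_edge_col(self, f: int) -> int:
        """First background column to the right of the insert at frame f."""
        return self.start_col + self.speed * f + self.insert_size[1]


def make_moving_insert_sequence(
    spec: MovingInsertSpec,
    noise: NoiseParams,
    mode: SampleMode = "poisson_gaussian",
    seed: int | None = None,
) -> tuple[FrameSequence, FrameSequence, list[ROISpec]]:
    """Render the moving-insert phantom and its per-frame edge ROIs.

    Returns ``(clean, noisy, edge_roi_per_frame)``. Each ROI is centred on
    the insert's leading vertical edge, spans ``2*edge_halfwidth + 1``
    columns and the insert rows minus ``corner_exclusion`` at top and
    bottom (always >= 10 rows), so perfectly registered horizontal
    profiles across the edge can be extracted at every frame.
    """
    ih, iw = spec.insert_size
    row0 = spec.insert_row0()
    if row0 < 0 or row0 + ih > spec.frame_height:
        raise ValueError("insert exceeds the frame vertically")
    last_edge = spec.leading_edge_col(spec.n_frames - 1)
    if spec.start_col < 0 or last_edge > spec.frame_width:
        bad = next(
            f for f in range(spec.n_frames)
            if spec.leading_edge_col(f) > spec.frame_width
        )
        raise ValueError(f"insert exits the frame at frame {bad}")

    base = np.full((spec.frame_height, spec.frame_width), spec.background_level)
    yy, xx = np.indices(base.shape)
    for (cy, cx), r, level in spec.circles:
        base[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = level

    frames = np.empty((spec.n_frames,) + base.shape)
    rois: list[ROISpec] = []
    for f in range(spec.n_frames):
        frame = base.copy()
        c0 = spec.start_col + spec.speed * f
        frame[row0:row0 + ih, c0:c0 + iw] = spec.insert_level
        frames[f] = frame
        edge = spec.leading_edge_col(f)  # first background column
        left = max(0, edge - 1 - spec.edge_halfwidth)
        right = min(spec.frame_width, edge + spec.edge_halfwidth)
        rois.append(ROISpec(
            top=row0 + spec.corner_exclusion,
            left=left,
            height=ih - 2 * spec.corner_exclusion,
            width=right - left,
        ))

    clean = FrameSequence(frames, meta={"phantom": "moving_insert", "seed": seed})
    if noise.a_gain == 0 and noise.b_offset == 0:
        noisy = clean.copy_with(frames.copy())
    else:
        noisy = sample_noisy(clean, noise, mode=mode, seed=seed)
    return clean, noisy, rois
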