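"""Sequence, configuration and manifest input/output.

Frame sequences travel as multi-frame TIFF (8/16-bit integer or 32/64-bit
float) or as raw binary with a JSON sidecar describing dtype, shape and
byte order. All computation happens in floating-point a.u.; integer
inputs are scaled on read (default: divide by 2^bit_depth - 1, matching
the magnitude of noise slopes fitted on 16-bit fluoroscopy data
normalized to [0, 1]).

Coordinates are (t, row, col), 0-based, with half-open ROIs, everywhere
in the package. Every CLI run writes a JSON manifest with the fully
resolved configuration and seed, sufficient to reproduce its outputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import tifffile

from .noise_model import FrameSequence

ScalePolicy = Union[str, float]


def _int_scale(dtype: np.dtype) -> float:
    return float(2 ** (8 * dtype.itemsize) - 1)


def read_sequence(path: str | Path, scale_policy: ScalePolicy = "auto") -> FrameSequence:
    """Read a multi-frame TIFF or raw-binary-with-sidecar sequence.

    ``scale_policy``: ``"auto"`` divides integer data by ``2^bit_depth - 1``;
    ``"none"`` keeps raw values; a float divides by that value. Frame
    order follows file order.
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        data = tifffile.imread(path)
    elif path.suffix.lower() in {".raw", ".bin"}:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"raw input requires a sidecar: {sidecar}")
        meta = json.loads(sidecar.read_text())
        dtype = np.dtype(meta["dtype"])
        data = np.fromfile(path, dtype=dtype).reshape(meta["shape"])
        if meta.get("order", "C") != "C":
            raise ValueError("only C-ordered raw data is supported")
    else:
        raise ValueError(f"unsupported sequence format: {path.suffix!r}")

    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"expected a (t, row, col) stack, got shape {data.shape}")

    bit_depth = None
    if np.issubdtype(data.dtype, np.integer):
        bit_depth = 8 * data.dtype.itemsize
        if scale_policy == "auto":
            scale = _int_scale(data.dtype)
        elif scale_policy == "none":
            scale = 1.0
        else:
            scale = float(scale_policy)
        frames = data.astype(np.float64) / scale
    elif np.issubdtype(data.dtype, np.floating):
        scale = 1.0 if scale_policy in ("auto", "none") else float(scale_policy)
        frames = data.astype(np.float64) / scale
    else:
        raise ValueError(f"unsupported dtype {data.dtype}")
    return FrameSequence(frames, bit_depth_hint=bit_depth,
                         meta={"source": str(path), "scale": scale})


def write_sequence(
    seq: FrameSequence,
    path: str | Path,
    dtype_policy: str = "float32",
) -> dict:
    """Write a sequence as multi-frame TIFF; returns write metadata.

    ``"float32"``/``"float64"`` are lossless (up to the float32 cast);
    ``"uint16"`` quantizes with ``round(value * 65535)``, reporting the
    scale and the number of clipped pixels.
    """
    path = Path(path)
    info: dict = {"path": str(path), "dtype": dtype_policy}
    if dtype_policy in ("float32", "float64"):
        tifffile.imwrite(path, seq.frames.astype(dtype_policy))
    elif dtype_policy == "uint16":
        scaled = np.round(seq.frames * 65535.0)
        clipped = int(np.count_nonzero((scaled < 0) | (scaled > 65535)))
        info.update(scale=65535.0, clipped=clipped)
        tifffile.imwrite(path, np.clip(scaled, 0, 65535).astype(np.uint16))
    else:
        raise ValueError(f"unsupported dtype_policy {dtype_policy!r}")
    return info


def write_manifest(path: str | Path, config: dict) -> None:
    Path(path).write_text(json.dumps(config, indent=2, sort_keys=True, default=str) + "\n")


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
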