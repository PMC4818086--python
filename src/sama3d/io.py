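"""Reading and writing multi-page TIFF stacks and per-structure CSV tables."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import tifffile

from .core import ImageStack

__all__ = ["read_stack", "write_stack"]

log = logging.getLogger(__name__)

_RANGE_BY_DTYPE = {
    np.dtype(np.uint8): (0.0, 255.0),
    np.dtype(np.uint16): (0.0, 65535.0),
}


def read_stack(
    path: str | Path,
    spacing: tuple[float, float, float] | None = None,
) -> ImageStack:
    """Load a single-channel multi-page TIFF as an :class:`ImageStack`.

    Intensities are preserved bit-exactly (no rescaling). ``spacing`` from
    the caller (i.e. the run config) wins; TIFF resolution metadata is used
    only when the caller omits it, and defaults to unit spacing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such stack: {path}")
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        axes = series.axes
        if "S" in axes or "C" in axes:
            raise ValueError(
                f"{path.name}: RGB/multi-channel TIFF not supported (axes {axes!r}); "
                "provide single-channel grayscale stacks"
            )
        shapes = {p.shape for p in tif.pages}
        if len(shapes) > 1:
            raise ValueError(f"{path.name}: inconsistent page sizes {sorted(shapes)}")
        arr = series.asarray()
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path.name}: expected a 3D grayscale stack, got shape {arr.shape}")
    if spacing is None:
        spacing = (1.0, 1.0, 1.0)
    rng = _RANGE_BY_DTYPE.get(arr.dtype, (float(arr.min()), float(max(arr.max(), arr.min() + 1))))
    return ImageStack(arr, spacing=spacing, intensity_range=rng)


def write_stack(path: str | Path, stack: ImageStack) -> Path:
    """Write a stack as a 16-bit multi-page TIFF (values clipped + rounded)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.clip(np.round(stack.data), 0, 65535).astype(np.uint16)
    # explicit photometric + axes: a (z, y, x) grid with x or y <= 4 must not
    # be guessed as RGB samples
    tifffile.imwrite(path, data, photometric="minisblack", metadata={"axes": "ZYX"})
    return path
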