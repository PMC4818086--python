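"""Tier-1 preprocessing: homogenize a z-stack so one threshold segments it.

The stages mirror the standard confocal clean-up sequence for 3D cultures:
local background removal, 3D rank filtering (median / minimum / maximum /
variance), Gaussian smoothing of structure surfaces, depth-luminosity
compensation via a running average of per-slice maxima, per-slice hole
filling so lumena do not perturb morphometrics, and an optional
gradient-based separation step for crowded images in which neighbouring
structures merge through poorly resolved voxels.

All filters operate in voxel units; Gaussian sigma is the only
spacing-aware parameter. Filters preserve grid shape, spacing and the
declared intensity range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .core import ImageStack

__all__ = [
    "Tier1Config",
    "Tier1Result",
    "subtract_background",
    "rank_filter_3d",
    "gaussian_blur_3d",
    "compensate_depth",
    "fill_holes_2d",
    "gradient_separation",
    "run_tier1",
]

log = logging.getLogger(__name__)

RankKind = Literal["median", "minimum", "maximum", "variance"]

#: cap on the per-slice gain applied by depth compensation; prevents
#: near-empty slices from being amplified into pure noise
GAIN_CAP = 10.0


def subtract_background(stack: ImageStack, radius: int = 32) -> ImageStack:
    """Remove the slowly varying local background of each slice.

    The background estimate is a per-slice grayscale opening (minimum- then
    maximum-filter) with a square window of side ``2*radius + 1``; the window
    must be larger than the structures of interest so they survive
    subtraction intact. Output is clamped at zero.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1 voxel")
    nz, ny, nx = stack.shape
    size = 2 * radius + 1
    if size > ny or size > nx:
        raise ValueError(f"background window {size} exceeds slice size ({ny}, {nx})")
    footprint = (1, size, size)  # per-slice: no mixing across z
    bg = ndi.minimum_filter(stack.data, size=footprint, mode="reflect")
    bg = ndi.maximum_filter(bg, size=footprint, mode="reflect")
    return stack.with_data(np.maximum(stack.data - bg, 0.0))


def rank_filter_3d(stack: ImageStack, kind: RankKind, radius: int = 1) -> ImageStack:
    """3D rank/statistic filter over a cubic ``(2r+1)^3`` neighbourhood.

    ``variance`` is the local second central moment (computed via box means
    of the value and its square); the others are order statistics. Edges are
    handled by reflection.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    size = 2 * radius + 1
    data = stack.data
    if kind == "median":
        out = ndi.median_filter(data, size=size, mode="reflect")
    elif kind == "minimum":
        out = ndi.minimum_filter(data, size=size, mode="reflect")
    elif kind == "maximum":
        out = ndi.maximum_filter(data, size=size, mode="reflect")
    elif kind == "variance":
        d = data.astype(np.float64)
        mean = ndi.uniform_filter(d, size=size, mode="reflect")
        mean_sq = ndi.uniform_filter(d * d, size=size, mode="reflect")
        out = np.maximum(mean_sq - mean * mean, 0.0)
    else:
        raise ValueError(f"unknown rank filter kind {kind!r}")
    return stack.with_data(out)


def gaussian_blur_3d(stack: ImageStack, sigma: float = 1.0) -> ImageStack:
    """Separable Gaussian smoothing; ``sigma`` is physical and converted
    per-axis through the voxel spacing, so anisotropic stacks blur
    isotropically in physical space."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return stack.with_data(stack.data)
    sig_vox = [sigma / s for s in stack.spacing]
    return stack.with_data(ndi.gaussian_filter(stack.data, sigma=sig_vox, mode="reflect"))


def compensate_depth(stack: ImageStack, percentile: float = 99.9) -> ImageStack:
    """Equalize per-slice luminosity against depth-dependent attenuation.

    For slice i, the slice luminosity m_i is a robust maximum (the given
    percentile, 100 = exact max); r_i is the mean of m over the window
    {i-1, i, i+1}, truncated at the stack ends. Every slice is scaled by
    g_i = R / r_i with R = max_i r_i, so the brightest neighbourhood is the
    reference and all gains are >= 1. Gains are capped at ``GAIN_CAP`` (an
    all-zero slice would otherwise divide by zero) and output is clipped to
    the declared intensity range.
    """
    data = stack.data
    nz = data.shape[0]
    m = np.percentile(data.reshape(nz, -1), percentile, axis=1)
    # running mean over {i-1, i, i+1}, truncated at the ends
    r = np.empty(nz)
    for i in range(nz):
        lo, hi = max(0, i - 1), min(nz, i + 2)
        r[i] = m[lo:hi].mean()
    R = r.max()
    if R <= 0:
        log.warning("compensate_depth: stack is empty, returning input unchanged")
        return stack.with_data(data)
    with np.errstate(divide="ignore"):
        gains = np.where(r > 0, R / np.maximum(r, 1e-30), GAIN_CAP)
    capped = gains > GAIN_CAP
    if capped.any():
        log.warning("compensate_depth: gain capped at %gx on %d slice(s)", GAIN_CAP, capped.sum())
        gains = np.minimum(gains, GAIN_CAP)
    out = np.clip(data * gains[:, None, None].astype(np.float32), *stack.intensity_range)
    return stack.with_data(out)


def fill_holes_2d(binary: np.ndarray) -> np.ndarray:
    """Fill enclosed background regions slice by slice.

    Any background region of a z-slice not connected to the slice border
    becomes foreground — this closes lumen cross-sections so morphometrics
    measure the filled structure. Idempotent.
    """
    binary = np.asarray(binary, dtype=bool)
    out = np.empty_like(binary)
    for i in range(binary.shape[0]):
        out[i] = ndi.binary_fill_holes(binary[i])
    return out


def gradient_separation(stack: ImageStack) -> ImageStack:
    """Carve apart structures merged through poorly resolved voxels.

    The 3D morphological gradient (maximum- minus minimum-filter, radius 1)
    is large exactly at object edges; subtracting it from the image erodes
    the dim bridging voxels between touching structures while leaving deep
    interiors untouched. Output clamped at zero.
    """
    grad = ndi.maximum_filter(stack.data, size=3, mode="reflect") - ndi.minimum_filter(
        stack.data, size=3, mode="reflect"
    )
    return stack.with_data(np.maximum(stack.data - grad, 0.0))


@dataclass
class Tier1Config:
    """Stage toggles and parameters for the mandatory Tier-1 pass."""

    background_radius: int = 32
    subtract_background_on: bool = True
    median_radius: int = 1
    median_on: bool = True
    minmax_radius: int = 1
    minimum_on: bool = False
    maximum_on: bool = False
    variance_on: bool = False
    gaussian_sigma: float = 1.0
    depth_compensation_on: bool = True
    depth_percentile: float = 99.9
    gradient_separation_on: bool = False  # for crowded images only
    threshold: float | str = "otsu"
    denoise_hook: Callable[[ImageStack], ImageStack] | None = None


@dataclass
class Tier1Result:
    """Two processed branches plus the threshold used for re-masking.

    ``for_morphometrics`` has lumena filled (hole voxels raised to the
    threshold) so downstream binarization yields solid structures;
    ``for_lumen`` preserves interior darkness for cavity segmentation.
    """

    for_morphometrics: ImageStack
    for_lumen: ImageStack
    structure_threshold: float
    structure_mask: np.ndarray


def _stage(name: str, fn, *args):
    try:
        out = fn(*args)
    except Exception as exc:  # re-raise with the failing stage named
        raise RuntimeError(f"tier1 stage {name!r} failed: {exc}") from exc
    log.info("tier1 %-22s intensity range [%g, %g]", name, out.data.min(), out.data.max())
    return out


def run_tier1(stack: ImageStack, config: Tier1Config | None = None) -> Tier1Result:
    """The mandatory preprocessing pass feeding all later tiers.

    Order: background subtraction -> optional denoise hook -> rank filters
    -> Gaussian blur -> depth compensation -> optional gradient separation.
    The morphometrics branch is then thresholded and per-slice hole-filled;
    the chosen threshold is recorded so segmentation reuses it.
    """
    cfg = config or Tier1Config()
    s = stack
    if cfg.subtract_background_on:
        s = _stage("subtract_background", subtract_background, s, cfg.background_radius)
    if cfg.denoise_hook is not None:
        s = _stage("denoise_hook", cfg.denoise_hook, s)
    if cfg.median_on:
        s = _stage("median", rank_filter_3d, s, "median", cfg.median_radius)
    if cfg.minimum_on:
        s = _stage("minimum", rank_filter_3d, s, "minimum", cfg.minmax_radius)
    if cfg.maximum_on:
        s = _stage("maximum", rank_filter_3d, s, "maximum", cfg.minmax_radius)
    if cfg.variance_on:
        s = _stage("variance", rank_filter_3d, s, "variance", cfg.minmax_radius)
    if cfg.gaussian_sigma > 0:
        s = _stage("gaussian_blur", gaussian_blur_3d, s, cfg.gaussian_sigma)
    if cfg.depth_compensation_on:
        s = _stage("compensate_depth", compensate_depth, s, cfg.depth_percentile)
    if cfg.gradient_separation_on:
        s = _stage("gradient_separation", gradient_separation, s)

    if cfg.threshold == "otsu":
        thr = float(threshold_otsu(s.data))
    else:
        thr = float(cfg.threshold)  # type: ignore[arg-type]
    log.info("tier1 structure threshold %g", thr)

    mask = s.data > thr
    filled = fill_holes_2d(mask)
    morph = s.data.copy()
    # raise filled-in lumen voxels just above threshold so re-binarization
    # at `thr` reproduces the filled mask exactly
    morph[filled & ~mask] = thr + max(1.0, abs(thr) * 1e-3)
    return Tier1Result(
        for_morphometrics=s.with_data(morph),
        for_lumen=s,
        structure_threshold=thr,
        structure_mask=filled,
    )
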