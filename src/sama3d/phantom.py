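"""Computer-generated validation stacks with known ground truth.

Each phantom stack mimics a confocal z-stack of 3D epithelial cultures: a
population of ellipsoidal "structures" at random positions, orientations and
sizes, each optionally hollowed by a smaller concentric ellipsoidal lumen
that appears dark against the bright shell. Four standard conditions probe
different analysis endpoints:

* ``C1`` — reference: isotropic size distribution, every structure hollow.
* ``C2`` — elongation: the sampling maximum of one principal semi-axis is
  doubled, so structures are stretched along a random direction.
* ``C3`` — lumen formation: each structure has only a 50% chance of a lumen.
* ``C4`` — complexity: each structure is two perpendicular ellipsoids
  sharing a center (a branched, cross-like shape).

Six stacks per condition is the standard validation design; the defaults
below (grid, intensities, size ranges) are chosen so structures are large
enough for stable second moments yet a full condition runs on a desktop.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .core import ImageStack

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "CONDITIONS",
    "make_condition_spec",
    "rasterize_ellipsoid",
    "generate_stack",
    "generate_condition",
    "apply_artifacts",
    "write_condition",
]

#: Default voxel grid (z, y, x). Anisotropy is handled downstream via spacing.
DEFAULT_GRID: tuple[int, int, int] = (64, 256, 256)


@dataclass
class PhantomSpec:
    """Parameters of one phantom condition.

    Structures are prolate, duct-like ellipsoids: the designated (major)
    semi-axis samples uniformly from ``major_axis_range`` and the two minor
    semi-axes from ``semi_axis_range``, with a uniform random orientation —
    so the size distribution treats every spatial direction alike. The
    prolateness is deliberate: epithelial ducts are elongated, and a
    thinning skeleton only retains an arm whose protrusion exceeds its
    half-thickness, so near-spherical phantoms would make branching
    undetectable by construction. ``axis_elongation_factor`` multiplies the
    upper bound of the major-axis interval (the elongation condition uses
    2.0). ``lumen_radius_fraction_range`` is the interval for the single
    fraction of the parent's semi-axes used for the concentric lumen, kept
    inside (0, 1) so lumena are strictly interior; the default floor keeps
    the thinnest lumen semi-axis at >= 2 voxels, i.e. resolvable after
    smoothing.
    """

    condition: str = "C1"
    n_structures: int = 40
    grid_shape: tuple[int, int, int] = DEFAULT_GRID
    semi_axis_range: tuple[float, float] = (5.0, 7.0)
    major_axis_range: tuple[float, float] = (14.0, 20.0)
    axis_elongation_factor: float = 1.0
    lumen_probability: float = 1.0
    lumen_radius_fraction_range: tuple[float, float] = (0.5, 0.6)
    perpendicular_pair: bool = False
    n_stacks: int = 6
    foreground_mean: float = 200.0
    background_mean: float = 20.0
    noise_sd: float = 0.0
    depth_decay: float = 1.0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    min_clearance: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_structures <= 0:
            raise ValueError("n_structures must be positive")
        if not 0.0 <= self.lumen_probability <= 1.0:
            raise ValueError("lumen_probability must lie in [0, 1]")
        for name in ("semi_axis_range", "major_axis_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive interval")
        flo, fhi = self.lumen_radius_fraction_range
        if not (0.0 < flo <= fhi < 1.0):
            raise ValueError("lumen_radius_fraction_range must lie strictly inside (0, 1)")
        if self.axis_elongation_factor < 1.0:
            raise ValueError("axis_elongation_factor must be >= 1")
        if not 0.0 < self.depth_decay <= 1.0:
            raise ValueError("depth_decay must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class GroundTruth:
    """Per-stack truth against which detection and measurement are scored.

    ``structure_labels`` and ``lumen_labels`` share label ids: the lumen grid
    carries its parent structure's label. ``table`` has one row per structure
    with columns ``label, cz, cy, cx, axis_long, axis_mid, axis_short,
    has_lumen, lumen_voxels, n_parts, n_voxels``.
    """

    structure_labels: np.ndarray
    lumen_labels: np.ndarray
    table: pd.DataFrame

    @property
    def n_structures(self) -> int:
        return len(self.table)


_CONDITION_OVERRIDES: dict[str, dict] = {
    "C1": {},
    "C2": {"axis_elongation_factor": 2.0},
    "C3": {"lumen_probability": 0.5},
    "C4": {"perpendicular_pair": True},
}
CONDITIONS: tuple[str, ...] = tuple(_CONDITION_OVERRIDES)


def make_condition_spec(condition: str, **overrides) -> PhantomSpec:
    """Build the spec for one of the standard conditions C1..C4.

    Keyword overrides replace any :class:`PhantomSpec` field, e.g.
    ``make_condition_spec("C1", n_structures=10)`` for a scaled-down run.
    """
    cond = condition.upper()
    if cond not in _CONDITION_OVERRIDES:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    fields = {"condition": cond, **_CONDITION_OVERRIDES[cond], **overrides}
    return PhantomSpec(**fields)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation matrix (via a random unit quaternion)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _axis_angle_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle), np.sin(angle)
    ax, ay, az = axis
    K = np.array([[0, -az, ay], [az, 0, -ax], [-ay, ax, 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def _ellipsoid_bbox_halfextent(semi_axes: Sequence[float], rotation: np.ndarray) -> np.ndarray:
    # tight axis-aligned half-extent of a rotated ellipsoid:
    # e_i = sqrt(sum_j (R_ij * a_j)^2)
    a = np.asarray(semi_axes, dtype=float)
    return np.sqrt(((rotation * a[None, :]) ** 2).sum(axis=1))


def rasterize_ellipsoid(
    center: Sequence[float],
    semi_axes: Sequence[float],
    rotation: np.ndarray | None,
    grid_shape: Sequence[int],
) -> np.ndarray:
    """Boolean mask of the voxels whose centers lie inside the ellipsoid.

    A voxel at integer index p is included iff ``|A^-1 R^T (p - c)| <= 1``
    where A = diag(semi_axes) and R rotates the body frame into the grid.
    The mask is clipped at the grid bounds.
    """
    center = np.asarray(center, dtype=float)
    semi_axes = np.asarray(semi_axes, dtype=float)
    grid_shape = tuple(int(s) for s in grid_shape)
    if np.any(semi_axes <= 0):
        raise ValueError("semi-axes must be strictly positive")
    if np.any(center < 0) or np.any(center >= np.asarray(grid_shape)):
        raise ValueError("center must lie inside the grid")
    R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)

    ext = _ellipsoid_bbox_halfextent(semi_axes, R)
    lo = np.maximum(np.floor(center - ext).astype(int), 0)
    hi = np.minimum(np.ceil(center + ext).astype(int) + 1, grid_shape)
    out = np.zeros(grid_shape, dtype=bool)
    if np.any(lo >= hi):
        return out
    zz, yy, xx = np.meshgrid(*(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1).astype(float) - center
    body = pts @ R  # (p - c) @ R == R^T (p - c) row-wise
    inside = ((body / semi_axes) ** 2).sum(axis=-1) <= 1.0
    out[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = inside
    return out


def _sample_semi_axes(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Body-frame semi-axes: axis 0 is the designated (major) axis.

    The elongation condition widens only the major axis's sampling maximum;
    random orientation then spreads the long direction over the sphere.
    """
    mlo, mhi = spec.major_axis_range
    lo, hi = spec.semi_axis_range
    major = rng.uniform(mlo, mhi * spec.axis_elongation_factor)
    return np.array([major, rng.uniform(lo, hi), rng.uniform(lo, hi)])


def _place_structure(
    spec: PhantomSpec, rng: np.random.Generator, occupied: np.ndarray, max_tries: int = 200
) -> tuple[np.ndarray, np.ndarray | None, dict]:
    """Rejection-sample one non-overlapping structure.

    Returns (structure mask, lumen mask or None, truth row dict).
    """
    shape = np.asarray(spec.grid_shape)
    struct26 = np.ones((3, 3, 3), dtype=bool)
    for _ in range(max_tries):
        axes1 = _sample_semi_axes(spec, rng)
        R1 = _random_rotation(rng)
        parts = [(axes1, R1)]
        if spec.perpendicular_pair:
            long_dir = R1[:, int(np.argmax(axes1))]
            # random axis perpendicular to the first part's long axis
            v = rng.normal(size=3)
            v -= v.dot(long_dir) * long_dir
            v /= np.linalg.norm(v)
            R2 = _axis_angle_rotation(v, np.pi / 2) @ R1
            parts.append((_sample_semi_axes(spec, rng), R2))

        ext = np.max([_ellipsoid_bbox_halfextent(a, R) for a, R in parts], axis=0)
        margin = ext + spec.min_clearance + 1
        if np.any(2 * margin >= shape):
            continue
        center = np.array([rng.uniform(m, s - m) for m, s in zip(margin, shape)])

        mask = rasterize_ellipsoid(center, parts[0][0], parts[0][1], spec.grid_shape)
        for a, R in parts[1:]:
            mask |= rasterize_ellipsoid(center, a, R, spec.grid_shape)

        # clearance check within an expanded bounding box
        lo = np.maximum((center - margin).astype(int), 0)
        hi = np.minimum((center + margin).astype(int) + 1, shape)
        sub = tuple(slice(l, h) for l, h in zip(lo, hi))
        grown = ndi.binary_dilation(mask[sub], structure=struct26, iterations=spec.min_clearance)
        if (grown & occupied[sub]).any():
            continue

        lumen = None
        lumen_voxels = 0
        has_lumen = rng.random() < spec.lumen_probability
        if has_lumen:
            frac = rng.uniform(*spec.lumen_radius_fraction_range)
            lumen = rasterize_ellipsoid(center, axes1 * frac, R1, spec.grid_shape)
            lumen &= mask
            lumen_voxels = int(lumen.sum())

        srt = np.sort(axes1)[::-1]
        row = {
            "cz": center[0],
            "cy": center[1],
            "cx": center[2],
            "axis_long": srt[0],
            "axis_mid": srt[1],
            "axis_short": srt[2],
            "has_lumen": bool(has_lumen),
            "lumen_voxels": lumen_voxels,
            "n_parts": len(parts),
            "n_voxels": int(mask.sum()),
        }
        return mask, lumen, row
    raise RuntimeError(
        f"could not place structure after {max_tries} attempts; "
        "use a larger grid_shape or fewer/smaller structures"
    )


def generate_stack(spec: PhantomSpec, seed: int | None = None) -> tuple[ImageStack, GroundTruth]:
    """Render one phantom stack and its ground truth.

    Fully reproducible: the same spec and seed give bit-identical output.
    Structures are placed with at least ``spec.min_clearance`` voxels of
    clearance between them (rejection sampling) so the generated count is in
    principle recoverable by segmentation.
    """
    if seed is None:
        seed = spec.seed if spec.seed is not None else 0
    rng = np.random.default_rng(seed)

    structure_labels = np.zeros(spec.grid_shape, dtype=np.int32)
    lumen_labels = np.zeros(spec.grid_shape, dtype=np.int32)
    occupied = np.zeros(spec.grid_shape, dtype=bool)
    rows = []
    for label in range(1, spec.n_structures + 1):
        mask, lumen, row = _place_structure(spec, rng, occupied)
        structure_labels[mask] = label
        occupied |= mask
        if lumen is not None:
            lumen_labels[lumen] = label
        row["label"] = label
        rows.append(row)

    img = np.full(spec.grid_shape, spec.background_mean, dtype=np.float32)
    img[structure_labels > 0] = spec.foreground_mean
    img[lumen_labels > 0] = spec.background_mean  # dark hole, not zero

    stack = ImageStack(img, spacing=spec.spacing, intensity_range=(0.0, 255.0))
    if spec.depth_decay != 1.0 or spec.noise_sd > 0:
        stack = apply_artifacts(stack, spec.noise_sd, spec.depth_decay, seed=seed + 1)

    cols = [
        "label", "cz", "cy", "cx", "axis_long", "axis_mid", "axis_short",
        "has_lumen", "lumen_voxels", "n_parts", "n_voxels",
    ]
    table = pd.DataFrame(rows)[cols]
    return stack, GroundTruth(structure_labels, lumen_labels, table)


def generate_condition(
    condition: str, seed: int, n_stacks: int | None = None, **overrides
) -> list[tuple[ImageStack, GroundTruth]]:
    """Generate all stacks of one condition (default six), seeded per stack."""
    spec = make_condition_spec(condition, **overrides)
    n = spec.n_stacks if n_stacks is None else n_stacks
    return [generate_stack(spec, seed=seed + i) for i in range(n)]


def apply_artifacts(
    stack: ImageStack,
    noise_sd: float,
    depth_decay: float,
    seed: int | None = None,
) -> ImageStack:
    """Degrade a clean phantom with depth attenuation and Gaussian noise.

    Slice i is multiplied by ``depth_decay ** i`` (mimicking luminosity loss
    away from the objective), then i.i.d. Gaussian noise of standard
    deviation ``noise_sd`` is added; the result is clipped to the stack's
    declared intensity range.
    """
    if not 0.0 < depth_decay <= 1.0:
        raise ValueError("depth_decay must lie in (0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    nz = stack.shape[0]
    gains = depth_decay ** np.arange(nz, dtype=np.float64)
    out = stack.data * gains[:, None, None]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    out = np.clip(out, *stack.intensity_range)
    return stack.with_data(out)


def write_condition(
    out_dir: str | Path,
    condition: str,
    seed: int,
    n_stacks: int | None = None,
    write_truth: bool = True,
    **overrides,
) -> pd.DataFrame:
    """Write a condition's stacks as 16-bit multi-page TIFFs plus a manifest.

    Produces ``<cond>_<i>.tif`` (intensity), optional
    ``<cond>_<i>_labels.tif`` / ``<cond>_<i>_lumen_labels.tif`` ground-truth
    grids, and appends per-structure truth rows to ``manifest.csv``.
    Returns the manifest table.
    """
    from .io import write_stack  # deferred: avoids import cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs = generate_condition(condition, seed=seed, n_stacks=n_stacks, **overrides)
    manifest_rows = []
    for i, (stack, truth) in enumerate(pairs):
        stack_id = f"{condition}_{i}"
        write_stack(out_dir / f"{stack_id}.tif", stack)
        if write_truth:
            import tifffile

            tifffile.imwrite(out_dir / f"{stack_id}_labels.tif",
                             truth.structure_labels.astype(np.uint16))
            tifffile.imwrite(out_dir / f"{stack_id}_lumen_labels.tif",
                             truth.lumen_labels.astype(np.uint16))
        t = truth.table.copy()
        t.insert(0, "stack", stack_id)
        t.insert(1, "condition", condition)
        t.insert(2, "seed", seed + i)
        manifest_rows.append(t)
    manifest = pd.concat(manifest_rows, ignore_index=True)
    path = out_dir / "manifest.csv"
    header = not path.exists()
    manifest.to_csv(path, mode="a", header=header, index=False)
    return manifest
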