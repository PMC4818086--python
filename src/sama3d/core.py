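"""Core in-memory containers shared by every stage of the pipeline.

An :class:`ImageStack` is a 3D grid of intensities (z, y, x) with an
anisotropic voxel spacing; a :class:`LabelVolume` is an integer grid on the
same geometry in which label 0 is background and labels 1..K identify
26-connected structures (or lumena).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ImageStack", "LabelVolume"]


@dataclass
class ImageStack:
    """A single-channel 3D image.

    Parameters
    ----------
    data
        Intensity grid, axis order (z, y, x). Stored as float32 internally
        so filters do not overflow; the original bit depth is kept in
        ``intensity_range``.
    spacing
        Physical voxel size (dz, dy, dx), in micrometres or arbitrary units.
    intensity_range
        Declared (min, max) of the value range of origin, e.g. (0, 255) for
        8-bit input. Stages that clip (depth compensation, artifact
        simulation) clip to this range.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    intensity_range: tuple[float, float] = (0.0, 255.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("ImageStack requires a non-empty 3D (z, y, x) grid")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")
        lo, hi = self.intensity_range
        if not hi > lo:
            raise ValueError("intensity_range must satisfy max > min")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def with_data(self, data: np.ndarray) -> "ImageStack":
        """New stack with the same geometry/range but different intensities."""
        return replace(self, data=np.asarray(data, dtype=np.float32))


@dataclass
class LabelVolume:
    """Integer-labeled 3D grid; 0 = background, labels 1..K contiguous."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D (z, y, x)")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]

    @property
    def n_labels(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def ids(self) -> list[int]:
        return list(range(1, self.n_labels + 1))

    def mask(self, label_id: int) -> np.ndarray:
        return self.labels == label_id
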