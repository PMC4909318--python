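"""Calibrated image stacks and 2.5D projections.

A confocal z-stack is reduced to a *Maximum Intensity Projection* (MIP)
plus a *height view* (Z-buffer): for every lateral position the MIP keeps
the brightest voxel along z and the height view keeps the slice index at
which that maximum occurred.  Over a solid fluorescent object the height
view is locally smooth (the brightest voxel sits on the object surface or
interior), while over background it is essentially random — this contrast
is what the downstream segmentation exploits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageStack", "ProjectionPair", "compute_projection"]


@dataclass
class ImageStack:
    """A single-channel 3D intensity volume with anisotropic calibration.

    Parameters
    ----------
    voxels
        Intensities indexed ``(z, y, x)``; finite and non-negative.
    pixel_size_xy
        Lateral pixel size in micrometres.
    z_step
        Distance between consecutive slices in micrometres.  The z index
        is assumed to increase with imaging depth into the sample; use
        :meth:`flipped_z` for stacks acquired in the opposite order.
    channel_name
        Free-text channel label (e.g. ``"stable"`` or ``"marker"``).
    """

    voxels: np.ndarray
    pixel_size_xy: float
    z_step: float
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D (z, y, x), got {self.voxels.ndim}D")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel intensities must be finite")
        if self.voxels.size and self.voxels.min() < 0:
            raise ValueError("voxel intensities must be >= 0")
        if not (self.z_step > 0 and self.pixel_size_xy > 0):
            raise ValueError("pixel_size_xy and z_step must be positive")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def check_axial_sampling(self, cell_diameter: float) -> None:
        """Warn when the z-step exceeds the average cell diameter.

        The 2.5D method assumes axial sampling fine enough that every cell
        appears in at least one slice; a coarser z-step degrades the height
        view and the axial profiles but is not a hard error.
        """
        if self.z_step > cell_diameter:
            warnings.warn(
                f"z_step ({self.z_step} um) exceeds the average cell diameter "
                f"({cell_diameter} um); the height view may be unreliable",
                stacklevel=2,
            )

    def flipped_z(self) -> "ImageStack":
        """Return a copy with the slice order reversed (depth axis flip)."""
        return ImageStack(
            self.voxels[::-1].copy(), self.pixel_size_xy, self.z_step, self.channel_name
        )


@dataclass
class ProjectionPair:
    """MIP and height view of a stack, sharing its lateral calibration."""

    mip: np.ndarray
    height: np.ndarray  # integer z slice indices
    z_step: float
    pixel_size_xy: float
    n_slices: int = field(default=0)

    def __post_init__(self) -> None:
        if self.mip.shape != self.height.shape:
            raise ValueError("mip and height must have identical shapes")
        if self.n_slices and self.height.size:
            if self.height.min() < 0 or self.height.max() >= self.n_slices:
                raise ValueError("height values must lie in [0, n_slices)")

    @property
    def height_um(self) -> np.ndarray:
        """Height view converted to micrometres."""
        return self.height * self.z_step


def compute_projection(stack: ImageStack) -> ProjectionPair:
    """Compute the MIP and height view of a stack.

    For every pixel ``(x, y)``, ``mip = max_z voxels(z, y, x)`` and
    ``height`` holds a z attaining that maximum (ties broken towards the
    smallest z, i.e. the shallowest slice).

    Raises
    ------
    ValueError
        If the stack has fewer than two slices (a single plane carries no
        depth information).
    """
    if stack.n_slices < 2:
        raise ValueError("stack must contain at least 2 z-slices")
    mip = stack.voxels.max(axis=0)
    height = stack.voxels.argmax(axis=0).astype(np.int32)
    return ProjectionPair(
        mip=mip,
        height=height,
        z_step=stack.z_step,
        pixel_size_xy=stack.pixel_size_xy,
        n_slices=stack.n_slices,
    )
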