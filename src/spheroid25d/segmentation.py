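"""2D spheroid segmentation from the MIP / height-view pair.

Spheroids are segmented not by intensity but by *local homogeneity of the
height view*: over a solid object the z of the brightest voxel varies
slowly from pixel to pixel, while over background it is noise.  A disk
range filter (local max minus min) turns this into a per-pixel
inhomogeneity score; thresholding it low selects object pixels.  A second
threshold on the mean MIP intensity of each connected component removes
spurious dim objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as cc_label
from skimage.morphology import disk, remove_small_objects

from .stack import ProjectionPair

__all__ = [
    "SegmentationParams",
    "SpheroidMask2D",
    "SegmentationResult",
    "range_filter",
    "auto_threshold_zrange",
    "estimate_background_mean",
    "segment_spheroids",
]

Auto = Union[float, str]  # a number or the literal "auto"


@dataclass
class SegmentationParams:
    """Tunable parameters of the 2D segmentation step.

    cell_diameter : um, expected average cell diameter (default 12).
    r_range : um, neighbourhood radius of the range filter (default 3,
        one quarter of the cell diameter).
    max_z_range : threshold on the range-filtered height view, in z-slice
        units; ``"auto"`` derives it from the histogram's first peak.
    min_mip : threshold on the mean MIP intensity of a segmented object;
        ``"auto"`` uses the mean background intensity of the MIP.
    min_object_area : um^2, objects smaller than this are removed as
        speckle; ``None`` uses one cell footprint pi*(cell_diameter/2)^2.
    """

    cell_diameter: float = 12.0
    r_range: float = 3.0
    max_z_range: Auto = "auto"
    min_mip: Auto = "auto"
    min_object_area: float | None = None

    def __post_init__(self) -> None:
        if self.cell_diameter <= 0 or self.r_range <= 0:
            raise ValueError("cell_diameter and r_range must be positive")

    def resolved_min_area(self) -> float:
        if self.min_object_area is not None:
            return self.min_object_area
        return np.pi * (self.cell_diameter / 2.0) ** 2


@dataclass
class SpheroidMask2D:
    """One segmented spheroid: a labelled 8-connected 2D pixel region."""

    label: int
    mask: np.ndarray  # full-frame boolean mask
    mean_mip_intensity: float
    area_um2: float
    touches_border: bool = False
    # populated by the ellipsoid stage
    circularity: float | None = None
    roundness_class: str | None = None

    @property
    def pixels(self) -> set[tuple[int, int]]:
        """0-based ``(x, y)`` coordinates of the mask pixels."""
        ys, xs = np.nonzero(self.mask)
        return set(zip(xs.tolist(), ys.tolist()))

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class SegmentationResult:
    spheroids: list[SpheroidMask2D]
    labels: np.ndarray  # int label image, 0 = background
    max_z_range: float = field(default=np.nan)
    min_mip: float = field(default=np.nan)


def range_filter(height: np.ndarray, r_range_px: int) -> np.ndarray:
    """Local max-minus-min of the height view over a disk neighbourhood.

    Image-border neighbourhoods are clipped to valid pixels (edge
    replication is equivalent: every replicated value is itself a member
    of the clipped disk).
    """
    if r_range_px < 1:
        raise ValueError("r_range_px must be >= 1")
    footprint = disk(r_range_px)
    h = np.asarray(height)
    hi = ndi.maximum_filter(h, footprint=footprint, mode="nearest")
    lo = ndi.minimum_filter(h, footprint=footprint, mode="nearest")
    return hi - lo


def auto_threshold_zrange(
    range_image: np.ndarray, n_slices: int | None = None
) -> float:
    """Derive ``max_z_range`` from the histogram of the range-filtered view.

    Object pixels pile up in a sharp peak at small z-ranges, background in
    a broad distribution at large ranges.  The threshold is taken at the
    extent of that first peak: build the integer-bin histogram, smooth with
    a 3-bin moving average, find the first local maximum, then return the
    first bin after it whose smoothed count falls below 10% of the peak
    count.

    Falls back (with a warning) to half the slice count — or half the
    maximum observed range when ``n_slices`` is unknown — for degenerate
    unimodal/constant histograms.
    """
    vals = np.asarray(range_image).ravel()
    vals = np.round(vals).astype(np.int64)

    def _fallback(reason: str) -> float:
        if n_slices is not None:
            thr = n_slices / 2.0
        else:
            thr = max(float(vals.max()), 1.0) / 2.0
        warnings.warn(
            f"auto max_z_range: {reason}; falling back to {thr}", stacklevel=2
        )
        return thr

    if np.unique(vals).size < 2:
        return _fallback("constant range image")

    hist = np.bincount(vals)
    # 3-bin moving average; edge bins average over the available neighbours
    kernel = np.ones(3) / 3.0
    smooth = np.convolve(hist.astype(float), kernel, mode="same")
    smooth[0] = (hist[0] + hist[1]) / 2.0 if hist.size > 1 else hist[0]

    # first local maximum of the smoothed histogram
    peak = None
    for i in range(smooth.size):
        left = smooth[i - 1] if i > 0 else -np.inf
        right = smooth[i + 1] if i + 1 < smooth.size else -np.inf
        if smooth[i] >= left and smooth[i] >= right:
            peak = i
            break
    if peak is None:
        return _fallback("no histogram peak found")

    cutoff = 0.1 * smooth[peak]
    for j in range(peak + 1, smooth.size):
        if smooth[j] < cutoff:
            return float(j)
    return _fallback("first histogram peak has no clear extent")


def estimate_background_mean(mip: np.ndarray, foreground: np.ndarray) -> float:
    """Arithmetic mean of the MIP over pixels outside ``foreground``."""
    fg = np.asarray(foreground, dtype=bool)
    if fg.all():
        raise ValueError("foreground covers the whole image; no background left")
    return float(np.asarray(mip)[~fg].mean())


def segment_spheroids(
    proj: ProjectionPair, params: SegmentationParams | None = None
) -> SegmentationResult:
    """Segment 2D spheroid masks from a projection pair.

    Pipeline: range-filter the height view -> threshold at ``max_z_range``
    (foreground = range <= threshold) -> fill holes and remove
    sub-cell-sized speckle -> 8-connected component labelling -> discard
    components whose mean MIP intensity is below ``min_mip``.  Surviving
    components are relabelled consecutively from 1.
    """
    params = params or SegmentationParams()
    r_px = max(1, int(round(params.r_range / proj.pixel_size_xy)))
    zrange = range_filter(proj.height, r_px)

    if params.max_z_range == "auto":
        n_slices = proj.n_slices or (int(np.max(proj.height)) + 1)
        max_z_range = auto_threshold_zrange(zrange, n_slices=n_slices)
    else:
        max_z_range = float(params.max_z_range)

    fg = zrange <= max_z_range
    fg = ndi.binary_fill_holes(fg)

    min_area_px = params.resolved_min_area() / proj.pixel_size_xy**2
    if min_area_px >= 1:
        # removes objects with size <= max_size, hence the -1
        fg = remove_small_objects(fg, max_size=int(np.ceil(min_area_px)) - 1)

    if params.min_mip == "auto":
        if fg.all():
            raise ValueError("segmentation foreground covers the entire image")
        min_mip = estimate_background_mean(proj.mip, fg)
    else:
        min_mip = float(params.min_mip)

    raw_labels = cc_label(fg, connectivity=2)
    mip = np.asarray(proj.mip, dtype=float)
    px_area = proj.pixel_size_xy**2

    spheroids: list[SpheroidMask2D] = []
    labels = np.zeros_like(raw_labels)
    next_label = 0
    for lab in range(1, raw_labels.max() + 1):
        mask = raw_labels == lab
        mean_int = float(mip[mask].mean())
        if mean_int < min_mip:
            continue
        next_label += 1
        labels[mask] = next_label
        ys, xs = np.nonzero(mask)
        touches = bool(
            ys.min() == 0
            or xs.min() == 0
            or ys.max() == mask.shape[0] - 1
            or xs.max() == mask.shape[1] - 1
        )
        spheroids.append(
            SpheroidMask2D(
                label=next_label,
                mask=mask,
                mean_mip_intensity=mean_int,
                area_um2=float(mask.sum()) * px_area,
                touches_border=touches,
            )
        )
    return SegmentationResult(
        spheroids=spheroids, labels=labels, max_z_range=max_z_range, min_mip=min_mip
    )
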