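"""Ground-truth comparison of the 2D segmentation.

The manual ground truth is a set of 2D masks, one per spheroid, each
annotated with one of five classes: (1) well separated, (2) overlapping
with a brighter spheroid, (3) overlapping with a dimmer spheroid,
(4) merely touching another spheroid, (5) touching the image border.

Matching: an automatic mask that covers more than half of a ground-truth
region is its (unique — masks are disjoint) match.  Sensitivity is
TP / (TP + FN) with a Wilson score interval.  Contour accuracy weights
every misclassified pixel by a sigmoid of its distance to the
ground-truth contour, so sub-resolution outline jitter contributes
little while gross errors saturate at weight one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.stats import norm

from .roi import read_roi_zip
from .segmentation import SpheroidMask2D

__all__ = [
    "GroundTruthRegion",
    "MatchResult",
    "match_regions",
    "sensitivity_wilson",
    "contour_accuracy",
    "load_ground_truth",
    "GT_CLASS_NAMES",
]

GT_CLASS_NAMES = {
    1: "well-separated",
    2: "overlapping-brighter",
    3: "overlapping-dimmer",
    4: "touching",
    5: "border",
}

# RoiManager color convention for the five classes
_COLOR_TO_CLASS = {
    (255, 0, 0): 1,  # red
    (0, 255, 0): 2,  # green
    (255, 0, 255): 3,  # magenta
    (0, 255, 255): 4,  # cyan
    (0, 0, 255): 5,  # blue
}


@dataclass
class GroundTruthRegion:
    mask: np.ndarray  # boolean, full frame
    gt_class: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.gt_class not in GT_CLASS_NAMES:
            raise ValueError(f"gt_class must be in 1..5, got {self.gt_class}")


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int]]  # (candidate index, ground-truth index)
    sensitivity: float
    wilson_ci: tuple[float, float]
    merge_events: list[tuple[int, list[int]]] = field(default_factory=list)
    per_pair_accuracy: list[float] = field(default_factory=list)

    @property
    def fp_ratio(self) -> float:
        """FP / P: false positives relative to the ground-truth count."""
        total = self.tp + self.fn
        return self.fp / total if total else np.nan


def _as_mask(m) -> np.ndarray:
    if isinstance(m, SpheroidMask2D):
        return m.mask
    if isinstance(m, GroundTruthRegion):
        return m.mask
    return np.asarray(m, dtype=bool)


def match_regions(
    candidates: list, ground_truth: list, confidence: float = 0.95
) -> MatchResult:
    """Match automatic masks to ground-truth regions by > 50% coverage.

    For each ground-truth region the candidate covering more than half of
    its area is its match (at most one exists since candidates are
    disjoint).  A candidate claiming several ground-truth regions — a
    segmentation mask merging multiple spheroids — keeps the one with the
    largest covered fraction; the rest become false negatives and the
    event is recorded.  Candidates matching nothing are false positives;
    unmatched ground-truth regions are false negatives.
    """
    cand = [_as_mask(m) for m in candidates]
    gt = [_as_mask(g) for g in ground_truth]

    claims: dict[int, list[tuple[float, int]]] = {}
    for j, gmask in enumerate(gt):
        g_area = gmask.sum()
        if g_area == 0:
            continue
        for i, cmask in enumerate(cand):
            frac = np.logical_and(cmask, gmask).sum() / g_area
            if frac > 0.5:
                claims.setdefault(i, []).append((frac, j))
                break  # disjoint candidates: at most one can exceed 50%

    pairs: list[tuple[int, int]] = []
    merge_events: list[tuple[int, list[int]]] = []
    for i, claimed in claims.items():
        claimed.sort(reverse=True)
        pairs.append((i, claimed[0][1]))
        if len(claimed) > 1:
            merge_events.append((i, [j for _, j in claimed]))

    matched_gt = {j for _, j in pairs}
    matched_cand = {i for i, _ in pairs}
    tp = len(pairs)
    fn = len(gt) - len(matched_gt)
    fp = len(cand) - len(matched_cand)
    sens, lo, hi = sensitivity_wilson(tp, fn, confidence) if tp + fn else (np.nan,) * 3
    return MatchResult(
        tp=tp,
        fp=fp,
        fn=fn,
        pairs=sorted(pairs),
        sensitivity=sens,
        wilson_ci=(lo, hi),
        merge_events=merge_events,
    )


def sensitivity_wilson(
    tp: int, fn: int, confidence: float = 0.95
) -> tuple[float, float, float]:
    """Detection sensitivity with its Wilson score confidence interval.

    p_hat = TP / (TP + FN); the interval is
    ``(p_hat + z^2/2n +/- z sqrt(p_hat (1 - p_hat)/n + z^2/4n^2)) / (1 + z^2/n)``
    with n = TP + FN and z the standard-normal quantile for the
    confidence level.  Endpoints always lie in [0, 1] and bracket p_hat.
    """
    n = tp + fn
    if n <= 0:
        raise ValueError("TP + FN must be positive")
    p = tp / n
    z = norm.ppf(0.5 + confidence / 2.0)
    denom = 1.0 + z * z / n
    centre = p + z * z / (2.0 * n)
    half = z * np.sqrt(p * (1.0 - p) / n + z * z / (4.0 * n * n))
    lo = (centre - half) / denom
    hi = (centre + half) / denom
    # guard against rounding pushing the endpoints past [0, p] / [p, 1]
    return p, min(max(lo, 0.0), p), max(min(hi, 1.0), p)


def contour_accuracy(
    m_i,
    m_gt,
    pixel_size_xy: float,
    x0: float = 1.5,
    k: float = 2.0,
) -> float:
    """Sigmoid-weighted contour accuracy of a matched mask pair.

    Every pixel of the symmetric difference contributes
    ``f(d) = 1 / (1 + exp(-k (d - x0)))`` where d is its Euclidean
    distance (um) to the ground-truth contour; the defaults x0 = 1.5 um,
    k = 2 um^-1 make a pixel half a weight at 1.5 um and a full weight
    beyond ~4 um.  The penalty e is the sum normalised by the
    ground-truth area (pixels); accuracy = 1 - e (it can go negative for
    grossly oversized masks).
    """
    a = _as_mask(m_i)
    g = _as_mask(m_gt)
    g_area = int(g.sum())
    if g_area == 0:
        raise ValueError("ground-truth mask is empty")
    contour = g & ~ndi.binary_erosion(
        g, structure=np.ones((3, 3), bool), border_value=0
    )
    dist = ndi.distance_transform_edt(~contour, sampling=pixel_size_xy)
    diff = a ^ g
    if not diff.any():
        return 1.0
    d = dist[diff]
    f = 1.0 / (1.0 + np.exp(-k * (d - x0)))
    return float(1.0 - f.sum() / g_area)


def load_ground_truth(path, shape: tuple[int, int]) -> list[GroundTruthRegion]:
    """Load 5-class ground truth from an ImageJ RoiManager .zip archive.

    The class is decoded from each contour's stroke color (red, green,
    magenta, cyan, blue for classes 1-5); ROIs with an unknown or missing
    color default to class 1 (well separated).
    """
    regions = []
    for roi in read_roi_zip(path):
        gt_class = _COLOR_TO_CLASS.get(roi.stroke_rgb, 1)
        regions.append(
            GroundTruthRegion(mask=roi.to_mask(shape), gt_class=gt_class, name=roi.name)
        )
    return regions
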