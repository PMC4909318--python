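"""Full 2.5D analysis pipeline: projection -> segmentation -> ellipsoid
fitting -> attenuation classification -> spot detection -> corrected
counts.  Also provides the baseline plain-MIP mode used for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .attenuation import Visibility, analyzable_depth, classify_visibility
from .ellipsoid import extrapolate_ellipsoid, filter_by_circularity, fit_ellipse
from .io import RunConfig
from .segmentation import SegmentationParams, segment_spheroids
from .spots import (
    SpheroidContext,
    SpotParams,
    assign_and_count,
    detect_spots,
    median_mask_intensity,
    optimal_log_scale,
)
from .stack import ImageStack, compute_projection

__all__ = ["SpheroidRecord", "PipelineResult", "run_pipeline"]

log = logging.getLogger("spheroid25d")


@dataclass
class SpheroidRecord:
    """Per-spheroid output feature set (one row of the results table)."""

    label: int
    center_x_um: float
    center_y_um: float
    center_z_um: float
    axis_a_um: float
    axis_b_um: float
    axis_c_um: float
    orientation_rad: float
    area_um2: float
    volume_um3: float
    mean_intensity: float
    circularity: float
    roundness_class: str
    attenuation_class: str
    analyzable_depth_um: float
    n_spots_raw: int
    n_spots_corrected: float
    touches_border: bool


@dataclass
class PipelineResult:
    records: pd.DataFrame  # one row per spheroid (SpheroidRecord columns)
    spot_table: pd.DataFrame  # one row per detected spot
    summary: dict

    def write_csv(self, records_path, spots_path) -> None:
        self.records.to_csv(records_path, index=False, float_format="%.6g")
        self.spot_table.to_csv(spots_path, index=False, float_format="%.6g")


def run_pipeline(stacks: dict[str, ImageStack], config: RunConfig | None = None) -> PipelineResult:
    """Run the full 2.5D analysis on one two-channel stack.

    ``stacks`` maps channel names to calibrated stacks; the stable
    (whole-cell) channel drives segmentation and attenuation estimation,
    the marker channel drives spot detection.  With
    ``config.baseline_2d`` the ellipsoid/attenuation stages still run
    (the features are reported) but counts are plain per-mask spot
    counts without attenuation correction.
    """
    config = config or RunConfig()
    stable = stacks[config.stable_channel]
    marker = stacks[config.marker_channel]
    if config.flip_z:
        stable = stable.flipped_z()
        marker = marker.flipped_z()
    stable.check_axial_sampling(config.cell_diameter)

    # --- projection + segmentation (stable channel)
    proj = compute_projection(stable)
    seg = segment_spheroids(
        proj,
        SegmentationParams(
            cell_diameter=config.cell_diameter,
            r_range=config.r_range,
            max_z_range=config.max_z_range,
            min_mip=config.min_mip,
        ),
    )
    spheroids = [
        s for s in seg.spheroids if config.include_border or not s.touches_border
    ]
    log.info(
        "segmentation: %d spheroids (max_z_range=%.3g, min_mip=%.3g)",
        len(spheroids),
        seg.max_z_range,
        seg.min_mip,
    )

    # --- ellipse fit + circularity filter
    kept, rejected = filter_by_circularity(spheroids, config.min_circularity)

    records: list[SpheroidRecord] = []
    contexts: list[SpheroidContext] = []
    class_counts = {v.value: 0 for v in Visibility}

    for s in rejected:
        records.append(_record_stub(s, proj))

    for s in kept:
        try:
            ellipse, _ = fit_ellipse(s, proj.pixel_size_xy)
            ellipsoid, profile = extrapolate_ellipsoid(
                ellipse, s, proj, stable, min_radius=config.min_radius
            )
            depth = analyzable_depth(profile, config.attenuation_percentage)
            vis = classify_visibility(ellipsoid, depth.depth)
        except (ValueError, RuntimeError) as exc:
            log.warning("spheroid %d skipped: %s", s.label, exc)
            records.append(_record_stub(s, proj))
            continue
        class_counts[vis.value] += 1
        contexts.append(
            SpheroidContext(
                label=s.label,
                ellipsoid=ellipsoid,
                visibility=vis,
                z_top=profile.z_top,
                depth=depth.depth,
            )
        )
        records.append(
            SpheroidRecord(
                label=s.label,
                center_x_um=ellipsoid.center_x,
                center_y_um=ellipsoid.center_y,
                center_z_um=ellipsoid.center_z,
                axis_a_um=ellipsoid.a,
                axis_b_um=ellipsoid.b,
                axis_c_um=ellipsoid.c,
                orientation_rad=ellipsoid.orientation_xy,
                area_um2=s.area_um2,
                volume_um3=ellipsoid.volume,
                mean_intensity=s.mean_mip_intensity,
                circularity=s.circularity,
                roundness_class=s.roundness_class,
                attenuation_class=vis.value,
                analyzable_depth_um=depth.depth,
                n_spots_raw=0,
                n_spots_corrected=np.nan,
                touches_border=s.touches_border,
            )
        )

    # --- spot detection (marker channel)
    marker_proj = compute_projection(marker)
    spot_scale = config.spot_scale
    if spot_scale == "auto":
        spot_scale = optimal_log_scale(
            marker_proj.mip, config.max_spot_radius, marker.pixel_size_xy
        )
        log.info("spot scale resolved to %.3g um", spot_scale)
    if (seg.labels > 0).any():
        threshold = median_mask_intensity(marker_proj.mip, seg.labels)
    else:
        threshold = float(np.median(np.asarray(marker_proj.mip)))
    params = SpotParams(
        max_spot_radius=config.max_spot_radius,
        scale_sigma=spot_scale,
        mode=config.spot_mode,
    )
    source = marker if config.spot_mode == "3d" else marker_proj
    spots = detect_spots(source, params, intensity_threshold=threshold)
    log.info("spot detection: %d spots (threshold %.3g)", len(spots), threshold)

    if config.baseline_2d:
        # baseline counts cover every 2D mask, elliptical or not
        from .ellipsoid import Ellipsoid3D

        covered = {c.label for c in contexts}
        for s in spheroids:
            if s.label not in covered:
                ys, xs = np.nonzero(s.mask)
                contexts.append(
                    SpheroidContext(
                        label=s.label,
                        ellipsoid=Ellipsoid3D(
                            float(xs.mean()) * proj.pixel_size_xy,
                            float(ys.mean()) * proj.pixel_size_xy,
                            0.0, 1.0, 1.0, 1.0,
                        ),
                        visibility=Visibility.FULL,
                        z_top=0.0,
                        depth=0.0,
                    )
                )

    counts, unassigned = assign_and_count(
        spots, contexts, seg.labels, proj.pixel_size_xy, baseline_2d=config.baseline_2d
    )
    for rec in records:
        if rec.label in counts:
            cr = counts[rec.label]
            rec.n_spots_raw = cr.raw_count
            rec.n_spots_corrected = (
                np.nan if cr.corrected_count is None else cr.corrected_count
            )

    records_df = pd.DataFrame([asdict(r) for r in records])
    if records_df.empty:
        records_df = pd.DataFrame(
            columns=[f.name for f in SpheroidRecord.__dataclass_fields__.values()]
        )
    spot_df = pd.DataFrame(
        [
            {
                "x_um": s.x,
                "y_um": s.y,
                "z_um": s.z,
                "x_px": s.x / proj.pixel_size_xy,
                "y_px": s.y / proj.pixel_size_xy,
                "z_slice": s.z / proj.z_step,
                "intensity": s.intensity,
                "spheroid_label": -1 if s.spheroid_label is None else s.spheroid_label,
                "in_analyzable_region": s.in_analyzable_region,
                "mode": s.mode,
            }
            for s in spots
        ]
    )
    if spot_df.empty:
        spot_df = pd.DataFrame(
            columns=[
                "x_um", "y_um", "z_um", "x_px", "y_px", "z_slice",
                "intensity", "spheroid_label", "in_analyzable_region", "mode",
            ]
        )

    fg = int((seg.labels > 0).sum())
    bg = int(seg.labels.size - fg)
    summary = {
        "n_spheroids": len(spheroids),
        "n_elliptical": len(kept),
        "n_non_elliptical": len(rejected),
        "visibility_counts": class_counts,
        "foreground_background_ratio": fg / bg if bg else np.inf,
        "n_spots": len(spots),
        "n_spots_unassigned": unassigned,
        "resolved": {
            "max_z_range": seg.max_z_range,
            "min_mip": seg.min_mip,
            "spot_scale_um": float(spot_scale),
            "spot_intensity_threshold": threshold,
        },
        "config": config.to_dict(),
        "labels": seg.labels,
    }
    return PipelineResult(records=records_df, spot_table=spot_df, summary=summary)


def _record_stub(s, proj) -> SpheroidRecord:
    """Record for a spheroid without a valid 3D fit (non-elliptical/failed)."""
    ys, xs = np.nonzero(s.mask)
    px = proj.pixel_size_xy
    return SpheroidRecord(
        label=s.label,
        center_x_um=float(xs.mean()) * px,
        center_y_um=float(ys.mean()) * px,
        center_z_um=np.nan,
        axis_a_um=np.nan,
        axis_b_um=np.nan,
        axis_c_um=np.nan,
        orientation_rad=np.nan,
        area_um2=s.area_um2,
        volume_um3=np.nan,
        mean_intensity=s.mean_mip_intensity,
        circularity=s.circularity if s.circularity is not None else np.nan,
        roundness_class=s.roundness_class or "non-elliptical",
        attenuation_class="n/a",
        analyzable_depth_um=np.nan,
        n_spots_raw=0,
        n_spots_corrected=np.nan,
        touches_border=s.touches_border,
    )
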