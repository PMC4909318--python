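"""Stack I/O (TIFF / OME-TIFF), run configuration, and result export."""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from xml.etree import ElementTree

import numpy as np
import tifffile
import yaml

from .stack import ImageStack

__all__ = ["RunConfig", "read_stack", "write_stacks", "write_label_tiff"]


@dataclass
class RunConfig:
    """All pipeline parameters with their documented defaults.

    Auto-resolved parameters (``"auto"``) are derived from the image at
    run time: ``max_z_range`` from the range-filtered height-view
    histogram, ``min_mip`` from the MIP background mean, ``spot_scale``
    from the LoG scale optimisation of the marker MIP.
    """

    cell_diameter: float = 12.0  # um
    r_range: float = 3.0  # um, range-filter radius
    max_z_range: float | str = "auto"  # z-slice units
    min_mip: float | str = "auto"  # intensity
    min_radius: float = 24.0  # um, small-spheroid fallback for the z-axis
    attenuation_percentage: float = 50.0  # P_min, percent
    max_spot_radius: float = 8.0  # um
    spot_scale: float | str = "auto"  # um, LoG sigma
    min_circularity: float = 0.7
    stable_channel: str = "stable"
    marker_channel: str = "marker"
    spot_mode: str = "3d"  # "3d" | "2.5d"
    baseline_2d: bool = False
    flip_z: bool = False
    include_border: bool = True  # keep border-touching spheroids (flagged)
    pixel_size_xy: float | None = None  # um, metadata override
    z_step: float | None = None  # um, metadata override
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def _parse_ome_calibration(ome_xml: str) -> tuple[float | None, float | None, list[str]]:
    """Extract (pixel_size_xy, z_step, channel names) from OME-XML."""
    try:
        root = ElementTree.fromstring(ome_xml)
    except ElementTree.ParseError:
        return None, None, []
    ns = {"ome": root.tag.split("}")[0].strip("{")} if "}" in root.tag else {}
    px = root.find(".//ome:Pixels", ns) if ns else root.find(".//Pixels")
    if px is None:
        return None, None, []
    size_x = px.get("PhysicalSizeX")
    size_z = px.get("PhysicalSizeZ")
    chans = px.findall("ome:Channel", ns) if ns else px.findall("Channel")
    names = [c.get("Name") or f"channel-{i}" for i, c in enumerate(chans)]
    return (
        float(size_x) if size_x else None,
        float(size_z) if size_z else None,
        names,
    )


def read_stack(
    path,
    channel_map: dict[str, int] | None = None,
    pixel_size_xy: float | None = None,
    z_step: float | None = None,
    flip_z: bool = False,
) -> dict[str, ImageStack]:
    """Read a (multi-channel) z-stack from TIFF / OME-TIFF.

    ``channel_map`` maps channel names to indices; without it, OME
    channel names (or ``channel-0`` ...) are used.  Calibration comes
    from OME metadata unless overridden; missing calibration without an
    override is an error.  Arrays are interpreted as (Z, Y, X) or, for
    4D data, by the OME axes string (default ZCYX).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        axes = None
        meta_px = meta_dz = None
        ome_names: list[str] = []
        if tf.ome_metadata:
            meta_px, meta_dz, ome_names = _parse_ome_calibration(tf.ome_metadata)
            axes = tf.series[0].axes if tf.series else None

    px = pixel_size_xy or meta_px
    dz = z_step or meta_dz
    if px is None or dz is None:
        raise ValueError(
            f"{path}: missing pixel-size/z-step calibration; pass explicit overrides"
        )

    if data.ndim == 3:
        per_channel = {0: data}
    elif data.ndim == 4:
        if axes and axes.upper().startswith("CZ"):
            data = np.moveaxis(data, 0, 1)  # CZYX -> ZCYX
        per_channel = {c: data[:, c] for c in range(data.shape[1])}
    else:
        raise ValueError(f"{path}: expected a 3D or 4D TIFF, got {data.ndim}D")

    if next(iter(per_channel.values())).shape[0] < 2:
        raise ValueError(f"{path}: stack must contain at least 2 z-slices")

    if channel_map is None:
        names = ome_names or [f"channel-{c}" for c in per_channel]
        channel_map = {name: c for c, name in enumerate(names)}

    stacks: dict[str, ImageStack] = {}
    for name, idx in channel_map.items():
        if idx not in per_channel:
            raise KeyError(f"{path}: channel {name!r} (index {idx}) not found")
        vox = per_channel[idx]
        stack = ImageStack(vox, px, dz, channel_name=name)
        stacks[name] = stack.flipped_z() if flip_z else stack
    return stacks


def write_stacks(path, stacks: dict[str, ImageStack]) -> None:
    """Write channels as one OME-TIFF (axes ZCYX, calibration embedded)."""
    names = list(stacks)
    first = stacks[names[0]]
    data = np.stack([stacks[n].voxels for n in names], axis=1)
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "ZCYX",
            "PhysicalSizeX": first.pixel_size_xy,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": first.pixel_size_xy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": first.z_step,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": names},
        },
    )


def write_label_tiff(path, labels: np.ndarray) -> None:
    """Export a label image as a 16-bit single-plane TIFF."""
    lab = np.asarray(labels)
    if lab.max() > np.iinfo(np.uint16).max:
        warnings.warn("label values exceed 16-bit range; clipping", stacklevel=2)
    tifffile.imwrite(path, lab.astype(np.uint16), photometric="minisblack")


def write_summary_json(path, summary: dict) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
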