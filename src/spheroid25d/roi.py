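"""Minimal ImageJ ROI codec (.roi files and RoiManager .zip archives).

Supports the subset needed for 2D spheroid ground truth: polygon,
freehand, traced, oval and rectangle ROIs, with stroke colors — manual
annotations conventionally encode a class per contour color.  The binary
layout follows ImageJ's RoiDecoder (big-endian, 64-byte header, "Iout"
magic, int16 coordinates relative to the bounding box).
"""

from __future__ import annotations

import struct
import zipfile
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon

__all__ = ["ImageJRoi", "read_roi", "write_roi", "read_roi_zip", "write_roi_zip"]

_MAGIC = b"Iout"
_TYPE_POLYGON = 0
_TYPE_RECT = 1
_TYPE_OVAL = 2
_TYPE_FREEHAND = 7
_TYPE_TRACED = 8
_SUPPORTED = {_TYPE_POLYGON, _TYPE_RECT, _TYPE_OVAL, _TYPE_FREEHAND, _TYPE_TRACED}


@dataclass
class ImageJRoi:
    """A decoded ImageJ ROI."""

    roi_type: int
    top: int
    left: int
    bottom: int
    right: int
    # absolute (x, y) vertices for polygon-like types, empty for rect/oval
    coords: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))
    stroke_rgb: tuple[int, int, int] | None = None
    name: str = ""

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Rasterise the ROI interior onto a frame of the given shape."""
        mask = np.zeros(shape, dtype=bool)
        if self.roi_type in (_TYPE_POLYGON, _TYPE_FREEHAND, _TYPE_TRACED):
            if len(self.coords) < 3:
                return mask
            rr, cc = draw_polygon(
                self.coords[:, 1], self.coords[:, 0], shape=shape
            )
            mask[rr, cc] = True
        elif self.roi_type == _TYPE_RECT:
            mask[
                max(self.top, 0) : min(self.bottom, shape[0]),
                max(self.left, 0) : min(self.right, shape[1]),
            ] = True
        elif self.roi_type == _TYPE_OVAL:
            cy = (self.top + self.bottom - 1) / 2.0
            cx = (self.left + self.right - 1) / 2.0
            ry = (self.bottom - self.top) / 2.0
            rx = (self.right - self.left) / 2.0
            rr, cc = draw_ellipse(cy, cx, ry, rx, shape=shape)
            mask[rr, cc] = True
        return mask


def read_roi(data: bytes, name: str = "") -> ImageJRoi:
    """Decode a single .roi byte blob."""
    if data[:4] != _MAGIC:
        raise ValueError("not an ImageJ ROI (missing 'Iout' magic)")
    roi_type = data[6]
    if roi_type not in _SUPPORTED:
        raise ValueError(f"unsupported ROI type {roi_type}")
    top, left, bottom, right, n = struct.unpack(">hhhhH", data[8:18])
    stroke = struct.unpack(">I", data[40:44])[0]
    stroke_rgb = None
    if stroke:
        stroke_rgb = ((stroke >> 16) & 0xFF, (stroke >> 8) & 0xFF, stroke & 0xFF)
    coords = np.empty((0, 2), int)
    if n and roi_type in (_TYPE_POLYGON, _TYPE_FREEHAND, _TYPE_TRACED):
        base = 64
        xs = np.frombuffer(data, dtype=">h", count=n, offset=base) + left
        ys = np.frombuffer(data, dtype=">h", count=n, offset=base + 2 * n) + top
        coords = np.stack([xs, ys], axis=1).astype(int)
    return ImageJRoi(
        roi_type=roi_type,
        top=top,
        left=left,
        bottom=bottom,
        right=right,
        coords=coords,
        stroke_rgb=stroke_rgb,
        name=name,
    )


def write_roi(roi: ImageJRoi) -> bytes:
    """Encode an ROI to the ImageJ binary format (version 226 header)."""
    if roi.roi_type in (_TYPE_POLYGON, _TYPE_FREEHAND, _TYPE_TRACED):
        xs = roi.coords[:, 0]
        ys = roi.coords[:, 1]
        left, top = int(xs.min()), int(ys.min())
        right, bottom = int(xs.max()) + 1, int(ys.max()) + 1
        n = len(roi.coords)
    else:
        left, top, right, bottom = roi.left, roi.top, roi.right, roi.bottom
        n = 0
    header = bytearray(64)
    header[0:4] = _MAGIC
    struct.pack_into(">h", header, 4, 226)  # version
    header[6] = roi.roi_type
    struct.pack_into(">hhhhH", header, 8, top, left, bottom, right, n)
    if roi.stroke_rgb is not None:
        r, g, b = roi.stroke_rgb
        struct.pack_into(">I", header, 40, (0xFF << 24) | (r << 16) | (g << 8) | b)
    out = bytes(header)
    if n:
        out += np.asarray(roi.coords[:, 0] - left, dtype=">h").tobytes()
        out += np.asarray(roi.coords[:, 1] - top, dtype=">h").tobytes()
    return out


def read_roi_zip(path) -> list[ImageJRoi]:
    """Read all ROIs from a RoiManager .zip archive."""
    rois: list[ImageJRoi] = []
    with zipfile.ZipFile(path) as zf:
        for info in sorted(zf.infolist(), key=lambda i: i.filename):
            if info.filename.lower().endswith(".roi"):
                rois.append(read_roi(zf.read(info), name=info.filename[:-4]))
    return rois


def write_roi_zip(path, rois: list[ImageJRoi]) -> None:
    """Write ROIs to a RoiManager-compatible .zip archive."""
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for i, roi in enumerate(rois):
            name = roi.name or f"roi-{i + 1:04d}"
            zf.writestr(f"{name}.roi", write_roi(roi))
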