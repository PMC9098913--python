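"""Image, ROI and table I/O.

TIFF stacks are single-channel, one file per channel; calibration (pixel
size in um, frame interval in s) comes from ImageJ-style TIFF metadata or a
JSON sidecar (``<stack>.json``), with explicit arguments taking precedence
(a conflict is logged, not fatal).  ImageJ ``.roi`` files are supported for
rectangle ROIs only — the only ROI type the analyses use.
"""

from __future__ import annotations

import json
import logging
import struct
from pathlib import Path

import numpy as np
import tifffile

from .core import ImageSeries

logger = logging.getLogger("slbkit")

__all__ = ["load_image_series", "save_image_series", "read_imagej_roi",
           "write_imagej_roi"]


def load_image_series(path: str | Path, pixel_size: float | None = None,
                      frame_interval: float | None = None,
                      channel_label: str = "") -> ImageSeries:
    """Read a single-channel TIFF stack with physical calibration.

    Calibration resolution order: explicit arguments > JSON sidecar >
    ImageJ TIFF metadata.  Missing calibration with no override is an error.
    Multi-channel (4D) stacks are rejected with instructions to supply
    per-channel files.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray()
        meta_ps, meta_fi = _tiff_calibration(tif)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(
            f"{path}: stack has shape {frames.shape}; multi-channel "
            "interleaved TIFFs are unsupported — split into one "
            "single-channel stack per file")
    side = _sidecar(path)
    ps = _resolve("pixel_size", pixel_size, side.get("pixel_size_um"),
                  meta_ps, path)
    fi = _resolve("frame_interval", frame_interval,
                  side.get("frame_interval_s"), meta_fi, path)
    return ImageSeries(frames.astype(float), ps, fi,
                       channel_label or side.get("channel_label", ""))


def _resolve(name, explicit, sidecar_val, meta_val, path):
    vals = [v for v in (explicit, sidecar_val, meta_val) if v is not None]
    if not vals:
        raise ValueError(
            f"{path}: no {name} in TIFF metadata or sidecar; "
            f"pass {name}= explicitly")
    if explicit is not None:
        for other in (sidecar_val, meta_val):
            if other is not None and not np.isclose(explicit, other):
                logger.warning("%s: explicit %s=%g overrides file value %g",
                               path, name, explicit, other)
        return float(explicit)
    return float(vals[0])


def _sidecar(path: Path) -> dict:
    sc = path.with_suffix(path.suffix + ".json")
    if sc.exists():
        return json.loads(sc.read_text())
    return {}


def _tiff_calibration(tif) -> tuple[float | None, float | None]:
    ps = fi = None
    meta = tif.imagej_metadata or {}
    if "finterval" in meta:
        fi = float(meta["finterval"])
    try:
        page = tif.pages[0]
        xres = page.tags.get("XResolution")
        if xres is not None:
            num, den = xres.value
            if num:
                ps = den / num  # pixels per unit -> unit per pixel
    except (AttributeError, IndexError, ZeroDivisionError):
        pass
    return ps, fi


def save_image_series(series: ImageSeries, path: str | Path) -> None:
    """Write a stack as ImageJ-compatible TIFF plus a JSON sidecar."""
    path = Path(path)
    res = 1.0 / series.pixel_size
    tifffile.imwrite(
        path, series.frames.astype(np.float32), imagej=True,
        resolution=(res, res),
        metadata={"finterval": series.frame_interval, "unit": "um",
                  "axes": "TYX"})
    sidecar = {"pixel_size_um": series.pixel_size,
               "frame_interval_s": series.frame_interval,
               "channel_label": series.channel_label}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2))


# ---------------------------------------------------------------------------
# ImageJ .roi rectangles

_ROI_TYPE_NAMES = {0: "polygon", 1: "rectangle", 2: "oval", 3: "line",
                   4: "freeline", 5: "polyline", 6: "no-roi", 7: "freehand",
                   8: "traced", 9: "angle", 10: "point"}


def read_imagej_roi(path: str | Path) -> tuple[int, int, int, int]:
    """Rectangle from an ImageJ ``.roi`` file as (x, y, w, h) in pixels.

    Coordinates are 0-based with origin top-left, half-open on right and
    bottom.  Non-rectangle ROI types raise with the type name.
    """
    data = Path(path).read_bytes()
    if len(data) < 64 or data[:4] != b"Iout":
        raise ValueError(f"{path}: not an ImageJ ROI file")
    roi_type = data[6]
    if roi_type != 1:
        name = _ROI_TYPE_NAMES.get(roi_type, f"type {roi_type}")
        raise ValueError(
            f"{path}: unsupported ROI type '{name}'; only rectangles "
            "are supported")
    top, left, bottom, right = struct.unpack(">4h", data[8:16])
    if right <= left or bottom <= top:
        raise ValueError(f"{path}: degenerate rectangle")
    return left, top, right - left, bottom - top


def write_imagej_roi(roi: tuple[int, int, int, int],
                     path: str | Path) -> None:
    """Write a rectangle (x, y, w, h) as a minimal ImageJ ``.roi`` file."""
    x, y, w, h = (int(v) for v in roi)
    if w <= 0 or h <= 0:
        raise ValueError("ROI width and height must be positive")
    header = bytearray(64)
    header[0:4] = b"Iout"
    struct.pack_into(">h", header, 4, 227)  # version
    header[6] = 1  # rectangle
    struct.pack_into(">4h", header, 8, y, x, y + h, x + w)
    Path(path).write_bytes(bytes(header))
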