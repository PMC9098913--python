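"""Reading and writing single-particle track files.

Two dialects are supported:

* CSV with columns ``track_id, frame, t_s, x_um, y_um`` (positions already in
  micrometres; ``t_s`` is redundant with ``frame * frame_interval`` and is
  checked on read when present),
* TrackMate-dialect XML (the ``<Tracks><particle><detection .../>`` layout of
  TrackMate's "export tracks" action), with ``frameInterval`` and
  ``spaceUnits`` attributes on the root element.

Both preserve frame gaps.
"""

from __future__ import annotations

import csv
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .core import Track

__all__ = ["read_tracks", "write_tracks"]


def read_tracks(path: str | Path, dialect: str | None = None,
                frame_interval: float | None = None,
                pixel_size: float | None = None) -> list[Track]:
    """Read tracks from a CSV or TrackMate-dialect XML file.

    Parameters
    ----------
    dialect : {"csv", "trackmate_xml"}, optional
        Inferred from the file suffix when omitted.
    frame_interval : float, optional
        Overrides (or supplies, if the file lacks it) the frame interval in
        seconds.  Missing calibration with no override is an error.
    pixel_size : float, optional
        If given for XML files whose ``spaceUnits`` is ``"pixel"``, positions
        are converted to micrometres.  CSV positions are always micrometres.
    """
    path = Path(path)
    if dialect is None:
        dialect = "trackmate_xml" if path.suffix.lower() == ".xml" else "csv"
    if dialect == "csv":
        return _read_csv(path, frame_interval)
    if dialect == "trackmate_xml":
        return _read_trackmate_xml(path, frame_interval, pixel_size)
    raise ValueError(f"unknown track dialect: {dialect!r}")


def _read_csv(path: Path, frame_interval: float | None) -> list[Track]:
    rows: dict[int, list[tuple[int, float, float]]] = {}
    interval = frame_interval
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        fields = set(reader.fieldnames or [])
        missing = {"track_id", "frame", "x_um", "y_um"} - fields
        if missing:
            raise ValueError(f"track CSV missing columns: {sorted(missing)}")
        has_t = "t_s" in fields
        for row in reader:
            tid = int(row["track_id"])
            frame = int(row["frame"])
            rows.setdefault(tid, []).append(
                (frame, float(row["x_um"]), float(row["y_um"])))
            if interval is None and has_t and frame > 0:
                t = float(row["t_s"])
                if t > 0:
                    interval = t / frame
    if interval is None:
        raise ValueError(
            "frame interval not derivable from file; pass frame_interval=")
    tracks = []
    for tid in sorted(rows):
        data = sorted(rows[tid])
        frames = np.array([d[0] for d in data])
        tracks.append(Track(track_id=tid, frames=frames,
                            x=np.array([d[1] for d in data]),
                            y=np.array([d[2] for d in data]),
                            frame_interval=interval))
    return tracks


def _read_trackmate_xml(path: Path, frame_interval: float | None,
                        pixel_size: float | None) -> list[Track]:
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise ValueError(f"malformed track XML {path}: {exc}") from exc
    root = tree.getroot()
    if root.tag != "Tracks":
        raise ValueError(
            f"unexpected root element <{root.tag}>; expected <Tracks>")
    interval = frame_interval
    if interval is None:
        attr = root.get("frameInterval")
        if attr is None:
            raise ValueError(
                "XML lacks frameInterval; pass frame_interval= explicitly")
        interval = float(attr)
    scale = 1.0
    units = root.get("spaceUnits", "µm")
    if units in ("pixel", "px"):
        if pixel_size is None:
            raise ValueError(
                "XML positions are in pixels; pass pixel_size= (um/px)")
        scale = pixel_size
    tracks = []
    for tid, particle in enumerate(root.findall("particle")):
        frames, xs, ys = [], [], []
        for det in particle.findall("detection"):
            try:
                frames.append(int(float(det.get("t"))))
                xs.append(float(det.get("x")) * scale)
                ys.append(float(det.get("y")) * scale)
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"bad detection in particle {tid} of {path}: "
                    f"{ET.tostring(det, encoding='unicode').strip()}"
                ) from exc
        order = np.argsort(frames)
        tracks.append(Track(track_id=tid,
                            frames=np.asarray(frames)[order],
                            x=np.asarray(xs)[order],
                            y=np.asarray(ys)[order],
                            frame_interval=interval))
    return tracks


def write_tracks(tracks: list[Track], path: str | Path,
                 dialect: str | None = None) -> None:
    """Write tracks as CSV or TrackMate-dialect XML (by suffix or dialect)."""
    path = Path(path)
    if dialect is None:
        dialect = "trackmate_xml" if path.suffix.lower() == ".xml" else "csv"
    if dialect == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["track_id", "frame", "t_s", "x_um", "y_um"])
            for t in tracks:
                for f, x, y in zip(t.frames, t.x, t.y):
                    w.writerow([t.track_id, int(f),
                                repr(float(f * t.frame_interval)),
                                repr(float(x)), repr(float(y))])
    elif dialect == "trackmate_xml":
        interval = tracks[0].frame_interval if tracks else 0.0
        root = ET.Element("Tracks", nTracks=str(len(tracks)),
                          spaceUnits="µm", timeUnits="s",
                          frameInterval=repr(float(interval)))
        for t in tracks:
            particle = ET.SubElement(root, "particle", nSpots=str(len(t)))
            for f, x, y in zip(t.frames, t.x, t.y):
                ET.SubElement(particle, "detection", t=str(int(f)),
                              x=repr(float(x)), y=repr(float(y)), z="0.0")
        ET.ElementTree(root).write(path, encoding="utf-8",
                                   xml_declaration=True)
    else:
        raise ValueError(f"unknown track dialect: {dialect!r}")
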