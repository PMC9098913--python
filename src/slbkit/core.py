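"""Shared containers for image series, particle tracks, fit results and events.

Conventions used throughout the package:

* images are ``(T, H, W)`` arrays of nonnegative float intensities, row-major
  with origin top-left; physical x = column * pixel_size, y = row * pixel_size
* track coordinates are physical micrometres; frames are 0-based integers and
  times are ``frame * frame_interval`` seconds
* rectangle ROIs are ``(x, y, w, h)`` in pixels, half-open on right/bottom
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageSeries:
    """Time-ordered stack of 2D intensity frames with physical calibration.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Nonnegative intensities.
    pixel_size : float
        Pixel edge length in micrometres.
    frame_interval : float
        Time between frame starts in seconds.
    channel_label : str
        Free-text channel name.
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.frames.shape[0] < 1:
            raise ValueError("image series needs at least one frame")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def with_frames(self, frames: np.ndarray) -> "ImageSeries":
        """New series with the same calibration but different pixel data."""
        return ImageSeries(frames, self.pixel_size, self.frame_interval,
                           self.channel_label)


@dataclass
class Track:
    """One particle's time-ordered positions in physical units.

    ``frames`` must be strictly increasing; gaps (missing frames) are allowed
    and preserved — downstream windowed statistics skip windows spanning gaps.
    """

    track_id: int
    frames: np.ndarray  # integer frame indices, strictly increasing
    x: np.ndarray  # um
    y: np.ndarray  # um
    frame_interval: float  # s

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.frames)
        if not (len(self.x) == len(self.y) == n):
            raise ValueError("frames, x, y must have equal length")
        if n >= 2 and not np.all(np.diff(self.frames) > 0):
            raise ValueError("frames must be strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("track coordinates must be finite")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return self.frames * self.frame_interval

    @property
    def duration(self) -> float:
        """Track duration in seconds (first to last observed frame)."""
        return float((self.frames[-1] - self.frames[0]) * self.frame_interval)

    @property
    def net_displacement(self) -> float:
        """Straight-line distance between first and last position (um)."""
        return float(np.hypot(self.x[-1] - self.x[0], self.y[-1] - self.y[0]))


@dataclass
class ConfinementEvent:
    """A contiguous confined segment of a track."""

    track_id: int
    start_time: float  # s
    end_time: float  # s
    centroid: tuple[float, float]  # um
    mean_p: float  # um^-2

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


@dataclass
class PackingProfile:
    """Per-window packing coefficients of one track.

    ``p_values[k]`` belongs to the window starting at ``times[k]`` and covering
    ``window_n`` displacements (``window_n + 1`` positions).  Windows that
    contain frame gaps are NaN; degenerate (collinear) windows are +inf.
    """

    track_id: int
    times: np.ndarray  # s, start time of each window
    p_values: np.ndarray  # um^-2
    window_n: int
    frame_interval: float  # s


@dataclass
class RecoveryProfile:
    """1D fluorescence profile around a bleach window over recovery time.

    ``intensities[k, i]`` is the normalized fluorescence at ``positions[i]``
    and ``times[k]`` (seconds since bleach).  Intensities are expressed as a
    fraction of the pre-bleach steady state, so full recovery approaches 1.
    """

    positions: np.ndarray  # um along the projection axis
    times: np.ndarray  # s since bleach
    intensities: np.ndarray  # (n_times, n_positions)
    bleach_window: tuple[float, float]  # um
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if self.intensities.shape != (len(self.times), len(self.positions)):
            raise ValueError("intensities must be (n_times, n_positions)")


@dataclass
class FretTrace:
    """Donor/acceptor intensity time traces around an acceptor-bleach step."""

    times: np.ndarray  # s
    donor: np.ndarray
    acceptor: np.ndarray
    bleach_frame: int
    background: tuple[float, float] = (0.0, 0.0)  # (donor, acceptor)
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if not (len(self.times) == len(self.donor) == len(self.acceptor)):
            raise ValueError("times, donor, acceptor must have equal length")
        if not 0 <= self.bleach_frame < len(self.times):
            raise ValueError("bleach_frame out of range")


@dataclass
class BindingSeries:
    """Concentration/response pairs from a titration (QCM-D, MST, ...)."""

    concentrations: np.ndarray  # uM, strictly increasing
    responses: np.ndarray  # instrument units
    response_sd: np.ndarray | None = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if len(self.concentrations) != len(self.responses):
            raise ValueError("concentrations and responses must match")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be nonnegative")
        if not np.all(np.diff(self.concentrations) > 0):
            raise ValueError("concentrations must be strictly increasing")
        if self.response_sd is not None:
            self.response_sd = np.asarray(self.response_sd, dtype=float)


@dataclass
class FitResult:
    """Named parameters with uncertainties and goodness-of-fit of a model fit.

    ``success`` is False for flagged (degenerate / non-converged) fits; the
    reason is in ``message``.  Flagged results are returned, never raised, so
    batch pipelines can record them.
    """

    params: dict[str, float]
    stderr: dict[str, float]
    r_squared: float
    model_name: str
    success: bool = True
    message: str = ""

    def __getitem__(self, name: str) -> float:
        return self.params[name]


def rect_slices(roi: tuple[int, int, int, int]) -> tuple[slice, slice]:
    """(x, y, w, h) pixel rectangle -> (row, col) slices, half-open."""
    x, y, w, h = (int(v) for v in roi)
    if w <= 0 or h <= 0:
        raise ValueError("ROI width and height must be positive")
    return slice(y, y + h), slice(x, x + w)


def default_center_roi(shape: tuple[int, int],
                       fraction: float = 0.8) -> tuple[int, int, int, int]:
    """Centered rectangle covering ``fraction`` of each image dimension."""
    h, w = shape
    rw, rh = max(1, int(round(w * fraction))), max(1, int(round(h * fraction)))
    return ((w - rw) // 2, (h - rh) // 2, rw, rh)
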