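"""Seeded generators of synthetic tracks, movies, profiles, traces and curves.

These emulate the statistical structure of the supported-lipid-bilayer TIRF
experiments the package analyses, with known ground truth:

* two-state single-molecule tracks that switch between free diffusion and
  transient confinement on filament-bound anchor sites,
* membrane dwell times observed at several time-lapse intervals with
  per-frame photobleaching,
* dual-colour movies of treadmilling filament networks with a co-localizing
  (or decoupled) second channel,
* 1D FRAP recovery profiles from a diffusion + exchange model,
* donor/acceptor FRET traces with an acceptor-bleach step, and
* Hill-model binding curves.

Every generator is fully reproducible from its integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import BindingSeries, FretTrace, ImageSeries, RecoveryProfile, Track

__all__ = [
    "DiskZone", "SegmentZone", "TwoStateSimConfig", "GroundTruthEvent",
    "DwellSimConfig", "FilamentMovieConfig", "random_filament_zones",
    "simulate_two_state_tracks", "simulate_dwell_tracks",
    "simulate_filament_movie", "simulate_frap_profiles",
    "simulate_fret_trace", "simulate_binding_curve",
]


# ---------------------------------------------------------------------------
# trap-zone geometry


@dataclass(frozen=True)
class DiskZone:
    """Stationary disk inside which a free molecule may bind."""

    cx: float  # um
    cy: float  # um
    radius: float  # um

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (x - self.cx) ** 2 + (y - self.cy) ** 2 <= self.radius ** 2


@dataclass(frozen=True)
class SegmentZone:
    """Line segment with a capture radius (a filament with binding sites)."""

    x0: float
    y0: float
    x1: float
    y1: float
    radius: float  # um

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        dx, dy = self.x1 - self.x0, self.y1 - self.y0
        seg_len2 = dx * dx + dy * dy
        if seg_len2 == 0:
            d2 = (x - self.x0) ** 2 + (y - self.y0) ** 2
        else:
            t = np.clip(((x - self.x0) * dx + (y - self.y0) * dy) / seg_len2,
                        0.0, 1.0)
            d2 = (x - (self.x0 + t * dx)) ** 2 + (y - (self.y0 + t * dy)) ** 2
        return d2 <= self.radius ** 2


def random_filament_zones(fov_size: float, n_segments: int = 30,
                          capture_radius: float = 0.025,
                          rng: np.random.Generator | None = None,
                          seed: int | None = None) -> list[SegmentZone]:
    """Random filament network spanning the field of view.

    Segments are chords of the FOV with random orientation; the default count
    and 25 nm capture radius give an area coverage of roughly 10-15% in a
    10 um FOV, a realistic filament-network density.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    zones = []
    for _ in range(n_segments):
        cx, cy = rng.uniform(0, fov_size, 2)
        theta = rng.uniform(0, np.pi)
        half = fov_size  # chord long enough to span; clipped to FOV below
        x0, y0 = cx - half * np.cos(theta), cy - half * np.sin(theta)
        x1, y1 = cx + half * np.cos(theta), cy + half * np.sin(theta)
        x0, y0, x1, y1 = _clip_segment(x0, y0, x1, y1, fov_size)
        zones.append(SegmentZone(x0, y0, x1, y1, capture_radius))
    return zones


def _clip_segment(x0, y0, x1, y1, size):
    """Liang-Barsky clip of a segment to the [0, size]^2 box."""
    dx, dy = x1 - x0, y1 - y0
    t0, t1 = 0.0, 1.0
    for p, q in ((-dx, x0), (dx, size - x0), (-dy, y0), (dy, size - y0)):
        if p == 0:
            if q < 0:
                return x0, y0, x0, y0
            continue
        r = q / p
        if p < 0:
            t0 = max(t0, r)
        else:
            t1 = min(t1, r)
    if t0 > t1:
        return x0, y0, x0, y0
    return x0 + t0 * dx, y0 + t0 * dy, x0 + t1 * dx, y0 + t1 * dy


# ---------------------------------------------------------------------------
# two-state track simulation


@dataclass
class TwoStateSimConfig:
    """Parameters of the two-state (free / trapped) diffusion simulation.

    Defaults follow the validation conditions of the confinement detector:
    50 molecules per field of view, free diffusion 0.2 um^2/s, trapped
    diffusion 0.002 um^2/s, binding 0.3 /s while over a trap zone, unbinding
    1.5 /s, crossing probability 1.  Localization noise defaults to 20 nm sd
    per axis (typical TIRF single-molecule precision).
    """

    n_molecules: int = 50
    fov_size: float = 10.0  # um
    d_free: float = 0.2  # um^2/s
    d_trapped: float = 0.002  # um^2/s
    k_bind: float = 0.3  # 1/s, while over a trap zone
    k_unbind: float = 1.5  # 1/s
    trap_zones: list | None = None  # None -> random filament network
    trap_radius: float = 0.025  # um, confinement disk around the anchor
    crossing_probability: float = 1.0
    frame_interval: float = 0.051  # s
    n_frames: int = 600
    localization_noise_sd: float = 0.020  # um, per axis
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("d_free", "d_trapped", "k_bind", "k_unbind",
                     "frame_interval", "fov_size", "localization_noise_sd",
                     "trap_radius"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and nonnegative")
        if self.fov_size <= 0:
            raise ValueError("fov_size must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.d_trapped > self.d_free:
            raise ValueError("d_trapped must not exceed d_free")
        if not 0 <= self.crossing_probability <= 1:
            raise ValueError("crossing_probability must be in [0, 1]")
        if self.n_molecules < 0 or self.n_frames < 2:
            raise ValueError("n_molecules >= 0 and n_frames >= 2 required")


@dataclass(frozen=True)
class GroundTruthEvent:
    """One simulated trapped interval (the detector's ground truth)."""

    track_id: int
    start_time: float  # s
    end_time: float  # s
    zone_id: int

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


def _reflect_interval(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect coordinates into [lo, hi] (billiard boundary)."""
    span = hi - lo
    v = np.mod(v - lo, 2 * span)
    v = np.where(v > span, 2 * span - v, v)
    return v + lo


def simulate_two_state_tracks(
        config: TwoStateSimConfig,
) -> tuple[list[Track], list[GroundTruthEvent]]:
    """Simulate single-molecule tracks switching between free and trapped
    diffusion, together with the ground-truth trapped intervals.

    Free molecules take Gaussian steps with per-axis sd ``sqrt(2 d_free dt)``
    and reflect at the FOV boundary.  While a free molecule lies within a trap
    zone, it binds within a frame with probability ``1 - exp(-k_bind dt)``.
    A trapped molecule diffuses with ``d_trapped`` reflected inside a disk of
    ``trap_radius`` around its binding position (the anchor), and unbinds with
    probability ``1 - exp(-k_unbind dt)``.  State transitions are evaluated
    once per frame; sub-frame switching is ignored.  Observed positions carry
    independent Gaussian localization noise.

    Returns
    -------
    tracks : list of Track
        Observed (noisy) positions, one track per molecule, full movie length.
    events : list of GroundTruthEvent
        Every trapped interval, with times that are multiples of the frame
        interval.
    """
    rng = np.random.default_rng(config.seed)
    zones = config.trap_zones
    if zones is None:
        zones = random_filament_zones(config.fov_size, rng=rng)
    m, T, dt = config.n_molecules, config.n_frames, config.frame_interval
    if m == 0:
        return [], []

    p_bind = 1.0 - math.exp(-config.k_bind * dt)
    p_unbind = 1.0 - math.exp(-config.k_unbind * dt)
    sd_free = math.sqrt(2.0 * config.d_free * dt)
    sd_trap = math.sqrt(2.0 * config.d_trapped * dt)

    x = rng.uniform(0, config.fov_size, m)
    y = rng.uniform(0, config.fov_size, m)
    trapped = np.zeros(m, dtype=bool)
    anchor_x = np.zeros(m)
    anchor_y = np.zeros(m)
    zone_of = np.full(m, -1, dtype=int)
    event_start = np.full(m, -1, dtype=int)

    xs = np.empty((T, m))
    ys = np.empty((T, m))
    xs[0], ys[0] = x, y
    events: list[GroundTruthEvent] = []
    # state at frame 0 is free for everyone; record occupancy per frame
    for t in range(1, T):
        # --- move
        free = ~trapped
        if free.any():
            nx = x[free] + rng.normal(0.0, sd_free, free.sum())
            ny = y[free] + rng.normal(0.0, sd_free, free.sum())
            nx = _reflect_interval(nx, 0.0, config.fov_size)
            ny = _reflect_interval(ny, 0.0, config.fov_size)
            if config.crossing_probability < 1.0:
                # molecules stepping from outside into a zone are blocked
                # (step rejected) with probability 1 - crossing_probability
                was_in = _in_any_zone(zones, x[free], y[free])[0]
                now_in = _in_any_zone(zones, nx, ny)[0]
                entering = ~was_in & now_in
                blocked = entering & (rng.random(entering.size)
                                      > config.crossing_probability)
                nx[blocked] = x[free][blocked]
                ny[blocked] = y[free][blocked]
            x[free], y[free] = nx, ny
        if trapped.any():
            tx = x[trapped] + rng.normal(0.0, sd_trap, trapped.sum())
            ty = y[trapped] + rng.normal(0.0, sd_trap, trapped.sum())
            # reflect radially into the anchor disk
            dx = tx - anchor_x[trapped]
            dy = ty - anchor_y[trapped]
            r = np.hypot(dx, dy)
            out = r > config.trap_radius
            if out.any():
                # fold the radius back inside (r -> 2R - r, clipped at 0)
                r_new = np.clip(2 * config.trap_radius - r[out], 0.0,
                                config.trap_radius)
                scale = np.where(r[out] > 0, r_new / r[out], 0.0)
                dx[out] *= scale
                dy[out] *= scale
            x[trapped] = anchor_x[trapped] + dx
            y[trapped] = anchor_y[trapped] + dy

        # --- state transitions (evaluated once per frame; a molecule makes
        # at most one transition per frame, so a just-unbound molecule
        # cannot rebind until the next frame)
        was_trapped = trapped.copy()
        if trapped.any():
            unbind = trapped & (rng.random(m) < p_unbind)
            for i in np.nonzero(unbind)[0]:
                events.append(GroundTruthEvent(
                    track_id=int(i),
                    start_time=event_start[i] * dt,
                    end_time=t * dt,
                    zone_id=int(zone_of[i])))
            trapped[unbind] = False
            zone_of[unbind] = -1
            event_start[unbind] = -1
        free = ~trapped & ~was_trapped
        if free.any() and config.k_bind > 0 and zones:
            in_zone, which = _in_any_zone(zones, x[free], y[free])
            bind = in_zone & (rng.random(free.sum()) < p_bind)
            idx = np.nonzero(free)[0][bind]
            trapped[idx] = True
            anchor_x[idx] = x[idx]
            anchor_y[idx] = y[idx]
            zone_of[idx] = which[bind]
            event_start[idx] = t

        xs[t], ys[t] = x, y

    # close events still open at the end of the movie
    for i in np.nonzero(trapped)[0]:
        events.append(GroundTruthEvent(
            track_id=int(i), start_time=event_start[i] * dt,
            end_time=T * dt, zone_id=int(zone_of[i])))

    noise = config.localization_noise_sd
    obs_x = xs + rng.normal(0.0, noise, xs.shape) if noise > 0 else xs
    obs_y = ys + rng.normal(0.0, noise, ys.shape) if noise > 0 else ys

    frames = np.arange(T)
    tracks = [Track(track_id=i, frames=frames.copy(), x=obs_x[:, i].copy(),
                    y=obs_y[:, i].copy(), frame_interval=dt)
              for i in range(m)]
    events.sort(key=lambda e: (e.track_id, e.start_time))
    return tracks, events


def _in_any_zone(zones, x, y):
    """(inside_any, index_of_first_containing_zone) for each point."""
    inside = np.zeros(x.shape, dtype=bool)
    which = np.full(x.shape, -1, dtype=int)
    for j, z in enumerate(zones):
        hit = z.contains(x, y) & ~inside
        inside |= hit
        which[hit] = j
    return inside, which


# ---------------------------------------------------------------------------
# dwell-time simulation (time-lapse imaging with photobleaching)


@dataclass
class DwellSimConfig:
    """Membrane dwell times observed at several time-lapse intervals.

    Single molecules unbind with rate ``k_off_true`` and bleach with rate
    ``bleach_rate`` but only while the laser is on, i.e. during the
    ``integration_time`` of each exposure.  Observed dwell = frames observed
    times the lapse interval.
    """

    k_off_true: float = 0.05  # 1/s
    bleach_rate: float = 4.0  # 1/s during integration
    integration_time: float = 0.05  # s
    lapse_intervals: tuple[float, ...] = (0.125, 0.25, 0.5, 1.0, 2.0)  # s
    n_molecules_per_interval: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.lapse_intervals) == 0:
            raise ValueError("lapse_intervals must not be empty")
        for name in ("k_off_true", "bleach_rate", "integration_time"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if any(tl < self.integration_time for tl in self.lapse_intervals):
            raise ValueError(
                "lapse_intervals must be >= integration_time")

    @property
    def bleach_number(self) -> float:
        """k_b * tau_int, the per-frame bleaching exponent."""
        return self.bleach_rate * self.integration_time


def simulate_dwell_tracks(config: DwellSimConfig) -> dict[float, np.ndarray]:
    """Observed dwell durations per lapse interval.

    Per frame, a molecule disappears with probability
    ``1 - exp(-(k_off * tau_tl + k_b * tau_int))`` — unbinding acts over the
    whole lapse interval, bleaching only during the integration time.  The
    number of frames a molecule is observed is geometric; the observed dwell
    duration is ``frames * tau_tl``.
    """
    rng = np.random.default_rng(config.seed)
    out: dict[float, np.ndarray] = {}
    for tau_tl in config.lapse_intervals:
        n = config.n_molecules_per_interval
        if n == 0:
            out[tau_tl] = np.empty(0)
            continue
        x = config.k_off_true * tau_tl + config.bleach_number
        q = 1.0 - math.exp(-x)
        if q <= 0:
            raise ValueError(
                "zero disappearance probability: molecules never vanish")
        frames = rng.geometric(q, size=n)
        out[tau_tl] = frames * tau_tl
    return out


# ---------------------------------------------------------------------------
# dual-colour treadmilling filament movies


@dataclass
class NoiseModel:
    """Shot + read noise: Poisson at ``photons_per_unit`` then Gaussian sd."""

    photons_per_unit: float = 0.0  # 0 disables shot noise
    read_noise_sd: float = 0.0  # intensity units
    baseline: float = 0.0


@dataclass
class FilamentMovieConfig:
    """Dual-colour movie of a treadmilling filament network.

    Channel 1 renders the filament line density (front advances, rear
    retracts at ``treadmill_speed`` — the filament translates at constant
    length) convolved with a Gaussian PSF.  Channel 2 mixes
    ``channel2_coupling`` of the channel-1 density with a homogeneous
    background carrying the remaining weight, mimicking a second protein that
    is partly filament-bound and partly membrane-bound everywhere.
    """

    n_filaments: int = 25
    treadmill_speed: float = 0.04  # um/s
    filament_length: float = 3.0  # um
    psf_sigma: float = 0.12  # um
    channel2_coupling: float = 1.0  # in [0, 1]
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    fov_size: float = 10.0  # um
    pixel_size: float = 0.1  # um
    frame_interval: float = 2.0  # s
    n_frames: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.channel2_coupling <= 1:
            raise ValueError("channel2_coupling must be in [0, 1]")
        if self.treadmill_speed < 0:
            raise ValueError("treadmill_speed must be nonnegative")
        if self.n_frames < 2:
            raise ValueError("a movie needs at least 2 frames")


def simulate_filament_movie(
        config: FilamentMovieConfig) -> tuple[ImageSeries, ImageSeries]:
    """Render the two channels of a treadmilling filament movie."""
    rng = np.random.default_rng(config.seed)
    npx = int(round(config.fov_size / config.pixel_size))
    # filament = anchored line: position of its center drifts along its axis
    cx = rng.uniform(0, config.fov_size, config.n_filaments)
    cy = rng.uniform(0, config.fov_size, config.n_filaments)
    theta = rng.uniform(0, np.pi, config.n_filaments)
    direction = rng.choice([-1.0, 1.0], config.n_filaments)
    ux, uy = np.cos(theta) * direction, np.sin(theta) * direction

    # sample points along each filament for rasterization
    n_samples = max(8, int(config.filament_length / config.pixel_size) * 2)
    s = np.linspace(-0.5, 0.5, n_samples) * config.filament_length

    ch1 = np.empty((config.n_frames, npx, npx))
    ch2 = np.empty_like(ch1)
    sigma_px = config.psf_sigma / config.pixel_size
    for t in range(config.n_frames):
        shift = config.treadmill_speed * t * config.frame_interval
        px = (cx[:, None] + (s[None, :] + shift) * ux[:, None]).ravel()
        py = (cy[:, None] + (s[None, :] + shift) * uy[:, None]).ravel()
        px = np.mod(px, config.fov_size)  # wrap: fronts re-enter the FOV
        py = np.mod(py, config.fov_size)
        img, _, _ = np.histogram2d(py, px, bins=npx,
                                   range=[[0, config.fov_size],
                                          [0, config.fov_size]])
        density = gaussian_filter(img, sigma_px, mode="wrap")
        c = config.channel2_coupling
        uniform_level = density.mean()
        ch1[t] = density
        ch2[t] = c * density + (1.0 - c) * uniform_level

    nm = config.noise_model
    for ch in (ch1, ch2):
        if nm.photons_per_unit > 0:
            ch[:] = rng.poisson(ch * nm.photons_per_unit) / nm.photons_per_unit
        if nm.read_noise_sd > 0:
            ch += rng.normal(0.0, nm.read_noise_sd, ch.shape)
        ch += nm.baseline
        np.clip(ch, 0.0, None, out=ch)

    a = ImageSeries(ch1, config.pixel_size, config.frame_interval, "channel1")
    b = ImageSeries(ch2, config.pixel_size, config.frame_interval, "channel2")
    return a, b


# ---------------------------------------------------------------------------
# FRAP recovery profiles (forward model of the frapfret module)


def simulate_frap_profiles(d_coeff: float, k_off: float,
                           domain_length: float,
                           bleach_window: tuple[float, float],
                           bleach_depth: float,
                           times: np.ndarray,
                           noise_sd: float = 0.0,
                           n_positions: int = 200,
                           seed: int = 0) -> RecoveryProfile:
    """Forward-integrate the 1D diffusion + exchange recovery model.

    The model is ``df/dt = D d2f/dx2 + k_off (1 - f)`` with reflecting
    (zero-flux) boundaries at 0 and ``domain_length``, starting from a
    step-bleached profile (``1 - bleach_depth`` inside the window, 1 outside).
    Gaussian noise of sd ``noise_sd`` (as a fraction of the pre-bleach level)
    is added to the sampled profiles.  Ground-truth parameters are recorded
    in ``RecoveryProfile.truth``.
    """
    from .frapfret import integrate_recovery  # shared forward model

    if domain_length <= 0:
        raise ValueError("domain_length must be positive")
    if not 0 <= bleach_depth <= 1:
        raise ValueError("bleach_depth must be in [0, 1]")
    x0, x1 = bleach_window
    if not (0 <= x0 < x1 <= domain_length):
        raise ValueError("bleach_window must lie inside the domain")
    times = np.asarray(times, dtype=float)
    positions = (np.arange(n_positions) + 0.5) * (domain_length / n_positions)
    f0 = np.where((positions >= x0) & (positions <= x1),
                  1.0 - bleach_depth, 1.0)
    profiles = integrate_recovery(f0, positions, times, d_coeff, k_off)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        profiles = profiles + rng.normal(0.0, noise_sd, profiles.shape)
    return RecoveryProfile(
        positions=positions, times=times, intensities=profiles,
        bleach_window=(x0, x1),
        truth={"d_coeff": d_coeff, "k_off": k_off,
               "bleach_depth": bleach_depth})


# ---------------------------------------------------------------------------
# FRET traces and binding curves


def simulate_fret_trace(e_true: float, donor_pre_level: float,
                        bleach_frame: int, n_frames: int,
                        noise_sd: float = 0.0, seed: int = 0,
                        acceptor_pre_level: float | None = None,
                        frame_interval: float = 1.0) -> FretTrace:
    """Donor/acceptor traces around an acceptor photobleach step.

    The donor jumps at ``bleach_frame`` from its quenched pre level to
    ``pre / (1 - e_true)`` (dequenching by the FRET efficiency ``e_true``);
    the acceptor drops to near background.
    """
    if not 0 <= e_true < 1:
        raise ValueError("e_true must be in [0, 1)")
    if not 0 <= bleach_frame < n_frames:
        raise ValueError("bleach_frame out of range")
    rng = np.random.default_rng(seed)
    times = np.arange(n_frames) * frame_interval
    donor = np.full(n_frames, donor_pre_level, dtype=float)
    donor[bleach_frame:] = donor_pre_level / (1.0 - e_true)
    if acceptor_pre_level is None:
        acceptor_pre_level = donor_pre_level
    acceptor = np.full(n_frames, acceptor_pre_level, dtype=float)
    acceptor[bleach_frame:] = 0.02 * acceptor_pre_level
    if noise_sd > 0:
        donor = donor + rng.normal(0.0, noise_sd * donor_pre_level, n_frames)
        acceptor = acceptor + rng.normal(0.0, noise_sd * acceptor_pre_level,
                                         n_frames)
    return FretTrace(times=times, donor=donor, acceptor=acceptor,
                     bleach_frame=bleach_frame,
                     truth={"e_true": e_true})


def simulate_binding_curve(model: str, params: dict,
                           concentrations: np.ndarray,
                           noise_sd: float = 0.0,
                           seed: int = 0) -> BindingSeries:
    """Evaluate a named Hill form at given concentrations, plus noise.

    ``model`` is ``"hill_qcmd"`` (params S, E, n, k — frequency-shift
    convention, E may be below S) or ``"hill_mst"`` (params U, B, EC50, n).
    ``noise_sd`` is absolute, in response units.
    """
    from .binding_geom import hill_qcmd, hill_mst  # shared model curves

    c = np.asarray(concentrations, dtype=float)
    if model == "hill_qcmd":
        y = hill_qcmd(c, params["S"], params["E"], params["n"], params["k"])
    elif model == "hill_mst":
        y = hill_mst(c, params["U"], params["B"], params["EC50"], params["n"])
    else:
        raise ValueError(f"unknown binding model: {model!r}")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, y.shape)
    return BindingSeries(concentrations=c, responses=y,
                         truth=dict(params, model=model))
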