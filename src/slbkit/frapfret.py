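"""FRET efficiency estimation and FRAP recovery-profile decomposition.

Acceptor-photobleaching FRET: destroying the acceptor dye removes the energy
transfer channel, so the donor dequenches.  With background-subtracted donor
intensities ``I_pre`` (before) and ``I_post`` (after the bleach), the
efficiency is ``E = (I_post - I_pre) / I_post``; equivalently
``gain / (gain + I_pre)`` with ``gain = I_post - I_pre``.

FRAP decomposition: on a supported bilayer, fluorescence recovers into a
bleached stripe both by exchange with the (unbleached, effectively infinite)
solution reservoir and by lateral diffusion along the membrane.  Pure
exchange lifts the whole bleached profile uniformly — its shape does not
change — whereas diffusion rounds the edges of the stripe.  Fitting the full
space-time recovery profile to the reaction-diffusion model

    df/dt = D d2f/dx2 + k_off (1 - f)

(f = fluorescence as a fraction of the pre-bleach steady state, reflecting
boundaries at the profile ends) therefore separates the diffusion
coefficient D from the membrane exchange rate k_off.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_banded
from scipy.optimize import least_squares

from .core import FitResult, FretTrace, ImageSeries, RecoveryProfile, \
    rect_slices

__all__ = [
    "fret_efficiency_ap", "fret_efficiency_spectral",
    "extract_recovery_profile", "fit_frap", "integrate_recovery",
]


# ---------------------------------------------------------------------------
# FRET


def fret_efficiency_ap(trace: FretTrace, pre_frames: int | None = None,
                       post_frames: int | None = None,
                       literal: bool = False,
                       require_bleach: bool = True) -> float:
    """FRET efficiency (%) from an acceptor-photobleaching donor trace.

    ``I_pre`` is the mean background-subtracted donor intensity over the
    ``pre_frames`` frames before the bleach, ``I_post`` over the
    ``post_frames`` frames after it.  The default uses all available frames
    on each side.  The estimator is ``E = 100 (I_post - I_pre) / I_post``,
    clipped to [0, 100] (the unclipped value is returned when negative only
    via ValueError diagnostics — noise can push E slightly below 0).

    ``literal=True`` instead evaluates ``100 I_post / (I_post + I_pre)``,
    the printed-formula reading whose no-transfer baseline is 50%; it exists
    for reproduction studies only.

    Raises
    ------
    ValueError
        If the acceptor does not drop by at least 50% at the bleach frame
        (no acceptor photobleach happened) or if ``I_post <= 0``.
    """
    b = trace.bleach_frame
    if b < 1 or b >= len(trace.times):
        raise ValueError("bleach_frame leaves no pre- or post-bleach frames")
    pre_lo = 0 if pre_frames is None else max(0, b - pre_frames)
    post_hi = len(trace.times) if post_frames is None else \
        min(len(trace.times), b + post_frames)
    donor = trace.donor - trace.background[0]
    acceptor = trace.acceptor - trace.background[1]
    if require_bleach:
        acc_pre = float(np.mean(acceptor[pre_lo:b]))
        acc_post = float(np.mean(acceptor[b:post_hi]))
        if not (acc_pre > 0 and acc_post < 0.5 * acc_pre):
            raise ValueError(
                f"acceptor dropped only {acc_pre - acc_post:.3g} of "
                f"{acc_pre:.3g}: no acceptor photobleach detected")
    i_pre = float(np.mean(donor[pre_lo:b]))
    i_post = float(np.mean(donor[b:post_hi]))
    if i_post <= 0:
        raise ValueError("post-bleach donor intensity must be positive")
    if literal:
        return 100.0 * i_post / (i_post + i_pre)
    e = 100.0 * (i_post - i_pre) / i_post
    return float(np.clip(e, 0.0, 100.0))


def fret_efficiency_spectral(spectrum, donor_peak_nm: float = 565.0,
                             acceptor_peak_nm: float = 670.0) -> float:
    """Proximity-ratio FRET efficiency (%) from an emission spectrum.

    ``E = 100 Fa / (Fd + Fa)`` with ``Fa`` the acceptor emission at the
    acceptor peak wavelength and ``Fd`` the donor emission at the donor peak
    (nearest sampled wavelength).  The spectrum must be background-corrected.
    """
    arr = np.asarray(spectrum, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        arr = np.column_stack(spectrum)
    wl, inten = arr[:, 0], arr[:, 1]
    for peak in (donor_peak_nm, acceptor_peak_nm):
        if peak < wl.min() - 5 or peak > wl.max() + 5:
            raise ValueError(
                f"spectrum does not cover {peak} nm "
                f"(range {wl.min()}-{wl.max()} nm)")
    fd = float(inten[np.argmin(np.abs(wl - donor_peak_nm))])
    fa = float(inten[np.argmin(np.abs(wl - acceptor_peak_nm))])
    if fd + fa <= 0:
        raise ValueError("zero total emission at the two peaks")
    return 100.0 * fa / (fd + fa)


# ---------------------------------------------------------------------------
# FRAP forward model


def integrate_recovery(f0: np.ndarray, positions: np.ndarray,
                       times: np.ndarray, d_coeff: float,
                       k_off: float) -> np.ndarray:
    """Integrate ``df/dt = D f_xx + k_off (1 - f)`` with zero-flux ends.

    Crank-Nicolson in time on the given spatial grid, starting from ``f0`` at
    ``times[0]``; returns the profile at each requested time (first row is
    ``f0``).  The Neumann boundary uses the conservative flux form, so with
    ``k_off = 0`` the spatial mean is conserved to machine precision.
    """
    f0 = np.asarray(f0, dtype=float)
    positions = np.asarray(positions, dtype=float)
    times = np.asarray(times, dtype=float)
    n = len(positions)
    dx = positions[1] - positions[0]
    if not np.allclose(np.diff(positions), dx):
        raise ValueError("positions must be uniformly spaced")
    out = np.empty((len(times), n))
    out[0] = f0

    # substep so that both processes are well resolved
    max_dt = np.inf
    if k_off > 0:
        max_dt = min(max_dt, 0.05 / k_off)
    if d_coeff > 0:
        max_dt = min(max_dt, 0.5 * dx * dx / d_coeff)

    lap_mid = np.full(n, -2.0)
    lap_mid[0] = lap_mid[-1] = -1.0  # conservative zero-flux boundary
    f = f0.copy()
    for k in range(1, len(times)):
        span = times[k] - times[k - 1]
        if span < 0:
            raise ValueError("times must be nondecreasing")
        n_sub = max(1, int(np.ceil(span / max_dt))) if np.isfinite(max_dt) \
            else 1
        dt = span / n_sub if n_sub else 0.0
        if dt > 0:
            r = d_coeff * dt / (dx * dx)
            # (I - (dt/2) A) f_new = (I + (dt/2) A) f + dt k_off 1
            # with A = D L - k_off I
            ab = np.zeros((3, n))
            ab[0, 1:] = -0.5 * r
            ab[1] = 1.0 - 0.5 * (r * lap_mid - dt * k_off)
            ab[2, :-1] = -0.5 * r
            for _ in range(n_sub):
                rhs = f + 0.5 * (r * _lap(f, lap_mid) - dt * k_off * f) \
                    + dt * k_off
                f = solve_banded((1, 1), ab, rhs)
        out[k] = f
    return out


def _lap(f: np.ndarray, mid: np.ndarray) -> np.ndarray:
    """Dimensionless conservative Laplacian (dx^2 factored into r)."""
    out = mid * f
    out[:-1] += f[1:]
    out[1:] += f[:-1]
    return out


# ---------------------------------------------------------------------------
# profile extraction


def extract_recovery_profile(series: ImageSeries,
                             bleach_roi: tuple[int, int, int, int],
                             axis: str = "x",
                             n_prebleach: int = 1,
                             mirror: bool = False,
                             bleach_correct_roi=None) -> RecoveryProfile:
    """Project a bleached movie to a 1D recovery profile.

    The intensity is mean-projected across the non-selected axis (restricted
    to the bleach ROI's extent on that axis) and normalized to the mean
    pre-bleach profile, so the output is a fraction of the pre-bleach steady
    state.  Times are mid-exposure, measured from the first post-bleach
    frame.

    Parameters
    ----------
    axis : {"x", "y"}
        Profile axis: "x" profiles along columns, "y" along rows.
    n_prebleach : int
        Number of leading frames acquired before the bleach.
    mirror : bool
        Average the profile with its reflection about the bleach-window
        center (for asymmetric bleaching).
    bleach_correct_roi : rectangle, optional
        Reference region far from the bleach; each post-bleach profile is
        divided by that region's intensity ratio to its pre-bleach mean
        (global acquisition-bleaching correction).
    """
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    T, H, W = series.frames.shape
    x, y, w, h = bleach_roi
    if x < 0 or y < 0 or x + w > W or y + h > H:
        raise ValueError("bleach ROI outside the image")
    if not 1 <= n_prebleach < T:
        raise ValueError("need pre- and post-bleach frames")

    rs, cs = rect_slices(bleach_roi)
    if axis == "x":
        prof = series.frames[:, rs, :].mean(axis=1)  # (T, W)
        coords = np.arange(W) * series.pixel_size
        win = (x * series.pixel_size, (x + w) * series.pixel_size)
    else:
        prof = series.frames[:, :, cs].mean(axis=2)  # (T, H)
        coords = np.arange(H) * series.pixel_size
        win = (y * series.pixel_size, (y + h) * series.pixel_size)

    pre = prof[:n_prebleach].mean(axis=0)
    if np.any(pre <= 0):
        raise ValueError("pre-bleach profile has non-positive values")
    norm = prof[n_prebleach:] / pre

    if bleach_correct_roi is not None:
        rr, rc = rect_slices(bleach_correct_roi)
        ref = series.frames[:, rr, rc].mean(axis=(1, 2))
        ref_pre = ref[:n_prebleach].mean()
        ratio = ref[n_prebleach:] / ref_pre
        norm = norm / ratio[:, None]

    if mirror:
        center = 0.5 * (win[0] + win[1])
        mirrored = np.empty_like(norm)
        for i in range(norm.shape[0]):
            mirrored[i] = np.interp(2 * center - coords, coords, norm[i],
                                    left=norm[i, -1], right=norm[i, 0])
        norm = 0.5 * (norm + mirrored)

    # mid-exposure times since the first post-bleach frame start
    times = (np.arange(T - n_prebleach) + 0.5) * series.frame_interval
    return RecoveryProfile(positions=coords, times=times, intensities=norm,
                           bleach_window=win)


# ---------------------------------------------------------------------------
# FRAP fitting


def recovery_modes(f0: np.ndarray, length: float, times: np.ndarray,
                   d_coeff: float, k_off: float) -> np.ndarray:
    """Exact eigenfunction solution of the recovery model on a uniform grid.

    Writes ``f = 1 - g`` with ``g' = D g_xx - k_off g``; the zero-flux
    eigenfunctions are cosines, so ``g`` is evolved exactly by damping each
    cosine mode (DCT) of the initial deficit with
    ``exp(-(D (pi m / L)^2 + k_off) t)``.  Samples are treated as midpoints
    of a domain of total ``length``.  Used by the fitter as a fast exact
    integrator — an independent numerical route from the finite-difference
    forward model.
    """
    from scipy.fft import dct, idct

    g0 = 1.0 - np.asarray(f0, dtype=float)
    n = len(g0)
    coeff = dct(g0, type=2, norm="ortho")
    m = np.arange(n)
    lam = d_coeff * (np.pi * m / length) ** 2 + k_off
    out = np.empty((len(times), n))
    for i, t in enumerate(times):
        out[i] = 1.0 - idct(coeff * np.exp(-lam * t), type=2, norm="ortho")
    return out


def fit_frap(profile: RecoveryProfile) -> FitResult:
    """Fit the diffusion + exchange model to a recovery profile.

    Least squares over all (x, t) samples of the model evolved from the
    first post-bleach profile (the initial condition) with reflecting
    boundaries at the profile ends, using the exact cosine-mode integrator.

    Returns D_coeff (um^2/s) and k_off (1/s) with stderr from the Jacobian;
    parameters at their lower bound (0) are flagged in the message.
    """
    f = profile.intensities
    if f.shape[0] < 5:
        raise ValueError("need at least 5 post-bleach time points")
    x0, x1 = profile.bleach_window
    dx = profile.positions[1] - profile.positions[0]
    if dx > (x1 - x0) / 4:
        raise ValueError("spatial sampling coarser than 1/4 bleach window")
    depth0 = 1.0 - f[0].min()
    if depth0 < 0.05:
        raise ValueError("profile is not bleached: nothing to fit")

    data = f[1:]
    times = profile.times - profile.times[0]  # model time from the IC frame
    length = dx * len(profile.positions)

    def resid(p):
        model = recovery_modes(f[0], length, times[1:], p[0], p[1])
        return (model - data).ravel()

    # initial guesses: k from the mean recovery rate of the bleached deficit
    mean_def = np.clip(1.0 - data.mean(axis=1), 1e-9, None)
    k0 = max(1e-3, -np.polyfit(times[1:], np.log(mean_def), 1)[0])
    d0 = 0.05 * (x1 - x0) ** 2 / max(times[-1], 1e-9)
    res = least_squares(resid, x0=[d0, k0], bounds=([0, 0],
                                                    [np.inf, np.inf]),
                        xtol=1e-12, ftol=1e-12)
    d, k = res.x

    # stderr from the Gauss-Newton approximation of the covariance
    m = res.fun.size
    dof = max(1, m - 2)
    s2 = float(res.fun @ res.fun) / dof
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        err = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        err = np.full(2, np.nan)
    # resolution floor on D: a diffusion length below half a sample spacing
    # over the whole observation window is unresolvable (and fitting the
    # measured, noisy initial profile biases D upward by about this much),
    # so it enters the quoted uncertainty as a systematic term
    d_res = dx * dx / (8.0 * max(times[-1], 1e-12))
    err[0] = float(np.hypot(err[0], d_res))
    ss_tot = float(((data - data.mean()) ** 2).sum())
    r2 = 1.0 - float(res.fun @ res.fun) / ss_tot if ss_tot > 0 else 1.0
    msgs = []
    if not res.success:
        msgs.append(f"optimizer: {res.message}")
    if d <= 1.96 * err[0]:
        msgs.append("D indistinguishable from 0 (pure exchange regime)")
    if k <= 1.96 * err[1]:
        msgs.append("k_off indistinguishable from 0 (pure diffusion "
                    "regime)")
    return FitResult(
        params={"D_coeff": float(d), "k_off": float(k)},
        stderr={"D_coeff": float(err[0]), "k_off": float(err[1])},
        r_squared=r2, model_name="frap_diffusion_exchange",
        success=bool(res.success), message="; ".join(msgs))
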