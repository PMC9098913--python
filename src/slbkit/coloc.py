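"""Image-level colocalization and correlation statistics for dual-colour
time-lapse movies of membrane-bound filament networks.

The static overlap of two channels is measured by the Pearson correlation
coefficient (PCC) over an ROI.  Co-movement of growing filament ends
("co-treadmilling") is measured on differential movies — consecutive-frame
subtractions that isolate the growing ends — by the PCC between the two
differential channels (PCC_diff).  Reorganization dynamics of the filament
pattern are quantified by the temporal autocorrelation of one channel and its
monoexponential decay rate.  Pixel-wise intensity-slope regression estimates
the relative binding capacity of one structure for the other channel's
protein, and the recruitment-rate fit extracts the rate at which
colocalization builds up after protein addition.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

import lmfit

from .core import FitResult, ImageSeries, default_center_roi, rect_slices

__all__ = [
    "pearson_cc", "normalize_series", "differential_series", "pcc_diff",
    "temporal_autocorrelation", "fit_exp_decay", "intensity_slope",
    "recruitment_rate", "CorrelationCurve", "align_translation",
]


class CorrelationCurve:
    """Correlation values against time lag (seconds)."""

    def __init__(self, lags: np.ndarray, values: np.ndarray):
        self.lags = np.asarray(lags, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if len(self.lags) != len(self.values):
            raise ValueError("lags and values must have equal length")


def _roi_pixels(img: np.ndarray, roi) -> np.ndarray:
    if roi is None:
        return np.asarray(img, dtype=float).ravel()
    rs, cs = rect_slices(roi)
    out = np.asarray(img, dtype=float)[rs, cs]
    if out.size == 0:
        raise ValueError("ROI lies outside the image")
    return out.ravel()


def pearson_cc(img_a: np.ndarray, img_b: np.ndarray, roi=None) -> float:
    """Pearson correlation of two channels' pixel intensities over an ROI.

    Raises
    ------
    ValueError
        If either channel has zero variance inside the ROI (the correlation
        is undefined).
    """
    a, b = np.asarray(img_a, dtype=float), np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must have the same shape")
    av, bv = _roi_pixels(a, roi), _roi_pixels(b, roi)
    if av.size < 2:
        raise ValueError("need at least 2 pixels")
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        raise ValueError("zero variance in a channel: correlation undefined")
    r = np.corrcoef(av, bv)[0, 1]
    return float(np.clip(r, -1.0, 1.0))


def normalize_series(series: ImageSeries,
                     method: str = "frame_mean") -> ImageSeries:
    """Intensity correction across frames.

    ``frame_mean`` divides each frame by its spatial mean, removing global
    photobleaching decay; ``none`` returns the input unchanged.
    """
    if method == "none":
        return series
    if method != "frame_mean":
        raise ValueError(f"unknown normalization method: {method!r}")
    means = series.frames.mean(axis=(1, 2))
    if np.any(means == 0):
        raise ValueError("frame with zero mean cannot be normalized")
    return series.with_frames(series.frames / means[:, None, None])


def differential_series(series: ImageSeries,
                        lag_frames: int = 1) -> ImageSeries:
    """Consecutive-frame subtraction isolating growth fronts.

    Output frame ``i`` is ``max(0, frame[i + lag] - frame[i])``; only
    intensity gains remain, which for a treadmilling filament are its growing
    ends.  The output has ``T - lag`` frames.
    """
    if lag_frames < 1:
        raise ValueError("lag_frames must be >= 1")
    if lag_frames >= series.n_frames:
        raise ValueError("lag_frames must be smaller than the frame count")
    diff = series.frames[lag_frames:] - series.frames[:-lag_frames]
    return series.with_frames(np.clip(diff, 0.0, None))


def pcc_diff(series_a: ImageSeries, series_b: ImageSeries,
             lag_frames: int = 1, roi=None,
             normalize: str = "none") -> tuple[np.ndarray, float]:
    """Per-frame PCC between the differential movies of two channels.

    Frames whose differential image has zero variance in either channel are
    skipped (returned as NaN); the mean is over the valid frames.

    Returns
    -------
    values : ndarray
        Per-differential-frame Pearson coefficients (NaN where skipped).
    mean : float
        Mean over valid frames.
    """
    if series_a.frames.shape != series_b.frames.shape:
        raise ValueError("series must have identical shapes and frame counts")
    if series_a.frame_interval != series_b.frame_interval:
        raise ValueError("series must have identical frame intervals")
    a = differential_series(normalize_series(series_a, normalize), lag_frames)
    b = differential_series(normalize_series(series_b, normalize), lag_frames)
    vals = np.empty(a.n_frames)
    for i in range(a.n_frames):
        try:
            vals[i] = pearson_cc(a.frames[i], b.frames[i], roi)
        except ValueError:
            vals[i] = np.nan
    valid = vals[np.isfinite(vals)]
    if valid.size == 0:
        raise ValueError("no differential frame had nonzero variance")
    return vals, float(valid.mean())


def temporal_autocorrelation(series: ImageSeries, roi=None,
                             averaged: bool = False) -> CorrelationCurve:
    """PCC of the first frame against later frames at increasing lag.

    At lag 0 the value is exactly 1.  With ``averaged=True`` the curve value
    at lag ``k`` is instead the mean PCC over all frame pairs ``(i, i + k)``,
    a noise-robust variant.
    """
    if series.n_frames < 3:
        raise ValueError("need at least 3 frames")
    if roi is None:
        roi = default_center_roi(series.shape)
    T = series.n_frames
    lags = np.arange(T) * series.frame_interval
    vals = np.empty(T)
    vals[0] = 1.0
    for k in range(1, T):
        if averaged:
            rs = [pearson_cc(series.frames[i], series.frames[i + k], roi)
                  for i in range(T - k)]
            vals[k] = float(np.mean(rs))
        else:
            vals[k] = pearson_cc(series.frames[0], series.frames[k], roi)
    return CorrelationCurve(lags, vals)


def _fit_result_from_lmfit(res, model_name: str) -> FitResult:
    params = {k: float(v.value) for k, v in res.params.items()}
    stderr = {k: float(v.stderr) if v.stderr is not None else float("nan")
              for k, v in res.params.items()}
    ss_res = float(np.sum(res.residual ** 2))
    data = res.residual + res.best_fit
    ss_tot = float(np.sum((data - data.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return FitResult(params=params, stderr=stderr, r_squared=r2,
                     model_name=model_name, success=bool(res.success),
                     message=res.message if not res.success else "")


def fit_exp_decay(curve: CorrelationCurve) -> FitResult:
    """Fit ``y = a * exp(-b t) + k`` to a correlation curve.

    Returns a flagged (``success=False``) result when the decay rate is not
    identifiable (e.g. a constant curve) instead of raising.
    """
    if len(curve.lags) < 4:
        raise ValueError("need at least 4 points to fit the decay")
    t, y = curve.lags, curve.values
    if np.ptp(y) < 1e-12:
        return FitResult(params={"a": 0.0, "b": float("nan"),
                                 "k": float(y.mean()),
                                 "half_time": float("nan")},
                         stderr={}, r_squared=float("nan"),
                         model_name="monoexp_decay", success=False,
                         message="constant curve: decay rate unidentifiable")

    def model(t, a, b, k):
        return a * np.exp(-b * t) + k

    gmodel = lmfit.Model(model)
    # initial decay rate from the lag at which the curve falls halfway
    drop = y[0] - y[-1]
    half_idx = np.argmax(y <= y[0] - drop / 2) or 1
    b0 = np.log(2) / max(t[half_idx], t[1])
    pars = gmodel.make_params(a=drop, b=b0, k=y[-1])
    pars["b"].min = 0.0
    res = gmodel.fit(y, pars, t=t)
    out = _fit_result_from_lmfit(res, "monoexp_decay")
    b = out.params.get("b", float("nan"))
    out.params["half_time"] = float(np.log(2) / b) if b and b > 0 \
        else float("nan")
    if not np.isfinite(b) or b <= 0:
        out.success = False
        out.message = out.message or "non-positive decay rate"
    return out


def intensity_slope(img_a: np.ndarray, img_b: np.ndarray, roi=None,
                    background: str = "percentile_1") -> FitResult:
    """Ordinary least squares of channel-b on channel-a pixel intensities.

    The slope estimates the relative binding capacity of the structure in
    channel a for the protein in channel b.  ``background="percentile_1"``
    subtracts each channel's 1st percentile (camera offset) first.
    """
    a = _roi_pixels(np.asarray(img_a, dtype=float), roi)
    b = _roi_pixels(np.asarray(img_b, dtype=float), roi)
    if a.size < 10:
        raise ValueError("need at least 10 pixels")
    if background == "percentile_1":
        a = a - np.percentile(a, 1)
        b = b - np.percentile(b, 1)
    elif background != "none":
        raise ValueError(f"unknown background mode: {background!r}")
    if np.ptp(a) == 0:
        raise ValueError("zero variance in channel a")
    lr = stats.linregress(a, b)
    return FitResult(
        params={"k": float(lr.slope), "d": float(lr.intercept)},
        stderr={"k": float(lr.stderr), "d": float(lr.intercept_stderr)},
        r_squared=float(lr.rvalue ** 2), model_name="linear_slope")


def recruitment_rate(pcc_vs_time) -> FitResult:
    """Fit ``y = a (1 - exp(-b t)) + c`` to a PCC-versus-time series.

    ``b`` (1/s) is the recruitment rate of the diffusing protein towards the
    filament structure after addition at t = 0.
    """
    arr = np.asarray(pcc_vs_time, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        arr = np.column_stack(pcc_vs_time)
    t, y = arr[:, 0], arr[:, 1]
    if len(t) < 4:
        raise ValueError("need at least 4 time points")
    if np.ptp(y) < 1e-12:
        return FitResult(params={"a": 0.0, "b": float("nan"),
                                 "c": float(y.mean())},
                         stderr={}, r_squared=float("nan"),
                         model_name="power_law_exponential", success=False,
                         message="flat series: rate unidentifiable")

    def model(t, a, b, c):
        return a * (1.0 - np.exp(-b * t)) + c

    gmodel = lmfit.Model(model)
    rise = y[-1] - y[0]
    t_half = t[np.argmax(y >= y[0] + rise / 2)] or t[1]
    pars = gmodel.make_params(a=rise, b=np.log(2) / max(t_half, t[1] or 1e-9),
                              c=y[0])
    pars["b"].min = 0.0
    res = gmodel.fit(y, pars, t=t)
    return _fit_result_from_lmfit(res, "power_law_exponential")


def align_translation(ref: np.ndarray, moving: np.ndarray) -> tuple[int, int]:
    """Integer-pixel translation (dy, dx) maximizing cross-correlation.

    Convenience for channel registration of pre-acquired stacks; rotation and
    scale are assumed corrected upstream.
    """
    ref = np.asarray(ref, dtype=float)
    moving = np.asarray(moving, dtype=float)
    f = np.fft.rfft2(ref - ref.mean())
    g = np.fft.rfft2(moving - moving.mean())
    cc = np.fft.irfft2(f * np.conj(g), s=ref.shape)
    dy, dx = np.unravel_index(np.argmax(cc), cc.shape)
    if dy > ref.shape[0] // 2:
        dy -= ref.shape[0]
    if dx > ref.shape[1] // 2:
        dx -= ref.shape[1]
    return int(dy), int(dx)
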