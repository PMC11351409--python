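"""Slow-phase gain and oscillation-frequency estimation for one recording.

The VOR gain of a sinusoidal test is the magnitude of the slope of a
zero-intercept least-squares regression of eye velocity on head velocity,
fitted over slow-phase samples only.  Saccades are removed in two stages:

1. candidate detection — samples where the eye-velocity derivative exceeds
   an acceleration threshold are flagged, padded on both sides, and merged
   into saccade intervals;
2. robust refinement — the regression is refitted iteratively, rejecting
   samples whose residual exceeds ``residual_k`` scaled median absolute
   deviations, until the retained set is stable.

Gains are computed separately for rightward and leftward head motion, since
suppression may be direction-specific; near-zero head velocities inside a
deadband are excluded as ill-conditioned.  The actual oscillation frequency
(the examiner rarely hits the metronome target exactly) is taken from the
head-velocity spectral peak with local refinement, cross-checked against the
zero-crossing count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .errors import (
    DegenerateInputError,
    DesaccadeError,
    EstimationError,
    QvorError,
)
from .io_vhit import Paradigm, VelocityTrace
from .preprocess import (
    AnalysisWindow,
    DEFAULT_WINDOW,
    drop_nonfinite,
    select_analysis_window,
    trim_recording,
)

__all__ = [
    "DesaccadeParams",
    "Direction",
    "ParadigmResult",
    "detect_saccades",
    "split_by_direction",
    "estimate_slope_gain",
    "estimate_frequency",
    "analyze_paradigm",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DesaccadeParams:
    """Tunables of the two-stage saccade-removal procedure.

    accel_threshold : deg/s^2
        Eye-velocity derivative above which a sample is a saccade candidate.
    pad_ms : ms
        Exclusion padding applied on both sides of each detection.
    residual_k : unitless
        Robust rejection multiplier on the scaled MAD of fit residuals.
    residual_floor_dps : deg/s
        Lower bound on the rejection threshold, so that near-noiseless
        traces do not reject everything.
    """

    accel_threshold: float = 4000.0
    pad_ms: float = 40.0
    residual_k: float = 3.0
    residual_floor_dps: float = 0.5
    max_iter: int = 10
    convergence_tol: float = 1e-6
    min_retained: int = 50

    def __post_init__(self) -> None:
        if min(self.accel_threshold, self.pad_ms, self.residual_k,
               self.convergence_tol) <= 0:
            raise ValueError("DesaccadeParams values must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


class Direction:
    RIGHT = "rightward"
    LEFT = "leftward"
    EXCLUDED = "excluded"


@dataclass
class ParadigmResult:
    """Direction-specific gains plus diagnostics for one recording."""

    paradigm: Paradigm
    gain_right: float
    gain_left: float
    frequency_hz: float
    n_retained_right: int
    n_retained_left: int
    residual_sd: float
    saccade_intervals: list[tuple[float, float]]
    converged: bool
    slope_sign_right: int = -1
    slope_sign_left: int = -1


def _merge_intervals(
    intervals: list[tuple[float, float]]
) -> list[tuple[float, float]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for start, end in intervals[1:]:
        if start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def detect_saccades(
    trace: VelocityTrace, params: DesaccadeParams = DesaccadeParams()
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Flag saccadic samples by eye-velocity derivative thresholding.

    Returns a boolean mask over the trace samples (True = retained
    slow-phase sample) and the merged, padded saccade intervals in seconds.
    """
    t = trace.time
    if t[-1] - t[0] < 1.0:
        raise DesaccadeError("need at least 1 s of data to desaccade")
    eye = trace.eye_velocity
    # central differences; one-sided at the ends
    accel = np.gradient(eye, t)
    candidate = np.abs(accel) > params.accel_threshold

    pad_s = params.pad_ms / 1000.0
    intervals = [(t[i] - pad_s, t[i] + pad_s) for i in np.flatnonzero(candidate)]
    intervals = _merge_intervals(intervals)

    mask = np.ones(t.size, dtype=bool)
    for start, end in intervals:
        mask &= ~((t >= start) & (t <= end))
    if mask.sum() < params.min_retained:
        raise DesaccadeError(
            f"only {int(mask.sum())} slow-phase samples retained "
            f"(minimum {params.min_retained})"
        )
    return mask, intervals


def split_by_direction(
    trace: VelocityTrace, deadband: float = 10.0
) -> np.ndarray:
    """Label each sample rightward/leftward/excluded by head velocity sign.

    Samples with |head velocity| <= deadband are excluded: near the
    oscillation turnaround the eye/head velocity ratio is ill-conditioned.
    """
    labels = np.full(trace.n_samples, Direction.EXCLUDED, dtype=object)
    labels[trace.head_velocity > deadband] = Direction.RIGHT
    labels[trace.head_velocity < -deadband] = Direction.LEFT
    return labels


def _zero_intercept_slope(head: np.ndarray, eye: np.ndarray) -> float:
    denom = float(np.dot(head, head))
    if denom <= 0 or not np.isfinite(denom):
        raise DegenerateInputError("head velocity has no variance; cannot fit gain")
    return float(np.dot(head, eye) / denom)


def estimate_slope_gain(
    trace: VelocityTrace,
    retained_mask: np.ndarray,
    direction_labels: np.ndarray,
    direction: str,
    params: DesaccadeParams = DesaccadeParams(),
) -> tuple[float, dict]:
    """Gain for one head-motion direction by robust zero-intercept regression.

    The slope of eye velocity on head velocity is refitted iteratively,
    dropping samples whose residual exceeds ``residual_k`` scaled MADs of the
    current residuals (never below ``residual_floor_dps``), until the retained
    set stabilizes or ``max_iter`` fits have been done.  The returned gain is
    the magnitude of the final slope; under the rightward-positive sign
    convention a compensatory response has a negative slope, and a positive
    one is logged as a warning (some exports pre-invert the eye channel).
    """
    select = retained_mask & (direction_labels == direction)
    head = trace.head_velocity[select]
    eye = trace.eye_velocity[select]
    if head.size < params.min_retained:
        raise EstimationError(
            f"{direction}: only {head.size} retained samples "
            f"(minimum {params.min_retained})"
        )

    keep = np.ones(head.size, dtype=bool)
    slope = _zero_intercept_slope(head, eye)
    converged = True
    for _ in range(params.max_iter - 1):
        resid = eye[keep] - slope * head[keep]
        mad = np.median(np.abs(resid - np.median(resid)))
        thresh = max(params.residual_k * 1.4826 * mad, params.residual_floor_dps)
        if not np.isfinite(thresh):
            break
        new_keep = keep.copy()
        new_keep[keep] = np.abs(resid) <= thresh
        if new_keep.sum() < params.min_retained:
            break
        new_slope = _zero_intercept_slope(head[new_keep], eye[new_keep])
        done = (new_keep == keep).all() or (
            abs(new_slope - slope) <= params.convergence_tol * max(1.0, abs(slope))
        )
        keep, slope = new_keep, new_slope
        if done:
            break
    else:
        if params.max_iter > 1:
            converged = False

    resid = eye[keep] - slope * head[keep]
    if slope > 0:
        logger.warning(
            "%s slope is positive (+%.3f): eye channel may be pre-inverted",
            direction,
            slope,
        )
    diagnostics = {
        "n_retained": int(keep.sum()),
        "residual_sd": float(np.std(resid)) if resid.size else 0.0,
        "slope": slope,
        "converged": converged,
    }
    return abs(slope), diagnostics


def _dft_power(freq: float, t: np.ndarray, x: np.ndarray) -> float:
    phase = 2.0 * np.pi * freq * t
    return float(np.dot(x, np.cos(phase)) ** 2 + np.dot(x, np.sin(phase)) ** 2)


def estimate_frequency(
    trace: VelocityTrace,
    *,
    band_hz: tuple[float, float] = (0.2, 2.0),
    crosscheck_tol_hz: float = 0.05,
) -> float:
    """Dominant head-oscillation frequency in Hz.

    A Hann-windowed, zero-padded periodogram locates the spectral peak in
    ``band_hz``; the estimate is refined by locally maximizing the windowed
    DFT power as a continuous function of frequency.  A zero-crossing-rate
    estimate cross-checks the result; disagreement beyond
    ``crosscheck_tol_hz`` is logged as a warning.
    """
    head = trace.head_velocity
    t = trace.time
    fs = trace.sample_rate
    span = t[-1] - t[0]
    if span < 2.0 / band_hz[1]:
        raise EstimationError("trace too short for frequency estimation")
    x = head - head.mean()
    rms = np.sqrt(np.mean(x**2))
    if rms < 1e-9:
        raise EstimationError("head velocity has no oscillation")

    nfft = int(2 ** np.ceil(np.log2(x.size * 8)))
    freqs, power = signal.periodogram(x, fs=fs, window="hann", nfft=nfft)
    in_band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not in_band.any() or power[in_band].max() <= 0:
        raise EstimationError(f"no spectral peak in band {band_hz} Hz")
    band_power = power[in_band]
    noise_floor = np.median(power[freqs > 0]) if (freqs > 0).any() else 0.0
    if band_power.max() < 10.0 * max(noise_floor, 1e-300):
        raise EstimationError(
            f"no spectral peak above noise floor in band {band_hz} Hz"
        )
    f_peak = freqs[in_band][int(np.argmax(band_power))]

    # parabolic interpolation on log-power around the discrete peak
    i_peak = int(np.flatnonzero(freqs == f_peak)[0])
    if 0 < i_peak < freqs.size - 1 and power[i_peak - 1] > 0 and power[i_peak + 1] > 0:
        y0, y1, y2 = np.log(power[i_peak - 1 : i_peak + 2])
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            f_peak += 0.5 * (y0 - y2) / denom * (freqs[1] - freqs[0])

    # continuous local refinement of the Hann-windowed DFT power
    w = np.hanning(x.size)
    xw = x * w
    df = fs / nfft
    res = optimize.minimize_scalar(
        lambda f: -_dft_power(f, t, xw),
        bounds=(max(band_hz[0], f_peak - 2 * df * 8), min(band_hz[1], f_peak + 2 * df * 8)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    f_hat = float(res.x)

    # zero-crossing cross-check: crossings per second / 2 = frequency
    sign = np.sign(x)
    crossings = int(np.sum(sign[:-1] * sign[1:] < 0))
    f_zc = crossings / (2.0 * span)
    if abs(f_zc - f_hat) > crosscheck_tol_hz:
        logger.warning(
            "frequency cross-check disagreement: spectral %.3f Hz vs "
            "zero-crossing %.3f Hz",
            f_hat,
            f_zc,
        )
    return f_hat


def analyze_paradigm(
    trace: VelocityTrace,
    params: DesaccadeParams = DesaccadeParams(),
    *,
    window: AnalysisWindow = DEFAULT_WINDOW,
    trim_s: float = 1.0,
    deadband: float = 10.0,
) -> ParadigmResult:
    """Full single-recording pipeline: trim, window, desaccade, fit, frequency.

    Deterministic for fixed input and parameters.  Stage failures are
    re-raised with the stage name prefixed.
    """

    def _stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except QvorError as exc:
            raise type(exc)(f"{name}: {exc}") from exc

    trimmed = _stage("trim", trim_recording, trace, trim_s)
    windowed = _stage("window", select_analysis_window, trimmed, window)
    windowed, frac_missing = drop_nonfinite(windowed)
    if frac_missing:
        logger.info("dropped %.1f%% non-finite samples", 100 * frac_missing)
    mask, intervals = _stage("desaccade", detect_saccades, windowed, params)
    labels = split_by_direction(windowed, deadband)
    gain_r, diag_r = _stage(
        "gain_right", estimate_slope_gain, windowed, mask, labels,
        Direction.RIGHT, params,
    )
    gain_l, diag_l = _stage(
        "gain_left", estimate_slope_gain, windowed, mask, labels,
        Direction.LEFT, params,
    )
    freq = _stage("frequency", estimate_frequency, windowed)
    logger.info(
        "%s %s: gain R %.3f L %.3f, frequency %.3f Hz",
        trace.subject_id,
        trace.paradigm.value,
        gain_r,
        gain_l,
        freq,
    )
    return ParadigmResult(
        paradigm=trace.paradigm,
        gain_right=gain_r,
        gain_left=gain_l,
        frequency_hz=freq,
        n_retained_right=diag_r["n_retained"],
        n_retained_left=diag_l["n_retained"],
        residual_sd=float(
            np.hypot(diag_r["residual_sd"], diag_l["residual_sd"]) / np.sqrt(2)
        ),
        saccade_intervals=intervals,
        converged=diag_r["converged"] and diag_l["converged"],
        slope_sign_right=int(np.sign(diag_r["slope"])) if diag_r["slope"] else -1,
        slope_sign_left=int(np.sign(diag_l["slope"])) if diag_l["slope"] else -1,
    )
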