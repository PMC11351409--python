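"""Trimming, analysis-window selection and quality checks.

The acquisition protocol records 17 s of passive sinusoidal head oscillation.
The first and last second are discarded (acceleration/deceleration of the
examiner's movement), and of the remaining 15 s the central 5 s segment —
seconds 8 to 13 of the original recording — is analyzed.  Timestamps are
always referenced to the original recording start, so trimming does not
re-zero time and the window is specified in original-recording seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CoverageError, TooShortError
from .io_vhit import VelocityTrace

__all__ = [
    "AnalysisWindow",
    "QualityReport",
    "DEFAULT_WINDOW",
    "trim_recording",
    "select_analysis_window",
    "drop_nonfinite",
    "validate_trace",
]


@dataclass(frozen=True)
class AnalysisWindow:
    """Half-open time window [start_s, end_s) in original-recording seconds."""

    start_s: float = 8.0
    end_s: float = 13.0

    def __post_init__(self) -> None:
        if not (0 <= self.start_s < self.end_s):
            raise ValueError("require 0 <= start_s < end_s")

    @property
    def length_s(self) -> float:
        return self.end_s - self.start_s


DEFAULT_WINDOW = AnalysisWindow(8.0, 13.0)


@dataclass
class QualityReport:
    """Outcome of trace quality checks.  Problems are reported, not raised."""

    duration_s: float
    n_samples: int
    fraction_missing: float
    head_velocity_peak: float
    passes: bool
    messages: list[str] = field(default_factory=list)


def trim_recording(trace: VelocityTrace, trim_s: float = 1.0) -> VelocityTrace:
    """Remove the first and last ``trim_s`` seconds of the recording."""
    if trace.duration_s < 2 * trim_s + 1.0:
        raise TooShortError(
            f"recording of {trace.duration_s:.3f} s too short to trim {trim_s} s "
            "from each end"
        )
    t0 = trace.time[0]
    tend = trace.time[-1]
    keep = (trace.time >= t0 + trim_s - 1e-9) & (trace.time <= tend - trim_s + 1e-9)
    return trace.replace_samples(
        trace.time[keep], trace.head_velocity[keep], trace.eye_velocity[keep]
    )


def select_analysis_window(
    trace: VelocityTrace, window: AnalysisWindow = DEFAULT_WINDOW
) -> VelocityTrace:
    """Restrict a trace to the half-open window [start_s, end_s).

    The window is defined on original-recording time, so it composes
    transparently with :func:`trim_recording` as long as the window lies
    inside the trimmed span.
    """
    dt = 1.0 / trace.sample_rate
    # coverage: first sample at/before start, last sample reaching end - dt
    if trace.time[0] > window.start_s + 1e-9 or trace.time[-1] < window.end_s - dt - 1e-9:
        raise CoverageError(
            f"trace spans [{trace.time[0]:.3f}, {trace.time[-1]:.3f}] s and does "
            f"not cover window [{window.start_s}, {window.end_s}) s"
        )
    keep = (trace.time >= window.start_s - 1e-9) & (trace.time < window.end_s - 1e-9)
    return trace.replace_samples(
        trace.time[keep], trace.head_velocity[keep], trace.eye_velocity[keep]
    )


def drop_nonfinite(trace: VelocityTrace) -> tuple[VelocityTrace, float]:
    """Drop samples with non-finite velocities (blinks / track loss).

    Returns the cleaned trace and the fraction of samples dropped.  The
    cleaned trace may be non-uniform, so this is applied after windowing and
    consumed by the fitting stage, which does not require uniform spacing.
    """
    good = np.isfinite(trace.head_velocity) & np.isfinite(trace.eye_velocity)
    frac = 1.0 - good.mean()
    if frac == 0.0:
        return trace, 0.0
    # bypass the uniformity check: rebuild via object with gaps allowed
    cleaned = object.__new__(VelocityTrace)
    object.__setattr__(cleaned, "subject_id", trace.subject_id)
    object.__setattr__(cleaned, "paradigm", trace.paradigm)
    object.__setattr__(cleaned, "sample_rate", trace.sample_rate)
    object.__setattr__(cleaned, "time", trace.time[good])
    object.__setattr__(cleaned, "head_velocity", trace.head_velocity[good])
    object.__setattr__(cleaned, "eye_velocity", trace.eye_velocity[good])
    return cleaned, float(frac)


def validate_trace(
    trace: VelocityTrace,
    *,
    expected_duration_s: float = 17.0,
    max_missing_fraction: float = 0.1,
    window: AnalysisWindow = DEFAULT_WINDOW,
    min_head_peak_dps: float = 30.0,
) -> QualityReport:
    """Run protocol plausibility checks; never mutates the trace.

    The peak-head-velocity check flags recordings far below the protocol
    amplitude: a 35 deg arc at 0.75 Hz peaks near 82 deg/s, so peaks below
    ``min_head_peak_dps`` suggest the oscillation protocol was not followed.
    """
    messages: list[str] = []
    finite = np.isfinite(trace.head_velocity) & np.isfinite(trace.eye_velocity)
    fraction_missing = float(1.0 - finite.mean())
    head_peak = float(np.nanmax(np.abs(trace.head_velocity))) if finite.any() else 0.0

    passes = True
    if fraction_missing > max_missing_fraction:
        passes = False
        messages.append(
            f"missing data fraction {fraction_missing:.3f} exceeds limit "
            f"{max_missing_fraction:.3f}"
        )
    covers = trace.time[0] <= window.start_s + 1e-9 and (
        trace.time[-1] >= window.end_s - 1.0 / trace.sample_rate - 1e-9
    )
    if not covers:
        passes = False
        messages.append(
            f"recording does not cover analysis window "
            f"[{window.start_s}, {window.end_s}) s"
        )
    if abs(trace.duration_s - expected_duration_s) > 0.5:
        messages.append(
            f"duration {trace.duration_s:.2f} s differs from protocol "
            f"{expected_duration_s:.0f} s"
        )
    if head_peak < min_head_peak_dps:
        messages.append(
            f"peak head velocity {head_peak:.1f} deg/s below protocol amplitude "
            "(expected roughly 80 deg/s for a 35 deg arc at 0.75 Hz)"
        )
    return QualityReport(
        duration_s=trace.duration_s,
        n_samples=trace.n_samples,
        fraction_missing=fraction_missing,
        head_velocity_peak=head_peak,
        passes=passes,
        messages=messages,
    )
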