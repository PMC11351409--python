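"""Synthetic sinusoidal vHIT recordings and cohorts with known ground truth.

The generator emulates the clinical acquisition protocol: 17 s of passive
sinusoidal head oscillation over a ~35 deg arc at a nominal 0.75 Hz, paced
by a metronome the examiner never hits exactly (the achieved frequency runs
high by about +0.075 Hz).  Head position is a pure sinusoid, so head
velocity is a cosine with peak ``(arc/2) * 2*pi*f``; eye velocity is
``-true_gain x head velocity`` (compensatory, per the rightward-positive
sign convention) plus saccadic velocity pulses and additive Gaussian noise.

Saccades are raised-cosine velocity bumps at Poisson times.  In the
suppression paradigm they are catch-up saccades dragging the eye toward the
head-fixed target, so their sign follows the head velocity; in the
visually enhanced paradigm they are rare and bidirectional.

All randomness flows from a single seed; identical configs give
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_vhit import (
    DEFAULT_SAMPLE_RATE,
    Paradigm,
    SubjectRecord,
    VelocityTrace,
    write_subject_table,
    write_velocity_trace,
)

__all__ = [
    "TraceSimConfig",
    "GroundTruth",
    "GainDistribution",
    "CohortSimConfig",
    "SimulatedCohort",
    "generate_trace",
    "generate_cohort",
    "write_cohort",
    "true_bilateral_si",
]


@dataclass(frozen=True)
class TraceSimConfig:
    """Protocol parameters for one simulated recording.

    ``true_gain`` applies to both directions unless the side-specific
    ``true_gain_right``/``true_gain_left`` override it.  ``arc_amplitude``
    is peak-to-peak degrees (protocol range 30-40).
    """

    paradigm: Paradigm = Paradigm.VVOR
    true_gain: float = 1.0
    true_gain_right: float | None = None
    true_gain_left: float | None = None
    nominal_frequency: float = 0.75
    frequency_error: float = 0.0
    arc_amplitude: float = 35.0
    duration_s: float = 17.0
    sample_rate: float = DEFAULT_SAMPLE_RATE
    noise_sd: float = 0.0
    saccade_rate: float = 0.0
    saccade_peak_range: tuple[float, float] = (100.0, 300.0)
    saccade_duration_ms_range: tuple[float, float] = (30.0, 80.0)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "paradigm", Paradigm(self.paradigm))
        f = self.nominal_frequency + self.frequency_error
        if not 0 < f < self.sample_rate / 2:
            raise ValidationError(
                "effective frequency must lie in (0, sample_rate/2)"
            )
        if self.arc_amplitude <= 0:
            raise ValidationError("arc_amplitude must be positive")
        if self.duration_s < 13.0:
            raise ValidationError(
                "duration must cover the default analysis window (>= 13 s)"
            )
        if min(self.gain_right, self.gain_left) < 0:
            raise ValidationError("gains must be non-negative")
        if self.noise_sd < 0 or self.saccade_rate < 0:
            raise ValidationError("noise_sd and saccade_rate must be >= 0")

    @property
    def gain_right(self) -> float:
        return self.true_gain if self.true_gain_right is None else self.true_gain_right

    @property
    def gain_left(self) -> float:
        return self.true_gain if self.true_gain_left is None else self.true_gain_left

    @property
    def frequency(self) -> float:
        return self.nominal_frequency + self.frequency_error


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator injected into one trace."""

    true_gain_right: float
    true_gain_left: float
    true_frequency: float
    saccade_intervals: tuple
    noise_sd: float


def generate_trace(
    config: TraceSimConfig, *, subject_id: str = "sim"
) -> tuple[VelocityTrace, GroundTruth]:
    """Simulate one recording; deterministic for a fixed config (incl. seed)."""
    rng = np.random.default_rng(config.seed)
    fs = config.sample_rate
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs
    f = config.frequency
    peak_head = (config.arc_amplitude / 2.0) * 2.0 * np.pi * f
    head = peak_head * np.cos(2.0 * np.pi * f * t)

    gain = np.where(head >= 0, config.gain_right, config.gain_left)
    eye = -gain * head

    intervals: list[tuple[float, float]] = []
    if config.saccade_rate > 0:
        n_sac = rng.poisson(config.saccade_rate * config.duration_s)
        starts = np.sort(rng.uniform(0.0, config.duration_s, size=n_sac))
        for start in starts:
            dur = rng.uniform(*config.saccade_duration_ms_range) / 1000.0
            peak = rng.uniform(*config.saccade_peak_range)
            if start + dur > config.duration_s:
                continue
            centre = start + dur / 2.0
            head_at_centre = peak_head * np.cos(2.0 * np.pi * f * centre)
            if config.paradigm is Paradigm.VORS:
                sign = 1.0 if head_at_centre >= 0 else -1.0
            else:
                sign = rng.choice((-1.0, 1.0))
            in_pulse = (t >= start) & (t <= start + dur)
            s = (t[in_pulse] - start) / dur
            eye[in_pulse] += sign * peak * 0.5 * (1.0 - np.cos(2.0 * np.pi * s))
            intervals.append((float(start), float(start + dur)))

    if config.noise_sd > 0:
        eye = eye + rng.normal(0.0, config.noise_sd, size=n)

    trace = VelocityTrace(
        subject_id=subject_id,
        paradigm=config.paradigm,
        sample_rate=fs,
        time=t,
        head_velocity=head,
        eye_velocity=eye,
    )
    truth = GroundTruth(
        true_gain_right=config.gain_right,
        true_gain_left=config.gain_left,
        true_frequency=f,
        saccade_intervals=tuple(intervals),
        noise_sd=config.noise_sd,
    )
    return trace, truth


@dataclass(frozen=True)
class GainDistribution:
    """Truncated-normal gain model for one measure."""

    mean: float
    sd: float
    lower: float = 1e-3
    upper: float = np.inf

    def draw(self, rng: np.random.Generator) -> float:
        for _ in range(1000):
            g = rng.normal(self.mean, self.sd)
            if self.lower <= g <= self.upper:
                return float(g)
        raise ValidationError("gain distribution truncation too tight")


def _draw_correlated_pair(
    rng: np.random.Generator,
    dist_r: "GainDistribution",
    dist_l: "GainDistribution",
    rho: float,
) -> tuple[float, float]:
    """One right/left gain pair with within-subject correlation ``rho``."""
    for _ in range(1000):
        z_r = rng.standard_normal()
        z_l = rho * z_r + np.sqrt(1.0 - rho**2) * rng.standard_normal()
        g_r = dist_r.mean + dist_r.sd * z_r
        g_l = dist_l.mean + dist_l.sd * z_l
        if (dist_r.lower <= g_r <= dist_r.upper
                and dist_l.lower <= g_l <= dist_l.upper):
            return float(g_r), float(g_l)
    raise ValidationError("gain distribution truncation too tight")


#: Age-bin edges with healthy-cohort relative frequencies (counts out of 83).
_AGE_BIN_SPECS = (
    ((15.0, 20.0), 8),
    ((21.0, 30.0), 19),
    ((31.0, 40.0), 9),
    ((41.0, 50.0), 11),
    ((51.0, 60.0), 10),
    ((61.0, 70.0), 15),
    ((71.0, 80.0), 9),
    ((81.0, 90.0), 2),
)


def _default_gain_distributions() -> dict[str, GainDistribution]:
    # screening gains truncated at the 0.7 inclusion bound: the cohort is
    # post-screening by construction
    return {
        "himp_gain_r": GainDistribution(1.008, 0.099, lower=0.7),
        "himp_gain_l": GainDistribution(0.940, 0.096, lower=0.7),
        "shimp_gain_r": GainDistribution(0.939, 0.116, lower=0.05),
        "shimp_gain_l": GainDistribution(0.877, 0.104, lower=0.05),
        "qvvor_gain_r": GainDistribution(0.981, 0.070, lower=0.2),
        "qvvor_gain_l": GainDistribution(0.978, 0.077, lower=0.2),
        "qvors_gain_r": GainDistribution(0.334, 0.112, lower=0.05),
        "qvors_gain_l": GainDistribution(0.353, 0.110, lower=0.05),
    }


@dataclass(frozen=True)
class CohortSimConfig:
    """Whole-cohort simulation: demographics, gains, protocol noise."""

    n_subjects: int = 83
    n_female: int = 41
    gain_distributions: dict = field(default_factory=_default_gain_distributions)
    # Women suppress slightly better than men in the emulated population
    # (cohort bilateral SI means 0.270 vs 0.319 around an overall 0.295);
    # modeled as a multiplicative factor on the suppression-paradigm gains.
    vors_gain_factor_female: float = 0.270 / 0.295
    vors_gain_factor_male: float = 0.319 / 0.295
    # Within-subject correlation of right and left gains of one test: healthy
    # vestibular function is bilaterally symmetric, so the sides are strongly
    # correlated rather than independent draws.
    lr_gain_correlation: float = 0.75
    frequency_error_mean: float = 0.075
    frequency_error_sd: float = 0.02
    noise_sd: float = 3.0
    saccade_rate_vvor: float = 0.5
    saccade_rate_vors: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if not 0 <= self.n_female <= self.n_subjects:
            raise ValidationError("n_female must lie in [0, n_subjects]")


@dataclass
class SimulatedCohort:
    """In-memory simulated cohort: records, traces, and ground truth."""

    records: list[SubjectRecord]
    traces: dict  # (subject_id, Paradigm) -> VelocityTrace
    truth: pd.DataFrame  # one row per subject with every injected quantity
    seed: int


def true_bilateral_si(
    qvvor_r: float, qvvor_l: float, qvors_r: float, qvors_l: float
) -> float:
    """Bilateral SI implied by a subject's true gains (generator-side copy)."""
    asym_vvor = min(qvvor_r, qvvor_l) / max(qvvor_r, qvvor_l)
    asym_vors = min(qvors_r, qvors_l) / max(qvors_r, qvors_l)
    return (0.5 * (qvors_r + qvors_l) * asym_vors) / (
        0.5 * (qvvor_r + qvvor_l) * asym_vvor
    )


def generate_cohort(config: CohortSimConfig = CohortSimConfig()) -> SimulatedCohort:
    """Draw a full cohort and simulate both recordings per subject."""
    rng = np.random.default_rng(config.seed)

    # demographics
    sexes = np.array(["F"] * config.n_female
                     + ["M"] * (config.n_subjects - config.n_female))
    rng.shuffle(sexes)
    bin_probs = np.array([c for _, c in _AGE_BIN_SPECS], dtype=float)
    bin_probs /= bin_probs.sum()
    bin_idx = rng.choice(len(_AGE_BIN_SPECS), size=config.n_subjects, p=bin_probs)
    ages = np.array([
        rng.uniform(*_AGE_BIN_SPECS[i][0]) for i in bin_idx
    ])

    records: list[SubjectRecord] = []
    traces: dict = {}
    truth_rows = []
    for i in range(config.n_subjects):
        sid = f"S{i + 1:03d}"
        sex_factor = (config.vors_gain_factor_female if sexes[i] == "F"
                      else config.vors_gain_factor_male)
        dists = config.gain_distributions
        gains: dict[str, float] = {}
        for prefix in ("himp_gain", "shimp_gain", "qvvor_gain", "qvors_gain"):
            gains[f"{prefix}_r"], gains[f"{prefix}_l"] = _draw_correlated_pair(
                rng, dists[f"{prefix}_r"], dists[f"{prefix}_l"],
                config.lr_gain_correlation,
            )
        for name in ("qvors_gain_r", "qvors_gain_l"):
            gains[name] *= sex_factor
        freq_err_vvor = rng.normal(config.frequency_error_mean,
                                   config.frequency_error_sd)
        freq_err_vors = rng.normal(config.frequency_error_mean,
                                   config.frequency_error_sd)
        trace_seeds = rng.integers(0, 2**31 - 1, size=2)

        cfg_vvor = TraceSimConfig(
            paradigm=Paradigm.VVOR,
            true_gain_right=gains["qvvor_gain_r"],
            true_gain_left=gains["qvvor_gain_l"],
            frequency_error=float(freq_err_vvor),
            noise_sd=config.noise_sd,
            saccade_rate=config.saccade_rate_vvor,
            seed=int(trace_seeds[0]),
        )
        cfg_vors = TraceSimConfig(
            paradigm=Paradigm.VORS,
            true_gain_right=gains["qvors_gain_r"],
            true_gain_left=gains["qvors_gain_l"],
            frequency_error=float(freq_err_vors),
            noise_sd=config.noise_sd,
            saccade_rate=config.saccade_rate_vors,
            seed=int(trace_seeds[1]),
        )
        trace_vvor, truth_vvor = generate_trace(cfg_vvor, subject_id=sid)
        trace_vors, truth_vors = generate_trace(cfg_vors, subject_id=sid)
        traces[(sid, Paradigm.VVOR)] = trace_vvor
        traces[(sid, Paradigm.VORS)] = trace_vors

        records.append(
            SubjectRecord(
                subject_id=sid,
                age=float(ages[i]),
                sex=str(sexes[i]),
                himp_gain_r=gains["himp_gain_r"],
                himp_gain_l=gains["himp_gain_l"],
                shimp_gain_r=gains["shimp_gain_r"],
                shimp_gain_l=gains["shimp_gain_l"],
            )
        )
        truth_rows.append(
            {
                "subject_id": sid,
                "age": float(ages[i]),
                "sex": str(sexes[i]),
                **gains,
                "freq_vvor": truth_vvor.true_frequency,
                "freq_vors": truth_vors.true_frequency,
                "true_si_bilateral": true_bilateral_si(
                    gains["qvvor_gain_r"], gains["qvvor_gain_l"],
                    gains["qvors_gain_r"], gains["qvors_gain_l"],
                ),
                "n_saccades_vvor": len(truth_vvor.saccade_intervals),
                "n_saccades_vors": len(truth_vors.saccade_intervals),
            }
        )

    return SimulatedCohort(
        records=records,
        traces=traces,
        truth=pd.DataFrame(truth_rows),
        seed=config.seed,
    )


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> pd.DataFrame:
    """Persist a cohort as canonical-dialect CSVs plus ground truth + manifest.

    Trace files follow the pairing convention ``<subject_id>_<paradigm>.csv``.
    Returns the manifest DataFrame (also written as ``manifest.csv``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for (sid, paradigm), trace in sorted(cohort.traces.items(),
                                         key=lambda kv: (kv[0][0], kv[0][1].value)):
        name = f"{sid}_{paradigm.value}.csv"
        write_velocity_trace(trace, out / name)
        entries.append({"file": name, "subject_id": sid,
                        "paradigm": paradigm.value, "kind": "trace"})
    write_subject_table(cohort.records, out / "subjects.csv")
    entries.append({"file": "subjects.csv", "subject_id": "", "paradigm": "",
                    "kind": "subject_table"})
    cohort.truth.to_csv(out / "ground_truth.csv", index=False)
    entries.append({"file": "ground_truth.csv", "subject_id": "", "paradigm": "",
                    "kind": "ground_truth"})
    manifest = pd.DataFrame(entries)
    manifest.insert(0, "seed", cohort.seed)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
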