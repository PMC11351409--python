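"""Reading and writing vHIT-style velocity traces and subject tables.

A sinusoidal vHIT recording is exported by the device as a plain CSV of
time-stamped horizontal head and eye angular velocities.  The canonical
dialect written by this package is a comma-separated file with header
``time_s,head_velocity_dps,eye_velocity_dps``; :class:`FormatConfig` adapts
the reader to other exports (different delimiters, column names or indices,
millisecond or sample-index time stamps).

Sign convention: rightward head rotation is positive head velocity, and the
eye channel uses the same axis, so compensatory eye velocity is predominantly
negative while the head moves rightward.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, fields
from pathlib import Path
from typing import IO, Union

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, TimingError, ValidationError

__all__ = [
    "Paradigm",
    "VelocityTrace",
    "FormatConfig",
    "SubjectRecord",
    "read_velocity_trace",
    "write_velocity_trace",
    "read_subject_table",
    "write_subject_table",
    "DEFAULT_SAMPLE_RATE",
]

#: Default sampling rate of high-frame-rate vHIT cameras, samples/s.
DEFAULT_SAMPLE_RATE = 250.0

#: Allowed relative jitter in the sampling interval.
_TIME_UNIFORMITY_TOL_S = 1e-6


class Paradigm(str, enum.Enum):
    """Sinusoidal test paradigm: visually enhanced VOR or VOR suppression."""

    VVOR = "VVOR"
    VORS = "VORS"


class TimeUnit(str, enum.Enum):
    SECONDS = "seconds"
    MILLISECONDS = "milliseconds"
    SAMPLE_INDEX = "sample_index"


@dataclass(frozen=True)
class VelocityTrace:
    """Time-aligned head and eye angular velocity samples for one recording.

    Parameters
    ----------
    subject_id : str
        Identifier of the recorded subject.
    paradigm : Paradigm
        Which sinusoidal test this trace belongs to.
    sample_rate : float
        Sampling rate in samples per second.
    time : ndarray
        Time stamps in seconds, strictly increasing and uniformly spaced.
        Time is always referenced to the start of the original recording;
        trimming and windowing never re-zero it.
    head_velocity, eye_velocity : ndarray
        Angular velocities in deg/s (rightward positive).
    """

    subject_id: str
    paradigm: Paradigm
    sample_rate: float
    time: np.ndarray
    head_velocity: np.ndarray
    eye_velocity: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        h = np.asarray(self.head_velocity, dtype=float)
        e = np.asarray(self.eye_velocity, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "head_velocity", h)
        object.__setattr__(self, "eye_velocity", e)
        object.__setattr__(self, "paradigm", Paradigm(self.paradigm))
        if t.ndim != 1 or t.size < 2:
            raise ValidationError("trace requires at least 2 samples")
        if h.shape != t.shape or e.shape != t.shape:
            raise ValidationError(
                "head_velocity and eye_velocity must match time in length"
            )
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise TimingError("time stamps must be strictly increasing")
        if np.any(np.abs(dt - 1.0 / self.sample_rate) > _TIME_UNIFORMITY_TOL_S):
            raise TimingError(
                "non-uniform sampling interval beyond tolerance "
                f"(expected {1.0 / self.sample_rate:.6g} s)"
            )

    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    @property
    def duration_s(self) -> float:
        """Duration covered by the samples, in seconds (span + one period)."""
        return float(self.time[-1] - self.time[0]) + 1.0 / self.sample_rate

    def replace_samples(
        self, time: np.ndarray, head: np.ndarray, eye: np.ndarray
    ) -> "VelocityTrace":
        """Return a new trace with the same metadata and new samples."""
        return VelocityTrace(
            subject_id=self.subject_id,
            paradigm=self.paradigm,
            sample_rate=self.sample_rate,
            time=time,
            head_velocity=head,
            eye_velocity=eye,
        )


@dataclass(frozen=True)
class FormatConfig:
    """Dialect description for a vHIT CSV export."""

    delimiter: str = ","
    time_column: Union[str, int] = "time_s"
    head_column: Union[str, int] = "head_velocity_dps"
    eye_column: Union[str, int] = "eye_velocity_dps"
    has_header: bool = True
    time_unit: TimeUnit = TimeUnit.SECONDS

    def __post_init__(self) -> None:
        object.__setattr__(self, "time_unit", TimeUnit(self.time_unit))
        cols = [self.time_column, self.head_column, self.eye_column]
        if len(set(cols)) != 3:
            raise ValidationError("time/head/eye columns must be distinct")


@dataclass
class SubjectRecord:
    """Demographics plus per-test gains and frequencies for one subject.

    Impulsive HIMP/SHIMP gains arrive precomputed from the device; the
    sinusoidal qVVOR/qVORS gains and actual frequencies (``freq_vvor``,
    ``freq_vors``) are filled in by the analysis pipeline.
    """

    subject_id: str
    age: float
    sex: str
    himp_gain_r: float = np.nan
    himp_gain_l: float = np.nan
    shimp_gain_r: float = np.nan
    shimp_gain_l: float = np.nan
    qvvor_gain_r: float = np.nan
    qvvor_gain_l: float = np.nan
    qvors_gain_r: float = np.nan
    qvors_gain_l: float = np.nan
    freq_vvor: float = np.nan
    freq_vors: float = np.nan

    _GAIN_FIELDS = (
        "himp_gain_r",
        "himp_gain_l",
        "shimp_gain_r",
        "shimp_gain_l",
        "qvvor_gain_r",
        "qvvor_gain_l",
        "qvors_gain_r",
        "qvors_gain_l",
    )

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValidationError(f"subject {self.subject_id}: age must be >= 0")
        if self.sex not in ("F", "M"):
            raise ValidationError(
                f"subject {self.subject_id}: sex must be 'F' or 'M', got {self.sex!r}"
            )
        for name in self._GAIN_FIELDS:
            v = getattr(self, name)
            if np.isfinite(v) and v <= 0:
                raise ValidationError(
                    f"subject {self.subject_id}: {name} must be > 0, got {v}"
                )
        for name in ("freq_vvor", "freq_vors"):
            v = getattr(self, name)
            if np.isfinite(v) and v <= 0:
                raise ValidationError(
                    f"subject {self.subject_id}: {name} must be > 0, got {v}"
                )


def _resolve_column(df: pd.DataFrame, col: Union[str, int], what: str) -> pd.Series:
    if isinstance(col, int):
        if col >= df.shape[1]:
            raise FormatError(f"{what} column index {col} out of range")
        return df.iloc[:, col]
    if col not in df.columns:
        raise FormatError(f"missing {what} column {col!r}")
    return df[col]


def _to_float(series: pd.Series, what: str) -> np.ndarray:
    converted = pd.to_numeric(series, errors="coerce")
    raw_na = series.isna()
    bad = converted.isna() & ~raw_na
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"non-numeric value {series.iloc[row]!r} in {what} column at data row {row}"
        )
    return converted.to_numpy(dtype=float)


def read_velocity_trace(
    source: Union[str, Path, IO[str]],
    fmt: FormatConfig | None = None,
    *,
    subject_id: str = "",
    paradigm: Union[Paradigm, str] = Paradigm.VVOR,
    sample_rate: float | None = None,
) -> VelocityTrace:
    """Read one velocity trace from a CSV export.

    ``sample_rate`` is required when ``fmt.time_unit`` is ``sample_index``;
    otherwise it defaults to the rate inferred from the time stamps.
    """
    fmt = fmt or FormatConfig()
    header = 0 if fmt.has_header else None
    df = pd.read_csv(source, sep=fmt.delimiter, header=header, dtype=str,
                     skipinitialspace=True)
    if df.shape[0] < 2:
        raise ValidationError("trace requires at least 2 samples")
    t_raw = _to_float(_resolve_column(df, fmt.time_column, "time"), "time")
    head = _to_float(_resolve_column(df, fmt.head_column, "head velocity"), "head")
    eye = _to_float(_resolve_column(df, fmt.eye_column, "eye velocity"), "eye")

    if fmt.time_unit is TimeUnit.MILLISECONDS:
        t = t_raw / 1000.0
    elif fmt.time_unit is TimeUnit.SAMPLE_INDEX:
        if sample_rate is None:
            raise ValidationError(
                "sample_rate is required when time_unit is sample_index"
            )
        t = t_raw / sample_rate
    else:
        t = t_raw

    if sample_rate is None:
        dt = np.median(np.diff(t))
        if dt <= 0:
            raise TimingError("cannot infer sample rate from time stamps")
        sample_rate = 1.0 / dt

    return VelocityTrace(
        subject_id=subject_id,
        paradigm=Paradigm(paradigm),
        sample_rate=float(sample_rate),
        time=t,
        head_velocity=head,
        eye_velocity=eye,
    )


def write_velocity_trace(trace: VelocityTrace, dest: Union[str, Path, IO[str]]) -> None:
    """Write a trace in the canonical dialect, round-trippable by the reader."""
    df = pd.DataFrame(
        {
            "time_s": trace.time,
            "head_velocity_dps": trace.head_velocity,
            "eye_velocity_dps": trace.eye_velocity,
        }
    )
    df.to_csv(dest, index=False, float_format="%.9f")


_SUBJECT_COLUMNS = [f.name for f in fields(SubjectRecord)]


def read_subject_table(source: Union[str, Path, IO[str]]) -> list[SubjectRecord]:
    """Read a per-subject table (one row per subject) into records.

    Columns beyond ``subject_id, age, sex`` are optional; missing gain or
    frequency columns load as NaN.  Rows violating record invariants raise
    :class:`ValidationError` naming the row.
    """
    df = pd.read_csv(source, sep=None, engine="python")
    for required in ("subject_id", "age", "sex"):
        if required not in df.columns:
            raise FormatError(f"missing required column {required!r}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValidationError(f"duplicate subject_id {dup!r}")
    records: list[SubjectRecord] = []
    for i, row in df.iterrows():
        kwargs = {"subject_id": str(row["subject_id"]),
                  "age": float(row["age"]),
                  "sex": str(row["sex"])}
        for name in _SUBJECT_COLUMNS[3:]:
            if name in df.columns and pd.notna(row[name]):
                kwargs[name] = float(row[name])
        try:
            records.append(SubjectRecord(**kwargs))
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return records


def write_subject_table(records: list[SubjectRecord],
                        dest: Union[str, Path, IO[str]]) -> None:
    df = pd.DataFrame([{n: getattr(r, n) for n in _SUBJECT_COLUMNS} for r in records])
    df.to_csv(dest, index=False)
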