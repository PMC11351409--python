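"""Visual suppression indices from paired qVVOR/qVORS gains.

The unilateral suppression index (SI) of one side is the ratio of that
side's VOR-suppression gain to its visually enhanced VOR gain,

    SI(unilateral) = qVORS gain / qVVOR gain,

so 0 means perfect suppression and 1 none.  The bilateral SI combines both
sides, weighting each paradigm's mean gain by that paradigm's left/right
asymmetry (minor gain over major gain):

    SI(bilateral) = (mean qVORS gain x Asym_VORS) / (mean qVVOR gain x Asym_VVOR).

Each asymmetry factor belongs to its own paradigm's gain pair; applying one
common factor to numerator and denominator would cancel and reduce the index
to a plain ratio of means.  All indices are reported on the fraction scale;
multiplying by 100 for percent display is a formatting option only.

Subjects enter the sinusoidal protocol only after impulsive screening: a
pathological head-impulse (HIMP) gain below 0.7 on either side excludes the
subject.  A packaged normative table gives healthy-cohort percentiles for
the left, right and bilateral SIs, against which an individual value can be
placed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_vhit import SubjectRecord

__all__ = [
    "SuppressionIndices",
    "NormativeTable",
    "himp_inclusion_filter",
    "compute_asymmetry",
    "compute_unilateral_si",
    "compute_bilateral_si",
    "compute_indices",
    "percentile_placement",
    "load_normative_table",
    "HIMP_PATHOLOGICAL_GAIN",
    "QVVOR_GAIN_FLOOR",
]

#: Screening threshold: HIMP gain below this is pathological and excludes.
HIMP_PATHOLOGICAL_GAIN = 0.7

#: qVVOR gains below this make the SI ratio unstable; result is flagged.
QVVOR_GAIN_FLOOR = 0.2

PERCENTILE_LEVELS = (5, 10, 25, 50, 75, 90, 95)


@dataclass
class SuppressionIndices:
    """All suppression indices for one subject (fraction scale)."""

    si_right: float
    si_left: float
    asym_vvor: float
    asym_vors: float
    si_bilateral: float
    flags: list = None

    def __post_init__(self) -> None:
        if self.flags is None:
            self.flags = []


@dataclass(frozen=True)
class NormativeTable:
    """Percentile reference values for the three suppression indices."""

    levels: tuple
    left_si: tuple
    right_si: tuple
    bilateral_si: tuple

    def __post_init__(self) -> None:
        for name in ("left_si", "right_si", "bilateral_si"):
            vals = np.asarray(getattr(self, name), dtype=float)
            if vals.size != len(self.levels):
                raise ValidationError(f"{name}: need one value per percentile level")
            if np.any(np.diff(vals) < 0):
                raise ValidationError(
                    f"{name}: percentile values must be non-decreasing"
                )

    def column(self, which_index: str) -> np.ndarray:
        try:
            return np.asarray(getattr(self, which_index), dtype=float)
        except AttributeError:
            raise ValidationError(
                f"unknown index {which_index!r}; expected left_si, right_si "
                "or bilateral_si"
            ) from None


def load_normative_table(source: Union[str, Path, None] = None) -> NormativeTable:
    """Load the packaged healthy-cohort normative table, or a replacement CSV.

    The CSV must have columns ``percentile,left_si,right_si,bilateral_si``.
    """
    if source is None:
        ref = importlib.resources.files("qvor") / "data" / "normative_si.csv"
        with ref.open("r") as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(source)
    for col in ("percentile", "left_si", "right_si", "bilateral_si"):
        if col not in df.columns:
            raise ValidationError(f"normative table missing column {col!r}")
    df = df.sort_values("percentile")
    return NormativeTable(
        levels=tuple(int(p) for p in df["percentile"]),
        left_si=tuple(df["left_si"]),
        right_si=tuple(df["right_si"]),
        bilateral_si=tuple(df["bilateral_si"]),
    )


def himp_inclusion_filter(record: SubjectRecord) -> tuple[bool, str]:
    """Screening rule: include only if both HIMP gains are >= 0.7.

    The threshold is strict on the pathological side: a gain of exactly 0.7
    is not pathological and the subject is included.
    """
    gains = {"right": record.himp_gain_r, "left": record.himp_gain_l}
    for side, g in gains.items():
        if not np.isfinite(g):
            raise ValidationError(
                f"subject {record.subject_id}: missing HIMP gain ({side})"
            )
    low = [side for side, g in gains.items() if g < HIMP_PATHOLOGICAL_GAIN]
    if low:
        return False, (
            f"pathological HIMP gain (< {HIMP_PATHOLOGICAL_GAIN}) on "
            f"{' and '.join(low)} side"
        )
    return True, "HIMP gains within normal limits"


def compute_asymmetry(gain_a: float, gain_b: float) -> float:
    """Left/right gain asymmetry: minor gain over major gain, in (0, 1]."""
    if gain_a <= 0 or gain_b <= 0:
        raise ValidationError("asymmetry requires positive gains")
    return min(gain_a, gain_b) / max(gain_a, gain_b)


def compute_unilateral_si(
    qvors_gain: float, qvvor_gain: float, *, floor: float = QVVOR_GAIN_FLOOR
) -> tuple[float, list]:
    """One-sided suppression index qVORS/qVVOR, with a reliability flag.

    Returns ``(si, flags)``; ``flags`` notes a qVVOR gain below ``floor``
    (the ratio is then ill-conditioned but still computed).
    """
    if qvvor_gain <= 0:
        raise ValidationError("qVVOR gain must be positive")
    if qvors_gain < 0:
        raise ValidationError("qVORS gain must be non-negative")
    flags = []
    if qvvor_gain < floor:
        flags.append(f"qVVOR gain {qvvor_gain:.3f} below reliability floor {floor}")
    return qvors_gain / qvvor_gain, flags


def compute_bilateral_si(
    qvvor_r: float, qvvor_l: float, qvors_r: float, qvors_l: float
) -> tuple[float, float, float]:
    """Asymmetry-corrected bilateral SI.

    Returns ``(si_bilateral, asym_vvor, asym_vors)`` where each asymmetry is
    the minor/major ratio of that paradigm's left/right gain pair and

        si = (mean(qVORS) * asym_VORS) / (mean(qVVOR) * asym_VVOR).
    """
    for g in (qvvor_r, qvvor_l, qvors_r, qvors_l):
        if g <= 0:
            raise ValidationError("bilateral SI requires four positive gains")
    asym_vvor = compute_asymmetry(qvvor_r, qvvor_l)
    asym_vors = compute_asymmetry(qvors_r, qvors_l)
    mean_vvor = 0.5 * (qvvor_r + qvvor_l)
    mean_vors = 0.5 * (qvors_r + qvors_l)
    si = (mean_vors * asym_vors) / (mean_vvor * asym_vvor)
    return si, asym_vvor, asym_vors


def compute_indices(record: SubjectRecord) -> SuppressionIndices:
    """All five suppression quantities for one analyzed subject."""
    si_r, flags_r = compute_unilateral_si(record.qvors_gain_r, record.qvvor_gain_r)
    si_l, flags_l = compute_unilateral_si(record.qvors_gain_l, record.qvvor_gain_l)
    si_bi, asym_vvor, asym_vors = compute_bilateral_si(
        record.qvvor_gain_r, record.qvvor_gain_l,
        record.qvors_gain_r, record.qvors_gain_l,
    )
    return SuppressionIndices(
        si_right=si_r,
        si_left=si_l,
        asym_vvor=asym_vvor,
        asym_vors=asym_vors,
        si_bilateral=si_bi,
        flags=[f"right: {m}" for m in flags_r] + [f"left: {m}" for m in flags_l],
    )


def percentile_placement(
    si_value: float, which_index: str, table: NormativeTable | None = None
) -> str:
    """Place an SI on the normative percentile table.

    Returns ``"below p5"``, ``"above p95"``, an exact level like ``"p50"``,
    or the bracketing band like ``"p25-p50"``.
    """
    table = table or load_normative_table()
    values = table.column(which_index)
    levels = table.levels
    if si_value < values[0]:
        return f"below p{levels[0]}"
    if si_value > values[-1]:
        return f"above p{levels[-1]}"
    exact = np.flatnonzero(np.isclose(values, si_value, rtol=0, atol=1e-12))
    if exact.size:
        return f"p{levels[int(exact[0])]}"
    hi = int(np.searchsorted(values, si_value))
    return f"p{levels[hi - 1]}-p{levels[hi]}"
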