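"""Study-level assembly: pair recordings, screen, index, and report.

This module ties the per-recording gain analysis to per-subject suppression
indices and the cohort statistics battery.  It operates either on an
in-memory simulated cohort or on a directory of trace CSVs following the
``<subject_id>_<paradigm>.csv`` pairing convention plus a subject table.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import cohort_stats as cs
from .errors import QvorError, ValidationError
from .gain_core import DesaccadeParams, analyze_paradigm
from .preprocess import AnalysisWindow, DEFAULT_WINDOW
from .io_vhit import (
    Paradigm,
    SubjectRecord,
    read_subject_table,
    read_velocity_trace,
)
from .suppression import compute_indices, himp_inclusion_filter
from .synthetic import SimulatedCohort

__all__ = [
    "analyze_subject",
    "analyze_cohort",
    "analyze_directory",
    "cohort_report",
    "FREQUENCY_TARGET_HZ",
]

logger = logging.getLogger(__name__)

#: Metronome-paced nominal oscillation frequency of the protocol.
FREQUENCY_TARGET_HZ = 0.75


def analyze_subject(
    record: SubjectRecord,
    trace_vvor,
    trace_vors,
    params: DesaccadeParams = DesaccadeParams(),
    window: AnalysisWindow = DEFAULT_WINDOW,
) -> dict:
    """Analyze one subject's paired recordings into a result row.

    Fills the record's sinusoidal gains/frequencies, computes all
    suppression indices, and returns a flat dict (one report row).
    """
    res_vvor = analyze_paradigm(trace_vvor, params, window=window)
    res_vors = analyze_paradigm(trace_vors, params, window=window)
    record.qvvor_gain_r = res_vvor.gain_right
    record.qvvor_gain_l = res_vvor.gain_left
    record.qvors_gain_r = res_vors.gain_right
    record.qvors_gain_l = res_vors.gain_left
    record.freq_vvor = res_vvor.frequency_hz
    record.freq_vors = res_vors.frequency_hz
    indices = compute_indices(record)
    row = {
        "subject_id": record.subject_id,
        "age": record.age,
        "sex": record.sex,
        "himp_gain_r": record.himp_gain_r,
        "himp_gain_l": record.himp_gain_l,
        "shimp_gain_r": record.shimp_gain_r,
        "shimp_gain_l": record.shimp_gain_l,
        "qvvor_gain_r": record.qvvor_gain_r,
        "qvvor_gain_l": record.qvvor_gain_l,
        "qvors_gain_r": record.qvors_gain_r,
        "qvors_gain_l": record.qvors_gain_l,
        "freq_vvor": record.freq_vvor,
        "freq_vors": record.freq_vors,
        "si_right": indices.si_right,
        "si_left": indices.si_left,
        "asym_vvor": indices.asym_vvor,
        "asym_vors": indices.asym_vors,
        "si_bilateral": indices.si_bilateral,
        "flags": "; ".join(indices.flags),
    }
    return row


def analyze_cohort(
    cohort: SimulatedCohort,
    params: DesaccadeParams = DesaccadeParams(),
    window: AnalysisWindow = DEFAULT_WINDOW,
) -> tuple[pd.DataFrame, list[dict]]:
    """Run the full pipeline on an in-memory simulated cohort.

    Returns the per-subject results table (screen-passing subjects only) and
    the list of exclusions ``[{subject_id, reason}, ...]``.
    """
    rows, exclusions = [], []
    for record in cohort.records:
        include, reason = himp_inclusion_filter(record)
        if not include:
            exclusions.append({"subject_id": record.subject_id, "reason": reason})
            continue
        rows.append(
            analyze_subject(
                record,
                cohort.traces[(record.subject_id, Paradigm.VVOR)],
                cohort.traces[(record.subject_id, Paradigm.VORS)],
                params,
                window,
            )
        )
    return pd.DataFrame(rows), exclusions


def _pair_traces(directory: Path) -> dict[str, dict[Paradigm, Path]]:
    pairs: dict[str, dict[Paradigm, Path]] = {}
    for path in sorted(directory.glob("*_*.csv")):
        stem = path.stem
        sid, _, tag = stem.rpartition("_")
        if tag not in (p.value for p in Paradigm) or not sid:
            continue
        pairs.setdefault(sid, {})[Paradigm(tag)] = path
    return pairs


def analyze_directory(
    directory: str | Path,
    subject_table: str | Path | None = None,
    params: DesaccadeParams = DesaccadeParams(),
    window: AnalysisWindow = DEFAULT_WINDOW,
) -> tuple[pd.DataFrame, list[dict], list[dict]]:
    """Analyze every paired recording under ``directory``.

    Subjects present in the optional subject table are screened with the
    HIMP inclusion rule; per-file failures are collected, not fatal.
    Returns ``(results, exclusions, failures)``.
    """
    directory = Path(directory)
    if subject_table is None:
        candidate = directory / "subjects.csv"
        subject_table = candidate if candidate.exists() else None
    records: dict[str, SubjectRecord] = {}
    if subject_table is not None:
        records = {r.subject_id: r for r in read_subject_table(subject_table)}

    rows, exclusions, failures = [], [], []
    for sid, paths in _pair_traces(directory).items():
        missing = [p.value for p in Paradigm if p not in paths]
        if missing:
            failures.append(
                {"subject_id": sid,
                 "error": f"unpaired traces: missing {', '.join(missing)}"}
            )
            continue
        record = records.get(sid) or SubjectRecord(
            subject_id=sid, age=0.0, sex="F"
        )
        if sid in records:
            include, reason = himp_inclusion_filter(record)
            if not include:
                exclusions.append({"subject_id": sid, "reason": reason})
                continue
        try:
            trace_vvor = read_velocity_trace(
                paths[Paradigm.VVOR], subject_id=sid, paradigm=Paradigm.VVOR
            )
            trace_vors = read_velocity_trace(
                paths[Paradigm.VORS], subject_id=sid, paradigm=Paradigm.VORS
            )
            rows.append(
                analyze_subject(record, trace_vvor, trace_vors, params, window)
            )
        except (QvorError, pd.errors.ParserError, OSError) as exc:
            logger.error("subject %s failed: %s", sid, exc)
            failures.append({"subject_id": sid, "error": str(exc)})
    return pd.DataFrame(rows), exclusions, failures


_GAIN_MEASURES = [
    "himp_gain_r", "himp_gain_l", "shimp_gain_r", "shimp_gain_l",
    "qvvor_gain_r", "qvvor_gain_l", "qvors_gain_r", "qvors_gain_l",
]
_SI_MEASURES = ["si_right", "si_left", "si_bilateral"]


def cohort_report(results: pd.DataFrame) -> dict:
    """The full cohort statistics battery on an analyzed subject table.

    Blocks: gain/SI summaries (overall, by sex, by age bin), normality
    screening, achieved-frequency tests against the 0.75 Hz target, bilateral
    SI sex comparison, Levene + one-way ANOVA across age bins, and the SI
    percentile table.  Deterministic; JSON-serializable.
    """
    if len(results) < 2:
        raise ValidationError("cohort report needs at least 2 subjects")
    measures = [m for m in _GAIN_MEASURES + _SI_MEASURES if m in results.columns]

    report: dict = {"n_subjects": int(len(results))}
    report["summary_overall"] = [
        asdict(s) for s in cs.summarize_cohort(results, measures)
    ]
    report["summary_by_age"] = [
        asdict(s) for s in cs.summarize_cohort(results, _SI_MEASURES, group_by="age")
    ]

    report["normality"] = {
        m: asdict(cs.test_normality(results[m].dropna()))
        for m in _SI_MEASURES
        if results[m].notna().sum() >= 5
    }

    report["frequency_tests"] = {}
    for col in ("freq_vvor", "freq_vors"):
        vals = results[col].dropna()
        if len(vals) >= 6:
            res = cs.test_frequency_vs_target(vals, FREQUENCY_TARGET_HZ)
            report["frequency_tests"][col] = {
                **asdict(res), "mean_frequency_hz": float(vals.mean()),
            }

    sexes = results["sex"].dropna().unique()
    if len(sexes) == 2 and results.groupby("sex")["si_bilateral"].count().min() >= 2:
        res = cs.compare_groups(results["si_bilateral"], results["sex"])
        group_means = results.groupby("sex")["si_bilateral"].mean().to_dict()
        report["summary_by_sex"] = [
            asdict(s)
            for s in cs.summarize_cohort(results, _SI_MEASURES, group_by="sex")
        ]
        report["sex_comparison"] = {**asdict(res), "group_means": group_means}
    else:
        report["sex_comparison"] = {"skipped": "need two sexes with n >= 2 each"}
        logger.info("sex comparison skipped: single-sex cohort")

    age_labels = results["age"].map(cs.age_bin_label)
    multi = age_labels.value_counts()
    usable = multi[multi >= 2].index
    mask = age_labels.isin(usable)
    if usable.size >= 2:
        levene, anova = cs.anova_by_groups(
            results.loc[mask, "si_bilateral"], age_labels[mask]
        )
        report["age_groups"] = {"levene": asdict(levene), "anova": asdict(anova)}
    else:
        report["age_groups"] = {"skipped": "need >= 2 age bins with n >= 2"}

    report["percentiles"] = {
        m: {f"p{int(lv)}": v
            for lv, v in cs.compute_percentiles(results[m].dropna()).items()}
        for m in _SI_MEASURES
    }
    return report
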