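"""Reporting surfaces: classification tables, stratified summaries, stats report.

Rendering conventions follow clinical-study style: percentages displayed as
whole numbers, p-values to three decimals with a "<0.001" floor, medians with
interquartile ranges.  Machine-readable output (JSON / CSV) keeps full
precision; rounding is applied only in rendered tables.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .classifier import poor_outcome
from .cohort_model import ComplicationCall, Outcome, PatientRecord, Timepoint
from .cohort_stats import (
    OrEstimate,
    ProportionEstimate,
    chisq_contingency,
    kruskal_wallis,
    logistic_or,
    proportion_ci,
)
from .lus_scoring import score_exam
from .physiology import OewsChart, load_default_chart, oews, sf_ratio

__all__ = [
    "fmt_p",
    "exam_calls_frame",
    "patient_calls_frame",
    "stratum_table",
    "prevalence_report",
    "outcome_model_report",
    "characteristics_table",
    "full_report",
]

COMPLICATION_TYPES = ["ards", "fluid_overload", "pneumonia", "atelectasis", "effusion"]

GROUPS = [  # (distress, complication) in display order
    ((True, True), "distress_with_complication"),
    ((True, False), "distress_no_complication"),
    ((False, True), "no_distress_with_complication"),
    ((False, False), "no_distress_no_complication"),
]


def fmt_p(p: float) -> str:
    """Display a p-value to three decimals with a '<0.001' floor."""
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def _group_of(call: ComplicationCall) -> tuple[bool, bool]:
    return (call.respiratory_distress_any, call.any_complication)


def exam_calls_frame(calls: list[ComplicationCall]) -> pd.DataFrame:
    """One row per classified exam, with the five complication flags."""
    rows = []
    for c in calls:
        for e in c.exam_calls:
            rows.append({
                "patient_id": e.patient_id,
                "timepoint": e.timepoint.value,
                "hours_from_admission": e.hours_from_admission,
                **{t: getattr(e, t) for t in COMPLICATION_TYPES},
            })
    return pd.DataFrame(rows)


def patient_calls_frame(calls: list[ComplicationCall]) -> pd.DataFrame:
    """One row per patient: stay-level flags and onset category."""
    rows = []
    for c in calls:
        rows.append({
            "patient_id": c.patient_id,
            "respiratory_distress_any": c.respiratory_distress_any,
            "any_complication": c.any_complication,
            "types_present": ";".join(sorted(c.types_present)),
            "first_onset": c.first_onset.value,
            "poor_outcome": c.poor_outcome,
        })
    return pd.DataFrame(rows)


def stratum_table(
    cohort: list[PatientRecord], calls: list[ComplicationCall], yates: bool = True
) -> pd.DataFrame:
    """Four-stratum summary (complication types and outcomes per group).

    Rows: the five complication types (n and % of the group; counts are
    non-exclusive categories), then poor outcome / death / transfer.  Columns
    are the four distress x complication groups with their sizes, plus the
    chi-square p-value comparing complication prevalence across strata.
    """
    by_pid = {p.patient_id: p for p in cohort}
    members = {g: [c for c in calls if _group_of(c) == g] for g, _ in GROUPS}
    rows = {}
    for t in COMPLICATION_TYPES:
        rows[t] = [sum(t in c.types_present for c in members[g]) for g, _ in GROUPS]
    rows["poor_outcome"] = [sum(c.poor_outcome for c in members[g]) for g, _ in GROUPS]
    rows["death"] = [
        sum(by_pid[c.patient_id].outcome is Outcome.DIED for c in members[g])
        for g, _ in GROUPS
    ]
    rows["transfer"] = [
        sum(by_pid[c.patient_id].outcome is Outcome.TRANSFERRED for c in members[g])
        for g, _ in GROUPS
    ]
    frame = pd.DataFrame(rows, index=[f"{name} (n={len(members[g])})" for g, name in GROUPS]).T
    sizes = [len(members[g]) for g, _ in GROUPS]
    pcts = frame.to_numpy(dtype=float) / np.maximum(np.array(sizes, dtype=float), 1) * 100
    for j, col in enumerate(frame.columns):
        frame[col] = [f"{int(n)} ({pcts[i, j]:.1f})" for i, n in enumerate(frame[col])]
    # distress strata complication contrast: [[with, without] per stratum]
    contrast = np.array([
        [len(members[(True, True)]), len(members[(True, False)])],
        [len(members[(False, True)]), len(members[(False, False)])],
    ])
    if contrast.sum(axis=0).min() > 0 and contrast.sum(axis=1).min() > 0:
        _, p = chisq_contingency(contrast, yates=yates)
        p_display = fmt_p(p)
    else:  # degenerate margins: no contrast to test
        p_display = ""
    frame["p_value"] = [p_display if t == "ards" else "" for t in frame.index]
    return frame


def prevalence_report(
    cohort: list[PatientRecord],
    calls: list[ComplicationCall],
    ci_method: str = "clopper_pearson",
    yates: bool = True,
) -> dict:
    """Prevalence estimates, onset timing, and LUS-score summaries (full precision)."""
    n = len(cohort)
    by_pid = {p.patient_id: p for p in cohort}

    def prop(x: int, d: int) -> dict:
        est: ProportionEstimate = proportion_ci(x, d, method=ci_method)
        return {
            "numerator": est.numerator, "denominator": est.denominator,
            "percent": est.point, "ci_low": est.ci_low, "ci_high": est.ci_high,
            "method": est.method,
        }

    overall = sum(c.any_complication for c in calls)
    distress = [c for c in calls if c.respiratory_distress_any]
    no_distress = [c for c in calls if not c.respiratory_distress_any]
    d_comp = sum(c.any_complication for c in distress)
    nd_comp = sum(c.any_complication for c in no_distress)
    table = [[d_comp, len(distress) - d_comp], [nd_comp, len(no_distress) - nd_comp]]
    stat, p_strata = chisq_contingency(table, yates=yates)

    onset = {}
    for key, group in (("distress", distress), ("no_distress", no_distress)):
        pos = [c for c in group if c.any_complication]
        onset[key] = {
            cat: {
                "count": sum(c.first_onset.value == cat for c in pos),
                "percent": (100.0 * sum(c.first_onset.value == cat for c in pos) / len(pos))
                if pos else float("nan"),
            }
            for cat in ("admission", "first_24h", "thereafter")
        }

    pos_scores, neg_scores = [], []
    for c in calls:
        exams = {e.timepoint: e for e in by_pid[c.patient_id].exams}
        for e in c.exam_calls:
            g = score_exam(exams[e.timepoint]).global_score
            (pos_scores if e.any_flag else neg_scores).append(g)

    def med_iqr(vals: list) -> dict:
        if not vals:
            return {"median": float("nan"), "q1": float("nan"), "q3": float("nan"), "n": 0}
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        return {"median": float(med), "q1": float(q1), "q3": float(q3), "n": len(vals)}

    return {
        "n_patients": n,
        "any_complication": prop(overall, n),
        "by_stratum": {
            "distress": prop(d_comp, len(distress)) if distress else None,
            "no_distress": prop(nd_comp, len(no_distress)) if no_distress else None,
            "chi2_statistic": stat,
            "p_value": p_strata,
            "yates": yates,
        },
        "period_prevalence_by_type": {
            t: prop(sum(t in c.types_present for c in calls), n)
            for t in COMPLICATION_TYPES
        },
        "onset_timing": onset,
        "lus_score": {
            "complication_positive_exams": med_iqr(pos_scores),
            "negative_exams": med_iqr(neg_scores),
        },
        "outcomes": {
            "poor_outcome": prop(sum(c.poor_outcome for c in calls), n),
            "deaths": sum(p.outcome is Outcome.DIED for p in cohort),
            "transfers": sum(p.outcome is Outcome.TRANSFERRED for p in cohort),
        },
    }


def outcome_model_report(
    cohort: list[PatientRecord],
    calls: list[ComplicationCall],
    chart: Optional[OewsChart] = None,
) -> dict:
    """Association of any-complication with poor outcome.

    Reports the unadjusted logistic odds ratio and the odds ratio adjusted
    for severity of illness on admission (OEWS entered as a continuous
    integer covariate).
    """
    chart = chart or load_default_chart()
    y = [int(c.poor_outcome) for c in calls]
    x = [int(c.any_complication) for c in calls]
    by_pid = {p.patient_id: p for p in cohort}
    scores = [
        oews(by_pid[c.patient_id].observation_for(Timepoint.ADMISSION), chart)
        for c in calls
    ]

    def as_dict(est: OrEstimate) -> dict:
        return {
            "odds_ratio": est.odds_ratio, "ci_low": est.ci_low, "ci_high": est.ci_high,
            "adjusted_for": est.adjusted_for, "converged": est.converged,
            "message": est.message,
        }

    return {
        "unadjusted": as_dict(logistic_or(y, x)),
        "adjusted": as_dict(
            logistic_or(y, x, covariates=np.array(scores), covariate_names=["oews"])
        ),
    }


def characteristics_table(
    cohort: list[PatientRecord], calls: list[ComplicationCall]
) -> pd.DataFrame:
    """Baseline characteristics by study group: median (IQR) or n (%), with p-values.

    Numeric rows are compared across the four groups with Kruskal-Wallis;
    binary rows with the chi-square test (no Yates beyond 2x2).  With fewer
    than two non-degenerate groups the p-value is left blank.
    """
    by_pid = {p.patient_id: p for p in cohort}
    groups = {g: [by_pid[c.patient_id] for c in calls if _group_of(c) == g]
              for g, _ in GROUPS}

    def admission_obs(p: PatientRecord):
        return p.observation_for(Timepoint.ADMISSION)

    numeric_rows = {
        "age_years": lambda p: p.age,
        "bmi_kg_m2": lambda p: p.bmi,
        "respiratory_rate": lambda p: admission_obs(p).respiratory_rate,
        "spo2_fio2_ratio": lambda p: sf_ratio(
            admission_obs(p).spo2, admission_obs(p).o2_flow_lpm),
        "heart_rate": lambda p: admission_obs(p).heart_rate,
        "hemoglobin_g_dl": lambda p: admission_obs(p).hemoglobin_g_dl,
        "lactate_mmol_l": lambda p: admission_obs(p).lactate_mmol_l,
        "length_of_stay_days": lambda p: p.length_of_stay_days,
    }
    binary_rows = {
        "oxygen_therapy": lambda p: admission_obs(p).o2_flow_lpm > 0,
        "malaria_positive": lambda p: p.malaria_positive,
        "general_anesthesia": lambda p: p.anesthesia.value == "general",
        "transfusion": lambda p: admission_obs(p).transfusion,
    }

    records = []
    for name, fn in numeric_rows.items():
        cells, samples = [], []
        for g, _ in GROUPS:
            vals = [fn(p) for p in groups[g] if fn(p) is not None]
            samples.append(vals)
            if vals:
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
                cells.append(f"{med:.1f} ({q1:.1f}, {q3:.1f})")
            else:
                cells.append("-")
        usable = [s for s in samples if s]
        if len(usable) >= 2 and len(set(v for s in usable for v in s)) > 1:
            _, p = kruskal_wallis(usable)
            cells.append(fmt_p(p))
        else:
            cells.append("")
        records.append([name, *cells])
    for name, fn in binary_rows.items():
        cells, counts = [], []
        for g, _ in GROUPS:
            k = sum(bool(fn(p)) for p in groups[g])
            m = len(groups[g])
            counts.append([k, m - k])
            cells.append(f"{k} ({100.0 * k / m:.1f})" if m else "-")
        table = [row for row in counts if sum(row) > 0]
        if len(table) >= 2 and sum(row[0] for row in table) not in (0, sum(map(sum, table))):
            _, p = chisq_contingency(table, yates=False)
            cells.append(fmt_p(p))
        else:
            cells.append("")
        records.append([name, *cells])

    columns = ["variable"] + [f"{name} (n={len(groups[g])})" for g, name in GROUPS] + ["p_value"]
    return pd.DataFrame(records, columns=columns).set_index("variable")


def full_report(
    cohort: list[PatientRecord],
    calls: list[ComplicationCall],
    ci_method: str = "clopper_pearson",
    yates: bool = True,
    chart: Optional[OewsChart] = None,
) -> dict:
    """The complete stats report keyed by analysis name (full precision)."""
    return {
        "prevalence": prevalence_report(cohort, calls, ci_method=ci_method, yates=yates),
        "outcome_model": outcome_model_report(cohort, calls, chart=chart),
    }
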