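"""Synthetic cohorts: a deterministic study fixture and a seeded simulator.

Two generators are provided.

:func:`build_paper_fixture` constructs, deterministically and without any
randomness, a cohort of 166 granular patient records — region-level
aeration scores and artifact flags, vitals, oxygen therapy, fluid balances,
IVC diameters, comorbidity flags and outcomes, **never** complication
labels — arranged so that running the rule engine over it reproduces the
published group structure exactly: strata 21/36/14/95 by respiratory
distress x complication, the per-stratum complication-type counts,
outcome counts, the timing-of-onset distribution, the exam schedule
(166 admission + 121 at 24 h + 86 at 48 h + 10 event exams), and the
global-aeration-score distribution of positive versus negative exams
(median 4, IQR 3-9, versus median 0, IQR 0-1).  The builder self-verifies
by running the classifier and raising :class:`FixtureError` on any
mismatch, so every printed count is asserted at build time.

:func:`simulate_cohort` draws granular cohorts from a configurable
generative model (distress prevalence, per-stratum complication
probabilities, vitals distributions calibrated to the study's medians and
IQRs, and a logistic outcome model with a configurable odds ratio); region
patterns are generated conditional on the assigned class so the classifier
recovers the generative labels.  :func:`simulate_outcome_frame` is a
vectorized label-level counterpart used for parameter-recovery studies at
large n.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .classifier import classify_cohort
from .cohort_model import (
    AdmissionReason,
    Anesthesia,
    Avpu,
    ClinicalObservation,
    ComplicationCall,
    DeliverySurgery,
    LusExam,
    OnsetCategory,
    Outcome,
    PatientRecord,
    RegionFinding,
    RegionId,
    Timepoint,
)
from .lus_scoring import score_exam
from .physiology import load_default_chart, oews

__all__ = [
    "FixtureError",
    "FIXTURE_EXPECTED",
    "build_paper_fixture",
    "verify_fixture",
    "SimulationConfig",
    "simulate_cohort",
    "simulate_outcome_frame",
    "label_recovery",
]


class FixtureError(RuntimeError):
    """The deterministic fixture failed its build-time self-verification."""


# ---------------------------------------------------------------------------
# Region-pattern builders (shared by the fixture and the simulator)
# ---------------------------------------------------------------------------

_L = [r for r in RegionId if r.side == "L"]
_R = [r for r in RegionId if r.side == "R"]

#: anchor regions guaranteeing >= 2 B-pattern regions per hemithorax
_BILATERAL_ANCHORS = [
    RegionId.L_VENTRAL_SUPERIOR,
    RegionId.R_VENTRAL_SUPERIOR,
    RegionId.L_VENTRAL_INFERIOR,
    RegionId.R_VENTRAL_INFERIOR,
]
_BILATERAL_EXTRAS = [
    RegionId.L_LATERAL_SUPERIOR,
    RegionId.R_LATERAL_SUPERIOR,
    RegionId.L_LATERAL_INFERIOR,
    RegionId.R_LATERAL_INFERIOR,
    RegionId.L_POSTEROLATERAL_SUPERIOR,
    RegionId.R_POSTEROLATERAL_SUPERIOR,
    RegionId.L_POSTEROLATERAL_INFERIOR,
    RegionId.R_POSTEROLATERAL_INFERIOR,
]


def _assemble(scores: dict[RegionId, int], effusion_on: Sequence[RegionId] = ()) -> list[RegionFinding]:
    return [
        RegionFinding(
            region_id=rid,
            examinable=True,
            aeration_score=scores.get(rid, 0),
            effusion=rid in effusion_on,
            subpleural_consolidation=scores.get(rid, 0) == 3,
        )
        for rid in RegionId
    ]


def bilateral_interstitial_pattern(
    global_score: int, with_effusion: bool = False
) -> list[RegionFinding]:
    """B-pattern regions on both sides summing to ``global_score`` (6..24).

    At least two B-pattern regions per hemithorax; scores are 1 or 2 only,
    and the ventral anchor regions never carry an effusion flag, so the
    pattern always satisfies the bilateral-opacity criterion.
    """
    if not 6 <= global_score <= 24:
        raise ValueError("bilateral interstitial pattern supports scores 6..24")
    scores = {rid: 1 for rid in _BILATERAL_ANCHORS}
    rem = global_score - 4
    for rid in _BILATERAL_ANCHORS:
        if rem > 0:
            scores[rid] = 2
            rem -= 1
    for rid in _BILATERAL_EXTRAS:
        if rem >= 2:
            scores[rid] = 2
            rem -= 2
        elif rem == 1:
            scores[rid] = 1
            rem -= 1
    effusion = [RegionId.R_POSTEROLATERAL_INFERIOR] if with_effusion else []
    return _assemble(scores, effusion)


def focal_consolidation_pattern(
    global_score: int, with_effusion: bool = False
) -> list[RegionFinding]:
    """One consolidated region (score 3) plus optional same-side B-pattern (3..5)."""
    if not 3 <= global_score <= 5:
        raise ValueError("focal consolidation pattern supports scores 3..5")
    scores = {RegionId.R_POSTEROLATERAL_INFERIOR: 3}
    if global_score > 3:
        scores[RegionId.R_LATERAL_INFERIOR] = global_score - 3
    effusion = [RegionId.R_POSTEROLATERAL_INFERIOR] if with_effusion else []
    return _assemble(scores, effusion)


def focal_interstitial_pattern(
    global_score: int, with_effusion: bool = False
) -> list[RegionFinding]:
    """Focal/multifocal B-pattern on one side, no consolidation (2..4)."""
    if not 2 <= global_score <= 4:
        raise ValueError("focal interstitial pattern supports scores 2..4")
    scores = {RegionId.R_LATERAL_SUPERIOR: 2}
    if global_score > 2:
        scores[RegionId.R_LATERAL_INFERIOR] = global_score - 2
    effusion = [RegionId.R_POSTEROLATERAL_INFERIOR] if with_effusion else []
    return _assemble(scores, effusion)


def effusion_only_pattern(global_score: int) -> list[RegionFinding]:
    """Pleural effusion in one region with at most a minor focal B-pattern (0..2)."""
    if not 0 <= global_score <= 2:
        raise ValueError("effusion-only pattern supports scores 0..2")
    scores = {}
    if global_score > 0:
        scores[RegionId.L_LATERAL_INFERIOR] = global_score
    return _assemble(scores, [RegionId.R_POSTEROLATERAL_INFERIOR])


def negative_pattern(global_score: int) -> list[RegionFinding]:
    """A negative exam: no effusion, no consolidation, a single focal B region at most."""
    if not 0 <= global_score <= 2:
        raise ValueError("negative pattern supports scores 0..2")
    scores = {}
    if global_score > 0:
        scores[RegionId.L_VENTRAL_INFERIOR] = global_score
    return _assemble(scores)


_PATTERNS = {
    "ards": bilateral_interstitial_pattern,
    "fluid_overload": bilateral_interstitial_pattern,
    "pneumonia": focal_interstitial_pattern,
    "atelectasis": focal_consolidation_pattern,
}


# ---------------------------------------------------------------------------
# The deterministic fixture
# ---------------------------------------------------------------------------

#: Every published count the fixture reproduces; asserted at build time.
FIXTURE_EXPECTED = {
    "n_patients": 166,
    "strata": {  # (distress, complication) -> patients
        (True, True): 21,
        (True, False): 36,
        (False, True): 14,
        (False, False): 95,
    },
    "any_complication": 35,
    "types_distress": {
        "ards": 6,
        "fluid_overload": 6,
        "effusion": 8,
        "pneumonia": 2,
        "atelectasis": 6,
    },
    "types_no_distress": {"effusion": 3, "pneumonia": 1, "atelectasis": 11},
    "poor_outcome_by_group": [6, 5, 3, 4],
    "deaths_by_group": [0, 5, 1, 2],
    "transfers_by_group": [6, 0, 2, 2],
    "onset_distress": {"admission": 14, "first_24h": 5, "thereafter": 2},
    "onset_no_distress": {"admission": 8, "first_24h": 5, "thereafter": 1},
    "exam_schedule": {"admission": 166, "h24": 121, "h48": 86, "event": 10},
    "positive_exam_score_median_iqr": (4.0, 3.0, 9.0),
    "negative_exam_score_median_iqr": (0.0, 0.0, 1.0),
}

# global-score multisets (verified to yield the published medians/IQRs)
_ARDS_SCORES = [8, 8, 9, 9, 9, 9, 10, 10, 12, 12, 12, 12, 14, 14, 16, 16, 18, 18, 20, 22, 24]
_FO_SCORES = [6, 6, 6, 6, 7, 7, 7, 8, 8, 8, 9, 9, 9, 9, 10, 10, 11, 12, 12]
_PNEUMONIA_SCORES = [2, 2, 3, 3, 3, 4, 4]
_ATELECTASIS_SCORES = [3] * 20 + [4] * 18 + [5] * 5
_EFFUSION_SCORES = [1, 1, 2, 2, 2, 2]
_NEGATIVE_SCORES = [0] * 190 + [1] * 70 + [2] * 27

_ONSET_HOURS = {"admission": 0.0, "h24": 24.0, "event30": 30.0, "h48": 48.0}


class _Plan:
    """Declarative description of one fixture patient."""

    __slots__ = (
        "pid", "group", "ptype", "coexist_effusion", "onset",
        "has_h24", "has_h48", "has_event", "outcome",
    )

    def __init__(self, pid, group, ptype, coexist_effusion, onset,
                 has_h24, has_h48, has_event, outcome):
        self.pid = pid
        self.group = group          # 'A' distress+comp, 'B' distress only,
        self.ptype = ptype          # 'C' comp only, 'D' neither
        self.coexist_effusion = coexist_effusion
        self.onset = onset          # key of _ONSET_HOURS or None
        self.has_h24 = has_h24
        self.has_h48 = has_h48
        self.has_event = has_event
        self.outcome = outcome


def _fixture_plans() -> list[_Plan]:
    plans: list[_Plan] = []

    def pid(i: int) -> str:
        return f"P{i:03d}"

    # --- group A: respiratory distress with complication (21 patients) ---
    a_types = (["ards"] * 6 + ["fluid_overload"] * 6 + ["pneumonia"] * 2
               + ["atelectasis"] * 6 + ["effusion"])
    a_coexist = {1, 2, 7, 8, 13, 15, 16}          # 7 coexisting effusion flags
    a_onset = {5: "h24", 6: "event30", 11: "h24", 12: "h48",
               14: "h24", 19: "h24", 20: "h24"}   # default: admission
    a_transfer = {1, 2, 3, 4, 5, 6}
    for k in range(1, 22):
        plans.append(_Plan(
            pid=pid(k), group="A", ptype=a_types[k - 1],
            coexist_effusion=k in a_coexist,
            onset=a_onset.get(k, "admission"),
            has_h24=True, has_h48=True, has_event=k <= 10,
            outcome=Outcome.TRANSFERRED if k in a_transfer else Outcome.DISCHARGED,
        ))

    # --- group B: respiratory distress without complication (36) ---
    for k in range(22, 58):
        plans.append(_Plan(
            pid=pid(k), group="B", ptype=None, coexist_effusion=False, onset=None,
            has_h24=True, has_h48=True, has_event=False,
            outcome=Outcome.DIED if k <= 26 else Outcome.DISCHARGED,
        ))

    # --- group C: complication without respiratory distress (14) ---
    c_types = ["atelectasis"] * 11 + ["pneumonia"] + ["effusion"] * 2
    c_onset = {7: "h24", 8: "h24", 9: "h24", 10: "h24", 11: "h48", 14: "h24"}
    c_outcomes = {1: Outcome.DIED, 2: Outcome.TRANSFERRED, 3: Outcome.TRANSFERRED}
    for j in range(1, 15):
        k = 57 + j
        plans.append(_Plan(
            pid=pid(k), group="C", ptype=c_types[j - 1],
            coexist_effusion=j == 11,
            onset=c_onset.get(j, "admission"),
            has_h24=True, has_h48=j <= 11, has_event=False,
            outcome=c_outcomes.get(j, Outcome.DISCHARGED),
        ))

    # --- group D: neither (95) ---
    d_outcomes = {1: Outcome.DIED, 2: Outcome.DIED,
                  3: Outcome.TRANSFERRED, 4: Outcome.TRANSFERRED}
    for j in range(1, 96):
        k = 71 + j
        plans.append(_Plan(
            pid=pid(k), group="D", ptype=None, coexist_effusion=False, onset=None,
            has_h24=5 <= j <= 54, has_h48=5 <= j <= 22, has_event=False,
            outcome=d_outcomes.get(j, Outcome.DISCHARGED),
        ))
    return plans


def _fixture_regions(plan: _Plan, positive: bool, score: int) -> list[RegionFinding]:
    if not positive:
        return negative_pattern(score)
    if plan.ptype == "effusion":
        return effusion_only_pattern(score)
    return _PATTERNS[plan.ptype](score, with_effusion=plan.coexist_effusion)


def _fixture_observation(
    plan: _Plan, tp: Timepoint, hours: float, positive: bool, i: int
) -> tuple[ClinicalObservation, Optional[float], Optional[float]]:
    """Observation plus (ivc_max, ivc_min) for one exam; ``i`` = patient index."""
    fields = dict(
        patient_id=plan.pid,
        timepoint=tp,
        respiratory_rate=24.0,
        spo2=99.0,
        o2_flow_lpm=0.0,
        accessory_muscles=False,
        nasal_flaring=False,
        heart_rate=95.0 + (i * 7) % 30,
        systolic_bp=100.0 + (i * 5) % 30,
        diastolic_bp=60.0 + (i * 3) % 25,
        temperature_c=36.5 + 0.1 * (i % 8),
        avpu=Avpu.ALERT,
        hemoglobin_g_dl=6.5 + (i % 40) / 10.0,
        lactate_mmol_l=2.0 + (i % 30) / 10.0,
        wbc_per_mm3=None,
        fluid_balance_24h_ml=None if tp is Timepoint.ADMISSION else 400.0,
        vasopressors=False,
        diuretics=False,
        transfusion=i % 2 == 0,
    )
    ivc: tuple[Optional[float], Optional[float]] = (None, None)

    if plan.group == "A":
        t = plan.ptype
        if t == "ards":
            ivc = (18.0, 10.0)
            if positive:
                fields.update(respiratory_rate=34.0, spo2=92.0, o2_flow_lpm=5.0,
                              accessory_muscles=True)
            else:
                fields.update(respiratory_rate=31.0, spo2=97.0)
        elif t == "fluid_overload":
            fields.update(respiratory_rate=32.0, spo2=96.0)
            if positive:
                ivc = (26.0, 14.0)
                fields.update(diuretics=True)
                if tp is not Timepoint.ADMISSION:
                    fields.update(fluid_balance_24h_ml=1500.0)
            else:
                ivc = (18.0, 10.0)
        elif t == "pneumonia":
            fields.update(respiratory_rate=32.0, spo2=97.0)
            if plan.pid == "P014":  # leukocytosis arm of the definition
                fields.update(respiratory_rate=33.0, temperature_c=37.1,
                              wbc_per_mm3=14500.0 if positive else None)
            else:
                fields.update(temperature_c=38.8 if positive else 37.2)
        elif t == "atelectasis":
            fields.update(respiratory_rate=32.0, spo2=98.0)
        else:  # effusion only
            fields.update(respiratory_rate=31.0, spo2=98.0)
    elif plan.group == "B":
        fields.update(respiratory_rate=32.0 + (i % 5),
                      hemoglobin_g_dl=5.5 + (i % 25) / 10.0,
                      lactate_mmol_l=4.0 + (i % 35) / 10.0)
        if i < 36:  # first 15 of group B (i = 21..35) receive oxygen
            fields.update(spo2=93.0, o2_flow_lpm=3.0)
        else:
            fields.update(spo2=96.0 + (i % 4))
        if i % 5 == 0:
            fields.update(accessory_muscles=True)
    elif plan.group == "C":
        fields.update(respiratory_rate=22.0 + (i % 3), spo2=98.0 + (i % 2))
        if plan.ptype == "pneumonia":
            fields.update(temperature_c=38.8 if positive else 37.0)
    else:  # group D
        fields.update(respiratory_rate=22.0 + (i % 5), spo2=98.0 + (i % 2))
        if i % 4 == 0:
            ivc = (16.0, 9.0)

    return ClinicalObservation(**fields), ivc[0], ivc[1]


def build_paper_fixture() -> list[PatientRecord]:
    """Build the deterministic 166-patient fixture (granular inputs only).

    Two calls return byte-identical cohorts.  The builder runs the rule
    engine on the finished cohort and raises :class:`FixtureError` if any
    published count is not reproduced.
    """
    plans = _fixture_plans()
    score_pools = {
        "ards": list(_ARDS_SCORES),
        "fluid_overload": list(_FO_SCORES),
        "pneumonia": list(_PNEUMONIA_SCORES),
        "atelectasis": list(_ATELECTASIS_SCORES),
        "effusion": list(_EFFUSION_SCORES),
    }
    negative_pool = list(_NEGATIVE_SCORES)

    reasons = (
        [AdmissionReason.ANTEPARTUM_HEMORRHAGE] * 45
        + [AdmissionReason.POSTPARTUM_HEMORRHAGE] * 14
        + [AdmissionReason.UTERINE_RUPTURE] * 22
        + [AdmissionReason.SEVERE_PREECLAMPSIA] * 30
        + [AdmissionReason.OBSTRUCTED_LABOR] * 15
        + [AdmissionReason.ECTOPIC_PREGNANCY] * 7
        + [AdmissionReason.SEPSIS] * 11
        + [AdmissionReason.SICKLE_CELL_DISEASE] * 5
        + [AdmissionReason.OTHER] * 17
    )
    deliveries = (
        [DeliverySurgery.SPONTANEOUS_VAGINAL] * 17
        + [DeliverySurgery.CESAREAN_SECTION] * 68
        + [DeliverySurgery.OTHER_SURGERY] * 37
        + [DeliverySurgery.NONE] * 44
    )
    anesthesias = (
        [Anesthesia.GENERAL] * 84 + [Anesthesia.SPINAL] * 18 + [Anesthesia.NONE] * 64
    )
    # deterministic interleaving so reasons are not group-aligned
    perm = sorted(range(166), key=lambda i: (i * 59) % 166)

    cohort: list[PatientRecord] = []
    for i, plan in enumerate(plans):
        schedule: list[tuple[Timepoint, float]] = [(Timepoint.ADMISSION, 1.0)]
        if plan.has_h24:
            schedule.append((Timepoint.H24, 24.0))
        if plan.has_event:
            schedule.append((Timepoint.EVENT, 30.0))
        if plan.has_h48:
            schedule.append((Timepoint.H48, 48.0))

        onset_hours = _ONSET_HOURS[plan.onset] if plan.onset else math.inf
        exams, observations = [], []
        for tp, hours in schedule:
            positive = hours >= onset_hours
            if positive:
                score = score_pools[plan.ptype].pop(0)
            else:
                score = negative_pool.pop(0)
            obs, ivc_max, ivc_min = _fixture_observation(plan, tp, hours, positive, i)
            exams.append(
                LusExam(
                    patient_id=plan.pid,
                    timepoint=tp,
                    hours_from_admission=hours,
                    regions=_fixture_regions(plan, positive, score),
                    ivc_max_mm=ivc_max,
                    ivc_min_mm=ivc_min,
                )
            )
            observations.append(obs)

        j = perm[i]
        reason = reasons[j]
        cohort.append(
            PatientRecord(
                patient_id=plan.pid,
                age=20.0 + (i * 7) % 21,
                gestational_age=30.0 + i % 10,
                gravidity=1 + i % 5,
                parity=i % 4,
                bmi=(23.0 if plan.group != "C" else 25.0) + (i % 8) * 0.5,
                admission_reason=reason,
                history_cardiac_failure=plan.pid == "P100",
                sickle_cell=reason is AdmissionReason.SICKLE_CELL_DISEASE,
                malaria_positive=i % 14 == 0,
                delivery_surgery=deliveries[j],
                anesthesia=anesthesias[j],
                exams=exams,
                observations=observations,
                outcome=plan.outcome,
                length_of_stay_days={"A": 3.0, "B": 3.0, "C": 3.5, "D": 3.0}[plan.group]
                + (i % 3) * 0.5,
            )
        )

    for name, pool in score_pools.items():
        if pool:
            raise FixtureError(f"unused {name} scores remain: {pool}")
    if negative_pool:
        raise FixtureError(f"{len(negative_pool)} unused negative scores remain")
    verify_fixture(cohort)
    return cohort


def _median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    q1, med, q3 = np.percentile(np.asarray(values, dtype=float), [25, 50, 75])
    return float(med), float(q1), float(q3)


def verify_fixture(cohort: list[PatientRecord]) -> list[ComplicationCall]:
    """Run the classifier over the fixture and assert every published count."""
    exp = FIXTURE_EXPECTED
    calls = classify_cohort(cohort)

    def check(label: str, got, want) -> None:
        if got != want:
            raise FixtureError(f"fixture self-check failed: {label}: got {got!r}, expected {want!r}")

    check("n_patients", len(cohort), exp["n_patients"])

    strata = {(True, True): 0, (True, False): 0, (False, True): 0, (False, False): 0}
    for c in calls:
        strata[(c.respiratory_distress_any, c.any_complication)] += 1
    check("strata", strata, exp["strata"])
    check("any_complication", sum(c.any_complication for c in calls), exp["any_complication"])

    for stratum, key in ((True, "types_distress"), (False, "types_no_distress")):
        counts: dict[str, int] = {}
        for c in calls:
            if c.respiratory_distress_any is stratum and c.any_complication:
                for t in c.types_present:
                    counts[t] = counts.get(t, 0) + 1
        check(key, counts, exp[key])

    groups = [(True, True), (True, False), (False, True), (False, False)]
    by_pid = {p.patient_id: p for p in cohort}
    for metric, want in (
        ("poor_outcome_by_group", exp["poor_outcome_by_group"]),
        ("deaths_by_group", exp["deaths_by_group"]),
        ("transfers_by_group", exp["transfers_by_group"]),
    ):
        got = []
        for g in groups:
            members = [c for c in calls if (c.respiratory_distress_any, c.any_complication) == g]
            if metric == "poor_outcome_by_group":
                got.append(sum(c.poor_outcome for c in members))
            elif metric == "deaths_by_group":
                got.append(sum(by_pid[c.patient_id].outcome is Outcome.DIED for c in members))
            else:
                got.append(sum(by_pid[c.patient_id].outcome is Outcome.TRANSFERRED for c in members))
        check(metric, got, want)

    for stratum, key in ((True, "onset_distress"), (False, "onset_no_distress")):
        onset: dict[str, int] = {}
        for c in calls:
            if c.respiratory_distress_any is stratum and c.any_complication:
                onset[c.first_onset.value] = onset.get(c.first_onset.value, 0) + 1
        check(key, onset, exp[key])

    schedule: dict[str, int] = {}
    for p in cohort:
        for e in p.exams:
            schedule[e.timepoint.value] = schedule.get(e.timepoint.value, 0) + 1
    check("exam_schedule", schedule, exp["exam_schedule"])

    pos_scores, neg_scores = [], []
    for c in calls:
        exams = {e.timepoint: e for e in by_pid[c.patient_id].exams}
        for call in c.exam_calls:
            g = score_exam(exams[call.timepoint]).global_score
            (pos_scores if call.any_flag else neg_scores).append(g)
    check("positive_exam_score_median_iqr", _median_iqr(pos_scores),
          exp["positive_exam_score_median_iqr"])
    check("negative_exam_score_median_iqr", _median_iqr(neg_scores),
          exp["negative_exam_score_median_iqr"])
    return calls


# ---------------------------------------------------------------------------
# Stochastic simulator
# ---------------------------------------------------------------------------

class VitalsParams(BaseModel):
    """Location/scale (on the natural scale) for truncated-normal vitals.

    Locations are the study-cohort medians; scales are IQR/1.349.  Hard
    truncation bounds are applied in the generator to keep each simulated
    patient consistent with its assigned class.
    """

    rr_distress: tuple[float, float] = (31.0, 4.0)
    rr_no_distress: tuple[float, float] = (24.0, 1.6)
    spo2_hypoxemic: tuple[float, float] = (92.0, 2.0)
    spo2_normal: tuple[float, float] = (99.0, 0.8)
    heart_rate: tuple[float, float] = (105.0, 13.0)
    systolic_bp: tuple[float, float] = (110.0, 15.0)
    diastolic_bp: tuple[float, float] = (70.0, 10.0)
    temperature: tuple[float, float] = (37.0, 0.4)
    hemoglobin: tuple[float, float] = (7.9, 2.6)
    lactate: tuple[float, float] = (4.5, 3.3)
    bmi: tuple[float, float] = (23.9, 2.6)
    age: tuple[float, float] = (25.0, 5.9)
    gestational_age: tuple[float, float] = (36.0, 4.4)
    oews_distress: tuple[float, float] = (4.0, 1.8)
    oews_no_distress: tuple[float, float] = (2.8, 1.4)


class SimulationConfig(BaseModel):
    """Generative model for stochastic cohorts; the seed is mandatory.

    Defaults encode the study conditions: 34% respiratory-distress
    prevalence, per-stratum complication probabilities 21/57 and 14/109
    (overall 21%), complication-type mixes and onset timing matching the
    observed distributions, the 166/121/86 exam schedule, and a logistic
    poor-outcome model with odds ratio 5.0 for any complication adjusted
    for the admission early-warning score.
    """

    n_patients: int = Field(default=166, gt=0)
    seed: int
    distress_prevalence: float = Field(default=0.34, ge=0, le=1)
    p_complication_distress: float = Field(default=21.0 / 57.0, ge=0, le=1)
    p_complication_no_distress: float = Field(default=14.0 / 109.0, ge=0, le=1)
    type_probs_distress: dict[str, float] = Field(
        default_factory=lambda: {
            "ards": 6 / 21, "fluid_overload": 6 / 21, "pneumonia": 2 / 21,
            "atelectasis": 6 / 21, "effusion": 1 / 21,
        }
    )
    type_probs_no_distress: dict[str, float] = Field(
        default_factory=lambda: {"atelectasis": 11 / 14, "pneumonia": 1 / 14,
                                 "effusion": 2 / 14}
    )
    p_coexisting_effusion_distress: float = Field(default=7.0 / 20.0, ge=0, le=1)
    p_coexisting_effusion_no_distress: float = Field(default=1.0 / 12.0, ge=0, le=1)
    onset_probs: tuple[float, float, float] = (22 / 35, 10 / 35, 3 / 35)
    p_h24: float = Field(default=121.0 / 166.0, ge=0, le=1)
    p_h48_given_h24: float = Field(default=86.0 / 121.0, ge=0, le=1)
    vitals: VitalsParams = Field(default_factory=VitalsParams)
    outcome_intercept: float = -3.2
    outcome_log_or: float = math.log(5.0)
    outcome_beta_oews: float = 0.15

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        for name in ("type_probs_distress", "type_probs_no_distress"):
            probs = getattr(self, name)
            if any(not 0 <= v <= 1 for v in probs.values()):
                raise ValueError(f"{name}: probabilities must lie in [0, 1]")
            if probs and abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name}: probabilities must sum to 1")
            unknown = set(probs) - {"ards", "fluid_overload", "pneumonia",
                                    "atelectasis", "effusion"}
            if unknown:
                raise ValueError(f"{name}: unknown complication types {sorted(unknown)}")
        if abs(sum(self.onset_probs) - 1.0) > 1e-9 or any(p < 0 for p in self.onset_probs):
            raise ValueError("onset_probs must be non-negative and sum to 1")
        return self


def _trunc_normal(rng: np.random.Generator, loc: float, scale: float,
                  low: float, high: float) -> float:
    """Truncation by resampling (scales here make rejection rare)."""
    for _ in range(64):
        v = rng.normal(loc, scale)
        if low <= v <= high:
            return float(v)
    return float(min(max(loc, low), high))


_SCORE_RANGES = {
    "ards": (8, 16), "fluid_overload": (6, 12), "pneumonia": (2, 4),
    "atelectasis": (3, 5), "effusion": (0, 2),
}


def _simulated_patient(
    rng: np.random.Generator, config: SimulationConfig, index: int
) -> tuple[PatientRecord, dict]:
    v = config.vitals
    distress = rng.random() < config.distress_prevalence
    p_comp = config.p_complication_distress if distress else config.p_complication_no_distress
    complication = rng.random() < p_comp
    ptype = None
    coexist = False
    if complication:
        probs = config.type_probs_distress if distress else config.type_probs_no_distress
        if distress:
            names = ["ards", "fluid_overload", "pneumonia", "atelectasis", "effusion"]
        else:
            names = ["atelectasis", "pneumonia", "effusion"]
        ptype = str(rng.choice(names, p=[probs.get(n, 0.0) for n in names]))
        p_co = (config.p_coexisting_effusion_distress if distress
                else config.p_coexisting_effusion_no_distress)
        coexist = ptype != "effusion" and rng.random() < p_co

    has_h24 = rng.random() < config.p_h24
    has_h48 = has_h24 and rng.random() < config.p_h48_given_h24
    onset_hours = math.inf
    if complication:
        onset = rng.choice(3, p=list(config.onset_probs))
        if onset == 1:
            has_h24 = True
            onset_hours = 24.0
        elif onset == 2:
            has_h24 = has_h48 = True
            onset_hours = 48.0
        else:
            onset_hours = 0.0

    pid = f"S{index:05d}"
    schedule = [(Timepoint.ADMISSION, 1.0)]
    if has_h24:
        schedule.append((Timepoint.H24, 24.0))
    if has_h48:
        schedule.append((Timepoint.H48, 48.0))

    exams, observations = [], []
    for tp, hours in schedule:
        positive = complication and hours >= onset_hours
        if positive:
            low, high = _SCORE_RANGES[ptype]
            g = int(rng.integers(low, high + 1))
            if ptype == "effusion":
                regions = effusion_only_pattern(g)
            else:
                regions = _PATTERNS[ptype](g, with_effusion=coexist)
        else:
            g = int(rng.choice([0, 1, 2], p=[0.66, 0.25, 0.09]))
            regions = negative_pattern(g)

        hypoxemic = positive and ptype == "ards"
        if hypoxemic:
            spo2 = _trunc_normal(rng, *v.spo2_hypoxemic, 85.0, 96.0)
            flow = 5.0
        elif distress:
            spo2 = _trunc_normal(rng, 97.0, 1.2, 94.0, 100.0)
            flow = 0.0
        else:
            spo2 = _trunc_normal(rng, *v.spo2_normal, 97.0, 100.0)
            flow = 0.0
        rr = (_trunc_normal(rng, *v.rr_distress, 30.0, 45.0) if distress
              else _trunc_normal(rng, *v.rr_no_distress, 16.0, 28.0))
        febrile = positive and ptype == "pneumonia"
        temp = (_trunc_normal(rng, 38.8, 0.3, 38.4, 40.0) if febrile
                else _trunc_normal(rng, *v.temperature, 35.5, 38.0))
        overloaded = positive and ptype == "fluid_overload"
        if tp is Timepoint.ADMISSION:
            balance = None
        elif overloaded:
            balance = _trunc_normal(rng, 1600.0, 300.0, 1100.0, 3000.0)
        else:
            balance = _trunc_normal(rng, 400.0, 250.0, -500.0, 900.0)
        ivc_max = _trunc_normal(rng, 26.0, 1.5, 23.5, 32.0) if overloaded else (
            _trunc_normal(rng, 17.0, 2.0, 10.0, 22.5) if rng.random() < 0.5 else None)

        observations.append(ClinicalObservation(
            patient_id=pid, timepoint=tp,
            respiratory_rate=rr, spo2=spo2, o2_flow_lpm=flow,
            accessory_muscles=bool(hypoxemic),
            heart_rate=_trunc_normal(rng, *v.heart_rate, 50.0, 170.0),
            systolic_bp=_trunc_normal(rng, *v.systolic_bp, 70.0, 200.0),
            diastolic_bp=_trunc_normal(rng, *v.diastolic_bp, 40.0, 120.0),
            temperature_c=temp,
            hemoglobin_g_dl=_trunc_normal(rng, *v.hemoglobin, 3.0, 16.0),
            lactate_mmol_l=_trunc_normal(rng, *v.lactate, 0.5, 15.0),
            fluid_balance_24h_ml=balance,
        ))
        exams.append(LusExam(
            patient_id=pid, timepoint=tp, hours_from_admission=hours,
            regions=regions, ivc_max_mm=ivc_max,
            ivc_min_mm=None if ivc_max is None else round(ivc_max * 0.55, 1),
        ))

    reasons = list(AdmissionReason)
    record = PatientRecord(
        patient_id=pid,
        age=_trunc_normal(rng, *v.age, 15.0, 45.0),
        gestational_age=_trunc_normal(rng, *v.gestational_age, 22.0, 42.0),
        gravidity=int(rng.integers(1, 7)),
        parity=int(rng.integers(0, 5)),
        bmi=_trunc_normal(rng, *v.bmi, 17.0, 40.0),
        admission_reason=reasons[int(rng.integers(0, len(reasons)))],
        history_cardiac_failure=False,
        malaria_positive=bool(rng.random() < 0.072),
        delivery_surgery=list(DeliverySurgery)[int(rng.integers(0, 4))],
        anesthesia=list(Anesthesia)[int(rng.integers(0, 3))],
        exams=exams,
        observations=observations,
        outcome=Outcome.DISCHARGED,  # assigned below from the logistic model
        length_of_stay_days=_trunc_normal(rng, 3.0, 1.0, 1.0, 10.0),
    )
    labels = {"distress": distress, "complication": complication,
              "types": (set() if not complication
                        else {ptype} | ({"effusion"} if coexist else set()))}
    return record, labels


def simulate_cohort(
    config: SimulationConfig, return_labels: bool = False
) -> list[PatientRecord] | tuple[list[PatientRecord], list[dict]]:
    """Draw a seeded, reproducible granular cohort from the generative model.

    Region patterns are generated conditional on the assigned complication
    class so the classifier recovers the assigned labels; the poor-outcome
    indicator is drawn from the logistic model (intercept + log-OR x
    any-complication + coefficient x admission OEWS).
    """
    rng = np.random.default_rng(config.seed)
    chart = load_default_chart()
    cohort, labels = [], []
    for index in range(config.n_patients):
        record, lab = _simulated_patient(rng, config, index)
        score = oews(record.observation_for(Timepoint.ADMISSION), chart)
        eta = (config.outcome_intercept
               + config.outcome_log_or * float(lab["complication"])
               + config.outcome_beta_oews * score)
        poor = rng.random() < 1.0 / (1.0 + math.exp(-eta))
        if poor:
            outcome = Outcome.TRANSFERRED if rng.random() < 0.55 else Outcome.DIED
            record = record.model_copy(update={"outcome": outcome})
        lab["oews"] = score
        lab["poor_outcome"] = poor
        cohort.append(record)
        labels.append(lab)
    if return_labels:
        return cohort, labels
    return cohort


def simulate_outcome_frame(config: SimulationConfig, n: Optional[int] = None,
                           rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Vectorized label-level draw from the same generative model.

    Returns a DataFrame with columns ``distress``, ``complication``,
    ``oews`` and ``poor_outcome`` — the resolution needed for outcome-model
    parameter-recovery studies, where materializing full granular records
    adds nothing.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = n or config.n_patients
    v = config.vitals
    distress = rng.random(n) < config.distress_prevalence
    p_comp = np.where(distress, config.p_complication_distress,
                      config.p_complication_no_distress)
    complication = rng.random(n) < p_comp
    loc = np.where(distress, v.oews_distress[0], v.oews_no_distress[0])
    scale = np.where(distress, v.oews_distress[1], v.oews_no_distress[1])
    oews_score = np.clip(np.round(rng.normal(loc, scale)), 0, 14).astype(int)
    eta = (config.outcome_intercept + config.outcome_log_or * complication
           + config.outcome_beta_oews * oews_score)
    poor = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))
    return pd.DataFrame({
        "distress": distress, "complication": complication,
        "oews": oews_score, "poor_outcome": poor,
    })


def label_recovery(cohort: list[PatientRecord], labels: list[dict]) -> float:
    """Fraction of simulated patients whose classifier calls match the labels."""
    calls = classify_cohort(cohort)
    hits = 0
    for call, lab in zip(calls, labels):
        if (call.any_complication == lab["complication"]
                and call.respiratory_distress_any == lab["distress"]
                and call.types_present == lab["types"]):
            hits += 1
    return hits / len(cohort)
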