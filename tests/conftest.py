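"""Shared builders and session-scoped fixtures for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")

from luscohort.classifier import classify_cohort
from luscohort.cohort_model import (
    ClinicalObservation,
    LusExam,
    PatientRecord,
    RegionFinding,
    RegionId,
    Timepoint,
)
from luscohort.physiology import load_default_chart
from luscohort.synthetic_cohort import build_paper_fixture


def make_regions(scores=None, effusion_on=(), unexaminable=()):
    """Build 12 regions; ``scores`` maps RegionId -> 0..3 (default 0)."""
    scores = scores or {}
    return [
        RegionFinding(
            region_id=rid,
            examinable=rid not in unexaminable,
            aeration_score=None if rid in unexaminable else scores.get(rid, 0),
            effusion=rid in effusion_on,
        )
        for rid in RegionId
    ]


def make_exam(scores=None, effusion_on=(), unexaminable=(), ivc_max=None,
              pid="T1", timepoint=Timepoint.ADMISSION, hours=1.0):
    return LusExam(
        patient_id=pid,
        timepoint=timepoint,
        hours_from_admission=hours,
        regions=make_regions(scores, effusion_on, unexaminable),
        ivc_max_mm=ivc_max,
    )


def make_obs(pid="T1", timepoint=Timepoint.ADMISSION, rr=20.0, spo2=99.0, flow=0.0,
             accessory=False, nasal=False, temp=37.0, wbc=None, balance=None, **kw):
    return ClinicalObservation(
        patient_id=pid,
        timepoint=timepoint,
        respiratory_rate=rr,
        spo2=spo2,
        o2_flow_lpm=flow,
        accessory_muscles=accessory,
        nasal_flaring=nasal,
        heart_rate=kw.pop("heart_rate", 95.0),
        systolic_bp=kw.pop("systolic_bp", 110.0),
        diastolic_bp=kw.pop("diastolic_bp", 70.0),
        temperature_c=temp,
        wbc_per_mm3=wbc,
        fluid_balance_24h_ml=balance,
        **kw,
    )


def make_patient(exams, observations, pid="T1", outcome="discharged",
                 cardiac_history=False):
    return PatientRecord(
        patient_id=pid,
        age=25.0,
        gestational_age=36.0,
        gravidity=2,
        parity=1,
        bmi=24.0,
        admission_reason="other",
        history_cardiac_failure=cardiac_history,
        exams=exams,
        observations=observations,
        outcome=outcome,
        length_of_stay_days=3.0,
    )


def single_exam_patient(exam, obs, outcome="discharged", cardiac_history=False):
    return make_patient([exam], [obs], pid=exam.patient_id, outcome=outcome,
                        cardiac_history=cardiac_history)


def random_exam_case(rng: np.random.Generator, pid="X"):
    """A random (exam, observation, patient) triple spanning the rule space."""
    regions = []
    for rid in RegionId:
        examinable = rng.random() > 0.05
        regions.append(
            RegionFinding(
                region_id=rid,
                examinable=examinable,
                aeration_score=int(rng.integers(0, 4)) if examinable else None,
                effusion=bool(rng.random() < 0.15),
            )
        )
    exam = LusExam(
        patient_id=pid,
        timepoint=Timepoint.ADMISSION,
        hours_from_admission=1.0,
        regions=regions,
        ivc_max_mm=float(rng.uniform(10, 30)) if rng.random() < 0.7 else None,
    )
    obs = ClinicalObservation(
        patient_id=pid,
        timepoint=Timepoint.ADMISSION,
        respiratory_rate=float(rng.uniform(12, 45)),
        spo2=float(rng.uniform(80, 100)),
        o2_flow_lpm=float(rng.choice([0.0, 0.0, 2.0, 5.0, 10.0])),
        accessory_muscles=bool(rng.random() < 0.2),
        heart_rate=float(rng.uniform(60, 150)),
        systolic_bp=float(rng.uniform(80, 170)),
        diastolic_bp=float(rng.uniform(50, 110)),
        temperature_c=float(rng.uniform(36, 40)) if rng.random() < 0.8 else None,
        wbc_per_mm3=float(rng.uniform(4000, 20000)) if rng.random() < 0.3 else None,
        fluid_balance_24h_ml=float(rng.uniform(-500, 3000)) if rng.random() < 0.7 else None,
    )
    patient = make_patient(
        [exam], [obs], pid=pid, cardiac_history=bool(rng.random() < 0.1)
    )
    return exam, obs, patient


@pytest.fixture(scope="session")
def fixture_cohort():
    return build_paper_fixture()


@pytest.fixture(scope="session")
def fixture_calls(fixture_cohort):
    return classify_cohort(fixture_cohort)


@pytest.fixture(scope="session")
def default_chart():
    return load_default_chart()
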