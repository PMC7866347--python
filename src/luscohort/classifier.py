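"""Rule engine: per-exam complication calls, stay-level aggregation, outcomes.

Five pulmonary complications are derived from each LUS exam paired with its
clinical observation:

* **effusion** — any region with a pleural-effusion finding; independent of
  all other calls (non-exclusive category).
* **fluid overload** (hydrostatic pulmonary edema) — bilateral interstitial
  syndrome or effusion, together with a positive fluid balance (> 1,000 mL
  over the last 24 h) and/or IVC plethora (maximal diameter > 23 mm).
* **ARDS** — S/F <= 315 plus bilateral opacities (bilateral interstitial
  syndrome and/or bilateral consolidation, not attributable solely to
  effusion), in a patient without a known history of cardiac failure and not
  diagnosed with fluid overload at that exam (origin-of-edema criterion in a
  setting without echocardiography).
* **pneumonia** — focal or multifocal interstitial syndrome and/or
  consolidation (any examinable region scored >= 1) plus fever > 38.3 C or
  white cell count > 12,000/mm3 when a count is available.  With both
  temperature and WBC missing the call is false, not unknown.
* **atelectasis** — focal consolidation (any region scored 3) that does not
  fall in the ARDS, pneumonia or fluid-overload case definitions.

The evaluation order fluid overload -> ARDS -> pneumonia -> atelectasis
encodes the exclusion clauses; it guarantees ARDS and fluid overload are
never both called at one exam, and atelectasis excludes the other three.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort_model import (
    ClinicalObservation,
    ComplicationCall,
    ExamCall,
    LusExam,
    OnsetCategory,
    Outcome,
    PatientRecord,
    Timepoint,
)
from .lus_scoring import bilateral_consolidation, bilateral_interstitial, ivc_plethora
from .physiology import (
    RR_DISTRESS_THRESHOLD,
    SF_DISTRESS_THRESHOLD,
    respiratory_distress,
    sf_ratio,
)

__all__ = [
    "Thresholds",
    "DEFAULT_THRESHOLDS",
    "classify_exam",
    "aggregate_stay",
    "classify_patient",
    "classify_cohort",
    "poor_outcome",
]


@dataclass(frozen=True)
class Thresholds:
    """Case-definition thresholds, overridable for sensitivity analyses.

    Defaults are the study cut-offs: RR >= 30 /min, S/F <= 315, IVC > 23 mm,
    fluid balance > 1000 mL/24 h, temperature > 38.3 C, WBC > 12,000 /mm3.
    """

    rr_per_min: float = RR_DISTRESS_THRESHOLD
    sf: float = SF_DISTRESS_THRESHOLD
    ivc_mm: float = 23.0
    fluid_ml: float = 1000.0
    temperature_c: float = 38.3
    wbc_per_mm3: float = 12000.0


DEFAULT_THRESHOLDS = Thresholds()


def _bilateral_opacities(exam: LusExam) -> bool:
    """Bilateral opacities not attributable solely to effusion.

    Requires the bilateral interstitial and/or bilateral consolidation
    pattern, and on each hemithorax at least one examinable region whose
    aeration score >= 1 is not accompanied by an effusion flag (so the
    opacity cannot be ascribed to the effusion alone).
    """
    if not (bilateral_interstitial(exam) or bilateral_consolidation(exam)):
        return False
    qualifying = {"L": False, "R": False}
    for r in exam.regions:
        if r.examinable and r.aeration_score >= 1 and not r.effusion:
            qualifying[r.region_id.side] = True
    return qualifying["L"] and qualifying["R"]


def classify_exam(
    exam: LusExam,
    obs: ClinicalObservation,
    patient: PatientRecord,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> ExamCall:
    """Apply the five case definitions to one exam/observation pair.

    Deterministic; raises ``ValueError`` if exam and observation are not
    paired (same patient and timepoint).
    """
    if exam.patient_id != obs.patient_id or exam.timepoint is not obs.timepoint:
        raise ValueError(
            f"unpaired exam/observation: exam {exam.patient_id}/{exam.timepoint.value} "
            f"vs observation {obs.patient_id}/{obs.timepoint.value}"
        )

    effusion = any(r.effusion for r in exam.regions)
    interstitial = bilateral_interstitial(exam)

    plethora = ivc_plethora(exam, thresholds.ivc_mm)
    balance_positive = (
        obs.fluid_balance_24h_ml is not None
        and obs.fluid_balance_24h_ml > thresholds.fluid_ml
    )
    fluid_overload = (interstitial or effusion) and (balance_positive or plethora is True)

    ards = (
        sf_ratio(obs.spo2, obs.o2_flow_lpm) <= thresholds.sf
        and _bilateral_opacities(exam)
        and not patient.history_cardiac_failure
        and not fluid_overload
    )

    any_opacity = any(r.examinable and r.aeration_score >= 1 for r in exam.regions)
    febrile = obs.temperature_c is not None and obs.temperature_c > thresholds.temperature_c
    leukocytosis = obs.wbc_per_mm3 is not None and obs.wbc_per_mm3 > thresholds.wbc_per_mm3
    pneumonia = any_opacity and (febrile or leukocytosis)

    any_consolidation = any(
        r.examinable and r.aeration_score == 3 for r in exam.regions
    )
    atelectasis = any_consolidation and not (ards or pneumonia or fluid_overload)

    return ExamCall(
        patient_id=exam.patient_id,
        timepoint=exam.timepoint,
        hours_from_admission=exam.hours_from_admission,
        ards=ards,
        fluid_overload=fluid_overload,
        pneumonia=pneumonia,
        atelectasis=atelectasis,
        effusion=effusion,
    )


def _onset_category(call: ExamCall) -> OnsetCategory:
    if call.timepoint is Timepoint.ADMISSION:
        return OnsetCategory.ADMISSION
    if call.hours_from_admission <= 24:
        return OnsetCategory.FIRST_24H
    return OnsetCategory.THEREAFTER


def poor_outcome(patient: PatientRecord) -> bool:
    """Composite poor outcome: transfer for escalation of care, or death."""
    return patient.outcome in (Outcome.TRANSFERRED, Outcome.DIED)


def aggregate_stay(
    patient: PatientRecord,
    calls: list[ExamCall],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> ComplicationCall:
    """Aggregate per-exam calls to the stay level for one patient.

    ``first_onset`` is the category of the earliest positive exam (exams
    ordered by hour offset, ties broken toward the earlier category):
    the admission exam maps to "admission", any later exam within 24 h of
    admission to "first_24h", and beyond that to "thereafter".
    ``respiratory_distress_any`` is true if the distress criteria hold at any
    observation during the stay.
    """
    if not calls:
        raise ValueError(f"patient {patient.patient_id}: no classified exams")
    order = {
        Timepoint.ADMISSION: 0,
        Timepoint.H24: 1,
        Timepoint.EVENT: 2,
        Timepoint.H48: 3,
    }
    ordered = sorted(calls, key=lambda c: (c.hours_from_admission, order[c.timepoint]))
    types: set[str] = set()
    first: OnsetCategory = OnsetCategory.NONE
    for call in ordered:
        if call.any_flag and first is OnsetCategory.NONE:
            first = _onset_category(call)
        types |= call.types()
    distress_any = any(
        respiratory_distress(o, thresholds.rr_per_min, thresholds.sf)
        for o in patient.observations
    )
    return ComplicationCall(
        patient_id=patient.patient_id,
        exam_calls=ordered,
        any_complication=bool(types),
        types_present=types,
        first_onset=first,
        respiratory_distress_any=distress_any,
        poor_outcome=poor_outcome(patient),
    )


def classify_patient(
    patient: PatientRecord, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> ComplicationCall:
    """Classify every exam of one patient and aggregate to the stay level."""
    calls = [
        classify_exam(exam, patient.observation_for(exam.timepoint), patient, thresholds)
        for exam in patient.exams_in_order()
    ]
    return aggregate_stay(patient, calls, thresholds)


def classify_cohort(
    cohort: list[PatientRecord], thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> list[ComplicationCall]:
    """Classify a cohort patient by patient (order-independent across patients)."""
    return [classify_patient(p, thresholds) for p in cohort]
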