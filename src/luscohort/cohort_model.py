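"""Domain types, validation, and readers/writers for granular cohort data.

The data model mirrors how a bedside lung-ultrasound (LUS) study is
recorded: each patient carries a series of timepointed 12-region LUS
examinations paired one-to-one with clinical observations (vitals, oxygen
therapy, point-of-care labs, fluid balance), plus admission demographics,
risk-factor flags and the discharge outcome.  All downstream logic (aeration
scoring, the complication rule engine, cohort statistics) consumes these
validated types only.

Two on-disk representations are supported:

* ``json`` — a single document with the patient list under ``"patients"``;
* ``csv-set`` — three UTF-8 comma-separated files in one directory
  (``patients.csv``, ``observations.csv``, ``lus_regions.csv``) keyed by
  ``patient_id`` (+ ``timepoint``).

Missing optional values are encoded as explicit nulls / empty cells, never
sentinel numbers, so that "if available" rules (e.g. the white-cell-count arm
of the pneumonia definition) can distinguish absent from zero.
"""

from __future__ import annotations

import enum
import json
import warnings
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field, ValidationError, model_validator

__all__ = [
    "RegionId",
    "Timepoint",
    "Avpu",
    "AdmissionReason",
    "DeliverySurgery",
    "Anesthesia",
    "Outcome",
    "OnsetCategory",
    "RegionFinding",
    "LusExam",
    "ClinicalObservation",
    "PatientRecord",
    "ExamCall",
    "ComplicationCall",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
]


class CohortValidationError(ValueError):
    """A record violated the cohort schema; the message names record and field."""


class RegionId(str, enum.Enum):
    """The 12 chest regions: side {L, R} x six zones, in canonical order."""

    L_VENTRAL_SUPERIOR = "L_ventral_superior"
    L_VENTRAL_INFERIOR = "L_ventral_inferior"
    L_LATERAL_SUPERIOR = "L_lateral_superior"
    L_LATERAL_INFERIOR = "L_lateral_inferior"
    L_POSTEROLATERAL_SUPERIOR = "L_posterolateral_superior"
    L_POSTEROLATERAL_INFERIOR = "L_posterolateral_inferior"
    R_VENTRAL_SUPERIOR = "R_ventral_superior"
    R_VENTRAL_INFERIOR = "R_ventral_inferior"
    R_LATERAL_SUPERIOR = "R_lateral_superior"
    R_LATERAL_INFERIOR = "R_lateral_inferior"
    R_POSTEROLATERAL_SUPERIOR = "R_posterolateral_superior"
    R_POSTEROLATERAL_INFERIOR = "R_posterolateral_inferior"

    @property
    def side(self) -> str:
        """Hemithorax: ``"L"`` or ``"R"``."""
        return self.value[0]


#: Canonical region ordering used by writers and pattern builders.
REGION_ORDER: tuple[RegionId, ...] = tuple(RegionId)


class Timepoint(str, enum.Enum):
    ADMISSION = "admission"
    H24 = "h24"
    H48 = "h48"
    EVENT = "event"


class Avpu(str, enum.Enum):
    ALERT = "alert"
    VOICE = "voice"
    PAIN = "pain"
    UNRESPONSIVE = "unresponsive"


class AdmissionReason(str, enum.Enum):
    ANTEPARTUM_HEMORRHAGE = "antepartum_hemorrhage"
    POSTPARTUM_HEMORRHAGE = "postpartum_hemorrhage"
    UTERINE_RUPTURE = "uterine_rupture"
    SEVERE_PREECLAMPSIA = "severe_preeclampsia"
    OBSTRUCTED_LABOR = "obstructed_labor"
    ECTOPIC_PREGNANCY = "ectopic_pregnancy"
    SEPSIS = "sepsis"
    SICKLE_CELL_DISEASE = "sickle_cell_disease"
    OTHER = "other"


class DeliverySurgery(str, enum.Enum):
    SPONTANEOUS_VAGINAL = "spontaneous_vaginal"
    CESAREAN_SECTION = "cesarean_section"
    OTHER_SURGERY = "other_surgery"
    NONE = "none"


class Anesthesia(str, enum.Enum):
    GENERAL = "general"
    SPINAL = "spinal"
    NONE = "none"


class Outcome(str, enum.Enum):
    DISCHARGED = "discharged"
    TRANSFERRED = "transferred"
    DIED = "died"


class OnsetCategory(str, enum.Enum):
    ADMISSION = "admission"
    FIRST_24H = "first_24h"
    THEREAFTER = "thereafter"
    NONE = "none"


class RegionFinding(BaseModel):
    """One chest region: aeration score 0-3 plus artifact flags.

    The aeration score follows the standard LUS grading — 0: A-pattern
    (<= 2 B-lines); 1: >= 3 separated B-lines; 2: coalescent B-lines;
    3: consolidation.  ``aeration_score`` is present exactly when the region
    was examinable (dressings or positioning can preclude scanning).
    ``effusion`` may be true with any aeration score.
    """

    region_id: RegionId
    examinable: bool = True
    aeration_score: Optional[int] = Field(default=None, ge=0, le=3)
    subpleural_consolidation: bool = False
    effusion: bool = False
    air_bronchogram: bool = False
    abnormal_pleural_line: bool = False

    @model_validator(mode="after")
    def _score_iff_examinable(self) -> "RegionFinding":
        if self.examinable and self.aeration_score is None:
            raise ValueError(
                f"region {self.region_id.value}: aeration_score required when examinable"
            )
        if not self.examinable and self.aeration_score is not None:
            raise ValueError(
                f"region {self.region_id.value}: aeration_score must be absent when "
                "not examinable"
            )
        return self


class LusExam(BaseModel):
    """A timepointed 12-region LUS examination plus IVC diameters (mm)."""

    patient_id: str
    timepoint: Timepoint
    hours_from_admission: float = Field(ge=0)
    regions: list[RegionFinding]
    ivc_max_mm: Optional[float] = Field(default=None, gt=0)
    ivc_min_mm: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "LusExam":
        ids = [r.region_id for r in self.regions]
        if len(self.regions) != 12 or len(set(ids)) != 12:
            missing = sorted(set(RegionId) - set(ids), key=list(RegionId).index)
            raise ValueError(
                f"exam {self.patient_id}/{self.timepoint.value}: expected exactly 12 "
                f"distinct regions, got {len(ids)}"
                + (f"; missing {[m.value for m in missing]}" if missing else "")
            )
        if (
            self.ivc_max_mm is not None
            and self.ivc_min_mm is not None
            and self.ivc_max_mm < self.ivc_min_mm
        ):
            raise ValueError(
                f"exam {self.patient_id}/{self.timepoint.value}: ivc_max_mm < ivc_min_mm"
            )
        if self.timepoint is Timepoint.ADMISSION and self.hours_from_admission > 6:
            raise ValueError(
                f"exam {self.patient_id}/admission: admission exam must occur within "
                "6 hours of admission"
            )
        return self

    def region(self, region_id: RegionId) -> RegionFinding:
        return next(r for r in self.regions if r.region_id is region_id)


class ClinicalObservation(BaseModel):
    """Vitals, oxygen therapy, labs and management data paired with an exam.

    ``o2_flow_lpm`` of 0 means room air.  Optional labs (``hemoglobin_g_dl``,
    ``lactate_mmol_l``, ``wbc_per_mm3``) and ``fluid_balance_24h_ml`` are None
    when not measured — never coerced to zero.  ``auscultation`` is free text,
    carried but unused by any rule.
    """

    patient_id: str
    timepoint: Timepoint
    respiratory_rate: float = Field(gt=0)
    spo2: float = Field(ge=0, le=100)
    o2_flow_lpm: float = Field(default=0.0, ge=0)
    accessory_muscles: bool = False
    nasal_flaring: bool = False
    heart_rate: float = Field(gt=0)
    systolic_bp: float = Field(gt=0)
    diastolic_bp: float = Field(gt=0)
    temperature_c: Optional[float] = None
    avpu: Avpu = Avpu.ALERT
    hemoglobin_g_dl: Optional[float] = Field(default=None, gt=0)
    lactate_mmol_l: Optional[float] = Field(default=None, ge=0)
    wbc_per_mm3: Optional[float] = Field(default=None, ge=0)
    fluid_balance_24h_ml: Optional[float] = None
    vasopressors: bool = False
    diuretics: bool = False
    transfusion: bool = False
    auscultation: Optional[str] = None


class PatientRecord(BaseModel):
    """One enrolled patient: demographics, risk flags, exam/observation series, outcome."""

    patient_id: str
    age: float = Field(gt=0)
    gestational_age: Optional[float] = Field(default=None, ge=0)
    gravidity: int = Field(ge=0)
    parity: int = Field(ge=0)
    bmi: Optional[float] = Field(default=None, gt=0)
    admission_reason: AdmissionReason
    history_cardiac_failure: bool = False
    sickle_cell: bool = False
    malaria_positive: bool = False
    delivery_surgery: DeliverySurgery = DeliverySurgery.NONE
    anesthesia: Anesthesia = Anesthesia.NONE
    exams: list[LusExam]
    observations: list[ClinicalObservation]
    outcome: Outcome
    length_of_stay_days: float = Field(gt=0)

    @model_validator(mode="after")
    def _check(self) -> "PatientRecord":
        pid = self.patient_id
        exam_tps = [e.timepoint for e in self.exams]
        if len(set(exam_tps)) != len(exam_tps):
            raise ValueError(f"patient {pid}: duplicate (patient, timepoint) exams")
        if Timepoint.ADMISSION not in exam_tps:
            raise ValueError(f"patient {pid}: admission exam is required")
        obs_tps = [o.timepoint for o in self.observations]
        if len(set(obs_tps)) != len(obs_tps):
            raise ValueError(f"patient {pid}: duplicate observation timepoints")
        if set(obs_tps) != set(exam_tps):
            raise ValueError(
                f"patient {pid}: exam and observation timepoints must pair one-to-one "
                f"(exams {sorted(t.value for t in exam_tps)}, "
                f"observations {sorted(t.value for t in obs_tps)})"
            )
        for e in self.exams:
            if e.patient_id != pid:
                raise ValueError(f"patient {pid}: exam carries patient_id {e.patient_id}")
        for o in self.observations:
            if o.patient_id != pid:
                raise ValueError(
                    f"patient {pid}: observation carries patient_id {o.patient_id}"
                )
        return self

    def observation_for(self, timepoint: Timepoint) -> ClinicalObservation:
        return next(o for o in self.observations if o.timepoint is timepoint)

    def exams_in_order(self) -> list[LusExam]:
        """Exams sorted by hour offset, admission first on ties."""
        order = {
            Timepoint.ADMISSION: 0,
            Timepoint.H24: 1,
            Timepoint.EVENT: 2,
            Timepoint.H48: 3,
        }
        return sorted(self.exams, key=lambda e: (e.hours_from_admission, order[e.timepoint]))


class ExamCall(BaseModel):
    """Per-exam complication flags emitted by the rule engine.

    ``ards`` and ``fluid_overload`` are mutually exclusive; ``atelectasis``
    excludes the other three parenchymal diagnoses; ``effusion`` is
    independent of all else (non-exclusive category).
    """

    patient_id: str
    timepoint: Timepoint
    hours_from_admission: float
    ards: bool = False
    fluid_overload: bool = False
    pneumonia: bool = False
    atelectasis: bool = False
    effusion: bool = False

    @model_validator(mode="after")
    def _exclusions(self) -> "ExamCall":
        if self.ards and self.fluid_overload:
            raise ValueError(
                f"{self.patient_id}/{self.timepoint.value}: ards and fluid_overload "
                "cannot both be called at one exam"
            )
        if self.atelectasis and (self.ards or self.pneumonia or self.fluid_overload):
            raise ValueError(
                f"{self.patient_id}/{self.timepoint.value}: atelectasis excludes "
                "ards/pneumonia/fluid_overload at the same exam"
            )
        return self

    @property
    def any_flag(self) -> bool:
        return any(
            (self.ards, self.fluid_overload, self.pneumonia, self.atelectasis, self.effusion)
        )

    def types(self) -> set[str]:
        return {
            name
            for name in ("ards", "fluid_overload", "pneumonia", "atelectasis", "effusion")
            if getattr(self, name)
        }


class ComplicationCall(BaseModel):
    """Stay-level aggregation of the per-exam calls for one patient."""

    patient_id: str
    exam_calls: list[ExamCall]
    any_complication: bool
    types_present: set[str]
    first_onset: OnsetCategory
    respiratory_distress_any: bool
    poor_outcome: bool

    @model_validator(mode="after")
    def _check(self) -> "ComplicationCall":
        if self.any_complication != bool(self.types_present):
            raise ValueError(
                f"patient {self.patient_id}: any_complication must equal "
                "types_present being nonempty"
            )
        if self.any_complication == (self.first_onset is OnsetCategory.NONE):
            raise ValueError(
                f"patient {self.patient_id}: first_onset 'none' iff no complication"
            )
        return self


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_PATIENT_SCALARS = [
    "patient_id",
    "age",
    "gestational_age",
    "gravidity",
    "parity",
    "bmi",
    "admission_reason",
    "history_cardiac_failure",
    "sickle_cell",
    "malaria_positive",
    "delivery_surgery",
    "anesthesia",
    "outcome",
    "length_of_stay_days",
]

# exam-level fields travel on the observation row (one-to-one pairing by timepoint)
_OBS_FIELDS = [
    "patient_id",
    "timepoint",
    "hours_from_admission",
    "ivc_max_mm",
    "ivc_min_mm",
    "respiratory_rate",
    "spo2",
    "o2_flow_lpm",
    "accessory_muscles",
    "nasal_flaring",
    "heart_rate",
    "systolic_bp",
    "diastolic_bp",
    "temperature_c",
    "avpu",
    "hemoglobin_g_dl",
    "lactate_mmol_l",
    "wbc_per_mm3",
    "fluid_balance_24h_ml",
    "vasopressors",
    "diuretics",
    "transfusion",
    "auscultation",
]

_REGION_FIELDS = [
    "patient_id",
    "timepoint",
    "region_id",
    "examinable",
    "aeration_score",
    "subpleural_consolidation",
    "effusion",
    "air_bronchogram",
    "abnormal_pleural_line",
]

_BOOL_COLUMNS = {
    "history_cardiac_failure",
    "sickle_cell",
    "malaria_positive",
    "accessory_muscles",
    "nasal_flaring",
    "vasopressors",
    "diuretics",
    "transfusion",
    "examinable",
    "subpleural_consolidation",
    "effusion",
    "air_bronchogram",
    "abnormal_pleural_line",
}


def _enum_value(v):
    return v.value if isinstance(v, enum.Enum) else v


def _cell(v):
    if v is None:
        return ""
    if isinstance(v, bool):
        return "true" if v else "false"
    return _enum_value(v)


def _parse_cell(col: str, v):
    if pd.isna(v) or v == "":
        return None
    if col in _BOOL_COLUMNS:
        if isinstance(v, bool):
            return v
        s = str(v).strip().lower()
        if s in ("true", "1", "1.0", "yes"):
            return True
        if s in ("false", "0", "0.0", "no"):
            return False
        raise CohortValidationError(f"column {col}: cannot parse boolean from {v!r}")
    return v


def cohort_to_json(cohort: list[PatientRecord]) -> str:
    """Serialize a cohort to a deterministic JSON document."""
    doc = {"patients": [p.model_dump(mode="json") for p in cohort]}
    return json.dumps(doc, indent=1, sort_keys=True)


def cohort_from_json(text: str) -> list[PatientRecord]:
    doc = json.loads(text)
    if not isinstance(doc, dict) or "patients" not in doc:
        raise CohortValidationError("JSON cohort must be an object with a 'patients' list")
    out = []
    for entry in doc["patients"]:
        try:
            out.append(PatientRecord.model_validate(entry))
        except ValidationError as err:
            pid = entry.get("patient_id", "<unknown>") if isinstance(entry, dict) else "?"
            raise CohortValidationError(f"patient {pid}: {err}") from err
    _check_unique_ids(out)
    return out


def _check_unique_ids(cohort: list[PatientRecord]) -> None:
    seen: set[str] = set()
    for p in cohort:
        if p.patient_id in seen:
            raise CohortValidationError(f"duplicate patient_id {p.patient_id}")
        seen.add(p.patient_id)


def _cohort_frames(cohort: list[PatientRecord]) -> dict[str, pd.DataFrame]:
    pat_rows, obs_rows, reg_rows = [], [], []
    for p in cohort:
        pat_rows.append({c: _cell(getattr(p, c)) for c in _PATIENT_SCALARS})
        exam_by_tp = {e.timepoint: e for e in p.exams}
        for o in p.observations:
            e = exam_by_tp[o.timepoint]
            row = {}
            for c in _OBS_FIELDS:
                src = e if c in ("hours_from_admission", "ivc_max_mm", "ivc_min_mm") else o
                row[c] = _cell(getattr(src, c))
            obs_rows.append(row)
        for e in p.exams_in_order():
            for r in e.regions:
                reg_rows.append(
                    {
                        "patient_id": p.patient_id,
                        "timepoint": e.timepoint.value,
                        **{c: _cell(getattr(r, c)) for c in _REGION_FIELDS[2:]},
                    }
                )
    return {
        "patients": pd.DataFrame(pat_rows, columns=_PATIENT_SCALARS),
        "observations": pd.DataFrame(obs_rows, columns=_OBS_FIELDS),
        "lus_regions": pd.DataFrame(reg_rows, columns=_REGION_FIELDS),
    }


def write_cohort(cohort: list[PatientRecord], path: str | Path, format: str = "json") -> None:
    """Write a validated cohort to ``path``.

    ``format="json"`` writes a single document; ``format="csv-set"`` writes
    patients.csv / observations.csv / lus_regions.csv into the directory
    ``path`` (created if absent).  ``read_cohort(write_cohort(c))`` returns a
    cohort equal field-for-field.
    """
    path = Path(path)
    if format == "json":
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(cohort_to_json(cohort), encoding="utf-8")
    elif format == "csv-set":
        path.mkdir(parents=True, exist_ok=True)
        for name, frame in _cohort_frames(cohort).items():
            frame.to_csv(path / f"{name}.csv", index=False, encoding="utf-8")
    else:
        raise ValueError(f"unknown cohort format {format!r}")


def _warn_unknown(df: pd.DataFrame, known: list[str], which: str) -> pd.DataFrame:
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        warnings.warn(f"{which}: ignoring unknown columns {unknown}", stacklevel=3)
    return df


def read_cohort(path: str | Path, format: str = "json") -> list[PatientRecord]:
    """Read and fully validate a cohort; every invariant is enforced.

    Raises :class:`CohortValidationError` naming the offending record and
    field on any schema violation.  Unknown columns are ignored with a
    warning.  An empty patient list is a valid (empty) cohort.
    """
    path = Path(path)
    if format == "json":
        return cohort_from_json(path.read_text(encoding="utf-8"))
    if format != "csv-set":
        raise ValueError(f"unknown cohort format {format!r}")

    def load(name: str, fields: list[str]) -> pd.DataFrame:
        f = path / f"{name}.csv"
        if not f.exists():
            raise CohortValidationError(f"missing cohort file {f}")
        df = pd.read_csv(f, dtype=str, keep_default_na=False, encoding="utf-8")
        return _warn_unknown(df, fields, name)[[c for c in fields if c in df.columns]]

    patients = load("patients", _PATIENT_SCALARS)
    observations = load("observations", _OBS_FIELDS)
    regions = load("lus_regions", _REGION_FIELDS)

    obs_by_pid: dict[str, list[dict]] = {}
    for _, row in observations.iterrows():
        obs_by_pid.setdefault(row["patient_id"], []).append(dict(row))
    reg_by_key: dict[tuple[str, str], list[dict]] = {}
    for _, row in regions.iterrows():
        reg_by_key.setdefault((row["patient_id"], row["timepoint"]), []).append(dict(row))

    out: list[PatientRecord] = []
    for _, prow in patients.iterrows():
        pid = prow["patient_id"]
        try:
            exams, obs = [], []
            seen_tp: set[str] = set()
            for orow in obs_by_pid.get(pid, []):
                tp = orow["timepoint"]
                if tp in seen_tp:
                    raise CohortValidationError(
                        f"patient {pid}: duplicate (patient, timepoint) exams at {tp!r}"
                    )
                seen_tp.add(tp)
                parsed = {c: _parse_cell(c, orow.get(c, "")) for c in _OBS_FIELDS}
                exam_kwargs = {
                    "patient_id": pid,
                    "timepoint": tp,
                    "hours_from_admission": parsed["hours_from_admission"],
                    "ivc_max_mm": parsed["ivc_max_mm"],
                    "ivc_min_mm": parsed["ivc_min_mm"],
                    "regions": [
                        {c: _parse_cell(c, rrow.get(c, "")) for c in _REGION_FIELDS[2:]}
                        for rrow in reg_by_key.get((pid, tp), [])
                    ],
                }
                exams.append(LusExam.model_validate(exam_kwargs))
                obs.append(
                    ClinicalObservation.model_validate(
                        {
                            c: parsed[c]
                            for c in _OBS_FIELDS
                            if c not in ("hours_from_admission", "ivc_max_mm", "ivc_min_mm")
                        }
                    )
                )
            record = {c: _parse_cell(c, prow.get(c, "")) for c in _PATIENT_SCALARS}
            record["exams"] = exams
            record["observations"] = obs
            out.append(PatientRecord.model_validate(record))
        except (ValidationError, ValueError) as err:
            if isinstance(err, CohortValidationError):
                raise
            raise CohortValidationError(f"patient {pid}: {err}") from err
    _check_unique_ids(out)
    return out
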