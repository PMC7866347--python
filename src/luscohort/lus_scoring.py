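"""Aeration-derived quantities from a 12-region lung-ultrasound exam.

The global aeration score is the sum of the per-region scores (0-3) over the
examinable regions, hence ranges 0-36 for a complete exam.  Unexaminable
regions are excluded from the sum — no imputation — and ``examined_regions``
is reported so callers can flag incomplete exams.  Bilateral pattern rules
(interstitial syndrome, consolidation) likewise count examinable regions only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .cohort_model import LusExam

__all__ = [
    "ExamAeration",
    "score_exam",
    "bilateral_interstitial",
    "bilateral_consolidation",
    "ivc_plethora",
    "IVC_PLETHORA_MM",
]

#: IVC maximal diameter above which the vena cava is considered plethoric
#: (strict inequality, mm).
IVC_PLETHORA_MM = 23.0


@dataclass(frozen=True)
class ExamAeration:
    """Summary of one exam's aeration findings.

    ``per_side_b_pattern_counts`` / ``per_side_consolidation_counts`` map
    hemithorax ("L"/"R") to the number of examinable regions with a B-pattern
    (score 1 or 2) respectively consolidation (score 3).  ``normal_aeration``
    requires all 12 regions examinable and scored 0: an incomplete exam can
    never be certified as fully normally aerated.
    """

    global_score: int
    examined_regions: int
    per_side_b_pattern_counts: dict
    per_side_consolidation_counts: dict
    any_effusion: bool
    normal_aeration: bool

    def __post_init__(self) -> None:
        if not 0 <= self.global_score <= 3 * self.examined_regions:
            raise ValueError("global_score must lie in [0, 3 * examined_regions]")


def score_exam(exam: LusExam) -> ExamAeration:
    """Compute the global aeration score and per-side pattern counts.

    Deterministic and invariant under permutation of region order.
    """
    b_counts = {"L": 0, "R": 0}
    c_counts = {"L": 0, "R": 0}
    total = 0
    examined = 0
    any_effusion = False
    for r in exam.regions:
        if r.effusion:
            any_effusion = True
        if not r.examinable:
            continue
        examined += 1
        total += r.aeration_score
        if r.aeration_score in (1, 2):
            b_counts[r.region_id.side] += 1
        elif r.aeration_score == 3:
            c_counts[r.region_id.side] += 1
    return ExamAeration(
        global_score=total,
        examined_regions=examined,
        per_side_b_pattern_counts=b_counts,
        per_side_consolidation_counts=c_counts,
        any_effusion=any_effusion,
        normal_aeration=(examined == 12 and total == 0),
    )


def bilateral_interstitial(exam: LusExam) -> bool:
    """Bilateral interstitial syndrome: >= 2 B-pattern regions per hemithorax."""
    counts = score_exam(exam).per_side_b_pattern_counts
    return counts["L"] >= 2 and counts["R"] >= 2


def bilateral_consolidation(exam: LusExam) -> bool:
    """>= 2 regions with consolidation (score 3) on each hemithorax."""
    counts = score_exam(exam).per_side_consolidation_counts
    return counts["L"] >= 2 and counts["R"] >= 2


def ivc_plethora(exam: LusExam, threshold_mm: float = IVC_PLETHORA_MM) -> Optional[bool]:
    """IVC plethora: maximal diameter strictly greater than ``threshold_mm``.

    Returns ``None`` (unknown) when the IVC was not measured; callers decide
    how unknown propagates (the fluid-overload rule treats it as false).
    """
    if exam.ivc_max_mm is None:
        return None
    return exam.ivc_max_mm > threshold_mm
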