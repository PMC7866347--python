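"""Oxygenation indices, respiratory-distress criteria and the early-warning score.

FiO2 is derived from the oxygen flow delivered by nasal prongs or face mask
as ``FiO2 = 0.21 + 0.03 x flow`` (L/min), capped at 1.0 — the linear formula
exceeds the physical bound above ~26 L/min.  The S/F ratio (SpO2 / FiO2)
replaces PaO2/FiO2 where arterial blood gases are unavailable; an S/F <= 315
is the hypoxemia criterion used both for respiratory distress and for the
ARDS case definition.

The (modified) obstetric early warning score (OEWS) sums per-parameter
weights read off banded charts of vital signs.  The engine is chart-agnostic:
a default chart ships as package data (``data/oews_default.yaml``) but any
chart with the same band schema can be supplied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml
from scipy import stats

from .cohort_model import Avpu, ClinicalObservation

__all__ = [
    "derive_fio2",
    "sf_ratio",
    "respiratory_distress",
    "OewsChart",
    "load_default_chart",
    "oews",
    "sample_size_for_proportion",
    "RR_DISTRESS_THRESHOLD",
    "SF_DISTRESS_THRESHOLD",
]

#: Respiratory-rate criterion for respiratory distress (breaths/min, >=).
RR_DISTRESS_THRESHOLD = 30.0
#: S/F-ratio criterion for respiratory distress and ARDS (<=).
SF_DISTRESS_THRESHOLD = 315.0


def derive_fio2(o2_flow_lpm: float) -> float:
    """Fraction of inspired oxygen from the O2 flow in L/min (0 = room air)."""
    if o2_flow_lpm < 0:
        raise ValueError("oxygen flow must be non-negative")
    return min(0.21 + 0.03 * o2_flow_lpm, 1.0)


def sf_ratio(spo2: float, o2_flow_lpm: float) -> float:
    """SpO2/FiO2 ratio, unrounded (threshold comparisons avoid display rounding)."""
    return spo2 / derive_fio2(o2_flow_lpm)


def respiratory_distress(
    obs: ClinicalObservation,
    rr_threshold: float = RR_DISTRESS_THRESHOLD,
    sf_threshold: float = SF_DISTRESS_THRESHOLD,
) -> bool:
    """Respiratory distress at one observation.

    True iff any criterion holds: respiratory rate >= ``rr_threshold``,
    S/F ratio <= ``sf_threshold``, or signs of difficult breathing (use of
    accessory muscles or nasal flaring).
    """
    return (
        obs.respiratory_rate >= rr_threshold
        or sf_ratio(obs.spo2, obs.o2_flow_lpm) <= sf_threshold
        or obs.accessory_muscles
        or obs.nasal_flaring
    )


@dataclass(frozen=True)
class OewsChart:
    """Banded early-warning chart: per-parameter [lower, upper) bands -> weight.

    ``bands`` maps a vital-sign name to an ordered list of ``(low, high,
    weight)`` tuples; bands must be contiguous, non-overlapping, and cover the
    physiologic range (low of the first band may be ``-inf``, high of the last
    ``+inf``).  ``avpu_weights`` maps each consciousness level to a weight.
    """

    bands: dict[str, list[tuple[float, float, int]]]
    avpu_weights: dict[Avpu, int]

    def __post_init__(self) -> None:
        for param, bands in self.bands.items():
            if not bands:
                raise ValueError(f"OEWS chart: parameter {param} has no bands")
            prev_high = None
            for low, high, weight in bands:
                if weight < 0:
                    raise ValueError(f"OEWS chart: negative weight for {param}")
                if high <= low:
                    raise ValueError(f"OEWS chart: empty band [{low}, {high}) for {param}")
                if prev_high is not None and low != prev_high:
                    raise ValueError(
                        f"OEWS chart: bands for {param} must be contiguous "
                        f"(gap or overlap at {low})"
                    )
                prev_high = high
        missing = set(Avpu) - set(self.avpu_weights)
        if missing:
            raise ValueError(f"OEWS chart: missing AVPU levels {sorted(m.value for m in missing)}")
        if any(w < 0 for w in self.avpu_weights.values()):
            raise ValueError("OEWS chart: negative AVPU weight")

    def weight(self, param: str, value: float) -> int:
        for low, high, w in self.bands[param]:
            if low <= value < high:
                return int(w)
        raise ValueError(f"OEWS chart: value {value} outside bands for {param}")

    @classmethod
    def from_dict(cls, doc: dict) -> "OewsChart":
        def num(x) -> float:
            if isinstance(x, str):
                s = x.strip().lower()
                if s in ("-inf", "inf", "+inf"):
                    return float(s)
            return float(x)

        try:
            bands = {
                param: [(num(b["low"]), num(b["high"]), int(b["weight"])) for b in blist]
                for param, blist in doc["bands"].items()
            }
            avpu = {Avpu(k): int(v) for k, v in doc["avpu_weights"].items()}
        except (KeyError, TypeError, ValueError) as err:
            raise ValueError(f"malformed OEWS chart: {err}") from err
        return cls(bands=bands, avpu_weights=avpu)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "OewsChart":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def load_default_chart() -> OewsChart:
    """Load the chart shipped as package data (best-effort standard bands)."""
    text = resources.files("luscohort").joinpath("data/oews_default.yaml").read_text("utf-8")
    return OewsChart.from_dict(yaml.safe_load(text))


_CHART_SOURCES = {
    "respiratory_rate": "respiratory_rate",
    "spo2": "spo2",
    "temperature": "temperature_c",
    "systolic_bp": "systolic_bp",
    "diastolic_bp": "diastolic_bp",
    "heart_rate": "heart_rate",
}


def oews(obs: ClinicalObservation, chart: OewsChart) -> int:
    """Sum the chart weights over the observation's vitals.

    A missing parameter (e.g. temperature not taken) contributes 0 with a
    warning rather than failing the score.
    """
    total = 0
    for param in chart.bands:
        attr = _CHART_SOURCES.get(param)
        if attr is None:
            raise ValueError(f"OEWS chart references unknown parameter {param!r}")
        value = getattr(obs, attr)
        if value is None:
            warnings.warn(
                f"OEWS: {param} missing for patient {obs.patient_id} at "
                f"{obs.timepoint.value}; contributes 0",
                stacklevel=2,
            )
            continue
        total += chart.weight(param, value)
    total += chart.avpu_weights[obs.avpu]
    return total


def sample_size_for_proportion(
    p: float,
    precision: float,
    confidence: float = 0.95,
    population: Optional[int] = None,
) -> int:
    """Sample size to estimate a proportion to a given absolute precision.

    ``n0 = z^2 p (1-p) / precision^2`` with the finite-population correction
    ``n = n0 / (1 + (n0 - 1) / N)`` when ``population`` is given; the result
    is rounded up.
    """
    if not 0 < p < 1:
        raise ValueError("p must lie strictly between 0 and 1")
    if precision <= 0:
        raise ValueError("precision must be positive")
    if not 0 < confidence < 1:
        raise ValueError("confidence must lie strictly between 0 and 1")
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    n0 = z * z * p * (1.0 - p) / (precision * precision)
    if population is not None:
        if population <= 0:
            raise ValueError("population must be positive")
        n0 = n0 / (1.0 + (n0 - 1.0) / population)
    return math.ceil(n0 - 1e-12)
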