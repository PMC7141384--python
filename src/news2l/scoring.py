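"""National Early Warning Score 2 (NEWS2) rubric and the NEWS2-L composite.

NEWS2 aggregates seven weighted clinical observations — respiratory rate,
oxygen saturation, supplemental oxygen, temperature, systolic blood pressure,
heart rate, and level of consciousness — into a 0–20 total with escalation
thresholds at >5 (or any single parameter scoring 3) and >7.

NEWS2-L adds the numeric point-of-care lactate value (mmol/L) to the NEWS2
total, producing a unitless composite used for prehospital risk
stratification after syncope.

Band edges follow the Royal College of Physicians NEWS2 chart.  Inputs are
compared at chart resolution: integers for respiratory rate, SpO2, systolic
pressure and heart rate; one decimal for temperature (values are rounded
half-up to one decimal before banding, so the chart's apparent gaps such as
38.0 -> 38.1 cannot be hit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Union

__all__ = [
    "SpO2Scale",
    "AVPU",
    "VitalSigns",
    "NEWS2Breakdown",
    "CompositeScore",
    "ScoringError",
    "score_respiratory_rate",
    "score_spo2",
    "score_supplemental_oxygen",
    "score_temperature",
    "score_systolic_bp",
    "score_pulse",
    "score_consciousness",
    "compute_news2",
    "compute_news2_l",
    "LACTATE_DEVICE_RANGE",
]

#: Measuring range of the point-of-care lactate device (mmol/L).  Values
#: outside it are accepted but flagged: the range is a device property, not
#: a definition of the composite score.
LACTATE_DEVICE_RANGE = (0.8, 21.7)

#: Total score of a patient with every parameter in its worst band
#: (3+3+2+3+3+3+3).
NEWS2_MAX_TOTAL = 20


class ScoringError(ValueError):
    """Raised when an observation set cannot be scored."""


class SpO2Scale(str, Enum):
    """Which oxygen-saturation weighting column applies.

    Scale 2 is reserved for patients with diagnosed hypercapnic respiratory
    insufficiency (typically COPD) whose target saturation is 88–92%.  It is
    clinical context supplied by the caller, never inferred from the
    saturation value itself.
    """

    SCALE1 = "scale1"
    SCALE2 = "scale2"


class AVPU(str, Enum):
    """Alert / Verbal / Pain / Unresponsive consciousness scale."""

    ALERT = "A"
    VERBAL = "V"
    PAIN = "P"
    UNRESPONSIVE = "U"


def _check_nonneg_int(value: Union[int, float], name: str) -> int:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise ScoringError(f"missing vital sign: {name}")
    if float(value) != int(value):
        raise ScoringError(f"{name} must be an integer, got {value!r}")
    value = int(value)
    if value < 0:
        raise ScoringError(f"{name} must be non-negative, got {value}")
    return value


def _round_half_up(x: float, decimals: int = 0) -> float:
    f = 10.0**decimals
    return math.floor(x * f + 0.5) / f


def score_respiratory_rate(rr: int) -> int:
    """Sub-score for respiratory rate (breaths/min).

    <=8 -> 3, 9-11 -> 1, 12-20 -> 0, 21-24 -> 2, >=25 -> 3.
    """
    rr = _check_nonneg_int(rr, "respiratory_rate")
    if rr <= 8:
        return 3
    if rr <= 11:
        return 1
    if rr <= 20:
        return 0
    if rr <= 24:
        return 2
    return 3


def score_spo2(spo2: int, scale: SpO2Scale = SpO2Scale.SCALE1, on_oxygen: bool = False) -> int:
    """Sub-score for peripheral oxygen saturation (%).

    Scale 1 (default): <=91 -> 3, 92-93 -> 2, 94-95 -> 1, >=96 -> 0,
    regardless of supplemental oxygen (oxygen enters the total only through
    its own sub-score).

    Scale 2 (hypercapnic respiratory insufficiency): <=83 -> 3, 84-85 -> 2,
    86-87 -> 1, 88-92 -> 0; above 92 the weight depends on supplemental
    oxygen — on air any value >=93 scores 0, on oxygen 93-94 -> 1,
    95-96 -> 2, >=97 -> 3 (supra-target saturation under oxygen therapy is
    itself abnormal for these patients).
    """
    spo2 = _check_nonneg_int(spo2, "spo2")
    if spo2 > 100:
        raise ScoringError(f"spo2 must be in [0, 100], got {spo2}")
    scale = SpO2Scale(scale)
    if scale is SpO2Scale.SCALE1:
        if spo2 <= 91:
            return 3
        if spo2 <= 93:
            return 2
        if spo2 <= 95:
            return 1
        return 0
    # scale 2
    if spo2 <= 83:
        return 3
    if spo2 <= 85:
        return 2
    if spo2 <= 87:
        return 1
    if spo2 <= 92:
        return 0
    if not on_oxygen:
        return 0
    if spo2 <= 94:
        return 1
    if spo2 <= 96:
        return 2
    return 3


def score_supplemental_oxygen(on_oxygen: bool) -> int:
    """Sub-score for supplemental oxygen: any oxygen therapy scores 2, air 0."""
    return 2 if on_oxygen else 0


def score_temperature(t: float) -> int:
    """Sub-score for tympanic temperature (deg C).

    <=35.0 -> 3, 35.1-36.0 -> 1, 36.1-38.0 -> 0, 38.1-39.0 -> 1, >=39.1 -> 2.
    The input is rounded half-up to one decimal before banding.
    """
    if t is None or (isinstance(t, float) and math.isnan(t)):
        raise ScoringError("missing vital sign: temperature")
    t = _round_half_up(float(t), 1)
    if t <= 35.0:
        return 3
    if t <= 36.0:
        return 1
    if t <= 38.0:
        return 0
    if t <= 39.0:
        return 1
    return 2


def score_systolic_bp(sbp: int) -> int:
    """Sub-score for systolic blood pressure (mmHg).

    <=90 -> 3, 91-100 -> 2, 101-110 -> 1, 111-219 -> 0, >=220 -> 3.
    """
    sbp = _check_nonneg_int(sbp, "systolic_bp")
    if sbp <= 90:
        return 3
    if sbp <= 100:
        return 2
    if sbp <= 110:
        return 1
    if sbp <= 219:
        return 0
    return 3


def score_pulse(hr: int) -> int:
    """Sub-score for heart rate (beats/min).

    <=40 -> 3, 41-50 -> 1, 51-90 -> 0, 91-110 -> 1, 111-130 -> 2, >=131 -> 3.
    """
    hr = _check_nonneg_int(hr, "heart_rate")
    if hr <= 40:
        return 3
    if hr <= 50:
        return 1
    if hr <= 90:
        return 0
    if hr <= 110:
        return 1
    if hr <= 130:
        return 2
    return 3


def score_consciousness(
    gcs: Optional[int] = None, avpu: Optional[Union[AVPU, str]] = None
) -> int:
    """Sub-score for level of consciousness.

    Exactly one of ``gcs`` (Glasgow Coma Scale, 3–15) or ``avpu`` must be
    supplied.  Alert (or GCS 15) scores 0; any degree of confusion — GCS
    below 15, or a non-Alert AVPU state — scores 3.  V, P and U are not
    distinguished because the rubric weights them identically.
    """
    has_gcs = gcs is not None and not (isinstance(gcs, float) and math.isnan(gcs))
    has_avpu = avpu is not None
    if has_gcs == has_avpu:
        raise ScoringError("supply exactly one of gcs or avpu")
    if has_gcs:
        gcs = int(gcs)
        if not 3 <= gcs <= 15:
            raise ScoringError(f"gcs must be in [3, 15], got {gcs}")
        return 0 if gcs == 15 else 3
    avpu = AVPU(avpu)
    return 0 if avpu is AVPU.ALERT else 3


@dataclass(frozen=True)
class VitalSigns:
    """One prehospital observation set, as recorded at first patient contact.

    Consciousness is represented either as a GCS score (3–15) or an AVPU
    category — exactly one of the two.
    """

    respiratory_rate: int
    spo2: int
    on_supplemental_oxygen: bool
    temperature: float
    systolic_bp: int
    heart_rate: int
    gcs: Optional[int] = None
    avpu: Optional[Union[AVPU, str]] = None
    spo2_scale: SpO2Scale = SpO2Scale.SCALE1

    def __post_init__(self) -> None:
        has_gcs = self.gcs is not None and not (
            isinstance(self.gcs, float) and math.isnan(self.gcs)
        )
        if has_gcs == (self.avpu is not None):
            raise ScoringError("supply exactly one of gcs or avpu")
        object.__setattr__(self, "spo2_scale", SpO2Scale(self.spo2_scale))


@dataclass(frozen=True)
class NEWS2Breakdown:
    """Per-parameter sub-scores, total, and escalation flags."""

    sub_scores: Mapping[str, int]
    total: int
    any_single_three: bool
    urgent_review: bool
    critical_review: bool


@dataclass(frozen=True)
class CompositeScore:
    """NEWS2 total plus point-of-care lactate (the NEWS2-L composite)."""

    news2_total: int
    lactate: float
    news2_l: float
    lactate_out_of_range: bool = False


def compute_news2(vitals: VitalSigns) -> NEWS2Breakdown:
    """Score a complete observation set against the NEWS2 chart.

    Raises :class:`ScoringError` naming the missing field if any vital is
    absent; incomplete observation sets are never partially scored.
    """
    sub_scores = {
        "respiratory_rate": score_respiratory_rate(vitals.respiratory_rate),
        "spo2": score_spo2(vitals.spo2, vitals.spo2_scale, vitals.on_supplemental_oxygen),
        "supplemental_oxygen": score_supplemental_oxygen(vitals.on_supplemental_oxygen),
        "temperature": score_temperature(vitals.temperature),
        "systolic_bp": score_systolic_bp(vitals.systolic_bp),
        "heart_rate": score_pulse(vitals.heart_rate),
        "consciousness": score_consciousness(vitals.gcs, vitals.avpu),
    }
    total = sum(sub_scores.values())
    any_single_three = any(s == 3 for s in sub_scores.values())
    return NEWS2Breakdown(
        sub_scores=sub_scores,
        total=total,
        any_single_three=any_single_three,
        urgent_review=total > 5 or any_single_three,
        critical_review=total > 7,
    )


def compute_news2_l(news2_total: int, lactate: float) -> CompositeScore:
    """Form the NEWS2-L composite: NEWS2 total plus lactate in mmol/L.

    Lactate must be strictly positive; values outside the point-of-care
    device's measuring range (0.8–21.7 mmol/L) are accepted but flagged so
    heavy-tailed synthetic cohorts remain scorable.
    """
    if lactate is None or (isinstance(lactate, float) and math.isnan(lactate)):
        raise ScoringError("missing lactate")
    lactate = float(lactate)
    if lactate <= 0:
        raise ScoringError(f"lactate must be positive, got {lactate}")
    news2_total = int(news2_total)
    if not 0 <= news2_total <= NEWS2_MAX_TOTAL:
        raise ScoringError(f"news2_total must be in [0, {NEWS2_MAX_TOTAL}]")
    lo, hi = LACTATE_DEVICE_RANGE
    return CompositeScore(
        news2_total=news2_total,
        lactate=lactate,
        news2_l=news2_total + lactate,
        lactate_out_of_range=not lo <= lactate <= hi,
    )
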