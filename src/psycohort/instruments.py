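"""Instrument scoring and classification rules.

Severity strata at baseline, side-effect bins of the global side-effect
score S, the DL/SL diagnostic overlap zone, treatment-response categories
from percent baseline-score reduction, and shared percentage formatting.

All thresholds default to the study conventions but can be overridden via
keyword arguments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

logger = logging.getLogger(__name__)

#: Assessment schedule in study days (baseline, day 3, day 10, then weekly).
SCHEDULE: tuple[int, ...] = (0, 3, 7, 10, 14, 21, 28, 35)

#: Item-count convention for the lifetime syndrome dimensions (items 0-4).
DIMENSION_ITEMS: Mapping[str, int] = {
    "thought_disorders": 7,
    "delusions": 8,
    "hallucinations": 6,
    "ego_consciousness": 6,
    "incongruent_affect": 5,
    "anergia": 7,
    "depressive": 12,
    "manic": 6,
    "suicide": 6,
}

ITEM_MAX = 4  # each syndrome item rated 0-4

#: score range (min, max) per syndrome dimension under the item convention
DIMENSION_RANGES: Mapping[str, tuple[float, float]] = {
    name: (0.0, ITEM_MAX * n) for name, n in DIMENSION_ITEMS.items()
}

DL_MAX = 48.0  # lifetime global depression score, 12 items x 0-4
SL_MAX = 80.0  # lifetime global schizophrenia score, 20 items x 0-4

#: total-score bounds per severity instrument
INSTRUMENT_BOUNDS: Mapping[str, tuple[float, float]] = {
    "HAM-D17": (0.0, 52.0),
    "HAM-D21": (0.0, 64.0),
    "PANSS-P": (7.0, 49.0),
    "PANSS-N": (7.0, 49.0),
    "PANSS-G": (16.0, 112.0),
    "MEDIS-global": (0.0, 144.0),
    "MEDIS-cluster": (0.0, 18.0),
}

#: instrument used for baseline severity / response per diagnosis class
SEVERITY_INSTRUMENT = {"F3": "HAM-D17", "F2": "PANSS-G"}
RESPONSE_INSTRUMENT = {"F3": "hamd17", "F2": "panss_p"}

#: minimum inclusion score at baseline (after washout) per diagnosis class
INCLUSION_THRESHOLD = {"F3": 15.0, "F2": 21.0}

#: responder threshold on percent baseline-score reduction
RESPONSE_THRESHOLD = {"F3": 0.50, "F2": 0.40}
PARTIAL_THRESHOLD = 0.20

#: minimum number of repeated assessments to count as a completer
MIN_ASSESSMENTS = 3


@dataclass(frozen=True)
class SyndromeProfile:
    """Lifetime syndrome dimension scores plus the DL/SL global scores."""

    dimensions: Mapping[str, float]
    dl: float
    sl: float

    def __post_init__(self) -> None:
        for name, value in self.dimensions.items():
            if name not in DIMENSION_RANGES:
                raise ValueError(f"unknown syndrome dimension {name!r}")
            lo, hi = DIMENSION_RANGES[name]
            if not lo <= value <= hi:
                raise ValueError(
                    f"dimension {name!r} score {value} outside [{lo}, {hi}]"
                )
        if not 0.0 <= self.dl <= DL_MAX:
            raise ValueError(f"DL score {self.dl} outside [0, {DL_MAX}]")
        if not 0.0 <= self.sl <= SL_MAX:
            raise ValueError(f"SL score {self.sl} outside [0, {SL_MAX}]")


@dataclass(frozen=True)
class SeverityScore:
    """A single severity measurement: instrument, study day, total score."""

    instrument: str
    day: int
    value: float

    def __post_init__(self) -> None:
        if self.instrument not in INSTRUMENT_BOUNDS:
            raise ValueError(f"unknown instrument {self.instrument!r}")
        if self.day not in SCHEDULE:
            raise ValueError(
                f"day {self.day} not in study schedule {SCHEDULE}"
            )
        lo, hi = INSTRUMENT_BOUNDS[self.instrument]
        if not lo <= self.value <= hi:
            raise ValueError(
                f"{self.instrument} score {self.value} outside [{lo}, {hi}]"
            )


@dataclass(frozen=True)
class AssessmentSeries:
    """Ordered longitudinal scores of one instrument for one patient."""

    instrument: str
    days: Sequence[int] = field(default_factory=tuple)
    values: Sequence[float] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.days) != len(self.values):
            raise ValueError("days and values must have equal length")
        if list(self.days) != sorted(set(self.days)):
            raise ValueError("days must be strictly increasing")
        for d in self.days:
            if d not in SCHEDULE:
                raise ValueError(f"day {d} not in study schedule {SCHEDULE}")

    def __len__(self) -> int:
        return len(self.days)

    @property
    def baseline(self) -> float:
        if not self.days or self.days[0] != 0:
            raise ValueError("series has no day-0 baseline")
        return float(self.values[0])

    @property
    def last(self) -> float:
        return float(self.values[-1])


def stratify_severity(baseline: SeverityScore, diagnosis: str) -> str:
    """Classify baseline severity into ``mild | moderate | severe``.

    F3 uses the HAM-D17 total (<20 mild, 20-24 moderate, >24 severe);
    F2 uses the PANSS-G total (<30 mild, 30-40 moderate, >40 severe).
    """
    if diagnosis not in SEVERITY_INSTRUMENT:
        raise ValueError(f"unknown diagnosis class {diagnosis!r}")
    expected = SEVERITY_INSTRUMENT[diagnosis]
    if baseline.instrument != expected:
        raise ValueError(
            f"{diagnosis} severity requires {expected}, got {baseline.instrument}"
        )
    if baseline.day != 0:
        raise ValueError("severity stratification uses the day-0 baseline")
    v = baseline.value
    if diagnosis == "F3":
        lo, hi = 20.0, 24.0
    else:
        lo, hi = 30.0, 40.0
    if v < lo:
        return "mild"
    if v <= hi:
        return "moderate"
    return "severe"


SIDE_EFFECT_BINS = ("none", "mild", "moderate", "severe", "very_severe")


def stratify_side_effects(s: float) -> str:
    """Bin the global side-effect score S.

    S<=10 none; 10<S<=30 mild; 30<S<=40 moderate; 40<S<=50 severe; S>50
    very severe.
    """
    if s < 0:
        raise ValueError(f"global side-effect score must be >= 0, got {s}")
    if s <= 10:
        return "none"
    if s <= 30:
        return "mild"
    if s <= 40:
        return "moderate"
    if s <= 50:
        return "severe"
    return "very_severe"


def classify_overlap(profile: SyndromeProfile, diagnosis: str) -> bool:
    """Diagnostic overlap zone on the DL x SL plane (strict inequalities).

    F2: SL > 35 and DL > 30.  F3: SL > 25 and DL > 35.
    """
    if diagnosis == "F2":
        return profile.sl > 35 and profile.dl > 30
    if diagnosis == "F3":
        return profile.sl > 25 and profile.dl > 35
    raise ValueError(f"unknown diagnosis class {diagnosis!r}")


def percent_reduction(baseline: float, value: float) -> float:
    """Signed proportional reduction from baseline; negative = worsening."""
    if baseline <= 0:
        raise ValueError(f"baseline must be > 0, got {baseline}")
    return (baseline - value) / baseline


def is_dropout(series: AssessmentSeries) -> bool:
    """True when fewer than ``MIN_ASSESSMENTS`` repeated assessments exist."""
    return len(series) < MIN_ASSESSMENTS


def classify_response(
    series: AssessmentSeries,
    diagnosis: str,
    *,
    strict_no_improvement: bool = False,
) -> str:
    """Classify a completer series as responder / partial / non_responder.

    Reduction is evaluated between the day-0 baseline and the last
    available assessment.  Responder: >=50% reduction (F3, HAM-D17) or
    >=40% (F2, PANSS-P).  Partial: >=20% but below the responder
    threshold.  Non-responder: the residual category, so the three labels
    partition every eligible series.  With ``strict_no_improvement`` the
    non_responder label is restricted to series with no improvement at
    all (reduction <= 0) and the in-between band is labelled ``minimal``.
    """
    if diagnosis not in RESPONSE_THRESHOLD:
        raise ValueError(f"unknown diagnosis class {diagnosis!r}")
    if is_dropout(series):
        raise ValueError(
            f"series with {len(series)} assessments is a dropout; "
            f"at least {MIN_ASSESSMENTS} required"
        )
    baseline = series.baseline
    if baseline == 0:
        raise ValueError("baseline score of 0 cannot be classified")
    reduction = percent_reduction(baseline, series.last)
    threshold = RESPONSE_THRESHOLD[diagnosis]
    if reduction >= threshold:
        return "responder"
    if reduction >= PARTIAL_THRESHOLD:
        return "partial"
    if strict_no_improvement and reduction > 0:
        return "minimal"
    return "non_responder"


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the reporting convention for percentages)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def percentage(count: int, total: int, decimals: int = 1) -> float:
    """``100 * count / total`` rounded half away from zero."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_away(100.0 * count / total, decimals)


def report_proportions(
    labels: Sequence[str], decimals: int = 1
) -> dict[str, float]:
    """Percentage per category label, rounded to ``decimals``.

    Keys are emitted in order of first appearance.
    """
    if len(labels) == 0:
        raise ValueError("cannot report proportions of an empty collection")
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    total = len(labels)
    return {lab: percentage(c, total, decimals) for lab, c in counts.items()}
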