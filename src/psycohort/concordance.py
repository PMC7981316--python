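"""Pairwise syndrome-profile concordance.

Concordance between two patients is 1 minus the mean absolute difference
of their range-normalized syndrome dimension scores, giving a symmetric
value in [0, 1] that is 1.0 iff the profiles coincide on the selected
dimensions.  The measure is pluggable: any callable mapping two
normalized score vectors to [0, 1] can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .instruments import DIMENSION_RANGES, SyndromeProfile

#: dimensions used by default: the full lifetime syndrome profile
DEFAULT_DIMENSIONS: tuple[str, ...] = tuple(DIMENSION_RANGES)

#: the key syndromes of the schizophrenic spectrum
CORE_SCHIZOPHRENIA_DIMENSIONS: tuple[str, ...] = (
    "thought_disorders",
    "delusions",
    "hallucinations",
    "ego_consciousness",
)

Measure = Callable[[np.ndarray, np.ndarray], float]


def mean_absolute_agreement(a: np.ndarray, b: np.ndarray) -> float:
    """1 - mean |a - b| over range-normalized score vectors."""
    return float(1.0 - np.mean(np.abs(a - b)))


def _normalize(scores: Mapping[str, float], dimensions: Sequence[str]) -> np.ndarray:
    out = np.empty(len(dimensions))
    for i, dim in enumerate(dimensions):
        if dim not in DIMENSION_RANGES:
            raise ValueError(f"unknown syndrome dimension {dim!r}")
        if dim not in scores:
            raise ValueError(f"profile is missing dimension {dim!r}")
        lo, hi = DIMENSION_RANGES[dim]
        out[i] = (scores[dim] - lo) / (hi - lo)
    return out


def concordance(
    a: SyndromeProfile | Mapping[str, float],
    b: SyndromeProfile | Mapping[str, float],
    dimensions: Sequence[str] = DEFAULT_DIMENSIONS,
    measure: Measure = mean_absolute_agreement,
) -> float:
    """Concordance of two syndrome profiles over the selected dimensions."""
    if len(dimensions) == 0:
        raise ValueError("dimension set must not be empty")
    sa = a.dimensions if isinstance(a, SyndromeProfile) else a
    sb = b.dimensions if isinstance(b, SyndromeProfile) else b
    return measure(_normalize(sa, dimensions), _normalize(sb, dimensions))


@dataclass(frozen=True)
class ConcordanceMatrix:
    """Upper-triangular pairwise concordance values plus summary stats."""

    patient_ids: tuple[str, ...]
    values: np.ndarray  # condensed upper triangle, length n(n-1)/2

    def __post_init__(self) -> None:
        n = len(self.patient_ids)
        if len(self.values) != n * (n - 1) // 2:
            raise ValueError(
                f"expected {n * (n - 1) // 2} pair values for {n} patients, "
                f"got {len(self.values)}"
            )

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_pairs(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if self.n_pairs > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        """Long-format pair table (patient_a, patient_b, concordance)."""
        n = self.n_patients
        ia, ib = np.triu_indices(n, k=1)
        return pd.DataFrame(
            {
                "patient_a": [self.patient_ids[i] for i in ia],
                "patient_b": [self.patient_ids[i] for i in ib],
                "concordance": self.values,
            }
        )

    def summary(self) -> dict[str, float]:
        return {"n_pairs": self.n_pairs, "mean": self.mean, "sd": self.sd}


def pairwise_concordance(
    profiles: pd.DataFrame,
    dimensions: Sequence[str] = DEFAULT_DIMENSIONS,
    id_column: str = "patient_id",
) -> ConcordanceMatrix:
    """All n(n-1)/2 unordered between-patient concordances.

    ``profiles`` holds one row per patient with one column per syndrome
    dimension (raw scores; normalization is applied internally).
    """
    if len(profiles) < 2:
        raise ValueError("pairwise concordance requires at least 2 patients")
    if len(dimensions) == 0:
        raise ValueError("dimension set must not be empty")
    ids = tuple(str(x) for x in profiles[id_column])
    mat = np.empty((len(profiles), len(dimensions)))
    for j, dim in enumerate(dimensions):
        if dim not in DIMENSION_RANGES:
            raise ValueError(f"unknown syndrome dimension {dim!r}")
        if dim not in profiles.columns:
            raise ValueError(f"profile table is missing dimension {dim!r}")
        lo, hi = DIMENSION_RANGES[dim]
        mat[:, j] = (profiles[dim].to_numpy(dtype=float) - lo) / (hi - lo)
    # condensed cityblock distance / n_dims == mean |delta|
    values = 1.0 - pdist(mat, metric="cityblock") / len(dimensions)
    return ConcordanceMatrix(patient_ids=ids, values=values)
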