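"""Constrained search for the largest IgM-linked patient subgroup.

The objective: find the largest subgroup of the analysis sample with
(1) a significant positive Pearson correlation between serum IgM and
the diagnosis-appropriate global syndrome score, and (2) a false-positive
response-prediction rate (observed non-responders among members) at or
below a ceiling.  Candidate memberships are proposed by thresholding
10-fold cross-validated membership scores from a sigmoid backprop
network trained on clinical features; on tiny samples the search is
exact (exhaustive subset enumeration under the same objective).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import neural_net as nn
from .instruments import (
    AssessmentSeries,
    MIN_ASSESSMENTS,
    RESPONSE_INSTRUMENT,
    classify_response,
    percentage,
    round_half_away,
)

#: previous-history syndrome dimensions used as clinical features
FEATURE_DIMS: tuple[str, ...] = (
    "thought_disorders",
    "delusions",
    "hallucinations",
    "ego_consciousness",
    "anergia",
    "incongruent_affect",
    "depressive",
)

#: baseline severity columns appended to the feature vector
FEATURE_BASELINES: tuple[str, ...] = ("hamd21", "panss_g")

#: column holding the diagnosis-appropriate global syndrome score
GLOBAL_SCORE_COLUMN = {"F2": "sl", "F3": "dl"}


@dataclass
class AnalysisSample:
    """Complete-data patients of one diagnosis class, ready for search."""

    diagnosis: str
    patient_ids: tuple[str, ...]
    features: np.ndarray  # (n, 9), min-max scaled to [0,1]
    igm: np.ndarray
    score: np.ndarray  # global syndrome score (SL for F2, DL for F3)
    response: np.ndarray  # responder | partial | non_responder

    @property
    def n(self) -> int:
        return len(self.patient_ids)

    @property
    def non_responder(self) -> np.ndarray:
        return self.response == "non_responder"


def _minmax(X: np.ndarray) -> np.ndarray:
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    span[span == 0] = 1.0
    return (X - lo) / span


def exclude_incomplete(cohort, diagnosis: str):
    """Complete-data analysis sample plus an exclusion report.

    Patients are excluded when any clinical feature, the IgM level, or
    the response label (which requires a baseline plus at least
    ``MIN_ASSESSMENTS`` assessments of the primary instrument) is
    missing.
    """
    patients = cohort.patients[cohort.patients["diagnosis"] == diagnosis]
    if len(patients) == 0:
        raise ValueError(f"cohort contains no {diagnosis} patients")
    feature_cols = [f"dim_{d}" for d in FEATURE_DIMS]
    score_col = GLOBAL_SCORE_COLUMN[diagnosis]
    resp_instrument = RESPONSE_INSTRUMENT[diagnosis]

    baseline = cohort.assessments[cohort.assessments["day"] == 0]
    baseline = baseline.drop_duplicates("patient_id").set_index("patient_id")
    by_patient = dict(tuple(cohort.assessments.groupby("patient_id")))

    ids, feats, igms, scores, resps = [], [], [], [], []
    n_excluded = 0
    for _, row in patients.iterrows():
        pid = row["patient_id"]
        static = [row[c] for c in feature_cols] + [row["igm"], row[score_col]]
        base = baseline.loc[pid] if pid in baseline.index else None
        if base is None or any(pd.isna(v) for v in static) or any(
            pd.isna(base[c]) for c in FEATURE_BASELINES
        ):
            n_excluded += 1
            continue
        series = by_patient.get(pid)
        series = series.sort_values("day") if series is not None else None
        if (
            series is None
            or len(series) < MIN_ASSESSMENTS
            or series[resp_instrument].isna().any()
        ):
            n_excluded += 1
            continue
        label = classify_response(
            AssessmentSeries(
                instrument=resp_instrument,
                days=tuple(series["day"]),
                values=tuple(series[resp_instrument]),
            ),
            diagnosis,
        )
        ids.append(pid)
        feats.append(
            [row[c] for c in feature_cols]
            + [base[c] for c in FEATURE_BASELINES]
        )
        igms.append(float(row["igm"]))
        scores.append(float(row[score_col]))
        resps.append(label)
    if not ids:
        raise ValueError(f"no complete-data {diagnosis} patients remain")
    report = {
        "diagnosis": diagnosis,
        "n_total": len(patients),
        "n_excluded": n_excluded,
        "excluded_pct": percentage(n_excluded, len(patients)),
        "n_sample": len(ids),
    }
    sample = AnalysisSample(
        diagnosis=diagnosis,
        patient_ids=tuple(ids),
        features=_minmax(np.asarray(feats, dtype=float)),
        igm=np.asarray(igms),
        score=np.asarray(scores),
        response=np.asarray(resps),
    )
    return sample, report


def pearson_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation via the t transform."""
    if n < 3:
        return 1.0
    r = min(max(r, -1.0), 1.0)
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return 2.0 * stats.t.sf(abs(t), n - 2)


def permutation_pvalue(
    x: np.ndarray, y: np.ndarray, n_perm: int = 10_000, seed: int = 0
) -> float:
    """Exact-style permutation p for |r| (useful for small member sets)."""
    rng = np.random.default_rng(seed)
    r_obs = abs(np.corrcoef(x, y)[0, 1])
    hits = 0
    for _ in range(n_perm):
        r = abs(np.corrcoef(x, rng.permutation(y))[0, 1])
        if r >= r_obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def variance_explained_pct(r: float) -> float:
    """Between-patient variance explained by a linear correlation: 100*r^2."""
    return 100.0 * r * r


def subgroup_statistics(
    members: np.ndarray,
    igm: np.ndarray,
    score: np.ndarray,
    response: np.ndarray,
) -> tuple[float, float, float, float]:
    """(r, two-sided p, false-positive rate, variance explained %).

    ``members`` is a boolean mask or index array into the sample arrays;
    the false-positive rate is the fraction of members observed as
    non-responders; variance explained is exactly 100*r**2.
    """
    members = np.asarray(members)
    idx = np.flatnonzero(members) if members.dtype == bool else members
    if len(idx) < 5:
        raise ValueError(f"need at least 5 members, got {len(idx)}")
    x, y = igm[idx], score[idx]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance IgM or score within the subgroup")
    r = float(np.corrcoef(x, y)[0, 1])
    p = pearson_pvalue(r, len(idx))
    resp = np.asarray(response)[idx]
    fp_rate = float(np.mean(resp == "non_responder"))
    return r, p, fp_rate, 100.0 * r * r


@dataclass(frozen=True)
class SearchConfig:
    min_r_pvalue: float = 0.05
    max_fp_rate: float = 0.125
    min_size: int = 10
    max_fraction: float = 0.5
    max_outer_iterations: int = 6
    restarts: int = 1
    init_fraction: float = 0.25
    k_folds: int = 10
    exact_threshold: int = 16  # exhaustive enumeration at or below this n
    epochs: int = 40
    hidden: tuple[int, ...] = (6,)
    alpha: float = 2.0
    tolerance: float = 5e-4
    net_weight: float = 3.0  # weight of the NN score rank in the ordering
    responder_bonus: float = 0.3  # label-evolution bonus, in units of n
    seed: int = 0


@dataclass
class SubgroupModel:
    """Result of the constrained subgroup search."""

    diagnosis: str
    member_ids: tuple[str, ...]
    fraction: float  # members / sample, 3 decimals
    r: float
    p_value: float
    fp_rate: float
    variance_explained_pct: float
    net: nn.NetModel | None = None
    igm_threshold: float | None = None  # set by the cutoff baseline only

    @property
    def found(self) -> bool:
        return len(self.member_ids) > 0

    @property
    def size(self) -> int:
        return len(self.member_ids)


def _no_solution(diagnosis: str) -> SubgroupModel:
    return SubgroupModel(
        diagnosis=diagnosis,
        member_ids=(),
        fraction=0.0,
        r=float("nan"),
        p_value=float("nan"),
        fp_rate=float("nan"),
        variance_explained_pct=float("nan"),
    )


def _feasible(sample, idx, cfg) -> tuple[bool, float, float, float, float]:
    r, p, fp, var = subgroup_statistics(
        np.asarray(idx), sample.igm, sample.score, sample.response
    )
    ok = r > 0 and p < cfg.min_r_pvalue and fp <= cfg.max_fp_rate
    return ok, r, p, fp, var


def _build_model(sample, idx, cfg, net=None) -> SubgroupModel:
    r, p, fp, var = subgroup_statistics(
        np.asarray(idx), sample.igm, sample.score, sample.response
    )
    ids = tuple(sample.patient_ids[i] for i in idx)
    return SubgroupModel(
        diagnosis=sample.diagnosis,
        member_ids=ids,
        fraction=round(len(idx) / sample.n, 3),
        r=r,
        p_value=p,
        fp_rate=fp,
        variance_explained_pct=var,
        net=net,
    )


def _select_best(sample, candidates, cfg):
    """Largest feasible candidate; ties broken by smaller p-value."""
    best_idx, best_key = None, None
    seen = set()
    for idx in candidates:
        key = tuple(sorted(int(i) for i in idx))
        if len(key) < cfg.min_size or key in seen:
            continue
        seen.add(key)
        try:
            ok, r, p, fp, var = _feasible(sample, np.asarray(key), cfg)
        except ValueError:
            continue
        if not ok:
            continue
        rank = (len(key), -p)
        if best_key is None or rank > best_key:
            best_key, best_idx = rank, np.asarray(key)
    return best_idx


def _exact_search(sample, cfg) -> SubgroupModel:
    n = sample.n
    indices = range(n)
    candidates = []
    max_size = n
    for size in range(max(cfg.min_size, 5), max_size + 1):
        candidates.extend(
            np.asarray(c) for c in itertools.combinations(indices, size)
        )
    best = _select_best(sample, candidates, cfg)
    if best is None:
        return _no_solution(sample.diagnosis)
    return _build_model(sample, best, cfg, net=_fit_final_net(sample, best, cfg))


def _fit_final_net(sample, idx, cfg) -> nn.NetModel:
    y = np.zeros(sample.n)
    y[idx] = 1.0
    net = nn.init_net(
        n_inputs=sample.features.shape[1],
        n_outputs=1,
        hidden=cfg.hidden,
        alpha=cfg.alpha,
        seed=np.random.default_rng((cfg.seed, 97)),
    )
    result = nn.train(
        net,
        sample.features,
        y,
        max_iterations=cfg.epochs * sample.n,
        tolerance=cfg.tolerance,
        seed=np.random.default_rng((cfg.seed, 98)),
    )
    return result.net


def _rank(v: np.ndarray) -> np.ndarray:
    return np.argsort(np.argsort(v)).astype(float)


def _link_residuals(sample, members: np.ndarray) -> np.ndarray:
    """|IgM - fitted line| from a trimmed fit on the current members.

    The line igm ~ score is fitted on the members, the worst 30% of
    member residuals are dropped, and the line is refitted, making the
    fit robust to label noise early in the search.
    """
    b, a = np.polyfit(sample.score[members], sample.igm[members], 1)
    resid_m = np.abs(sample.igm[members] - (a + b * sample.score[members]))
    keep = members[np.argsort(resid_m)[: max(5, int(0.7 * len(members)))]]
    b, a = np.polyfit(sample.score[keep], sample.igm[keep], 1)
    return np.abs(sample.igm - (a + b * sample.score))


def search(sample: AnalysisSample, config: SearchConfig | None = None) -> SubgroupModel:
    """Best feasible subgroup by the (size, then significance) objective.

    Iterated reassignment: membership labels are initialized from the
    responders whose standardized IgM and score co-move most strongly.
    Each outer iteration (1) retrains the network on the current labels
    and scores every patient by 10-fold cross-validated prediction,
    (2) combines that feature-based membership score with closeness to a
    robustly fitted member IgM-score line into one ordering, and
    (3) evolves the labels (responder status contributes a bonus at this
    step only).  Candidate memberships are the threshold sets of the
    final (converged) ordering at every admissible size.  Candidate
    generation never consults the feasibility constraints, so relaxing
    them can only enlarge the final answer: the largest
    constraint-satisfying candidate encountered.  Samples no larger than
    ``exact_threshold`` are searched exhaustively.
    """
    cfg = config or SearchConfig()
    if cfg.min_size > sample.n:
        return _no_solution(sample.diagnosis)
    if sample.n <= cfg.exact_threshold:
        return _exact_search(sample, cfg)

    max_size = max(cfg.min_size, int(math.ceil(cfg.max_fraction * sample.n)))
    z_igm = (sample.igm - sample.igm.mean()) / max(sample.igm.std(), 1e-12)
    z_score = (sample.score - sample.score.mean()) / max(
        sample.score.std(), 1e-12
    )
    co_rank = z_igm * z_score
    responder = (sample.response != "non_responder").astype(float)

    candidates: list[np.ndarray] = []
    for restart in range(cfg.restarts):
        n_labels = max(cfg.min_size, int(round(cfg.init_fraction * sample.n)))
        # responders first, co-movement as the tie-breaker within them
        members = np.argsort(co_rank + 100.0 * responder)[-n_labels:]
        for it in range(cfg.max_outer_iterations):
            y = np.zeros(sample.n)
            y[members] = 1.0
            plan = nn.kfold_split(
                sample.n,
                k=min(cfg.k_folds, sample.n),
                strata=y,
                seed=np.random.default_rng((cfg.seed, restart, it)),
            )
            cv = nn.cross_validate(
                {
                    "hidden": cfg.hidden,
                    "alpha": cfg.alpha,
                    "seed": (cfg.seed, restart, it, 7),
                    "max_iterations": cfg.epochs * sample.n,
                    "tolerance": cfg.tolerance,
                },
                sample.features,
                y,
                plan,
            )
            scores = cv.predictions[:, 0]
            resid = _link_residuals(sample, members)
            ordering = cfg.net_weight * _rank(scores) + _rank(-resid)
            if it < cfg.max_outer_iterations - 1:
                evolve = ordering + cfg.responder_bonus * sample.n * responder
                members = np.argsort(evolve)[-n_labels:]
        order = np.argsort(-ordering, kind="stable")
        for m in range(cfg.min_size, max_size + 1):
            candidates.append(order[:m])

    best = _select_best(sample, candidates, cfg)
    if best is None:
        return _no_solution(sample.diagnosis)
    return _build_model(sample, best, cfg, net=_fit_final_net(sample, best, cfg))


def cutoff_baseline(
    sample: AnalysisSample, config: SearchConfig | None = None
) -> SubgroupModel:
    """Best subgroup reachable with a single IgM threshold (comparison).

    Members are all patients with IgM at or above a candidate threshold;
    the same feasibility constraints as :func:`search` apply.
    """
    cfg = config or SearchConfig()
    order = np.argsort(-sample.igm, kind="stable")
    candidates = [order[:m] for m in range(cfg.min_size, sample.n + 1)]
    best = _select_best(sample, candidates, cfg)
    if best is None:
        return _no_solution(sample.diagnosis)
    model = _build_model(sample, best, cfg)
    model.igm_threshold = float(sample.igm[best].min())
    return model


def evaluate(model: SubgroupModel, sample: AnalysisSample) -> dict:
    """Report at the study's printed precisions, plus scatter data."""
    member_set = set(model.member_ids)
    scatter = pd.DataFrame(
        {
            "patient_id": sample.patient_ids,
            "score": sample.score,
            "igm": sample.igm,
            "member": [pid in member_set for pid in sample.patient_ids],
            "response": sample.response,
        }
    )
    if not model.found:
        return {
            "diagnosis": model.diagnosis,
            "found": False,
            "n_sample": sample.n,
            "scatter": scatter,
        }
    return {
        "diagnosis": model.diagnosis,
        "found": True,
        "n_sample": sample.n,
        "n_members": model.size,
        "subgroup_pct": percentage(model.size, sample.n),
        "r": round(model.r, 3),
        "p_value": float(f"{model.p_value:.2g}"),
        "fp_rate_pct": percentage(
            int(round(model.fp_rate * model.size)), model.size
        ),
        "variance_explained_pct": round_half_away(
            model.variance_explained_pct, 1
        ),
        "scatter": scatter,
    }


def jaccard(a: Sequence, b: Sequence) -> float:
    """Jaccard overlap of two membership sets (1.0 when both empty)."""
    sa, sb = set(a), set(b)
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)
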