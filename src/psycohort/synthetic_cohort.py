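"""Seeded synthetic cohort generator.

Emulates the tabular structure the downstream analyses expect: static
patient records (demographics, ward, lifetime syndrome profile, serum
IgM, medication count), longitudinal severity and side-effect scores on
the study schedule {0,3,7,10,14,21,28,35}, and a planted latent subgroup
in which IgM is linearly linked to the diagnosis-appropriate global
syndrome score and to treatment response.  Ground truth about the
planted subgroup is emitted separately from the analysis-facing tables.

Everything is deterministic for a fixed config+seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import instruments as ins
from .instruments import SCHEDULE

logger = logging.getLogger(__name__)

DIMENSIONS = tuple(ins.DIMENSION_ITEMS)
DIM_COLUMNS = tuple(f"dim_{d}" for d in DIMENSIONS)

MEDIS_CLUSTERS = (
    "sleep",
    "appetite",
    "sexuality",
    "gastrointestinal",
    "autonomic",
    "neurological",
    "cardiovascular",
    "cardiac_respiratory",
)
MEDIS_COLUMNS = tuple(f"medis_{c}" for c in MEDIS_CLUSTERS)
MEDIS_CLUSTER_MAX = 18.0

#: target share of drug-count variance per side-effect cluster
DEFAULT_SIDE_EFFECT_R2: Mapping[str, float] = {
    "sleep": 0.10,
    "appetite": 0.08,
    "sexuality": 0.178,
    "gastrointestinal": 0.118,
    "autonomic": 0.09,
    "neurological": 0.07,
    "cardiovascular": 0.184,
    "cardiac_respiratory": 0.133,
}

#: per-dimension probability that the syndrome is clinically present
ACTIVITY = {
    "F2": {
        "thought_disorders": 0.70,
        "delusions": 0.65,
        "hallucinations": 0.55,
        "ego_consciousness": 0.55,
        "incongruent_affect": 0.50,
        "anergia": 0.50,
        "depressive": 0.40,
        "manic": 0.30,
        "suicide": 0.35,
    },
    "F3": {
        "thought_disorders": 0.20,
        "delusions": 0.18,
        "hallucinations": 0.12,
        "ego_consciousness": 0.30,
        "incongruent_affect": 0.22,
        "anergia": 0.60,
        "depressive": 0.95,
        "manic": 0.20,
        "suicide": 0.50,
    },
}

#: dimensions whose normalized mean forms the lifetime schizophrenia score
SL_SOURCE_DIMS = (
    "thought_disorders",
    "delusions",
    "hallucinations",
    "ego_consciousness",
    "incongruent_affect",
    "anergia",
)

# syndrome-score mixture geometry (normalized 0-1 scale); tuned so a
# default F2 cohort shows a mean pairwise concordance near 0.536
DIM_BASE = 0.05
DIM_SEPARATION = 0.87
DIM_NOISE_SD = 0.21
DIM_SHARED_LOADING = 0.45  # weight of the patient-level severity factor

DEFAULT_RESPONSE_LINK: Mapping[str, float] = {
    # logit of the responder probability
    "intercept_f3": -0.405,  # ~40% responders among non-members
    "intercept_f2": -0.944,  # ~28%
    "member": 3.9,  # members respond ~97% of the time
    "igm": 0.0,
    "severity": 0.0,
    "partial_given_nonresponse": 0.15,
}

MEMBERSHIP_MODES = ("features", "random", "igm_cutoff")


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic cohort generator."""

    n_f3: int = 195
    n_f2: int = 84
    subgroup_fraction_f3: float = 0.196
    subgroup_fraction_f2: float = 0.225
    planted_correlation: float = 0.8
    igm_log_mean: float = 0.0
    igm_log_sd: float = 0.425  # ~2.5% of background patients above 2.3 g/L
    igm_link_intercept: float = 1.1
    igm_link_slope: float = 1.6
    n_wards: int = 6
    ward_drug_effect_sd: float = 1.0
    drug_count_mean_f3: float = 3.2
    drug_count_mean_f2: float = 3.5
    drug_count_resid_sd: float = 1.7
    side_effect_slope: float = 0.5
    side_effect_r2: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SIDE_EFFECT_R2)
    )
    response_link: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RESPONSE_LINK)
    )
    membership_mode: str = "features"
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_f3 < 0 or self.n_f2 < 0 or self.n_f3 + self.n_f2 < 1:
            raise ValueError(
                f"cohort sizes must be non-negative and sum to >= 1, "
                f"got n_f3={self.n_f3}, n_f2={self.n_f2}"
            )
        for name in ("subgroup_fraction_f3", "subgroup_fraction_f2",
                     "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not 0.0 < self.planted_correlation <= 1.0:
            raise ValueError(
                "planted_correlation must be in (0,1] "
                f"(1 = noiseless link), got {self.planted_correlation}"
            )
        if self.igm_log_sd <= 0:
            raise ValueError("igm_log_sd must be positive")
        if self.n_wards < 1:
            raise ValueError("n_wards must be a positive count")
        if self.ward_drug_effect_sd < 0:
            raise ValueError("ward_drug_effect_sd must be >= 0")
        if self.drug_count_mean_f3 < 0 or self.drug_count_mean_f2 < 0:
            raise ValueError("drug-count means must be >= 0")
        if self.side_effect_slope < 0:
            raise ValueError("side_effect_slope must be >= 0")
        if self.membership_mode not in MEMBERSHIP_MODES:
            raise ValueError(
                f"membership_mode must be one of {MEMBERSHIP_MODES}, "
                f"got {self.membership_mode!r}"
            )
        for cluster, r2 in self.side_effect_r2.items():
            if cluster not in MEDIS_CLUSTERS:
                raise ValueError(f"unknown MEDIS cluster {cluster!r}")
            if not 0.0 <= r2 < 1.0:
                raise ValueError(f"side_effect_r2[{cluster!r}] must be in [0,1)")


@dataclass
class Cohort:
    """Analysis-facing tables plus the separate planted-truth table."""

    patients: pd.DataFrame
    assessments: pd.DataFrame
    truth: pd.DataFrame

    def validate(self) -> None:
        ids = set(self.patients["patient_id"])
        if len(ids) != len(self.patients):
            dupes = self.patients["patient_id"][
                self.patients["patient_id"].duplicated()
            ]
            raise ValueError(f"duplicate patient ids: {sorted(set(dupes))}")
        orphan = set(self.assessments["patient_id"]) - ids
        if orphan:
            raise ValueError(f"assessments reference unknown patients {sorted(orphan)}")
        bad_days = set(self.assessments["day"]) - set(SCHEDULE)
        if bad_days:
            raise ValueError(
                f"assessment days {sorted(bad_days)} outside schedule {SCHEDULE}"
            )
        have_day0 = set(
            self.assessments.loc[self.assessments["day"] == 0, "patient_id"]
        )
        missing = ids - have_day0
        if missing:
            raise ValueError(f"patients without day-0 assessment: {sorted(missing)}")

    @property
    def n_patients(self) -> int:
        return len(self.patients)


def _improvement_rate() -> float:
    """Decay rate with ~70% of total improvement reached by day 14."""
    return brentq(
        lambda lam: (1 - math.exp(-14 * lam)) - 0.70 * (1 - math.exp(-35 * lam)),
        1e-4,
        1.0,
    )


_LAMBDA_70 = _improvement_rate()


def _truncnorm(rng, mean, sd, lo, hi, size):
    """Resampling-based truncated normal (vectorized, deterministic)."""
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _syndrome_scores(rng, diagnosis: str, n: int) -> dict[str, np.ndarray]:
    """Normalized (0-1) syndrome dimension scores with a bimodal
    active/inactive mixture and a shared patient-level severity factor."""
    shared = rng.normal(0.0, 1.0, n)
    norms = {}
    for dim in DIMENSIONS:
        active = rng.random(n) < ACTIVITY[diagnosis][dim]
        noise = DIM_SHARED_LOADING * shared + math.sqrt(
            1 - DIM_SHARED_LOADING**2
        ) * rng.normal(0.0, 1.0, n)
        norms[dim] = np.clip(
            DIM_BASE + DIM_SEPARATION * active + DIM_NOISE_SD * noise, 0.0, 1.0
        )
    return norms


def _plant_members(rng, cfg, diagnosis, norms, igm, n):
    """Choose planted-subgroup members per the configured mode."""
    fraction = (
        cfg.subgroup_fraction_f2 if diagnosis == "F2" else cfg.subgroup_fraction_f3
    )
    n_members = int(round(fraction * n))
    member = np.zeros(n, dtype=bool)
    if n_members == 0:
        return member
    if cfg.membership_mode == "random":
        member[rng.choice(n, size=n_members, replace=False)] = True
    elif cfg.membership_mode == "igm_cutoff":
        member[np.argsort(igm)[-n_members:]] = True
    else:  # features: AND of two syndrome dimensions, with a margin so
        # the latent class is identifiable from the feature vector
        score = np.minimum(
            norms["ego_consciousness"], norms["incongruent_affect"]
        ) + 0.01 * rng.normal(0.0, 1.0, n)
        member[np.argsort(score)[-n_members:]] = True
        lo_cut, hi_cut = 0.55, 0.68
        for dim in ("ego_consciousness", "incongruent_affect"):
            v = norms[dim]
            low = member & (v < hi_cut)
            v[low] = rng.uniform(hi_cut, 0.95, int(low.sum()))
        e = norms["ego_consciousness"]
        i = norms["incongruent_affect"]
        clash = (~member) & (np.minimum(e, i) > lo_cut)
        for idx in np.flatnonzero(clash):
            dim = "ego_consciousness" if e[idx] <= i[idx] else "incongruent_affect"
            norms[dim][idx] = rng.uniform(0.2, lo_cut - 0.03)
    return member


def _plant_igm_link(rng, cfg, member, g_norm, igm):
    """Inside the subgroup, overwrite IgM with a + b*score + noise whose
    variance is set from the members' sample score spread so the planted
    correlation is hit.  Returns the updated IgM array."""
    m = np.flatnonzero(member)
    if len(m) == 0:
        return igm
    r = cfg.planted_correlation
    b = cfg.igm_link_slope
    sd_g = float(np.std(g_norm[m])) if len(m) > 1 else 0.0
    noise_sd = 0.0 if r >= 1.0 else b * sd_g * math.sqrt(1.0 / r**2 - 1.0)
    igm = igm.copy()
    igm[m] = np.maximum(
        0.05,
        cfg.igm_link_intercept + b * g_norm[m] + rng.normal(0.0, noise_sd, len(m)),
    )
    return igm


def _plant_score_link(rng, cfg, member, igm, g_norm):
    """igm_cutoff mode: membership IS an IgM threshold, so the link is
    planted the other way round (score follows IgM within members)."""
    m = np.flatnonzero(member)
    if len(m) == 0:
        return g_norm
    r = cfg.planted_correlation
    z = (igm[m] - igm[m].mean()) / max(igm[m].std(), 1e-9)
    noise_sd = 0.0 if r >= 1.0 else 0.15 * math.sqrt(1.0 / r**2 - 1.0)
    g_norm = g_norm.copy()
    g_norm[m] = np.clip(
        0.55 + 0.15 * z + rng.normal(0.0, noise_sd, len(m)), 0.0, 1.0
    )
    return g_norm


def _response_class(rng, cfg, diagnosis, member, igm, sev_z):
    link = cfg.response_link
    intercept = link["intercept_f2"] if diagnosis == "F2" else link["intercept_f3"]
    logit = (
        intercept
        + link["member"] * member.astype(float)
        + link["igm"] * (igm - 1.0)
        + link["severity"] * sev_z
    )
    p_resp = 1.0 / (1.0 + np.exp(-logit))
    responder = rng.random(len(member)) < p_resp
    partial = (~responder) & (
        rng.random(len(member)) < link["partial_given_nonresponse"]
    )
    out = np.where(responder, "responder", np.where(partial, "partial", "non_responder"))
    return out


def _planted_reduction(rng, response_class, threshold, max_reduction):
    """Total percent reduction at day 35, consistent with the planted
    response class under the endpoint classification rule."""
    n = len(response_class)
    u = rng.random(n)
    red = np.empty(n)
    for i, cls in enumerate(response_class):
        hi = max_reduction[i]
        if cls == "responder":
            lo = min(threshold + 0.03, hi - 0.01)
            red[i] = lo + u[i] * (hi - lo)
        elif cls == "partial":
            red[i] = 0.22 + u[i] * (threshold - 0.02 - 0.22)
        else:
            red[i] = -0.05 + u[i] * (0.17 + 0.05)
    return red


def _trajectory(baseline, reduction, lam, days, floor):
    f35 = 1.0 - math.exp(-35.0 * lam)
    vals = []
    for d in days:
        frac = (1.0 - math.exp(-lam * d)) / f35
        vals.append(max(floor, baseline * (1.0 - reduction * frac)))
    return vals


def _generate_block(rng, cfg: GeneratorConfig, diagnosis: str, n: int,
                    start_index: int, ward_effects: np.ndarray):
    """All per-patient draws for one diagnosis block."""
    ids = [f"P{start_index + i:04d}" for i in range(n)]
    sex = np.where(rng.random(n) < (0.49 if diagnosis == "F2" else 0.60), "F", "M")
    age_mean = 38.6 if diagnosis == "F2" else 42.8
    age = np.round(_truncnorm(rng, age_mean, 12.4, 18.0, 75.0, n), 1)
    ward = rng.integers(0, cfg.n_wards, n)

    # medication counts: diagnosis mean + ward effect + mild demographics
    drug_mean = cfg.drug_count_mean_f2 if diagnosis == "F2" else cfg.drug_count_mean_f3
    base = (
        drug_mean
        + ward_effects[ward]
        + 0.5 * ((sex == "F").astype(float) - 0.5)
        + 0.03 * (age - age_mean)
    )
    n_drugs = np.maximum(
        0, np.round(base + rng.normal(0.0, cfg.drug_count_resid_sd, n))
    ).astype(int)

    # lifetime syndrome profile
    norms = _syndrome_scores(rng, diagnosis, n)
    sl_norm = np.clip(
        np.mean([norms[d] for d in SL_SOURCE_DIMS], axis=0)
        + rng.normal(0.0, 0.04, n),
        0.0,
        1.0,
    )

    # background IgM, then the planted subgroup and its linear link
    igm = np.exp(rng.normal(cfg.igm_log_mean, cfg.igm_log_sd, n))
    member = _plant_members(rng, cfg, diagnosis, norms, igm, n)
    if cfg.membership_mode == "igm_cutoff":
        if diagnosis == "F2":
            sl_norm = _plant_score_link(rng, cfg, member, igm, sl_norm)
        else:
            norms["depressive"] = _plant_score_link(
                rng, cfg, member, igm, norms["depressive"]
            )

    dims = {d: np.round(norms[d] * ins.DIMENSION_RANGES[d][1], 1) for d in DIMENSIONS}
    dl = dims["depressive"]  # DL is the 12-item depressive score
    sl = np.round(sl_norm * ins.SL_MAX, 1)
    if cfg.membership_mode != "igm_cutoff":
        # plant on the emitted (rounded) scores so the noiseless limit
        # yields an exact within-subgroup correlation of 1
        g_norm = (sl / ins.SL_MAX) if diagnosis == "F2" else (dl / ins.DL_MAX)
        igm = _plant_igm_link(rng, cfg, member, g_norm, igm)

    # baseline severities (inclusion rule enforced by truncation)
    if diagnosis == "F3":
        hamd17 = np.round(_truncnorm(rng, 23.1, 5.7, 15.0, 48.0, n), 1)
        panss_g = np.round(_truncnorm(rng, 30.0, 7.0, 16.0, 80.0, n), 1)
        panss_p = np.round(
            _truncnorm(rng, 12.0, 4.0, 7.0, 35.0, n) + 8.0 * norms["delusions"], 1
        )
    else:
        hamd17 = np.round(_truncnorm(rng, 15.4, 6.0, 2.0, 40.0, n), 1)
        panss_g = np.round(_truncnorm(rng, 35.8, 8.8, 21.0, 80.0, n), 1)
        panss_p = np.round(_truncnorm(rng, 22.0, 5.0, 10.0, 45.0, n), 1)
    panss_p = np.minimum(panss_p, 45.0)
    hamd21 = np.minimum(np.round(hamd17 + rng.uniform(1.0, 8.0, n), 1), 64.0)
    panss_n = np.round(_truncnorm(rng, 18.0 if diagnosis == "F2" else 12.0,
                                  5.0, 7.0, 45.0, n), 1)
    paranoid = (
        (norms["delusions"] > 0.5) | (norms["hallucinations"] > 0.5)
    ).astype(int)

    # planted response class and total reduction of the primary instrument
    sev_primary = hamd17 if diagnosis == "F3" else panss_p
    sev_z = (sev_primary - sev_primary.mean()) / max(sev_primary.std(), 1e-9)
    response_class = _response_class(rng, cfg, diagnosis, member, igm, sev_z)
    threshold = ins.RESPONSE_THRESHOLD[diagnosis]
    floor_primary = 0.0 if diagnosis == "F3" else 7.0
    max_red = 1.0 - (floor_primary + 0.5) / sev_primary
    max_red = np.minimum(0.85, max_red)
    reduction = _planted_reduction(rng, response_class, threshold, max_red)

    # side-effect cluster base scores driven by the drug count
    slope = cfg.side_effect_slope
    sd_drugs = max(float(np.std(n_drugs)), 1e-9)
    medis_base = {}
    for cluster in MEDIS_CLUSTERS:
        r2 = cfg.side_effect_r2.get(cluster, 0.0)
        if slope > 0 and r2 > 0:
            noise_sd = slope * sd_drugs * math.sqrt((1.0 - r2) / r2)
        else:
            noise_sd = 2.0
        medis_base[cluster] = np.clip(
            8.0 * slope + slope * n_drugs + rng.normal(0.0, noise_sd, n),
            0.0,
            MEDIS_CLUSTER_MAX,
        )

    patients = pd.DataFrame(
        {
            "patient_id": ids,
            "diagnosis": diagnosis,
            "sex": sex,
            "age": age,
            "ward": [f"W{w + 1}" for w in ward],
            "n_drugs": n_drugs,
            "igm": igm,  # full precision: the planted link is exact when noiseless
            **{f"dim_{d}": dims[d] for d in DIMENSIONS},
            "dl": np.round(dl, 1),
            "sl": sl,
            "paranoid_hamd21": paranoid,
        }
    )
    truth = pd.DataFrame(
        {
            "patient_id": ids,
            "in_subgroup": member.astype(int),
            "response_class_true": response_class,
            "planted_reduction": np.round(reduction, 4),
        }
    )

    # longitudinal assessments
    lam = _LAMBDA_70 * np.exp(rng.normal(0.0, 0.3, n))
    rows = []
    secondary_red = rng.uniform(0.05, 0.35, (n, 4))
    for i in range(n):
        days = [0] + [
            d for d in SCHEDULE[1:] if rng.random() >= cfg.missing_rate
        ]
        h17 = _trajectory(hamd17[i], reduction[i] if diagnosis == "F3" else
                          secondary_red[i, 0], lam[i], days, 0.0)
        pp = _trajectory(panss_p[i], reduction[i] if diagnosis == "F2" else
                         secondary_red[i, 1], lam[i], days, 7.0)
        h21 = _trajectory(hamd21[i], secondary_red[i, 2] if diagnosis == "F2"
                          else reduction[i] * 0.9, lam[i], days, 0.0)
        pg = _trajectory(panss_g[i], secondary_red[i, 3], lam[i], days, 16.0)
        pn = _trajectory(panss_n[i], secondary_red[i, 3] * 0.8, lam[i], days, 7.0)
        for t, day in enumerate(days):
            clusters = {
                f"medis_{c}": round(
                    float(
                        np.clip(
                            medis_base[c][i] + rng.normal(0.0, 0.8),
                            0.0,
                            MEDIS_CLUSTER_MAX,
                        )
                    ),
                    1,
                )
                for c in MEDIS_CLUSTERS
            }
            rows.append(
                {
                    "patient_id": ids[i],
                    "day": day,
                    "hamd17": round(h17[t], 1),
                    "hamd21": round(h21[t], 1),
                    "panss_p": round(pp[t], 1),
                    "panss_n": round(pn[t], 1),
                    "panss_g": round(pg[t], 1),
                    **clusters,
                    "medis_global": round(sum(clusters.values()), 1),
                }
            )
    assessments = pd.DataFrame(rows)
    return patients, assessments, truth


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate a full synthetic cohort; deterministic for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    ward_effects = rng.normal(0.0, config.ward_drug_effect_sd, config.n_wards)
    ward_effects -= ward_effects.mean()  # keep the overall drug mean on target

    blocks = []
    start = 1
    for diagnosis, n in (("F3", config.n_f3), ("F2", config.n_f2)):
        if n == 0:
            continue
        blocks.append(
            _generate_block(rng, config, diagnosis, n, start, ward_effects)
        )
        start += n
    patients = pd.concat([b[0] for b in blocks], ignore_index=True)
    assessments = pd.concat([b[1] for b in blocks], ignore_index=True)
    truth = pd.concat([b[2] for b in blocks], ignore_index=True)
    cohort = Cohort(patients=patients, assessments=assessments, truth=truth)
    cohort.validate()
    return cohort


def cohort_summary(cohort: Cohort) -> pd.DataFrame:
    """Per-diagnosis summary: baseline severity, drug counts, side-effect
    bin prevalence, and response-category proportions."""
    if cohort.n_patients == 0:
        raise ValueError("cannot summarize an empty cohort")
    from .instruments import (
        AssessmentSeries,
        RESPONSE_INSTRUMENT,
        classify_response,
        is_dropout,
        report_proportions,
        stratify_side_effects,
    )

    rows = []
    baseline = cohort.assessments[cohort.assessments["day"] == 0].set_index(
        "patient_id"
    )
    for diagnosis in ("F3", "F2"):
        sub = cohort.patients[cohort.patients["diagnosis"] == diagnosis]
        if len(sub) == 0:
            logger.warning("no %s patients in cohort; stratum omitted", diagnosis)
            continue
        sev_col = "hamd17" if diagnosis == "F3" else "panss_g"
        sev = baseline.loc[sub["patient_id"], sev_col]
        labels = []
        peak_s = []
        for pid in sub["patient_id"]:
            series = cohort.assessments[cohort.assessments["patient_id"] == pid]
            series = series.sort_values("day")
            peak_s.append(float(series["medis_global"].max()))
            s = AssessmentSeries(
                instrument=RESPONSE_INSTRUMENT[diagnosis],
                days=tuple(series["day"]),
                values=tuple(series[RESPONSE_INSTRUMENT[diagnosis]]),
            )
            labels.append(
                "dropout" if is_dropout(s) else classify_response(s, diagnosis)
            )
        bins = [stratify_side_effects(s) for s in peak_s]
        row = {
            "diagnosis": diagnosis,
            "n": len(sub),
            "baseline_mean": float(sev.mean()),
            "baseline_sd": float(sev.std(ddof=1)),
            "drug_count_mean": float(sub["n_drugs"].mean()),
            "drug_count_sd": float(sub["n_drugs"].std(ddof=1)),
            "polypharmacy_pct": ins.percentage(
                int((sub["n_drugs"] >= 2).sum()), len(sub)
            ),
        }
        bin_pct = report_proportions(bins)
        for b in ins.SIDE_EFFECT_BINS:
            row[f"side_effects_{b}_pct"] = bin_pct.get(b, 0.0)
        resp_pct = report_proportions(labels)
        for lab in ("responder", "partial", "non_responder", "dropout"):
            row[f"{lab}_pct"] = resp_pct.get(lab, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


#: named generator presets used throughout the test and calibration suites
PRESETS: Mapping[str, GeneratorConfig] = {
    "paper": GeneratorConfig(),
    "paper-f2": GeneratorConfig(
        n_f3=0, n_f2=80, subgroup_fraction_f2=0.225, planted_correlation=0.8
    ),
    "paper-f3": GeneratorConfig(
        n_f3=179, n_f2=0, subgroup_fraction_f3=0.196, planted_correlation=0.8
    ),
    "paper-sideeffects": GeneratorConfig(),
    "null": GeneratorConfig(
        subgroup_fraction_f2=0.0, subgroup_fraction_f3=0.0
    ),
    "null-f2": GeneratorConfig(
        n_f3=0, n_f2=80, subgroup_fraction_f2=0.0, subgroup_fraction_f3=0.0
    ),
    "igm-cutoff-f2": GeneratorConfig(
        n_f3=0,
        n_f2=80,
        subgroup_fraction_f2=0.225,
        planted_correlation=0.9,
        membership_mode="igm_cutoff",
    ),
}


def preset(name: str, **overrides) -> GeneratorConfig:
    """Look up a preset, optionally overriding fields (e.g. seed)."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return replace(PRESETS[name], **overrides)
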