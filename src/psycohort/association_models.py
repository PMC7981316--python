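"""Variance-decomposition analyses.

Side-effect variance explained by the simultaneous drug count (ordinary
least squares, one univariate model per MEDIS cluster), and the
determinants of polypharmacy: a linear additive model on gender, age and
diagnosis, a ward-only decomposition, and a nonlinear network model on
all four parameters whose variance share is computed from 10-fold
cross-validated out-of-fold predictions only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import neural_net as nn
from .instruments import round_half_away
from .synthetic_cohort import MEDIS_CLUSTERS, Cohort


@dataclass
class VarianceReport:
    outcome: str
    predictors: tuple[str, ...]
    model_kind: str  # "linear" | "nn"
    variance_explained_pct: float
    n: int
    coefficients: pd.DataFrame | None = None  # linear models only
    in_sample_pct: float | None = None  # diagnostic for nn models

    def __post_init__(self) -> None:
        if not 0.0 <= self.variance_explained_pct <= 100.0:
            raise ValueError(
                "variance_explained_pct must be in [0,100], got "
                f"{self.variance_explained_pct}"
            )


def fit_linear(
    outcome: np.ndarray | pd.Series,
    predictors: pd.DataFrame,
    outcome_name: str = "outcome",
) -> VarianceReport:
    """OLS with intercept; variance explained = 100 * R^2."""
    y = np.asarray(outcome, dtype=float)
    X = pd.get_dummies(predictors, drop_first=True, dtype=float)
    if len(y) <= X.shape[1] + 1:
        raise ValueError(
            f"need n > #predictors + 1, got n={len(y)} with "
            f"{X.shape[1]} predictors"
        )
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, design).fit()
    coefs = pd.DataFrame(
        {
            "term": design.columns,
            "estimate": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "p_value": fit.pvalues.to_numpy(),
        }
    )
    return VarianceReport(
        outcome=outcome_name,
        predictors=tuple(predictors.columns),
        model_kind="linear",
        variance_explained_pct=100.0 * float(fit.rsquared),
        n=len(y),
        coefficients=coefs,
    )


def patient_side_effect_scores(cohort: Cohort) -> pd.DataFrame:
    """Per-patient mean MEDIS cluster scores across available visits."""
    cols = [f"medis_{c}" for c in MEDIS_CLUSTERS]
    means = cohort.assessments.groupby("patient_id")[cols].mean()
    return cohort.patients[["patient_id", "n_drugs"]].merge(
        means, on="patient_id", how="inner"
    )


def drug_side_effect_analysis(cohort: Cohort) -> dict[str, VarianceReport]:
    """One univariate regression (cluster score ~ drug count) per cluster."""
    table = patient_side_effect_scores(cohort)
    if len(table) < 3:
        raise ValueError("need at least 3 patients for the side-effect analysis")
    reports = {}
    for cluster in MEDIS_CLUSTERS:
        reports[cluster] = fit_linear(
            table[f"medis_{cluster}"],
            table[["n_drugs"]],
            outcome_name=f"medis_{cluster}",
        )
    return reports


def _nn_variance(
    y: np.ndarray,
    X: np.ndarray,
    seed: int,
    k: int = 10,
    hidden: tuple[int, ...] = (6,),
    alpha: float = 1.0,
    epochs: int = 80,
) -> tuple[float, float]:
    """(cross-validated, in-sample) variance % from a sigmoid network.

    The outcome is min-max scaled into (0,1) for training and the
    cross-validated share is 100 * (1 - SSE_oof / SST), clipped at 0.
    """
    lo, hi = y.min(), y.max()
    if hi == lo:
        return 0.0, 0.0
    y01 = (y - lo) / (hi - lo)
    plan = nn.kfold_split(len(y), k=min(k, len(y)), seed=np.random.default_rng((seed, 1)))
    cv = nn.cross_validate(
        {
            "hidden": hidden,
            "alpha": alpha,
            "seed": (seed, 2),
            "max_iterations": epochs * len(y),
            "tolerance": 1e-7,
        },
        X,
        y01,
        plan,
    )
    sst = float(np.sum((y01 - y01.mean()) ** 2))
    sse = float(np.sum((y01 - cv.predictions[:, 0]) ** 2))
    cv_pct = max(0.0, 100.0 * (1.0 - sse / sst))
    net = nn.init_net(
        X.shape[1], 1, hidden=hidden, alpha=alpha,
        seed=np.random.default_rng((seed, 3)),
    )
    fit = nn.train(
        net, X, y01, max_iterations=epochs * len(y), tolerance=1e-7,
        seed=np.random.default_rng((seed, 4)),
    )
    sse_in = float(np.sum((y01 - nn.predict(fit.net, X)[:, 0]) ** 2))
    in_pct = max(0.0, 100.0 * (1.0 - sse_in / sst))
    return cv_pct, in_pct


def polypharmacy_determinants(
    cohort: Cohort, seed: int = 0
) -> dict[str, VarianceReport]:
    """Variance in the number of drugs explained by patient factors.

    Returns three reports: ``linear`` (gender + age + diagnosis,
    additive), ``ward`` (ward indicators only), and ``nn`` (all four
    parameters combined in a network with interactions, cross-validated).
    """
    required = {"sex", "age", "diagnosis", "ward", "n_drugs"}
    missing = required - set(cohort.patients.columns)
    if missing:
        raise ValueError(f"patient table is missing columns {sorted(missing)}")
    pat = cohort.patients
    y = pat["n_drugs"].to_numpy(dtype=float)
    if np.all(y == y[0]):
        zero = lambda name, preds, kind: VarianceReport(  # noqa: E731
            outcome="n_drugs", predictors=preds, model_kind=kind,
            variance_explained_pct=0.0, n=len(y),
        )
        return {
            "linear": zero("n_drugs", ("sex", "age", "diagnosis"), "linear"),
            "ward": zero("n_drugs", ("ward",), "linear"),
            "nn": zero("n_drugs", ("sex", "age", "diagnosis", "ward"), "nn"),
        }

    demo = pat[["sex", "age", "diagnosis"]].copy()
    # single-diagnosis cohorts would make the indicator constant
    if demo["diagnosis"].nunique() == 1:
        demo = demo[["sex", "age"]]
    linear = fit_linear(y, demo, outcome_name="n_drugs")

    ward = fit_linear(y, pat[["ward"]], outcome_name="n_drugs")

    X = pd.get_dummies(
        pat[["sex", "diagnosis", "ward"]], drop_first=True, dtype=float
    )
    age = pat["age"].to_numpy(dtype=float)
    X["age"] = (age - age.min()) / max(age.max() - age.min(), 1e-12)
    cv_pct, in_pct = _nn_variance(y, X.to_numpy(dtype=float), seed=seed)
    nn_report = VarianceReport(
        outcome="n_drugs",
        predictors=("sex", "age", "diagnosis", "ward"),
        model_kind="nn",
        variance_explained_pct=cv_pct,
        n=len(y),
        in_sample_pct=in_pct,
    )
    return {"linear": linear, "ward": ward, "nn": nn_report}


def write_coefficient_tables(
    reports: dict[str, VarianceReport], directory, prefix: str
) -> None:
    """One delimited coefficient table per linear model."""
    from pathlib import Path

    directory = Path(directory)
    for name, report in reports.items():
        if report.coefficients is not None:
            report.coefficients.to_csv(
                directory / f"{prefix}_coefficients_{name}.csv", index=False
            )


def summarize_reports(reports: dict[str, VarianceReport]) -> pd.DataFrame:
    rows = [
        {
            "analysis": name,
            "outcome": r.outcome,
            "model": r.model_kind,
            "n": r.n,
            "variance_explained_pct": round_half_away(
                r.variance_explained_pct, 1
            ),
        }
        for name, r in reports.items()
    ]
    return pd.DataFrame(rows)
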