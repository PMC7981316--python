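"""Cohort file readers/writers, pipeline configuration and driver.

Interchange format: plain comma-separated UTF-8 tables with a header row
(patients.csv, assessments.csv, and the separately-kept truth.csv); the
generator config travels as YAML.  Every pipeline run directory carries
a provenance.json with the config hash and seeds, making reruns
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import association_models as am
from . import concordance as cc
from . import subgroup_discovery as sd
from .instruments import SCHEDULE
from .synthetic_cohort import (
    Cohort,
    DIM_COLUMNS,
    GeneratorConfig,
    MEDIS_COLUMNS,
    cohort_summary,
    generate_cohort,
    preset,
)

logger = logging.getLogger(__name__)

PATIENT_COLUMNS = (
    "patient_id",
    "diagnosis",
    "sex",
    "age",
    "ward",
    "n_drugs",
    "igm",
    *DIM_COLUMNS,
    "dl",
    "sl",
    "paranoid_hamd21",
)
ASSESSMENT_COLUMNS = (
    "patient_id",
    "day",
    "hamd17",
    "hamd21",
    "panss_p",
    "panss_n",
    "panss_g",
    *MEDIS_COLUMNS,
    "medis_global",
)


class SchemaError(ValueError):
    """A cohort file violates the data dictionary."""


def _check_columns(df: pd.DataFrame, required, name: str) -> None:
    missing = set(required) - set(df.columns)
    if missing:
        raise SchemaError(f"{name} is missing columns {sorted(missing)}")


def read_cohort(
    patients_path: str | Path,
    assessments_path: str | Path,
    truth_path: str | Path | None = None,
) -> Cohort:
    """Load and validate a cohort from delimited text tables."""
    patients = pd.read_csv(patients_path)
    assessments = pd.read_csv(assessments_path)
    _check_columns(patients, PATIENT_COLUMNS, "patients table")
    _check_columns(assessments, ASSESSMENT_COLUMNS, "assessments table")
    dupes = patients.loc[patients["patient_id"].duplicated(), "patient_id"]
    if len(dupes):
        raise SchemaError(f"duplicate patient ids: {sorted(set(dupes))}")
    bad = assessments.loc[~assessments["day"].isin(SCHEDULE)]
    if len(bad):
        rows = bad.index[:5].tolist()
        raise SchemaError(
            f"assessment days {sorted(set(bad['day']))} (rows {rows}) are "
            f"outside the allowed schedule {SCHEDULE}"
        )
    truth = (
        pd.read_csv(truth_path)
        if truth_path is not None
        else pd.DataFrame(columns=["patient_id", "in_subgroup"])
    )
    cohort = Cohort(patients=patients, assessments=assessments, truth=truth)
    cohort.validate()
    return cohort


def write_cohort(
    cohort: Cohort,
    directory: str | Path,
    include_truth: bool = True,
) -> dict[str, Path]:
    """Write patients/assessments (and the truth table separately)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "patients": directory / "patients.csv",
        "assessments": directory / "assessments.csv",
    }
    cohort.patients.to_csv(paths["patients"], index=False)
    cohort.assessments.to_csv(paths["assessments"], index=False)
    if include_truth:
        paths["truth"] = directory / "truth.csv"
        cohort.truth.to_csv(paths["truth"], index=False)
    return paths


def write_config(config: GeneratorConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)
    )


def read_config(path: str | Path) -> GeneratorConfig:
    data = yaml.safe_load(Path(path).read_text())
    return GeneratorConfig(**data)


def score_cohort(cohort: Cohort) -> pd.DataFrame:
    """Patient table with classification labels appended as columns:
    severity stratum, overlap-zone flag, response class (or dropout),
    and the peak side-effect bin."""
    from . import instruments as ins

    rows = []
    by_patient = dict(tuple(cohort.assessments.groupby("patient_id")))
    for _, row in cohort.patients.iterrows():
        diagnosis = row["diagnosis"]
        series = by_patient[row["patient_id"]].sort_values("day")
        sev_col = "hamd17" if diagnosis == "F3" else "panss_g"
        baseline = ins.SeverityScore(
            ins.SEVERITY_INSTRUMENT[diagnosis],
            0,
            float(series.iloc[0][sev_col]),
        )
        resp_col = ins.RESPONSE_INSTRUMENT[diagnosis]
        resp_series = ins.AssessmentSeries(
            instrument=resp_col,
            days=tuple(series["day"]),
            values=tuple(series[resp_col]),
        )
        profile = ins.SyndromeProfile({}, dl=row["dl"], sl=row["sl"])
        rows.append(
            {
                "patient_id": row["patient_id"],
                "severity_stratum": ins.stratify_severity(baseline, diagnosis),
                "overlap_zone": ins.classify_overlap(profile, diagnosis),
                "response_class": (
                    "dropout"
                    if ins.is_dropout(resp_series)
                    else ins.classify_response(resp_series, diagnosis)
                ),
                "side_effect_bin": ins.stratify_side_effects(
                    float(series["medis_global"].max())
                ),
            }
        )
    return cohort.patients.merge(pd.DataFrame(rows), on="patient_id")


@dataclass
class PipelineConfig:
    """End-to-end run configuration: exactly one input source."""

    preset_name: str | None = "paper"
    patients_path: str | None = None
    assessments_path: str | None = None
    run_concordance: bool = True
    run_discovery: tuple[str, ...] = ("F2", "F3")
    run_variance: bool = True
    seed: int = 0
    out_dir: str = "runs/latest"
    search: sd.SearchConfig = field(default_factory=sd.SearchConfig)

    def validate(self) -> None:
        generating = self.preset_name is not None
        loading = self.patients_path is not None
        if generating == loading:
            raise ValueError(
                "exactly one input source required: a generator preset "
                "XOR cohort file paths"
            )
        if loading and self.assessments_path is None:
            raise ValueError("assessments_path required when loading a cohort")


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        return dataclasses.asdict(o) if dataclasses.is_dataclass(o) else str(o)

    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Generate/load a cohort and run every enabled analysis stage.

    Returns the run directory; every artifact is stamped via
    provenance.json and reruns with the same config are byte-identical.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    handler = logging.FileHandler(out / "run.log", mode="w")
    logging.getLogger().addHandler(handler)
    try:
        if config.preset_name is not None:
            gen = preset(config.preset_name, seed=config.seed)
            logger.info("stage generate: preset %s", config.preset_name)
            cohort = generate_cohort(gen)
            write_cohort(cohort, out / "cohort")
            write_config(gen, out / "cohort" / "config.yaml")
        else:
            logger.info("stage load: %s", config.patients_path)
            cohort = read_cohort(config.patients_path, config.assessments_path)

        logger.info("stage score")
        cohort_summary(cohort).to_csv(out / "summary.csv", index=False)
        score_cohort(cohort).to_csv(out / "patients_scored.csv", index=False)

        if config.run_concordance:
            logger.info("stage concordance")
            profiles = cohort.patients.rename(
                columns={c: c.removeprefix("dim_") for c in DIM_COLUMNS}
            )
            for diagnosis in ("F2", "F3"):
                sub = profiles[profiles["diagnosis"] == diagnosis]
                if len(sub) < 2:
                    continue
                matrix = cc.pairwise_concordance(sub)
                matrix.to_frame().to_csv(
                    out / f"concordance_pairs_{diagnosis}.csv", index=False
                )
                (out / f"concordance_summary_{diagnosis}.json").write_text(
                    json.dumps(matrix.summary(), indent=2)
                )

        for diagnosis in config.run_discovery:
            if (cohort.patients["diagnosis"] == diagnosis).sum() == 0:
                continue
            logger.info("stage discovery %s", diagnosis)
            sample, report = sd.exclude_incomplete(cohort, diagnosis)
            model = sd.search(
                sample, dataclasses.replace(config.search, seed=config.seed)
            )
            result = sd.evaluate(model, sample)
            scatter = result.pop("scatter")
            scatter.to_csv(out / f"discovery_scatter_{diagnosis}.csv", index=False)
            result["exclusions"] = report
            (out / f"discovery_{diagnosis}.json").write_text(
                json.dumps(result, indent=2)
            )

        if config.run_variance:
            logger.info("stage variance")
            side = am.drug_side_effect_analysis(cohort)
            am.summarize_reports(side).to_csv(
                out / "variance_side_effects.csv", index=False
            )
            am.write_coefficient_tables(side, out, "side_effects")
            poly = am.polypharmacy_determinants(cohort, seed=config.seed)
            am.summarize_reports(poly).to_csv(
                out / "variance_polypharmacy.csv", index=False
            )
            am.write_coefficient_tables(poly, out, "polypharmacy")

        provenance = {
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "preset": config.preset_name,
            "stages": {
                "concordance": config.run_concordance,
                "discovery": list(config.run_discovery),
                "variance": config.run_variance,
            },
        }
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    except Exception:
        logger.exception("pipeline stage failed")
        raise
    finally:
        logging.getLogger().removeHandler(handler)
        handler.close()
    return out
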