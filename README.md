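# psycohort

Synthetic psychiatric cohort simulation and analysis pipeline:

- **`synthetic_cohort`** — seeded generator of tidy cohort tables
  (patients, longitudinal assessments) for two diagnosis classes
  (F2 = schizophrenic disorders, F3 = depressive disorders), with a
  planted latent subgroup in which serum IgM is linearly linked to the
  global syndrome score and to treatment response. Ground truth about
  the planted subgroup is emitted separately (`truth.csv`) and never
  enters the analysis-facing tables.
- **`instruments`** — scoring and classification rules: baseline
  severity strata, global side-effect score bins, the DL/SL diagnostic
  overlap zone, responder / partial / non-responder categories from
  percent baseline-score reduction, and the shared percentage rounding
  convention (half away from zero, one decimal).
- **`concordance`** — all n(n−1)/2 pairwise between-patient
  syndrome-profile concordances (1 − mean absolute range-normalized
  difference; the measure is pluggable).
- **`neural_net`** — a from-scratch multi-layer sigmoid network with
  online backpropagation (gradient checked against central finite
  differences), plus a stratified k-fold cross-validation harness
  (default k = 10).
- **`subgroup_discovery`** — constrained search for the largest patient
  subgroup with a significant positive IgM–score correlation and a low
  false-positive response-prediction rate, driven by 10-fold
  cross-validated network membership scores; exhaustive enumeration on
  tiny samples; a single-IgM-threshold baseline for comparison.
- **`association_models`** — variance decomposition: side-effect
  cluster scores vs. drug count (OLS), and the determinants of
  polypharmacy (linear additive model vs. a cross-validated nonlinear
  network model).
- **`io` / `cli`** — CSV cohort round-trips with schema validation, a
  seeded end-to-end pipeline driver, and the `psycohort` command line.

## CLI

```bash
psycohort simulate --preset paper --seed 1 --out out/cohort
psycohort score --patients out/cohort/patients.csv --assessments out/cohort/assessments.csv --out out
psycohort concordance --patients ... --assessments ... --diagnosis F2 --out out
psycohort discover --patients ... --assessments ... --diagnosis F2 --seed 1 --out out
psycohort variance --patients ... --assessments ... --analysis side-effects --out out
psycohort run-all --preset paper --seed 1 --out runs/demo
```

Presets (see `psycohort.synthetic_cohort.PRESETS`): `paper` (195 F3 +
84 F2), `paper-f2` / `paper-f3` (single-diagnosis analysis samples with
a planted subgroup), `null` / `null-f2` (IgM independent of everything),
`igm-cutoff-f2` (membership is a pure IgM threshold), and
`paper-sideeffects`.

Every run is deterministic for a fixed seed; pipeline runs stamp a
`provenance.json` (config hash + seeds) and rerunning the same config is
byte-identical.

## Data dictionary

See [docs/data_dictionary.md](docs/data_dictionary.md) for every column
of `patients.csv`, `assessments.csv`, and `truth.csv`.
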