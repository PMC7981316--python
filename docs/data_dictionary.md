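# Data dictionary

All tables are comma-separated UTF-8 with a header row.

## patients.csv — one row per patient (static data)

| column | type | description |
| --- | --- | --- |
| patient_id | str | unique identifier `P0001`… |
| diagnosis | str | primary diagnosis class, `F2` (schizophrenic) or `F3` (depressive) |
| sex | str | `F` / `M` |
| age | float | years at entry |
| ward | str | ward identifier `W1`…`Wk` (psychiatrist in charge) |
| n_drugs | int | number of simultaneous psychotropic medications (0 = psychotherapy alone, 1 = monotherapy, ≥2 = polypharmacy) |
| igm | float | serum immunoglobulin-M level, g/L |
| dim_thought_disorders | float | lifetime syndrome score, 7 items × 0–4 → [0, 28] |
| dim_delusions | float | 8 items → [0, 32] |
| dim_hallucinations | float | 6 items → [0, 24] |
| dim_ego_consciousness | float | 6 items → [0, 24] |
| dim_incongruent_affect | float | 5 items → [0, 20] |
| dim_anergia | float | 7 items → [0, 28] |
| dim_depressive | float | 12 items → [0, 48] |
| dim_manic | float | 6 items → [0, 24] |
| dim_suicide | float | 6 items → [0, 24] |
| dl | float | lifetime global depression score (12 items, [0, 48]; equals dim_depressive) |
| sl | float | lifetime global schizophrenia score (20 items, [0, 80]) |
| paranoid_hamd21 | int | 1 if the HAM-D21 paranoid-symptom criterion is met |

## assessments.csv — one row per patient-visit

| column | type | description |
| --- | --- | --- |
| patient_id | str | foreign key into patients.csv |
| day | int | study day, one of {0, 3, 7, 10, 14, 21, 28, 35}; day 0 always present |
| hamd17 | float | 17-item Hamilton Depression total, [0, 52] |
| hamd21 | float | 21-item Hamilton Depression total, [0, 64] |
| panss_p | float | PANSS positive scale, [7, 49] |
| panss_n | float | PANSS negative scale, [7, 49] |
| panss_g | float | PANSS general psychopathology scale, [16, 112] |
| medis_sleep … medis_cardiac_respiratory | float | eight side-effect cluster scores, each [0, 18] |
| medis_global | float | global side-effect score S = sum of the clusters, [0, 144] |

## truth.csv — planted ground truth (never consumed by the analyses)

| column | type | description |
| --- | --- | --- |
| patient_id | str | foreign key |
| in_subgroup | int | 1 if the patient belongs to the planted IgM-linked subgroup |
| response_class_true | str | planted responder / partial / non_responder class |
| planted_reduction | float | planted total percent reduction of the primary severity score at day 35 |

## config.yaml

YAML dump of `GeneratorConfig` (cohort sizes, subgroup fractions,
planted correlation, IgM distribution, ward/drug/side-effect/response
parameters, missingness, seed).
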