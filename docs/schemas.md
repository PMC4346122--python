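# CSV schemas

All tabular I/O is plain CSV. Identifiers are opaque strings; indicator
columns take values 0/1.

## Clinical feature table (`classify --features`)

One row per patient. Required columns, exactly:

| column | meaning |
|---|---|
| `patient_id` | unique identifier |
| `progressive_course` | progressive course of illness |
| `parkinsonism` | bradykinesia or rigidity (core) |
| `dystonia` | (core) |
| `myoclonus` | (core) |
| `impaired_voluntary_limb_control` | alien-limb phenomena (core) |
| `cortical_sensory_deficit` | symmetric or asymmetric (core) |
| `visual_hallucinations` | exclusion |
| `rbd` | REM sleep behavior disorder (exclusion) |
| `cerebellar_ataxia` | exclusion |
| `autonomic_dysfunction` | prominent autonomic dysfunction (exclusion) |
| `fluctuating_alertness` | exclusion |
| `rest_tremor` | prominent rest tremor (exclusion) |
| `nonfluent_or_motor_speech` | agrammatism, non-fluent speech or motor speech deficits (fv) |
| `behavioral_change` | apathy, disinhibition or loss of empathy (fv) |
| `lower_extremity_apraxia` | apraxia primarily affecting lower extremities (fv) |
| `executive_worse_than_mem_visuospatial` | executive dysfunction greater than memory/visuospatial impairment (fv) |
| `logopenic_aphasia` | tpv |
| `gerstmann_or_balint` | elements of Gerstmann or Balint syndrome (tpv) |
| `mem_visuospatial_worse_than_executive` | memory/visuospatial impairment greater than executive dysfunction (tpv) |

The two cognitive-profile columns are mutually exclusive; a row with both
set, or with any column missing, is rejected (no imputation).

## ROI uptake tables (`quantify --uptake`, `--controls`)

Long format, one row per (patient, ROI, hemisphere):

| column | values |
|---|---|
| `patient_id` | string |
| `roi` | `frontal`, `temporoparietal`, `common`, `pons` |
| `side` | `left`, `right` |
| `mean_uptake` | positive real, raw tracer units |

Pons rows provide the SUVR denominator (the mean of a patient's pons rows
is used). Bilateral values are computed as the mean of left and right SUVR.

## Time–activity curves (`quantify --tacs <dir>`)

One CSV per patient, named `<patient_id>.csv`:

| column | meaning |
|---|---|
| `mid_time_min` | frame mid-time, minutes, strictly increasing |
| `target_activity` | target-tissue concentration |
| `reference_activity` | reference-tissue (cerebellar grey) concentration |

## Reference labels (`evaluate --reference`, `simulate` output `labels.csv`)

| column | meaning |
|---|---|
| `patient_id` | string |
| `pib_positive` | 0/1 amyloid status |
| `group` (simulate output) | `pib_pos` / `pib_neg` |
| `global_dvr` (simulate output) | global PIB DVR |

## Call tables (`evaluate --calls`)

`patient_id` plus one column per modality, values `fv`/`tpv` (or empty for
a patient lacking that modality; such patients are excluded pairwise for
that modality only).
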