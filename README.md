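# strokemap

Anatomo-functional mapping of post-stroke visuospatial deficits: from raw
paper-and-pencil test responses to multivariate lesion- and
disconnection-symptom maps with permutation-based family-wise-error control.

## Who this is for

Researchers studying hemispatial neglect and related visuospatial disorders
after unilateral stroke, who have per-patient binary lesion masks in a common
stereotaxic space, a grey-matter parcellation, a streamline set, and a battery
of clinical test scores — and who want to know *which brain locations and
connections, when damaged, predict which behavioral deficits*. A synthetic
cohort generator with planted ground truth makes every stage of the pipeline
testable without any patient data.

## What it computes

**Behavioral scoring** (`strokemap.scoring`). Eight scores from four tests,
signed so that positive = left-lateralized deficit:

- `apples_ego` — z-scored egocentric centre of cancellation (CoC): mean
  horizontal position of the cancelled targets, normalized by the page
  half-width and referenced to a normative mean/SD;
- `apples_allo` — allocentric error asymmetry
  *A* = (Contra_err − Ipsi_err) / Whole_corr over the opened-apple distractors;
- `bisect20`, `bisect5` — mean signed bisection deviation (mm) for 20 cm and
  5 cm lines;
- `clock_asym` — left-minus-right tally of clock-hour omissions (1 point),
  midline-crossing translocations (1 point) and within-side translocations
  beyond a 30° cone (0.5 point);
- `clock_margin` — left-minus-right difference of the margins between the
  clock circumference and the most lateral hour marks (mm);
- `moca_cube`, `moca_clock` — construction scores inverted so that higher =
  more impaired.

**Factor decomposition** (`strokemap.factors`). PCA of the 8×8 correlation
matrix of the (absolute-valued) scores, Kaiser rule for the number of
components, direct-oblimin rotation with Kaiser normalization (implemented
via gradient projection), regression-method subject scores. The per-patient
component scores C1..Ck are the targets of all mapping analyses.

**Lesion quantification** (`strokemap.lesion`). Left lesions are
mirror-flipped across the midsagittal plane; each lesion is summarized as
(i) binary voxels, (ii) % damage per parcel, (iii) % of streamlines
interrupted per tract, and (iv) % of streamlines interrupted per parcel pair
(n(n−1)/2 potential edges). Features damaged in < 10% of patients are
excluded.

**SVR lesion-symptom mapping** (`strokemap.svr`). An epsilon-SVR (linear
kernel by default) predicts a behavioral component from all features jointly
after regressing lesion volume out of both behavior and features and
adjusting for age, gender and time post-stroke. The back-projected,
unit-norm weight vector is the SVR-β map. Significance comes from permuting
the adjusted behavior vector and refitting: per-feature one-tailed p values;
FWE control via the max-statistic distribution of the studentized β
("corrected z"); at the voxel level, cluster-extent correction with a
p < 0.005 forming threshold and a cluster-level p < 0.05.

**Synthetic cohorts** (`strokemap.simulate`). A mirror-symmetric parcellation
(60 parcels per hemisphere, ≈3 cm³ each), straight-line streamline bundles
including homotopic callosal-like ones, blob-shaped single-hemisphere lesions
grown to log-uniform volumes (16–96 cm³), behavioral scores that are noisy
linear functions of damage to designated parcels/tracts, and raw test
responses that the scoring module maps back onto those scores.

## Worked example

```python
from strokemap.pipeline import RunConfig, run_full
from strokemap.simulate import SimulationConfig
from strokemap.svr import SVRConfig

cfg = RunConfig(
    output_dir="demo_out",
    simulation=SimulationConfig(n_patients=60),
    svr=SVRConfig(n_permutations=500),
    levels=("parcel", "tract"),
    seed=7,
)
report = run_full(cfg)
print("factors:", report["stages"]["factors"])
print("parcel LSM:", report["stages"]["lsm"]["parcel"])
```

prints

```
factors: {'k': 3, 'variance_explained_top_k_pct': 75.8619926407098,
 'eigenvalues': [2.8125, 1.8447, 1.4117, 0.6761, 0.452, 0.3173, 0.2708, 0.215]}
parcel LSM: {'C1': {'n_features_retained': 60, 'n_survivors': 2},
 'C2': {'n_features_retained': 60, 'n_survivors': 1},
 'C3': {'n_features_retained': 60, 'n_survivors': 1}}
```

Three eigenvalues exceed 1, so three components are retained, explaining
75.9% of the variance — the planted three-block effect structure (a
frontal-like parcel driving the cancellation/long-bisection scores, a
temporoparietal-like parcel the constructional scores, a dorsal tract the
clock scores). At the parcel level, 60 of 120 parcels pass the 10% coverage
threshold (left-hemisphere parcels are empty after flipping), and each
component shows one or two FWE-surviving parcels — the planted sources.
All artifacts (score TSVs, factor report, damage tables, per-feature β/p
tables, `report.json` with config hash and seeds) are written under
`demo_out/`.

The same pipeline runs from the shell:

```bash
strokemap simulate --seed 7 --out cohort/
strokemap run --config run.yaml --seed 7 --out results/
strokemap lsm --level parcel --permutations 5000 --seed 7 --config run.yaml
```

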