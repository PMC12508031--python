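# hemiasym

Surface-based analysis of functional hemispheric asymmetry in task fMRI.

Many cognitive functions lateralize: language engages the left hemisphere
more than the right, hand movements drive the contralateral motor cortex,
and attention and emotion processing lean rightward.  `hemiasym` is a
Python library for quantifying that lateralization vertex by vertex on a
symmetric cortical mesh and relating it to activation strength and
behavioral performance.  It is written for neuroimaging researchers who
work with paired left/right cortical signal maps (e.g. CIFTI-2 dscalar
task contrasts on the fs_LR 32k surface) together with per-subject
covariates and task accuracy scores.

## The measures and models

For mirrored vertex pairs with left and right signal estimates *L* and *R*:

- **Laterality index**  Δ = (L − R) / (|L| + |R|), dimensionless and
  bounded in [−1, 1]; positive = leftward lateralization.  Where the
  bilateral denominator is numerically zero, Δ is defined as 0 and the
  vertex is flagged.
- **Bilateral amplitude**  A = (|L| + |R|) / 2, the mean absolute
  activation across hemispheres.

Both maps are averaged within 12 canonical functional networks (VIS1,
VIS2, SMM, CON, DAN, LAN, FPN, AUD, DMN, PMM, VMM, ORA) per subject and
task epoch.  Networks are ranked by the RMS of cohort-mean asymmetry
across epochs, epochs by the signed mean across networks.  Group
inference uses vertex-wise one-sample t-tests with Benjamini–Hochberg
FDR correction, after regressing out age and grand-mean re-centering
across sex × race cells.

The amplitude–asymmetry coupling is quantified by Pearson correlations
across subjects (per vertex, averaged over epochs, and per
network × epoch cell) with Cohen's d = 2r/√(1−r²), amplitude-binned group
summaries, and a linear-vs-cubic AIC comparison.

Prediction uses two-block PLS regression: 153 predictors (mean amplitude
in 9 major networks × 17 epochs) predict either the matching 153
asymmetry values or accuracy in the 12 non-motor epochs, with 10-fold
within-sample cross-validation, two-fold cross-cohort validation between
covariate-matched discovery/replication halves, and
Bonferroni-corrected predicted-vs-observed correlation heatmaps.
Network-level component scores follow PC_{i,n} = Σ_j A_{i,j} ω_{i,j,n}.

A seeded synthetic cohort generator produces data with exactly this
statistical structure — network-structured amplitude, planted
lateralization, amplitude→asymmetry coupling, and accuracy linearly tied
to brain measures plus age/sex effects — so every stage is testable
against planted ground truth.

## Worked example

```python
import hemiasym as ha

cohort = ha.generate_cohort(ha.CohortConfig(n_subjects=100, n_vertices=48, seed=7))
lan = cohort.partition == "LAN"
j = cohort.epochs.index("story")
print(cohort.asymmetry()[:, j, :][:, lan].mean())   # 0.245
```

The cohort-mean language-network laterality in the story epoch is 0.245
against a planted Δ of 0.25 — the generator's multiplicative (1 ± δ)
parameterization makes planted truth directly recoverable.  Running
`python examples/05_pls_prediction.py` trains the amplitude→asymmetry
PLS model on a 400-subject cohort and prints, per direction of the
two-fold cross-cohort validation:

```
discovery_to_replication: mean held-out r = 0.156; 48/153 cells
Bonferroni-significant (networks: DAN, LAN, FPN)
```

i.e. amplitude predicts held-out asymmetry exactly in the networks where
the generator plants the coupling.  The other scripts in `examples/`
demonstrate cohort simulation, asymmetry/amplitude maps with the
hemisphere-correspondence check, network ranking and motor contrasts,
coupling analysis with AIC model comparison, and the accuracy models.

A thin CLI mirrors the pipeline stages:

```bash
hemiasym simulate --n-subjects 100 --out run/
hemiasym report --n-subjects 200 --seed 1 --out run/
```

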