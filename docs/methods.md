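# Methods

## Laterality index and bilateral amplitude

The per-vertex laterality index Δ = (L − R)/(|L| + |R|) compares signal
estimates at mirrored vertices of a symmetric cortical mesh; it is
scale-invariant (Δ(cL, cR) = Δ(L, R) for c > 0), antisymmetric under
hemisphere swap, and bounded in [−1, 1] because |L − R| ≤ |L| + |R|.
The bilateral amplitude A = (|L| + |R|)/2 carries the activation
magnitude that Δ normalizes away.

**Degenerate denominators.** Nothing constrains |L| + |R| away from
zero in real contrast maps.  Below a threshold `eps` (default 1e−12
signal units) Δ is defined as 0 and the vertex count is recorded on the
returned map.  This keeps the index bounded and deterministic and flags
pathological inputs instead of emitting NaN or ±∞.

**Hemisphere correspondence.** The left–right subtraction is only
meaningful if vertex v of each hemisphere is the mirrored anatomical
homologue of the other.  `verify_correspondence` re-centers each
hemisphere's vertex coordinates to its own bounding-box center, negates
the right hemisphere's x-axis (mirror convention across the midsagittal
plane), and correlates coordinates per axis; all three correlations must
exceed 0.995 on a properly mirrored mesh.  The check is sensitive: a
random vertex permutation collapses the correlations to ≈ 0, while
jitter at 0.1% of the bounding-box extent does not break the threshold.

## Network aggregation and ranking

Vertex maps are averaged (unweighted arithmetic mean; no vertex-area
weighting) within a 12-network cortical partition per subject × epoch,
giving a subjects × (network, epoch) matrix.  Aggregation is linear, so
it commutes with covariate adjustment.

Networks are ranked by the root-mean-square of their cohort-mean values
across epochs — RMS because asymmetry is signed and opposing epochs
(left- vs right-hand movement) would cancel in a plain mean.  Epochs are
ranked by the signed mean across networks, preserving direction.
Cohort-mean-first is the default (mean over subjects per cell, then
RMS/mean over cells); a subject-level RMS variant is exposed via
`rank_networks(..., subject_level=True)`.  Ties break by alphabetical
label order for determinism.  The motor contrast subtracts each
subject × network's mean over the five movement epochs from each motor
epoch, so the five contrasts sum to zero by construction.

## Group statistics

Covariate adjustment is age regression first (per-variable least-squares
residuals plus the original grand mean, leaving values orthogonal to
centered age), then categorical normalization over sex × race cells.
"Grand-mean scaling" is implemented as additive re-centering — each
cell shifted so its mean equals the pooled grand mean — because network
contrast values are signed and a literal multiplicative rescaling is
ill-defined when a cell mean approaches zero; the multiplicative variant
remains available behind `multiplicative=True` and raises on near-zero
cell means.  The chain preserves every variable's pooled grand mean.

The discovery/replication split is stratified by sex with a
largest-remainder apportionment of the discovery quota across strata
(default ratio 0.51), so sex proportions are preserved by construction
while age and BMI balance follows from seeded randomization; the
returned balance report carries two-sample t-tests (age, BMI) and a
two-proportion z-test (sex) so balance is verified, not assumed.

Vertex-wise inference is a one-sample t-test per vertex across subjects
(two-sided, n−1 df) with Benjamini–Hochberg adjustment across all
vertices of one map and Cohen's d = mean/sd.  Zero-variance vertices
yield t = ±∞ with p = 0 and are counted separately rather than silently
dropped.  Bonferroni correction is used only for the prediction heatmaps
and accuracy correlations, where the displayed family is small and
explicit (153 asymmetry cells, 12 accuracy epochs, 9 × 12 univariate
cells).  The r→d conversion d = 2r/√(1−r²) carries an optional Hedges
small-sample factor.

## Amplitude–asymmetry coupling

Per-epoch Pearson r between amplitude and asymmetry across subjects is
computed at every vertex and the 17 per-epoch r-maps are averaged as
plain correlations (Fisher-z averaging available as an option; for the
moderate r values involved the two differ by < 0.05).  Network-level
coupling correlates the aggregated matrices per (network, epoch) cell,
with undefined (zero-variance) cells flagged, never zero-filled.
Amplitude-binned group means (subjects ranked by amplitude, consecutive
groups of 10, final group possibly smaller, subject-id tie-break) are a
presentation device; subject-level statistics are always reported
alongside.

**Polynomial comparison.** Degrees 1–3 are fit by least squares under a
Gaussian likelihood with k = degree + 2 parameters (coefficients plus
the noise variance), AIC = 2k − 2 logLik.  The percentage form of the
AIC difference is 100·(AIC₁ − AIC_d)/|AIC₁|, with the raw difference
emitted alongside since the percentage depends on the arbitrary AIC
offset.  Degree selection follows the Burnham–Anderson parsimony
convention: the smallest degree within 2 AIC units of the minimum.  Pure
argmin selection (available via `parsimony_delta=0`) would pick a
spurious higher degree in ~22% of linear-truth samples — P(χ²₁ > 2) ≈
0.16 alone — whereas the Δ = 2 rule keeps that below 10% while still
selecting degree ≥ 2 essentially always on genuinely quadratic
low-noise data.  Residual sums of squares at rounding-error level are
treated as exact fits (AIC −∞, smallest exact degree selected) so
noise-free inputs do not produce log-of-zero artifacts.

## PLS prediction framework

The predictor block is the subjects × 153 matrix of mean amplitude in
the 9 major networks × 17 epochs (network-major, epoch-minor column
order); the three minor networks (ORA, VMM, PMM) are excluded as small
and diffusely activated.  Responses are either the matching asymmetry
block or accuracy in the 12 non-motor epochs (the motor paradigm has no
accuracy metric).

The regression is two-block NIPALS PLS (scikit-learn's
`PLSRegression`) with training-set centering and unit-variance scaling
of every column, making predictions invariant to affine rescaling of
predictors — necessary because network signal scales differ.  Training
score vectors are mutually orthogonal, and in the saturated limit
(components = full predictor rank) predictions coincide with ordinary
least squares, which the tests verify against a `numpy.linalg.lstsq`
oracle.  Per-component explained predictor variance is
‖t_a‖²‖p_a‖²/((n−1)·p) on the standardized block.

Component count (default cap 12) is chosen by seeded plain k-fold
cross-validation (k = 10, no stratification), minimizing mean held-out
squared error with the smaller count on ties.  Cross-cohort validation
trains on one matched half and correlates predicted with observed
responses per variable in the other half, in both directions; masks are
Bonferroni over the response family (α = 0.05/153 or 0.05/12), with the
uncorrected display threshold also exposed.  Heatmap correlations are
computed across subjects per response variable, not pooled.

Network-level component scores contract the (cohort-mean or
per-subject) network × epoch matrix with the loadings tensor,
PC_{i,n} = Σ_j A_{i,j} ω_{i,j,n}; ω defaults to the X-loadings, with
X-weights selectable.  Covariate effects on per-subject latent scores
are two-sample t-tests (M vs F) and Pearson correlations with age per
component, two-sided.

Covariate adjustment (age regression, grand-mean re-centering) precedes
feature construction by default, mirroring the vertex-wise pipeline
order; the pipeline exposes it as a toggle.

## Synthetic cohort generator

The generator emulates first-level task-contrast maps, not BOLD time
series.  For subject s (amplitude factor g_s ~ N(0, σ_subject)), epoch
e, vertex v in network k:

    δ = clip(δ_planted[k,e] + β_coupling[k,e]·g_s, −1, 1)
    L = μ[k,e]·(1+δ)·(1+g_s) + N(0, σ_vertex)
    R = μ[k,e]·(1−δ)·(1+g_s) + N(0, σ_vertex)

The multiplicative (1 ± δ) form makes the noise-free realized Δ equal
the planted δ exactly, so planted truth is checkable at machine
precision.  Accuracy for non-motor epochs is intercept + amp_weight ×
(realized subject-mean amplitude) + asym_weight × (realized subject-mean
asymmetry) + age_slope × (age − 28.8) + sex_offset × 1[male] + N(0,
σ_accuracy), clipped to [0, 1] with the clipped fraction recorded
(defaults keep it below 1%).

Defaults emulate a large healthy young-adult cohort: 989 subjects, age
28.8 ± 3.7 (61% female), BMI 26.4 ± 5; toy mesh of 120 vertices in
contiguous equal network blocks (full 32,492-vertex maps supported).
Signal means are 1.0 baseline with task-appropriate elevations (visual
networks in visually driven epochs, language/auditory in story and
math, somatomotor in movement, frontoparietal/dorsal-attention in
demanding cognitive epochs).  Planted lateralization: leftward language
(δ = 0.25 story, 0.10 math), contralateral motor (±0.15–0.20 in SMM),
small frontoparietal and dorsal-attention effects.  Coupling defaults:
β = 0.2 in LAN, 0.1 in FPN and DAN, 0 elsewhere.  Noise scales:
σ_subject = 0.15 (dimensionless), σ_vertex = 0.10 signal units,
σ_accuracy = 0.05.  Sex is coded {F, M} with F as reference; right
coordinates are the x-negated mirror of the left, with optional jitter.
Epoch-to-epoch accuracy correlations beyond the shared amplitude factor
are not modeled; epochs are generated independently.

**What the generator does not emulate:** spatial autocorrelation within
networks (vertex noise is iid), hemodynamic variation, registration
error, site or motion artifacts, and non-Gaussian accuracy
distributions (true ceiling effects appear only through clipping).
Passing tests therefore demonstrate the correctness of the estimators
under the assumed generative structure, not robustness to real-data
artifacts.

## Problem sizes and numerical choices

The test and acceptance workloads run on toy meshes (24–48 vertices, 12
networks) with cohorts of 40–500 subjects, sizes at which every planted
effect is comfortably detectable while brute-force oracles remain
practical; vertex count affects only within-network averaging noise, so
conclusions transfer to the full mesh.  All randomness flows through
explicit integer seeds (`numpy.random.default_rng`); identical configs
are bit-identical.  Ranking ties break alphabetically; CV ties prefer
fewer components; undefined correlations are reported as missing.

## Known limitations

- The generator's single per-subject amplitude factor makes all
  networks' amplitudes strongly collinear — deliberately matching the
  multicollinearity PLS is meant to handle, but it means network-level
  specificity claims rest on the planted coupling/lateralization terms.
- Cross-cohort heatmap p-values assume independent test subjects and
  Gaussian-ish responses; no permutation inference is provided.
- No spatial smoothing, surface registration, or resampling: inputs are
  assumed already on a mirrored-homology mesh, and the correspondence
  check only verifies, never fixes, that property.
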