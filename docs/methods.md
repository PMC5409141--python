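# Methods

This note documents the models, parameter choices and numerical decisions
behind `mlsct`, and what the synthetic phantom does and does not establish
about behavior on clinical data.

## Pipeline model and assumptions

The framework assumes a hip/thigh CT in Hounsfield units with an air
background, both legs in the field of view, a prior femoral-bone mask on the
same grid, and a water reference CT_H2O from an in-scan calibration insert
(or an explicit configuration value).  All density-dependent steps are
anchored to two subject-specific references: the adipose value CT_AT
(measured in the subject's own subcutaneous fat) and CT_H2O.  This makes the
segmentation independent of scanner make and calibration drift up to an
affine HU transform — the contrast scale C = (HU − CT_AT)/(CT_H2O − CT_AT)
is invariant under global HU shifts applied consistently to data and
references (property-tested).

The fascia is not detected directly (it is thin and has low contrast against
the surrounding fat); instead the intrafascial volume is built from the
inside out: grade-dependent potential-muscle classification → per-leg
morphological compactification (VOI_IFA) → candidate growing with a local
noise-adaptive threshold → operator-seeded ray-reflection shielding of fat
gaps → merge and smoothing.  The fascia is the surface of the result.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| surface threshold fraction | 0.70 | – | skin threshold between sphere min/max HU |
| surface sphere radius | 10 | voxels | skin-straddling spectrum/seed sphere |
| adipose growing range | [−190, −30] | HU | CT_AT reference region |
| muscle depth minimum | 10 | voxels | excludes dermis/shallow tissue |
| candidate band | 15 | voxels | growing horizon around the fascia approximation; also the ray horizon |
| shielding quorum | 0.65 → 17/26 | rays | gap voxel accepted as shielded |
| local threshold factor | 2 | SD | accept HU ≥ mean₂₆ − 2·SD₂₆ |
| closing element semi-axes | (5, 5, 10) | voxels | z-elongated ellipsoid; matches the axial run of muscles |
| smoothing radius | 2 | voxels | opening+closing ball; removes porous debris |
| histogram trim | 30% of mode | – | cuts vessel/edema tails of the SAT spectrum |
| T_AT factor | mean + 2·SD | HU | adipose threshold from SAT* |
| HDM constant | 35 | HU | 100%-muscle threshold offset above water |
| femur dilation | 1 | voxel | suppresses partial-volume cortical voxels |
| GMM fit window | [−200, 200] | HU | excludes the bone spike from the two-Gaussian model |

Every constant is config-exposed (`AnalysisConfig`) with validated ranges.
Element sizes for compactification and smoothing are genuinely free choices
(only qualitative extents are constrained by the method); the defaults above
close EML holes and PAT concavities up to ~10 voxels while preserving
pockets deep enough to need seeding.

## Ambiguities resolved

- **SAT\* construction.**  The trimmed SAT spectrum is symmetrized by
  discarding bins below the mode and mirroring the upper half about it; T_AT
  = mean + 2·SD of the mirrored spectrum.  Note the 30%-of-mode trim
  truncates a Gaussian at ≈ ±1.55σ, so the SAT* SD is ≈ 0.76σ — T_AT is
  defined by the procedure, not by the untrimmed moments.  It is verified
  against an independent brute-force trimmed-statistic oracle and is
  invariant to sub-threshold contamination (1% vessel voxels shift it by
  < 0.5 HU in tests).
- **Distances** (candidate band, ray horizon) are Euclidean; ray casting
  uses the 26 integer lattice directions with unit voxel steps.
- **Ties pass** at every threshold (Heaviside Θ(0) = 1, HU exactly at a
  local threshold accepted, concentration exactly 0% lands in bin B2, 100%
  in HDM); concentrations are floored to integer percent so the printed bin
  ranges partition the domain.
- **Femur-connection condition** is evaluated on connected components of the
  contrast/aggregation survivors (the only order in which it is decidable).
- **MT initialization.**  The muscle-component height starts at the
  VOI_AT:VOI_MLS voxel ratio times the modal count; its peak starts at
  T_HDM, the only phantom-anchored muscle-scale value in the calibration.
- **Surfaces are lateral.**  Grid faces and analysis-slab end faces never
  count as body surface or fascia: anatomy continues beyond the scanned
  extent, and treating cut faces as surface would corrupt dermis- and
  fascia-connectivity at the slab ends.
- **Slab direction.**  VOI_US extends distally from the acetabulum end
  slice.

## Noise experiment protocol

`noise_experiment` adds Gaussian noise so the total reaches k× the current
level (default k = 2, the operational definition of simulating 135 mAs from
a 170 mAs acquisition; variances add, so sd_add = sd·√(k²−1)).  A 1/√mAs
quantum-noise mode is also provided — note 170→135 mAs corresponds to
×1.12, not ×2; the doubling convention is kept as the operational default.

By default the replay holds the *fascia-level* state of the recorded
session — body, slab, VOI_IF, dermis and the calibration references CT_H2O
and CT_AT — and re-derives everything histogram-based (T_AT, the MLS
Gaussian mixture, MT, concentration bins) plus all features on the noisy
volume.  Rationale: the water value is a per-scan calibration, and the
fascia is an operator-validated anatomical boundary; the noise question is
how measurements respond given that calibration.  A full re-segmentation
mode (`mode="full"`) exists; on phantoms it adds a systematic fascia-edge
drift of a few tenths of a percent to SAT/IF densities because the phantom's
fascia sheet sits at a single sharp contrast value — behavior the frozen
protocol isolates away.

## The synthetic phantom

The phantom renders, per axial slice, nested elliptic rings per leg (dermis
100 HU, SAT −100 HU, a 2-voxel fascia at −40 HU, perimuscular fat pockets at
−110 HU over half the circumference, muscle 40 HU, femur 700 HU), EML
speckles in the muscle, optional edema blobs in the SAT, a soft-tissue
bridge joining the legs (as the perineal region does in a hip scan), a water
insert below, smooth per-slice center jitter, low-frequency HU texture in
muscle (2 HU SD, emulating intramyocellular-lipid heterogeneity) and SAT
(3.5 HU SD), and white Gaussian noise.

Deliberate rendering choices: the fascia HU must lie in the contrast band
C ∈ [0.5, 1] — below it the candidate predicate can never reach the fascia
and the method (correctly) fails to recover it; internal fat is set slightly
leaner than SAT (−110 vs −100 HU) because a noiseless SAT spectrum makes
T_AT equal the SAT mean exactly and the strict HU < T_AT rule would
otherwise classify no PAT; the textures keep noiseless histograms from
collapsing into single-bin spikes that would defeat the histogram-based
thresholds (and the GMM seed rule HU > b, which no voxel satisfies when all
muscle equals b exactly).

Ground-truth compartment volumes are derived from the label map *by the
method's definitions*: intrafascia includes the fascia sheet; anatomical
muscle M = intrafascia minus PAT minus the dilated femur therefore includes
the sheet (clinically the fascia is sub-voxel thin and is never subtracted).

What the phantom does **not** emulate: beam hardening, scatter,
reconstruction kernels, anisotropic partial-volume effects, individual
muscle anatomy, genital organs, or a fascia whose contrast varies along its
course.  Passing phantom tests therefore demonstrates algorithmic
correctness and noise/calibration behavior of the implementation, not
clinical segmentation accuracy.

## Texture feature estimators

The method names the features; the estimators are standard definitions:

- **G_avg**: volume-weighted mean of the morphological pattern spectrum
  (openings with Euclidean balls of increasing diameter, 1 mm steps, via
  exact distance transforms).
- **FD**: box counting on the compartment boundary (6-connected surface),
  dyadic box sizes capped at one eighth of the bounding-box extent — coarser
  boxes saturate and bias the slope; least-squares slope of log N vs
  log(1/ε).  Solid-set counting and custom scales are available (a level-3
  Menger sponge counted at its ternary scales reproduces log20/log3).
- **Ψ**: Wadell sphericity with the surface area from a marching-cubes mesh
  whose orientation-dependent staircase inflation (up to ~13% for oblique
  surfaces; measured on digitized planes and frozen as a 9×9 lookup over the
  sorted normal octant) is divided out per triangle.  The correction is
  gated by the curvature of a Gaussian-smoothed orientation field (σ = 1
  voxel, gate 0.2 voxel⁻¹) so genuine sharp features — which are not
  staircase artifacts — keep their raw mesh area.  This keeps a digital ball
  ≥ 0.97 and an axis-aligned cube within 0.03 of (π/6)^(1/3)
  simultaneously; pure mesh area fails the former, orientation-averaged
  configuration weights fail the latter.  For masks of only a few voxels the
  area estimate is unreliable and Ψ can exceed 1.

## Precision statistics

CV_RMS = 100·√(mean over subjects of (SD/|mean|)²) with sample SD (ddof 1);
CV_100 is the percentage cohort CV divided by 100, i.e. simply SD/|mean|,
reported on that scale so reanalysis errors can be compared against cohort
variation directly.  Replaying a persisted session is bit-deterministic (no
randomness anywhere in the segmentation path), so the automation floor of
the reanalysis precision is exactly zero — tested via mask checksums and
feature equality.

## Known limitations

- Operator inputs (grade, acetabulum slice, trochanter slice, gap seeds,
  reject markers) come from session files; no interactive tooling.
- The optional deformable-model fascia refinement is out of scope.
- Sphericity under strongly anisotropic spacing uses a geometric-mean voxel
  face scale (exact only for isotropic grids).
- The GMM assumes exactly two tissue modes in the fit window; cohorts with
  destroyed muscle tissue may not separate into adipose/muscle modes.
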