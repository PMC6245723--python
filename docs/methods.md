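# Methods

## Scope and units

The unit of scoring is a *clip*: one stabilized video sequence of the
sublingual microcirculation, represented by manually traced vessel
centerlines (piecewise-linear, μm), a lumen diameter per vessel, and a
per-vessel semiquantitative flow score (0 absent, 1 sluggish, 2
moderate, 3 brisk; *perfused* means ≥ 2). Coordinates use the raster
convention — origin top-left, x rightward, y downward — and the field
of view (FOV) is the half-open rectangle [0, W) × [0, H); the default
synthetic FOV is 1000 × 750 μm, a plausible handheld-microscope field,
and no density metric depends on the choice after area normalization.

Vessels are classed by lumen diameter: small < 20 μm, medium 20–50 μm
(both boundaries inclusive of medium), large > 50 μm. Only small
vessels — the capillary range where gas exchange happens — enter any
reported metric; medium and large vessels are carried in the data model
and deliberately inert.

## The six metrics

* **TVD** (mm/mm²): total small-vessel centerline length *inside the
  FOV* divided by FOV area. Out-of-view portions of a trace are removed
  by exact polyline–rectangle clipping (shapely); points on the FOV
  boundary count as inside.
* **PPV**: perfused small-vessel in-view length / total small-vessel
  in-view length. Missing (not 0) when no small-vessel length is in
  view — the analysis stage must distinguish "nothing visible" from
  "nothing perfused". PPV is computed as perfused/total, the direction
  that yields a proportion in [0, 1].
* **PVD** (mm/mm²): PPV × TVD, identically equal to perfused in-view
  length / area at clip level. The identity is asserted to 1e-12 in the
  tests; after clip averaging it is *not* re-imposed (means of ratios
  are not ratios of means), and only PVD ≤ TVD survives aggregation.
* **MFI**: the FOV is split into four equal quadrants at (W/2, H/2);
  each quadrant's *mode* flow score is the score carrying the greatest
  clipped small-vessel length there, and MFI is the mean of the modes.
  Ties break to the lower score (conservative: under-calls perfusion;
  configurable). Quadrants with no small-vessel length are skipped
  rather than scored 0 — absence of visible vessels is not absent
  flow — with a `zero` option for sensitivity analyses. MFI is missing
  only when all four quadrants are empty.
* **Heterogeneity index**: (max − min)/mean over the same quadrant
  modes; 0 when the mean mode is 0 (all-absent flow is homogeneous);
  missing with fewer than two scored quadrants. The index is computed
  per clip and then averaged across a subject-time-point's clips, never
  recomputed on pooled quadrants, because the clip is the unit of
  scoring.
* **De Backer score** (n/mm): crossings between small-vessel
  centerlines and a grid of three vertical plus three horizontal lines,
  divided by total grid length 3(W+H). "Equally spaced" places the
  lines at 1/4, 1/2, 3/4 of each dimension (equal gaps including the
  implicit border gaps). Crossing counting follows what a human rater
  does: each connected component of the intersection with one grid line
  counts once, so a vertex exactly on a line counts once (not once per
  incident segment), a tangent touch counts once, and a sub-segment
  running along a grid line counts once regardless of overlap length.
  Crossings are counted on centerlines, consistent with the tracing
  workflow; by default only small vessels count (flag to include all
  sizes).

A traced vessel lying exactly on the quadrant midline is clipped into
both adjacent quadrants; this measure-zero double count cannot occur
for continuous random traces and is irrelevant to the mode.

## Clip quality and aggregation

Each clip carries five boolean quality flags (pressure artifact,
content artifact, focus, brightness, stability); the ordinal quality
score is the count of clean flags. Selection excludes clips with
pressure or content artifacts or duration outside the 3–10 s
stabilized-sequence window, ranks the rest by ordinal quality, then
duration, then clip id, and keeps at most three per subject-time-point.
Subject-time-point values are unweighted means over selected clips,
skipping missing values; a metric is missing only when missing in every
clip.

## Synthetic data

No raw videos from the source study were deposited, so the generator is
the test bed for every downstream stage. It emulates the *statistical*
structure of the design, not vascular biology:

* **Per-clip networks.** Small-vessel centerlines are random walks with
  20 μm steps and Gaussian turning angles (SD = tortuosity, default
  0.35 rad), confined to the FOV, laid down until total centerline
  length reaches target_TVD × area, with the final vessel truncated to
  land on the budget exactly — the generator is calibrated by
  construction, and the pipeline-computed TVD of a clip equals its
  target to floating-point error. Perfusion is Bernoulli(ppv_target)
  per vessel, the flow score drawn conditionally on perfusion status
  (defaults put most mass on score 3, matching observed MFI medians
  ≈ 2.9 and the abundance of heterogeneity-index zeros). With
  probability `heterogeneity_boost` one random quadrant's vessels flow
  one class lower (3→2, 1→0, preserving perfusion status and hence
  PPV), which spreads the quadrant modes. A few medium/large vessels
  wander freely and verify the exclusion rule.
* **Cohorts.** 207 subjects by default, randomized 1:1:1 to
  EGDT / protocolized-noninvasive / usual care, death drawn at 19.3%.
  Subject-time TVD targets are group (survival) × time-point means and
  SDs as observed in the source cohort (survivors 22.6/23.0/22.1,
  nonsurvivors 21.1/21.7/19.3 mm/mm² at 6/24/72 h), decomposed into a
  subject-level Gaussian random effect carrying 60% of the variance
  (the intraclass correlation the GEE working correlation models — a
  stated assumption, not an observed quantity) and independent
  time-level noise; clips within a subject-time share the target up to
  1 mm/mm² jitter. PPV gets a subject-level logit-normal effect (SD
  0.5) around 0.90. Time points are attempted with probability 0.86
  and pass quality with probability 0.83/0.75/0.82 at 6/24/72 h;
  analyzable time points receive 1–3 clips with mean 2.8. Ages,
  Charlson indices, SOFA and the seven macrocirculatory parameters are
  drawn from survival-conditional Gaussians with the cohort's group
  means and SDs; driving pressure is always derived as MAP − CVP, never
  drawn. Survival influences traces *only* through these configured
  parameters (no leakage), and macro parameters are independent of the
  networks unless a coupling is injected for a recovery test.
* **Determinism.** Seed streams are keyed by (master, subject, time,
  clip) via `SeedSequence` spawn keys, so identical seeds give
  byte-identical output files and adding a subject does not perturb the
  others.
* **Metrics-level simulator.** For many-replicate calibration studies
  of the analysis stage a companion simulator draws subject-time metric
  values directly from the same latent model (zero-inflated gamma for
  the heterogeneity index, truncated normal for MFI, De Backer ≈
  (2/π)·TVD as integral geometry predicts for isotropic curves), because
  building thousands of vessel networks would add geometry time but no
  statistical information.

What the generator does **not** emulate: branching topology, vessel
curvature statistics of real mucosa, temporal flow dynamics within a
clip, site/operator effects, and informative missingness (dropout is
independent of severity). Passing tests therefore demonstrate the
pipeline's correctness and calibration under the design's statistical
structure, not biological realism of the traces.

## Analysis stage

All models are GEEs with the subject as cluster, fitted by statsmodels.
The family registry is fixed: Gaussian identity for TVD, PVD and
De Backer; gamma log for the skewed positive MFI and PPV; Tweedie with
log link for the heterogeneity index; binomial logit for mortality. The
Tweedie variance power defaults to 1.5, mid-range of the
compound-Poisson interval (1, 2) that permits the exact zeros dominating
the heterogeneity index; it is configurable.

* **Working correlation** is unstructured over the three time points.
  A fit that fails or does not converge (tolerance 1e-8, 200 iterations)
  is retried with an independence working correlation and flagged in the
  output rather than raised — GEE point estimates remain consistent
  under working-correlation misspecification. The mortality models use
  independence *by design*: the death indicator is constant within a
  subject, so any non-diagonal working correlation is singular there
  and collapses the estimating equations; with independence the model
  is logistic regression with cluster-robust errors.
* **Inference** uses the bias-reduced (Mancl–DeRouen) sandwich
  covariance with normal-reference Wald tests. The plain sandwich is
  anticonservative with cluster counts in the tens (per-arm subgroups
  of a ~60-subject null design rejected at ~8–9% nominal 5% in pilot
  simulations); the bias-reduced form restores calibration, which the
  acceptance suite verifies for every family at 500 null replicates.
* **Arm models** regress each metric on EGDT and noninvasive indicators
  (usual care as reference) plus age and Charlson index. An arm×time
  interaction model is fitted first; when no interaction term reaches
  p < 0.05 the main-effects model is reported. Pairwise arm contrasts
  are unadjusted and gated on the overall model (the Fisher LSD
  convention).
* **Mortality models** regress death on each metric across all time
  points, adjusted for age and Charlson; per-time-point survivor /
  nonsurvivor summaries report mean ± SD for the near-normal densities
  and median [IQR] for MFI, PPV and the heterogeneity index. A metric
  constant across subjects yields a flagged degenerate row, not a crash.
* **Macro–micro models** regress each metric on each of MAP, SBP, DBP,
  HR, CVP, MAP−CVP and lactate (pairwise deletion of missing macro
  values), with the metric's own family; the MAP−CVP identity is
  verified before fitting. Survivor/nonsurvivor macro comparisons are
  Welch t-tests pooled over time points.
* Reported percentages round half-up at the printed precision
  (74.5% → 75%), matching publication arithmetic.

## Problem sizes in the test and acceptance suites

Oracle equivalence uses 1000 random clips against an independent
Liang–Barsky clipping oracle (exact), a stratified 10⁴-samples-per-
segment length oracle (0.1% tolerance), and a 0.1 μm rasterized
crossing oracle (exact match). Generator closure scores 138 clips
calibrated to the survivor 6-h TVD cell (mean 22.6, SD 4.2 mm/mm²) and
requires the sample mean within 2 SE. Type-I calibration runs 500 null
replicates at 60 subjects per replicate for each family (acceptance
band 3 binomial SEs around 0.05); direction recovery runs 200
replicates at the full cohort size of 207 and requires the
survivor-favoring TVD sign in ≥ 80%. The full suite completes in a few
minutes on one CPU.

## Known limitations

* Flow is scored per traced vessel, not per sub-segment; a vessel with
  spatially varying flow is a single class.
* The quadrant mode is length-weighted, one of several defensible
  readings of "predominant flow"; count-weighted modes would differ on
  clips with many short vessels.
* Real cohort effect estimates (arm and mortality betas on patient
  data) are out of reach without the original videos; the analysis
  stage is validated by simulation calibration and direction recovery,
  not by reproducing published coefficients.
* The Tweedie working model treats the heterogeneity index marginally;
  its exact-zero mass is emulated, but the power parameter is a
  modelling choice, not estimated.
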