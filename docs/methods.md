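# Methods

## The analysis model

The package links two imaging-derived descriptions of a DBS program to
behavioural change scores Δ = (DBS-on value) − (DBS-off value), so a
negative Δ means the measure decreased with stimulation on.

**Location.** The stimulation volume (VAT) is intersected with an STN
parcellation. The nucleus is split along its dorsolateral–ventromedial
axis into a *motor* and a *non-motor* (associative + limbic) territory;
associative and limbic are carried separately in the label map but
combined for all headline statistics. Overlap is the fraction of VAT
voxels inside a territory, `|VAT ∩ region| / |VAT|`, computed per
hemisphere and averaged; the outside-STN remainder closes the partition
to 1 exactly (same grid, exclusive labels). Overlap fractions are
rank-correlated (Spearman, average ranks) with each Δ.

**Connectivity.** The bilateral VAT (voxelwise union of hemispheres) is
the seed for all streamline operations. A fibre "touches" the seed iff
any point of the streamline, after arc-length resampling to ≤ 0.5 mm
steps, falls inside a seed voxel of the 1 mm grid (voxel = half-open box
around the affine image of its integer index). Three derived measures:

* *ROI fibre counts* — raw counts of streamlines touching both the seed
  and a cortical ROI mask (unweighted: counts are counts).
* *Mass t-screen* — for every fibre, subjects split into
  connected/unconnected groups; the pooled-variance two-sample t of Δ
  (connected − unconnected, so positive t means connected subjects show
  the larger change) is the fibre's discriminative score. Fibres with
  fewer than `min_group = 2` subjects on either side are *excluded*
  (not zeroed). The 20% highest |t| (ceil rule; ties broken by fibre id
  ascending; signs preserved) are retained as the discriminative
  profile. A Welch variant and signed-descending ranking exist as
  options; the defaults are the pooled t and |t| ranking, because the
  retained profile is interpreted with both signs.
* *R-maps* — per voxel, Spearman ρ across subjects between the
  VAT-to-voxel fibre density (each connected fibre counted once per
  voxel) and Δ; voxels with non-varying density are undefined (NaN),
  never zero-filled.

No multiple-comparison correction is applied anywhere: the screen and
the correlation tables are exploratory and all p-values are reported
uncorrected, at α = 0.05.

**Prediction.** Leave-one-out: for each held-out subject the screen is
re-run on the remaining cohort; every subject's binary connectivity
fingerprint (1 = touches the fibre, 0 = does not, defined over the whole
fibre universe since both states are observed) is Pearson-correlated
with the retained t-profile (zero-filled outside the retained set); an
OLS line Δ ~ fingerprint-correlation fitted on the training subjects
predicts the held-out Δ. Overall predictability is the Pearson R between
predicted and observed Δ.

The fingerprint is defined over the full fibre universe rather than the
retained set alone: restricting it to the retained set makes the
predictor undefined (zero variance) for any subject touching all — or
none — of the retained fibres, which in practice voided 2–4 of 14
predictions per fold. Over the universe it degenerates only for a
subject touching no fibre at all.

**Significance of R.** Cross-validated correlations are biased negative
under the null (each prediction is anchored to a training mean that
excludes the held-out case): measured over 500 label permutations, the
null R here has mean ≈ −0.20, and a naive two-sided t-based p rejects at
rate 0.20 instead of 0.05. The default p is therefore a label
permutation test — the *entire* leave-one-out loop re-run per shuffle
(B = 199 by default), one-sided (greater), since only a positive
predicted-observed correlation is evidence of predictability. The
parametric p remains available for comparison. The permutation test is
exactly calibrated by construction; the suite verifies the empirical
rate (0.036 with B = 199, inside the binomial 95% band around 0.05,
which is the expected 0.045 up to discreteness).

## Group behavioural statistics

Trial outcomes partition exhaustively: *invalid* (no detected saccade),
*anticipatory* (latency < 90 ms, removed entirely — a guess launched
before the stimulus could be processed), *error* (first saccade toward
the target), *correct* (away). "Valid" trials are errors + corrects;
the error rate is errors / valid; mean latency is over correct trials
only. The 90 ms boundary itself counts as valid (the cutoff is
`latency < 90`, equivalent to "> 89 ms" for integer milliseconds).
Paired t-tests use the exact textbook formulas
(`t = mean(Δ)/(sd(Δ)/√n)`, df = n − 1, CI = mean ± t₀.₉₇₅,df·se) and are
also available directly from summary statistics, which reproduces
printed group tables from their means/sds. Cumulative latency
distributions are probit-scaled with proportions clipped to
[1/(2N), 1 − 1/(2N)] so the transform stays finite.

Spearman p-values use the t-approximation for n ≥ 10 and an exhaustive
permutation of one rank vector below that (exact under ties as well);
zero-variance inputs raise rather than returning 0.

## The electric-field stand-in

The field model is a deliberate simplification: each active contact is a
point source in a homogeneous medium, `E(r) = k·I_c/r²` (V/mm) with
`I_c` the contact's share of the total current (mA) and
`k = 0.6 V·mm/mA` by default, summed over active contacts, with `r`
clamped below at the lead radius (0.65 mm). What this preserves — and
what the downstream analysis actually consumes — is the 0.2 V/mm
activation-threshold semantics, exact linearity in amplitude (hence VAT
monotonicity), and directional steering through segment current shares.
A single contact with `k·I = 0.8 V·mm` has an analytic VAT radius of
2.0 mm; its voxelization at 1 mm differs from the sphere volume by 1.5%.
With the default k, a typical 2 mA ring program gives a ~2.4 mm VAT
radius, the scale usually reported for therapeutic programs. What the
model does not represent: tissue heterogeneity/anisotropy, the
electrode's insulating body, pulse-width effects, and axon activation
models — absolute VAT volumes are therefore not comparable to
patient-specific modelling, while within-cohort contrasts (the only
thing the statistics use) are.

The lead is modelled with ring contacts at the distal and proximal poles
and two rows of three 120° segments between them (centres 2 mm apart,
distal ring centre 1.5 mm above the tip). VAT masks keep only the
connected component(s) containing active contacts, so a distant
secondary lobe cannot masquerade as stimulation.

## The synthetic cohort

The generator emulates the study conditions end to end: 14 subjects,
bilateral 8-contact directional leads, three blocks of 50 antisaccades
per DBS condition (150 trials/condition), targets at ±10°, one 1 mm
isotropic "standard space" (identity affine, 64³) shared by every
artifact.

* **Anatomy.** Each STN is an ellipsoid (semi-axes 4.5 × 3.5 × 3 mm)
  split by a plane perpendicular to the dorsolateral axis placed at the
  exact quantile that makes the non-motor share 35% of STN voxels (30%
  of that limbic). Eight cortical ROIs are 3 mm spheres at fixed,
  hemisphere-mirrored positions.
* **Fibres.** Three bundle families per hemisphere (30 fibres each),
  cubic splines through jittered waypoints: *ventromedial* fibres
  terminate at topographically spread depths inside the non-motor
  territory and leave medially toward the ACC; *dorsolateral* fibres
  traverse the nucleus dorsoventrally toward the FEF — any VAT that
  reaches the STN touches them, so they fail the min-group rule and
  carry no discriminative signal, as widely shared motor fibres should;
  *bypass* fibres pass 6.2 mm lateral to the STN centre (never entering
  the nucleus) toward the SEF.
* **Leads.** Per subject, lead position varies along the
  dorsolateral–ventromedial axis (−3.5 … +2 mm) and laterally
  (0 … 4 mm), shared between hemispheres up to a 0.4 mm jitter;
  amplitudes are uniform in 1.5–3.5 mA on the distal ring. This spreads
  the cohort over non-motor overlaps of ~0–0.6 and bypass exposures of
  ~0–0.9.
* **Outcomes.** Δerror = 0.5 × (bilateral non-motor overlap) + ε and
  Δlatency = −60 ms × (fraction of bypass fibres touched) + ε, with ε
  Gaussian. The noise scales default to 0.25 × the range of the
  noiseless planted Δ — the study's signal-to-noise condition — and can
  be set absolutely. Baseline error rates (0.45 ± 0.18, clipped) and
  latencies (355 ± 45 ms) are per-subject; trial tables are then sampled
  so that error status is Bernoulli among non-anticipatory trials and
  correct-trial latencies are lognormal (σ = 0.25) around the planted
  mean — aggregation recovers the planted values up to binomial/sampling
  error. A configurable fraction (3%) of trials is anticipatory.
* **Determinism.** All randomness flows from one seed sequence with
  named children per artifact; identical configs reproduce every
  artifact bit for bit.

What the generator does *not* emulate: realistic MRI intensities or STN
shape, fibre curvature statistics of real tractography, inter-subject
anatomical variability (one common atlas space), saccade main-sequence
kinematics, or EyeLink raw samples. Passing tests therefore demonstrate
that the *pipeline* recovers planted structure under controlled
conditions — not that the field model or the atlas would fit any real
patient.

## Numerical choices and edge cases

* Overlap of an *empty* VAT raises (the normalization divides by VAT
  volume); it is never reported as 0.
* Retention count is ⌈fraction × scored⌉, minimum 1 when anything is
  scored; an empty profile stays empty.
* In the mass screen, zero pooled variance yields t = 0 when the group
  means agree (no discrimination) and ±∞ when they differ (perfect
  separation); both-constant groups cannot occur with continuous Δ and
  group sizes ≥ 2.
* A missing hemisphere propagates NaN through the bilateral average with
  a warning; subjects missing a DBS condition are dropped from change
  scores with a warning.
* Streamline-touch membership is stable under step refinement in the
  superset sense: halving the 0.5 mm step never loses a fibre and adds
  only corner-tangent cases (≤ 2% of the synthetic tractogram). Exact
  step-invariance is unattainable because a fibre's chord through a
  voxel can be arbitrarily short.
* Spearman ρ under average ranks cannot reach 1 when one variable has
  ties; cohorts containing subjects with exactly zero non-motor overlap
  top out slightly below 1 even at vanishing noise.

## Known limitations

* The fingerprint-correlation predictor saturates: even at zero
  behavioural noise the leave-one-out R plateaus around 0.75–0.85,
  because a binary touch pattern compresses the graded overlap effect
  nonlinearly. The LOOCV is a validation device, not an optimal
  predictor.
* With ~180 synthetic fibres, the screen's retained set is small
  (~20–40); culprit-bundle recovery is reliable but not guaranteed for
  every noise draw at the default signal-to-noise (the planted effect
  itself can be washed out by an unlucky ε realization).
* The permutation p has resolution 1/(B+1); with the default B = 199 the
  smallest attainable p is 0.005.
* Atlas and data must share one grid; resampling between grids is
  nearest-neighbour and warned about, as the reference path assumes a
  single standard space.
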