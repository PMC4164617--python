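# Methods

`dwiresponse` implements the quantitative chain of a preclinical
diffusion-weighted MRI (DW-MRI) therapy-response study: a two-group tumor
xenograft design (therapy vs. control, 12 vs. 11 animals) imaged at
baseline and follow-up, analyzed via voxelwise apparent-diffusion-coefficient
(ADC) maps, volume-of-interest (VOI) summary metrics and a statistical
layer built around ROC analysis and Fisher's linear discriminant.  This
note records the models, the numerical choices and their rationale, and
what the synthetic data do and do not establish.

## Signal model and ADC fitting

Each voxel's magnitude signal across diffusion weightings b (s/mm^2)
follows the monoexponential model

    S(b) = S0 * exp(-b * ADC),

with ADC expressed throughout in units of 1e-3 mm^2/s.  The acquisition
protocol provides nine weightings (10, 25, 50, 80, 130, 200, 350, 550,
800 s/mm^2) and no b = 0 image, so S0 is a free parameter.  Both
parameters are estimated per voxel by unweighted least squares under the
constraints S0 > 0 and ADC in [0, 10]; the cap sits far above free water
(~3) and only rejects pathological fits, and hitting a bound still counts
as converged.

Numerically the fit uses variable projection: for fixed ADC the optimal
S0 is closed-form, leaving a 1-D profiled objective in ADC.  That profile
is minimized by a 257-point bracketing scan over [0, 10], golden-section
refinement inside the winning bracket, and finally a secant polish of the
stationarity condition (by the envelope theorem the profiled gradient is
proportional to sum_i r_i * b_i * exp(-b_i * ADC), which — unlike the RSS
itself — is not cancellation-limited near the optimum).  The combination is
deterministic, derivative-free until the polish, immune to the local
minima a descent method can hit on noisy decay curves, and recovers
noiseless data to machine precision (the residual-sum formulation is
computed from explicit residuals for the same reason).  A voxel is flagged
invalid rather than raising when at least half its signals are
non-positive or the profiled S0 is not positive; invalid voxels carry NaN
and are excluded from all statistics (zero-filling would bias the VOI
median downward).

The objective is unweighted and no Rician bias correction is applied.  At
the study's SNR this leaves a small downward ADC bias at b = 800 (visible
as the ~0.2 % median error at SNR 50 in the acceptance run); correcting it
would require a noise-floor model that the original analysis did not use.

Trace images (the average of three orthogonal diffusion directions) are
formed by `trace_average` before fitting; the synthetic phantom emits
trace-equivalent images directly, and direction-level simulation is out of
scope.

## Registration

Bulk motion between the acquisitions at different b-values corrupts the
per-voxel decay curves.  The series is therefore aligned along the
b-value dimension before fitting: translation-only, per 2-D slice, with
the lowest-b volume (highest SNR) as reference.  The estimator is phase
correlation — the spectrally whitened cross-power spectrum, regularized by
a small fraction of its peak magnitude — with the integer peak refined to
sub-voxel precision by a separable quadratic fit over the circular
neighbors; offsets below 1e-6 voxels are snapped to zero so exact integer
shifts are recovered exactly.  Resampling uses band-limited Fourier
interpolation (integer shifts reduce to exact rolls).  Boundary semantics
are circular, inherent to the Fourier model; phantoms keep objects away
from the edge.  Rotation is not modelled: in an anesthetized rodent with
axial slices, bulk motion is predominantly in-plane translation.
A slice that is constant in both reference and moving image (e.g. a
background-only slice of a noiseless phantom) carries no motion
information and passes through with zero shift; a slice constant on one
side only is a degenerate input and raises.

## VOI metrics

The representative tumor ADC of a session is the median of the voxelwise
ADC distribution over the valid voxels inside the VOI (even counts: mean
of the two central order statistics).  Tumor volume is the voxel count of
the (T2-geometry) mask times voxel footprint times effective slice
spacing (thickness + gap; the T2 protocol has gap 0, the term exists for
generality).  Growth is reported as percent of baseline,
100*(V_F - V_B)/V_B, and ADC change as the absolute difference
ADC_F - ADC_B.  Group summaries are median ± SD, and group medians of
changes are always medians of per-animal changes — never differences of
group medians, which are a different quantity.  The caliper volume
a*b*c*0.5 is provided for enrollment-style size checks.

In the image pipeline the ΔVOL masks are the T2-geometry masks when the
configuration provides them; phantom-mode sessions have a single geometry
and fall back to the DWI VOI.

## Synthetic data

**Phantom.**  An ellipsoidal tumor (default ADC 0.75, S0 1000) in a
homogeneous background (ADC 1.40, S0 400), optionally with a
higher-ADC necrotic core, sampled at the nine protocol b-values on the
protocol geometry (65x50 mm field of view, 68x52 matrix, 12 slices of
2 mm + 0.4 mm gap).  Noise is Rician — each voxel becomes
sqrt((v+n1)^2 + n2^2) with independent zero-mean Gaussians — because
magnitude MR images are Rician-distributed; it is parameterized by
SNR = S0_tumor/sigma, and it deliberately stresses the fit's low-signal
behavior at b = 800.  Bulk motion enters as per-b-value in-plane shifts
applied before noise (fractional shifts by Fourier interpolation, matching
the registration model).  The generator returns the ground-truth map, so
closure tests can score every stage.  The phantom does not emulate
anatomy, coil sensitivity, EPI distortion or perfusion/IVIM components:
passing tests demonstrate correctness of the estimation chain, not
robustness to those real-data effects.

**Cohort.**  Per group, the pair (ΔADC, ΔVOL%) is drawn from a Gaussian
copula with Gaussian margins; the copula correlation equals the Pearson
correlation of the pair under these margins, so the configured values are
used directly.  Gaussian margins mean the printed group medians serve as
locations without transformation.  Baseline ADC is Gaussian; baseline
volume is log-normal parameterized by its median and SD, because the
therapy group's volume spread (SD 449.1 vs median 347.8 mm^3) would give a
Gaussian substantial negative mass.  Follow-up values are derived from
baseline plus delta, so deltas are exact by construction.  Draws implying
non-positive volumes or ADCs (ΔVOL below -99.9 %, about 2.8 SD out in the
worst group) are rejected and redrawn.  Default parameters are the study
conditions: groups of 12 and 11; ΔADC +0.10±0.11 vs +0.03±0.09
(1e-3 mm^2/s); ΔVOL 33.30±47.30 % vs 96.43±31.66 %; baseline volumes
347.8±449.1 vs 219.7±79.5 mm^3; ΔADC-ΔVOL correlation 0.05 (therapy) vs
0.65 (control).  The true joint distribution of the original per-animal
values is unknowable from summaries; the generator targets exactly these
medians, spreads and correlations and nothing more.

All generators are deterministic under a fixed seed (seed streams are
spawned per b-value and per group), and different seeds differ.

## Statistics

Paired within-group comparisons use the Wilcoxon signed-rank test (zero
differences dropped, mid-ranks for ties, statistic min(W+, W-)); unpaired
between-group comparisons the Mann-Whitney U test (statistic
min(U_x, U_y)); the ΔADC-ΔVOL association Pearson's r with the t-based
two-sided p.  Both rank tests switch to their exact null distributions
when the (tie-free) effective sample size is at most 25 — so study-sized
groups always take the exact branch on continuous data — and otherwise use
the normal approximation with continuity/tie correction.  Two-sided p is
twice the one-sided tail, capped at 1.  The heavy lifting is delegated to
scipy; this package owns the branch selection and the degenerate-input
contracts, and the test suite verifies the exact branches against full
enumeration oracles.  No multiple-testing correction is applied, matching
the study design.

**ROC.**  Threshold candidates are the midpoints between consecutive
distinct scores plus ∓∞ sentinels — the convention of the standard ROC
packages, and the only one under which printed midpoint thresholds are
reproducible.  AUC is the trapezoidal area, identical to the tie-corrected
rank statistic (verified as an invariant).  The "optimal" operating point
maximizes Youden's J = sens + spec - 1, with ties broken by higher
specificity and then lower threshold; accuracy comes from the raw
confusion counts.  ΔADC enters with greater-is-positive (therapy ADC
rises), ΔVOL and the FLDA score with less-is-positive (therapy grows less
and scores below the cut).

**DeLong.**  Correlated AUCs measured on the same animals are compared via
placement values: per-positive and per-negative structural components,
sample covariance matrices (ddof 1) divided by the stratum sizes, and a
two-sided z-test on the AUC difference.  Zero estimated variance with
equal AUCs yields p = 1; with unequal AUCs it is a degenerate input.  The
acceptance suite checks the p-value against a stratified paired bootstrap
de-biased by the m/(m-1), n/(n-1) plugin factors (without the de-biasing
the comparison would measure the bootstrap's own small-sample bias, about
0.01 in p at n = 23), and its type-I error over 2000 null simulations.

**FLDA.**  The two-class Fisher direction is the inverse pooled
within-class covariance (denominator n1+n2-2) applied to the difference of
group means.  It is defined only up to positive scale; the canonical model
is unit-norm, oriented so the control group scores higher (therapy falls
below the threshold), and the stored threshold is the Youden-optimal cut
of the projected scores.  A `with_pinned_dadc` rescaling reproduces
reporting conventions that fix the ΔADC weight; only the weight ratio and
the induced classification are meaningful.  The discriminant is fitted and
evaluated on the same animals (resubstitution), mirroring the study
design; no cross-validation is attempted, and the optimistic bias of
resubstitution is a known property of the reported accuracies.

## Problem sizes and runtime

The test suite and the acceptance script run at deliberately modest sizes
chosen to make every check fast while keeping Monte-Carlo error well
inside the asserted tolerances: phantoms of 32x28x4 to 68x52x12 voxels
with 1.3-3.6 k tumor voxels, cohorts of 12/11 (study size) to 1e4 per
group for calibration, 100-500 replicate datasets for oracle equivalences
and AUC orderings, 1e5 bootstrap replicates and 2000 null simulations for
the DeLong checks.  The full suite completes in well under a minute on one
CPU.

## Known limitations

- No Rician-bias correction and unweighted least squares (documented
  above); at very low SNR the ADC is biased downward.
- Translation-only registration; no rotation, no inter-session
  (baseline-to-follow-up) registration — sessions are analyzed
  independently.
- The cohort generator reproduces first/second-order summaries and one
  correlation per group, not the unknown joint distribution of the
  original animals.
- NIfTI cannot carry slice thickness and gap separately; the JSON sidecar
  preserves both, the FSL-style `.bval` path assumes gap 0 on read.
- Histogram-shape analysis of the intra-VOI ADC distribution, IVIM and
  kurtosis models are out of scope.
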