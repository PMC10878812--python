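# Methods

This note documents the models, the inference scheme, the synthetic-data
generators and the numerical choices behind `dyadsync`, including the
points where the design was genuinely open and what the packaged choice
was.

## Pose similarity

**Pipeline.** Keypoints are consumed in the OpenPose BODY_25 index
convention (neck, shoulders, elbows, wrists; image pixels, y increasing
downward).  Person identity across frames uses an image-midline split on
the first two-person frame and nearest-centroid assignment afterwards —
appropriate for seated face-to-face dyads, which essentially never cross
sides.  A joint with detector confidence exactly 0 is missing; confidence
is otherwise unused (no confidence weighting).  Frames in which a person
has more than half of their joints missing are dropped rather than
imputed, because median-imputing a whole pose fabricates geometry.
Remaining missing coordinates are replaced by the per-joint median over
the recording; each coordinate series is then Savitzky–Golay filtered
(window 13 frames, polynomial order 2 — preserves quadratic kinematics
exactly).  Smoothing is applied per person after identity assignment.

**Score.** Each pose's distance matrix is scaled to unit Frobenius norm
(removing body size and camera distance), converted to an affinity
W = max(D̂) − D̂ with zero diagonal, and degree-normalized into
L̂ = I − Deg^(−1/2) W Deg^(−1/2).  The frame score is
1 / (1 + β‖L̂ₐ − L̂_b‖_F).

The comparison of pose matrices "via a Laplacian procedure" admits many
concrete formulas; this one was chosen because it is bounded in (0, 1],
equals 1 iff the normalized pose matrices coincide, is symmetric, and is
invariant to rigid motion and isotropic scaling.  The sensitivity β is
needed because ‖L̂ₐ − L̂_b‖_F between any two plausible seated upper-body
poses empirically tops out near 1 (measured over archetypal and random
pose pairs), so with β = 1 the score could not fall much below 0.5 for
real pose variation.  β = 3 is a packaged constant calibrated once so the
score spans the dynamic range reported for mirror-game dyads; it rescales
the metric without affecting any invariant.  The formula is isolated in
`laplacian_similarity` for substitution.

**Degenerate input.** A pose with all joints coincident has no defined
normalized Laplacian: if exactly one input is degenerate the score is 0
(with a warning); if both are, 1.0.

## Motion generator

Arm movement is parameterized per arm as a shoulder-relative angle,
reach, and elbow flare, each driven by sums of 2–4 random-phase sinusoids
(0.05–0.45 Hz) — smooth, band-limited, human-plausible trajectories with
controllable spectra.  The synchronized regime mirrors the participant's
tracks onto the confederate about the inter-person axis with a lag
(default 0.08 s) and adds smooth kinematic noise (default sd 3.5 px);
with zero lag and noise the labelled pose matrices coincide exactly and
the score is 1.  The control regime has one member move while the other
sits near-still (gentle sway about a hands-down rest pose), swapping
halfway; the confederate moves first.  Dropout (default 2% of
joint-frames) emulates detector misses.

Defaults: 300 s at 30 fps (~9000 frames per dyad).  The movement
amplitude, idle-pose parameters, mirror lag and kinematic noise are
packaged constants tuned **once** against the scorer so that the regime
means land at 0.80 (synchronized) and 0.43 (control); they were not
revisited afterwards.  The generator emulates the geometry and
missingness of pose-estimated video but not detector-specific artifacts
(identity switches, confidence gradients, occlusion-correlated noise), so
passing tests show the scorer's behavior on clean mirror-game-like
motion, not robustness to pose-estimation failure modes.

## Go/NoGo schedule and behaviour

The schedule generator produces 40 blocks (configurable, half AllGo, half
Mixed) of 12 trials; Mixed blocks contain 4 NoGo trials in random
positions (33%).  Timing: 2-s block cue, 1-s response window per trial
(≤500 ms stimulus + ≤500 ms blank), ITI uniform 0.5–1.5 s, inter-block
ISI uniform 16–22 s.  Block order and jitter are seeded.

Reaction times are generated on the log scale: cell locations are set so
that the *arithmetic* cell means (ms) hit their targets given the
residual sd (0.20, log scale) and participant random intercept/slope sds
(0.05 / 0.03); trials exceeding the 1000-ms response window are redrawn.
The packaged cell means anchor Control/AllGo at 230 ms and encode a
146.8-ms block-type effect and an 18.1-ms group effect with no
interaction.  (The reference descriptive table and the reference model
estimates are mutually inconsistent under any no-interaction generator —
a raw-mean block gap of 137 ms versus a model-scale effect of 146.8 ms —
and the calibration follows the model estimates, which are the recovered
quantities; as a result the Control/Mixed descriptive mean sits near
377 ms.)  The between-participant sds were likewise chosen to match the
interval widths the hierarchical model reports rather than the larger
descriptive sds, which conflate trial noise with participant spread.

Commission errors are Poisson counts per participant (lognormal rate
heterogeneity, sd 0.10 on the log scale), assigned to random NoGo trials;
a per-trial Bernoulli option exists for stress testing.  Count-scale
effects always refer to 80 NoGo trials (the full task's exposure) via a
log-exposure offset, so estimates are invariant to the number of blocks
simulated.  The speed–accuracy scenario (`speed_accuracy_params`) couples
each participant's expected mean RT to their log error rate with slope
−0.005 per ms and neutralizes group differences so the coupling is the
only RT–CE link; with the two-group defaults active, the between-group
speed–accuracy difference would add to the recovered slope.

**Model choices.** The RT model uses responded Go trials only (omissions
and NoGo responses excluded — standard Go/NoGo practice and the natural
support of the lognormal).  ms-scale effects are differences of posterior
marginal means over the lognormal link, E[RT | cell] = exp(η + (σ² +
var_u(cell))/2), marginalizing the random effects; effects are reported
in the treatment-coded direction (Mixed − AllGo; Synchronized − Control),
so both reference effects are positive.  The exploratory RT–CE model has
one count per participant, where an extra random intercept is not
separable from Poisson variation, so it is a fixed-effects Poisson
regression (the grouping structure of the reference analysis is not
printed; this reading is flagged here).  An extraversion covariate is
supported at the scoring level (summed 1–5 extraversion and 0–3
self-esteem Likert scales with reversed negative items) but is not in the
default models, having shown no meaningful contribution in the reference
analysis.

## fNIRS

**Forward model.**  Evoked concentration per long channel is the ROI's
peak amplitude (µM) times the block regressor (16-s boxcar at block
onsets convolved with the canonical HRF, scaled so one isolated block
peaks at 1).  Default HbR amplitudes are −1/3 of HbO (canonical
polarity).  A shared systemic series — slow drift (~0.004 Hz sinusoid
plus ramp) and a Mayer-wave sinusoid (default 0.095 Hz) — is added to
*all* channels with per-channel gains (HbR at 0.3× the HbO gain);
short (8 mm) channels carry systemic and noise but no evoked component.
Noise is AR(1) (default ρ = 0.4, sd 0.3 µM for HbO, half for HbR).
Concentrations are converted to two-wavelength intensity by inverting the
Beer–Lambert step exactly, so the analysis inverse recovers them; with
zero noise the first-level β equals the generating amplitude to machine
precision.  Cohorts add participant random intercepts and block-type
slopes (sd 0.3 / 0.2 µM per chromophore) — the structure the second-level
model assumes.  The generator does not emulate heartbeat or respiration
bands, motion artifacts, or channel-quality variation.

**First level.**  Downsampling filters with a zero-phase Butterworth
(corner 0.24 Hz, below the 0.3-Hz target Nyquist, protecting Mayer-wave
energy from aliasing) and resamples onto the 0.6-Hz grid; the task
regressors are built at the acquisition rate and passed through the same
resampling, keeping regressor and data consistent.  OD uses the temporal
mean as reference, OD = −ln(I/Ī).  The Beer–Lambert inversion uses the
standard Gratzer/Kollias decadic extinction coefficients (760 nm: HbO
586.0, HbR 1548.52; 850 nm: HbO 1058.0, HbR 691.32 cm⁻¹ M⁻¹) with
separation (cm) × ppf, ppf = 0.1 as the combined DPF/PVC factor;
natural-log OD is divided by ln 10 to match.  The drift basis is a
DCT-II set with frequencies up to 0.01 Hz (cutoff period 100 s); a
component lying exactly in the basis is absorbed completely, a generic
slow sine up to small leakage.  Short-channel principal components are
computed per chromophore on the converted, downsampled series and all
components are entered (whether the reference pipeline entered them
jointly or per chromophore is not stated; per-chromophore is the packaged
reading).  The AR(1) GLM is single-pass Cochrane–Orcutt via statsmodels
GLSAR (OLS → ρ̂ from lag-1 residual autocorrelation → prewhiten → refit);
iteration count configurable.  Channels outside 20–40 mm are rejected;
ROI pooling is inverse-variance (w = 1/SE²) with pooled SE = (Σw)^(−1/2);
an empty ROI is reported missing, never zero.

## Second level and inference engine

No MCMC probabilistic-programming framework is used.  All hierarchical
Gaussian models are linear mixed models, fitted by an exact-conditional
scheme: random effects and fixed effects are integrated analytically
(Woodbury identities per participant block), leaving a marginal posterior
over the few variance parameters (4 for the RT model, 13 for the
bivariate model); that marginal is maximized (L-BFGS with a Nelder–Mead
polish) and approximated by a Gaussian at the mode; variance-parameter
draws come from this Laplace approximation, and per draw the fixed
effects are sampled from their exact Gaussian conditional.  Poisson
models integrate the random intercept by 31-point Gauss–Hermite
quadrature and take a joint Laplace approximation.  With the data sizes
used (hundreds to thousands of observations), these posteriors are close
to Gaussian and parameter-recovery tests show near-nominal HPD coverage.
Diagnostics are optimizer convergence and Hessian conditioning; a
non-converged fit withholds its effect summaries.  Priors are weakly
informative and configurable: N(0, (10·scale)²) on coefficients,
lognormal-type priors centred at a data-scale guess on sds (the
pilot-derived priors of the reference analysis are not available).
Residual negative-curvature directions left by the optimizer are handled
by taking curvature magnitudes with a relative floor when forming the
Laplace covariance.

The bivariate (HbO, HbR) model has one fixed effect per
BlockType × ROI × Group × chromophore cell (40), participant random
intercepts and block-type slopes per chromophore with an unstructured
4×4 covariance (the cross-outcome linkage), and a free 2×2 residual
covariance across the chromophore pair within each (participant, ROI,
block type); a missing half of a pair is marginalized, never imputed.
Contrasts are formed on posterior cell-mean draws with equal weights
(balanced design): AllGo−Mixed per ROI (positive = AllGo more positive)
and Control−Synchronized per ROI × block type (positive = Control more
positive).  An effect is "substantial" when the 95% HPD excludes zero
and a "trend" when zero lies outside the 90% but inside the 95% HPD —
the quantitative reading of "zero in the tail" chosen here.

**HbO−HbR difference.**  d = β_HbO − β_HbR per (participant, ROI, block
type); positive d is a canonical response, negative an inverted one.  A
pair is classed *negatively correlated* (cortical-like) when the two
point estimates have opposite signs — per-pair sign opposition is the
only correlation notion available for a single pair of point estimates;
the rule is isolated for substitution.  The negative-only filter retains
those rows for the conservative difference model `d ~ 1 + BlockType *
ROI * Group + (1 + BlockType | ID)`; cells emptied by the filter are
flagged and their contrasts suppressed.  The brain–behaviour model adds
per-cell slopes on standardized mean RT and commission-error count (and
their product), reported per original units; its random term is read as
(1 + BlockType | ID), the only well-formed reading of the printed
formula.

## Orchestration

One YAML config with per-stage sections drives the full chain; every
stochastic stage derives its seed from the single run seed, and re-runs
are byte-identical.  The run directory's manifest records stage
configuration hashes, seeds and SHA-256 hashes of every output; re-runs
reuse cached outputs when hashes match and refuse corrupted
intermediates.  The default pipeline sizes (3 dyads at 60 s, 12
participants per group over 20 blocks, 6 fNIRS participants per group on
a reduced montage) are chosen so a complete run finishes in well under a
minute; all sizes scale up through the config.

## Problem sizes used in verification

The test suite and the acceptance script verify the chain at reduced
scale: RT effects at 20 participants/group over 20 blocks (10 replicate
cohorts, posterior means averaged); commission errors and the
speed–accuracy slope at 30/group over the full 40 blocks; similarity at
10 dyads per regime at full duration (300 s, 30 fps); fNIRS at 15
participants/group, 10 blocks, on a 10-long/4-short montage, with the
short-channel benefit measured as an RMSE ratio over 100 single-subject
replicates.  These sizes give Monte-Carlo error comfortably inside the
documented tolerances.

## Known limitations

* Posterior inference is approximate (Laplace over variance parameters);
  extremely small cohorts or near-zero variance components push the
  approximation hardest — convergence flags should be checked there.
* The Laplacian score formula and its sensitivity constant are one
  defensible reading of an underspecified comparison procedure; scores
  are comparable within this package, not across implementations.
* The negative-correlation classification uses point-estimate signs
  only; it ignores estimate uncertainty, so near-zero estimates classify
  noisily.
* The generators match the statistical structure the models assume; they
  do not probe model misspecification (non-lognormal RTs, non-AR(1)
  noise, HRF mismatch).
* Coverage statements for the 40 second-level cells are correlated
  through shared participant effects; misses cluster rather than occur
  independently.
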