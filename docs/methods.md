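# Methods

This note documents the models, algorithms and numerical choices behind
`circoord`, in the package's own words: what is computed, under which
assumptions, and what the synthetic-data tests do and do not establish.

## Kinematics preprocessing

**Inputs.** One trial is a uniformly sampled time series (default 60 Hz)
of the vertical center-of-mass (COM) position and the sagittal-plane
angular velocities of the bilateral hip, knee and ankle, signed positive
for hip/knee flexion and ankle dorsiflexion.  Files follow the
OpenSim-style storage dialect: optional header lines terminated by
`endheader`, then a whitespace-delimited numeric table whose first column
is time.  Column names are mapped via a configurable `column_map`.

**Filtering.** All series pass through a low-pass Butterworth filter
applied forward and backward (`scipy.signal.filtfilt`), giving zero phase
lag.  The configured order (default 4) is the *net* order: a 2nd-order
design applied twice.  This convention is explicit because "4th-order
zero-phase" is reported ambiguously across motion-capture toolchains; the
alternative (4th-order design, net 8th) is one config value away.  The
default cutoff is 8 Hz, configurable; residual-analysis-based cutoff
selection is out of scope.

**Phase segmentation.** The trial splits at COM landmarks: Loading =
[trial start, COM global minimum), Jump = [COM minimum, maximum of the
post-minimum COM segment).  Ties resolve to the earliest index.  An
optional motion-onset detector (first sample with |COM velocity| above a
threshold, default 0.02 m/s) can replace the trial start, but is off by
default since onset is not part of the phase definitions.  Filtering
precedes segmentation; the filter order/segmentation order is otherwise
unspecified in the underlying methodology, and filtering first keeps the
landmark indices stable against sample-level noise.

**Time normalization.** Each phase window is linearly interpolated onto a
uniform percent grid with `n_points` = 101 (0–100% inclusive); endpoints
are preserved exactly, and resampling a uniform grid onto its own length
is the identity.

## Vector coding

The coupling angle of a proximal/distal joint pair is
γ = atan2(ω_proximal, ω_distal) mapped to [0°, 360°); it is undefined when
both velocities are zero.  Working from angular velocities (rather than
angle–angle plots) preserves temporal information and respects the
three-dimensional angular dynamics the velocities already encode.

**Undefined samples.** Beyond the exact both-zero case, grid points whose
interpolation support includes a *pre-filter* zero-velocity sample for
both joints of a pair are masked.  Rationale: a motionless joint's
post-filter velocity is pure numerical ringing of the IIR filter (relative
magnitude ~10⁻⁶–10⁻³), and its direction is meaningless, yet a circular
mean weights every sample equally — a handful of such samples can shift a
phase mean by degrees.  On real data (where measured velocities are never
exactly zero) the mask is empty and behaviour is identical to the plain
definition.

**Pattern bins.** Coordination patterns partition [0°, 360°) into
half-open 45° sectors: [0,45)∪[180,225) in-phase distal, [45,90)∪[225,270)
in-phase proximal, [90,135)∪[270,315) anti-phase distal,
[135,180)∪[315,360) anti-phase proximal; the pure proximal axes 90°/270°
are assigned to in-phase proximal so every velocity axis is classified by
the joint that is actually moving.  The bin table as published leaves the
45° multiples partially unassigned and double-assigns 90°/270°; the
half-open convention restores a total, non-overlapping partition.  A known
tension of the published scheme is preserved deliberately: within the
anti-phase quadrants the bin *labels* run opposite to the
dominancy-percentage convention (`dominancy_percent`, linear in angular
distance from the nearest distal axis, D100–P0 at 0°/180°); both are
implemented exactly as defined, and the continuous mean angle — not the
bins — is what enters inference.

**Circular means.** Per trial, coupling and phase, the mean angle is
computed from the mean cosine x̄ and sine ȳ via the piecewise
quadrant-mapped arctangent (equivalent to atan2(ȳ, x̄) mod 360°, verified
to < 10⁻⁹ degrees against that oracle), with resultant length
R = √(x̄² + ȳ²).  Undefined samples are excluded from n rather than
imputed; a zero resultant (e.g. antipodal angles) raises an explicit
error.  Each trial contributes one observation per coupling × phase (12
per trial): trials are repeated measures within subject, and keeping them
separate preserves information for the mixed model.  A per-condition
aggregation helper (`condition_summary`) reports circular mean ± circular
standard deviation (√(−2 ln R), labelled as such since a ± column is
otherwise ambiguous) for summary tables.

## The projected-normal circular mixed-effects model

**Model.** For observation i with angle θᵢ (radians), subject s(i) and
design row xᵢ (intercept, 3 condition dummies, 1 phase dummy, 3
interaction terms; reference cell P1/Loading):

    yᵢ = rᵢ (cos θᵢ, sin θᵢ),   yᵢ ~ N₂(μᵢ, I₂),
    μᵢ = (xᵢᵀβ_I + u_I,s(i) ,  xᵢᵀβ_II + u_II,s(i)),
    u_c,s ~ N(0, σ_c²)  independently per latent component c ∈ {I, II}.

Marginalising the latent length rᵢ > 0 gives the projected normal
distribution on the circle.  Random intercepts sit on *both* latent
components (a subject offsets both its preferred direction and its
concentration); a one-component variant would constrain subjects to share
concentration, which nothing in the data motivates.

**Priors.** β coefficients: independent N(0, 100²) — effectively flat on
the latent scale of these data (cell norms ~5–20).  Random-intercept
variances: inverse-gamma(0.1, 0.1), weakly informative.  Both are
configurable (`ModelSpec`).

**Sampler.** A data-augmentation Gibbs sampler:

1. *Latent lengths.* p(rᵢ | ·) ∝ rᵢ exp(−(rᵢ − tᵢ)²/2) on rᵢ > 0 with
   tᵢ = uᵢᵀμᵢ.  A slice variable bounds (rᵢ − tᵢ)², and the draw from the
   density ∝ r on the resulting interval is exact by inverse CDF
   (r = √(r₁² + V(r₂² − r₁²)), V ~ U(0,1)).
2. *Fixed effects.* Given r, each latent component is a Gaussian linear
   model with unit residual variance: conjugate multivariate-normal
   update via a pre-factored Cholesky of XᵀX + I/τ².
3. *Random intercepts and variances.* Conjugate normal and inverse-gamma
   updates per component.

Default run lengths are 4 chains × 35,000 post-burn-in iterations,
burn-in 13,000, thinning 8; simulation studies use the *reduced sampler*
(4 chains × 2,000 retained draws, burn-in 500, no thinning), which keeps a
single fit near one second while leaving contrast posteriors accurate —
verified against a dense-grid numerical posterior (below).  Chains are
seeded via `numpy.random.SeedSequence(seed).spawn`, making every fit
bit-reproducible for a fixed seed, config and input.

**Identifiability and diagnostics.** The likelihood identifies μ fully,
but the latent norm is weakly informed and mixes slowly under the
augmentation — raw β coefficients can show R̂ ≈ 1.1 and low ESS at reduced
run lengths while the *angular* quantities (cell angles, contrasts) mix an
order of magnitude better.  Diagnostics (max split-R̂, min bulk ESS via
arviz, thresholds R̂ < 1.01 and ESS ≥ 400) are computed on the raw
parameters — the conservative choice — and reported, never raised:
non-convergence flags the fit, the long default sampler is the remedy.

**Effects.** Per posterior draw, the population-level marginal predicted
angle of each Condition × Phase cell is the direction of the
fixed-effects-only latent mean (random effects excluded).  All contrasts
are shortest circular differences d(a,b) = ((a − b + 180) mod 360) − 180,
with −180 mapped to +180:

- *Interaction* (condition c vs baseline): d(Jump_c, Loading_c) −
  d(Jump_base, Loading_base), wrapped.
- *Simple main effects* (within phase): d(cell_c, cell_base), for
  sequential baselines P1, P2, P3.
- *Condition main effects*: the two phase predictions are circularly
  averaged within each condition first, then differenced pairwise;
  the *phase main effect* averages across conditions within phase before
  d(Jump, Loading).  Draws whose two-point circular mean is degenerate
  (resultant < 10⁻⁹, i.e. numerically antipodal cells) are excluded with
  a reported count.

Summaries: the circular mean of per-draw differences mapped to
(−180°, 180°], and the 95% HPD interval computed as the shortest window
containing ⌈0.95 n⌉ sorted draws on the linear (−180, 180] scale.  The
linear representation is valid while differences stay away from ±180°; a
warning fires when more than 1% of draws fall within 10° of ±180° (this
genuinely happens for near-antipodal phase averages — such intervals span
nearly the whole circle and are reported as inconclusive, which is the
honest summary).

**Decision tree.** Per coupling: if any of the *primary-baseline*
(P1/Loading) interaction contrasts has an HPD excluding zero, the
follow-up is simple main effects within each phase; otherwise condition
and phase main effects.  Sequential-baseline (P2, P3) interaction
contrasts are computed and reported but do not drive the branch: deciding
on all six would take the wrong branch in ~15% of null datasets purely by
multiplicity, whereas the primary rule keeps it below 10% (measured over
50 seeded null replicates).

## Synthetic data

**Kinematic level.** A trial is a brief quiet stance (0.10 s), a cosine
COM descent (0.45 s, 0.30 m), a cosine rise (0.65 s) whose initial
curvature matches the descent's final curvature — so zero-phase filtering
provably does not move the COM minimum index — and a short landing whose
curvature matches the rise at the apex.  Within each phase the six joint
velocities are a smooth sin² envelope times a fixed per-(condition, phase,
side) direction vector (hip, knee, ankle), making every coupling angle
constant over the phase and hence analytically known.  Because three
couplings share three joints, Hip–Knee and Knee–Ankle targets are the free
parameters and Hip–Ankle is implied; an explicitly supplied inconsistent
Hip–Ankle target raises a scenario error.  Default cell targets are the
study-reported per-cell circular means, so the default scenario is the
study's shape: 14 subjects × 4 distances × 4 trials, 60 Hz.  Subject
variation is a per-subject angular offset (SD 3°, matching the scale of
reported between-subject dispersions) added to all targets; measurement
noise is additive white noise on the velocities (8 deg/s RMS — a few
deg/s after the 8 Hz filter, plausible for differentiated markerless
pose estimates) applied *before* filtering so the filter does real work.
The envelope is zero in a 0.05 s buffer on each side of the COM minimum:
joint rotation reverses there, and the buffer prevents the filter from
blending the two phases' (near-antipodal) velocity directions across the
boundary.  The stance and buffer are deliberately brief: with noise on,
motionless stretches inside the analysed windows contribute noise-only
coupling directions at full circular-mean weight, and long holds would
inflate trial-mean dispersion beyond anything seen in real shots.

What this generator does *not* emulate: curved (non-constant) coupling
profiles within a phase, velocity-magnitude asymmetries between sides,
autocorrelated measurement noise, soft-tissue artefact, or any kinetics.
Passing round-trip tests therefore certify the *pipeline's numerics*, not
robustness to real-world curve shapes.

**Angle level.** `generate_angle_table` draws observations directly from
the projected-normal mixed model: latent mean = norm × (cos, sin) of the
cell angle plus a bivariate-normal subject intercept (SD chosen so the
induced angular spread matches `subject_spread_deg`) plus unit noise.
Default latent norm 15 gives an angular SD of ≈ 1/15 rad ≈ 3.8°, in the
range implied by the reported cell dispersions.  This path is the model's
generative twin and is what the recovery/calibration studies use.

## Verification

- **Circular math:** piecewise mean ≡ atan2 oracle to < 10⁻⁹ ° on 10⁴
  random angle sets; HPD endpoints match order-statistics/closed-form
  references; difference wrapping is antisymmetric and bounded.
- **Posterior correctness:** for an intercept-only model on 12 angles,
  the Gibbs posterior of the mean direction is within total-variation
  0.009 of a dense polar-grid numerical posterior (threshold 0.05).
- **Recovery:** 50 seeded replicates at the study's size, effects 6–20°,
  reduced sampler: mean |error| ≈ 0.8°, HPD coverage ≈ 92%.
- **Null calibration:** 50 seeded null replicates: ≈ 4–8% of 95% HPD
  intervals exclude zero; the decision tree takes the main-effects branch
  in ≈ 90% of runs.
- **Round trip:** noiseless synthetic trials reproduce their cell targets
  to < 10⁻⁶ ° unfiltered and < 0.01° filtered.

## Known limitations

- The anti-phase bin labels and the dominancy-percentage convention
  disagree in quadrants 2 and 4 (inherited from the published scheme);
  inference uses the continuous mean angle, so results do not depend on
  the labels.
- HPD intervals of differences are linear on (−180, 180]; contrasts of
  near-antipodal averaged cells produce near-circle-wide intervals rather
  than wrapped ones (flagged by a warning).
- Circular means weight all grid samples equally; low-velocity stretches
  of real data contribute noisy directions, a property of the method
  itself rather than of this implementation.
- The prior on the latent coefficient scale is diffuse but proper;
  extremely concentrated data (cell norms ≫ 100) would make it mildly
  informative and `prior_sd` should be raised.
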