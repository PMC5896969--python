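# Methods

`hipload` estimates the hip joint contact force (HJF) of a walking or
standing subject from optical skin-marker trajectories and force-plate
recordings, and quantifies how well such an estimate agrees with a
telemetered in vivo measurement from an instrumented hip implant.  The
pipeline mirrors the classic two-step simulation used in patient-specific
musculoskeletal modelling — marker-based model scaling, then inverse
dynamics with muscle recruitment — and exposes the four modelling choices
whose influence the factorial study quantifies: the hip-joint-width source,
the muscle strength, the recruitment criterion, and the muscle model.

## The body model

A reduced rigid-body model stands in for a full cadaver-based lower limb:

* Segments: pelvis root, a lumped head–arms–trunk (HAT) segment rigidly
  fused to the pelvis, and bilateral femur/shank/foot chains.  Segment
  masses are fixed anthropometric fractions of body mass (HAT 0.678, thigh
  0.100, shank 0.0465, foot 0.0145 per side; they sum to 1), segment
  lengths are fractions of body height (femur 0.245, shank 0.246, foot
  0.152).
* Joints: spherical 3-DOF hips; revolute knees and ankles (flexion axes).
  16 generalized coordinates in total (pelvis pose + 5 per leg).
* Hip joint width (HJW): the distance between the hip centers, placed at
  ±HJW/2 about the mid-sagittal plane.  Mode `"CT"` freezes it at the
  CT-measured value during the kinematic optimization; mode `"C3D"` leaves
  it as a free parameter estimated from the markers.
* Muscles: seven hip-spanning groups per leg (anterior/posterior gluteus
  medius, gluteus maximus, iliopsoas, adductor group, rectus-femoris
  equivalent, TFL equivalent) with straight-line paths and lumped PCSAs in
  the physiological range.  Each group is subdivided into three fascicles
  whose femoral insertions sit at different radial distances from the hip
  center (factors 1.2 / 1.0 / 0.55 with PCSA split 0.40 / 0.35 / 0.25).
  This mimics how cadaver-based models split broad muscles into fascicles
  and is load-bearing for the strength sweep: the fascicle moment arms form
  a ladder, so when the strength parameter is lowered the long-levered
  fascicles saturate first and force redistributes to progressively
  shorter-levered, force-costlier fascicles.  With a single fascicle per
  group the transition from "no saturation" to "infeasible" is nearly
  instantaneous, which is not how richly fasciculated models behave.

### Scaling laws

Longitudinal dimensions scale per segment with the factors estimated from
the markers.  Cross-sections follow an area ("fat") scaling factor
`sqrt((m/m0)/(h/h0))` with the reference body (75 kg, 1.74 m); PCSA is
multiplied by this factor directly, perpendicular linear dimensions by its
square root.  The law is monotone in mass at fixed height (a 21 % heavier
subject gets 10 % more PCSA) — the published scaling laws this emulates do
not state their constants, so the constant here is a documented package
choice.

## Step 1 — kinematics

Per-frame poses and per-subject segment scales are fit to the 25-marker
protocol by weighted least squares:

* Marker weights `w = 1/(1 + (r/r0)^2)` with `r0 = 20 mm`, recomputed once
  after an initial unweighted pass; invalid frames get weight 0.  This
  down-weights markers with soft-tissue artifact or dropouts.
* The outer optimization over log-scales (and HJW in C3D mode) is a small
  damped Gauss–Newton (Levenberg–Marquardt) loop with nested warm-started
  per-frame pose solves; only cost-decreasing steps are accepted, so the
  reported objective history is monotone by construction.  Iteration cap
  200, relative tolerance 1e-8.
* Per-frame pose solves use `scipy.optimize.least_squares`
  (Levenberg–Marquardt) with an analytic Jacobian assembled by the chain
  rule through the SO(3) right Jacobian of the rotation-vector
  parametrization.
* Velocities and accelerations are central differences of
  zero-phase-filtered trajectories (2nd-order Butterworth, 6 Hz cutoff,
  skipped when the sampling rate is too low to support it).

The pelvis markers sit laterally at exactly ±HJW/2, so the lateral spread
of the pelvis cluster identifies the hip joint width in C3D mode.  A
lateral pelvic soft-tissue offset of δ per side would inflate the width by
2δ if the pelvis markers alone were fit; the leg markers (whose femur
origin is the hip center) pull the estimate partway back, so the realized
inflation is roughly 0.6–1.5 δ per side depending on posture — the
qualitative effect (marker-derived HJW overestimates, CT mode immune) is
what matters for the C3D-vs-CT comparison.

## Step 2 — dynamics

Net hip loads come from a bottom-up Newton–Euler balance of the distal
chain (foot + shank + femur of the analysed side): gravity and
ground-reaction terms are exact; translational inertia uses the filtered
COM accelerations; rotational inertia of the thin leg segments is
neglected (its moments are an order of magnitude below the gravitational
terms for these motions).  Equilibrium is enforced at the three hip DOFs
only; other joints are resolved by ideal torque providers.  g = 9.81 m/s².

Muscle strengths:

* simple model — `N_i = sigma * PCSA_i`, independent of length and
  velocity, no passive element;
* Hill-type model — active cap `sigma * PCSA * fl(l) * fv(v)` with a
  Gaussian force–length curve (width 0.45 on normalized length), a Hill
  hyperbola force–velocity curve (zero at the maximal shortening velocity,
  eccentric plateau 1.5), and a quadratic passive element that engages
  above optimal length.  The tendon is rigid and there are no activation
  dynamics; consequently the "optimal fiber lengths" are effective
  musculotendon values, inflated relative to anatomical fiber lengths to
  absorb the compliance a real tendon would provide.  Normalized length is
  unity at the neutral-pose musculotendon length.

Recruitment:

* PN — minimize `sum_i (f_i/N_i)^3` subject to `C f = d`, `0 ≤ f ≤ cap`.
  Solved by a semismooth Newton iteration on the dual (the KKT map
  `f_i = N_i (N_i c_i·λ / p)^(1/(p-1))` clipped to the bounds), warm-started
  across frames; a well-scaled p-norm SLSQP refinement and an LP
  feasibility start serve as fallbacks.  For powers above 3 a continuation
  in p rescales the dual through the KKT relation.
* MM — minimize the maximum activation, as a linear program (HiGHS);
  among minimax-optimal solutions a secondary pass minimizes `sum f_i^2`
  at the optimal envelope, fixing uniqueness deterministically.
* Upper bounds `f ≤ N` (simple) or `f ≤ active cap + passive` (Hill) are on
  by default; bound infeasibility is the pipeline's only failure mode, and
  a single infeasible frame fails the whole trial (excluded from
  aggregation).

A property worth recording: the maximum activation under PN is
non-increasing in the power p for single-DOF load sharing, and converges to
the MM value as p → ∞; with several coupled DOFs the exact optima can
violate the monotonicity transiently (we confirmed a counterexample with an
independent high-accuracy solver), which is why the convergence test uses
single-DOF problems.  Even at p = 17 the exact PN maximum activation sits a
few percent (relative) above the MM optimum; convergence is asserted in
absolute activation units (< 0.01).

The hip contact force on the femoral head is the intersegmental force minus
the summed muscle pulls, expressed in the mechanical-axis (ISB-style) femur
frame.

## Frame conventions and the telemetry frame

The lab frame is +X anterior, +Y left, +Z up; femur frames sit at the hip
center with the long axis down.  The telemetry ("OrthoLoad-style") femoral
frame differs from the mechanical-axis frame by the implant-stem obliquity:
by default a 15° frontal-plane (adduction-ward, side-mirrored) and 5°
sagittal-plane rotation, configurable.  Under this rotation the
stance-phase contact force is medial (+ML), posterior (−PA) and inferior
(−IS), the standard sign pattern of instrumented-implant recordings; left
trials are mirrored in ML so both sides share the medial-positive
convention.  The rotation is an isometry, so the resultant is unchanged.

## Synthetic data

Real validation data (marker trajectories, force plates and telemetered
hip forces of instrumented-implant patients) is not freely redistributable.
The generator therefore emulates it, with the printed anthropometrics of
the ten-subject instrumented-implant cohort as the default population:

* One-leg stance: the stance leg is anchored, the contralateral leg lifts
  during a ramp–hold–lower cycle, and the vertical load ramps from half to
  full body weight.  The stance-hip adduction angle is calibrated by a
  scalar root find so that the ground-truth plateau resultant matches the
  requested magnitude (default 259 %BW, the cohort-mean in vivo peak-phase
  load).
* Level walking: prescribed sinusoidal hip flexion, a double knee-flexion
  wave, adduction bumps timed with the two force peaks, and a double-bump
  vertical ground reaction on a smooth base, with the shear component
  tilting the force line toward the hip (keeping sagittal hip moments in
  the physiological tens of N·m).  The two bump amplitudes are calibrated
  by a secant iteration so the truth resultant peaks (default 255 and
  230 %BW at 15 % and 45 % of the cycle) hit their targets; contralateral
  toe-off and heel-strike events bracket them.
* Ground truth is computed through the pipeline's own inverse dynamics and
  recruitment (reference combination: CT width, 90 N/cm², PN, simple
  model), so a perfect reconstruction has known-zero error on every metric.
* Imperfections: isotropic marker noise (default σ = 2 mm), a
  BMI-dependent lateral pelvis-marker offset (`scale · max(0, BMI − 25)` mm
  per side plus a slow drift) emulating the pelvic soft-tissue layer, and a
  pseudo-telemetry measurement that differs from truth by smooth correlated
  noise (σ = 5 %BW, 4-sample kernel) and a small sensor-frame misalignment
  (3°, about an axis perpendicular to the mean force so the induced angular
  deviation equals the configured angle).

What passing tests on this data do and do not show: the synthetic trials
are model-consistent by construction, so end-to-end errors reflect only the
injected imperfections and the parameter-combination mismatch — not
modelling error against a real body.  Absolute deviations are therefore
much smaller than validation studies against real telemetry report (a few
percent rather than tens of percent); the qualitative orderings (CT beats
marker-derived width for high-BMI subjects, polynomial recruitment with the
simple muscle model beats min/max, errors explode when strength drops below
the saturation level) are the reproducible content.

## Validation metrics

All comparisons run on a common 101-point 0–100 % cycle grid in %BW
(`100·F/(m·g)`), in the telemetry frame.  The peak force phase (PFP) is
found on the *measured* series: for stance, the longest contiguous run
above 75 % of the maximum resultant within the central [25 %, 75 %] of the
cycle (the omitted quarters cover leg lifting/lowering); for walking,
±2.5 % of the cycle around the resultant's local maximum nearest the
contralateral toe-off.  PD^PFP compares window-averaged resultants (one
value per subject); MAPE^PFP is the cohort mean of |PD^PFP|.  MAD^PFP is
the angle between the window-mean force vectors, in 3D and projected onto
the sagittal (PA–IS), frontal (ML–IS) and transverse (ML–PA) planes.  RMSE
and MAE are pointwise over the full cycle per component and on the
resultant.  Pearson r² with slope/intercept regresses simulated on
measured; cohort statistics pool all subjects' resampled cycles (equal
samples per subject, so pooled means equal means of subject means), with
per-subject tables also emitted.  Bland–Altman uses the nonparametric
limits of agreement median(d) ± 1.45·IQR(d) with linear-interpolation
quantiles.  Normality is checked with a Kolmogorov–Smirnov test against a
fitted normal, and group differences with a two-sided Mann–Whitney U test
(α = 0.05; no continuity correction, so identical samples give p = 1).

## The factorial study and the strength sweep

`factorial_sweep` crosses {C3D, CT} × {40, 90 N/cm²} × {PN, MM} ×
{simple, Hill} over every subject and activity (16 × 10 × 2 = 320 runs),
sharing the kinematic solution across combinations that differ only in
dynamics parameters.  Unsuccessful (infeasible) runs are recorded and
excluded from aggregation.

`strength_sweep` reduces the muscle strength gradually at CT + PN + simple
and reports the full-cycle mean absolute resultant error (MAE_R) per
strength, the share of runs with saturated fascicles, and Mann–Whitney
p-values between consecutive strengths.  On the default synthetic cohort
the curve is flat above the saturation level (polynomial recruitment is
invariant under uniform strength scaling while no bound is active), rises
below it as load shifts to short-levered reserve fascicles, and collapses
into infeasibility at the lowest strengths.  Because the elevation is
within-subject while between-subject spread is larger, the significance of
the rise is assessed pairwise per subject and activity (Wilcoxon signed
rank of the elevation relative to the same run at the highest strength);
the between-group Mann–Whitney values are reported alongside.

## Numerical choices and degenerate inputs

* Equilibrium tolerance: feasible recruitment satisfies
  `‖Cf − d‖∞ ≤ 1e-6·‖d‖∞` and `f ≥ −1e-9` N.
* Quantiles: linear interpolation of order statistics everywhere,
  including the Bland–Altman worked example d = {1..5} → median 3,
  LOA (0.1, 5.9).
* Zero-variance series make r² undefined (flagged, not raised);
  zero-length plane projections report an angle of 0 with a degenerate
  flag; an empty stance plateau or a missing gait event raises a
  diagnostic error.
* Determinism: every stochastic element (subject proportions, noise,
  drift, misalignment axis) derives from explicit integer seeds through
  `numpy.random.SeedSequence`; identical inputs reproduce results
  bit-identically.
* Problem sizes: 101-frame trials, 21 fascicles per leg, ten subjects and
  two activities per study; a full factorial plus strength sweep completes
  in minutes on a single core.

## Known limitations

* The model is a deliberate reduction: no patella or two-part knee/ankle
  joints, no lumbar spine detail, no via-point muscle wrapping, no
  EMG-informed co-contraction, no implant neck geometry.
* The only failure mode is recruitment infeasibility; real simulation
  pipelines also fail for numerical or modelling reasons this package does
  not emulate.  In particular, because the bounded PN and MM criteria share
  one feasible set here, failures cannot single out MM the way a richer
  pipeline's numerics may; at the default study conditions no failures
  occur at all.
* Soft-tissue artifact is a lateral pelvis-marker offset plus drift;
  real artifact is task- and location-dependent.
* The stem-obliquity rotation between the mechanical-axis and telemetry
  femoral frames is a configurable package default, not a reconstruction
  of any specific implant's axes.
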