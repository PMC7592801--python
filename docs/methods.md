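# Methods

This note documents the models implemented in `gaitmet`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not establish about real data.

## Sign conventions

Generalized sagittal coordinates are hip extension, knee extension and
ankle plantarflexion, all positive. Moments share the convention; a
positive moment arm produces a positive moment, and muscle-tendon length
satisfies `d l_mt / d θ = −r(θ)` exactly because `l_mt` is built from the
antiderivative of each moment-arm polynomial. Fiber velocity is the time
derivative of fiber length (lengthening positive); the fiber *work* rate
uses shortening-positive velocity so that positive power is positive work.

## Muscle-tendon model

Each muscle is a Hill-type equilibrium unit: contractile element (CE) with
Gaussian active force-length `fl = exp(−((l̃−1)/(0.5 w))²)` (`w` is the
per-muscle width coefficient; the 0.5 shape factor puts ~2% of peak force
at `l̃ = 1 ± w`), a Hill force-velocity hyperbola (concentric curvature
`a_f = 0.25`, eccentric plateau 1.5·f_max with curvature 10), a linear
fiber damping β = 0.1 (Millard-style regularization), a parallel elastic
fiber element (exponential, reaching f_max at 70% fiber strain), a
series tendon with an exponential toe reaching f_max at 4.5% strain
(shape 40) that continues linearly above 10% strain, and constant-thickness
pennation (`l_f sin α` constant).

Fiber length is the state. At every evaluation the fiber velocity solves
the damped equilibrium `a·fl·fv(ṽ) + β ṽ = f_t/cos α − f_pe` in closed form
(one quadratic per force-velocity branch; the left side is strictly
increasing in ṽ, so the root is unique). No iterative root finding happens
inside the integration loop, and the reported states satisfy the
tendon-fiber force equilibrium to machine precision.

Integration is classical fixed-step RK4 on the sampling grid, with
automatic per-muscle substepping: the dominant eigenvalue of the fiber ODE
is estimated as `v_max l_opt k_tendon / β` and the substep count keeps it
inside the RK4 stability region. Muscles whose tendon is shorter than half
the optimal fiber length (here the gluteus maximus, 5 cm tendon vs 15 cm
fiber) are integrated with a **rigid tendon** — the standard recommendation
for short tendons, whose compliance is both numerically stiff and
mechanically negligible. During calibration the rigid/compliant mode is
fixed from the base parameters so the cost surface stays continuous while
candidate lengths vary. In rigid mode a net pushing force is floored at
`−f_pe` (a real muscle would simply unload the tendon), which keeps tendon
force nonnegative.

Activation follows first-order dynamics with asymmetric time constants
(τ_act = 10 ms, τ_deact = 40 ms), integrated with the exact exponential
update so constant-excitation responses are analytically exact. Default
initial states are the first excitation sample and a rigid-tendon fiber
estimate; every trial simulation prepends two warm-up strides of input that
are discarded from outputs, after which trajectories are stride-periodic to
well under 1%.

Safeguards for extreme parameter candidates (needed because calibration
explores a 50–150% box): fiber length is clamped to [0.2, 2.2]·l_opt, the
normalized fiber speed to ±5·v_max, and the tendon force is linear above
10% strain, so the cost function stays finite everywhere in the box.

## Muscle energetics

Per muscle and sample, metabolic rate is partitioned into

* activation-maintenance heat `h_AM = (25 f_slow + 153 f_fast) A^0.6` W/kg
  muscle, where `A = u` while excitation exceeds activation and `(u+a)/2`
  otherwise, and `(f_slow, f_fast)` are the effective fiber-type fractions
  under *orderly recruitment* (entirely slow at zero activation, the
  anatomical ratio at full activation, linear interpolation in between);
* shortening–lengthening heat, velocity-proportional with per-fiber-type
  shortening coefficients `α_S,slow = 4·25 / v_max,slow` (slow-fiber
  maximum velocity is 0.4·v_max) and `α_S,fast = 153 / v_max`, activation
  exponent 2.0, and a lengthening coefficient 4·α_S,slow with linear
  activation scaling;
* the signed CE mechanical work rate (negative during lengthening — kept,
  not zeroed).

Above optimal length both heat rates scale with the active force-length
value; both are multiplied by the aerobic factor S = 1.5. Muscle mass is
`f_max / σ · l_opt · ρ` with σ = 600 000 N/m² and ρ = 1059.7 kg/m³. The
per-muscle total is clamped at zero per sample (negative work cannot
synthesize ATP) and scaled by muscle mass per body mass. Basal metabolism
is not modeled: all outputs are net rates, matching the net-of-standing
measurement convention. The exact heat-rate coefficient values are a named
configuration set (`EnergeticsCoefficients`); every property the tests
assert (component additivity, nonnegativity after clamping, exact
S-scaling, zero drive → zero rate, mass linearity) holds for any admissible
set.

Muscle-group shares follow the functional grouping plantarflexors
(soleus + both gastrocnemii), knee extensors (vastus medialis + rectus
femoris), hip extensors (gluteus maximus), dorsiflexors (tibialis
anterior), knee flexors (biceps femoris). The rectus femoris is counted
with the knee extensors so the five groups partition the whole muscle set
and shares sum to 100%.

## Joint-space estimator

Per joint and sample: `c_AM |M| + c_SL |M ω| + P⁺/η⁺ + |P⁻|/η⁻`, with
packaged defaults `c_AM = 0.55 W·kg⁻¹ per N·m·kg⁻¹`, `c_SL = 0.12`,
η⁺ = 0.25, η⁻ = 1.20 (eccentric work cheaper), and an optional moment
dead-band (default 0). All terms are nonnegative per sample, the limb
profile is exactly the sum over joints, and zero input gives zero output
(no basal term). The unilateral analysis zeroes every contralateral and
non-lower-limb channel (idempotent masking) and reports the right side.
Metabolic cost is attributed to plantarflexors/dorsiflexors and
extensors/flexors by the sign of the joint moment at each sample.

## Calibration

Tendon slack length and optimal fiber length are calibrated per muscle
against reference joint moments with the cost

```
MSE_ankle + MSE_knee + MSE_hip-extension + 10⁶ (ZFP + PDP + PRP)
```

where the hip error is evaluated only where the reference hip moment is in
the extension direction (the model has no uni-articular hip flexor), ZFP
counts muscles whose tendon force never exceeds 1 N over the stride, PDP is
1 if the soleus stride-mean force is below the mean of the two gastrocnemii
means (strict inequality), and PRP counts muscles whose fiber leaves
`[l_opt(1−w), l_opt(1+w)]` (closed bounds) at any sample.

The optimizer is a generalized pattern search with an expanding/contracting
mesh, opportunistic polling with last-success-first ordering, and box
constraints at 50–150% of each muscle's starting values. It terminates when
all penalties are zero and the improvement falls below 10⁻⁶ with the mesh
refined below 10⁻³ (relative), or after 300 poll iterations. Rather than
searching all 16 parameters jointly — which stalls in long `l_opt`/`l_slack`
compensation valleys — the search runs **block-coordinate**: a 2-D search
per muscle, swept distal to proximal (the ankle muscles are pinned by the
largest moment signal; the hip muscles, constrained only through the
masked extension window, adapt last), followed by small coupled groups
(the three plantarflexors, vastus + rectus, biceps femoris + gluteus,
tibialis + soleus), cycled until a full cycle improves the cost by less
than 10⁻⁶. Each block's poll set includes the analytic tangent of the
compensation valley, `(1, −cos α · l_opt/l_slack)` in the normalized mesh
coordinates, and the inner block searches refine 100× past the outer
tolerance so shallow directions (short-tendon slack lengths) are not
abandoned early. Only the polled block is re-simulated per evaluation.
A failed simulation returns a large finite sentinel cost and the search
continues; persistent failure aborts with an error.

On a noise-free truth-known trial (joint moments produced by the muscle
model itself), calibration started from a uniform +20% perturbation of all
16 parameters recovers every length within 5% (worst: gluteus slack length,
≈4.7%) with a residual moment MSE near 10⁻⁵ (N·m/kg)².

### Identifiability and the default model

Two length parameters per muscle are only jointly identifiable from joint
moments if the fiber excursion crosses the optimum of the force-length
curve — a Gaussian flank is locally self-similar, so muscles that operate
on one flank admit a near-degenerate family of (l_opt, l_slack) solutions.
The packaged default geometry therefore sets each muscle's neutral-pose
operating point (`reference_fiber_norm` in the model file) so its gait
excursion straddles l_opt, consistent with in vivo imaging of human gait.
Likewise, the medial and lateral gastrocnemius share one (mirrored) EMG
signal, so only their force sum would be observable if their moment arms
were proportional; the default arms are non-proportional
(0.050/−0.022 vs 0.045/−0.016 m), which separates them.

## Synthetic gait generator

The generator emulates a treadmill study at 1 m/s: seven conditions
(grades −6°/0°/+6° with level shoes; shoe inclinations −7°/−3°/+3°/+7° on
the level), six participants drawn from a population with mass
79.9 ± 13.8 kg, stride period 1.12 ± 0.07 s and stance fraction
0.65 ± 0.012. Signals are smooth periodic raised-cosine bump templates:
sagittal joint angles and moments, a double-bump single-leg vertical GRF
supported exactly on the stance fraction whose two-leg stride average
equals body weight by construction, and EMG envelopes in [0,1] scaled by
per-muscle MVC values. Grade scales plantarflexor/hip-extensor drive and
positive leg work up (uphill) and negative work up (downhill); shoe
inclination perturbs the ankle moment and tibialis/plantarflexor drive.
Stride-average VO₂/VCO₂ pairs are emitted with condition multipliers
matching the reported calorimetry effect sizes (+111% at +6°, −36% at −6°,
smaller shoe effects), RER 0.85, standing rate 1.4 W/kg and a baseline net
rate of 3.3 W/kg. Noise is multiplicative lognormal on per-stride
amplitudes (factors interpolated across stride midpoints so series stay
smooth) plus small additive white noise; `noise_sd = 0` yields exactly
periodic trials, and every generator is bitwise deterministic under its
seed.

What the generator does **not** emulate: marker-level kinematics and 3-D
GRF components, soft-tissue and marker artifacts, inter-muscular crosstalk
in EMG, breath-by-breath gas dynamics, frontal-plane mechanics, and any
systematic discrepancy between muscle-generated and inverse-dynamics
moments (truth trials are self-consistent by construction). Passing tests
therefore establish internal correctness and recoverability, not clinical
validity on real recordings.

## Signal processing and statistics

EMG: zero-phase 4th-order Butterworth 20 Hz high-pass, full-wave
rectification, 6 Hz low-pass; MVC normalization with per-trial
re-normalization if the maximum exceeds 1. GRF: zero-phase 6 Hz low-pass.
Contact detection uses a 20 N threshold with 50 ms debouncing (both values
configurable; thresholds of this order are conventional). Phases follow
the event order ipsi HS < contra TO < contra HS < ipsi TO; with the default
65% stance they fall at 15/50/65% of the stride. Time normalization is
linear interpolation onto a uniform percent-of-stride grid (default 1001
points; the examples and acceptance runs use 201). Outlier screening drops
stride-average values outside median ± 3·IQR (linear-interpolation
quartiles; a zero IQR retains everything). Net metabolic rate uses a
Brockway-form weighted sum (16.58 J/ml O₂, 4.51 J/ml CO₂ — configurable)
per body mass minus the standing rate.

The repeated-measures correlation is computed by within-subject centering,
equivalent to ANCOVA with subject intercepts and a common slope:
`r = S_xy / √(S_xx S_yy)` on centered data, `df = N − k − 1`, p from
`F = r² df / (1 − r²)` on (1, df). With one subject it reduces to the
Pearson correlation. Degenerate cases: no within-subject x-variation is an
error; y constant within subjects returns r = 0, p = 1. The slope reported
for estimation-versus-calorimetry percent changes is the common slope of
calorimetry on the estimate, so a slope above one means the estimator
under-responds to the measured change. Method comparison removes
stride-average outliers per method first, correlates percent changes
separately for the grade and shoe families, and compares the two
estimators' four phase averages per condition with Bonferroni adjustment
over conditions at α = 0.05.

## Problem sizes

The default generator rate is 2000 Hz (the instrumentation rate the
pipeline is designed for); the test suite and the acceptance script run the
same operations at 100–500 Hz with 2–4 strides per trial and a
201-point stride grid, which resolves every curve and event involved while
keeping a full run in minutes on one CPU. Calibration examples use the
six-participant, seven-condition design with one truth-known recovery
experiment.

## Known limitations

* Constant (or low-order polynomial) moment arms instead of 3-D muscle
  paths with wrapping; the geometry file is replaceable.
* No uni-articular hip flexor and no upper body, so absolute rates
  undershoot whole-body calorimetry by design; analyses are relative.
* Heat-rate and joint-space coefficients are packaged defaults, not values
  fitted to any experimental dataset; conclusions that depend on their
  exact magnitudes should refit them.
* The damped force-velocity inversion slightly blends damping force into
  the contractile force at very low activation; the equilibrium residual
  remains exact, and the energetics use the same contractile force
  consistently.
* MAT-file ingestion depends on a user-supplied key map; it does not guess
  container layouts.
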