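# Methods

## Coordinate conventions and kinematic model

All knee-level quantities live in a 2-D sagittal, tibia-fixed frame: origin
at the tibial plateau reference point (taken as the knee centre), x
anterior, y proximal, z out of the sagittal plane so that internal extensor
moments are positive. Flexion is in degrees, 0° = full extension, flexion
positive; the model range is a hard [0°, 135°] — out-of-range angles raise
rather than extrapolate, because the candidate force scheme is meaningless
outside the range the linkage was built for.

The knee is the classical crossed four-bar linkage: tibial plateau link
(flat facet on y = 0), anterior and posterior cruciate links treated as
rigid isometric fibres, and a femoral link joining the two cruciate femoral
attachments, rigid with the femur. Given θ, the femoral link direction is
its full-extension orientation rotated by θ; closure is a two-circle
intersection (proximal branch), solved in closed form. The instant centre
is the crossing of the cruciate lines; the tibiofemoral contact point is
the foot of the perpendicular from the instant centre to the plateau, so
the contact line (the common normal of a flat facet) passes through the
instant centre by construction. Closure holds to < 1e-9 m over the whole
range, and the contact point migrates posteriorly monotonically with
flexion (femoral rollback, ≈ 24 mm at the reference scale).

The extensor mechanism: the trochlea is a circular arc fixed in the femur
(centre at a polar offset from the AC femoral attachment); the patella is a
point body at `trochlea_radius + patella_thickness` from the arc centre and
`patellar_tendon_length` from the tibial tuberosity (anterior intersection
branch). The quadriceps pulls the patella along the femoral shaft direction
(plus a small angular offset); when that straight line would cut the
trochlea arc — from roughly 75° of flexion on with the default geometry —
the tendon wraps and its effective pull becomes the tangent from the
patella to the arc, continuous at engagement. The hamstrings insert on the
posterior plateau and pull parallel to the femoral shaft. The tibial
tuberosity sits on a fixed anterior-distal 45° ray from the origin at
distance `tuberosity_distance`; this ray is a frame convention, not a
parameter.

Exactly M = 14 scalars (11 linear, 3 angular) define the geometry, all
registered by name with a linear/angular tag, and all linear parameters
scale by `tibia_length / reference_tibia_length`. The shipped
`default_geometry.json` is a synthetic stand-in (its name and note say so):
values were chosen once, by a feasibility search, for (i) four-bar and
patella-loop solvability over the full 0–135° range, (ii) monotone
rollback, (iii) tensile quadriceps / compressive patellofemoral solutions
at every angle, and (iv) extensor force ratios at 90° near the values this
class of model reports (F_QT : F_PF : F_PT ≈ 1.8 : 1.7 : 1, F_TF/F_PT ≈
1.4). It is not a measured anatomy.

## Net knee load and force resolution

Inverse dynamics is planar end-to-end (the reported quantities are all
sagittal). A Newton–Euler recursion over foot and shank — Winter's
anthropometric coefficients by default, configurable — reduces ground
reaction, gravity and (optionally) finite-difference inertial terms to the
knee point. `NetKneeLoad` stores the applied external force (anterior,
proximal) plus the internal extensor moment demand; the quasi-static flag
zeroes accelerations and is the default, matching the synthetic trials'
construction.

The five-structure force system is reduced to four candidates, one per
(tendon, ligament) pair in the fixed order PT-AC, PT-PC, HT-AC, HT-PC; each
is an exact 3×3 linear solve of the two force and one moment equations.
Admissibility means all three magnitudes ≥ −tol with tol = 1e-9 N relative
to the load scale (tensile tendons/ligaments, compressive contact stored
positive). Among admissible candidates the one with the smallest TF contact
force is retained, ties broken by enumeration order. If no candidate is
admissible the minimum-total-violation candidate is returned flagged
`fallback=true` — never silently — which keeps waveforms analyzable while
marking the sample as outside the model's feasible regime. With the default
geometry and cohort this happens only beyond ~115° of flexion (≈ 10% of DKB
samples), consistent with the model's separately established ~100° validity
limit; every force output beyond 100° carries `valid_flag = false`
regardless.

If the patellar tendon is loaded, the patella three-force body (PT pull
toward the tuberosity, QT pull along the — possibly wrapped — quadriceps
line, PF push along the contact normal, all concurrent at the patella
point) yields F_QT and F_PF from a 2×2 solve; a slack patellar tendon
leaves both at zero. Co-contraction is excluded by construction (one tendon
per sample), a fidelity limit of the model class itself.

## Brace simulation

Brace moment/angle curves are polynomials M(θ) = c₁θ + c₂θ² (zero at full
extension, non-negative over the range — violated configs fail at load
time), optionally clamped above a plateau angle. The injection follows the
force picture rather than a pure couple: F_B = M/r_B applied anteriorly at
r_B = 0.20 m below the knee adds +F_B to the applied anterior force and −M
to the extensor demand; a `pure_couple` switch drops the force term for
comparison. r_B is configurable. No hysteresis: curves are functions of
angle alone, so descent/ascent differences in braced results come from the
movement's load asymmetry.

The three shipped curves (squat: linear, 0.19 N·m/deg; general: quadratic,
0.0014 N·m/deg²; plateau: quadratic, 0.0017 N·m/deg², clamped at 100°) are
visually plausible stand-ins flagged `approximate: true`; bench
calibrations for real braces are proprietary. They were set so the
squat ≥ plateau ≥ general ordering holds through mid-flexion and the
braced-force reductions at 90° land in the 30–50% band this brace class is
designed for. No test asserts absolute braced-force magnitudes.

## Synthetic cohort

The generator emulates the study conditions: n = 8 subjects (mass
66 ± 12 kg truncated to [40, 110]; height 164 ± 8 cm; 6/8 female; tibia =
0.246 × height), three repetitions per leg on side-by-side force plates,
peak flexion drawn from N(122°, 8°) truncated to [105°, 135°] so every
trial passes the ≤ 135° inclusion rule and the 90° crossing exists in both
phases. Flexion is a squared-sine bump peaking at 50% of the cycle, blended
with standing-posture offsets: the start posture is standardized
(4.0° ± 2.5°) while the end posture drifts more (8.0° ± 4.0°), as seen in
repeated squat testing. The prescribed internal extensor moment is a warped
sine peaking at the load-skew fraction of the cycle (default 0.60 — loads
peak later than the flexion angle), scaled to 1.0 N·m/kg at peak per leg
(± 10% between subjects), a deep two-legged squat level; smooth
few-mode Fourier noise (2%) perturbs the prescription. Vertical ground
reaction is half body weight per leg with a mirrored between-leg share
(± 2%) and a smooth modulation vanishing at the start, so the two plates
sum to body weight at the quasi-static start. The centre of pressure is
then *solved* from the prescribed moment under quasi-static equilibrium —
trials are forward-constructed, so the inverse-dynamics stage recovers the
prescribed loads to machine precision and every downstream stage is
testable against known ground truth. All randomness flows from the master
seed through independent, deterministic per-subject/rep/leg streams.

What the generator does **not** emulate: marker noise and soft-tissue
artifact, filtering artefacts, horizontal shear forces, inertial
(non-quasi-static) load components, co-contraction, and — most importantly
for the statistics — anatomical geometry variation beyond uniform tibia
scaling. Passing tests on this cohort therefore demonstrate internal
consistency and the model's structural behaviours, not agreement with any
particular human dataset.

## Uncertainty propagation

Linear parameters carry δ = ±5 mm, angular ±5° (imaging-precision level);
ground reactions and inertia are treated as true. δF_νᵢ is the central
half-difference |F(+δ) − F(−δ)|/2 of the full pipeline — symmetric and
second-order accurate; one-sided alternatives were rejected as
first-order. Deviations are computed per subject on a 1° descent-phase
flexion grid, averaged across subjects *before* squaring and combining
(the averaging-order choice is exposed), then δF² = Σ δF_νᵢ²/M,
ε_νᵢ = δF_νᵢ²/(δF²M) (uniform 1/M with a degenerate flag where δF = 0), and
υ = δF²/σ_F² with σ_F the between-subject SD on the same grid (υ = +inf
flagged where σ_F = 0). Fallback-flagged samples are masked before
interpolation: they are constraint-violating pseudo-solutions, and leaving
them in injects numerical garbage into δF and σ_F above ~100°.

The Monte-Carlo cross-check draws all 14 parameters jointly, each normal
with SD δᵢ/√M, so that for a locally linear response the output SD
estimates exactly the mean-square quantity the Taylor combination computes;
unsolvable draws are discarded and counted. Below 60° of flexion the two
agree within a few percent.

A known limitation, documented rather than hidden: with the default
geometry the variability ratio for the extensor-mechanism channels (QT, PF)
is *not* monotone over [60°, 110°] — the quadriceps wrap that keeps the
patella loop well-conditioned to 135° (a hard solvability requirement of
this package) also stabilizes those channels against geometric
perturbation, so δF plateaus while forces and between-subject spread keep
growing. The TF and PC channels do show the expected monotone uncertainty
growth with flexion (υ_TF ≈ 0.6 at 60° rising past 2.8 at 90°), and PC is
by far the least trustworthy channel at any depth, matching the caution
this model class attaches to PC force estimates.

## Waveform statistics

Waveforms are linearly time-normalised to 101 cycle points. The SPM paired
t continuum uses the exact per-node paired t; the critical threshold t*
solves the expected-Euler-characteristic equation for a 1-D t field at the
study α = 0.067 (two-tailed, α/2 per tail), with resel count
(Q−1)/FWHM and FWHM estimated from normalised residual gradients. α = 0.067
is kept verbatim as the configured study-wide default for the three
brace-vs-none comparisons (note: a conventional Bonferroni of 0.05 over 3
would be 0.0167; the override is one argument away). If the EC equation has
no finite root — very rough fields at very low degrees of freedom — t* is
+inf and nothing is declared significant, which is the honest reading. A
sign-flip permutation backend (exhaustive to 2¹² flips, seeded Monte-Carlo
beyond) provides the assumption-light alternative; the two thresholds agree
within ~10% on smooth n = 8 fields. Suprathreshold clusters are maximal
runs of |t| > t*, reported as cycle-percent intervals with peak-level
p-values, and mapped through the mean flexion waveform to knee angles: a
boundary before the flexion peak is a descent crossing, at/after it an
ascent crossing. Zero-variance nodes get t = 0 (no effect) or signed
infinity (deterministic effect), flagged.

Scalar comparisons at 90° interpolate each trial to the first crossing of
90° in each phase (linear in the bracketing samples), average repetitions
and legs within subject, and use the two-sided paired t with Cohen's
d = mean(diff)/SD(diff); zero-variance differences are flagged rather than
silently propagated. `rmse_by_angle` compares synchronized prediction /
measurement pairs within an angle window (RMSE plus t-based 95% CI of the
binned bias) for validation against instrumented-implant data the user
supplies; no such data ship with the package.

## Orchestration and determinism

`run_experiment` reuses identical trial inputs across the no-brace and
three braced conditions (the invariant-kinematics assumption), averages the
three repetitions and both legs within subject before statistics (the
conservative gait-analysis default), propagates the >100° validity flag
into every report, and fails loudly if the fallback fraction exceeds a
configurable limit (default 20%, above the ~10% the deep-flexion degeneracy
produces on the default cohort). Identical config + seed reproduce every
report byte-for-byte. Problem sizes used throughout the shipped analyses —
8 subjects × 2 legs × 3 repetitions × 111 samples, 1–2° sensitivity grids,
200–250 Monte-Carlo draws — were chosen as the smallest sizes at which the
reported quantities are stable to well within their between-subject spread.
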