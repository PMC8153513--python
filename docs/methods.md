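# Methods

This note records the model, the numerical choices behind it, and the
places where the design was genuinely open. Everything quantitative
claimed here is computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted from memory.

## Geometry and layers

The cross-section is a block of medial-lateral height 8.40 mm and
inferior-superior depth 10.51 mm with anterior-posterior glottal length
ℓ_gl = 17.00 mm, the dimensions of the M5-style silicone folds the model
emulates. The published M5 coordinates are not reproduced; the medial
surface is a configurable polyline (normalised by the block dimensions so
scaling the dimensions scales the profile affinely) whose default was
fixed once from the M5 description: a ~46° inferior ramp, a rounded
glottal entrance, a ~1.5 mm medial face with a ~5.7° convergent taper
whose superior end touches the midline (so the resting fold is in gentle
point contact and `x0 = 8.4 mm` literally means "no medial compression"),
and a rounded superior edge. Coordinates use a lateral-wall origin with x
increasing medially; the contact plane sits at x = 8.40 mm.

Layers are bands between transfinite isolines of the wall-to-surface
blend: the cover occupies the outer 14% of the span, the ligament the
next 16%, the body the rest. These fractions are inputs (the layered
structure is treated as known), read qualitatively from the silicone
fold's construction; they taper toward the attachments rather than being
a constant-thickness shell. Meshing is a deterministic structured scheme
(Coons blend split into triangles, medial-chain vertices pinned into the
row parameterisation so element areas sum exactly to the profile area);
no randomised insertion, so re-meshing is bit-identical. A target of 205
elements yields 210 elements / 128 nodes.

Only the lateral wall is clamped by default. The experimental mount does
touch the inferior/superior faces of the silicone folds, but clamping
either face suppresses self-oscillation at every viscosity in the prior
box (measured directly); the fold needs its rotational compliance to
flutter, and the real silicone is merely held, not bonded, on those
faces. `triangulate(..., fixation="wall+faces")` provides the stiffer
mount for comparison.

## Elasticity, damping, and locking

Each layer is isotropic plane strain with C = λJ + μS (J the
dilatational, S = diag(2,2,1) the shear shape matrix), Lamé parameters
from (E, ν), ν = 0.4995 for near-incompressible silicone, unit
out-of-plane depth (ℓ_gl enters only observables). Damping follows the
Kelvin–Voigt substitution μ → μ + η d/dt applied where μ appears in the
Lamé split, giving the element integrand η BᵀSB. Applying the
substitution to the factored form C/μ instead would multiply dilatational
damping by (λ+2μ)/μ ≈ 2000 at ν = 0.4995; measured consequence: the fold
cannot self-oscillate at any viscosity in the 1–7 Poise prior. The
shear-only form is therefore the implemented one. Viscosity is carried in
Poise and converted (×0.1 Pa·s) at assembly.

Constant-strain triangles lock volumetrically at ν = 0.4995: the discrete
incompressibility constraints stiffen the mesh by roughly an order of
magnitude (the lowest mode rises from ~57 Hz at ν = 0.3 to ~148 Hz at
ν = 0.4995 on the same mesh) and kill self-oscillation outright. The
default assembly therefore uses nodal mean-dilatation mixed integration:
the volumetric strain is averaged over node-centred patches (patch volume
= one third of each adjacent element) before being penalised with the
patch-averaged λ. This passes the uniform-strain patch test to 1e-8,
preserves the three rigid-body modes, and restores physical compliance;
`assemble(..., volumetric="element")` keeps the textbook displacement
form for comparison. Mass is the consistent linear-triangle matrix; the
global dof ordering is [all x, then all z].

## Flow model

Each free-surface node is a station of a symmetric channel with local
area A(s) = 2(midline − x(s))ℓ_gl, floored at 0.001 mm² during contact so
the branch rule stays finite (the floor also bounds the suction at
(A_sep/A)² ≤ 1.69 since no station is below the minimum). The jet
separates at A_sep = 1.3 A_min. Two readings of the branch rule exist
because the printed form depends only on area: applied verbatim
everywhere, wide stations *above* the glottis feel full subglottal
pressure. Measured consequences of the verbatim reading: a cold-started
closed glottis is pinned shut by permanent suction at the contact point,
and the opening and closing phases become aerodynamically symmetric, so
net cycle work never beats damping — no oscillation anywhere in the prior
box. The default therefore assigns p_sup to stations superior to the
minimum section (separation at the minimum), the standard quasi-steady
reading; `supraglottal_mode=False` restores the verbatim rule. Pressure
acts along the deformed surface inward normal, integrated edge-wise with
the constant edge pressure splitting equally between end nodes. The flow
rate Q = 1.3 A_min √(2Δp/ϱ) uses air density ϱ = 1.14 kg/m³ and is zero
for a closed glottis or non-positive driving pressure.

## Time integration and contact

The system is advanced by a three-level finite-difference scheme: central
differences for inertia and damping, stiffness averaged over θ_{n+1} and
θ_{n−1}. The scheme is second-order, exactly non-dissipative for η = 0
(unit-modulus roots; energy drift < 1% over 1000 steps is verified), and
unconditionally stable — necessary because with ν = 0.4995 the
dilatational wave speed puts ω_max·h far beyond the ω_max·h < 2 limit of
a fully explicit update at the default h = 0.05 ms (which makes the
solver a 20,000 fps camera). The left-hand operator is factorised once
per simulation as a dense inverse (a few hundred dofs); the inner loop is
a numba kernel, with a pure-python reference path that the tests hold to
bit-identical output.

Contact is a hard projection: any node whose x exceeds the midline after
a step is forced onto it; the holding force is the residual of the
discrete momentum balance at the clamped dof (verified to 1e-8 against an
independent recomputation from the stored trajectory), compressive while
contact persists. No separate velocity reset is applied: a node held at
the midline across steps has zero centred velocity by construction, and
release happens when the unconstrained update carries it off the wall.
Contact pressure divides the nodal force by tributary length (half the
adjacent edge lengths) times ℓ_gl.

Medial compression `x0` caps the x-coordinate of every node before
integration: the static problem Kθ₀ = F_c under that cap is solved by
active-set iteration (clamp violators at the cap, relax, clamp new
violators, release tensile reactions). For a linear material this fixed
point is path-independent, so it equals the limit of pushing nodes
medially in small increments with elastic relaxation in between. Stored
elastic energy grows monotonically as x0 decreases (tested).

## Observation pipeline

Simulated GAWs are decimated to the camera rate by integer stride (no
anti-alias filter: the source is smooth and the ratio 20,000/2000 is
exact), trimmed of the first 250 ms, and phase-aligned to the measurement
by the integer-sample shift that maximises the cross-correlation of the
mean-removed first-two-cycle windows. The shift is searched within one
fundamental period, estimated from the measurement's autocorrelation peak
(threshold-crossing cycle detection chatters when the noise SD is
comparable to the 1% open threshold): whole-period shifts are
unidentifiable for a near-periodic signal, and accepting one poisons the
likelihood by comparing unrelated cycles. Waveform metrics delimit cycles
at 1% of the maximum area; OQ = open time / period, SQ = opening /
closing time with the in-cycle peak splitting the open phase, f0 from the
mean period.

## Inference

Plain importance sampling from the independent uniform priors
(E_bdy 9–15 kPa, E_cvr 250–950 Pa, E_lig 0.5–3 kPa, p_sub 400–1800 Pa,
ρ 950–1200 kg/m³, η 1–7 P, optionally x0 7.4–8.4 mm; ν and p_sup fixed),
Gaussian likelihood −‖A_m − A_s‖²/2σ_e² with σ_e = 1 mm² over the 300 ms
comparison window (600 samples at 2000 fps; simulations run 550 ms and
lose 250 ms to the trim), log-sum-exp-stabilised weights (the raw product
of 600 Gaussian factors underflows), multinomial resampling, and
resampled mean/SD as estimate/uncertainty. Unstable draws — the priors
include corners that do not phonate or destabilise the coupled update —
carry weight zero and are counted, not fatal. Per-sample work depends
only on the sample row, so results are invariant to the worker count.

### Known limitation: weight degeneracy at desk scale

The forward model is deterministic and a ~1% parameter change detunes the
fundamental frequency enough to decorrelate the 60-cycle comparison
window, costing thousands of log-likelihood units. At ensembles of
10²–10³ draws in six dimensions, the best draw therefore dominates all
others (measured effective sample size ≈ 1.0): the resampled SD collapses
toward zero and *understates* the true uncertainty, and the point
estimate is the single best prior draw, which at these ensemble sizes
still carries tens of percent of error (the estimator's own sensitivity
sweep shows errors stabilising only as ensembles grow toward 10⁴–10⁵, at
which scale the ridge of near-correct frequencies begins to be populated).
The `ess` and `failures` fields of every summary expose this; treat
posterior SDs from small ensembles as lower bounds. A likelihood
normalised per sample (mean- rather than sum-of-squares) would spread the
weights and is a natural extension, but the implemented form is the
squared two-norm.

## Synthetic data

The generator stands in for a high-speed-video recording: simulate at
known properties, decimate, trim, then add i.i.d. N(0, σ²) noise to each
area sample (after downsampling — measurement noise lives at the camera
rate), flooring negative areas at zero. It refuses truths that do not
sustain oscillation. It reports the realised noise-to-peak ratio rather
than asserting one; with σ = 1 mm² the default configuration realises
~1.7% of its ~60 mm² peak. What it does not emulate: segmentation
artifacts, pixel quantisation, left-right asymmetry, residual glottal
opening during the closed phase, or any forward-model error — so recovery
results on this data probe the sampler under the assumed error model, not
robustness to model mismatch.

## Problem sizes used by the tests and the acceptance script

Meshes of 120–210 elements; 550 ms simulations at h = 0.05 ms; recovery
ensembles of 2000 draws; sensitivity sweeps over ensembles {100, 500,
2000} and steps {0.1, 0.05} ms at 300 draws. Meshes of ≥ ~170 elements
give a regular, h-converged limit cycle (f0 changes < 0.1% when h is
halved at 205 elements); the 120-element mesh sits in a deterministic
subharmonic regime, which is retained deliberately as the harder test of
the machinery. Coarser models within these ranges change waveform detail
but preserve the qualitative trends the suite asserts (contact pressure
increasing with subglottal pressure and with medial compression;
uncertainty non-increasing with ensemble size; uncertainty decreasing
with the time step).
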