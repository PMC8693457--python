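# Methods

## Scenario and frames

The simulated observer translates at speed s = 2 m/s over an infinite ground
plane, eye height h = 1.8 m, while fixating a floor point 20° below the
horizontal. Two frames are used: the *retinal* frame (z along gaze, x right,
y up, image plane at f = 1, so image coordinates are tangents of visual
angle) and the *world* frame (y against gravity, z along the gaze azimuth).
They differ by a single rotation about x by the gaze depression. Headings
are parametrized by a lateral offset β (azimuth about the world-vertical
axis, ±20° in the protocol) and a vertical angle v ∈ [−3.5°, 3.5°] relative
to ground-parallel.

Flow is the instantaneous time derivative of the perspective projection
(translation term scaled by inverse depth, plus a depth-independent rotation
term). The experiment's 0.3 s motion episode is not simulated as a time
series; the instantaneous field at trial onset stands in for it. The
pursuit rotation Ω is solved in closed form to null the undistorted flow at
the image origin (Ω_X = T_Y/Z_f, Ω_Y = −T_X/Z_f, Ω_Z = 0, with Z_f =
h/sin(gaze depression) the fixation depth) and is reused unchanged in the
distorted conditions, i.e. pursuit is driven by the undistorted target
motion.

## Candidate-heading grid

Candidates form a 70°×20° rectangular grid centered on the
toward-the-fixation-point, ground-parallel direction. Grid coordinates are
(azimuth about the world-vertical axis relative to the gaze azimuth,
elevation = world-vertical angle + gaze depression). This chart was chosen
over pure retinal spherical coordinates for one reason: it places every
protocol heading (β, v) exactly at the node (β, v + 20°), so the "exact
recovery" property is meaningful at any grid step whose multiples include
the protocol angles. The full-fidelity step is 0.25°; 0.5° and 1° presets
are provided for desk-scale work, and all PSE statements inherit a ±step
quantization bound. Each node maps to a unit translation direction in the
retinal frame for residual evaluation.

## Subspace residual

For N flow vectors and candidate direction t, the admissible flows form the
column space of a 2N×(N+2) matrix (one inverse-depth column per point plus
two torsion-free rotation columns). Because each depth column touches only
one point's two rows, the orthogonal-complement projection factorizes: at
each point, only the flow component along the unit vector perpendicular to
the translation template A(p)t survives the depth fit, and the residual is
the minimum over (Ω_X, Ω_Y) of an N×2 linear least-squares problem on those
scalar components. This reduction is algebraically exact whenever no
template vector vanishes (a template vanishes only if a candidate direction
passes exactly through a sample point — a measure-zero event that would
contribute one 2-D instead of 1-D constraint; the implementation then drops
that point's contribution). The 2×2 normal equations are solved in closed
form; when their determinant falls below 1e−10 of its scale the solver
falls back to a rank-revealing least squares. With N ≤ 2 the subspace spans
everything and the residual is identically zero; such patches are flagged
uninformative and excluded. Residuals scale as the square of a global
velocity scale, so heading estimates are invariant to walking speed and to
the (unspecified) physical units of the flow.

Patches: 50 centers drawn uniformly over the part of the 55°-radius
visual-field disc (azimuthal-equidistant chart) whose rays hit the ground,
each with area (1.04° + 0.61 ε)² and 10 points uniform in the patch disc,
rejection-sampled until all points are inside the FoV and on visible
ground. For effective-FoV analyses a patch contributes only when *all* its
points lie within the effective radius, measured on the sampled
(undistorted) geometry so that the retained sets are identical across
conditions and nested across radii. Argmin ties are broken by distance to
the grid center, then lexicographically, and counted in the trial table.

## Synthetic lens

The proprietary ray-trace data are replaced by a closed-form stand-in.
Lens coordinates are angles seen from the eye's nodal point
(eye–lens distance q = 19.3 mm: 12 mm vertex + 7.3 mm nodal depth). Mean
sphere follows a logistic corridor S(l_y) = far + add·σ((c_y − l_y)/w) with
far = 0 dpt, add = 2 dpt, corridor center (0°, −15°) and scale w = 15°
(a 12–20 mm physical corridor subtends tens of degrees at q, hence the
wide default); the oblique astigmatic term grows off-corridor at the
Minkwitz rate and saturates laterally, X = |dS/dl_y| · falloff ·
tanh(l_x/falloff), odd in l_x so the lens is mirror-symmetric. A ray
crossing at lens angle ℓ is deviated by the generalized Prentice rule
δ = P(ℓ) · qℓ (small-angle, applied in the visual-field chart), and the
distortion field for a gaze direction g samples δ(g + θ) − δ(g) over the
21×21 grid (±tan 55° in tangent units), anchored so F(0) = 0 because the
eye fixates through the lens. This reproduces the qualitative PAL pattern —
mild distortion for central view, strong skew pulled into the field center
for peripheral view, prominent lower-periphery distortion — but it is *not*
a reconstruction of any commercial design: absolute deflections and the
sign/size of downstream PSE shifts are properties of the stand-in, and the
deflection scale is exposed through the lens parameters.

Distortion fields are bilinearly interpolated per component; Jacobians come
from central differences of the mapped grid (or from supplied derivative
columns), themselves bilinearly interpolated, which reproduces affine maps
exactly. No extrapolation: out-of-domain queries raise. Identity fields are
detected and short-circuited so they are bit-transparent. The inverse (the
backward warp a display shader would use) is a per-component bivariate
polynomial least-squares fit on the grid nodes; the default total degree 9
keeps the node roundtrip ‖F(F⁻¹(p)) − p‖ below 1e−3 tangent units for the
synthetic lens including the grid corners at ~64° eccentricity (degree 5
reaches only ~2.6e−3 there); the degree is configurable and the roundtrip
tolerance is re-checked at every call, which also flags folded maps.

## Psychometrics

Estimates are mapped to answers by the sign of the world-vertical heading
component; an exactly ground-parallel estimate counts 0.5 for each
category and enters the binomial likelihood as a fractional success. The
psychometric model p(a) = λ + (1−2λ)Φ((a − PSE)/σ) is fitted by bounded
maximum likelihood (L-BFGS-B, multi-start including the empirical 50%
crossing; σ ≥ 1e−3°, λ ∈ [0, 0.1]). A point-estimate ML fit was chosen over
a Bayesian fit because only the PSE point estimate is consumed downstream.
Deterministic model data can be perfectly separated; the σ lower bound
makes that case well-posed and leaves the PSE at the crossing. Parameter
recovery at the experimental trial structure (15 angles × 12 reps): median
PSE error < 0.15° and RMSE ≈ 0.17° across PSE ∈ [−1, 1], σ ∈ [0.5, 2],
λ ≤ 0.05 (checked in the test suite). ΔPSE is the difference to the
undistorted condition; one-sample t-tests against zero summarize per-run
ΔPSE samples.

## Protocol and seeding

One run evaluates 90 combinations (3 conditions × 2 lateral offsets × 15
vertical angles); the full protocol is 50 runs. Child seeds derive from
(master seed, run, offset index, angle index), so patch geometry is shared
across conditions within a cell — condition contrasts are paired, which
reduces variance without biasing means — and adding or removing conditions
does not perturb the remaining randomness. Tables are byte-reproducible
under a fixed master seed. The FoV sweep reuses the per-patch residual
surfaces across radii (only the summation set changes), making the sweep
nearly free beyond the base simulation.

Desk-scale presets used by the shipped scripts: the acceptance script runs
the undistorted protocol at 12 runs with a 0.5° grid; the test suite uses
1° grids and 2–10 runs. These sizes are the package's default trade-off
between resolution and turnaround; the full-fidelity settings (50 runs,
0.25°) are one config change away.

## What the synthetic data do and do not show

The generator family covers the study's *inputs* (lens distortion fields,
observer responses), not its human data. Passing tests establish the
geometry, the estimator, and the psychometric machinery — e.g. that
undistorted flow always yields PSE = 0, and that distortions of the
synthetic lens induce finite, FoV-dependent PSE shifts. They do not
establish the sign or magnitude of the shifts for any real lens: with the
default stand-in, the peripheral-view ΔPSE at 50–55° FoV comes out
*positive* (estimates biased downward), whereas commercial designs with a
different spatial layout of distortion can shift it the other way — the
sign depends on FoV and on lens detail. Real lens grids can be loaded
through the tabular grid format to repeat the analysis for an actual
design.

## Known limitations

Monocular, instantaneous flow only; single infinite ground plane; no
torsional pursuit; no blur/astigmatic image degradation (pure geometric
distortion); the subspace search spans translations only (no rotational
misperception); depth positivity is not enforced in the residual, matching
the classic unconstrained formulation.
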