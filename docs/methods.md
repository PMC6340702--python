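# Methods

## The problem and the model

Retinotopic maps assign each position on visual cortex a preferred position
in the visual field, summarized per surface vertex by a pRF center (polar
angle θ ∈ [0°, 180°] from the upper vertical meridian within one hemifield,
eccentricity ρ in degrees of visual angle) and a pRF size. Voxel-wise pRF
fits are noisy, incomplete (they miss the vertical meridians and everything
beyond the stimulus aperture), and carry no notion of map topology.
`retmap` treats map inference as Bayesian registration: a 2D retinotopy
model (the prior — a template assigning (θ, ρ, visual area) to every point
of a flattened model region) is combined with a subject's measurements (the
observation) by warping the subject's flattened cortical mesh until its
measured vertices sit on the model positions that represent their measured
coordinates, under hard topological constraints.

The registered configuration minimizes

    F(x) = Fe(x) + Fθ(x) + Fp(x) + Fφ(x)

over the 2D vertex coordinates x, starting from the prior-aligned reference
x0:

- **Fe** (edges): per edge, a harmonic penalty ½(r − r0)² plus an
  infinite-well barrier ½[((r0−q0)/(r−q0) − 1)² + ((q1−r0)/(q1−r) − 1)²]
  that diverges as the length r approaches the bounds q0 or q1; the sum is
  divided by |E|.
- **Fθ** (corner angles): the same harmonic + barrier structure on each
  triangle corner angle α with singularities at 0 and π, divided by |Θ|.
- **Fp** (perimeter): ½ Σ ‖x_u − x0_u‖² over perimeter vertices, pinning
  the outer rim of the map projection.
- **Fφ** (anchors): −(1/|Φ|) Σ w·exp(−‖x_u − y‖²/σ²): inverted-Gaussian
  wells drawing each measured vertex u toward each model point y where some
  area represents u's measured (θ, ρ).

Interpreting exp(−(Fe+Fθ+Fp)) as the prior over warps and exp(−Fφ) as the
likelihood of the measurements, minimizing F maximizes the posterior; the
barrier terms encode a prior probability of exactly zero for any warp that
inverts a triangle, which is what guarantees a topologically clean result:
any closed region of the visual field maps to a connected patch of the
inferred map.

Because only coordinates move and vertex identity is fixed, predictions
transfer to the subject's native space without inverting the registration:
each native vertex is assigned the model's (θ, ρ, area) at its registered
position.

## Anchors

For every vertex with variance explained ω ≥ 0.1 and finite measurements,
one anchor is built per modeled area that represents the measured (θ, ρ)
(areas covering only a quarterfield contribute no anchor for measurements
in the other quarterfield; measurements outside the model's eccentricity
range are skipped). The anchor point y is found by inverting the area's
field map: the area's faces are triangulated in visual-field coordinates
and the measured point is located barycentrically.

- **σ** is the distance from the anchor point to the nearest other
  (non-coincident) anchor point of the same vertex, capped at 20ε (ε = the
  reference mesh's mean edge length) and floored at ε/2. The cap keeps far
  wells from flattening into uselessness; the floor keeps wells from
  becoming sharper than the mesh can resolve (without it, a vertex measured
  exactly on a meridian gets coincident anchors in the two adjacent areas
  and σ → 0, which destabilizes the step-size control).
- **w** starts at ω and is reduced ×0.25 when the field sign of the faces
  around the vertex (computed from the measured visual-field coordinates)
  contradicts the target area's field sign, and by
  exp(−ln²(s_obs/s_model)/(2·ln²2)) for pRF-size disagreement with the
  area's linear size-vs-eccentricity function. Both factors are
  configurable and can be disabled.

## Minimization

Plain gradient descent with three safeguards, run for a fixed 2500 steps:

- the step is scaled so the largest per-vertex displacement is ε/50;
- each vertex's gradient magnitude is multiplied by (1 + X·noise_scale),
  X ~ Exp(1), direction preserved (noise_scale defaults to 1.0, median
  factor ≈ 1.7); this jitter speeds escape from shallow ledges without
  changing the reachable minimum, and is fully seeded;
- a proposed step that crosses a singularity (any corner angle leaving
  (0, π), any edge leaving (q0, q1)) or that increases F is rejected and
  retried at half size, up to 50 times, then skipped. With noise disabled
  the potential sequence is therefore strictly non-increasing, and in all
  cases every *accepted* configuration is admissible — topology cannot
  break mid-trajectory, which the result object records step by step.

Defaults: q0 = 0 and q1 = 2·r0 per edge (edges may shrink toward zero and
at most double), backtrack factor 0.5, no early stopping. All defaults are
exposed on `MinimizerConfig` / `RegistrationSystem`.

Before registration the subject's map and measurements are resampled onto a
uniform equilateral lattice (edge length 0.2 map units in the simulation
studies, ~900 vertices): uniform triangles keep the angle barriers far from
their singularities and make ε/50 a meaningful global step size. Angular
fields are interpolated through their visual-field Cartesian embedding,
never as raw angles. The registered displacement field is interpolated back
to the native vertices (zero displacement outside the resampled hull).

## Model building

A model is built from labeled boundary contours on a flat mesh: foveal /
peripheral contours clamp scaled eccentricity to ∓1, vertical-meridian
contours clamp scaled polar angle to ∓1, the horizontal meridian clamps it
to 0. Contours are snapped to the nearest mesh vertices (ties to the lowest
index). The interior minimizes

    f(θ̂, ρ̂) = (θ̂·ρ̂)² + Σ_(u,v)∈E [(θ̂u−θ̂v)² + (ρ̂u−ρ̂v)²] / (2‖xu−xv‖)

— fields as smooth as possible along edges and as orthogonal to each other
as possible, boundary values fixed. Each field given the other is a sparse
SPD linear solve (the rank-one orthogonality coupling is folded in with the
Sherman–Morrison identity), so alternating solves decrease f monotonically;
but block alternation crawls in the valley of the coupling term, so after
three alternations the solver switches to damped Newton steps — the full
Hessian is (sparse Laplacian blocks + diagonal coupling) + rank-one, one
sparse factorization plus a Sherman–Morrison correction per step — and
converges quadratically to joint gradient norm < 1e-8.

Scaled fields are then rescaled: θ = 90(θ̂+1); eccentricity through the
two-parameter exponential ρ = t_min + a(exp(b·s) − 1), s = (ρ̂+1)/2, with
(a, b) root-found so the raw field's minimum, median and maximum land on
configured targets (defaults 0°, 3°, 90° — half the map inside ~3° mirrors
foveal cortical magnification). Monotonicity of the fitted map is verified;
non-monotone parameterizations are rejected.

## The synthetic generator

`retmap.synthetic` generates the study conditions used throughout the
tests: a banded model (V1 flanked by mirror-image V2/V3 bands and an outer
ring of hV4/V3a so out-of-target anchors exert realistic pull), built
through the same boundary-fill code path as a hand-labeled model; subjects
as smooth random warps of the model mesh (sum of Gaussian bumps, tapered to
zero at the map perimeter — the rim of a map projection is anatomically
anchored — normalized to a requested mean displacement, default 5 mean edge
lengths, then shrunk if needed until no triangle approaches inversion); and
noisy measurements: additive Gaussian polar-angle noise (sd 20°/scan),
multiplicative log-normal eccentricity noise (log-sd 0.1), Gaussian pRF-size
noise floored at 0.01°, Beta(12, 3) variance explained, a 12° stimulus
aperture and a ±10° vertical-meridian dropout band outside/inside of which
ω collapses to ~0 (and measured angles never enter the meridian band —
measured maps systematically miss the vertical meridians), plus a few
coherent high-ω artifact blobs imitating vessel artifacts. Averaging k
scans shrinks the noise like 1/√k.

What the generator does **not** emulate: 3D folding and curvature (the
fixture lives directly on a flat map; the orthographic projection code is
exercised on synthetic spheres instead), anatomical inter-subject
alignment (identity alignment is assumed), BOLD time series and pRF
solving, spatially correlated noise beyond the artifact blobs, and the
foveal confluence's true geometry. Passing tests therefore demonstrate the
mechanics and the statistical behavior of the inference under controlled
misalignment and noise — not performance on real fMRI maps.

## Numerical choices and degenerate inputs

- Faces with |signed area| < 1e-12 are excluded from corner-angle and
  field-sign computation; field sign of a degenerate visual-field image
  is 0; missing visual-field values mark a face NaN rather than raising.
- Vertex surface area = one third of each incident face's area (conserves
  total area exactly).
- Point-in-triangle location searches nearest face centroids first and
  resolves ties (a query on a shared edge) to the lowest face index;
  barycentric interpolation reproduces affine fields to machine precision.
- The eccentricity rescale solves its one nonlinear equation by bisection
  (`brentq`) on b ∈ [−50, 50] with an explicit b→0 (linear) limit.
- Anchors whose measured coordinates no area represents are skipped, not
  errors; a vertex with zero usable measurements contributes nothing.
- With zero usable measurements the pipeline returns exactly the
  prior-alone lookup (bit-identical), since the gradient at x0 is
  identically zero without anchors.

## Problem sizes

The default fixture model is a 41×81 grid (3321 vertices) on a 4×8 map;
registrations run on the ~900-vertex uniform resampling for 2500 steps
(~20 s each); the simulation studies use 10 seeded subjects (acceptance
tests) or 5 (acceptance script). These sizes give stable orderings of the
prediction errors across seeds while keeping a full study in minutes.

## Known limitations

- The true configuration is not an exact fixed point of the potential:
  even with noiseless measurements at perfect alignment, each vertex's
  anchors in *neighboring* areas pull with relative strength
  e^(−1)·w_neighbor/w_own (a consequence of σ equaling the distance to the
  nearest other anchor), displacing the minimum by a few percent of the
  distance to the nearest area boundary. Under the default weight factors
  this leaves a median residual of ~0.4° polar angle on the fixture —
  negligible against measurement noise, but not zero.
- Solutions that genuinely violate the model's topology (atypical polar
  angle reversals, achiasmic organization) are unreachable by construction;
  the method assigns them zero prior probability.
- The scaled error divides by validation eccentricity and so inflates near
  the fovea; banded breakdowns are reported alongside.
- The minimizer is first-order; convergence within 2500 steps is verified
  empirically on the fixture sizes, not guaranteed.
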