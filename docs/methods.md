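# Methods

`speckletomo` reconstructs per-vessel blood-flow speeds from multi-source
laser speckle contrast images of a known 3D vascular geometry.  This note
records the model, the numerical choices, and the limits of what the
synthetic studies demonstrate.

## Forward model

### Photon transport

Light propagation is modeled with a voxelized Monte Carlo transport code.
The geometry is an isotropic voxel grid (default 5 µm pitch) labeled by
vessel strand — a *strand* being a continuous vessel segment between
bifurcations — with three optical classes (capillary, noncapillary,
extravascular), each carrying absorption µa, scattering µs, and
Henyey–Greenstein anisotropy g.  Defaults (mm⁻¹): capillaries
(0.2, 65, 0.98), noncapillaries (0.2, 90, 0.98), extravascular tissue
(0.02, 10, 0.9).

A collimated 40 µm beam enters at normal incidence.  Photons are tracked
by exact ray–voxel stepping; scattering sites are drawn from the local
scattering coefficient accumulated across voxel boundaries; absorption is
handled continuously, each photon carrying the weight
P = exp(−Σᵢ µa,ᵢ ℓᵢ) over its path.  Boundaries are index matched (no
Fresnel reflection); photons crossing the top surface are detected at
their exit position, all other exits are discarded.  Russian roulette
(threshold 10⁻⁴, survival 0.1) and a 10⁵-event cap terminate stragglers.
A two-level scheme skips vessel-free 40 µm blocks in one step, which
matters because the extravascular mean free path (100 µm) spans ~20 fine
voxels.  Per-photon random streams are counter-based (splitmix64 keyed by
seed and photon id), so results are bit-reproducible and independent of
chunking or execution order.

At every scattering event inside a vessel the photon accumulates the
momentum-transfer coefficient q = (k̂_out − k̂_in)·d̂ into the bucket of
the vessel's flow group, with d̂ the local centerline direction.  The
per-photon momentum transfer at flow map V is then Y = Σᵢ qᵢ vᵢ.  Flow is
modeled as plug flow (a single scalar speed per strand along the
centerline); an inversion recovering one unknown per strand cannot
resolve a radial profile, so the plug model is the natural parameterization.

### Speckle contrast

For one detector the field autocorrelation of the detected ensemble is
g₁(t) = Σₙ Pₙ exp(−2j k₀ Yₙ t) (weights normalized per detector so
g₁(0)=1), and the exposure-integrated contrast is

    K² = (1/T) ∫₀ᵀ β |g₁(t)|² (1 − t/T) dt .

Expanding |g₁|² into photon pairs and integrating each cosine exactly:

    K² = β [ ½ Σₙ Pₙ² + Σₙ<ₘ Pₙ Pₘ sinc²(k₀ T Aₙₘ) ],   Aₙₘ = Yₙ − Yₘ,

with sinc²(x) = sin²x/x².  This closed form (no quadrature error) is the
production path; a trapezoid quadrature of |g₁|² is kept as an
independent cross-check and agrees to ~10⁻⁹ in K at 10⁴ lag points.  As
written, the static limit is K² = β/2; the factor-2 convention found in
parts of the LSCI literature is not applied.  β defaults to 1 (no
instrumentation mismatch in simulation).  Wavelength default 785 nm
(k₀ = 2π/0.785 µm⁻¹); exposure default 3 ms.  Velocities are held in
mm/s at the API surface and converted once to µm/s to match k₀.

Numerical guards: sinc² and its derivative switch to series below
|x| < 10⁻⁴ (10⁻³ for the derivative) to avoid cancellation.  The pair
kernels evaluate sin/cos through one shared inline routine (Cody–Waite
argument reduction plus minimax polynomials, ~10⁻¹⁶ absolute error over
the phase range that occurs here), which keeps the O(M²) loops fast and
trig results identical across kernels.  They are
compiled under strict IEEE semantics with arithmetic mirrored
term for term between the contrast and gradient paths, and per-detector
momentum transfers come from one canonical sparse product shared by image
generation and reconstruction: a model evaluated on the very trajectories
behind a measurement then reproduces it *bitwise*, so the inversion's
fixed point at truth is exact rather than approximate (important because
a scale-invariant Adam step amplifies even 1-ulp residuals).

## Inverse model

The unknown is the vector V of per-group centerline speeds.  The data
misfit is a weighted sum of squared per-detector contrast residuals over
all sources and usable detectors.  Two weighting conventions are
provided: uniform, and photon-count weighting (default), which weights
each detector's squared residual by its detected photon count — the
inverse-variance weighting for Monte Carlo sampling noise in K, whose
variance scales like 1/M.  At the photon budgets of a single-machine
study the detector noise is strongly heteroscedastic (counts vary by
~100× across the grid), and uniform weighting measurably degrades the
recoverable accuracy; at very large photon budgets the two coincide.

### Gradients

The derivative of K̂² w.r.t. vᵢ follows by differentiating the pair sum:

    ∂K̂²/∂vᵢ = β k₀ T Σₙ<ₘ Pₙ Pₘ (qₙᵢ − qₘᵢ) · 2 sin x (x cos x − sin x)/x³,

with x = k₀ T Aₙₘ, combined with the chain rule through K̂ = √(K̂²) and
the residual prefactor.  The O(M²) pair loop is fused in a single kernel
that separates the static photons (Y = 0) analytically, reducing the
quadratic cost to the dynamic subset.  A vectorized forward-difference
route re-evaluates the same stored-trajectory forward at V + ε eᵢ for all
groups (perturbation of fixed Monte Carlo trajectories, not a new
simulation); the two routes agree to 10⁻³ relative (norm) at
ε = 10⁻⁶ × mean flow and the comparison is a standing test.  The
analytic route is the default at every strand count: in this fused-kernel
implementation it shares the pair loop with the forward evaluation and is
strictly cheaper than the (G+1)-evaluation difference route; the
difference route remains available (`gradient_method="fd"`, or `"auto"`
for a small-problem crossover).

### Optimizer

Reconstruction is mini-batch proximal gradient descent: per iteration,
each source contributes a batch of detectors drawn with replacement
(default 1/8 of the usable detectors); the accumulated gradient feeds an
Adam update (β₁=0.8, β₂=0.999, η=0.1, bias-corrected), followed by the
exact TV1D proximal operator (direct, non-iterative single-pass method
with backtracking segment flushes, validated against an exact dual
box-constrained least-squares solution) with weight γ=10⁻³ applied along
the radius-sorted group ordering (noncapillaries by descending radius,
then capillary groups by id), a Nesterov extrapolation with
t_k = ½(1+√(1+4t²_{k−1})), and a projection onto V ≥ 0.  Flows
initialize at 1 mm/s.  Stopping: at N_iter (default 200), or when the
batch cost falls below e_tol (default 0, i.e. run out the iterations).

Several stabilizations, all configurable, depart from the plain recipe;
each was adopted after the plain variant measurably failed or stalled on
exact-data (identical-trajectory) control problems where the correct
behavior is known:

* **Nesterov cap.**  The uncapped extrapolation coefficient approaches 1
  while Adam's normalized steps do not decay, so the extrapolated
  iterate displacement grows without bound; on an exact-data problem the
  plain combination diverges (iterates reach tens of mm/s) while Adam
  alone converges to <0.1% median error.  Adaptive restart does not
  rescue it because Adam's per-coordinate rescaling breaks the restart
  test's geometry.  The extrapolation coefficient is therefore capped at
  `nesterov_cap` (default 0, i.e. acceleration off; 1 restores the
  uncapped rule).
* **Importance sampling.**  With photon-count weighting, sampling
  detectors uniformly and weighting their contributions by count makes
  the mini-batch gradient variance very large (a few heavy detectors
  dominate).  Stochastic batches are instead drawn with probability
  proportional to detector weight with equal contributions — the same
  expected gradient, far lower variance.  Deterministic full-batch
  sweeps weight contributions explicitly.
* **Moment restarts.**  With β₂ = 0.999 and a run of only ~200
  iterations, the second-moment accumulator keeps the large gradients of
  the early travel phase alive for the whole run, which collapses the
  effective step of exactly those coordinates whose gradients have since
  decayed — the optimizer stalls far from the optimum.  Resetting the
  moment accumulators (and the bias-correction counter) every
  `moment_restart_every` iterations (default 25) re-anchors the step
  scale to the current gradient; on a full-batch control problem this
  changed the 100-iteration median error from ~15% to ~2.5%.
* **SVRG control variate.**  The mini-batch gradient optionally
  subtracts per-detector gradients evaluated at a periodically refreshed
  anchor iterate and adds the full-batch anchor gradient
  (`variance_reduction="svrg"`, anchor every 40 iterations; anchor
  gradients are cached, so the extra cost is one full sweep per refresh).
  Near convergence the batch term nearly cancels and the gradient noise
  drops to the anchor-displacement scale.
* **Late annealing and tail averaging.**  After `eta_anneal_after`
  iterations the learning rate decays hyperbolically, and the returned
  flow map averages the last `tail_average` iterates (default 40); an
  exact fixed point is returned unchanged.  Together these damp the
  residual stochastic jitter of constant-step Adam.

With all defaults the reconstruction reaches the data-noise floor of
the desk-scale study (measured against a bound-constrained full-batch
quasi-Newton solve of the same weighted cost) within the 200-iteration
budget.

## Synthetic phantom and the desk-scale study

The phantom builder lays out horizontal vessel layers (alternating x/y
orientation per layer, evenly spaced) and descending vessels normal to
the surface that bifurcate from the first layer, rasterized by the
voxel-center-within-radius rule (nearest centerline wins at contacts).
Ground-truth speeds are drawn uniformly in [0.3, 5] mm/s per flow group,
or via a monotone radius→speed lookup spanning 0.3 mm/s (capillary) to
6 mm/s (large vessels).  Vessels under 5.5 µm radius are classed as
capillaries, and capillaries sharing a 250 µm cube can be pooled into one
flow unknown.

The standing validation study uses a 0.6×0.6×0.4 mm phantom at 5 µm
pitch: two horizontal layers (depths 100 and 250 µm, radii 20 and 15 µm,
three vessels each) plus two descending vessels (radius 12 µm, reaching
350 µm), giving 8 flow groups; four sources at the quadrant centers; a
40×40 grid of 15 µm pixels with a 200 µm exclusion disk per source and a
300 µm circular aperture.  Ground-truth images come from one trajectory
set and the reconstruction runs against an independently seeded second
set.  The photon budget is 6×10⁷ per source, chosen so that typical
detectors hold hundreds to thousands of photons — the regime in which
the per-detector contrast estimate is stable; reconstruction quality is
data-noise-limited and scales like the inverse square root of the photon
count.  Reported errors are per-group |v̂−v*|/v* in percent; groups
sampled by fewer than 50 dynamically scattered photons (peripheral
vasculature) are reported but excluded from summaries, since their
gradients are too small to converge in a bounded iteration budget.

What these studies do not emulate: camera shot/read noise and the 7×7
spatial window estimator of experimental LSCI (model contrast is
computed directly), Fresnel index mismatch at the surface, pulsatile or
profile-resolved flow, and vectorization errors in the geometry (the
reconstruction gets the true strand table).  Passing them shows the
inversion recovers flows when the geometry and optics are known and the
only corruptions are Monte Carlo sampling noise and (in the noise study)
additive Gaussian measurement noise.

## Noise study

Additive noise at level N perturbs each valid pixel of the ground-truth
images with i.i.d. Normal(0, σ), σ = N × mean valid K (a relative
convention, so "1% noise" means 1% of typical contrast; an absolute mode
is available).  Values are floored at a small positive constant.  The
sweep reconstructs at each level over several noise seeds and
stratifies errors by depth and orientation.

## Known limitations

* The O(M²) pair kernels assume per-detector photon counts of order 10³;
  an optional per-detector photon subsample exists for much larger MC runs.
* Superstrand merging concatenates the two largest-radius strands at
  each bifurcation (ties to the lower id); radii of merged traces are
  length-weighted means, which coarsens radius-sorted TV ordering for
  strongly tapered vessels.
* The phantom geometry uses straight vessels; curved/tortuous geometry
  exercises the same per-voxel direction machinery but is only covered
  by construction, not by a dedicated study.
* Parallel execution is limited to order-independent photon chunks; no
  distributed/multi-node support.
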