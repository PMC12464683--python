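# Methods

This note documents the models, conventions, numerical choices, and known
limitations behind the package. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Problem statement

A scalar field `b(x, t)` (above-ground tree biomass in grams, positions in
meters, time in years) is measured at `p` scattered space–time points. We
assume `b` is smooth and satisfies an autonomous PDE of the form
`∂b/∂t = F_β(b, ∇b, ∇²b)`, with `F_β` a linear combination of candidate
terms. The task is to identify which terms matter and with what
coefficients. The a priori family is the advection–reaction–diffusion (ADR)
operator

    ∂b/∂t = ρ b − v·∇b + ∇·(d ∇b)

with reaction rate ρ [1/y], transport velocity v [m/y], and diagonal
diffusion d [m²/y]. In the biological reading, ρ captures exponential mass
growth, v₃ the rising crown, and d the isotropic crown expansion.

## Scaled frame

All fitting happens on dimensionless variables:

    B = b/σ_b,  τ = (t − t̄)/σ_t,  ξᵢ = (xᵢ − x̄ᵢ)/σᵢ .

Conventions, fixed once and used everywhere:

* **Population standard deviations** (divide by n, not n−1).
* **The field is scaled but not centred**; the coordinates are centred and
  scaled. The asymmetry is deliberate and matters for unit conversion.
* The zero-field boundary condition `b = 0` on ∂Ω is treated as metadata: it
  is honoured by the generators to numerical tolerance (see below) but never
  enforced by a penalty, because the extrapolation objective contains only
  data misfit and weight decay.

Chain rule gives the coefficient maps between frames. If the scaled-frame
identification returns `∂B/∂τ = ρ_s B − v_s·∇_ξ B + d_s Δ_ξ B`, then

    ρ = ρ_s/σ_t,   vᵢ = v_{s,i} σᵢ/σ_t,   dᵢ = d_{s,i} σᵢ²/σ_t .

Two subtleties:

* The catalogues carry a **single isotropic Laplacian weight**. Under
  anisotropic scaling (σ₁ ≠ σ₃) the scaled-frame image of an isotropic
  physical Laplacian is *not* a multiple of the scaled Laplacian sum, so the
  single weight is only exactly representable when the σᵢ are equal. The
  physical conversion therefore uses the mean of σᵢ² and warns when the σᵢ
  spread exceeds 10%. For the same reason the ADR generator's default
  sampling box for recovery experiments is **cubic** (every axis padded to
  the longest side), which makes the grid coordinate spreads — and hence the
  σᵢ — identical and keeps recovery well-posed and exact.
* Radial and angular velocities convert with σ₁, asserting σ₁ ≈ σ₂ (same
  warning), since anisotropic scaling distorts circles.

**Sign convention.** The identification layer learns raw weights w in
`∂B/∂τ = Σ wᵢ·termᵢ`. Reported coefficients follow the ADR convention
(v = −w on first-derivative terms; ρ, d = w), so a crown rising along +x₃
yields a positive v₃. Both raw weights and converted coefficients are kept.

## Surrogate (extrapolation step)

A dense feed-forward network 4 → 16 → 32 → 32 → 32 → 1 with tanh hidden
activations and linear output. tanh is required because the differentiation
step needs second derivatives; piecewise-linear activations are rejected at
configuration time. Defaults: L2 kernel coefficient 1e-6 (weights only,
biases unpenalized), Adam learning rate 1e-4 (β₁ = 0.9, β₂ = 0.999,
ε = 1e-7), batch size 16 (2 and 64 are the other studied values), 100
epochs, Glorot-uniform initialization seeded from the config. No early
stopping: a fixed epoch count keeps runs comparable and deterministic.

The printed objective `J₁ = ½Σ|residual|² + (c_α/2)‖α‖²` is exposed as
`j1_loss` for testing; the trainer minimizes the equivalent per-batch
mean-squared form with per-layer L2 — the standard deep-learning realization
of the same objective (the two regularization knobs, global c_α and the
per-layer 1e-6, are kept distinct).

The network, its training, and its input derivatives are implemented
directly in numpy. Derivatives up to second order are obtained by
**forward-mode propagation** of directional first and second derivatives
through the layers (linear layers map them linearly; an activation f gives
s′ = f′(z)z′ and s″ = f′(z)z″ + f″(z)z′²). This is mathematically identical
to automatic differentiation and exact to floating point, which the test
suite verifies against central finite differences (relative error < 1e-5 at
order 1 with h = 1e-4, < 1e-3 at order 2 with h = 1e-3, over 100 seeded
random points). Mixed partials (∂²/∂ξ₁∂ξ₂) are not implemented — no default
catalogue uses them — and are rejected with a capability error.

An **analytic-oracle backend** wraps any closed-form field together with its
derivatives behind the same interface. It makes every downstream stage exact
and is the backbone of the validation strategy: differentiation and
identification can be tested independently of training noise.

## Cylindrical terms

The trees motivating the catalogues are roughly axially symmetric, so two
catalogues express transport as `∂B/∂r` and `(1/r)∂B/∂θ` about the vertical
axis through the scaled-frame origin (the data centroid; a configurable
offset handles off-centre trunks). Both are obtained by chain rule from the
Cartesian gradient — the surrogate is never reparameterized:

    ∂B/∂r = cosθ ∂B/∂ξ₁ + sinθ ∂B/∂ξ₂ ,
    (1/r)∂B/∂θ = −sinθ ∂B/∂ξ₁ + cosθ ∂B/∂ξ₂ ,  θ = atan2(ξ₂, ξ₁).

Points with r < 1e-8 (scaled units) are masked and dropped from cylindrical
libraries (rows removed from X and Y alike) rather than imputed, to avoid
biasing the fit. On an exactly axisymmetric field the angular column has
(numerically) zero variance; normalization then raises a degenerate-term
error naming the term, which is the intended behaviour — the term must be
removed from the catalogue, not silently zeroed. "Numerically zero" is
std ≤ 1e-10 × max(1, max|column|), since rounding leaves the column at the
1e-17 level rather than exactly zero.

## Term library and identification

The four standard catalogues are

| id  | terms                                              | weights            |
|-----|----------------------------------------------------|--------------------|
| I   | B, ∂B/∂ξ₃, Δ-sum                                   | ρ, v₃, d           |
| II  | B, ∂B/∂ξ₁, ∂B/∂ξ₂, ∂B/∂ξ₃, Δ-sum                   | ρ, v₁, v₂, v₃, d   |
| III | B, ∂B/∂r, ∂B/∂ξ₃, Δ-sum                            | ρ, v_r, v₃, d      |
| IV  | B, ∂B/∂r, (1/r)∂B/∂θ, ∂B/∂ξ₃, Δ-sum                | ρ, v_r, v_θ, v₃, d |

where Δ-sum is the component-wise sum of pure second derivatives. The
collocation points default to the measurement points. Library columns and
the target Y = ∂B/∂τ are each normalized by their population standard
deviation (Y* = Y/σ_Y, Xᵢ* = Xᵢ/σ_Xᵢ); back-mapping is
β_scaled,i = β*ᵢ σ_Y/σ_Xᵢ.

The objective is `J₂(β) = ½Σⱼ|Y*ⱼ − Σᵢ βᵢX*ᵢⱼ|² + c_β|β|₁`. The L1 penalty
is **unsquared** (a squared variant sits behind a config flag): the penalty
exists to sparsify, and the unsquared form is the one with a sparsifying
proximal map. Backends:

* `gradient` — the perceptron realization: a single linear layer with the
  bias structurally fixed at zero, mini-batch Adam, per-batch loss
  mean(residual²) + c_β|β|₁, L1 subgradient 0 at 0, seeded shuffling. The
  default learning rate 1e-6 is deliberately conservative and slow; tests
  and the acceptance script use 1e-3, which converges to the
  least-squares solution within 1e-3 in 5000 full-batch epochs.
* `ols` — `numpy.linalg.lstsq`, the deterministic reference; raises on
  underdetermined (q < n) or ill-conditioned (cond > 1e12) libraries.
* `ridge` / `lasso` — scikit-learn with `fit_intercept=False`; the lasso
  alpha is c_β/q so the solved objective equals the sum-scaled J₂ exactly
  (tolerance 1e-10, max 1e5 iterations of coordinate descent).

Keeping the gradient backend hand-written and the penalized backends on
scikit-learn preserves a genuine dual route: the perceptron-style trainer is
always checked against an independent solver.

## Synthetic data

Both generators are sums of separable Gaussian bells with time-varying
weight, centre, and width, so values and all needed derivatives are closed
form.

**Exact ADR solution.** For a Gaussian initial condition the free-space ADR
equation has the exact solution

    b(x,t) = A e^{ρt} Πᵢ N(xᵢ; x0ᵢ + vᵢt, σ0ᵢ² + 2dᵢt) ,

a drifting, spreading, exponentially growing bump. Defaults (the study
conditions for recovery): ρ = 0.3 /y, v = (0, 0, 0.5) m/y, d = 0.01 m²/y
isotropic, σ0 = 0.6 m, A = 1000 g, T = 10 y — a field whose crown-like bump
climbs 5 m over the 10-year horizon while its mass grows twenty-fold.
The generator's core guarantee, asserted in the tests via an independent
residual oracle (and the time derivative re-checked by finite differences),
is that the field satisfies its PDE with relative residual < 1e-6 everywhere
sampled; in practice it is at rounding level.

**Sampling.** Regular voxel grids (typical field voxelization: 0.2 m cubes,
0.1 y steps; tests use coarser grids, see below), with the grid centred
inside the box so that a symmetric domain keeps the data centroid — and
hence the cylindrical axis — on the tree axis. The free-space solution
stands in for a zero-boundary problem: sampling raises a domain-too-small
error if the clean field on the grid's boundary faces exceeds 1e-6 of its
sampled maximum. The default box margin (8.5 initial/final standard
deviations beyond the centre excursion) leaves headroom for coarse grids
whose outermost points sit up to half a step inside the box.

**Noise** is multiplicative, `b·(1 + ε)` with ε ~ N(0, noise_sd²), because
biomass spans orders of magnitude across a tree; an additive model would
drown the canopy fringe. Noisy negatives are clipped to zero to preserve the
non-negativity invariant — a documented bias that is negligible at the 1%
level studied but material at high noise.

**Noise ablation for identification.** The robustness of the sparse
identification to measurement-level noise is tested by propagating 1%
multiplicative noise directly into the term library (every X and Y entry),
with the derivatives themselves taken from the exact oracle. This isolates
the identification stage: noise applied only to the raw measurements, with
an oracle surrogate, would enter solely through the scaling parameters and
cancel exactly under unit conversion, testing nothing; noise filtered
through network training would confound identification robustness with
training error, which the stochastic-pipeline experiment measures
separately.

**Tree mimics.** Phenomenological crown-plus-trunk fields for three
architectural growth forms: an ellipsoidal crown whose centre rises at a
preset rate (rauh-like 0.5 m/y, massart-like 0.3 m/y, prevost-like
0.2 m/y — so crown heights gain ≈5 m, 3 m, and 2 m over 10 years) and whose
radius grows at 0.15–0.20 m/y, above a thin vertical trunk, with total mass
1000·e^{0.3t} g split 80/20 crown/trunk. These fields satisfy no exact PDE;
they exist to test qualitative behaviour (the identified v₃ must rank the
architectures by their construction) and, being exactly axisymmetric, to
exercise the degenerate angular-term path of catalogue IV.

What the generators deliberately do **not** emulate: discrete organs and
branching architecture, leaf turnover (a candidate explanation for low
identified transport on real data), occlusion and sensor artefacts, and
non-Gaussian heteroscedastic noise. Passing tests therefore demonstrate the
correctness of the machinery and well-posedness of recovery, not fidelity of
any particular PDE to real trees.

## Problem sizes and seeds

The test suite and acceptance script run the workflow at sizes chosen to
exercise every path at comfortable desk scale: recovery experiments use the
cubic ADR box at dx = 1.5 m, dt = 2 y (10,368 records); the stochastic
network pipeline uses dx = 1.8 m, dt = 2.5 y (5,000 records, batch 16, 100
epochs); the tree-mimic contrast uses dx = 1.2 m, dt = 1 y (≈50,000
records, oracle surrogate). One global seed fans out to per-stage seeds by
fixed offsets, so any stage can be rerun in isolation and full runs are
bit-reproducible; reports embed the config hash, seeds, and library
versions.

## Known limitations

* Candidate terms are linear in B and at most second order, without mixed
  partials; nonlinear terms (B², B∂B) and term generation are out of scope.
* The gradient identification backend at its default learning rate 1e-6
  converges very slowly; use 1e-3–1e-5 or a closed-form backend in practice.
* Physical conversion of the isotropic diffusion weight and of cylindrical
  velocities is exact only under (near-)isotropic coordinate scaling.
* The network surrogate's second derivatives are the exact derivatives of an
  approximate fit: on under-trained surrogates the Laplacian column is the
  least reliable, and identified d inherits that error — visible in the
  stochastic-pipeline results, where ρ and d are recovered far less
  accurately than v₃.
* No uncertainty quantification on coefficients; batch-size sensitivity is
  reported (sweep support in the pipeline) but not analyzed further.
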