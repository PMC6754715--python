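# Methods

## Model space and discretization

All models live on a bounded measurement interval [l, u] (a rating scale,
by default 0–100). The Hilbert space L²[l, u] is discretized on a
cell-centered uniform grid of `n_cells` cells; amplitudes sit on cell
midpoints and the inner product is the midpoint quadrature
⟨ψ|φ⟩ = Δ Σᵢ ψᵢ* φᵢ with Δ the spacing. Because the quadrature weight is a
single scalar, Hermiticity, unitarity and projector algebra in the plain
matrix sense coincide with the weighted sense.

Interval thresholds snap to the nearest **cell boundary**, so every
interval projector P(a) is an exact 0/1 diagonal matrix; bins are
half-open (a, b] and a bin projector is the difference P(b) − P(a) of
nested interval projectors. Consequences: projector algebra is exact
(P(a)P(b) = P(min(a,b)) without round-off), complete bin partitions sum
exactly to the identity, and sequential tables normalize to 1 up to
floating-point error. The default resolution for a 0–100 scale is 101
cells (one per rating point); coarser grids are used for fitting (below).

No fixed-form quadrature constant is ever assumed for states: every state
is normalized numerically on its grid.

## Observables, sequential measurement, collapse

An observable is a labelled variable whose cumulative event "X ≤ x" is
represented by P_X(x) = U_X P(x) U_X†, with U_X a basis-change unitary
(identity = the native rating basis). Two observables commute exactly when
they share a basis. For an ordered context [x, y, …] and one bin per step,
the sequential operator is the right-to-left product
Q = … P_Y(b₂) P_X(b₁) — **the first-measured projector acts on the state
first**; this order convention is the most error-prone piece of the
machinery and is pinned by dense-trace oracle tests. The probability of
the outcome tuple is ‖Qψ‖² = tr[QρQ†] with ρ = ψψ†. Q is a projector only
in the commuting case; otherwise Q†Q is a POVM element.

Measurement schedules interleave unitary evolution U(t) = e^{−itH} with
projective measurements. Outcome paths are enumerated with *unnormalized*
branch amplitudes, squared only at the leaves; this equals the product of
collapse-conditional probabilities (the chain rule is a test invariant)
and keeps zero-probability branches as structural zeros instead of
errors. Interference is quantified as the difference between the later
marginal pooled over an earlier measurement's outcomes and the same
marginal with no earlier measurement, plus its total-variation distance.
Pooling needs no renormalization because the first-step partition is
complete.

### Two-factor space

The supported product-space structure is one (possibly) non-commuting pair
X, Y acting on the left tensor factor and any observables commuting with
both on the right factor. For a product state ψ_L ⊗ ψ_R the joint table
factorizes into (left-factor sequential table) × (right-factor table),
independent of where the right-factor steps sit in the order; the
implementation computes it in this factorized form and the test-suite pins
it against a brute-force dense oracle on the 36-dimensional product space.
Contexts with two non-commuting pairs and one commuting pair reduce, when
they occur at all, to a shared basis plus a change of variables and are
out of scope; such contexts are rejected with a structure error.

## Hermitian generators and unitaries

Two constructions are provided:

* **Kernel method**: H_ij = exp(−((x_i − x_j)/bandwidth)²) at grid
  midpoints — real, symmetric, positive semi-definite. The associated
  unitary is U = Σ e^{+iλⱼ} VⱼVⱼ†.
* **Hamiltonian method**: H = −σ D₂ + diag(V(x)) with D₂ the three-point
  second difference over Δ² and hard-wall (Dirichlet) boundaries — the
  natural choice for a bounded rating scale (particle in a box). Potentials:
  none, linear μ·x, quadratic x², or tabulated. The propagator is
  U(t) = Σ e^{−itλⱼ} VⱼVⱼ†.

All unitaries are built by eigendecomposition of the Hermitian generator,
never by series methods, so they are unitary to round-off at every size
used (defect < 1e−10 up to 512 cells). The two exponent signs coexist by
convention: `spectral_unitary(H) == evolution_unitary(H, −1)` exactly, and
negative times are therefore allowed in the propagator. On the
400-cell box [−8, 8] the quadratic-potential Hamiltonian reproduces the
harmonic-oscillator spectrum E_k = (2k+1)√σ to ≪1%, which fixes both the
stencil scaling and the boundary treatment.

## Initial states

* **Uniform**: real constant amplitude on a sub-interval, normalized.
* **Truncated complex Gaussian**:
  ψ(x) = C e^{ipx} e^{−((x−μ)/σ)²/2} inside [l, u], zero outside, C by
  numerical normalization. The squared magnitudes form (up to truncation)
  a Gaussian density with mean μ and standard deviation **σ/√2**; tests
  assert this value, which follows from squaring the amplitude envelope.
  The momentum p only rotates phases at t = 0.

Under free dynamics (V = 0, kinetic coefficient σ_H) a packet with p > 0
drifts right at a rate proportional to p (the realized rate is 2σ_H·p —
the dispersion relation of the discrete Laplacian; "rate equal to p"
holds only for σ_H = 1/2, so the package documents the proportionality
per configuration instead of asserting a unit rate) and its variance grows
∝ t² before wall contact; with p = 0 the mean is stationary to machine
precision. Both behaviours are test invariants (drift-rate ratio within
10%, variance-growth exponent fitted in [1.8, 2.2] on the early-time
window t ∈ [0.5, 3] of a 0–100 box at 256 cells).

## Markov comparator

The classical density follows ∂p/∂t = (σ²/2)∂²p/∂x² − μ∂p/∂x in
finite-volume form on the same grid: central differencing for diffusion,
first-order upwinding for drift, zero-flux (reflecting) walls. The
generator's columns sum to zero exactly (mass conservation) and its
off-diagonal rates are non-negative, so e^{tA} preserves positivity.
Propagation is by dense matrix exponential; an independently coded
Crank–Nicolson stepper serves as a cross-check oracle. Accuracy: against
the closed-form advection–diffusion Gaussian (s₀ = 3, μ = 1, σ = 0.5,
t = 1 on a 512-cell [0, 60] box, chosen so boundaries are untouched) the
sup-norm density error is < 1e−3; the leading upwind error is itself
diffusive (≈ μΔ/2), so drift accuracy is first order in Δ while the pure
diffusion limit is second order (halving Δ quarters the error).

Classical measurement restricts and renormalizes the density. Because
evolution and restriction are linear, pooling over any earlier
measurement reproduces the unmeasured later marginal *exactly* — marginal
invariance holds to ~1e−15 for arbitrary schedules, the defining contrast
with the quantum model's collapse-induced interference.

## Context-free model, EM and the G² test

The classical null holds that one joint distribution over all registered
variables reproduces every context's table as a margin. Its MLE is fitted
by EM over the latent full joint: the E-step allocates each observed
context-cell count across unobserved variables proportionally to the
current joint; the M-step renormalizes pooled pseudo-counts. The observed
log-likelihood is monotone (test invariant); both orders of the same
variable set are treated as replicate observations of one margin, so
order effects cannot be absorbed and load onto the test statistic.

The context-effect statistic is
G² = 2 Σ_c Σ_cells n log(n / (N_c p̂)) against saturated per-context
multinomials. Degrees of freedom: Σ_c (cells_c − 1) minus the number of
free joint parameters, counted as fitted joint cells above 1e−10
(structural zeros removed) minus one; the formula is echoed in every
report because no single convention is standard for latent-margin models.
When the joint has more free parameters than the margins constrain (e.g.
three 5-bin variables observed only pairwise) df ≤ 0 and the p-value is
reported as NaN rather than fabricated. Expected probabilities are floored
at 1e−12 inside logs; observed zero cells contribute zero to G².

Calibration (computed by the acceptance suite): with two 3×3-binned
contexts (both orders) at 5000 trials each, the type-I error at α = 0.05
over 500 null replicates lies in [0.03, 0.08]; power against the δ = 0.1
order-effect perturbation exceeds 95%.

## Two-parameter model fitting and comparison

Both generative models expose the same two free parameters (μ, σ):
quantum — kinetic coefficient σ and linear-potential slope μ; Markov —
drift μ and diffusion σ. Matched assumptions: the Markov initial density
is the squared magnitude of the quantum initial state. Fitting maximizes
the multinomial log-likelihood by bounded Nelder–Mead: a coarse lattice
scan of the bounded box supplies the first start and the remaining
restarts are drawn from a generator seeded by `seed`, so fits are
bit-identical under a seed (default 5 restarts, 250 function evaluations
each; recovery simulations use 2–3 restarts). Non-convergence is flagged,
never raised. BIC = k log N − 2 ℓ with k = 2; ΔBIC = BIC_A − BIC_B,
negative favouring A. Holdout prediction computes an unseen condition's
table at the fitted parameters with no refitting.

## Desk-scale study conditions

The canned three-condition design requests ratings at (0.5, 1.5),
(1.5, 2.5) and (0.5, 2.5) seconds, 5 equal bins on 0–100, Gaussian initial
state (center 50, width 20, p = 0), 50 grid cells. True parameters —
quantum (μ = 0.08, σ = 50), Markov (μ = 10, σ = 15) — were chosen once so
that both models produce visible dynamics at these time points: Markov
drift ≈ 25 rating points and diffusion sd ≈ 24 points by 2.5 s; quantum
mean displacement ≈ −σμt² ≈ −30 points with comparable spreading, and a
first-rating collapse that shifts the later marginal by ≈ 0.14 total
variation. Recovery at 10⁴ trials per condition returns both models'
parameters within a few percent, and the fit-two/predict-the-third
protocol identifies the generating model in ≈100 of 100 replicates per
direction at desk scale.

## What the synthetic data do and do not show

Generators draw exact multinomial counts from model tables with one seeded
PCG64 stream per dataset and stamp provenance (generator, parameters,
seed, rng) in the metadata. They emulate the *statistical* structure of
multi-context binned rating experiments — overlapping contexts, order
manipulations, timed measurement schedules — under the exact generating
model. They do not emulate subject heterogeneity (single state vector, no
mixed states), response times, lapses/omissions, or scale-use artifacts
(end-point avoidance, rounding to multiples of 10). Passing recovery tests
therefore shows the pipeline is correct and identifiable under its own
assumptions, not that real judgement data satisfy them.

## Known limitations

* Pure states only; heterogeneous populations would need density matrices.
* The two-factor space supports exactly one non-commuting pair plus
  commuting observables; general n-variable commutation graphs are out of
  scope.
* The Markov comparator has reflecting walls and constant coefficients;
  absorbing-boundary (choice-RT) variants are not modelled.
* The df accounting for the G² test is one documented convention among
  several possible for latent-margin models.
* Upwind drift makes Markov accuracy first-order in spacing when μ ≠ 0;
  use finer grids for strongly drifting regimes.
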