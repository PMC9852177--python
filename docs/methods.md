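# Methods

## Model and quantities of interest

For a fixed n × d matrix A of rank d with left-singular basis U, a random
k × n sketching matrix S is an ε-subspace embedding exactly when the
*distortion*

    D(S) = σ_max(I_d − UᵀSᵀSU)
         = max(|1 − λ_min(UᵀSᵀSU)|, |1 − λ_max(UᵀSᵀSU)|)

is at most ε. Two operating characteristics are computed:

* the **embedding probability** ψ(ε) = Pr(D(S) ≤ ε);
* the **convergence probability** γ of the Hessian-sketch iteration
  β⁽ᵗ⁺¹⁾ = β⁽ᵗ⁾ + (X̃ᵀX̃)⁻¹Xᵀ(y − Xβ⁽ᵗ⁾), which converges (for any starting
  point) iff λ_max((X̃ᵀX̃)⁻¹XᵀX) < 2, i.e. iff λ_min(UᵀSᵀSU) > ½.

For the Gaussian sketch (i.i.d. N(0, 1/k) entries), UᵀSᵀSU is exactly
Wishart(k, I_d/k) whatever the data (*pivotality*), so both probabilities
are data-free functionals of the extreme Wishart eigenvalues. Their
Tracy–Widom approximations, in the regime n ≫ k and d/k → α ∈ (0, 1], are

    ψ̂(ε) = F₁((ε + 1 − μ₊)/σ₊),        γ̂ = F₁((ν − log ½)/τ),

with (writing r_k = √(k − ½), r_d = √(d − ½))

    μ₊ = (r_k + r_d)²/k,               σ₊ = ((r_k + r_d)/k)·(1/r_k + 1/r_d)^{1/3},
    μ₋ = (r_k − r_d)²,                 σ₋ = (r_k − r_d)·|1/r_k − 1/r_d|^{1/3},
    τ  = σ₋/μ₋,                        ν  = log μ₋ − log k − τ²/8.

These are the largest/smallest-eigenvalue centering and scaling constants
with O(d^{−2/3}) convergence; γ̂ uses the logarithmic law of λ_min.

### Conventions adopted

* **σ₊ is a product, not a quotient.** The cube-root factor multiplies the
  leading term. This is fixed by the underlying eigenvalue limit theorems
  and confirmed here by Monte-Carlo: at (k, d) = (2000, 100) the
  sup-distance between the simulated distortion CDF and ψ̂ is ≈ 0.01 with
  the product form and ≈ 0.6 with the quotient.
* **τ > 0.** The factor (1/r_k − 1/r_d) is negative for k > d; its
  magnitude is used so that γ̂ is increasing in k with limit 1, matching the
  exact probability Pr(λ_min > ½) (validated against Wishart Monte-Carlo
  within binomial error). With a negative τ the formula would predict
  certain divergence for generous sketch sizes, which is contradicted by
  direct simulation.
* All logarithms are natural; probability outputs are clamped to [0, 1].
* k = d is allowed in the embedding constants (α = 1 boundary) but rejected
  in the convergence constants, where λ_min is degenerate.

### Spectral-edge (proportional-regime) step approximation

When d/n → γ̄ ∈ (0,1), k/n → ξ ∈ (γ̄,1), d/k → α, the spectrum of UᵀSᵀSU
under the subsampled randomized Hadamard transform (sampling without
replacement) concentrates on deterministic edges

    λ_min/max → (√(1−γ̄) ∓ √((1−ξ)α))²,

giving a step-function approximation to ψ: 1 if ε ≥ σ*, else 0, with
σ* = max|1 − edge|. At (γ̄, ξ, α) = (0.01, 0.2, 0.05) this gives
σ* ≈ 0.42799. In that regime the Hadamard sketch beats the Tracy–Widom
prediction (its empirical curve lies left of ψ̂ and concentrates near σ*);
as d/n → 0 the Tracy–Widom curve takes over. Whether the
without-replacement limits apply verbatim to the with-replacement variant
is left to the caller: the module computes the formula for either.

### Uniform sketch

Uniform row subsampling (rescaled by √(n/k)) carries no comparable limit
law; the package exposes Vershynin's leverage-based tail bound: with
probability ≥ 1 − 2d·exp(−ct²), all singular values of SU lie within
1 ± t√(rn/k), r an upper bound on the leverage scores h_i = ‖u_i‖² ≥ d/n.
The absolute constant c is not pinned down by the theory; it is a required
parameter defaulting to 1, and the bound should be read qualitatively. The
experiments instead demonstrate the uniform sketch's failure mode directly
(high-leverage rows are missed by subsampling).

## Sketch constructions

All four families are exposed as matrix-free apply functions (the contract)
and as materialized dense operators (the test oracle). One seeded
`numpy.random.Generator` per call draws the ingredients in a fixed
documented order (signs before row indices), so the two paths agree to
round-off and identical (spec, seed, input) gives bit-identical output.

* **Gaussian**: S ~ i.i.d. N(0, 1/k); O(ndk).
* **Hadamard (SRHT)**: S = ΦHD/√k. A is zero-padded to n′ = 2^⌈log₂n⌉
  (Sylvester Hadamard matrices always exist there), D is a Rademacher sign
  diagonal, H is applied by the fast Walsh–Hadamard butterfly in
  O(n′ d log n′), Φ subsamples k rows — with replacement by default,
  without replacement as the variant used in proportional-regime analyses.
* **Clarkson–Woodruff (CountSketch)**: every input row gets an independent
  uniform output bucket and sign (the standard CountSketch law; the
  selection law is a design choice, uniform being canonical), accumulated
  in O(nd) via a sort + segmented reduction — no dense S, each entry of A
  touched once.
* **Uniform**: k rows sampled uniformly with replacement, scaled by √(n/k).

## Monte-Carlo oracles

`simulate_gaussian_distortions` exploits pivotality: a draw is the
distortion of GᵀG with G a k × d matrix of N(0, 1/k) — no n-dimensional
object is ever formed, and draws are batched through BLAS.
`sketch_distortions` is the general oracle: sketch U itself B times and
record each realized distortion through the d × d symmetric
eigendecomposition (never an n × n projector). `simulate_wishart_extreme_eigs`
returns (λ_min, λ_max) pairs for convergence-probability checks.

## Solver

The preconditioner X̃ᵀX̃ is Cholesky-factorized once and reused; a singular
factorization raises a dedicated error and counts as non-convergence in
experiment drivers. Convergence is *first-passage*: the run stops the first
time ‖Xᵀ(y − Xβ)‖₂ < tol (absolute, default 1e-6) within max_iter (default
2000), matching the standard experimental protocol with β⁽⁰⁾ = 0. Two
guards extend the protocol: a run whose gradient norm exceeds 10¹² × its
initial value stops early (overflow guard, counts as divergence), and the
condition check λ_max < 2 is computed through the symmetric generalized
eigenproblem with Cholesky whitening rather than explicit inversion.

The sketched-OLS report applies one sketch draw jointly to [y, X, U]
(linearity gives the same S on each block), so the realized distortion of
the very draw used for the solve is measured exactly and the error bound
‖β_S − β_F‖² ≤ ε²·RSS_F/σ_min(X)² can be verified rather than assumed.
When y lies in col(X) the stacked matrix (y, X) is rank d, not d + 1; the
basis uses the actual rank.

## Tracy–Widom evaluation

F₁ is evaluated from a plain-text grid asset (s from −10 to 7, step 0.01)
interpolated with monotone cubic (PCHIP) splines; outside the grid the
leading-order tail asymptotics (log F₁ ~ −|s|³/24 on the left,
log(1 − F₁) ~ −(2/3)s^{3/2} − (3/2)log s on the right) are continued with
constants fitted at the grid edges. The grid is generated by
`tools/gen_tw1_grid.py` — *not* part of the library path — via the Fredholm
determinant F₁(s) = det(I − V_s) with kernel V_s(x, y) = Ai((x+y)/2)/2 on
L²(s, ∞), discretized by Gauss–Legendre quadrature (spectrally convergent;
refinement deltas ~1e-14). Direct Painlevé II integration was rejected: the
Hastings–McLeod solution is unstable to double-precision perturbations on
the left axis. Accuracy of the shipped table is ~1e-12 at the nodes and
better than 1e-4 everywhere after interpolation; the quantile function
inverts the interpolant by bracketed root-finding (roundtrip error < 1e-6).

## Synthetic data

* `gen_ar1_gaussian(n, d, rho=0.5)`: rows i.i.d. N(0, Σ), Σ_ij = ρ^{|i−j|},
  generated by the stationary AR(1) recursion per row (O(nd)). ρ = 0.5 is
  the simulation design the spectral-step experiment reproduces.
* `gen_regression`: AR(1) design plus y = Xβ* + noise, β* standard normal
  fixed by the seed, noise_sd defaulting to 1 — a library choice (the
  convergence probability is invariant to y, so the noise model only needs
  to be plausible, not calibrated).
* `gen_diluted_outliers`: a standard-normal bulk plus a fixed set of
  heavy coordinate-aligned rows (default scale 128). Max leverage decays
  like s²/(s² + n) — large at small n, vanishing as n grows. This is the
  world in which sketch universality is *observable*: with flat-leverage
  designs (i.i.d./AR(1)) the structured sketches are already
  indistinguishable from the Gaussian law at a few thousand rows, so a
  trend test there would measure only Monte-Carlo noise.
* `bootstrap_enlarge`: row resampling with replacement (duplicating rows
  spreads leverage mass, the mechanism behind improving universality on
  enlarged real datasets).

What the generators do *not* emulate: discreteness and LD structure of real
genotypes, heteroskedastic or heavy-tailed noise, missingness. A green
universality test therefore establishes the leverage-driven mechanism, not
robustness to every feature of real data. Experiment drivers accept a user
matrix, so the same analyses can be re-run on real data by anyone holding
it.

## Testing strategy and tolerances

Exact identities (dense-operator agreement ≤ 1e-12 relative at n ≤ 64,
leverage sum = rank ≤ 1e-8, FWHT involution) are asserted directly.
Stochastic claims use explicit error budgets: binomial standard errors
(3–4 SE bands), two-sample Kolmogorov–Smirnov critical values at the 1%
level for pivotality, and sup-distance bounds that combine the measured
finite-d bias of the Tracy–Widom approximation with Monte-Carlo noise at
the stated B. The headline agreement checks are desk-scaled versions of the
full experiments (e.g. 10,000 Wishart draws at d = 100, k = 2000; the
solver pipeline at n = 5000, d = 20, R = 200 at the sketch size where
γ̂ ≈ ½), sized to keep the whole suite around two minutes on one CPU.

## Known limitations

* The O(d^{−2/3}) rate constants are not computed; rate claims are
  qualitative.
* Iterative extreme-eigenvalue solvers are not used: the full d × d
  eigendecomposition is exact and cheap at the library's scale (d up to a
  few thousand); very large d would want Lanczos-type solvers.
* Out-of-core matrices, data-aware (leverage-sampling) sketches, and
  accelerated/momentum iterations are out of scope.
* The uniform-sketch bound is qualitative (unknown absolute constant).
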