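# twsketch

Randomized sketching for tall data matrices, with closed-form
**Tracy–Widom operating characteristics**: how likely is a random sketch to
be an ε-subspace embedding, and how likely is a sketch-preconditioned
least-squares solver to converge?

## The problem

Given an n × d dataset **A** with n ≫ d (a genotype/covariate design matrix,
a tall regression problem), a *sketch* compresses it to a k × d surrogate
**SA** through a random k × n matrix **S** whose distribution does not
depend on the data. Downstream linear analyses on **SA** are trustworthy
when **S** is an *ε-subspace embedding*:

    (1 − ε)‖Az‖² ≤ ‖SAz‖² ≤ (1 + ε)‖Az‖²   for all z,

equivalently σ_max(I_d − UᵀSᵀSU) ≤ ε with U the left-singular basis of A.
Classical results only bound the probability of this event from below, and
the bounds are loose. For the Gaussian sketch, UᵀSᵀSU is exactly
Wishart(k, I_d/k) — independent of the data — and random-matrix theory gives
sharp *point estimates*:

* **embedding probability**  ψ̂(ε) = F₁((ε + 1 − μ_{k,d}) / σ_{k,d}),
* **solver convergence probability**  γ̂ = F₁((ν_{k,d} − log ½) / τ_{k,d}),

where F₁ is the Tracy–Widom distribution of the Gaussian orthogonal
ensemble and μ, σ, τ, ν are explicit functions of k and d built from the
centering/scaling constants of the extreme Wishart eigenvalues. The same
limits hold for the fast structured sketches (subsampled randomized
Hadamard, CountSketch) once n is large relative to the maximum leverage
score of the data — a universality the package verifies empirically.

The convergence statement concerns the Hessian-sketch iteration for least
squares,

    β⁽ᵗ⁺¹⁾ = β⁽ᵗ⁾ + (X̃ᵀX̃)⁻¹ Xᵀ(y − Xβ⁽ᵗ⁾),   X̃ = SX,

which converges iff λ_max((X̃ᵀX̃)⁻¹XᵀX) < 2, i.e. iff λ_min(UᵀSᵀSU) > ½.

## What's inside

| module | contents |
| --- | --- |
| `sketch_core` | Gaussian, Hadamard (SRHT), Clarkson–Woodruff (CountSketch) and uniform sketches; fast Walsh–Hadamard transform; dense-operator oracles |
| `tw_dist` | Tracy–Widom F₁ CDF/quantile from a shipped high-precision grid |
| `spectral_theory` | the closed-form ψ̂, γ̂, spectral-edge (ESD) step approximation, uniform-sketch leverage bound |
| `mc_oracle` | distortion statistic, Wishart Monte-Carlo oracles, empirical embedding probability |
| `precond_solver` | the preconditioned iteration, its convergence condition, sketch-and-solve OLS with the error-bound check |
| `experiments` | AR(1) and outlier-dilution generators, leverage diagnostics, figure-style experiment drivers |
| `io` / `cli` | delimited/`.npy` matrix I/O and the `twsketch` command-line tool |

## Worked example

```python
import numpy as np
import twsketch as tw

# a tall synthetic design: 100,000 rows, 50 AR(1)-correlated columns
A = tw.gen_ar1_gaussian(100_000, 50, rho=0.5, seed=0)

spec = tw.SketchSpec(family="clarkson_woodruff", k=1000, seed=1)
sketched = tw.apply_sketch(A, spec)          # (1000, 50), computed in O(nd)

# how distorted are such sketches?  oracle vs closed form
sample = tw.sketch_distortions(A, spec, B=200, seed=2)
print("median realized distortion:", np.median(sample.draws))
print("TW median distortion:      ", tw.embedding_quantile_tw(0.5, 1000, 50))
print("TW P(embedding at eps=0.5):", tw.embedding_prob_tw(0.5, 1000, 50))
print("MC P(embedding at eps=0.5):", tw.empirical_embedding_prob(sample, 0.5))
```

prints

```
median realized distortion: 0.4705
TW median distortion:       0.4665
TW P(embedding at eps=0.5): 0.878
MC P(embedding at eps=0.5): 0.87
```

i.e. the Tracy–Widom approximation derived for the *Gaussian* sketch
predicts the CountSketch distortion on this tall matrix to about a percent.
The same comparison from the shell:

```sh
$ twsketch embed-prob --k 400 --d 20 --epsilon 0.6 --mc 2000 --seed 1
{
  "d": 20,
  "epsilon": 0.6,
  "k": 400,
  "mc_draws": 2000,
  "mc_probability": 0.998,
  "tw_probability": 0.9974893934877914
}
```

Other subcommands: `sketch`, `distortion`, `conv-prob`, `solve`,
`conv-empirical`, and `experiment` (YAML-configured embedding/convergence
sweeps emitting JSON reports).

## Acceptance script

`scripts/acceptance.py` recomputes the package's two analytic thresholds
from scratch by running the solver machinery itself: the critical
preconditioned eigenvalue separating convergence from divergence of the
iteration (located by bisection over constructed preconditioners on a
2-variable problem), and the supremum distortion ε for which every
ε-subspace embedding guarantees convergence (located by bisection over
worst-case sketched Gram matrices). Run from the repository root:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The broader statistical claims — Monte-Carlo agreement of both Tracy–Widom
approximations, universality of the structured sketches, the spectral-edge
step, and the exact algebraic identities — are exercised by
`tests/test_acceptance.py`.

See `docs/methods.md` for the model, conventions, and numerical choices.
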