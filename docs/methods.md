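# Methods

## Model

An extreme learning machine maps inputs through a frozen random hidden
layer `h(x) = g(Ax + b)` — here `A`, `b` are i.i.d. uniform on [−1, 1],
`g` is the logistic sigmoid, and only the number of hidden nodes `L` and
the seed are free — and fits a linear read-out `β ∈ R^{L×M}` against
one-hot targets `T ∈ {0,1}^{N×M}`. 0/1 target coding is the default
because it matches the (0, 1) range of the sigmoid hidden layer; −1/+1
coding is available behind a flag.

The robust read-out minimizes

```
F(β) = Σᵢ (1 − exp(−‖ξᵢ‖²/2σ²)) + (λ/2)‖β‖₂,₁ + (C/2) Tr((Hβ)ᵀ Z (Hβ)),
ξᵢ = tᵢ − h(xᵢ)β.
```

* The first term is the correntropy induced loss. It is non-convex but
  bounded by 1 per sample, so outliers and mislabelled samples saturate
  rather than dominate. For multi-target problems the per-sample error is
  the squared Euclidean norm of the residual row — the only reading under
  which the per-sample reweighting below is a scalar.
* `‖β‖₂,₁ = Σⱼ ‖βⱼ‖₂` sums the row norms of the output weights; it zeroes
  entire rows, i.e. disconnects hidden nodes, giving a sparser network.
* `Z = D − W` is the combinatorial Laplacian of the binary same-label
  adjacency of the training samples (`W_ij = 1` iff `yᵢ = yⱼ, i ≠ j`), so
  the trace term is `½ Σ_ij W_ij ‖ŷᵢ − ŷⱼ‖²`: same-class samples should
  receive similar outputs. The labels are the only graph the method uses;
  an optional heat-kernel/row-normalized variant exists but is off by
  default. The penalty acts at training time only — prediction is the
  plain forward pass `argmax h(x)β`.

## Optimizer

The loss term admits a half-quadratic (conjugate-function) rewrite: for
`f(τ) = −τ log(−τ) + τ` with `τ < 0`,

```
1 − exp(−v) = inf_{τ<0} (1 − vτ + f(τ)),   attained at τ = −exp(−v),
```

with `v = ‖ξᵢ‖²/2σ²`. Each outer iteration therefore:

1. updates `τᵢ = −exp(−‖ξᵢ‖²/2σ²)` exactly and sets `ω = diag(−τ)`;
2. solves the now convex subproblem
   `min_β Σωᵢ‖ξᵢ‖²/2σ² + (λ/2)‖β‖₂,₁ + (C/2)Tr((Hβ)ᵀZHβ)`
   by alternating the L2,1 reweighting diagonal
   `D = diag(1/(2√(‖βⱼ‖² + κ)))` with the closed-form solve of the
   weighted quadratic, until `β` is stationary (at most `inner_max_iter`
   sweeps, relative-β-change threshold `inner_tol`).

With `η = λσ²`, `ρ = Cσ²` the quadratic solve is

```
β = (ηD + HᵀωH + ρHᵀZH)⁻¹ HᵀωT                                   (N ≥ L)
β = (1/η)D⁻¹Hᵀ (I + (1/η)ωHD⁻¹Hᵀ + (C/λ)ZHD⁻¹Hᵀ)⁻¹ ωT           (N < L)
```

— two algebraically equivalent forms of the same stationarity equation,
chosen so the linear system is `min(N, L)`-dimensional. `HᵀZH` is constant
across iterations and computed once. Step 1 is an exact block
minimization and step 2 is a majorize-minimize descent, so the κ-smoothed
objective is non-increasing; the tests assert this at 1e−8 slack. β is
initialized with the ridge solution at `γ = C` (cheap, deterministic, and
gives iteration 1 meaningful residuals; a zero initialization is available
but makes all ω equal at the first step). The loop stops when the relative
objective change falls below `tol` (default 1e−4) or after `max_iter = 40`
outer iterations. On the two-Gaussian benchmark it converges in 3–6 outer
iterations.

Treating the β-subproblem exactly (rather than taking a single reweighting
step per outer iteration) is a deliberate design choice: the subproblem is
convex with a cheap fixed-point solve, and resolving it fully gives the
outer loop its fast, few-iteration convergence. Setting
`inner_max_iter = 1` recovers the single-step alternation, which descends
the same objective but needs several times more iterations to reach the
same tolerance.

Per outer iteration the dominant costs are `HᵀωH` and the
`min(N, L)`-dimensional solve, i.e. `O(L²N)` when `N ≥ L` (`HᵀZH` is paid
once); K iterations cost `K·O(L²N)`.

## Baselines

* **relm** — ridge read-out `min ½‖β‖² + (γ/2)‖T − Hβ‖²`, one linear
  solve, with the `L×L` / `N×N` branch pair related by the Woodbury
  identity (tested to 1e−8 relative agreement).
* **l21rfelm** — `min ½‖β‖₂,₁ + (C/2)‖T − Hβ‖²`; iteratively reweighted
  with the same κ-smoothed D as the robust model.
* **lr21elm** — `min ‖β‖₂,₁ + C‖T − Hβ‖₂,₁`; two reweighting diagonals,
  one over β rows and one over residual rows, so entire outlier *samples*
  are down-weighted (a milder robustness mechanism than the bounded loss).

Both printed `N < L` formulas in the source derivations omit an inverse on
the bracketed matrix (and the robust update's dual form writes `D` where
`D⁻¹` is required); the implementations use the inverse forms, which are
the ones that satisfy the stationarity conditions, and the tests verify
each solver against a generic numerical minimizer of its objective.

## Parameters and scales

| parameter | default | meaning and scale |
|---|---|---|
| `sigma` | 1.0 | correntropy bandwidth. Residual norms a few × σ saturate the loss. With 0/1 one-hot targets, residual norms live in [0, √2]; σ ≈ 0.5 separates outliers (ω ≈ e⁻³) from inliers (ω ≈ 1), which is what the robustness demo uses. |
| `lam` | 1.0 | L2,1 penalty weight; at 1 it prunes most of a 100-node layer on the planar benchmark while keeping accuracy. |
| `C` | 0.01 | graph weight. Each sample has ~class-size neighbours, so the *effective* per-sample graph weight is ≈ C × class size; keep `C ≲ 1/class size` if the graph is meant to be a mild regularizer. This matters doubly under label noise, because flipped labels corrupt the graph as well as the loss — the robustness demo therefore uses C = 1e−4 at 500 samples per class. |
| `n_hidden` | 100 | hidden nodes L. |
| `kappa` | 1e−6 | smoothing inside row-norm reciprocals, keeping D finite at zero rows. |
| `tol`, `max_iter` | 1e−4, 40 | outer-loop stopping rule. |
| `inner_max_iter`, `inner_tol` | 30, 1e−8 | exactness of the convex subproblem solve. |

Grid search defaults mirror the ranges a user would sweep:
σ ∈ {2^−4.5 … 2^4.5}, λ, C ∈ {10⁻⁴ … 10⁵}, L ∈ {100 … 2000}, scored by
ten-fold stratified CV on macro one-vs-rest accuracy.

Features are min-max scaled to [0, 1] by default (fitted on training data
only): raw expression scales would pin the sigmoid layer to its saturated
tails. Disable with `--no-normalize`.

## Evaluation

Multiclass runs are scored one-vs-rest: per class, Acc, Pre, Recall and F
from the binary confusion table, then arithmetically averaged over classes
(macro). Undefined 0/0 ratios are reported as 0 with a logged warning.
Plain multiclass accuracy is exposed alongside; for binary problems the
two coincide. Repeated-run reports list the sample variance of the
run-level metrics (variance, not standard deviation — the column is
labelled).

## Synthetic benchmark: what it does and does not show

The generator draws two isotropic Gaussian classes in the plane
(N([−2,−2], I) and N([2,2], I); defaults 300 per class) and injects label
noise by flipping randomly chosen class-2 labels to class 1, features
untouched. Robustness runs train on the noisy draw and score on a fresh
clean draw — clean-test accuracy is the quantitative proxy for "the
decision boundary did not move".

This benchmark isolates exactly one failure mode: supervision corrupted by
cross-class label flips on an otherwise easily separable problem. It does
not emulate the marginal distributions, feature correlations, batch
effects or class imbalance of real expression matrices, and the classes
are far better separated than real cancer subtypes; passing it shows the
robust loss mechanism works (mislabelled points receive ω ≈ 0), not that
the method attains any particular accuracy on real omics data. For real
tables the CLI consumes user-supplied CSV/TSV.

## Numerical notes and limitations

* Linear systems are solved by symmetric positive-definite (Cholesky)
  solves, never explicit inversion; the two-branch forms keep the system
  at `min(N, L)`.
* Prediction ties at the argmax break to the lowest class index; the class
  codebook is lexicographically ordered at load time.
* The objective is non-convex: the half-quadratic loop finds a stationary
  point that depends on the initialization. The ridge initialization is
  deterministic, so fits are exactly reproducible given a seed.
* `Z` is stored dense (`N×N`); at a few thousand training samples this is
  fine, far beyond that the graph penalty becomes the memory bottleneck.
* Acceptance and test problem sizes (N ≤ 1000, L ≤ 100) are chosen to keep
  the full suite fast while exercising both `N ≥ L` and `N < L` code
  paths.
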