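# robustelm

Robust multiclass classification of high-dimensional feature tables —
gene-expression matrices in particular — with extreme learning machines
(ELMs) whose read-out layer is made robust to label noise and outliers.

Real omics training sets are small, wide, and imperfectly labelled. An ELM
fixes a random nonlinear hidden layer `h(x)` and fits only the linear output
weights `β`, which makes it fast, but the usual squared loss lets a handful
of mislabelled samples drag the decision boundary. This package implements
a read-out that minimizes

```
F(β) = Σᵢ (1 − exp(−‖tᵢ − h(xᵢ)β‖² / 2σ²))   (bounded correntropy loss)
     + (λ/2) ‖β‖₂,₁                           (row sparsity: prunes hidden nodes)
     + (C/2) Tr((Hβ)ᵀ Z Hβ)                   (same-label graph smoothness)
```

where `H` is the hidden output matrix, `tᵢ` the one-hot target of sample
`i`, and `Z` the graph Laplacian of the same-label adjacency of the
training set. The correntropy loss saturates at 1, so a grossly mislabelled
sample can shift the objective by at most a constant. The non-convex
problem is solved by half-quadratic iteration: per-sample weights
`ωᵢ = exp(−‖ξᵢ‖²/2σ²) ∈ (0,1]` are updated in closed form, and the
remaining convex subproblem in `β` is solved exactly via L2,1 reweighting —
each iteration provably decreases the objective, and convergence is reached
in a handful of iterations.

Three reference read-outs are included for comparison: the ridge ELM
(`relm`), the node-sparse L2,1-penalized ELM (`l21rfelm`), and the doubly
row-sparse ELM with an L2,1 loss (`lr21elm`), plus macro one-vs-rest
evaluation metrics, stratified K-fold grid search, and generators for a
synthetic label-noise robustness benchmark.

## Worked example

Train on two Gaussian classes (500 points each, centred at [−2,−2] and
[2,2]) after flipping 100 class-2 labels into class 1, then score on a
clean draw:

```python
import numpy as np
from robustelm import (SyntheticSpec, gaussian_classes, fit, predict,
                       classification_metrics)
from robustelm.io import MinMaxNormalizer

train = gaussian_classes(SyntheticSpec(n_per_class=(500, 500), n_noise=100, seed=0))
test = gaussian_classes(SyntheticSpec(n_per_class=(500, 500), seed=1))
scaler = MinMaxNormalizer().fit(train.X)
X_tr, X_te = scaler.transform(train.X), scaler.transform(test.X)

robust = fit(X_tr, train.y, method="csrgelm", seed=0, sigma=0.5, lam=1.0, C=1e-4)
ridge = fit(X_tr, train.y, method="relm", seed=0, gamma=1.0)

print("iterations:", robust.weights.n_iterations)
flipped = np.array(train.flipped_indices)
om = robust.hq_state.omega
print("median omega, flipped vs clean: %.3f vs %.3f"
      % (np.median(om[flipped]), np.median(np.delete(om, flipped))))
for name, m in [("csrgelm", robust), ("relm", ridge)]:
    rep = classification_metrics(test.y, predict(m, X_te))
    print(f"{name}: clean-test accuracy {rep.accuracy:.4f}")
```

prints

```
iterations: 6
median omega, flipped vs clean: 0.041 vs 0.958
csrgelm: clean-test accuracy 1.0000
relm: clean-test accuracy 0.9900
```

The half-quadratic weights tell the story: the 100 mislabelled points end
up with ω ≈ 0.04 (soft-removed from the fit) while genuine points keep
ω ≈ 0.96, so the robust boundary ignores the noise that pulls the ridge
boundary off target. On the same run, 97 of the 100 output-weight rows are
driven to (near) zero by the L2,1 penalty — the fitted network effectively
uses 3 hidden nodes.

The same pipeline is available from the shell:

```bash
robustelm simulate train.csv --n-per-class 500 --n-noise 100 --seed 0
robustelm fit train.csv model.npz --method csrgelm --sigma 0.5 --lam 1.0 --c 1e-4
robustelm predict model.npz test.csv predictions.csv --label-column label
robustelm robustness-demo --n-per-class 500 --n-noise 100 --n-seeds 20
```

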