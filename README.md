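# mklfuse

Dual-norm multiple kernel learning (MKL) for fusing heterogeneous
biomedical data sources: one-class SVM ranking (gene/candidate
prioritization), SVM and least-squares SVM (LSSVM) classification over a
learned combination of kernel matrices.

## The problem and the method

Given p positive semi-definite kernel (Gram) matrices K₁ … K_p over the
same samples — e.g. one per genomic data source, or linear/RBF/polynomial/
clinical kernels over one clinical table — the package learns a predictor
on the combined kernel

    Ω(θ) = Σⱼ θⱼ Kⱼ,  θⱼ ≥ 0,

jointly with the weights θ. Each machine's dual objective contains the
per-kernel quadratic terms ηⱼ (e.g. ηⱼ = ½ αᵀYKⱼYα for the SVM); choosing
θ adversarially over a norm ball makes the combined term a *dual norm* of
η, and the norm controls the character of the fusion:

* **L∞ (Chebyshev) mode** — θ on the simplex (L1-regularized weights):
  maxⱼ ηⱼ. Sparse: one or two dominant sources take all the mass.
  An optional floor θ_min/p per source ("regularized L∞") tempers this.
* **L1 mode** — uniform averaging, θⱼ = 1/p.
* **L2 mode** — ‖θ‖₂ = 1: the bound is ‖η‖₂, tight at θ ∝ η
  (Cauchy–Schwarz equality). Non-sparse: every informative source keeps a
  positive weight.
* **Ln mode** — ‖θ‖_m = 1 with 1/m + 1/n = 1: the bound ‖η‖ₙ is tight at
  θⱼ ∝ ηⱼ^(n/m) (Hölder equality), interpolating between the two regimes.

Each problem can be solved two ways — a one-shot conic/QP solve of the
epigraph formulation ("direct"), or a semi-infinite-programming wrapper
("sip") that alternates a small master problem over θ with ordinary
single-kernel fits — and the two agree to ~1e-4 in θ on the shipped
benchmarks. For the LSSVM, the regularization parameter λ can be estimated
jointly with θ by appending an identity matrix as kernel p+1 (λ̂ = 1/θ_{p+1}),
replacing a 21-point cross-validation grid search with a single training
pass. Class-weighted SVM and sample-weighted LSSVM variants handle
imbalanced data.

See `docs/methods.md` for the formulations, solver details and numerical
choices.

## Worked example

Six unit-diagonal linear kernels over a synthetic two-class fusion dataset:
two views carry class signal (class-mean separations 3.0 and 2.5 noise
s.d.), four are pure noise. Train on 100 samples, test on 50:

```python
import numpy as np
from mklfuse import (NormSpec, generate_fusion_dataset, fit_svm_mkl,
                     error_of_auc)
from mklfuse.svm import predict

ds = generate_fusion_dataset(n_samples=150, informative=(3.0, 2.5),
                             n_noise_views=4, n_features=10, seed=7)
ks = ds.kernel_set()                      # 6 unit-diagonal linear kernels
ids = np.array(ds.sample_ids)
train, test = ids[:100], ids[100:]

for mode in ("inf", "two"):
    model = fit_svm_mkl(ks.subset(train), ds.labels[:100], C=1.0,
                        spec=NormSpec(mode), formulation="sip")
    _, scores = predict(model, ks.cross(test, train))
    err = error_of_auc(scores, ds.labels[100:])
    print(f"L-{mode:3s}  theta = {np.round(model.theta, 3)}  "
          f"test error of AUC = {err:.3f}")
```

prints

```
L-inf  theta = [0.387 0.407 0.142 0.002 0.062 0.   ]  test error of AUC = 0.010
L-two  theta = [0.536 0.651 0.32  0.23  0.297 0.213]  test error of AUC = 0.008
```

The Chebyshev weights concentrate on the two informative views and zero
out noise sources; the L2 weights (‖θ‖₂ = 1) rank the sources the same way
but keep every kernel in the combination. Both fusions rank held-out
samples nearly perfectly (error of AUC = 1 − AUC ≈ 0.01).

## Command line

The same functionality is exposed as a CLI over kernel files (TSV matrices
with sample ids as header row and first column):

```bash
mklfuse kernels  --input features.tsv --type rbf --width-multiplier 4 --output k_rbf4.tsv
mklfuse rank     --kernels k1.tsv --kernels k2.tsv --norm two --nu 0.5 \
                 --train-ids train.txt --candidate-ids candidates.txt --output ranking.tsv
mklfuse classify svm   --kernels k1.tsv --kernels k2.tsv --labels labels.tsv \
                       --norm inf --formulation sip --output predictions.tsv
mklfuse classify lssvm --kernels k1.tsv --kernels k2.tsv --labels labels.tsv \
                       --norm two --lambda estimate --output predictions.tsv
mklfuse benchmark --config benchmark.yaml --out results/
```

Kernel builders: linear, RBF (width = multiplier × average per-feature
variance; multipliers 4/6/8 give the standard family), polynomial (degrees
2–4, bias 1), k-mer spectrum string kernel (FASTA input), and the clinical
kernel for mixed continuous/ordinal/categorical patient tables. Every run
can write a JSON manifest (resolved config, seeds, θ, λ̂, SIP trace)
sufficient to reproduce it exactly.

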