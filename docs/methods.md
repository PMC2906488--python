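# Methods

## The model family

`mklfuse` learns predictors over a weighted combination of Gram matrices,

    Ω(θ) = Σ_{j=1}^p θ_j K_j,    θ_j ≥ 0,

optimizing the kernel weights θ jointly with the model's dual variables.
Every machine in the package has a dual problem whose kernel-dependent part
is a quadratic form, so fusing p sources produces a vector of per-kernel
quadratic terms

    η_j(d) = c · dᵀ H_j d   (c = 1 for the one-class SVM, ½ otherwise),

where d collects the dual variables and H_j is built from K_j (and the task
labels, for classification). Choosing θ adversarially over a norm ball
turns Σ_j θ_j η_j into a *dual norm* of η:

| weight constraint (primal) | value of max Σθ_jη_j (dual) | character of θ |
|---|---|---|
| Σθ_j = 1 (L1)            | max_j η_j (Chebyshev, "L∞ mode") | sparse: mass on the active set |
| θ_j = 1/p (uniform)       | mean of η ("L1 mode")            | fixed uniform averaging |
| ‖θ‖₂ = 1                 | ‖η‖₂ ("L2 mode")                 | non-sparse, θ ∝ η |
| ‖θ‖_m = 1, 1/m + 1/n = 1 | ‖η‖_n ("Ln mode")                | interpolates via θ_j ∝ η_j^{n/m} |

Hölder's inequality Σθ_jη_j ≤ ‖θ‖_m‖η‖_n is tight at θ_j ∝ η_j^{n/m}; this
equality condition is both the proof of the table above and the
coefficient-recovery rule used to read θ off a solved dual point
(`recover_theta`). The L2 mode exists because the Chebyshev solution
discards all but the currently dominant sources — undesirable when a
benchmark's dominant source (e.g. literature-derived similarity in gene
prioritization) is exactly the one expected to be least informative about
*new* discoveries. The non-sparse L2 weights keep every informative source
in the combination.

Machines:

* **One-class SVM** (ranking/prioritization): dual min αᵀΩα over the
  capped simplex {Σα = 1, 0 ≤ α_i ≤ 1/(νN)}. Candidates are scored by
  Σ_i α_i Ω(x, x_i); the offset ρ cancels in rankings and is computed only
  on demand. An optional θ_min ∈ [0, 1] lower-bounds each weight at θ_min/p
  inside the Chebyshev mode (the "regularized L∞" variant).
* **SVM** (classification): the usual box-and-equality dual; multi-class
  problems use one-vs-all coding with a *single θ shared across tasks* by
  summing the per-task quadratic terms inside the norm. Class-weighted
  variants rescale the box to 0 ≤ α_i ≤ C·w(y_i).
* **LSSVM** (classification): squared-error loss with equality
  constraints; a single-kernel fit is one bordered linear system, and the
  coefficient matrix is factorized once and reused for all one-vs-all
  right-hand sides. The regularization parameter λ can be estimated jointly
  with θ by appending the identity matrix as kernel p+1: λ̂ = 1/θ_{p+1}.
  Weighted LSSVM replaces the identity block by diag(1/v_i).

### An ordering fact worth stating explicitly

For fixed η, ‖η‖_n is non-increasing in n, so the adversarial bound over
the L2 sphere *dominates* the Chebyshev bound (the simplex is contained in
the unit L2 ball). For the one-class machine this gives, at the respective
optima,

    t*(L2) ≥ t*(L∞) ≥ uniform-average objective,

and the tests assert exactly this chain. The Chebyshev value is the upper
bound *among simplex-constrained combinations* (hence ≥ the uniform
average), not an upper bound over the L2 sphere.

## Solvers

Two independent routes solve each min-max problem; their agreement is a
standing regression check.

**Direct (one-shot) solves.** The Chebyshev mode uses the epigraph form
(minimize t subject to η_j(d) ≤ t plus the machine's own constraints),
solved by `scipy.optimize.minimize(method="trust-constr")` with exact
Jacobians and Hessians; θ is read from the Lagrange multipliers of the p
quadratic constraints and renormalized onto the simplex (with the θ_min/p
floor added for the regularized variant). The L2/Ln modes minimize the
smooth convex composite ‖η(d)‖_n directly with SLSQP and recover θ from the
Hölder equality condition at the optimum. Both are interior-point-accurate
to ~1e-9 on the problem sizes this package targets (N up to a few hundred).

**SIP (wrapper) solves.** The semi-infinite formulation exchanges a growing
finite set of dual points between (a) a restricted master problem over θ —
a linear program on the simplex for the Chebyshev mode (HiGHS), a small
QCLP with the relaxation ‖θ‖_m ≤ 1 for L2/Ln (SLSQP; PSD kernels guarantee
the constraint is tight at the optimum) — and (b) the machine's plain
single-kernel learner on Ω(θ). Inner learners: libsvm (via scikit-learn's
`SVC`/`OneClassSVM`, tolerance 1e-9/1e-8 with an iteration cap) for the SVM
machines, one LU-factorized linear solve for the LSSVM. The loop stops when
the relative constraint violation |1 − u/S(θ)| drops below ε = 5·10⁻⁴
(default) *and* the master's weight update has settled below 1e-4 in the
max norm; the second condition removes the weight indeterminacy that a pure
objective-gap stop leaves behind and makes runs from different random
starts agree to ~1e-4. After the stop, θ is taken from one final master
solve that includes the last generated dual point.

Whichever route produced θ, the reported model (α, b or β, b) is refit by a
single-kernel solve at the final Ω(θ). At the optimum the two coincide;
operationally this makes direct and SIP models give identical predictions
and guarantees the LSSVM residual invariant on every fit.

**Numerical choices.**

* Master-problem data (η, L) are rescaled by their largest magnitude before
  each LP/QCLP; the optimal θ is scale-invariant but the solvers are not.
* η entries below 1e-12 are clamped to 0 before normalization (PSD
  round-off); an all-zero η yields uniform θ with a warning.
* Chebyshev tie-breaking: argmax ties within 1e-9 relative share the mass
  evenly.
* The LSSVM bordered system is solved by LU with up to three steps of
  iterative refinement; the recorded residual is the normwise *backward
  error* ‖A·sol − rhs‖∞ / (‖A‖·‖sol‖∞ + ‖rhs‖∞), which is asserted ≤ 1e-8
  on every fit. (With sparse Chebyshev λ-estimation the system can be
  near-singular and β large, so an absolute residual would be
  scale-dependent and meaningless.)
* In Chebyshev λ-estimation the master keeps θ_{p+1} ≥ 2⁻¹⁰, i.e.
  λ̂ ≤ 2¹⁰ — the upper end of the standard validation grid. Without the
  bound, separable low-rank problems drive the identity weight to an exact
  zero vertex (λ̂ → ∞), the inner system becomes singular and the exchange
  loop stalls. This caps exactly the pathology that makes sparse λ
  estimation unreliable in the first place.
* ν = 1 in the one-class machine collapses the feasible set to the single
  point α = 1/N, which is returned exactly rather than passed to libsvm.
* `validate_psd` repairs indefinite inputs by clipping negative eigenvalues
  at zero — the minimal Frobenius-norm projection onto the PSD cone — never
  by shifting the diagonal.

## Default parameters

| parameter | default | why |
|---|---|---|
| ν (one-class SVM) | 0.5 | standard choice for prioritization benchmarks; caps any α at 2/N |
| θ_min (regularized L∞) | 0.5 | the usual rule-of-thumb floor; guarantees each source ≥ θ_min/p |
| C (SVM) | 1.0 | unit-diagonal kernels put margins on a common scale |
| ε (SIP stop) | 5·10⁻⁴ | relative duality-gap tolerance of the exchange loop |
| SIP max iterations | 200 | exchange converges in 5–40 iterations on these problem sizes |
| λ CV grid | 21 points, 2⁻¹⁰ … 2¹⁰ | log-uniform; the validation baseline needs 22 training passes vs 1 for joint estimation |
| kernel normalization | unit diagonal | heterogeneous sources must be on comparable scales before fusion; configurable (`trace`, `none`) |
| RBF width | σ² = multiplier × mean per-feature variance | scale-consistent reading of the covariance rule; reduces to multiplier × variance in 1-D; multipliers 4/6/8 give the standard family |
| polynomial kernels | degree 2–4, bias 1 | standard low-degree family for tabular data |

The clinical kernel scores each variable in [0, 1] — continuous and
ordinal variables by 1 − |a−b|/range with the range taken from the training
table, categorical variables by exact-match indicator — and averages over
variables. Constant variables are excluded with a warning. Ordinal
variables are treated like continuous ones on their numeric codes; if a
domain distinction is needed it can be encoded in the codes themselves.

## The synthetic generator, and what the tests do and do not show

`generate_fusion_dataset` emulates the heterogeneous-source fusion setting:
each view v draws class means with pairwise separation δ_v (in units of the
unit noise s.d., exact for two classes, regular-simplex construction for
more) and adds isotropic Gaussian noise; noise views have δ = 0 exactly.
Defaults — 100 samples, two informative views at δ = (3.0, 2.5), four noise
views, 10 features per view — put the informative sources clearly above the
noise floor, which is the regime the method targets (sources strong enough
that their weighting matters). Regeneration with the same seed is
bit-identical.

What the generator does *not* emulate: correlated noise across views,
heavy-tailed or discrete features, non-linear class boundaries, label
noise, and views of wildly different dimensionality. Consequently, passing
benchmarks here demonstrate solver correctness, protocol fidelity and the
qualitative sparse-vs-non-sparse contrast between norms — not that any norm
will win on a particular real dataset. On weakly informative views
(δ ≈ 1–2) the Chebyshev active set genuinely widens and its weights spread
over three or four kernels; that spread is the true optimum (confirmed by
the grid oracle), so the sharp concentration contrast should be expected
only when a few sources clearly dominate.

Benchmark protocols: the defector leave-one-out harness removes one known
item, ranks it against 99 candidates drawn without replacement from the
pool (test sets of 100), and averages the error of AUC (1 − AUC) over
defectors; 20 repetitions redraw the candidates. Repeated k-fold CV uses
random equal partitions (redrawn until every fold contains every class,
failing after 100 attempts) and reports one mean error of AUC per
repetition. Method comparisons use a two-sided paired t-test over the
per-repetition errors — the repetition structure makes a paired design the
natural choice. All randomness flows from a single integer seed through
deterministically derived sub-seeds.

## Problem sizes

The shipped test-suite and the acceptance script run everything at desk
scale: N = 30–200 samples, p = 2–7 kernels, 3-fold CV with 3 repetitions,
10 defector repetitions. These sizes were chosen so that the dense grid
oracle (≤ 10⁴ inner solves) and the cross-formulation comparisons remain
exhaustive; the solvers themselves handle larger N, with the LSSVM SIP path
scaling best (one linear system per iteration regardless of the number of
classes).

## Known limitations

* The direct (epigraph) route holds all p dual-scaled kernel blocks in
  memory and is intended for N up to a few hundred; use the SIP route
  beyond that.
* Only the exchange/discretization SIP is implemented — no low-rank kernel
  approximations and no SDP formulation of binary MKL.
* The L2/Ln master relies on the PSD-induced tightness of the ‖θ‖_m ≤ 1
  relaxation; indefinite "kernels" must be repaired (`validate_psd`) before
  fusion, or the recovered θ is meaningless.
* λ̂ from Chebyshev estimation is capped at 2¹⁰ (see above); the L2 mode
  needs no cap because its weights are strictly positive.
* The one-class ranking scores are comparable within one trained model
  only; the benchmark harness treats each leave-one-out run's ranking
  independently.
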