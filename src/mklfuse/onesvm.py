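"""One-class SVM multiple kernel learning for ranking / prioritization.

The one-class SVM of Tax & Duin / Schölkopf separates the training class
from the origin in feature space; its dual is

    minimize  αᵀ K α   s.t.  Σα_i = 1,  0 ≤ α_i ≤ 1/(νN).

Fusing p sources turns the quadratic into an adversarial combination of
per-kernel terms η_j(α) = αᵀK_jα: the Chebyshev (L∞) mode minimizes
max_j η_j — yielding sparse kernel weights, optionally tempered by a θ_min
floor — while the L2/Ln modes minimize ‖η‖_n and distribute weight over all
informative sources. Candidates are ranked by Σ_i α_i Ω(x, x_i) with Ω the
θ-combined kernel; the offset ρ is irrelevant for ranking and only computed
on request.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.svm import OneClassSVM

from ._solvers import solve_direct_inf, solve_direct_norm
from .kernels import CrossKernel, KernelInputError, KernelMatrix, KernelSet, \
    combine_cross, combine_kernels
from .norms import NormSpec, project_theta

DEFAULT_NU = 0.5
DEFAULT_THETA_MIN = 0.5


@dataclass
class OneSvmModel:
    """Fitted one-class SVM (possibly multi-kernel)."""

    alpha: np.ndarray
    theta: np.ndarray
    nu: float
    sample_ids: tuple[str, ...]
    spec: NormSpec
    kernel_names: tuple[str, ...]
    theta_min: Optional[float] = None
    objective: float = field(default=np.nan)   # outer value t* = ‖η‖ at optimum

    def rho(self, ks: KernelSet) -> float:
        """Offset from the KKT conditions: ρ = (Ωα)_i at free support vectors."""
        Om = combine_kernels(ks, self.theta).values
        g = Om @ self.alpha
        ub = 1.0 / (self.nu * len(self.alpha))
        free = (self.alpha > 1e-8) & (self.alpha < ub - 1e-8)
        return float(g[free].mean()) if free.any() else float(g[self.alpha > 1e-8].mean())


def fit_one_svm(K: KernelMatrix, nu: float = DEFAULT_NU) -> OneSvmModel:
    """Single-kernel one-class SVM fit (libsvm back-end).

    The dual variables are rescaled to the Σα = 1 convention so that
    0 ≤ α_i ≤ 1/(νN).
    """
    N = K.n
    if not 0 < nu <= 1:
        raise ValueError(f"nu must be in (0, 1], got {nu}")
    if nu * N < 1:
        raise ValueError(f"infeasible box: nu*N = {nu * N:.3f} < 1")
    if nu == 1.0:
        # box 0 ≤ α ≤ 1/N with Σα = 1: the feasible set is the single point 1/N
        alpha = np.full(N, 1.0 / N)
    else:
        oc = OneClassSVM(kernel="precomputed", nu=nu, tol=1e-8,
                         max_iter=2_000_000).fit(K.values)
        alpha = np.zeros(N)
        alpha[oc.support_] = oc.dual_coef_[0]
        alpha /= nu * N
    obj = float(alpha @ K.values @ alpha)
    return OneSvmModel(alpha, np.ones(1), nu, K.sample_ids, NormSpec("one"),
                       (K.name,), objective=obj)


def fit_one_svm_mkl(
    ks: KernelSet,
    nu: float = DEFAULT_NU,
    spec: NormSpec = NormSpec("inf"),
    theta_min: Optional[float] = None,
) -> OneSvmModel:
    """One-class SVM MKL: jointly solve for α and kernel weights θ.

    Mode "one" delegates to the single-kernel fit on the uniform average
    kernel. Mode "inf" solves min_α max_j αᵀK_jα (with an optional θ_min/p
    floor on each coefficient); modes "two"/"n" solve min_α ‖η(α)‖_n.
    """
    N, p = ks.n, ks.p
    if theta_min is not None:
        if spec.dual_mode != "inf":
            raise ValueError("theta_min regularization applies to mode 'inf' only")
        if not 0.0 <= theta_min <= 1.0:
            raise ValueError(f"theta_min must be in [0, 1], got {theta_min}")
    if not 0 < nu <= 1:
        raise ValueError(f"nu must be in (0, 1], got {nu}")
    if nu * N < 1:
        raise ValueError(f"infeasible box: nu*N = {nu * N:.3f} < 1")
    if p == 1:
        m = fit_one_svm(ks.kernels[0], nu)
        return OneSvmModel(m.alpha, np.ones(1), nu, ks.sample_ids, spec,
                           ks.names, theta_min, m.objective)
    if spec.dual_mode == "one":
        theta = np.full(p, 1.0 / p)
        m = fit_one_svm(combine_kernels(ks, theta), nu)
        return OneSvmModel(m.alpha, theta, nu, ks.sample_ids, spec, ks.names,
                           None, m.objective)

    ub = 1.0 / (nu * N)
    bounds = [(0.0, ub)] * N
    eqs = [(np.ones(N), 1.0)]
    Hs = ks.matrices()
    x0 = np.full(N, 1.0 / N)
    tmin = theta_min or 0.0
    if spec.dual_mode == "inf":
        alpha, t, theta, value = solve_direct_inf(
            Hs, 1.0, np.zeros(N), bounds, eqs, theta_min=tmin, x0=x0)
        obj = value  # (1-θmin)·t + (θmin/p)Ση at optimum
    else:
        alpha, eta, theta, obj = solve_direct_norm(
            Hs, 1.0, np.zeros(N), spec, bounds, eqs, x0=x0)
    theta = project_theta(theta, spec)
    if tmin:
        theta = np.maximum(theta, tmin / p)
        theta /= theta.sum()
    return OneSvmModel(alpha, theta, nu, ks.sample_ids, spec, ks.names,
                       theta_min, float(obj))


def rank_candidates(model: OneSvmModel, ks_cross: Sequence[CrossKernel]) -> np.ndarray:
    """Scores Σ_i α_i Ω(x, x_i) for each test sample; higher = more relevant.

    The cross blocks must come from the same kernel functions in the same
    source order as training (checked by name and by train-id alignment).
    """
    if len(ks_cross) != len(model.theta):
        raise KernelInputError("number of cross blocks does not match theta")
    for blk, name in zip(ks_cross, model.kernel_names):
        if blk.name != name:
            raise KernelInputError(
                f"cross-kernel source order mismatch: got {blk.name!r}, expected {name!r}")
        if blk.train_ids != model.sample_ids:
            raise KernelInputError(f"cross block {blk.name!r} train ids differ from model")
    Om = combine_cross(ks_cross, model.theta)
    return Om @ model.alpha
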