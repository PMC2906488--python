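"""SVM multiple kernel learning: binary, one-vs-all multi-class, weighted.

The soft-margin SVM dual with a combined kernel Ω(θ) = Σ_j θ_j K_j is

    max_α  1ᵀα - ½ αᵀ Y Ω Y α   s.t.  yᵀα = 0,  0 ≤ α_i ≤ C,

and learning θ adversarially (min over the norm ball) turns the quadratic
term into a dual norm of the per-kernel components η_j = ½ αᵀYK_jYα.
Two formulations are provided: the direct epigraph solve of the QCQP/SOCP,
and the semi-infinite-programming (SIP) wrapper that alternates a small
master problem over θ with plain single-kernel SVM fits (libsvm). Multiple
one-vs-all tasks share a single θ by summing their quadratic terms inside
the norm. Class-weighted variants rescale the box to 0 ≤ α_i ≤ C·w(y_i)
to counter class imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import block_diag
from sklearn.svm import SVC

from ._solvers import SipIteration, sip_optimize, solve_direct_inf, solve_direct_norm
from .kernels import CrossKernel, KernelInputError, KernelMatrix, KernelSet, \
    combine_cross, combine_kernels
from .norms import NormSpec, project_theta

DEFAULT_C = 1.0
DEFAULT_EPS = 5e-4


@dataclass
class SvmMklModel:
    """Fitted (multi-kernel, possibly multi-task) SVM.

    ``alpha`` is N×k of nonnegative dual variables, one column per
    one-vs-all task; ``Y`` the matching ±1 task labels; θ is shared across
    tasks. ``classes`` maps task columns back to the original labels (for a
    single binary task, ``classes = [negative, positive]``).
    """

    alpha: np.ndarray
    b: np.ndarray
    theta: np.ndarray
    Y: np.ndarray
    classes: np.ndarray
    C: float
    spec: NormSpec
    sample_ids: tuple[str, ...]
    kernel_names: tuple[str, ...]
    class_weights: Optional[dict] = None
    theta_min: Optional[float] = None
    sip_trace: Optional[list[SipIteration]] = None
    objective: float = field(default=np.nan)

    @property
    def n_tasks(self) -> int:
        return self.alpha.shape[1]


def _check_binary(y) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) != {-1.0, 1.0}:
        raise ValueError("labels must contain both classes coded -1/+1")
    return y


def _sample_weights(y, class_weights) -> np.ndarray:
    if class_weights is None:
        return np.ones(len(y))
    w = np.array([class_weights[int(v)] for v in y], dtype=float)
    if np.any(w <= 0):
        raise ValueError("class weights must be positive")
    return w


def fit_svm(K: KernelMatrix, y, C: float = DEFAULT_C,
            class_weights: Optional[dict] = None) -> tuple[np.ndarray, float]:
    """Single-kernel soft-margin SVM dual solve (libsvm back-end).

    Returns (alpha, b) with α_i ≥ 0 and the bias from the support-vector
    KKT conditions.
    """
    y = _check_binary(y)
    if C <= 0:
        raise ValueError("C must be positive")
    sw = _sample_weights(y, class_weights)
    clf = SVC(kernel="precomputed", C=C, tol=1e-9, max_iter=2_000_000)
    clf.fit(K.values, y, sample_weight=sw)
    alpha = np.zeros(K.n)
    alpha[clf.support_] = np.abs(clf.dual_coef_[0])
    return alpha, float(clf.intercept_[0])


def svm_dual_objective(K: np.ndarray, y, C: float,
                       class_weights: Optional[dict] = None) -> float:
    """Optimal dual value 1ᵀα - ½αᵀYKYα on one kernel (grid-oracle helper)."""
    y = _check_binary(y)
    alpha, _ = fit_svm(KernelMatrix(K), y, C, class_weights)
    s = alpha * y
    return float(alpha.sum() - 0.5 * s @ K @ s)


def _tasks_from_labels(labels) -> tuple[np.ndarray, np.ndarray]:
    """One-vs-all coding: returns (Y: N×k of ±1, classes). k=2 collapses to
    a single task whose +1 class is the second sorted label."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    if classes.size == 2:
        Y = np.where(labels == classes[1], 1.0, -1.0)[:, None]
        return Y, classes
    Y = np.column_stack([np.where(labels == c, 1.0, -1.0) for c in classes])
    return Y, classes


def _refit_tasks(Om: np.ndarray, Y: np.ndarray, C: float,
                 sw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    alphas, bs = [], []
    for q in range(Y.shape[1]):
        clf = SVC(kernel="precomputed", C=C, tol=1e-9, max_iter=2_000_000)
        clf.fit(Om, Y[:, q], sample_weight=sw)
        a = np.zeros(Om.shape[0])
        a[clf.support_] = np.abs(clf.dual_coef_[0])
        alphas.append(a)
        bs.append(float(clf.intercept_[0]))
    return np.column_stack(alphas), np.array(bs)


def _dual_value(Ks: list[np.ndarray], theta, alpha: np.ndarray, Y: np.ndarray) -> float:
    S = alpha * Y
    val = alpha.sum()
    for t, K in zip(theta, Ks):
        for q in range(Y.shape[1]):
            val -= 0.5 * t * S[:, q] @ K @ S[:, q]
    return float(val)


def fit_svm_mkl(
    ks: KernelSet,
    y,
    C: float = DEFAULT_C,
    spec: NormSpec = NormSpec("inf"),
    formulation: str = "direct",
    theta_min: Optional[float] = None,
    class_weights: Optional[dict] = None,
    eps: float = DEFAULT_EPS,
    max_iter: int = 200,
    seed: Optional[int] = None,
) -> SvmMklModel:
    """Binary SVM MKL under any dual norm, by direct or SIP formulation."""
    y = _check_binary(y)
    classes = np.array([-1.0, 1.0])
    return _fit_mkl_tasks(ks, y[:, None], classes, C, spec, formulation,
                          theta_min, class_weights, eps, max_iter, seed)


def fit_svm_mkl_multiclass(
    ks: KernelSet,
    labels,
    C: float = DEFAULT_C,
    spec: NormSpec = NormSpec("inf"),
    formulation: str = "direct",
    theta_min: Optional[float] = None,
    eps: float = DEFAULT_EPS,
    max_iter: int = 200,
    seed: Optional[int] = None,
) -> SvmMklModel:
    """One-vs-all multi-class SVM MKL with a single θ shared over tasks."""
    Y, classes = _tasks_from_labels(labels)
    return _fit_mkl_tasks(ks, Y, classes, C, spec, formulation, theta_min,
                          None, eps, max_iter, seed)


def fit_weighted_svm_mkl(
    ks: KernelSet,
    y,
    C: float = DEFAULT_C,
    class_weights: Optional[dict] = None,
    spec: NormSpec = NormSpec("inf"),
    formulation: str = "direct",
    theta_min: Optional[float] = None,
    eps: float = DEFAULT_EPS,
    max_iter: int = 200,
) -> SvmMklModel:
    """Class-weighted binary SVM MKL: box constraints 0 ≤ α_i ≤ C·w(y_i)."""
    return fit_svm_mkl(ks, y, C, spec, formulation, theta_min,
                       class_weights, eps, max_iter)


def _fit_mkl_tasks(ks, Y, classes, C, spec, formulation, theta_min,
                   class_weights, eps, max_iter, seed) -> SvmMklModel:
    N, p = ks.n, ks.p
    k = Y.shape[1]
    if theta_min is not None and spec.dual_mode != "inf":
        raise ValueError("theta_min regularization applies to mode 'inf' only")
    if theta_min is not None and not 0.0 <= theta_min <= 1.0:
        raise ValueError("theta_min must be in [0, 1]")
    for q in range(k):
        if len(np.unique(Y[:, q])) < 2:
            raise ValueError("a one-vs-all task has a single class (empty class?)")
    sw = _sample_weights(Y[:, 0], class_weights) if k == 1 else np.ones(N)
    Ks = ks.matrices()
    trace = None

    if p == 1 or spec.dual_mode == "one":
        theta = np.ones(1) if p == 1 else np.full(p, 1.0 / p)
    elif formulation == "sip":
        def inner(th):
            Om = sum(t * K for t, K in zip(th, Ks))
            L = 0.0
            Ssigned = np.empty((N, k))
            for q in range(k):
                clf = SVC(kernel="precomputed", C=C, tol=1e-9, max_iter=2_000_000)
                clf.fit(Om, Y[:, q], sample_weight=sw)
                a = np.zeros(N)
                a[clf.support_] = np.abs(clf.dual_coef_[0])
                L += a.sum()
                Ssigned[:, q] = a * Y[:, q]
            eta = np.array([0.5 * np.einsum("iq,ij,jq->", Ssigned, K, Ssigned)
                            for K in Ks])
            return L, eta
        rng = np.random.default_rng(seed) if seed is not None else None
        theta, trace = sip_optimize(inner, p, spec, theta_min or 0.0, eps,
                                    max_iter, rng=rng)
    elif formulation == "direct":
        Hs = [block_diag(*[np.outer(Y[:, q], Y[:, q]) * K for q in range(k)])
              for K in Ks] if k > 1 else \
             [(np.outer(Y[:, 0], Y[:, 0]) * K) for K in Ks]
        c_lin = np.ones(N * k)
        bounds = [(0.0, C * w) for _ in range(k) for w in sw]
        eqs = []
        for q in range(k):
            a = np.zeros(N * k)
            a[q * N:(q + 1) * N] = Y[:, q]
            eqs.append((a, 0.0))
        x0 = np.full(N * k, min(0.1 * C, 0.01))
        if spec.dual_mode == "inf":
            d, t, theta, _ = solve_direct_inf(Hs, 0.5, c_lin, bounds, eqs,
                                              theta_min=theta_min or 0.0, x0=x0)
        else:
            d, eta, theta, _ = solve_direct_norm(Hs, 0.5, c_lin, spec, bounds,
                                                 eqs, x0=x0)
    else:
        raise ValueError(f"unknown formulation {formulation!r}")

    theta = project_theta(theta, spec)
    if theta_min and spec.dual_mode == "inf":
        theta = np.maximum(theta, theta_min / p)
        theta /= theta.sum()
    Om = combine_kernels(ks, theta).values
    alpha, b = _refit_tasks(Om, Y, C, sw)
    obj = _dual_value(Ks, theta, alpha, Y)
    return SvmMklModel(alpha, b, theta, Y, classes, C, spec, ks.sample_ids,
                       ks.names, class_weights, theta_min, trace, obj)


def predict(model: SvmMklModel, ks_cross: Sequence[CrossKernel]):
    """Predicted labels and decision values on test samples.

    decision_q(x) = Σ_i α_iq y_iq Ω(x, x_i) + b_q; binary tasks take the
    sign, multi-class the argmax over tasks.
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
    dec = Om @ (model.alpha * model.Y) + model.b
    if model.n_tasks == 1:
        labels = np.where(dec[:, 0] >= 0, model.classes[1], model.classes[0])
        return labels, dec[:, 0]
    return model.classes[np.argmax(dec, axis=1)], dec
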