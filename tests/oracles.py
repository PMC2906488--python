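"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's solver code paths: generic scipy
QP solves, dense grid searches and pairwise enumerations.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import LinearConstraint, minimize


def qp_min_quadratic(K: np.ndarray, ub: float) -> tuple[np.ndarray, float]:
    """Generic QP reference for the one-class SVM dual:
    min aᵀKa s.t. Σa = 1, 0 ≤ a ≤ ub."""
    N = K.shape[0]
    res = minimize(
        lambda a: a @ K @ a, np.full(N, 1.0 / N),
        jac=lambda a: 2.0 * K @ a, hess=lambda a: 2.0 * K,
        method="trust-constr", bounds=[(0.0, ub)] * N,
        constraints=[LinearConstraint(np.ones(N), 1.0, 1.0)],
        options=dict(gtol=1e-12, xtol=1e-14, maxiter=5000),
    )
    return res.x, float(res.fun)


def qp_svm_dual(K: np.ndarray, y: np.ndarray, C: float) -> tuple[np.ndarray, float]:
    """Generic QP reference for the SVM dual:
    max 1ᵀa − ½aᵀYKYa s.t. yᵀa = 0, 0 ≤ a ≤ C. Returns (a, optimal value)."""
    N = K.shape[0]
    H = np.outer(y, y) * K

    res = minimize(
        lambda a: 0.5 * a @ H @ a - a.sum(),
        np.full(N, min(0.5 * C, 0.1)),
        jac=lambda a: H @ a - 1.0, hess=lambda a: H,
        method="trust-constr", bounds=[(0.0, C)] * N,
        constraints=[LinearConstraint(y, 0.0, 0.0)],
        options=dict(gtol=1e-12, xtol=1e-14, maxiter=5000),
    )
    return res.x, float(-res.fun)


def grid_max_weighted_sum(eta: np.ndarray, m: float, n_grid: int = 2001) -> float:
    """Dense-grid maximum of Σθ_jη_j over θ ≥ 0, ‖θ‖_m = 1 (p = 2 or 3)."""
    p = len(eta)
    s = np.linspace(0.0, 1.0, n_grid)
    if p == 2:
        pts = np.column_stack([s, 1.0 - s])
    elif p == 3:
        sc = np.linspace(0.0, 1.0, 201)
        a, b = np.meshgrid(sc, sc)
        keep = a + b <= 1.0
        pts = np.column_stack([a[keep], b[keep], 1.0 - a[keep] - b[keep]])
    else:
        raise ValueError("p <= 3 only")
    pts = np.maximum(pts, 0.0)
    pts = pts[np.any(pts > 0, axis=1)]
    if np.isinf(m):
        pts = np.ones_like(pts[:1])  # ||theta||_inf = 1 maximizer is all-ones
    else:
        pts = pts / (np.sum(pts**m, axis=1) ** (1.0 / m))[:, None]
    return float((pts @ eta).max())


def pairwise_auc(scores, labels) -> float:
    """AUC by enumeration of concordant pairs (+ half ties)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == labels.max()]
    neg = scores[labels == labels.min()]
    total = conc = 0.0
    for sp in pos:
        for sn in neg:
            total += 1
            if sp > sn:
                conc += 1
            elif sp == sn:
                conc += 0.5
    return conc / total


def entropy(theta: np.ndarray) -> float:
    """Shannon entropy of θ normalized to a distribution."""
    q = np.asarray(theta, dtype=float)
    q = q / q.sum()
    q = q[q > 0]
    return float(-(q * np.log(q)).sum())
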