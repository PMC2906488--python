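"""Internal optimization back-ends for the MKL machines.

Two routes solve the same min-max problem over kernel weights:

* direct: the epigraph (QCLP/QCQP) form is handed to scipy's interior-point
  machinery in one shot — ``solve_direct_inf`` (Chebyshev mode, θ read from
  the Lagrange multipliers of the quadratic constraints) and
  ``solve_direct_norm`` (L2/Ln modes, smooth norm-composite objective, θ
  recovered from the Hölder equality condition);
* sip: ``sip_optimize`` exchanges a growing finite set of dual points
  between a small master problem over θ (an LP in Chebyshev mode, a QCLP in
  L2/Ln mode) and the machine's single-kernel learner.

Both are expressed over a flattened dual vector d with per-kernel quadratic
terms η_j(d) = factor · dᵀ H_j d; machines supply the H_j and the linear
part of their dual objective.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import LinearConstraint, NonlinearConstraint, linprog, minimize

from .norms import NormSpec, project_theta, recover_theta

__all__ = [
    "SolverError",
    "SipConvergenceError",
    "SipIteration",
    "solve_direct_inf",
    "solve_direct_norm",
    "sip_optimize",
]


class SolverError(RuntimeError):
    """An optimization back-end failed to reach its tolerance."""


class SipConvergenceError(SolverError):
    """SIP loop exhausted its iteration budget; carries the trace."""

    def __init__(self, msg: str, trace: list):
        super().__init__(msg)
        self.trace = trace


@dataclass
class SipIteration:
    """One SIP loop record: master value u, weights θ, relative violation."""

    tau: int
    u: Optional[float]
    theta: np.ndarray
    violation: float
    objective: float


def _eta_all(d: np.ndarray, Hs: Sequence[np.ndarray], factor: float) -> np.ndarray:
    return np.array([factor * d @ H @ d for H in Hs])


def solve_direct_inf(
    Hs: Sequence[np.ndarray],
    factor: float,
    c_lin: np.ndarray,
    bounds,
    eq_vectors: Sequence[np.ndarray],
    theta_min: float = 0.0,
    ridge: float = 0.0,
    x0: Optional[np.ndarray] = None,
    gtol: float = 1e-9,
    maxiter: int = 3000,
):
    """Chebyshev-mode epigraph solve.

    minimize  (1-θ_min)·t + (θ_min/p)·Σ_j η_j(d) + dᵀdiag(ridge)d - c_lin·d
    s.t.      η_j(d) ≤ t,  bounds on d,  a·d = 0 for each equality vector.

    Returns (d, t, theta, value) where value is the minimized composite and
    θ combines the θ_min/p floor with the normalized constraint multipliers.
    """
    p = len(Hs)
    D = Hs[0].shape[0]
    nv = D + 1
    frac = theta_min / p

    rvec = np.broadcast_to(np.asarray(ridge, dtype=float), (D,))
    has_ridge = bool(np.any(rvec))

    def obj(z):
        d, t = z[:D], z[-1]
        v = (1.0 - theta_min) * t - c_lin @ d + d @ (rvec * d)
        if frac:
            v += frac * _eta_all(d, Hs, factor).sum()
        return v

    def jac(z):
        d = z[:D]
        g = np.empty(nv)
        g[:D] = -c_lin + 2.0 * rvec * d
        if frac:
            for H in Hs:
                g[:D] += frac * 2.0 * factor * (H @ d)
        g[-1] = 1.0 - theta_min
        return g

    Hsum = sum(Hs) if frac else None

    def hess(z):
        M = np.zeros((nv, nv))
        if has_ridge:
            M[:D, :D] += 2.0 * np.diag(rvec)
        if frac:
            M[:D, :D] += frac * 2.0 * factor * Hsum
        return M

    cons: list = [
        LinearConstraint(np.append(a, 0.0), b, b) for a, b in eq_vectors
    ]
    for H in Hs:
        cons.append(
            NonlinearConstraint(
                lambda z, H=H: factor * z[:D] @ H @ z[:D] - z[-1],
                -np.inf, 0.0,
                jac=lambda z, H=H: np.append(2.0 * factor * (H @ z[:D]), -1.0),
                hess=lambda z, v, H=H: _pad_hess(2.0 * factor * v[0] * H, nv),
            )
        )
    if x0 is None:
        x0 = np.zeros(D)
    t0 = float(_eta_all(x0, Hs, factor).max()) + 1.0
    z0 = np.append(x0, t0)
    bnds = list(bounds) + [(None, None)]
    res = minimize(
        obj, z0, jac=jac, hess=hess, method="trust-constr",
        bounds=bnds, constraints=cons,
        options=dict(gtol=gtol, xtol=1e-12, maxiter=maxiter),
    )
    if res.status not in (1, 2):
        raise SolverError(f"direct Chebyshev solve failed: {res.message}")
    d, t = res.x[:D], float(res.x[-1])
    mult = np.abs(np.array([res.v[len(eq_vectors) + j][0] for j in range(p)]))
    if mult.sum() <= 0:
        # no active quadratic constraint multiplier: fall back on eta argmax
        theta_free = recover_theta(_eta_all(d, Hs, factor), NormSpec("inf"))
    else:
        theta_free = mult / mult.sum()
    theta = frac + (1.0 - theta_min) * theta_free
    return d, t, theta, float(res.fun)


def _pad_hess(M: np.ndarray, nv: int) -> np.ndarray:
    out = np.zeros((nv, nv))
    out[: M.shape[0], : M.shape[1]] = M
    return out


def solve_direct_norm(
    Hs: Sequence[np.ndarray],
    factor: float,
    c_lin: np.ndarray,
    spec: NormSpec,
    bounds,
    eq_vectors: Sequence[np.ndarray],
    ridge: float = 0.0,
    x0: Optional[np.ndarray] = None,
    ftol: float = 1e-12,
    maxiter: int = 2000,
):
    """L2/Ln-mode direct solve of  minimize ‖η(d)‖_n + dᵀdiag(ridge)d - c_lin·d.

    The composite is convex and smooth wherever η ≠ 0 (η_j ≥ 0 by PSD);
    solved with SLSQP using the analytic gradient. Returns
    (d, eta, theta, value) with θ from the Hölder equality rule.
    """
    D = Hs[0].shape[0]
    n = spec.n
    tiny = 1e-14
    rvec = np.broadcast_to(np.asarray(ridge, dtype=float), (D,))

    def parts(d):
        eta = _eta_all(d, Hs, factor)
        nrm = float(np.sum(np.maximum(eta, 0.0) ** n) ** (1.0 / n)) if n != 2 \
            else float(np.linalg.norm(eta))
        return eta, nrm

    def obj(d):
        _, nrm = parts(d)
        return nrm + d @ (rvec * d) - c_lin @ d

    def jac(d):
        eta, nrm = parts(d)
        g = -c_lin + 2.0 * rvec * d
        if nrm > tiny:
            w = (np.maximum(eta, 0.0) / nrm) ** (n - 1.0)
            for wj, H in zip(w, Hs):
                if wj > 0:
                    g = g + wj * 2.0 * factor * (H @ d)
        return g

    cons = [
        {"type": "eq", "fun": (lambda d, a=a, b=b: a @ d - b),
         "jac": (lambda d, a=a: a)}
        for a, b in eq_vectors
    ]
    if x0 is None:
        x0 = np.zeros(D)
    res = minimize(
        obj, x0, jac=jac, method="SLSQP", bounds=bounds, constraints=cons,
        options=dict(maxiter=maxiter, ftol=ftol),
    )
    if not res.success and res.status != 8:  # 8: positive directional derivative, near-optimal
        raise SolverError(f"direct norm-mode solve failed: {res.message}")
    d = res.x
    eta, _ = parts(d)
    theta = recover_theta(eta, spec)
    return d, eta, theta, float(res.fun)


# ---------------------------------------------------------------------------
# SIP wrapper


def _master_inf(etas, Ls, p, theta_min, lb=None):
    nr = len(etas)
    # rescale: the argmin θ is invariant, HiGHS bounds on coefficients are not
    scale = max(1.0, float(np.abs(np.asarray(etas)).max()),
                float(np.abs(np.asarray(Ls)).max()))
    A_ub = np.hstack([-np.asarray(etas) / scale, -np.ones((nr, 1))])
    b_ub = -np.asarray(Ls) / scale
    A_eq = np.append(np.ones(p), 0.0)[None, :]
    lo = np.full(p, theta_min / p) if lb is None else np.maximum(lb, theta_min / p)
    res = linprog(
        np.append(np.zeros(p), 1.0), A_ub=A_ub, b_ub=b_ub,
        A_eq=A_eq, b_eq=[1.0],
        bounds=[(l, None) for l in lo] + [(None, None)],
        method="highs",
    )
    if not res.success:
        raise SolverError(f"SIP master LP failed: {res.message}")
    return res.x[:p], float(res.x[p]) * scale


def _master_norm(etas, Ls, p, spec, theta_start):
    # rescale the constraint data: argmin over θ is scale-invariant,
    # but SLSQP is not
    scale = max(1e-12, float(np.abs(np.asarray(etas)).max()),
                float(np.abs(np.asarray(Ls)).max()))
    E = np.asarray(etas) / scale
    Lv = np.asarray(Ls) / scale
    m = spec.conjugate_primal_m

    cons = [
        {"type": "ineq",
         "fun": lambda z: z[-1] - (Lv - E @ z[:p]),
         "jac": lambda z: np.hstack([E, np.ones((len(Lv), 1))])},
        {"type": "ineq",
         "fun": lambda z: np.array([1.0 - np.sum(np.maximum(z[:p], 0.0) ** m)]),
         "jac": lambda z: np.append(
             -m * np.maximum(z[:p], 0.0) ** (m - 1.0), 0.0)[None, :]},
    ]
    u0 = float(np.max(Lv - E @ theta_start))
    z0 = np.append(theta_start, u0)
    res = minimize(
        lambda z: z[-1], z0, jac=lambda z: np.append(np.zeros(p), 1.0),
        method="SLSQP", bounds=[(0.0, 1.0)] * p + [(None, None)],
        constraints=cons, options=dict(maxiter=500, ftol=1e-12),
    )
    if not res.success and res.status != 8:
        raise SolverError(f"SIP master QCLP failed: {res.message}")
    return np.maximum(res.x[:p], 0.0), float(res.x[-1]) * scale


def sip_optimize(
    inner: Callable[[np.ndarray], tuple[float, np.ndarray]],
    p: int,
    spec: NormSpec,
    theta_min: float = 0.0,
    eps: float = 5e-4,
    max_iter: int = 200,
    theta0: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
    theta_tol: float = 1e-4,
    lb: Optional[np.ndarray] = None,
):
    """Semi-infinite-programming wrapper (discretization / exchange method).

    ``inner(theta)`` fits the machine's single-kernel learner on the
    combined kernel and returns (L, η) at the new dual point, so that the
    outer objective is S(θ) = L - θ·η. The loop alternates the restricted
    master over θ with the single-kernel solve, stopping when the relative
    violation |1 - u/S| ≤ eps and the master's weight update has settled to
    within ``theta_tol``. Returns (theta, trace).
    """
    if theta0 is None:
        if rng is not None:
            theta0 = project_theta(rng.random(p) + 1e-3, spec)
        elif spec.dual_mode == "inf":
            theta0 = np.full(p, 1.0 / p)
        else:
            theta0 = np.full(p, p ** (-1.0 / spec.conjugate_primal_m))
        if spec.dual_mode == "inf" and theta_min:
            theta0 = np.maximum(theta0, theta_min / p)
            theta0 /= theta0.sum()
    theta = np.asarray(theta0, dtype=float)
    u = None
    etas: list[np.ndarray] = []
    Ls: list[float] = []
    trace: list[SipIteration] = []
    for tau in range(max_iter):
        L, eta = inner(theta)
        S = L - float(theta @ eta)
        if u is not None:
            viol = abs(1.0 - u / S) if abs(S) > 1e-12 else abs(S - u)
        else:
            viol = np.inf
        trace.append(SipIteration(tau, u, theta.copy(), viol, S))
        etas.append(np.asarray(eta, dtype=float))
        Ls.append(float(L))
        if spec.dual_mode == "inf":
            new_theta, new_u = _master_inf(etas, Ls, p, theta_min, lb)
        else:
            new_theta, new_u = _master_norm(etas, Ls, p, spec, theta)
        theta_step = float(np.abs(new_theta - theta).max())
        if viol <= eps and theta_step <= theta_tol:
            # the master already saw the final dual point: θ is sharpened
            return new_theta, trace
        theta, u = new_theta, new_u
    raise SipConvergenceError(
        f"SIP did not converge in {max_iter} iterations "
        f"(last violation {trace[-1].violation:.3e})", trace)
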