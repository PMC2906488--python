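"""Dual-norm machinery shared by every MKL machine.

A dual-norm mode names the norm applied to the vector of per-kernel
quadratic terms η_j = f_j(dual variables) in the dual problem:

====  ====================  ===============================
mode  norm on η (dual)      conjugate constraint on θ (primal)
====  ====================  ===============================
inf   Chebyshev max_j η_j   Σθ_j = 1 (L1, sparse weights)
one   Σ_j η_j               uniform averaging θ_j = 1/p
two   ‖η‖₂                  ‖θ‖₂ = 1 (non-sparse weights)
n     ‖η‖_n                 ‖θ‖_m = 1 with 1/m + 1/n = 1
====  ====================  ===============================

Hölder's inequality gives Σθ_jη_j ≤ ‖θ‖_m ‖η‖_n with equality at
θ_j ∝ η_j^(n/m); that equality condition is the coefficient-recovery rule
used to read kernel weights off a solved dual point.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

#: entries of η below this are clamped to 0 (PSD round-off)
ETA_CLAMP = 1e-12


def conjugate_norm(m: float) -> float:
    """Conjugate exponent n with 1/m + 1/n = 1; maps ∞↦1 and 1↦∞."""
    if m == math.inf:
        return 1.0
    if m == 1:
        return math.inf
    if m <= 1:
        raise ValueError(f"norm exponent must be > 1 or exactly 1/inf, got {m}")
    return m / (m - 1.0)


@dataclass(frozen=True)
class NormSpec:
    """Dual-norm mode with its conjugate primal exponent.

    ``dual_mode`` is one of "inf", "one", "two", "n"; for mode "n" the dual
    exponent ``n`` (> 1) must be given and the primal θ constraint is
    ‖θ‖_m = 1 with m = n/(n-1).
    """

    dual_mode: str = "inf"
    n: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.dual_mode not in ("inf", "one", "two", "n"):
            raise ValueError(f"unknown dual norm mode {self.dual_mode!r}")
        if self.dual_mode == "n":
            if self.n is None or not self.n > 1:
                raise ValueError("mode 'n' requires a dual exponent n > 1")
        else:
            object.__setattr__(
                self, "n",
                {"inf": math.inf, "one": 1.0, "two": 2.0}[self.dual_mode],
            )

    @property
    def conjugate_primal_m(self) -> float:
        """Exponent of the primal norm constraint on θ."""
        return conjugate_norm(self.n)

    @classmethod
    def parse(cls, norm: str, n: float = None) -> "NormSpec":
        """Build from a CLI-style token: "inf", "one", "two", "n" or "3"."""
        if norm in ("inf", "one", "two"):
            return cls(norm)
        if norm == "n":
            return cls("n", n)
        return cls("n", float(norm))


def _clean_eta(eta) -> np.ndarray:
    eta = np.asarray(eta, dtype=float)
    if eta.ndim != 1 or eta.size < 1:
        raise ValueError("eta must be a 1-D vector")
    if np.any(eta < -1e-10):
        raise ValueError(f"eta has negative entries (min {eta.min():.3e})")
    eta = eta.copy()
    eta[eta < ETA_CLAMP] = 0.0
    return eta


def holder_bound(eta, spec: NormSpec) -> float:
    """‖η‖_n — the value of max Σθ_jη_j over the conjugate ball ‖θ‖_m = 1."""
    eta = _clean_eta(eta)
    if spec.dual_mode == "inf":
        return float(eta.max())
    if spec.dual_mode == "one":
        return float(eta.sum())
    if spec.dual_mode == "two":
        return float(np.linalg.norm(eta))
    return float(np.sum(eta ** spec.n) ** (1.0 / spec.n))


def recover_theta(eta, spec: NormSpec, theta_min: float = None) -> np.ndarray:
    """Kernel coefficients from the Hölder-equality condition at a dual point.

    mode "two": θ = η/‖η‖₂ (Cauchy–Schwarz equality); mode "n":
    θ_j ∝ η_j^(n/m) normalized to ‖θ‖_m = 1; mode "inf": all mass on the
    argmax of η, ties (within 1e-9 relative) split evenly — with θ_min
    regularization the remaining (1-θ_min) mass goes to the argmax on top of
    the θ_min/p floor; mode "one": uniform 1/p.
    """
    eta = _clean_eta(eta)
    p = eta.size
    if spec.dual_mode == "one":
        return np.full(p, 1.0 / p)
    if eta.max() == 0.0:
        warnings.warn("all-zero quadratic terms: degenerate dual point, uniform theta")
        if spec.dual_mode == "inf":
            return np.full(p, 1.0 / p)
        return np.full(p, p ** (-1.0 / spec.conjugate_primal_m))
    if spec.dual_mode == "inf":
        top = eta.max()
        ties = eta >= top * (1.0 - 1e-9)
        theta = np.zeros(p)
        theta[ties] = 1.0 / ties.sum()
        if theta_min:
            theta = theta_min / p + (1.0 - theta_min) * theta
        return theta
    if spec.dual_mode == "two":
        return eta / np.linalg.norm(eta)
    m = spec.conjugate_primal_m
    theta = eta ** (spec.n / m)
    return theta / np.sum(theta ** m) ** (1.0 / m)


def theta_norm_violation(theta, spec: NormSpec) -> float:
    """|constraint residual| of θ under its norm; 0 means feasible-exact."""
    theta = np.asarray(theta, dtype=float)
    if spec.dual_mode in ("inf", "one"):
        return abs(theta.sum() - 1.0)
    m = spec.conjugate_primal_m
    return abs(float(np.sum(theta ** m) ** (1.0 / m)) - 1.0)


def project_theta(theta, spec: NormSpec) -> np.ndarray:
    """Renormalize a nonnegative θ onto its norm constraint (absorbs solver slack)."""
    theta = np.maximum(np.asarray(theta, dtype=float), 0.0)
    s = theta.sum() if spec.dual_mode in ("inf", "one") else \
        float(np.sum(theta ** spec.conjugate_primal_m) ** (1.0 / spec.conjugate_primal_m))
    if s <= 0:
        raise ValueError("cannot project an all-zero theta")
    return theta / s
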