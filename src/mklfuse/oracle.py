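"""Brute-force min-max oracle over a grid of the kernel-weight feasible set.

Intended for small instances (p ≤ 3, N ≤ 50) as an independent check of the
conic and SIP solvers: enumerate θ on a grid of the feasible set, call the
machine's single-kernel inner solver on Σθ_jK_j, and take the grid optimum
of the outer objective.
"""

from __future__ import annotations

import warnings
from typing import Callable

import numpy as np

from .kernels import KernelSet, combine_kernels
from .norms import NormSpec


def theta_grid(p: int, spec: NormSpec, resolution: float = 0.01) -> np.ndarray:
    """Grid over the feasible θ set: the simplex for inf/one, the positive
    part of the ‖θ‖_m = 1 sphere (simplex grid renormalized) for two/n."""
    if p == 1:
        pts = np.ones((1, 1))
    elif p == 2:
        s = np.linspace(0.0, 1.0, int(round(1.0 / resolution)) + 1)
        pts = np.column_stack([s, 1.0 - s])
    elif p == 3:
        s = np.linspace(0.0, 1.0, int(round(1.0 / resolution)) + 1)
        a, b = np.meshgrid(s, s)
        keep = a + b <= 1.0 + 1e-12
        pts = np.column_stack([a[keep], b[keep], 1.0 - a[keep] - b[keep]])
    else:
        raise ValueError("grid oracle supports p <= 3 only")
    if spec.dual_mode in ("inf", "one"):
        return pts
    m = spec.conjugate_primal_m
    nz = pts[np.any(pts > 0, axis=1)]
    norms = np.sum(nz**m, axis=1) ** (1.0 / m)
    return nz / norms[:, None]


def brute_force_minmax(
    ks: KernelSet,
    inner_solver: Callable[[np.ndarray], float],
    spec: NormSpec,
    grid_resolution: float = 0.01,
    sense: str = "min",
) -> tuple[np.ndarray, float]:
    """Grid optimum of the outer objective G(θ) = inner_solver(Σθ_jK_j).

    ``sense`` is the outer optimization direction: "min" for SVM/LSSVM
    classification (θ minimizes the inner maximum) and "max" for the 1-SVM
    min-max, where by convex-concave duality the order of optimization can
    be exchanged and θ maximizes the inner minimum.
    """
    if grid_resolution > 0.05:
        warnings.warn(
            f"grid resolution {grid_resolution} is coarse; the grid optimum may "
            "be farther from the true optimum than the requested tolerance")
    pts = theta_grid(ks.p, spec, grid_resolution)
    best_val = np.inf if sense == "min" else -np.inf
    best_theta = pts[0]
    for theta in pts:
        val = inner_solver(combine_kernels(ks, theta).values)
        if (sense == "min" and val < best_val) or (sense == "max" and val > best_val):
            best_val, best_theta = val, theta
    return best_theta, float(best_val)
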