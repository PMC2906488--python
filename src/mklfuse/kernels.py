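"""Kernel construction, validation, normalization and combination.

Every learner in this package consumes a :class:`KernelSet` — an ordered
collection of positive semi-definite Gram matrices over the same samples,
one per heterogeneous data source. This module builds those matrices from
feature tables, sequences and clinical variable tables, repairs numerical
PSD violations, and forms the weighted combinations Ω = Σ_j θ_j K_j.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Sequence
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

#: relative tolerance on symmetry checks
SYM_TOL = 1e-8
#: relative tolerance on the most negative admissible eigenvalue
PSD_TOL = 1e-6


class KernelInputError(ValueError):
    """Malformed kernel-construction input (dimension mismatch, bad ids...)."""


def _as_ids(sample_ids, n: int) -> tuple[str, ...]:
    if sample_ids is None:
        return tuple(f"s{i}" for i in range(n))
    ids = tuple(str(s) for s in sample_ids)
    if len(ids) != n:
        raise KernelInputError(f"{len(ids)} sample ids for {n} samples")
    if len(set(ids)) != len(ids):
        raise KernelInputError("duplicate sample ids")
    return ids


@dataclass
class KernelMatrix:
    """A named, square, symmetric Gram matrix with sample identifiers."""

    values: np.ndarray
    sample_ids: tuple[str, ...] = None  # type: ignore[assignment]
    name: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise KernelInputError(f"kernel must be square, got {self.values.shape}")
        self.sample_ids = _as_ids(self.sample_ids, self.values.shape[0])
        scale = max(1.0, float(np.abs(self.values).max()))
        if np.abs(self.values - self.values.T).max() > SYM_TOL * scale:
            raise KernelInputError(f"kernel '{self.name}' is not symmetric")
        # exact symmetrization absorbs representable round-off
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def subset(self, ids: Sequence[str]) -> "KernelMatrix":
        """Square sub-kernel over ``ids`` (training slice)."""
        idx = self._index(ids)
        return KernelMatrix(self.values[np.ix_(idx, idx)], tuple(ids), self.name)

    def cross(self, test_ids: Sequence[str], train_ids: Sequence[str]) -> "CrossKernel":
        """Rectangular test-vs-train block sliced from this kernel."""
        return CrossKernel(
            self.values[np.ix_(self._index(test_ids), self._index(train_ids))],
            tuple(test_ids), tuple(train_ids), self.name,
        )

    def _index(self, ids: Sequence[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([pos[str(s)] for s in ids], dtype=int)
        except KeyError as e:
            raise KernelInputError(f"unknown sample id {e.args[0]!r}") from None


@dataclass
class CrossKernel:
    """Test-vs-train kernel block K(x_test, x_train) for one source."""

    values: np.ndarray
    test_ids: tuple[str, ...]
    train_ids: tuple[str, ...]
    name: str = ""

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))


@dataclass
class KernelSet:
    """Ordered list of kernels sharing identical samples; ``p`` sources."""

    kernels: list[KernelMatrix] = field(default_factory=list)

    def __post_init__(self):
        if not self.kernels:
            raise KernelInputError("KernelSet needs at least one kernel")
        ids = self.kernels[0].sample_ids
        for k in self.kernels[1:]:
            if k.sample_ids != ids:
                raise KernelInputError(
                    f"kernel '{k.name}' has different sample ids than '{self.kernels[0].name}'"
                )

    @property
    def p(self) -> int:
        return len(self.kernels)

    @property
    def n(self) -> int:
        return self.kernels[0].n

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return self.kernels[0].sample_ids

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(k.name for k in self.kernels)

    def matrices(self) -> list[np.ndarray]:
        return [k.values for k in self.kernels]

    def subset(self, ids: Sequence[str]) -> "KernelSet":
        return KernelSet([k.subset(ids) for k in self.kernels])

    def cross(self, test_ids, train_ids) -> list[CrossKernel]:
        return [k.cross(test_ids, train_ids) for k in self.kernels]

    def __iter__(self):
        return iter(self.kernels)

    def __len__(self):
        return len(self.kernels)


@dataclass
class ClinicalTable:
    """Per-patient clinical variables with declared kinds.

    ``kinds[v]`` is one of ``"continuous"``, ``"ordinal"``, ``"categorical"``.
    Continuous/ordinal columns must be numeric; missing values must have been
    imputed or dropped by the caller.
    """

    values: "object"            # pandas DataFrame, samples x variables
    kinds: dict[str, str]
    sample_ids: tuple[str, ...] = None  # type: ignore[assignment]

    def __post_init__(self):
        import pandas as pd

        self.values = pd.DataFrame(self.values)
        if self.values.isna().any().any():
            raise KernelInputError("clinical table contains missing values")
        for v in self.values.columns:
            if v not in self.kinds:
                raise KernelInputError(f"no kind declared for variable {v!r}")
            if self.kinds[v] not in ("continuous", "ordinal", "categorical"):
                raise KernelInputError(f"bad kind {self.kinds[v]!r} for {v!r}")
        self.sample_ids = _as_ids(
            self.sample_ids if self.sample_ids is not None else self.values.index,
            len(self.values),
        )


# ---------------------------------------------------------------------------
# constructors

def linear_kernel(X, sample_ids=None, name: str = "linear", Z=None):
    """Inner-product kernel of sample rows; PSD by construction.

    With ``Z`` given, returns the rectangular test-vs-train block
    K(z_i, x_j) = <z_i, x_j> instead.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if np.isnan(X).any():
        raise KernelInputError("feature matrix contains missing values")
    if Z is None:
        return KernelMatrix(X @ X.T, sample_ids, name)
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[1] != X.shape[1]:
        raise KernelInputError("train/test feature dimension mismatch")
    ids = _as_ids(sample_ids, X.shape[0])
    return CrossKernel(Z @ X.T, _as_ids(None, Z.shape[0]), ids, name)


def rbf_kernel(X, width_multiplier: float = 4.0, sample_ids=None,
               name: Optional[str] = None, Z=None):
    """Gaussian kernel exp(-||x_i - x_j||^2 / (2 sigma^2)).

    The width follows the covariance-based rule used for heterogeneous
    clinical sources: sigma^2 = ``width_multiplier`` times the average of the
    per-feature sample variances (trace of the covariance matrix divided by
    the number of features), which reduces to multiplier-times-variance for
    one-dimensional data. Multipliers of 4, 6 and 8 give a family of kernels
    of increasing smoothness. The width is always computed from ``X`` (the
    training samples), also when a cross block against ``Z`` is requested.
    """
    if width_multiplier <= 0:
        raise KernelInputError("width_multiplier must be positive")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    var = np.var(X, axis=0, ddof=1).mean() if X.shape[0] > 1 else 0.0
    sigma2 = width_multiplier * var
    if sigma2 <= 0:
        raise KernelInputError("zero-variance data: RBF width sigma^2 = 0")
    name = name if name is not None else f"rbf{width_multiplier:g}"
    other = X if Z is None else np.atleast_2d(np.asarray(Z, dtype=float))
    sq = (
        np.sum(other**2, axis=1)[:, None]
        + np.sum(X**2, axis=1)[None, :]
        - 2.0 * other @ X.T
    )
    K = np.exp(-np.maximum(sq, 0.0) / (2.0 * sigma2))
    if Z is None:
        return KernelMatrix(K, sample_ids, name)
    return CrossKernel(K, _as_ids(None, other.shape[0]), _as_ids(sample_ids, X.shape[0]), name)


def polynomial_kernel(X, degree: int = 2, bias: float = 1.0, sample_ids=None,
                      name: Optional[str] = None, Z=None):
    """Polynomial kernel (<x_i, x_j> + bias)^degree."""
    if degree < 1:
        raise KernelInputError("degree must be >= 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    name = name if name is not None else f"poly{degree}"
    other = X if Z is None else np.atleast_2d(np.asarray(Z, dtype=float))
    K = (other @ X.T + bias) ** degree
    if Z is None:
        return KernelMatrix(K, sample_ids, name)
    return CrossKernel(K, _as_ids(None, other.shape[0]), _as_ids(sample_ids, X.shape[0]), name)


def _kmer_counts(sequences: Sequence[str], k: int) -> tuple[np.ndarray, list[str]]:
    """Materialize the k-mer count matrix (samples x observed k-mers)."""
    vocab: dict[str, int] = {}
    rows: list[dict[int, int]] = []
    for s in sequences:
        s = str(s)
        if len(s) < k:
            raise KernelInputError(f"sequence of length {len(s)} shorter than k={k}")
        counts: dict[int, int] = {}
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            j = vocab.setdefault(kmer, len(vocab))
            counts[j] = counts.get(j, 0) + 1
        rows.append(counts)
    M = np.zeros((len(sequences), len(vocab)))
    for i, counts in enumerate(rows):
        for j, c in counts.items():
            M[i, j] = c
    return M, sorted(vocab, key=vocab.get)


def spectrum_kernel(sequences: Sequence[str], k: int = 2, sample_ids=None,
                    name: Optional[str] = None, test_sequences=None):
    """Spectrum (k-mer) string kernel: inner product of k-mer count vectors."""
    if k < 1:
        raise KernelInputError("k must be >= 1")
    name = name if name is not None else f"spectrum{k}"
    M, vocab = _kmer_counts(list(sequences), k)
    if test_sequences is None:
        return KernelMatrix(M @ M.T, sample_ids, name)
    # count test k-mers in the train+test joint vocabulary
    joint, _ = _kmer_counts(list(sequences) + list(test_sequences), k)
    Mtr, Mte = joint[: len(M)], joint[len(M):]
    return CrossKernel(Mte @ Mtr.T, _as_ids(None, len(Mte)),
                       _as_ids(sample_ids, len(M)), name)


def clinical_kernel(table: ClinicalTable, name: str = "clinical",
                    test_table: Optional[ClinicalTable] = None):
    """Heterogeneous-variable similarity kernel for clinical data.

    Per variable, similarity in [0, 1]: continuous and ordinal variables use
    1 - |a - b| / range (range observed on the training table), categorical
    variables use the exact-match indicator. The kernel entry is the average
    over variables. Constant variables (range 0) are excluded with a warning.
    """
    cols = list(table.values.columns)
    if test_table is not None:
        missing = [c for c in cols if c not in test_table.values.columns]
        if missing:
            raise KernelInputError(f"test table lacks variables {missing}")
    n = len(table.values)
    other = table if test_table is None else test_table
    m = len(other.values)
    acc = np.zeros((m, n))
    used = 0
    for v in cols:
        kind = table.kinds[v]
        a = other.values[v].to_numpy()
        b = table.values[v].to_numpy()
        if kind in ("continuous", "ordinal"):
            a = a.astype(float)
            b = b.astype(float)
            rng = float(b.max() - b.min())
            if rng == 0.0:
                warnings.warn(f"clinical variable {v!r} is constant; excluded")
                logger.warning("clinical variable %r has zero range; excluded", v)
                continue
            sim = 1.0 - np.abs(a[:, None] - b[None, :]) / rng
        else:
            sim = (a[:, None] == b[None, :]).astype(float)
        acc += sim
        used += 1
    if used == 0:
        raise KernelInputError("no usable clinical variables")
    K = acc / used
    if test_table is None:
        return KernelMatrix(K, table.sample_ids, name)
    return CrossKernel(K, other.sample_ids, table.sample_ids, name)


# ---------------------------------------------------------------------------
# transforms

def center_and_normalize(K: KernelMatrix, mode: str = "unit_diag") -> KernelMatrix:
    """Rescale a kernel so heterogeneous sources are comparable before fusion.

    mode "unit_diag": cosine normalization K_ij / sqrt(K_ii K_jj);
    mode "trace": scale so trace(K) = N; mode "none": identity transform.
    """
    if mode == "none":
        return K
    V = K.values
    if mode == "unit_diag":
        d = np.diag(V)
        if np.any(d <= 0):
            raise KernelInputError(
                f"kernel '{K.name}' has non-positive diagonal; cannot unit-diag normalize"
            )
        s = 1.0 / np.sqrt(d)
        return KernelMatrix(V * np.outer(s, s), K.sample_ids, K.name)
    if mode == "trace":
        tr = float(np.trace(V))
        if tr <= 0:
            raise KernelInputError(f"kernel '{K.name}' has non-positive trace")
        return KernelMatrix(V * (K.n / tr), K.sample_ids, K.name)
    raise KernelInputError(f"unknown normalization mode {mode!r}")


def validate_psd(K: KernelMatrix, repair: bool = False) -> KernelMatrix:
    """Check positive semi-definiteness; optionally project onto the PSD cone.

    Repair clips negative eigenvalues at zero (minimal Frobenius-norm PSD
    projection) rather than shifting the diagonal. Without repair, raises if
    the minimum eigenvalue is below -PSD_TOL times the largest eigenvalue.
    """
    w, U = np.linalg.eigh(K.values)
    wmax = max(float(w[-1]), 0.0)
    if repair:
        if w[0] >= 0:
            return K
        return KernelMatrix((U * np.maximum(w, 0.0)) @ U.T, K.sample_ids, K.name)
    if w[0] < -PSD_TOL * max(wmax, 1e-30):
        raise KernelInputError(
            f"kernel '{K.name}' is not PSD: min eigenvalue {w[0]:.3e} "
            f"(max {wmax:.3e}); pass repair=True to project"
        )
    return K


def combine_kernels(ks: KernelSet, theta) -> KernelMatrix:
    """Weighted combination Ω = Σ_j θ_j K_j with nonnegative coefficients."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (ks.p,):
        raise KernelInputError(f"theta has length {theta.size}, expected p={ks.p}")
    if np.any(theta < -1e-12):
        raise KernelInputError("theta must be nonnegative")
    Om = np.zeros_like(ks.kernels[0].values)
    for t, k in zip(theta, ks.kernels):
        Om += t * k.values
    return KernelMatrix(Om, ks.sample_ids, "combined")


def combine_cross(blocks: Sequence[CrossKernel], theta) -> np.ndarray:
    """Weighted combination of rectangular test-vs-train blocks."""
    theta = np.asarray(theta, dtype=float)
    if len(blocks) != theta.size:
        raise KernelInputError("theta length does not match number of cross blocks")
    out = np.zeros_like(blocks[0].values)
    for t, b in zip(theta, blocks):
        out += t * b.values
    return out
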