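"""Readers and writers for kernel matrices, feature tables, labels, FASTA
sequences and JSON run manifests.

All tabular formats are delimited text (TSV by default, comma accepted);
kernel files carry the sample identifiers as both the header row and the
first column, and the reader enforces symmetry and id agreement.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .kernels import KernelInputError, KernelMatrix


class ParseError(ValueError):
    """A file violated its expected layout."""


def _read_table(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    try:
        try:
            # round_trip parsing keeps every written double bit-identical
            return pd.read_csv(path, sep=sep, index_col=0,
                               float_precision="round_trip")
        except (pd.errors.ParserError, ValueError):
            return pd.read_csv(path, sep=r"\s+|,|\t", engine="python",
                               index_col=0)
    except pd.errors.ParserError as e:
        raise ParseError(f"{path}: {e}") from None


def read_kernel_file(path) -> KernelMatrix:
    """Delimited kernel matrix with id header row and id first column."""
    df = _read_table(path)
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if row_ids != col_ids:
        raise ParseError(f"{path}: row ids and column ids differ "
                         f"(first mismatch near {_first_mismatch(row_ids, col_ids)})")
    if len(set(row_ids)) != len(row_ids):
        dup = [i for i in row_ids if row_ids.count(i) > 1][0]
        raise ParseError(f"{path}: duplicate sample id {dup!r}")
    values = df.to_numpy(dtype=float)
    if np.abs(values - values.T).max() > 1e-6 * max(1.0, np.abs(values).max()):
        i, j = np.unravel_index(np.abs(values - values.T).argmax(), values.shape)
        raise ParseError(f"{path}: asymmetric beyond 1e-6 at cell "
                         f"({row_ids[i]}, {row_ids[j]})")
    try:
        return KernelMatrix(values, tuple(row_ids), Path(str(path)).stem)
    except KernelInputError as e:
        raise ParseError(f"{path}: {e}") from None


def _first_mismatch(a, b):
    for x, y in zip(a, b):
        if x != y:
            return f"{x!r} vs {y!r}"
    return "length"


def write_kernel_file(K: KernelMatrix, path) -> None:
    pd.DataFrame(K.values, index=K.sample_ids, columns=K.sample_ids) \
        .to_csv(path, sep="\t")  # default shortest-repr floats round-trip exactly


def read_feature_table(path) -> tuple[np.ndarray, tuple[str, ...], tuple[str, ...]]:
    """Samples-by-features table with header; returns (X, sample_ids, features)."""
    df = _read_table(path)
    return (df.to_numpy(dtype=float), tuple(str(i) for i in df.index),
            tuple(str(c) for c in df.columns))


@dataclass
class LabelSet:
    """Sample labels with the internal ±1 / 1..k coding and its mapping."""

    sample_ids: tuple[str, ...]
    y: np.ndarray
    mapping: dict
    weights: Optional[np.ndarray] = None

    @property
    def n_classes(self) -> int:
        return len(self.mapping)

    def aligned_to(self, ids) -> "LabelSet":
        """Reorder by id to match a kernel's sample order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            idx = np.array([pos[str(s)] for s in ids])
        except KeyError as e:
            raise ParseError(f"label file lacks sample id {e.args[0]!r}") from None
        return LabelSet(tuple(str(s) for s in ids), self.y[idx], self.mapping,
                        None if self.weights is None else self.weights[idx])


def read_labels(path) -> LabelSet:
    """Two-column id,label text (optional third column: sample weight).

    Binary labels are coerced to −1/+1 (sorted order: first class ↦ −1);
    multi-class labels map to 1..k. The mapping is recorded on the result.
    """
    df = pd.read_csv(path, sep=r"\s+|,|\t", engine="python", header=None,
                     comment="#")
    if df.shape[1] not in (2, 3):
        raise ParseError(f"{path}: expected 2 or 3 columns, got {df.shape[1]}")
    ids = tuple(str(v) for v in df.iloc[:, 0])
    raw = df.iloc[:, 1].astype(str).to_numpy()
    classes = sorted(set(raw))
    if len(classes) < 2:
        raise ParseError(f"{path}: need at least two classes")
    if len(classes) == 2:
        mapping = {classes[0]: -1, classes[1]: 1}
    else:
        mapping = {c: i + 1 for i, c in enumerate(classes)}
    y = np.array([mapping[v] for v in raw], dtype=float)
    weights = df.iloc[:, 2].to_numpy(dtype=float) if df.shape[1] == 3 else None
    return LabelSet(ids, y, mapping, weights)


def write_manifest(results: dict, config: dict, path) -> None:
    """JSON manifest with everything needed to re-run exactly: the resolved
    configuration, seeds, kernel weights and traces, and versions."""
    import mklfuse

    manifest = {
        "config": _jsonable(config),
        "results": _jsonable(results),
        "versions": {
            "mklfuse": mklfuse.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(vars(obj))
    return obj


def read_fasta(path) -> tuple[list[str], tuple[str, ...]]:
    """Sequences and their ids from a FASTA file."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records")
    return [str(r.seq) for r in records], tuple(r.id for r in records)
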