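"""Scalar quantization and plug-in information estimates.

Continuous wavelet features are discretized with a Lloyd-Max scalar
quantizer (the MSE-optimal codebook for a fixed number of levels) and all
entropy / mutual-information quantities are then plug-in estimates on the
empirical joint distribution of the integer codes, in bits.

The selection stage consumes exactly two summaries of a labeled feature
table:

* the relevance profile ``r_j = I(F_j; C)``, and
* the interdependency matrix ``D[i, j] = I(F_j; C | F_i) - I(F_j; C)``,

where ``C`` is the binary alarm label.  ``D[i, j] > 0`` means knowing
feature ``i`` *increases* what feature ``j`` tells us about the class —
the two features are interdependent (synergistic); ``D[i, j] < 0`` marks
redundancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Quantizer",
    "DiscretizedFeatureTable",
    "lloyd_quantize",
    "discretize_table",
    "entropy",
    "joint_entropy",
    "mutual_information",
    "conditional_mutual_information",
    "interdependency_matrix",
]

#: default number of quantization levels
DEFAULT_LEVELS = 5
LLOYD_TOL = 1e-6
LLOYD_MAX_ITER = 500
_LN2 = np.log(2.0)


@dataclass(frozen=True)
class Quantizer:
    """A scalar codebook: representative ``levels`` and the cell
    ``boundaries`` between adjacent levels (``len(boundaries) ==
    n_levels - 1``).  Values equal to a boundary encode to the lower
    cell (left-closed cells)."""

    levels: np.ndarray
    boundaries: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", np.asarray(self.levels, dtype=float))
        object.__setattr__(self, "boundaries", np.asarray(self.boundaries, dtype=float))
        if self.levels.size < 1:
            raise ValueError("quantizer needs at least one level")
        if np.any(np.diff(self.levels) <= 0):
            raise ValueError("levels must be strictly increasing")
        if self.boundaries.size != self.levels.size - 1:
            raise ValueError("need exactly n_levels - 1 boundaries")

    @property
    def n_levels(self) -> int:
        return int(self.levels.size)

    def encode(self, values) -> np.ndarray:
        """Map reals to integer codes in ``[0, n_levels)``."""
        v = np.asarray(values, dtype=float)
        return np.searchsorted(self.boundaries, v, side="left").astype(np.int64)

    def decode(self, codes) -> np.ndarray:
        return self.levels[np.asarray(codes, dtype=np.int64)]


def lloyd_quantize(
    values,
    n_levels: int = DEFAULT_LEVELS,
    tol: float = LLOYD_TOL,
    max_iter: int = LLOYD_MAX_ITER,
) -> Quantizer:
    """Fit an ``n_levels``-level Lloyd-Max quantizer to ``values``.

    Alternates the two optimality conditions — boundaries at midpoints of
    adjacent levels, levels at the centroid (mean) of their cell — until
    the relative MSE change drops below ``tol`` or ``max_iter`` is hit.
    The codebook is initialized at the (2k-1)/(2*n_levels) sample
    quantiles; a cell that goes empty is re-seeded at the midpoint of the
    currently most populated cell.  Fully deterministic.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("cannot quantize an empty sequence")
    if n_levels < 1:
        raise ValueError(f"n_levels must be >= 1, got {n_levels}")
    lo, hi = float(v.min()), float(v.max())
    if n_levels == 1 or lo == hi:
        # constant input collapses to a single effective level
        return Quantizer(levels=np.array([float(v.mean())]), boundaries=np.empty(0))

    q = (2 * np.arange(1, n_levels + 1) - 1) / (2 * n_levels)
    levels = np.quantile(v, q)
    # quantile init can produce coincident levels on discrete data
    levels = _strictify(levels, lo, hi)

    prev_mse = np.inf
    for _ in range(max_iter):
        bounds = 0.5 * (levels[:-1] + levels[1:])
        codes = np.searchsorted(bounds, v, side="left")
        counts = np.bincount(codes, minlength=n_levels)
        sums = np.bincount(codes, weights=v, minlength=n_levels)
        new = levels.copy()
        occupied = counts > 0
        new[occupied] = sums[occupied] / counts[occupied]
        if not occupied.all():
            big = int(np.argmax(counts))
            cell_lo = bounds[big - 1] if big > 0 else lo
            cell_hi = bounds[big] if big < n_levels - 1 else hi
            new[~occupied] = 0.5 * (cell_lo + cell_hi)
        levels = _strictify(np.sort(new), lo, hi)
        mse = float(np.mean((v - levels[np.searchsorted(
            0.5 * (levels[:-1] + levels[1:]), v, side="left")]) ** 2))
        if prev_mse - mse <= tol * max(prev_mse, np.finfo(float).tiny) and np.isfinite(prev_mse):
            break
        prev_mse = mse
    return Quantizer(levels=levels, boundaries=0.5 * (levels[:-1] + levels[1:]))


def _strictify(levels: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Nudge coincident sorted levels apart so cells stay well defined."""
    out = levels.copy()
    eps = max(hi - lo, 1.0) * 1e-12
    for k in range(1, out.size):
        if out[k] <= out[k - 1]:
            out[k] = out[k - 1] + eps
    return out


@dataclass
class DiscretizedFeatureTable:
    """Integer-coded feature table: same shape as the input table, codes in
    ``[0, n_levels)`` per feature cell, label column carried through
    unchanged, per-column codebooks retained."""

    codes: pd.DataFrame
    label: pd.Series
    quantizers: Mapping[str, Quantizer] = field(repr=False)

    @property
    def feature_names(self) -> list[str]:
        return list(self.codes.columns)

    def to_frame(self) -> pd.DataFrame:
        out = self.codes.copy()
        out["label"] = self.label
        return out


def discretize_table(
    table: pd.DataFrame,
    n_levels: int = DEFAULT_LEVELS,
    label_col: str = "label",
) -> DiscretizedFeatureTable:
    """Quantize each feature column independently with its own Lloyd
    codebook; the label column is passed through untouched."""
    if table.shape[0] == 0:
        raise ValueError("feature table is empty")
    if label_col not in table.columns:
        raise ValueError(f"table has no {label_col!r} column")
    feats = [c for c in table.columns if c != label_col]
    codes = {}
    quantizers = {}
    for col in feats:
        try:
            qz = lloyd_quantize(table[col].to_numpy(), n_levels=n_levels)
        except ValueError as exc:
            raise ValueError(f"column {col!r}: {exc}") from exc
        quantizers[col] = qz
        codes[col] = qz.encode(table[col].to_numpy())
    return DiscretizedFeatureTable(
        codes=pd.DataFrame(codes, index=table.index),
        label=table[label_col].astype(np.int64),
        quantizers=quantizers,
    )


# ---------------------------------------------------------------------------
# plug-in estimators (bits)
# ---------------------------------------------------------------------------

def _counts_entropy(counts: np.ndarray, n: int, correction: bool) -> float:
    # sorted so the float sum depends only on the count multiset, making
    # e.g. mutual_information(x, c) == mutual_information(c, x) exact
    p = np.sort(counts[counts > 0]) / n
    h = float(-(p * np.log2(p)).sum())
    if correction:  # Miller–Madow first-order bias correction
        h += (p.size - 1) / (2.0 * n * _LN2)
    return h


def entropy(codes, correction: bool = False) -> float:
    """Plug-in Shannon entropy of an integer code sequence, in bits."""
    x = np.asarray(codes, dtype=np.int64).ravel()
    if x.size == 0:
        raise ValueError("entropy of an empty sequence is undefined")
    _, counts = np.unique(x, return_counts=True)
    return _counts_entropy(counts, x.size, correction)


def joint_entropy(*code_arrays, correction: bool = False) -> float:
    """Plug-in entropy of the joint distribution of several code arrays."""
    arrs = [np.asarray(a, dtype=np.int64).ravel() for a in code_arrays]
    n = arrs[0].size
    if n == 0:
        raise ValueError("entropy of an empty sequence is undefined")
    if any(a.size != n for a in arrs):
        raise ValueError("all code sequences must have equal length")
    key = arrs[0].copy()
    for a in arrs[1:]:
        key = key * (a.max() + 1) + a
    _, counts = np.unique(key, return_counts=True)
    return _counts_entropy(counts, n, correction)


def mutual_information(x, c, correction: bool = False) -> float:
    """Plug-in ``I(X;C) = H(X) + H(C) - H(X,C)``, clipped to ``>= 0``."""
    x = np.asarray(x, dtype=np.int64).ravel()
    c = np.asarray(c, dtype=np.int64).ravel()
    if x.size != c.size:
        raise ValueError(f"length mismatch: {x.size} vs {c.size}")
    mi = entropy(x, correction) + entropy(c, correction) - joint_entropy(x, c, correction=correction)
    return max(mi, 0.0)


def conditional_mutual_information(x, c, z, correction: bool = False) -> float:
    """Plug-in ``I(X;C|Z) = H(X,Z) + H(C,Z) - H(X,C,Z) - H(Z)``, clipped
    to ``>= 0`` (the plug-in value is a true CMI of the empirical joint,
    so only float rounding can push it below zero)."""
    x = np.asarray(x, dtype=np.int64).ravel()
    c = np.asarray(c, dtype=np.int64).ravel()
    z = np.asarray(z, dtype=np.int64).ravel()
    if not (x.size == c.size == z.size):
        raise ValueError("length mismatch between x, c, z")
    cmi = (
        joint_entropy(x, z, correction=correction)
        + joint_entropy(c, z, correction=correction)
        - joint_entropy(x, c, z, correction=correction)
        - entropy(z, correction)
    )
    return max(cmi, 0.0)


def interdependency_matrix(
    dtable: DiscretizedFeatureTable, correction: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Relevance profile and pairwise interdependency matrix.

    Returns ``(r, D)`` with ``r[j] = I(F_j; C)`` and
    ``D[i, j] = I(F_j; C | F_i) - I(F_j; C)`` for ``i != j``; the diagonal
    is fixed at 0 and never read by the coalition game.  Joint entropies
    are shared across the symmetric pair ``(i, j)``, so the cost is one
    pass over the samples per unordered pair.
    """
    names = dtable.feature_names
    n = len(names)
    if n < 2:
        raise ValueError("need at least 2 features")
    cols = [dtable.codes[c].to_numpy(dtype=np.int64) for c in names]
    lab = dtable.label.to_numpy(dtype=np.int64)

    h_c = entropy(lab, correction)
    h_f = np.array([entropy(cols[i], correction) for i in range(n)])
    h_fc = np.array([joint_entropy(cols[i], lab, correction=correction) for i in range(n)])
    r = np.maximum(h_f + h_c - h_fc, 0.0)

    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            h_ij = joint_entropy(cols[i], cols[j], correction=correction)
            h_ijc = joint_entropy(cols[i], cols[j], lab, correction=correction)
            # I(Fj;C|Fi) = H(Fj,Fi) + H(C,Fi) - H(Fj,C,Fi) - H(Fi)
            cmi_j_given_i = max(h_ij + h_fc[i] - h_ijc - h_f[i], 0.0)
            cmi_i_given_j = max(h_ij + h_fc[j] - h_ijc - h_f[j], 0.0)
            D[i, j] = cmi_j_given_i - r[j]
            D[j, i] = cmi_i_given_j - r[i]
    return r, D
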