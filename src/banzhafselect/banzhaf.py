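"""Simple coalition game on features and the Banzhaf power index.

Features are the players.  For a focal feature ``i`` and a coalition
``S`` of other features, the induced characteristic function is boolean:
``i`` swings ``S`` when (a) the mean relevance change
``(1/|S|) * sum_{j in S} D[i, j]`` is nonnegative and (b) ``i`` is
interdependent with at least half of the members, i.e.
``#{j in S : D[i, j] > 0} >= |S| / 2``.  The Banzhaf power of feature
``i`` is the fraction of the ``2^(n-1)`` coalitions of the other
features that it swings; the empty coalition counts in the denominator
but is never a swinger, so ``beta_i <= 1 - 2^-(n-1)``.

Exact enumeration is exponential, so it is capped (default 22 players)
and a uniform Monte-Carlo estimator — each other feature joins the
coalition independently with probability 1/2, which samples coalitions
uniformly — covers the large-``n`` regime with a binomial standard
error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BanzhafScores",
    "relevance",
    "relevance_change",
    "interdependent_count",
    "is_swinger",
    "banzhaf_exact",
    "banzhaf_monte_carlo",
    "compute_banzhaf",
    "rank_features",
]

EXACT_LIMIT = 22
DEFAULT_MC_SAMPLES = 20_000
_MC_CHUNK = 65_536


def _as_index_array(S) -> np.ndarray:
    return np.fromiter((int(j) for j in S), dtype=np.int64)


def relevance(S, r) -> float:
    """Coalition relevance: the mean of ``r_j = I(F_j;C)`` over members."""
    idx = _as_index_array(S)
    if idx.size == 0:
        raise ValueError("relevance of the empty coalition is undefined")
    return float(np.mean(np.asarray(r, dtype=float)[idx]))


def _check_focal(i: int, idx: np.ndarray) -> None:
    if np.any(idx == i):
        raise ValueError(f"focal feature {i} cannot be a coalition member")


def relevance_change(i: int, S, D) -> float:
    """Mean change of the coalition's relevance to the class when feature
    ``i`` becomes known: ``(1/|S|) sum_{j in S} D[i, j]``."""
    idx = _as_index_array(S)
    if idx.size == 0:
        raise ValueError("relevance change over the empty coalition is undefined")
    _check_focal(i, idx)
    return float(np.mean(np.asarray(D, dtype=float)[i, idx]))


def interdependent_count(i: int, S, D) -> int:
    """Number of members of ``S`` interdependent with ``i``
    (``D[i, j] > 0``, strict)."""
    idx = _as_index_array(S)
    _check_focal(i, idx)
    if idx.size == 0:
        return 0
    return int(np.count_nonzero(np.asarray(D, dtype=float)[i, idx] > 0.0))


def is_swinger(i: int, S, D) -> bool:
    """Swinger test: nonempty ``S``, nonnegative mean relevance change,
    and interdependence with at least half the members (real-valued
    half: |S|=5 requires 3)."""
    idx = _as_index_array(S)
    _check_focal(i, idx)
    if idx.size == 0:
        return False
    d = np.asarray(D, dtype=float)[i, idx]
    return bool(d.mean() >= 0.0 and np.count_nonzero(d > 0.0) * 2 >= idx.size)


def banzhaf_exact(i: int, D, exact_limit: int = EXACT_LIMIT) -> float:
    """Banzhaf power of feature ``i`` by exhaustive enumeration of all
    ``2^(n-1)`` coalitions of the other features.

    Uses a subset-sum dynamic program over bitmasks: three arrays of
    length ``2^(n-1)`` accumulate, for every mask, the coalition size,
    the sum of ``D[i, j]`` over members, and the count of strictly
    positive entries.  Refuses ``n > exact_limit`` (use the Monte-Carlo
    estimator there).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n > exact_limit:
        raise ValueError(
            f"n={n} exceeds exact enumeration limit {exact_limit}; "
            "use banzhaf_monte_carlo"
        )
    others = np.array([j for j in range(n) if j != i], dtype=np.int64)
    m = others.size
    d = D[i, others]
    pos = (d > 0.0).astype(np.int32)

    total = 1 << m
    sumd = np.zeros(total)
    npos = np.zeros(total, dtype=np.int32)
    size = np.zeros(total, dtype=np.int32)
    for j in range(m):
        s = 1 << j
        sumd.reshape(-1, 2 * s)[:, s:] += d[j]
        npos.reshape(-1, 2 * s)[:, s:] += pos[j]
        size.reshape(-1, 2 * s)[:, s:] += 1
    swings = (size > 0) & (sumd >= 0.0) & (2 * npos >= size)
    return float(np.count_nonzero(swings) / total)


def banzhaf_monte_carlo(
    i: int, D, n_samples: int = DEFAULT_MC_SAMPLES, seed: int | np.random.SeedSequence = 0
) -> tuple[float, float]:
    """Monte-Carlo Banzhaf power: samples coalitions of the other
    features uniformly and returns ``(beta_hat, stderr)`` with the
    binomial standard error ``sqrt(beta*(1-beta)/n_samples)``.
    Deterministic given the seed."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    others = np.array([j for j in range(n) if j != i], dtype=np.int64)
    d = D[i, others]
    pos = (d > 0.0).astype(float)
    rng = np.random.default_rng(seed)

    hits = 0
    done = 0
    while done < n_samples:
        chunk = min(_MC_CHUNK, n_samples - done)
        masks = rng.random((chunk, others.size)) < 0.5
        sizes = masks.sum(axis=1)
        sums = masks @ d
        npos = masks @ pos
        hits += int(np.count_nonzero((sizes > 0) & (sums >= 0.0) & (2 * npos >= sizes)))
        done += chunk
    beta = hits / n_samples
    stderr = float(np.sqrt(beta * (1.0 - beta) / n_samples))
    return float(beta), stderr


@dataclass
class BanzhafScores:
    """Per-feature Banzhaf power estimates plus estimation metadata."""

    beta: np.ndarray
    method: str  # "exact" | "monte_carlo"
    n_samples: int | None = None
    stderr: np.ndarray | None = None
    seed: int | None = None

    def ranking(self) -> np.ndarray:
        """Feature indices sorted by descending beta; ties broken by
        ascending index (stable)."""
        return np.argsort(-self.beta, kind="stable")


def compute_banzhaf(
    D,
    method: str = "auto",
    exact_limit: int = EXACT_LIMIT,
    n_samples: int = DEFAULT_MC_SAMPLES,
    seed: int | None = None,
) -> BanzhafScores:
    """Banzhaf power for every feature: exact enumeration when the game
    is small enough (``n <= exact_limit``), otherwise Monte-Carlo with
    per-feature streams spawned from one shared seed."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if method not in ("auto", "exact", "monte_carlo"):
        raise ValueError(f"unknown method {method!r}")
    if method == "auto":
        method = "exact" if n <= exact_limit else "monte_carlo"
    if method == "exact":
        beta = np.array([banzhaf_exact(i, D, exact_limit=exact_limit) for i in range(n)])
        return BanzhafScores(beta=beta, method="exact")
    if seed is None:
        raise ValueError("monte_carlo method requires a seed")
    children = np.random.SeedSequence(seed).spawn(n)
    beta = np.empty(n)
    stderr = np.empty(n)
    for i in range(n):
        beta[i], stderr[i] = banzhaf_monte_carlo(i, D, n_samples=n_samples, seed=children[i])
    return BanzhafScores(beta=beta, method="monte_carlo", n_samples=n_samples, stderr=stderr, seed=seed)


def rank_features(
    D,
    k: int = 20,
    method: str = "auto",
    feature_names: Sequence[str] | None = None,
    exact_limit: int = EXACT_LIMIT,
    n_samples: int = DEFAULT_MC_SAMPLES,
    seed: int | None = None,
) -> pd.DataFrame:
    """Top-``k`` features by Banzhaf power.

    Returns a DataFrame with columns rank, feature, beta, stderr, method,
    n_samples, seed (stderr/n_samples/seed are NA on the exact path).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    names = list(feature_names) if feature_names is not None else [str(i) for i in range(n)]
    if len(names) != n:
        raise ValueError("feature_names length must match D")
    scores = compute_banzhaf(D, method=method, exact_limit=exact_limit, n_samples=n_samples, seed=seed)
    order = scores.ranking()[:k]
    return pd.DataFrame(
        {
            "rank": np.arange(1, k + 1),
            "feature": [names[i] for i in order],
            "beta": scores.beta[order],
            "stderr": scores.stderr[order] if scores.stderr is not None else np.nan,
            "method": scores.method,
            "n_samples": scores.n_samples if scores.n_samples is not None else pd.NA,
            "seed": scores.seed if scores.seed is not None else pd.NA,
        }
    )
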