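"""Per-gene discretization of expression profiles via exact 1-D k-means.

Each gene's profile across all samples is clustered on its own into at most
``k`` levels.  Because the optimal 1-D k-means partition is contiguous in
sorted order, the exact optimum is found by dynamic programming over
contiguous partitions — no random initialization, fully deterministic.
Levels are relabeled 0..k-1 in order of increasing cluster mean, so a higher
raw value never receives a lower level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from airnet.exceptions import DimensionError, ParameterError


@dataclass(frozen=True)
class DiscreteMatrix:
    """Integer activation levels per (gene, sample), each in [0, k-1]."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    levels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels, dtype=int)
        object.__setattr__(self, "levels", levels)
        if levels.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DimensionError("levels shape does not match identifiers")
        if self.k < 1:
            raise ParameterError(f"k must be >= 1, got {self.k}")
        if levels.size and (levels.min() < 0 or levels.max() > self.k - 1):
            raise ParameterError("levels outside [0, k-1]")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.levels, index=list(self.gene_ids), columns=list(self.sample_ids)
        )


def kmeans_1d(values: Sequence[float], k: int, seed: int = 0) -> list[int]:
    """Exact 1-D k-means labels for ``values``, levels ordered by cluster mean.

    Solves the sum-of-squared-error-minimizing partition of the sorted values
    into at most ``k`` contiguous groups by dynamic programming.  ``seed`` is
    accepted for interface stability but unused: the solver is exact.

    Equal values always receive equal labels; with fewer distinct values than
    ``k`` the number of occupied levels equals the number of distinct values.
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise DimensionError("values must be one-dimensional")
    n = x.size
    if n == 0:
        return []

    # Cluster distinct values so ties can never be split across levels.
    distinct, inverse, counts = np.unique(x, return_inverse=True, return_counts=True)
    m = distinct.size
    k_eff = min(k, m)

    # Prefix sums over distinct values weighted by multiplicity; cost(i, j) is
    # the within-cluster SSE of distinct[i..j] inclusive.
    w = counts.astype(float)
    sw = np.concatenate(([0.0], np.cumsum(w)))
    swx = np.concatenate(([0.0], np.cumsum(w * distinct)))
    swx2 = np.concatenate(([0.0], np.cumsum(w * distinct**2)))

    def cost(i: int, j: int) -> float:
        weight = sw[j + 1] - sw[i]
        s1 = swx[j + 1] - swx[i]
        s2 = swx2[j + 1] - swx2[i]
        return max(s2 - s1 * s1 / weight, 0.0)

    # dp[c][j]: minimal SSE using c+1 clusters over distinct[0..j].
    dp = np.full((k_eff, m), np.inf)
    back = np.zeros((k_eff, m), dtype=int)
    for j in range(m):
        dp[0][j] = cost(0, j)
    for c in range(1, k_eff):
        for j in range(c, m):
            best, best_i = np.inf, c
            for i in range(c, j + 1):  # cluster c covers distinct[i..j]
                cand = dp[c - 1][i - 1] + cost(i, j)
                if cand < best:
                    best, best_i = cand, i
            dp[c][j] = best
            back[c][j] = best_i

    # Recover boundaries; labels already ordered by mean since values sorted.
    labels_distinct = np.zeros(m, dtype=int)
    j = m - 1
    for c in range(k_eff - 1, 0, -1):
        i = back[c][j]
        labels_distinct[i : j + 1] = c
        j = i - 1
    return [int(v) for v in labels_distinct[inverse]]


def discretize_matrix(m, k: int, seed: int = 0) -> DiscreteMatrix:
    """Discretize every gene of an ExpressionMatrix independently.

    Row-wise application of :func:`kmeans_1d`: the data for a single gene
    across all samples forms one clustering problem.
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    levels = np.empty(m.values.shape, dtype=int)
    for i in range(m.n_genes):
        levels[i] = kmeans_1d(m.values[i], k, seed)
    return DiscreteMatrix(m.gene_ids, m.sample_ids, levels, k)
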