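"""Change-correlation voting over all pairs of samples.

For every unordered gene pair (x, y) and every pair of samples (a, b), the
level changes dx = x[b] - x[a] and dy = y[b] - y[a] cast one vote:

* equal, non-zero changes (dx == dy != 0)            -> positive vote
* equal-magnitude, opposing changes (dx == -dy != 0) -> negative vote
* both changes zero (dx == dy == 0)                  -> zero-change vote
  (counts as positive evidence by default: neither gene moved)
* anything else                                      -> mixed, no vote

The influence value v = (p + q - n) / total lies in [-1, 1]; its sign
conveys promotion vs inhibition and |v| the strength of evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from airnet.exceptions import DimensionError, ParameterError, UndefinedValueError

PairMode = Literal["unordered", "ordered"]
MatchMode = Literal["strict", "sign"]


@dataclass(frozen=True)
class PairTally:
    """Vote counts for one gene pair over all compared sample pairs."""

    p_same: int
    n_opposed: int
    q_zero: int
    u_mixed: int

    @property
    def total(self) -> int:
        return self.p_same + self.n_opposed + self.q_zero + self.u_mixed

    def __post_init__(self) -> None:
        for name in ("p_same", "n_opposed", "q_zero", "u_mixed"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


@dataclass(frozen=True)
class InfluenceMatrix:
    """Symmetric signed influence values v for all unordered gene pairs."""

    gene_ids: tuple[str, ...]
    v: np.ndarray  # (n_genes, n_genes), symmetric, zero diagonal
    tallies: dict[frozenset[str], PairTally]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def value(self, gene_a: str, gene_b: str) -> float:
        i = self.gene_ids.index(gene_a)
        j = self.gene_ids.index(gene_b)
        return float(self.v[i, j])

    def pairs(self) -> list[tuple[tuple[str, str], float]]:
        """All unordered gene pairs with their v, lexicographic endpoints."""
        order = sorted(range(self.n_genes), key=lambda i: self.gene_ids[i])
        out = []
        for a in range(len(order)):
            for b in range(a + 1, len(order)):
                i, j = order[a], order[b]
                out.append(
                    ((self.gene_ids[i], self.gene_ids[j]), float(self.v[i, j]))
                )
        return out


def enumerate_sample_pairs(
    n_samples: int, mode: PairMode = "unordered"
) -> list[tuple[int, int]]:
    """Index pairs of samples to compare: C(n,2) unordered or n(n-1) ordered."""
    if n_samples < 1:
        raise ParameterError(f"n_samples must be >= 1, got {n_samples}")
    if mode == "unordered":
        return [(i, j) for i in range(n_samples) for j in range(i + 1, n_samples)]
    if mode == "ordered":
        return [
            (i, j) for i in range(n_samples) for j in range(n_samples) if i != j
        ]
    raise ValueError(f"unknown pair mode {mode!r}")


def tally_pair(
    levels_x: Sequence[int],
    levels_y: Sequence[int],
    pairs: Sequence[tuple[int, int]],
    match: MatchMode = "strict",
) -> PairTally:
    """Classify every sample pair for one gene pair into the four vote bins."""
    x = np.asarray(levels_x, dtype=int)
    y = np.asarray(levels_y, dtype=int)
    if x.shape != y.shape:
        raise DimensionError(
            f"level vectors differ in length: {x.size} vs {y.size}"
        )
    idx = np.asarray(pairs, dtype=int).reshape(-1, 2)
    dx = x[idx[:, 1]] - x[idx[:, 0]]
    dy = y[idx[:, 1]] - y[idx[:, 0]]
    if match == "sign":
        dx, dy = np.sign(dx), np.sign(dy)
    elif match != "strict":
        raise ValueError(f"unknown match mode {match!r}")
    q = int(np.count_nonzero((dx == 0) & (dy == 0)))
    p = int(np.count_nonzero((dx == dy) & (dx != 0)))
    n = int(np.count_nonzero((dx == -dy) & (dx != 0)))
    u = idx.shape[0] - p - n - q
    return PairTally(p_same=p, n_opposed=n, q_zero=q, u_mixed=u)


def influence_value(t: PairTally, include_zero_votes: bool = True) -> float:
    """Signed correlation-of-changes value in [-1, 1] from a vote tally."""
    if t.total == 0:
        raise UndefinedValueError("no sample pairs compared")
    numer = t.p_same - t.n_opposed
    if include_zero_votes:
        numer += t.q_zero
    return numer / t.total


def _delta_indicators(levels: np.ndarray, idx: np.ndarray, match: MatchMode):
    """Per-gene change matrices over sample pairs, split by change value."""
    deltas = levels[:, idx[:, 1]] - levels[:, idx[:, 0]]
    if match == "sign":
        deltas = np.sign(deltas)
    values = np.unique(deltas)
    return deltas, values


def influence_matrix(
    d,
    mode: PairMode = "unordered",
    include_zero_votes: bool = True,
    match: MatchMode = "strict",
    keep_tallies: bool = True,
) -> InfluenceMatrix:
    """Influence values for every unordered gene pair of a DiscreteMatrix.

    The tally is computed for all gene pairs at once via indicator-matrix
    products (one (genes x sample-pairs) boolean matrix per distinct change
    value), so large gene counts stay tractable.  ``keep_tallies=False``
    skips materializing the per-pair PairTally dict.
    """
    if d.n_samples < 2:
        raise DimensionError("at least 2 samples required")
    if match not in ("strict", "sign"):
        raise ValueError(f"unknown match mode {match!r}")
    levels = np.asarray(d.levels, dtype=int)
    idx = np.asarray(enumerate_sample_pairs(d.n_samples, mode), dtype=int)
    deltas, delta_values = _delta_indicators(levels, idx, match)
    n_pairs = idx.shape[0]
    g = d.n_genes

    p = np.zeros((g, g))
    n = np.zeros((g, g))
    for dv in delta_values:
        ind = (deltas == dv).astype(float)
        if dv == 0:
            q = ind @ ind.T
            continue
        p += ind @ ind.T
        opp = (deltas == -dv).astype(float)
        n += ind @ opp.T
    if 0 not in delta_values:
        q = np.zeros((g, g))

    numer = p - n + (q if include_zero_votes else 0.0)
    v = numer / n_pairs
    np.fill_diagonal(v, 0.0)

    tallies: dict[frozenset[str], PairTally] = {}
    if keep_tallies:
        for i in range(g):
            for j in range(i + 1, g):
                tallies[frozenset((d.gene_ids[i], d.gene_ids[j]))] = PairTally(
                    p_same=int(round(p[i, j])),
                    n_opposed=int(round(n[i, j])),
                    q_zero=int(round(q[i, j])),
                    u_mixed=n_pairs
                    - int(round(p[i, j] + n[i, j] + q[i, j])),
                )
    return InfluenceMatrix(gene_ids=tuple(d.gene_ids), v=v, tallies=tallies)
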