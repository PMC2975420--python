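"""Graph construction and thresholded-Kruskal pruning.

Every candidate gene pair gets weight w = 1 - |v|, so the minimum-cost
spanning forest keeps the most strongly correlated pairs.  Candidates are
processed in decreasing |v| (equivalently increasing w) and processing stops
at the first candidate with |v| below the threshold.  In ``forest`` mode a
disjoint-set union additionally rejects edges that would close a cycle; in
``threshold`` mode every candidate at or above the cutoff is kept.  Retained
edges carry their signed v, not w.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from airnet.exceptions import ParameterError

PruneMode = Literal["forest", "threshold"]


@dataclass(frozen=True)
class RegulatoryNetwork:
    """Undirected signed weighted graph over gene nodes."""

    nodes: frozenset[str]
    edges: dict[frozenset[str], float]
    threshold: float
    mode: PruneMode

    def __post_init__(self) -> None:
        for pair in self.edges:
            if len(pair) != 2:
                raise ParameterError(f"self-edge or malformed pair: {set(pair)}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_pairs(self) -> list[tuple[tuple[str, str], float]]:
        """Edges as ((a, b), v) with sorted endpoints, lexicographic order."""
        return sorted(
            ((tuple(sorted(pair)), v) for pair, v in self.edges.items()),
            key=lambda item: item[0],
        )


def edge_weights(im) -> list[tuple[tuple[str, str], float, float]]:
    """(pair, v, w) for every candidate gene pair, with w = 1 - |v|."""
    return [(pair, v, 1.0 - abs(v)) for pair, v in im.pairs()]


class _DisjointSet:
    def __init__(self, items: Iterable[str]) -> None:
        self._parent = {item: item for item in items}

    def find(self, item: str) -> str:
        root = item
        while self._parent[root] != root:
            root = self._parent[root]
        while self._parent[item] != root:  # path compression
            self._parent[item], item = root, self._parent[item]
        return root

    def union(self, a: str, b: str) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self._parent[rb] = ra
        return True


def kruskal_threshold(
    candidates: Sequence[tuple[tuple[str, str], float]],
    threshold: float,
    mode: PruneMode = "forest",
    nodes: Iterable[str] | None = None,
) -> RegulatoryNetwork:
    """Prune candidate edges by decreasing |v|, stopping below ``threshold``.

    ``candidates`` is a sequence of ((gene_a, gene_b), v).  Ties in |v| are
    broken by lexicographic endpoint order for deterministic output.  Pass
    ``nodes`` to include isolated genes in the result.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ParameterError(f"threshold must be in [0, 1], got {threshold}")
    if mode not in ("forest", "threshold"):
        raise ValueError(f"unknown prune mode {mode!r}")

    node_set = set(nodes) if nodes is not None else set()
    for (a, b), _ in candidates:
        node_set.update((a, b))

    ordered = sorted(
        candidates, key=lambda item: (-abs(item[1]), tuple(sorted(item[0])))
    )
    dsu = _DisjointSet(node_set)
    edges: dict[frozenset[str], float] = {}
    for (a, b), v in ordered:
        if abs(v) < threshold:
            break
        if mode == "forest":
            if dsu.union(a, b):
                edges[frozenset((a, b))] = v
        else:
            edges[frozenset((a, b))] = v
    return RegulatoryNetwork(
        nodes=frozenset(node_set), edges=edges, threshold=threshold, mode=mode
    )


def infer_network(
    expression,
    k: int = 2,
    threshold: float = 0.8,
    mode: PruneMode = "forest",
    pair_mode: str = "unordered",
    include_zero_votes: bool = True,
    match: str = "strict",
    seed: int = 0,
) -> RegulatoryNetwork:
    """Full pipeline: discretize -> influence -> weighted graph -> pruning."""
    from airnet.discretize import discretize_matrix
    from airnet.influence import influence_matrix

    disc = discretize_matrix(expression, k=k, seed=seed)
    im = influence_matrix(
        disc,
        mode=pair_mode,
        include_zero_votes=include_zero_votes,
        match=match,
        keep_tallies=False,
    )
    candidates = [(pair, v) for pair, v in im.pairs()]
    return kruskal_threshold(
        candidates, threshold=threshold, mode=mode, nodes=expression.gene_ids
    )
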