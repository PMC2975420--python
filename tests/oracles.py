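"""Independent brute-force oracles used to validate the package.

Each oracle re-derives its quantity by exhaustive enumeration or explicit
looping, sharing no code with the implementation it checks.
"""

from __future__ import annotations

from itertools import combinations


def kmeans_1d_sse(values: list[float], k: int) -> float:
    """Minimal within-cluster SSE over all <=k contiguous partitions.

    Enumerates every placement of cluster boundaries between *distinct*
    sorted values (equal values may not be split) and returns the best SSE.
    """
    distinct = sorted(set(values))
    m = len(distinct)
    k_eff = min(k, m)
    groups = {v: [x for x in values if x == v] for v in distinct}

    def sse(cluster_values: list[float]) -> float:
        mean = sum(cluster_values) / len(cluster_values)
        return sum((x - mean) ** 2 for x in cluster_values)

    best = float("inf")
    for n_clusters in range(1, k_eff + 1):
        for cuts in combinations(range(1, m), n_clusters - 1):
            bounds = (0, *cuts, m)
            total = 0.0
            for lo, hi in zip(bounds, bounds[1:]):
                members = [x for v in distinct[lo:hi] for x in groups[v]]
                total += sse(members)
            best = min(best, total)
    return best


def labels_sse(values: list[float], labels: list[int]) -> float:
    """Within-cluster SSE of a given labeling."""
    total = 0.0
    for level in set(labels):
        members = [v for v, lab in zip(values, labels) if lab == level]
        mean = sum(members) / len(members)
        total += sum((x - mean) ** 2 for x in members)
    return total


def tally_votes(
    levels_x: list[int], levels_y: list[int], pairs: list[tuple[int, int]]
) -> tuple[int, int, int, int]:
    """(p_same, n_opposed, q_zero, u_mixed) by explicit per-pair loop."""
    p = n = q = u = 0
    for a, b in pairs:
        dx = levels_x[b] - levels_x[a]
        dy = levels_y[b] - levels_y[a]
        if dx == 0 and dy == 0:
            q += 1
        elif dx == dy:
            p += 1
        elif dx == -dy:
            n += 1
        else:
            u += 1
    return p, n, q, u


def brute_force_mst_weight(
    nodes: list[str], edges: list[tuple[tuple[str, str], float]]
) -> float:
    """Total weight (w = 1 - |v|) of the minimum spanning tree.

    Tries every subset of |nodes| - 1 edges and keeps the cheapest one that
    connects all nodes.  Exponential; only for tiny graphs.
    """
    n = len(nodes)
    best = float("inf")
    for subset in combinations(edges, n - 1):
        parent = {node: node for node in nodes}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        acyclic = True
        for (a, b), _ in subset:
            ra, rb = find(a), find(b)
            if ra == rb:
                acyclic = False
                break
            parent[ra] = rb
        if acyclic and len({find(node) for node in nodes}) == 1:
            best = min(best, sum(1.0 - abs(v) for _, v in subset))
    return best


def sweep_auroc(labels: list[int]) -> float:
    """AUROC by explicit confusion-matrix sweep over every cut point.

    ``labels`` is the binary relevance of each item in rank order (best
    first); the ranking is assumed strict (no ties).
    """
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    points = [(0.0, 0.0)]
    tp = fp = 0
    for lab in labels:
        if lab:
            tp += 1
        else:
            fp += 1
        points.append((fp / n_neg, tp / n_pos))
    area = 0.0
    for (x0, y0), (x1, y1) in zip(points, points[1:]):
        area += (x1 - x0) * (y0 + y1) / 2
    return area


def sweep_aupr(labels: list[int]) -> float:
    """Average precision: mean of precision at each positive's rank."""
    n_pos = sum(labels)
    tp = 0
    total = 0.0
    for rank, lab in enumerate(labels, start=1):
        if lab:
            tp += 1
            total += tp / rank
    return total / n_pos
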