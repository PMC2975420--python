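"""Differential comparison of two inferred networks (e.g. case vs control).

Edges are keyed by unordered endpoint pair; shared edges are annotated with
the absolute difference of their signed strengths, exclusive edges are
partitioned by source network.  Edges whose sign flips between conditions
are flagged, since presence/absence and sign shifts drive hypothesis
generation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class NetworkDiff:
    """Shared/exclusive edge partition of two networks."""

    shared: dict[frozenset[str], tuple[float, float]]  # pair -> (v_a, v_b)
    only_a: dict[frozenset[str], float]
    only_b: dict[frozenset[str], float]
    labels: tuple[str, str]

    def delta(self, pair: frozenset[str]) -> float:
        v_a, v_b = self.shared[pair]
        return abs(v_a - v_b)

    def sign_flips(self) -> list[frozenset[str]]:
        """Shared edges whose promote/inhibit sign differs between conditions."""
        return [
            pair
            for pair, (v_a, v_b) in self.shared.items()
            if (v_a < 0) != (v_b < 0)
        ]


def diff_networks(a, b, labels: tuple[str, str] = ("A", "B")) -> NetworkDiff:
    """Partition the edges of two networks into shared and exclusive sets."""
    shared: dict[frozenset[str], tuple[float, float]] = {}
    only_a: dict[frozenset[str], float] = {}
    only_b: dict[frozenset[str], float] = {}
    for pair, v in a.edges.items():
        if pair in b.edges:
            shared[pair] = (v, b.edges[pair])
        else:
            only_a[pair] = v
    for pair, v in b.edges.items():
        if pair not in a.edges:
            only_b[pair] = v
    return NetworkDiff(shared=shared, only_a=only_a, only_b=only_b, labels=labels)


def write_diff(diff: NetworkDiff, path: str | Path) -> None:
    """TSV report: one row per edge with status, strengths, delta, sign flag."""
    label_a, label_b = diff.labels
    lines = [
        f"geneA\tgeneB\tstatus\tv_{label_a}\tv_{label_b}\tdelta\tsign_flip"
    ]
    for pair, (v_a, v_b) in sorted(diff.shared.items(), key=lambda kv: sorted(kv[0])):
        a, b = sorted(pair)
        flip = "yes" if (v_a < 0) != (v_b < 0) else "no"
        lines.append(
            f"{a}\t{b}\tshared\t{v_a!r}\t{v_b!r}\t{abs(v_a - v_b)!r}\t{flip}"
        )
    for status, edges in ((f"only_{label_a}", diff.only_a), (f"only_{label_b}", diff.only_b)):
        for pair, v in sorted(edges.items(), key=lambda kv: sorted(kv[0])):
            a, b = sorted(pair)
            col_a = repr(v) if status == f"only_{label_a}" else ""
            col_b = repr(v) if status == f"only_{label_b}" else ""
            lines.append(f"{a}\t{b}\t{status}\t{col_a}\t{col_b}\t\t")
    Path(path).write_text("\n".join(lines) + "\n")


def write_diff_dot(diff: NetworkDiff, path: str | Path) -> None:
    """DOT rendering: exclusive-to-A red, exclusive-to-B green, shared black."""
    lines = ["graph diff {"]
    nodes = set()
    for group in (diff.shared, diff.only_a, diff.only_b):
        for pair in group:
            nodes.update(pair)
    for node in sorted(nodes):
        lines.append(f'  "{node}";')
    for pair, (v_a, v_b) in sorted(diff.shared.items(), key=lambda kv: sorted(kv[0])):
        a, b = sorted(pair)
        lines.append(
            f'  "{a}" -- "{b}" [label="{abs(v_a - v_b):.3f}", color=black];'
        )
    for edges, color in ((diff.only_a, "red"), (diff.only_b, "green")):
        for pair in sorted(edges, key=sorted):
            a, b = sorted(pair)
            lines.append(f'  "{a}" -- "{b}" [color={color}];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
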