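"""Readers and writers for expression matrices, gold standards and networks.

Expression matrices are tab- or comma-delimited text with a header row of
sample identifiers and a first column of gene identifiers (``genes-in-rows``
orientation; DREAM-style files with genes in columns are supported through
the ``orientation`` flag).  Gold standards use the DREAM three-column layout
``geneA geneB {0|1}``.  Networks are written as edge-list TSV (lossless
round trip), SIF, or DOT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from airnet.exceptions import (
    DimensionError,
    FormatError,
    ReferenceError_,
)
from airnet.netbuild import RegulatoryNetwork

Orientation = Literal["genes-in-rows", "genes-in-columns"]
NetworkFormat = Literal["tsv", "sif", "dot"]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Real-valued genes x samples matrix with identifiers.

    Invariants: identifiers unique, every cell finite, at least one gene
    and two samples.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample identifiers")
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DimensionError(
                f"values shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.gene_ids) < 1:
            raise DimensionError("at least one gene required")
        if len(self.sample_ids) < 2:
            raise DimensionError("at least two samples required")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                f"non-finite value for gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
        )


@dataclass(frozen=True)
class GoldStandard:
    """Undirected reference edge set over a declared gene universe.

    ``signs`` optionally carries +1/-1 per edge (used by the simulator's
    ground truth); evaluation ignores it.
    """

    edges: frozenset[frozenset[str]]
    universe: frozenset[str]
    signs: dict[frozenset[str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for edge in self.edges:
            if len(edge) != 2:
                raise FormatError(f"self-pair or malformed edge: {set(edge)}")
            missing = edge - self.universe
            if missing:
                raise ReferenceError_(
                    f"edge endpoint(s) {sorted(missing)} not in universe"
                )

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def candidate_pairs(self) -> list[tuple[str, str]]:
        """All unordered gene pairs of the universe, lexicographic order."""
        genes = sorted(self.universe)
        return [
            (genes[i], genes[j])
            for i in range(len(genes))
            for j in range(i + 1, len(genes))
        ]


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def read_expression(
    path: str | Path, orientation: Orientation = "genes-in-rows"
) -> ExpressionMatrix:
    """Read a delimited expression table, normalizing to genes x samples.

    The first row holds identifiers for the columns, the first column for
    the rows; ``orientation`` declares which axis carries the genes.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty file")
    sep = _sniff_delimiter(text.splitlines()[0])
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas-specific parse errors
        raise FormatError(f"{path}: {exc}") from exc
    if orientation == "genes-in-columns":
        frame = frame.T
    elif orientation != "genes-in-rows":
        raise ValueError(f"unknown orientation {orientation!r}")

    gene_ids = tuple(str(g) for g in frame.index)
    sample_ids = tuple(str(s) for s in frame.columns)
    if len(set(gene_ids)) != len(gene_ids):
        dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise FormatError(f"{path}: duplicate gene identifier(s) {dupes}")
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise FormatError(f"{path}: duplicate sample identifier(s) {dupes}")

    values = np.empty(frame.shape, dtype=float)
    for i, gene in enumerate(gene_ids):
        for j, sample in enumerate(sample_ids):
            cell = frame.iat[i, j]
            if cell is None or (isinstance(cell, float) and math.isnan(cell)):
                raise FormatError(
                    f"{path}: missing value at gene {gene!r}, sample {sample!r}"
                )
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError) as exc:
                raise FormatError(
                    f"{path}: non-numeric value {cell!r} at gene {gene!r}, "
                    f"sample {sample!r}"
                ) from exc
    if values.shape[1] < 2:
        raise DimensionError(f"{path}: fewer than 2 samples")
    return ExpressionMatrix(gene_ids, sample_ids, values)


def write_expression(matrix, path: str | Path) -> None:
    """Write an expression-like matrix (also used for discretized output)."""
    frame = matrix.to_frame()
    frame.index.name = "gene"
    frame.to_csv(path, sep="\t")


def read_gold_standard(
    path: str | Path, universe: Iterable[str]
) -> GoldStandard:
    """Read a DREAM three-column edge list into an undirected gold standard.

    Lines are ``geneA geneB indicator`` with indicator 0/1; reciprocal
    directed duplicates collapse onto one undirected edge, absent pairs
    count as 0.
    """
    path = Path(path)
    universe_set = frozenset(universe)
    edges: set[frozenset[str]] = set()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
        a, b, flag = fields
        if flag not in ("0", "1"):
            raise FormatError(f"{path}:{lineno}: indicator must be 0 or 1, got {flag!r}")
        if a == b:
            raise FormatError(f"{path}:{lineno}: self-pair {a!r}")
        for g in (a, b):
            if g not in universe_set:
                raise ReferenceError_(f"{path}:{lineno}: gene {g!r} not in universe")
        if flag == "1":
            edges.add(frozenset((a, b)))
    return GoldStandard(frozenset(edges), universe_set)


def write_gold_standard(gold: GoldStandard, path: str | Path) -> None:
    """Write positive edges of a gold standard in DREAM three-column form."""
    lines = []
    for edge in sorted(gold.edges, key=sorted):
        a, b = sorted(edge)
        lines.append(f"{a}\t{b}\t1")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


_TSV_HEADER = "geneA\tgeneB\tv\tsign"


def _sign_label(v: float) -> str:
    return "inhibit" if v < 0 else "promote"


def write_network(
    network: RegulatoryNetwork, path: str | Path, format: NetworkFormat = "tsv"
) -> None:
    """Serialize a network as edge-list TSV (lossless), SIF, or DOT."""
    path = Path(path)
    edges = sorted(network.edges.items(), key=lambda kv: sorted(kv[0]))
    if format == "tsv":
        lines = [_TSV_HEADER]
        for pair, v in edges:
            a, b = sorted(pair)
            lines.append(f"{a}\t{b}\t{v!r}\t{_sign_label(v)}")
        path.write_text("\n".join(lines) + "\n")
    elif format == "sif":
        lines = []
        for pair, v in edges:
            a, b = sorted(pair)
            lines.append(f"{a}\t{_sign_label(v)}\t{b}")
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif format == "dot":
        lines = ["graph network {"]
        for node in sorted(network.nodes):
            lines.append(f'  "{node}";')
        for pair, v in edges:
            a, b = sorted(pair)
            style = "dashed" if v < 0 else "solid"
            lines.append(f'  "{a}" -- "{b}" [label="{v:.3f}", style={style}];')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path) -> RegulatoryNetwork:
    """Read an edge-list TSV written by :func:`write_network`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].split("\t")[:2] != ["geneA", "geneB"]:
        raise FormatError(f"{path}: missing edge-list header")
    nodes: set[str] = set()
    edges: dict[frozenset[str], float] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: expected >= 3 columns")
        a, b, v = fields[0], fields[1], float(fields[2])
        nodes.update((a, b))
        edges[frozenset((a, b))] = v
    return RegulatoryNetwork(
        nodes=frozenset(nodes), edges=edges, threshold=0.0, mode="threshold"
    )
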