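"""Synthetic ground-truth networks and perturbation expression data.

A simple one-hop additive propagation model: each gene draws a baseline,
each perturbation sample forces one gene to zero (null-mutant) or half
(knockdown) and shifts its direct neighbors by +/- coupling * baseline
according to edge sign, plus Gaussian noise.  This creates exactly the
change-correlation signal the inference pipeline is designed to detect,
without an ODE kinetics simulator.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Literal

import numpy as np

from airnet.exceptions import ParameterError
from airnet.io import ExpressionMatrix, GoldStandard

Design = Literal["null-mutant", "knockdown", "replicates"]


@dataclass(frozen=True)
class SyntheticStudy:
    """Ground truth + generated expression + per-sample design labels."""

    truth: GoldStandard
    expression: ExpressionMatrix
    design: tuple[str, ...]
    coupling: float
    noise_sd: float
    seed: int


def random_truth_network(
    n_genes: int, n_edges: int, sign_fraction: float = 0.0, seed: int = 0
) -> GoldStandard:
    """Uniformly sampled signed undirected network on genes G1..Gn.

    Each edge is negative (inhibiting) with probability ``sign_fraction``.
    """
    max_edges = comb(n_genes, 2)
    if not 0 <= n_edges <= max_edges:
        raise ParameterError(
            f"n_edges must be in [0, {max_edges}] for {n_genes} genes"
        )
    if not 0.0 <= sign_fraction <= 1.0:
        raise ParameterError("sign_fraction must be in [0, 1]")
    genes = [f"G{i + 1}" for i in range(n_genes)]
    all_pairs = [
        (genes[i], genes[j])
        for i in range(n_genes)
        for j in range(i + 1, n_genes)
    ]
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(all_pairs), size=n_edges, replace=False)
    signs: dict[frozenset[str], int] = {}
    edges: set[frozenset[str]] = set()
    for idx in sorted(chosen):
        pair = frozenset(all_pairs[idx])
        edges.add(pair)
        signs[pair] = -1 if rng.random() < sign_fraction else 1
    return GoldStandard(frozenset(edges), frozenset(genes), signs)


def simulate_expression(
    truth: GoldStandard,
    design: Design = "null-mutant",
    coupling: float = 0.8,
    noise_sd: float = 0.01,
    seed: int = 0,
    n_replicates: int = 10,
) -> SyntheticStudy:
    """Generate one wild-type column plus one column per gene perturbation.

    For the perturbed gene g the value is forced to 0 (null-mutant) or
    baseline/2 (knockdown); every neighbor of g in ``truth`` is shifted by
    sign * coupling * its own baseline (negative shift when the edge
    promotes and g is lost).  ``replicates`` instead draws noisy wild-type
    columns only.  Values are clipped to >= 0.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ParameterError("coupling must be in [0, 1]")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    if design not in ("null-mutant", "knockdown", "replicates"):
        raise ValueError(f"unknown design {design!r}")

    genes = sorted(truth.universe)
    n = len(genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)
    baseline = rng.uniform(0.3, 1.0, size=n)

    neighbors: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n)}
    for edge in sorted(truth.edges, key=sorted):
        a, b = sorted(edge)
        sign = truth.signs.get(edge, 1)
        ia, ib = gene_index[a], gene_index[b]
        neighbors[ia].append((ib, sign))
        neighbors[ib].append((ia, sign))

    if design == "replicates":
        sample_ids = ["wt"] + [f"rep{i + 1}" for i in range(n_replicates)]
        labels = ["wild-type"] + ["replicate"] * n_replicates
        values = np.tile(baseline[:, None], (1, len(sample_ids)))
    else:
        suffix = "(-/-)" if design == "null-mutant" else "(+/-)"
        sample_ids = ["wt"] + [f"{g}{suffix}" for g in genes]
        labels = ["wild-type"] + [
            "knockout" if design == "null-mutant" else "knockdown" for _ in genes
        ]
        values = np.tile(baseline[:, None], (1, n + 1))
        for col, g in enumerate(genes, start=1):
            gi = gene_index[g]
            values[gi, col] = 0.0 if design == "null-mutant" else baseline[gi] / 2
            # losing a promoter lowers its partners; losing an inhibitor
            # releases them
            for ni, sign in neighbors[gi]:
                values[ni, col] = baseline[ni] - sign * coupling * baseline[ni]

    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    values = np.clip(values, 0.0, None)

    expr = ExpressionMatrix(tuple(genes), tuple(sample_ids), values)
    return SyntheticStudy(
        truth=truth,
        expression=expr,
        design=tuple(labels),
        coupling=coupling,
        noise_sd=noise_sd,
        seed=seed,
    )
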