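"""Scoring of ranked edge predictions against a gold standard.

AUROC and AUPR of the ranking are compared with the same metrics on
uniformly random rankings of identical size, yielding empirical tail
p-values; the two p-values are combined as -log10(auroc_p * aupr_p) / 2.
Gold standards are undirected, so candidate pairs are unordered gene pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from airnet.exceptions import ParameterError, UndefinedValueError

Pair = tuple[str, str]


@dataclass(frozen=True)
class EvaluationResult:
    """AUROC/AUPR with empirical p-values and the combined log score."""

    auroc: float
    aupr: float
    auroc_p: float
    aupr_p: float
    score: float
    n_null: int

    def to_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "aupr": self.aupr,
            "auroc_p": self.auroc_p,
            "aupr_p": self.aupr_p,
            "score": self.score,
            "n_null": self.n_null,
        }


def rank_predictions(im) -> list[Pair]:
    """Candidate pairs sorted by decreasing |v|, lexicographic tie-break."""
    pairs = im.pairs()
    return [
        pair
        for pair, _ in sorted(pairs, key=lambda item: (-abs(item[1]), item[0]))
    ]


def _labels_and_scores(
    ranking: Sequence, gold
) -> tuple[np.ndarray, np.ndarray]:
    """Binary labels and descending scores for a ranking.

    Entries may be bare pairs (strict ordering: synthetic strictly
    descending scores) or (pair, score) tuples (tie-aware scoring).
    """
    labels, scores = [], []
    explicit = bool(ranking) and len(ranking[0]) == 2 and not isinstance(
        ranking[0][0], str
    )
    for rank, entry in enumerate(ranking):
        if explicit:
            pair, score = entry
        else:
            pair, score = entry, float(len(ranking) - rank)
        labels.append(1 if frozenset(pair) in gold.edges else 0)
        scores.append(float(score))
    y = np.asarray(labels)
    if y.sum() == 0:
        raise UndefinedValueError("gold standard has no positive pairs in ranking")
    if y.sum() == y.size:
        raise UndefinedValueError("gold standard has no negative pairs in ranking")
    return y, np.asarray(scores)


def auroc(ranking: Sequence, gold) -> float:
    """Area under the ROC curve of the ranking (ties trapezoid-averaged)."""
    y, scores = _labels_and_scores(ranking, gold)
    return float(roc_auc_score(y, scores))


def aupr(ranking: Sequence, gold) -> float:
    """Area under the precision-recall curve (step-wise average precision)."""
    y, scores = _labels_and_scores(ranking, gold)
    return float(average_precision_score(y, scores))


def _null_metrics(
    n_candidates: int, n_positives: int, n_null: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """AUROC and AUPR of ``n_null`` uniformly random rankings, vectorized.

    For a random permutation only the ranks of the positives matter; drawing
    them directly gives closed-form AUROC (Mann-Whitney) and AUPR (average
    precision) per draw without materializing rankings.
    """
    n_neg = n_candidates - n_positives
    aurocs = np.empty(n_null)
    auprs = np.empty(n_null)
    chunk = max(1, int(5e6) // max(n_candidates, 1))
    offsets = np.arange(n_positives)
    done = 0
    while done < n_null:
        size = min(chunk, n_null - done)
        keys = rng.random((size, n_candidates))
        pos = np.sort(np.argpartition(keys, n_positives - 1, axis=1)[:, :n_positives])
        u = n_positives * n_neg - pos.sum(axis=1) + offsets.sum()
        aurocs[done : done + size] = u / (n_positives * n_neg)
        auprs[done : done + size] = ((offsets + 1) / (pos + 1)).mean(axis=1)
        done += size
    return aurocs, auprs


def empirical_pvalues(
    observed_auroc: float,
    observed_aupr: float,
    n_candidates: int,
    n_positives: int,
    n_null: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Tail probabilities of matching/exceeding the observed metrics.

    The null model is a uniformly random permutation of the candidate
    ranking (equivalently, a random same-size network).  Add-one estimator:
    p = (1 + #{null >= observed}) / (1 + n_null), never zero.
    """
    if n_null < 1:
        raise ParameterError(f"n_null must be >= 1, got {n_null}")
    if not 0 < n_positives < n_candidates:
        raise UndefinedValueError(
            "need at least one positive and one negative candidate"
        )
    rng = np.random.default_rng(seed)
    null_auroc, null_aupr = _null_metrics(n_candidates, n_positives, n_null, rng)
    tol = 1e-12
    auroc_p = (1 + int((null_auroc >= observed_auroc - tol).sum())) / (1 + n_null)
    aupr_p = (1 + int((null_aupr >= observed_aupr - tol).sum())) / (1 + n_null)
    return auroc_p, aupr_p


def combined_score(auroc_p: float, aupr_p: float) -> float:
    """-log10(auroc_p * aupr_p) / 2."""
    if auroc_p <= 0 or aupr_p <= 0:
        raise ParameterError("p-values must be in (0, 1]")
    return -(math.log10(auroc_p) + math.log10(aupr_p)) / 2


def average_scores(results: Sequence[EvaluationResult]) -> EvaluationResult:
    """Mean p-values across same-sized networks, re-combined into one score."""
    if not results:
        raise ParameterError("empty result list")
    auroc_p = float(np.mean([r.auroc_p for r in results]))
    aupr_p = float(np.mean([r.aupr_p for r in results]))
    return EvaluationResult(
        auroc=float(np.mean([r.auroc for r in results])),
        aupr=float(np.mean([r.aupr for r in results])),
        auroc_p=auroc_p,
        aupr_p=aupr_p,
        score=combined_score(auroc_p, aupr_p),
        n_null=results[0].n_null,
    )


def evaluate_network(ranking: Sequence, gold, n_null: int = 10_000, seed: int = 0
                     ) -> EvaluationResult:
    """Score a ranking end to end: AUROC, AUPR, empirical p-values, score."""
    a = auroc(ranking, gold)
    pr = aupr(ranking, gold)
    n_pos = len(gold.edges)
    auroc_p, aupr_p = empirical_pvalues(
        a, pr, len(ranking), n_pos, n_null=n_null, seed=seed
    )
    return EvaluationResult(
        auroc=a,
        aupr=pr,
        auroc_p=auroc_p,
        aupr_p=aupr_p,
        score=combined_score(auroc_p, aupr_p),
        n_null=n_null,
    )
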