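"""Weighted Kolmogorov-Smirnov gene-set enrichment with leading edge.

Used for the residual-renal-function contrast: the uremic samples are
dichotomized into patients without residual renal function (anuric) and
patients who still produce urine, genes are ranked by a two-group metric,
and a gene set (e.g. TGF-beta receptor signaling) is scored by the signed
maximum deviation of a weighted hit/miss running sum.  "Core-enriched"
(leading-edge) genes are the set members at or before the peak of the
running sum (at or after, for a negative score).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ConfigurationError, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RankMetric",
    "RankedList",
    "EnrichmentResult",
    "rank_genes",
    "enrichment_score",
    "permutation_significance",
]


class RankMetric(str, enum.Enum):
    SIGNAL_TO_NOISE = "signal_to_noise"
    LOG2_RATIO_OF_MEANS = "log2_ratio_of_means"


@dataclass
class RankedList:
    """Genes ordered by a ranking metric, descending; ties broken by gene id."""

    gene_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in ranked list")
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.size != len(self.gene_ids):
            raise ValueError("scores and gene ids differ in length")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class EnrichmentResult:
    """Enrichment score with running sum and leading-edge genes."""

    es: float
    running_sum: np.ndarray
    peak_position: int
    leading_edge: list[str]
    gene_set_size: int


def _two_group_metric(
    X: np.ndarray, a_idx: np.ndarray, b_idx: np.ndarray, metric: RankMetric,
    variance_floor: bool,
) -> np.ndarray:
    mu_a = X[:, a_idx].mean(axis=1)
    mu_b = X[:, b_idx].mean(axis=1)
    if metric == RankMetric.LOG2_RATIO_OF_MEANS:
        return mu_a - mu_b
    sd_a = X[:, a_idx].std(axis=1, ddof=1)
    sd_b = X[:, b_idx].std(axis=1, ddof=1)
    if variance_floor:
        # classical floor: sd >= 0.2 * |mean| (and an absolute floor of 0.2)
        sd_a = np.maximum(sd_a, np.maximum(0.2 * np.abs(mu_a), 0.2))
        sd_b = np.maximum(sd_b, np.maximum(0.2 * np.abs(mu_b), 0.2))
    denom = sd_a + sd_b
    zero = denom == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        s2n = (mu_a - mu_b) / denom
    if zero.any():
        logger.warning(
            "%d gene(s) with zero pooled spread; ranked by mean difference",
            int(zero.sum()),
        )
        s2n[zero] = mu_a[zero] - mu_b[zero]
    return s2n


def rank_genes(
    matrix: ExpressionMatrix,
    group_a,
    group_b,
    metric: RankMetric | str = RankMetric.SIGNAL_TO_NOISE,
    variance_floor: bool = False,
) -> RankedList:
    """Rank genes by a two-group metric, descending.

    SIGNAL_TO_NOISE is (mu_A - mu_B) / (sd_A + sd_B) with sample standard
    deviations and no variance floor by default (with groups of five a
    floor dominates the denominator); genes whose pooled spread is exactly
    zero fall back to the mean difference with a warning.
    """
    metric = RankMetric(metric)
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ConfigurationError("groups overlap")
    if metric == RankMetric.SIGNAL_TO_NOISE and (len(group_a) < 2 or len(group_b) < 2):
        raise ConfigurationError("signal-to-noise needs >= 2 samples per group")
    cols = list(matrix.values.columns)
    try:
        a_idx = np.array([cols.index(s) for s in group_a])
        b_idx = np.array([cols.index(s) for s in group_b])
    except ValueError as exc:
        raise ConfigurationError(f"unknown sample in group: {exc}") from None
    X = matrix.values.to_numpy(dtype=float)
    scores = _two_group_metric(X, a_idx, b_idx, metric, variance_floor)
    order = sorted(
        range(len(scores)), key=lambda i: (-scores[i], matrix.gene_ids[i])
    )
    return RankedList(
        gene_ids=[matrix.gene_ids[i] for i in order], scores=scores[np.array(order)]
    )


def _running_sum(in_set: np.ndarray, scores: np.ndarray, weight_p: float):
    """Weighted-KS running sum over a membership mask (internal)."""
    n = in_set.size
    n_hit = int(in_set.sum())
    if n_hit == 0:
        raise ValueError("gene set has no members in the ranked list")
    if n_hit == n:
        raise ValueError("gene set covers the whole ranked list")
    if weight_p == 0:
        weights = np.ones(n)
    else:
        weights = np.abs(scores) ** weight_p
    nr = weights[in_set].sum()
    if nr == 0:
        # all member scores are zero: fall back to unweighted increments
        weights = np.ones(n)
        nr = float(n_hit)
    step = np.where(in_set, weights / nr, -1.0 / (n - n_hit))
    return np.cumsum(step)


def enrichment_score(
    ranked: RankedList, gene_set, weight_p: float = 1.0
) -> EnrichmentResult:
    """Weighted-KS enrichment score of a gene set on a ranked list.

    Hits increment the running sum by |score|^p normalized over hits;
    misses decrement by 1/(N - N_hit).  The enrichment score is the signed
    maximum-magnitude deviation; the running sum ends at zero.  The
    leading edge holds the set members at or before the peak for a
    positive score (at or after, for a negative one).
    """
    if weight_p < 0:
        raise ValueError("weight_p must be nonnegative")
    members = set(getattr(gene_set, "members", gene_set))
    in_set = np.fromiter(
        (g in members for g in ranked.gene_ids), dtype=bool, count=len(ranked)
    )
    running = _running_sum(in_set, ranked.scores, weight_p)
    peak = int(np.argmax(np.abs(running)))
    es = float(running[peak])
    if es >= 0:
        leading = [g for i, g in enumerate(ranked.gene_ids) if in_set[i] and i <= peak]
    else:
        leading = [g for i, g in enumerate(ranked.gene_ids) if in_set[i] and i >= peak]
    return EnrichmentResult(
        es=es,
        running_sum=running,
        peak_position=peak,
        leading_edge=leading,
        gene_set_size=int(in_set.sum()),
    )


def permutation_significance(
    matrix: ExpressionMatrix,
    group_a,
    group_b,
    gene_set,
    n_perm: int = 1000,
    seed: int | None = None,
    metric: RankMetric | str = RankMetric.SIGNAL_TO_NOISE,
    weight_p: float = 1.0,
) -> dict:
    """Phenotype-permutation nominal p for the enrichment score.

    Group labels are permuted across the pooled samples (group sizes
    preserved); p = (1 + #{|ES_perm| >= |ES_obs|}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ConfigurationError("need n_perm >= 100")
    group_a, group_b = list(group_a), list(group_b)
    pooled = group_a + group_b
    n_a = len(group_a)
    from math import comb

    if comb(len(pooled), n_a) < 2:
        raise ConfigurationError("groups too small to permute distinctly")

    metric = RankMetric(metric)
    members = set(getattr(gene_set, "members", gene_set))
    observed = enrichment_score(
        rank_genes(matrix, group_a, group_b, metric), gene_set, weight_p
    )

    cols = list(matrix.values.columns)
    pooled_idx = np.array([cols.index(s) for s in pooled])
    X = matrix.values.to_numpy(dtype=float)
    membership = np.fromiter(
        (g in members for g in matrix.gene_ids), dtype=bool, count=matrix.n_genes
    )
    gene_arr = np.array(matrix.gene_ids)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled_idx)
        a_idx, b_idx = perm[:n_a], perm[n_a:]
        scores = _two_group_metric(X, a_idx, b_idx, metric, variance_floor=False)
        order = np.lexsort((gene_arr, -scores))
        running = _running_sum(membership[order], scores[order], weight_p)
        es_perm = running[np.argmax(np.abs(running))]
        if abs(es_perm) >= abs(observed.es):
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return {"es": observed.es, "p": p, "n_perm": n_perm, "result": observed}
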