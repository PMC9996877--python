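"""Single-sample gene-set enrichment (ssGSEA).

For one sample, genes are ranked by expression (average ranks on ties,
highest expression = rank N).  Walking the genes in decreasing rank order,
the enrichment score is the integrated difference between the weighted
cumulative distribution of in-set gene ranks and the unweighted cumulative
distribution of out-of-set genes:

    P_hit(k)  = sum_{i in S, pos(i) <= k} r_i^alpha / sum_{i in S} r_i^alpha
    P_miss(k) = |{i not in S : pos(i) <= k}| / (N - |S|)
    ES        = sum_k (P_hit(k) - P_miss(k))

With ``normalize=True`` every ES produced by one call is divided by the
(max - min) over the call's full set x sample score matrix, so scores of
jointly evaluated sets share one scale — which is what makes the difference
of two set scores meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import ExpressionMatrix

__all__ = ["RankMatrix", "ScoreVector", "rank_transform", "ssgsea_score",
           "ssgsea_collection", "score_pair"]

DEFAULT_ALPHA = 0.25


class EnrichmentError(ValueError):
    pass


@dataclass
class RankMatrix:
    """Per-sample expression ranks: each column ranks 1..N ascending in
    expression (ties get average ranks, so column sums equal N(N+1)/2)."""

    ranks: pd.DataFrame
    tie_policy: str = "average"

    @property
    def n_genes(self) -> int:
        return self.ranks.shape[0]


@dataclass
class ScoreVector:
    """Per-sample enrichment scores for one gene set."""

    scores: pd.Series  # index = sample ids
    set_name: str
    alpha: float
    normalized: bool = False
    normalization_constant: float | None = None
    missing_genes: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.normalized and not (
            self.normalization_constant is not None and self.normalization_constant > 0
        ):
            raise EnrichmentError("normalized scores require a positive constant")


def rank_transform(expr: ExpressionMatrix) -> RankMatrix:
    """Rank each sample's genes (1 = lowest expression, N = highest)."""
    if expr.values.shape[0] < 2:
        raise EnrichmentError("enrichment undefined for a single-gene matrix")
    ranks = np.apply_along_axis(rankdata, 0, expr.values.to_numpy(float))
    return RankMatrix(
        pd.DataFrame(ranks, index=expr.gene_ids, columns=expr.sample_ids)
    )


def _resolve_set(gene_set, gene_index: dict[str, int], set_name: str):
    genes = list(gene_set)
    present = [g for g in genes if g in gene_index]
    missing = [g for g in genes if g not in gene_index]
    if missing:
        warnings.warn(
            f"set {set_name!r}: {len(missing)} gene(s) absent from the matrix "
            f"and dropped: {missing}",
            stacklevel=3,
        )
    if not present:
        raise EnrichmentError(f"set {set_name!r} has empty intersection with matrix")
    if len(present) == len(gene_index):
        raise EnrichmentError(f"set {set_name!r} covers every gene in the matrix")
    return present, missing


def _es_one_set(rank_cols: np.ndarray, in_set: np.ndarray, alpha: float) -> np.ndarray:
    """ES per sample by direct summation. rank_cols: genes x samples ranks."""
    n_genes, n_samples = rank_cols.shape
    n_in = int(in_set.sum())
    out = np.empty(n_samples)
    for j in range(n_samples):
        r = rank_cols[:, j]
        # decreasing rank; stable tie-break by gene position for determinism
        order = np.argsort(-r, kind="stable")
        hit = in_set[order]
        r_sorted = r[order]
        w = np.where(hit, r_sorted**alpha if alpha != 0 else 1.0, 0.0)
        p_hit = np.cumsum(w) / w.sum()
        p_miss = np.cumsum(~hit) / (n_genes - n_in)
        out[j] = np.sum(p_hit - p_miss)
    return out


def ssgsea_collection(
    expr: ExpressionMatrix,
    gene_sets: dict[str, list[str]],
    alpha: float = DEFAULT_ALPHA,
    normalize: bool = True,
) -> dict[str, ScoreVector]:
    """Score several gene sets in one call with a shared normalization.

    The normalization constant is the (max - min) of the raw score matrix
    over all sets and samples of this call, so set scores stay mutually
    comparable.
    """
    rm = rank_transform(expr)
    rank_arr = rm.ranks.to_numpy()
    gene_index = {g: i for i, g in enumerate(rm.ranks.index)}
    raw: dict[str, np.ndarray] = {}
    missing_by_set: dict[str, list[str]] = {}
    for name, genes in gene_sets.items():
        present, missing = _resolve_set(genes, gene_index, name)
        in_set = np.zeros(len(gene_index), dtype=bool)
        in_set[[gene_index[g] for g in present]] = True
        raw[name] = _es_one_set(rank_arr, in_set, alpha)
        missing_by_set[name] = missing
    const = None
    if normalize:
        allvals = np.concatenate(list(raw.values()))
        const = float(allvals.max() - allvals.min())
        if const <= 0:
            raise EnrichmentError(
                "degenerate score range: all enrichment scores identical"
            )
        raw = {k: v / const for k, v in raw.items()}
    return {
        name: ScoreVector(
            scores=pd.Series(vals, index=expr.sample_ids, name=name),
            set_name=name,
            alpha=alpha,
            normalized=normalize,
            normalization_constant=const,
            missing_genes=missing_by_set[name],
        )
        for name, vals in raw.items()
    }


def ssgsea_score(
    expr: ExpressionMatrix,
    gene_set,
    set_name: str = "set",
    alpha: float = DEFAULT_ALPHA,
    normalize: bool = False,
) -> ScoreVector:
    """Score a single gene set per sample."""
    return ssgsea_collection(expr, {set_name: list(gene_set)}, alpha, normalize)[
        set_name
    ]


def score_pair(
    expr: ExpressionMatrix,
    control_genes,
    core_genes,
    alpha: float = DEFAULT_ALPHA,
    normalize: bool = True,
) -> tuple[ScoreVector, ScoreVector]:
    """Score the clock-control and core-clock sets jointly.

    One call, one normalization constant: the control - core difference is
    then on a common scale.
    """
    res = ssgsea_collection(
        expr,
        {"control": list(control_genes), "core": list(core_genes)},
        alpha,
        normalize,
    )
    return res["control"], res["core"]
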