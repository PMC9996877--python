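"""Connectivity-map style compound scoring.

A query signature is built from the genes most positively and most
negatively correlated with the CRS.  Each compound in a signature library
supplies a full ranking of a gene universe; the bidirectional
Kolmogorov-Smirnov statistic asks whether the query's up-genes concentrate
at one extreme of that ranking and the down-genes at the other.

For a tag set T of size t with sorted positions V(1..t) in a ranking of n
genes:

    a = max_j ( j/t - V(j)/n )
    b = max_j ( V(j)/n - (j-1)/t )
    ks(T) = a if a > b else -b          (ties a = b resolve to -b)

The raw connectivity score is s = ks(up) - ks(down), set to 0 when both
components share a sign.  Within each cancer, raw scores are scaled to
[-100, 100] by dividing positives by the maximum positive and negatives by
the magnitude of the minimum negative (this deterministic extremal scaling
is this package's convention; no permutation-based tau normalization).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, SignatureLibrary

__all__ = [
    "QuerySignature",
    "crs_gene_signature",
    "ks_connectivity",
    "score_library",
    "scale_scores",
    "compound_screen",
]


class ConnectivityError(ValueError):
    pass


@dataclass
class QuerySignature:
    """Ordered up/down gene lists (most extreme CRS correlation first)."""

    up_genes: list[str]
    down_genes: list[str]
    n_top: int

    def __post_init__(self):
        if set(self.up_genes) & set(self.down_genes):
            raise ConnectivityError("up and down gene lists must be disjoint")
        if not self.up_genes or not self.down_genes:
            raise ConnectivityError("up and down gene lists must be non-empty")


def crs_gene_signature(
    expr: ExpressionMatrix, crs, n_top: int = 150, strict: bool = False
) -> QuerySignature:
    """Top ``n_top`` positively and negatively CRS-correlated genes.

    Per-gene Spearman correlation against the CRS; ties in rho are broken
    lexicographically by gene id so repeat runs are identical.  With fewer
    than 2*n_top correlated genes, ``strict=True`` raises and the default
    truncates with a warning.
    """
    crs_s = crs.crs if hasattr(crs, "crs") else pd.Series(crs)
    shared = [s for s in expr.sample_ids if s in crs_s.index]
    if len(shared) < 5:
        raise ConnectivityError(f"only {len(shared)} shared samples; need >= 5")
    y = crs_s.loc[shared].to_numpy(float)
    vals = expr.values.loc[:, shared].to_numpy(float)
    rho = np.full(vals.shape[0], np.nan)
    defined = np.ptp(vals, axis=1) > 0
    if np.ptp(y) == 0:
        raise ConnectivityError("CRS is constant; correlations undefined")
    if defined.any():
        rho[defined] = stats.spearmanr(vals[defined].T, y).statistic[:-1, -1] \
            if defined.sum() > 1 else stats.spearmanr(vals[defined][0], y).statistic
    genes = np.asarray(expr.gene_ids)
    ok = np.isfinite(rho)
    genes, rho = genes[ok], rho[ok]
    if len(genes) < 2 * n_top:
        msg = (
            f"only {len(genes)} genes with defined correlation "
            f"< 2 * n_top = {2 * n_top}"
        )
        if strict:
            raise ConnectivityError(msg)
        warnings.warn(msg + "; truncating", stacklevel=2)
        n_top = len(genes) // 2
        if n_top == 0:
            raise ConnectivityError("universe too small for any signature")
    # sort by descending rho, ties lexicographic by gene id
    order = np.lexsort((genes, -rho))
    up = list(genes[order][:n_top])
    down_order = np.lexsort((genes, rho))
    down = list(genes[down_order][:n_top])
    return QuerySignature(up, down, n_top)


def _ks_tag(positions: np.ndarray, n: int) -> float:
    """One-sided KS component for sorted 1-based tag positions."""
    t = len(positions)
    j = np.arange(1, t + 1)
    a = np.max(j / t - positions / n)
    b = np.max(positions / n - (j - 1) / t)
    return float(a) if a > b else float(-b)


def ks_connectivity(query: QuerySignature, ranking: list[str]) -> float:
    """Raw bidirectional KS connectivity of one compound ranking, in [-2, 2].

    Query genes absent from the ranking universe are dropped (warning); an
    empty tag set after dropping is an error.
    """
    pos = {g: i + 1 for i, g in enumerate(ranking)}
    n = len(ranking)
    tags = {}
    for name, genes in (("up", query.up_genes), ("down", query.down_genes)):
        present = np.sort(np.array([pos[g] for g in genes if g in pos], dtype=float))
        dropped = len(genes) - len(present)
        if dropped:
            warnings.warn(
                f"{dropped} {name}-gene(s) absent from the compound universe; dropped",
                stacklevel=2,
            )
        if len(present) == 0:
            raise ConnectivityError(f"empty {name} tag set after dropping")
        tags[name] = present
    ks_up = _ks_tag(tags["up"], n)
    ks_down = _ks_tag(tags["down"], n)
    if np.sign(ks_up) == np.sign(ks_down):
        return 0.0
    return ks_up - ks_down


def score_library(query: QuerySignature, library: SignatureLibrary) -> pd.Series:
    """Raw connectivity score for every compound in the library."""
    return pd.Series(
        {
            compound: ks_connectivity(query, ranking)
            for compound, ranking in library.rankings.items()
        },
        name="raw_score",
    )


def scale_scores(raw: pd.Series) -> pd.Series:
    """Map raw scores within one cancer to [-100, 100].

    Positive scores are divided by the maximum positive raw score (so the
    strongest mimic scores 100); negative scores by |minimum negative| (so
    the strongest reverter scores -100); zeros stay zero.
    """
    raw = pd.Series(raw, dtype=float)
    scaled = raw.copy()
    pos = raw[raw > 0]
    neg = raw[raw < 0]
    if len(pos):
        scaled[raw > 0] = 100.0 * (raw[raw > 0] / pos.max())
    if len(neg):
        scaled[raw < 0] = -100.0 * (raw[raw < 0] / neg.min())
    return scaled.rename("scaled_score")


def compound_screen(
    matrix: pd.DataFrame, thresh: float = 90.0, min_cancers: int = 10
) -> dict:
    """Screen a compound x cancer scaled-score matrix for consistent hits.

    A positive hit scores > ``thresh`` in at least ``min_cancers`` cancers;
    a negative hit scores < -``thresh`` likewise.  Missing cells count as
    non-hits.
    """
    filled = matrix.astype(float)
    pos_counts = (filled > thresh).sum(axis=1)
    neg_counts = (filled < -thresh).sum(axis=1)
    positive = sorted(pos_counts.index[pos_counts >= min_cancers])
    negative = sorted(neg_counts.index[neg_counts >= min_cancers])
    return {
        "positive": positive,
        "negative": negative,
        "positive_counts": pos_counts,
        "negative_counts": neg_counts,
    }
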