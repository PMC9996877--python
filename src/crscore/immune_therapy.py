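"""Immune microenvironment screens against the CRS.

Immune cell fraction matrices (e.g. CIBERSORT output) are consumed as
inputs — deconvolution itself is external.  This module compares fractions
between CRS groups (Wilcoxon rank-sum), correlates fractions and immune
checkpoint gene expression with the CRS (Spearman by default, Pearson
exposed), scores stromal/immune signatures by joint ssGSEA, and compares
CRS between therapy response groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .crs_model import CRSTable, compare_crs_groups
from .differential_genomics import bh_adjust
from .enrichment import DEFAULT_ALPHA, ssgsea_collection
from .io_formats import ExpressionMatrix, FractionMatrix, GeneSetCollection

__all__ = [
    "fraction_group_test",
    "fraction_crs_correlation",
    "signature_scores",
    "icg_screen",
    "response_compare",
]

# Purity transform constants from the original ESTIMATE publication
# (cos(a + b * ESTIMATE score)); opt-in, not part of the score itself.
_ESTIMATE_PURITY_A = 0.6049872018
_ESTIMATE_PURITY_B = 0.0001467884


class ImmuneError(ValueError):
    pass


def _crs_series(crs) -> pd.Series:
    if isinstance(crs, CRSTable):
        return crs.crs
    return pd.Series(crs)


def fraction_group_test(fractions: FractionMatrix, groups) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum per cell type between two CRS groups.

    ``groups`` maps sample id -> "high"/"low" (dict or Series).  Returns a
    DataFrame (cell_type, statistic, p, direction, significant) where
    direction is the sign of median(high) - median(low).
    """
    groups = pd.Series(groups)
    shared = [s for s in fractions.values.columns if s in groups.index]
    g = groups.loc[shared]
    levels = sorted(pd.unique(g))
    if len(levels) != 2:
        raise ImmuneError(f"need two group levels, got {levels}")
    if set(levels) == {"high", "low"}:
        hi, lo = "high", "low"
    else:
        hi, lo = levels[0], levels[1]
    if (g == lo).sum() < 2 or (g == hi).sum() < 2:
        raise ImmuneError("need >= 2 samples per group")
    rows = []
    for ct in fractions.values.index:
        x = fractions.values.loc[ct, shared]
        a = x[(g == hi).to_numpy()].to_numpy(float)
        b = x[(g == lo).to_numpy()].to_numpy(float)
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        direction = float(np.sign(np.median(a) - np.median(b)))
        rows.append((ct, float(res.statistic), float(res.pvalue), direction))
    out = pd.DataFrame(rows, columns=["cell_type", "statistic", "p", "direction"])
    out["significant"] = out["p"] < 0.05
    return out


def _correlate(x: np.ndarray, y: np.ndarray, method: str):
    if method == "spearman":
        return stats.spearmanr(x, y)
    if method == "pearson":
        return stats.pearsonr(x, y)
    raise ImmuneError(f"unknown correlation method {method!r}")


def fraction_crs_correlation(
    fractions: FractionMatrix, crs, method: str = "spearman"
) -> pd.DataFrame:
    """Correlate each cell type's fraction with the CRS across samples.

    BH adjustment runs across cell types; a cell type constant across
    samples has undefined correlation and yields a NaN record.
    """
    crs_s = _crs_series(crs)
    shared = [s for s in fractions.values.columns if s in crs_s.index]
    if len(shared) < 5:
        raise ImmuneError(f"only {len(shared)} shared samples; need >= 5")
    y = crs_s.loc[shared].to_numpy(float)
    rows = []
    for ct in fractions.values.index:
        x = fractions.values.loc[ct, shared].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((ct, np.nan, np.nan, len(shared)))
            continue
        rho, p = _correlate(x, y, method)
        rows.append((ct, float(rho), float(p), len(shared)))
    out = pd.DataFrame(rows, columns=["feature_id", "rho", "p", "n"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


@dataclass
class SignatureScores:
    """Per-sample stromal/immune ssGSEA scores; estimate = stromal + immune."""

    data: pd.DataFrame  # columns: sample_id, stromal, immune, estimate[, purity]

    def __post_init__(self):
        if not np.allclose(
            self.data["estimate"], self.data["stromal"] + self.data["immune"]
        ):
            raise ImmuneError("estimate must equal stromal + immune")


def signature_scores(
    expr: ExpressionMatrix,
    stromal_set,
    immune_set,
    alpha: float = DEFAULT_ALPHA,
    with_purity: bool = False,
) -> SignatureScores:
    """Stromal and immune signature enrichment per sample.

    Both signatures are scored in one unnormalized ssGSEA call; the combined
    score is their sum.  ``with_purity`` additionally applies the published
    ESTIMATE cosine purity transform (clipped to [0, 1]) — a convention
    borrowed from that method, emitted only on request.
    """
    res = ssgsea_collection(
        expr,
        {"stromal": list(stromal_set), "immune": list(immune_set)},
        alpha=alpha,
        normalize=False,
    )
    stromal = res["stromal"].scores
    immune = res["immune"].scores
    data = pd.DataFrame(
        {
            "sample_id": expr.sample_ids,
            "stromal": stromal.to_numpy(),
            "immune": immune.to_numpy(),
            "estimate": (stromal + immune).to_numpy(),
        }
    )
    if with_purity:
        purity = np.cos(_ESTIMATE_PURITY_A + _ESTIMATE_PURITY_B * data["estimate"])
        data["purity"] = np.clip(purity, 0.0, 1.0)
    return SignatureScores(data)


def icg_screen(
    expr: ExpressionMatrix,
    crs,
    icg_sets: GeneSetCollection,
    r_thresh: float = 0.7,
    p_thresh: float = 0.05,
    method: str = "spearman",
) -> dict:
    """Correlate immune checkpoint gene expression with the CRS and keep
    genes with |rho| > ``r_thresh`` and p < ``p_thresh``.

    Returns {"records": all per-gene records, "hits": the filtered records
    with a sign annotation, "missing": ICGs absent from the matrix}.
    """
    icgs: list[str] = []
    for name in icg_sets.names():
        icgs.extend(icg_sets[name])
    gene_set = set(expr.gene_ids)
    present = [g for g in icgs if g in gene_set]
    missing = [g for g in icgs if g not in gene_set]
    if not present:
        raise ImmuneError("no immune checkpoint gene present in the matrix")
    crs_s = _crs_series(crs)
    shared = [s for s in expr.sample_ids if s in crs_s.index]
    if len(shared) < 5:
        raise ImmuneError(f"only {len(shared)} shared samples; need >= 5")
    y = crs_s.loc[shared].to_numpy(float)
    rows = []
    for g in present:
        x = expr.values.loc[g, shared].to_numpy(float)
        if np.ptp(x) == 0:
            rows.append((g, np.nan, np.nan, len(shared)))
            continue
        rho, p = _correlate(x, y, method)
        rows.append((g, float(rho), float(p), len(shared)))
    records = pd.DataFrame(rows, columns=["feature_id", "rho", "p", "n"])
    records["q"] = bh_adjust(records["p"].to_numpy())
    hits = records[
        (records["rho"].abs() > r_thresh) & (records["p"] < p_thresh)
    ].copy()
    hits["sign"] = np.where(hits["rho"] > 0, "positive", "negative")
    return {"records": records, "hits": hits.reset_index(drop=True),
            "missing": missing, "method": method}


def response_compare(crs, response_labels) -> dict:
    """Compare CRS between two therapy-response groups.

    Wilcoxon rank-sum two-sided p plus the direction of the median
    difference (first label level minus second, levels sorted).
    """
    crs_s = _crs_series(crs)
    labels = pd.Series(response_labels)
    shared = [s for s in crs_s.index if s in labels.index]
    lab = labels.loc[shared].to_numpy()
    levels = sorted(pd.unique(lab))
    if len(levels) != 2:
        raise ImmuneError(f"need two response levels, got {levels}")
    vals = crs_s.loc[shared].to_numpy(float)
    a = vals[lab == levels[0]]
    b = vals[lab == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ImmuneError("need >= 2 samples per response group")
    stat, p, _ = compare_crs_groups(vals, lab, test="wilcoxon")
    diff = float(np.median(a) - np.median(b))
    return {
        "statistic": stat,
        "p": p,
        "levels": levels,
        "median_difference": diff,
        "direction": f"{levels[0]} {'lower' if diff < 0 else 'higher'} than {levels[1]}",
    }
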