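"""Tumor-vs-normal differential expression, unit conversion, and SNV/CNV
summaries.

Differential calls use Welch's t on log2 values with Benjamini-Hochberg
adjustment.  A gene is called up when its fold change exceeds 2 (log2 fold
change > 1) at p < 0.05, down when the fold change is below 1/2 at p < 0.05,
otherwise not significant; the gate uses the raw p, with the BH q reported
alongside.

GISTIC-style focal copy-number scores are thresholded at +/-0.3: scores in
[-0.3, 0.3] (inclusive) are neutral (0), above 0.3 amplified (+1), below
-0.3 deleted (-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CNVMatrix, ExpressionMatrix, MutationTable

__all__ = [
    "fpkm_to_tpm",
    "deg_call",
    "mutation_frequency",
    "cnv_categorize",
    "cnv_expression_correlation",
]

PSEUDOCOUNT = 1.0


class GenomicsError(ValueError):
    pass


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values (NaN-safe: NaNs propagate)."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        q[ok] = stats.false_discovery_control(p[ok], method="bh")
    return q


def fpkm_to_tpm(expr: ExpressionMatrix) -> ExpressionMatrix:
    """TPM_ij = FPKM_ij / sum_i FPKM_ij * 1e6; every column sums to 1e6."""
    if expr.unit != "FPKM":
        raise GenomicsError(f"expected FPKM input, got {expr.unit}")
    vals = expr.values.to_numpy(float)
    colsum = vals.sum(axis=0)
    if (colsum <= 0).any():
        bad = expr.sample_ids[int(np.argmax(colsum <= 0))]
        raise GenomicsError(f"sample {bad!r} has zero column sum")
    tpm = vals / colsum * 1e6
    return ExpressionMatrix(
        pd.DataFrame(tpm, index=expr.gene_ids, columns=expr.sample_ids), unit="TPM"
    )


def _to_log2(expr: ExpressionMatrix) -> np.ndarray:
    if expr.unit == "log2":
        return expr.values.to_numpy(float)
    return np.log2(expr.values.to_numpy(float) + PSEUDOCOUNT)


def deg_call(
    tumor: ExpressionMatrix,
    normal: ExpressionMatrix,
    fc_thresh: float = 2.0,
    p_thresh: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Welch's t on log2 values with fold-change-gated calls.

    Returns a DataFrame (gene_id, log2_fc, p, q, call) where call is "up"
    iff fold change > ``fc_thresh`` and p < ``p_thresh``, "down" iff fold
    change < 1/``fc_thresh`` and p < ``p_thresh``, else "ns".
    """
    if list(tumor.gene_ids) != list(normal.gene_ids):
        diff = set(tumor.gene_ids) ^ set(normal.gene_ids)
        raise GenomicsError(
            f"gene universes differ (symmetric difference: {sorted(diff)[:10]}"
            f"{'...' if len(diff) > 10 else ''}) or row order differs"
        )
    if tumor.values.shape[1] < 2 or normal.values.shape[1] < 2:
        raise GenomicsError("need >= 2 samples per side")
    lt = _to_log2(tumor)
    ln = _to_log2(normal)
    log2_fc = lt.mean(axis=1) - ln.mean(axis=1)
    with np.errstate(invalid="ignore"):
        res = stats.ttest_ind(lt, ln, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # identical constant rows yield nan p; treat as no evidence (p = 1)
    p = np.where(np.isnan(p) & (np.abs(log2_fc) < 1e-300), 1.0, p)
    q = bh_adjust(p)
    log2_gate = np.log2(fc_thresh)
    call = np.where(
        (log2_fc > log2_gate) & (p < p_thresh),
        "up",
        np.where((log2_fc < -log2_gate) & (p < p_thresh), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "gene_id": tumor.gene_ids,
            "log2_fc": log2_fc,
            "p": p,
            "q": q,
            "call": call,
        }
    )


def mutation_frequency(
    mut: MutationTable, display_min_freq: float | None = None
) -> dict:
    """Per-gene, per-cohort mutation frequency and class summaries.

    freq(gene, cohort) = distinct mutated samples / cohort size.  A gene
    mutated twice in one sample counts once, and its class becomes
    ``multi_hit``.  ``display_min_freq`` optionally filters the frequency
    table to genes whose overall proportion (all cohorts pooled) exceeds it.
    """
    d = mut.data
    rows = []
    class_rows = []
    for (cohort, gene), sub in d.groupby(["cohort", "gene_id"]):
        n_cohort = mut.cohort_sizes[str(cohort)]
        per_sample = sub.groupby("sample_id").size()
        n_mutated = len(per_sample)
        rows.append((gene, cohort, n_mutated, n_cohort, n_mutated / n_cohort))
        for sample, k in per_sample.items():
            cls = (
                "multi_hit"
                if k > 1
                else sub.loc[sub["sample_id"] == sample, "variant_class"].iloc[0]
            )
            class_rows.append((gene, cohort, sample, cls))
    freq = pd.DataFrame(
        rows, columns=["gene_id", "cohort", "n_mutated", "n_cohort", "freq"]
    )
    classes = pd.DataFrame(
        class_rows, columns=["gene_id", "cohort", "sample_id", "variant_class"]
    )
    class_counts = (
        classes.groupby("variant_class").size().rename("count").reset_index()
        if len(classes)
        else pd.DataFrame(columns=["variant_class", "count"])
    )
    total_n = sum(mut.cohort_sizes.values())
    mutated_samples = d["sample_id"].nunique() if len(d) else 0
    overall_fraction_mutated = mutated_samples / total_n if total_n else 0.0
    if display_min_freq is not None and len(freq):
        overall = (
            freq.groupby("gene_id")
            .apply(lambda s: s["n_mutated"].sum() / s["n_cohort"].sum(),
                   include_groups=False)
            .rename("overall_freq")
        )
        keep = overall[overall > display_min_freq].index
        freq = freq[freq["gene_id"].isin(keep)].reset_index(drop=True)
    return {
        "freq": freq,
        "per_sample_classes": classes,
        "class_counts": class_counts,
        "overall_fraction_mutated": overall_fraction_mutated,
    }


def cnv_categorize(
    cnv: CNVMatrix, lo: float = -0.3, hi: float = 0.3
) -> tuple[CNVMatrix, pd.DataFrame]:
    """Threshold focal scores into {-1, 0, 1} and tabulate per-gene rates.

    score > hi -> 1 (amplified); score < lo -> -1 (deleted); otherwise
    (boundaries inclusive) 0.  Returns the categorized matrix and a
    DataFrame (gene_id, amp_freq, del_freq).
    """
    if lo >= hi:
        raise GenomicsError("lo must be < hi")
    vals = cnv.values.to_numpy(float)
    cat = np.zeros_like(vals, dtype=int)
    cat[vals > hi] = 1
    cat[vals < lo] = -1
    cat_df = pd.DataFrame(cat, index=cnv.values.index, columns=cnv.values.columns)
    freq = pd.DataFrame(
        {
            "gene_id": list(cnv.values.index),
            "amp_freq": (cat == 1).mean(axis=1),
            "del_freq": (cat == -1).mean(axis=1),
        }
    )
    return CNVMatrix(cat_df, categorized=True), freq


def cnv_expression_correlation(
    cnv: CNVMatrix, expr: ExpressionMatrix
) -> pd.DataFrame:
    """Per-gene Spearman correlation between raw focal score and expression.

    Computed over the shared samples (>= 5 required); genes constant in CNV
    (or expression) have undefined correlation and are reported as NaN, with
    BH q over the defined genes.
    """
    if cnv.categorized:
        raise GenomicsError("use raw focal scores, not the categorized matrix")
    shared = [s for s in cnv.values.columns if s in set(expr.sample_ids)]
    if len(shared) < 5:
        raise GenomicsError(f"only {len(shared)} shared samples; need >= 5")
    genes = [g for g in cnv.values.index if g in set(expr.gene_ids)]
    rows = []
    for g in genes:
        x = cnv.values.loc[g, shared].to_numpy(float)
        y = expr.values.loc[g, shared].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((g, np.nan, np.nan, len(shared)))
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append((g, float(rho), float(p), len(shared)))
    out = pd.DataFrame(rows, columns=["gene_id", "rho", "p", "n"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
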