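"""The circadian rhythm score (CRS).

Per sample, CRS is the ssGSEA enrichment of the clock-control gene set minus
that of the core-clock gene set (the two sets are scored jointly so the
difference is on one scale).  In tumors where core-clock genes are
up-regulated and clock-control genes down-regulated, this difference moves —
the score quantifies how far a sample's transcriptome sits from a balanced
circadian program.

A ``sign_convention`` switch is exposed: the literal definition is
control - core, but reported group directions are sometimes plotted on the
negated axis; every output records which convention produced it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import io_formats
from .enrichment import DEFAULT_ALPHA, score_pair
from .io_formats import ExpressionMatrix, GeneSetCollection

__all__ = [
    "GeneSetPair",
    "CRSTable",
    "default_gene_set_pair",
    "compute_crs",
    "compare_crs_groups",
    "rhythm_amplitude",
]


class CRSError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSetPair:
    """The two disjoint circadian gene classes whose enrichment difference
    defines the CRS."""

    control_genes: tuple[str, ...]
    core_genes: tuple[str, ...]

    def __post_init__(self):
        if not self.control_genes or not self.core_genes:
            raise CRSError("both gene sets must be non-empty")
        if set(self.control_genes) & set(self.core_genes):
            raise CRSError("control and core gene sets must be disjoint")

    @classmethod
    def from_collection(
        cls,
        collection: GeneSetCollection,
        control_name: str = "clock_control",
        core_name: str = "core_clock",
    ) -> "GeneSetPair":
        return cls(
            tuple(collection[control_name]), tuple(collection[core_name])
        )


def default_gene_set_pair() -> GeneSetPair:
    """The bundled 13 clock-control / 35 core-clock gene pair."""
    return GeneSetPair.from_collection(io_formats.load_crg_sets())


@dataclass
class CRSTable:
    """Per-sample CRS with stratification metadata.

    ``data`` columns: sample_id, crs, group (high/low/unassigned), tissue
    (tumor/normal), cancer_type.  ``group`` is only ever assigned to tumor
    samples, after a cutpoint has been chosen.
    """

    data: pd.DataFrame
    sign_convention: str = "control_minus_core"
    alpha: float = DEFAULT_ALPHA
    normalized: bool = True

    def __post_init__(self):
        required = {"sample_id", "crs", "group", "tissue", "cancer_type"}
        missing = required - set(self.data.columns)
        if missing:
            raise CRSError(f"CRS table missing columns {sorted(missing)}")
        if not np.isfinite(self.data["crs"].to_numpy(float)).all():
            raise CRSError("non-finite CRS value")
        bad = self.data.loc[
            (self.data["tissue"] == "normal") & (self.data["group"] != "unassigned")
        ]
        if len(bad):
            raise CRSError("group labels may only be assigned to tumor samples")

    @property
    def crs(self) -> pd.Series:
        return pd.Series(
            self.data["crs"].to_numpy(float), index=list(self.data["sample_id"])
        )

    def tumor(self) -> pd.DataFrame:
        return self.data[self.data["tissue"] == "tumor"]

    def assign_groups(self, cutpoint: float) -> "CRSTable":
        """Label tumor samples: crs > cutpoint -> high, else low."""
        d = self.data.copy()
        tumor = d["tissue"] == "tumor"
        d.loc[tumor, "group"] = np.where(
            d.loc[tumor, "crs"] > cutpoint, "high", "low"
        )
        return CRSTable(d, self.sign_convention, self.alpha, self.normalized)


def compute_crs(
    expr: ExpressionMatrix,
    pair: GeneSetPair,
    alpha: float = DEFAULT_ALPHA,
    normalize: bool = True,
    sign_convention: str = "control_minus_core",
    tissue=None,
    cancer_type=None,
) -> CRSTable:
    """Compute the per-sample CRS.

    Parameters
    ----------
    tissue : mapping or sequence, optional
        Per-sample "tumor"/"normal" labels; defaults to "tumor" everywhere.
    cancer_type : str or mapping, optional
        Per-sample cancer type annotation; defaults to "NA".
    """
    if sign_convention not in ("control_minus_core", "core_minus_control"):
        raise CRSError(f"unknown sign convention {sign_convention!r}")
    ctrl, core = score_pair(
        expr, pair.control_genes, pair.core_genes, alpha=alpha, normalize=normalize
    )
    crs = ctrl.scores - core.scores
    if sign_convention == "core_minus_control":
        crs = -crs
    samples = expr.sample_ids
    if tissue is None:
        tissue_col = ["tumor"] * len(samples)
    elif isinstance(tissue, dict):
        tissue_col = [tissue[s] for s in samples]
    else:
        tissue_col = list(tissue)
    if cancer_type is None:
        type_col = ["NA"] * len(samples)
    elif isinstance(cancer_type, str):
        type_col = [cancer_type] * len(samples)
    else:
        type_col = [cancer_type[s] for s in samples]
    data = pd.DataFrame(
        {
            "sample_id": samples,
            "crs": crs.to_numpy(),
            "group": "unassigned",
            "tissue": tissue_col,
            "cancer_type": type_col,
        }
    )
    return CRSTable(data, sign_convention, alpha, normalize)


def compare_crs_groups(values, labels, test: str = "wilcoxon"):
    """Two-sided two-group comparison of per-sample scores.

    ``test="wilcoxon"`` is the rank-sum (Mann-Whitney) test, exact for small
    untied samples; ``test="t"`` is Welch's t.  Returns (statistic, p, test).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    levels = pd.unique(labels)
    if len(levels) != 2:
        raise CRSError(f"need exactly two label levels, got {len(levels)}")
    a = values[labels == levels[0]]
    b = values[labels == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise CRSError("need >= 2 observations per level")
    if test == "wilcoxon":
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    elif test == "t":
        res = stats.ttest_ind(a, b, equal_var=False)
    else:
        raise CRSError(f"unknown test {test!r}")
    return float(res.statistic), float(min(res.pvalue, 1.0)), test


def rhythm_amplitude(crs_by_time: pd.DataFrame) -> pd.Series:
    """Peak-to-trough range of the mean CRS over timepoints, per group.

    ``crs_by_time`` columns: group, timepoint_h, crs.  The range is
    max - min of per-timepoint mean CRS; one timepoint is an error.
    """
    for col in ("group", "timepoint_h", "crs"):
        if col not in crs_by_time.columns:
            raise CRSError(f"missing column {col!r}")
    out = {}
    for group, sub in crs_by_time.groupby("group"):
        means = sub.groupby("timepoint_h")["crs"].mean()
        if len(means) < 2:
            raise CRSError(f"group {group!r}: need >= 2 distinct timepoints")
        out[group] = float(means.max() - means.min())
    return pd.Series(out, name="crs_range")
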