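"""Readers, writers and validated in-memory containers for every format the
pipeline touches.

All tabular formats are strict TSV (tab-delimited, no comma autodetection —
gene descriptions may contain commas).  Parsers never silently coerce: every
dropped row or remapped label is recorded in the :class:`LoadReport` attached
to the returned object.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LoadReport",
    "ExpressionMatrix",
    "GeneSetCollection",
    "ClinicalTable",
    "MutationTable",
    "CNVMatrix",
    "FractionMatrix",
    "SignatureLibrary",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_maf_lite",
    "write_maf_lite",
    "read_cnv",
    "write_cnv",
    "read_fractions",
    "write_fractions",
    "read_signature_library",
    "write_signature_library",
]

VARIANT_CLASSES = (
    "missense",
    "nonsense",
    "multi_hit",
    "frameshift_ins",
    "frameshift_del",
    "splice_site",
    "inframe_ins",
    "inframe_del",
)

#: Synonym table mapping MAF-style variant classification strings onto the
#: eight canonical classes.  Unknown strings are rejected, never guessed.
VARIANT_CLASS_SYNONYMS = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Multi_Hit": "multi_hit",
    "Frame_Shift_Ins": "frameshift_ins",
    "Frame_Shift_Del": "frameshift_del",
    "Splice_Site": "splice_site",
    "In_Frame_Ins": "inframe_ins",
    "In_Frame_Del": "inframe_del",
}

FRACTION_SUM_TOL = 1e-6


class FormatError(ValueError):
    """Raised when an input file violates its documented dialect."""


@dataclass
class LoadReport:
    """What a parser did beyond verbatim reading: drops and remaps."""

    dropped_rows: int = 0
    dropped_row_ids: list[str] = field(default_factory=list)
    remapped_labels: dict[str, str] = field(default_factory=dict)
    duplicate_genes_removed: int = 0
    warnings: list[str] = field(default_factory=list)


def _strip_ids(ids) -> list[str]:
    return [str(x).strip() for x in ids]


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what}: {x!r}")
        seen.add(x)


# ---------------------------------------------------------------------------
# Expression matrices


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values in a single declared unit.

    ``values`` is a DataFrame indexed by gene id with sample ids as columns.
    Linear units (FPKM/TPM) require all values >= 0; log2 values are
    unrestricted reals.
    """

    values: pd.DataFrame
    unit: str  # "FPKM" | "TPM" | "log2"
    report: LoadReport = field(default_factory=LoadReport)

    def __post_init__(self):
        if self.unit not in ("FPKM", "TPM", "log2"):
            raise FormatError(f"unknown unit {self.unit!r}")
        self.values.index = _strip_ids(self.values.index)
        self.values.columns = _strip_ids(self.values.columns)
        _check_unique(self.values.index, "gene id")
        _check_unique(self.values.columns, "sample id")
        if self.values.isna().any().any():
            raise FormatError("missing values in expression matrix")
        if self.unit != "log2" and (self.values.to_numpy() < 0).any():
            raise FormatError(f"negative value under linear unit {self.unit}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)].copy(), self.unit)


def read_expression(path, unit: str) -> ExpressionMatrix:
    """Read a gene x sample TSV (first column gene ids, header sample ids).

    Rows containing any non-numeric or missing cell are dropped and counted
    in the load report; duplicate gene or sample ids are an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = _strip_ids(df.index)
    df.columns = _strip_ids(df.columns)
    _check_unique(df.columns, "sample id")
    _check_unique(df.index, "gene id")
    def _parse(cell):
        try:
            return float(cell)
        except (TypeError, ValueError):
            return np.nan

    numeric = df.map(_parse)
    bad = numeric.isna().any(axis=1)
    report = LoadReport(
        dropped_rows=int(bad.sum()), dropped_row_ids=list(numeric.index[bad])
    )
    numeric = numeric.loc[~bad]
    return ExpressionMatrix(numeric.astype(float), unit=unit, report=report)


def write_expression(expr: ExpressionMatrix, path) -> None:
    out = expr.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# Gene sets (GMT)


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT semantics)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    report: LoadReport = field(default_factory=LoadReport)

    def __post_init__(self):
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")
            _check_unique(genes, f"gene in set {name!r}")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: per line ``name<TAB>description<TAB>gene...``.

    In-set duplicate genes are removed (count logged in the report);
    duplicate set names or lines with fewer than three fields are errors.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    report = LoadReport()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name = fields[0].strip()
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            genes: list[str] = []
            seen: set[str] = set()
            for g in _strip_ids(fields[2:]):
                if not g:
                    continue
                if g in seen:
                    report.duplicate_genes_removed += 1
                    continue
                seen.add(g)
                genes.append(g)
            sets[name] = genes
            descriptions[name] = fields[1]
    return GeneSetCollection(sets, descriptions, report)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, ".")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Clinical tables


@dataclass
class ClinicalTable:
    """Per-sample overall survival and optional covariates.

    Mandatory columns: sample_id, os_time_days (> 0), os_event (0/1).
    Optional: age, sex, stage, response.
    """

    data: pd.DataFrame
    report: LoadReport = field(default_factory=LoadReport)

    def __post_init__(self):
        d = self.data
        for col in ("sample_id", "os_time_days", "os_event"):
            if col not in d.columns:
                raise FormatError(f"clinical table missing mandatory column {col!r}")
        d["sample_id"] = _strip_ids(d["sample_id"])
        _check_unique(d["sample_id"], "sample id")
        if (d["os_time_days"] <= 0).any():
            raise FormatError("os_time_days must be > 0")
        if not d["os_event"].isin([0, 1]).all():
            raise FormatError("os_event outside {0, 1}")
        self.data = d.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def time(self) -> np.ndarray:
        return self.data["os_time_days"].to_numpy(float)

    @property
    def event(self) -> np.ndarray:
        return self.data["os_event"].to_numpy(int)

    def subset(self, sample_ids) -> "ClinicalTable":
        keep = self.data[self.data["sample_id"].isin(set(sample_ids))].copy()
        order = {s: i for i, s in enumerate(sample_ids)}
        keep = keep.sort_values("sample_id", key=lambda s: s.map(order))
        return ClinicalTable(keep.reset_index(drop=True))


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("sample_id", "os_time_days", "os_event"):
        if col not in df.columns:
            raise FormatError(f"clinical table missing mandatory column {col!r}")
    df["os_time_days"] = pd.to_numeric(df["os_time_days"])
    df["os_event"] = pd.to_numeric(df["os_event"])
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Mutations (MAF-lite)


@dataclass
class MutationTable:
    """Rows of (sample_id, gene_id, variant_class) plus per-cohort sizes."""

    data: pd.DataFrame  # columns: sample_id, gene_id, variant_class[, cohort]
    cohort_sizes: dict[str, int]
    report: LoadReport = field(default_factory=LoadReport)

    def __post_init__(self):
        d = self.data
        for col in ("sample_id", "gene_id", "variant_class"):
            if col not in d.columns:
                raise FormatError(f"mutation table missing column {col!r}")
        bad = set(d["variant_class"]) - set(VARIANT_CLASSES)
        if bad:
            raise FormatError(
                f"unknown variant_class values {sorted(bad)}; "
                f"allowed: {list(VARIANT_CLASSES)}"
            )
        if "cohort" not in d.columns:
            d = d.assign(cohort="all")
        for cohort, sub in d.groupby("cohort"):
            n = self.cohort_sizes.get(str(cohort))
            if n is None:
                raise FormatError(f"no cohort size for cohort {cohort!r}")
            n_mutated = sub["sample_id"].nunique()
            if n < n_mutated:
                raise FormatError(
                    f"cohort {cohort!r}: size {n} < {n_mutated} distinct mutated samples"
                )
        self.data = d.reset_index(drop=True)


def read_maf_lite(path, cohort_sizes_path) -> MutationTable:
    """Read a MAF-lite TSV plus its ``cohort<TAB>n_samples`` sidecar.

    MAF-style variant classification strings (e.g. ``Missense_Mutation``) are
    remapped via the documented synonym table; anything else is rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    report = LoadReport()
    remapped = []
    for v in df["variant_class"]:
        if v in VARIANT_CLASSES:
            remapped.append(v)
        elif v in VARIANT_CLASS_SYNONYMS:
            remapped.append(VARIANT_CLASS_SYNONYMS[v])
            report.remapped_labels[v] = VARIANT_CLASS_SYNONYMS[v]
        else:
            raise FormatError(
                f"variant_class {v!r} is neither a canonical class "
                f"{list(VARIANT_CLASSES)} nor a known synonym"
            )
    df = df.assign(variant_class=remapped)
    sizes_df = pd.read_csv(cohort_sizes_path, sep="\t", dtype={"cohort": str})
    cohort_sizes = dict(zip(sizes_df["cohort"], sizes_df["n_samples"].astype(int)))
    return MutationTable(df, cohort_sizes, report)


def write_maf_lite(mut: MutationTable, path, cohort_sizes_path) -> None:
    mut.data.to_csv(path, sep="\t", index=False)
    pd.DataFrame(
        {"cohort": list(mut.cohort_sizes), "n_samples": list(mut.cohort_sizes.values())}
    ).to_csv(cohort_sizes_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Copy number


@dataclass
class CNVMatrix:
    """Gene x sample focal copy-number scores (GISTIC-style reals), or, after
    categorization, an integer matrix with entries in {-1, 0, 1}."""

    values: pd.DataFrame
    categorized: bool = False
    report: LoadReport = field(default_factory=LoadReport)

    def __post_init__(self):
        self.values.index = _strip_ids(self.values.index)
        self.values.columns = _strip_ids(self.values.columns)
        _check_unique(self.values.index, "gene id")
        _check_unique(self.values.columns, "sample id")
        if self.categorized:
            vals = self.values.to_numpy()
            if not np.isin(vals, (-1, 0, 1)).all():
                raise FormatError("categorized CNV entries must be in {-1, 0, 1}")


def read_cnv(path) -> CNVMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return CNVMatrix(df.astype(float))


def write_cnv(cnv: CNVMatrix, path) -> None:
    out = cnv.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# Immune cell fractions


@dataclass
class FractionMatrix:
    """Cell type x sample fractions; each sample column sums to 1."""

    values: pd.DataFrame
    report: LoadReport = field(default_factory=LoadReport)

    def __post_init__(self):
        self.values.index = _strip_ids(self.values.index)
        self.values.columns = _strip_ids(self.values.columns)
        _check_unique(self.values.index, "cell type")
        _check_unique(self.values.columns, "sample id")
        vals = self.values.to_numpy()
        if (vals < 0).any():
            raise FormatError("negative cell fraction")
        sums = vals.sum(axis=0)
        off = np.abs(sums - 1.0) > FRACTION_SUM_TOL
        if off.any():
            bad = self.values.columns[off][0]
            raise FormatError(
                f"fraction column {bad!r} sums to {sums[off][0]:.6g}, expected 1"
            )


def read_fractions(path) -> FractionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return FractionMatrix(df.astype(float))


def write_fractions(frac: FractionMatrix, path) -> None:
    out = frac.values.copy()
    out.index.name = "cell_type"
    out.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# Compound signature libraries


@dataclass
class SignatureLibrary:
    """Compound -> complete gene ranking over a common universe.

    ``rankings[compound]`` lists gene ids from rank 1 (most up-regulated by
    the compound) to rank N.  Every compound ranks the same universe.
    """

    rankings: dict[str, list[str]]
    report: LoadReport = field(default_factory=LoadReport)

    def __post_init__(self):
        if not self.rankings:
            raise FormatError("empty signature library")
        universe = None
        for compound, genes in self.rankings.items():
            _check_unique(genes, f"gene in ranking for {compound!r}")
            s = frozenset(genes)
            if universe is None:
                universe = s
            elif s != universe:
                raise FormatError(
                    f"compound {compound!r} ranks a different gene universe"
                )
        self.universe = universe

    def compounds(self) -> list[str]:
        return list(self.rankings)


def read_signature_library(path) -> SignatureLibrary:
    """Read a long-format TSV with columns compound_id, rank, gene_id."""
    df = pd.read_csv(path, sep="\t", dtype={"compound_id": str, "gene_id": str})
    rankings: dict[str, list[str]] = {}
    for compound, sub in df.groupby("compound_id", sort=False):
        sub = sub.sort_values("rank")
        ranks = sub["rank"].to_numpy()
        if not np.array_equal(ranks, np.arange(1, len(ranks) + 1)):
            raise FormatError(
                f"compound {compound!r}: ranks are not a complete 1..N sequence"
            )
        rankings[str(compound)] = _strip_ids(sub["gene_id"])
    return SignatureLibrary(rankings)


def write_signature_library(lib: SignatureLibrary, path) -> None:
    rows = []
    for compound, genes in lib.rankings.items():
        for rank, gene in enumerate(genes, start=1):
            rows.append((compound, rank, gene))
    pd.DataFrame(rows, columns=["compound_id", "rank", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Bundled gene lists


def _data_path(name: str) -> Path:
    return Path(__file__).parent / "data" / name


def load_crg_sets() -> GeneSetCollection:
    """Bundled circadian rhythm gene lists: 13 clock-control + 35 core-clock."""
    return read_gmt(_data_path("crg.gmt"))


def load_icg_set() -> GeneSetCollection:
    """Bundled immune checkpoint gene list (60 genes)."""
    return read_gmt(_data_path("icg.gmt"))


def load_estimate_signatures() -> GeneSetCollection:
    """Bundled synthetic stand-in stromal/immune signatures."""
    return read_gmt(_data_path("estimate_signatures_synthetic.gmt"))
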