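"""FPKM expression profiling: bins, expressed calls, family tables, heat maps.

Expression levels are FPKM (fragments per kilobase of transcript per
million mapped fragments), supplied as a gene x tissue table. FPKM values
are grouped into six categories on a log decade scale:

    [0, 1)          no or extremely low expression
    [1, 10)         very low
    [10, 100)       low
    [100, 1000)     moderate
    [1000, 10000)   high
    [10000, inf)    very high

Intervals are left-closed/right-open, so a boundary value (exactly 10,
1000, ...) falls in the upper bin. A gene is called "expressed" in a tissue
when FPKM >= `expressed_min_fpkm` (default 1, i.e. anything above the
lowest category); the threshold is configuration and is printed in every
report header. Heat-map matrices are log10(FPKM + pseudocount).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from cuticula.config import RunConfig
from cuticula.cp_classifier import FamilyCall

_DEFAULT = RunConfig()

#: Ordered bin vocabulary and lower edges (upper edge of the last is +inf).
EXPRESSION_BINS = (
    "none_or_extremely_low", "very_low", "low", "moderate", "high", "very_high",
)
BIN_EDGES = (0.0, 1.0, 10.0, 100.0, 1000.0, 10000.0)

#: Table row order: CPR split into its subfamilies, then the other families.
STRATA = (
    "CPR_RR-1", "CPR_RR-2", "CPR_RR-3", "CPR_RR-NC",
    "CPAP1", "CPAP3", "CPCFC", "CPLCP", "CPLCA",
    "CPF", "CPFL", "CPT", "CPG", "CPH", "18aa",
)


def stratum_of(call: FamilyCall) -> str:
    if call.family == "CPR":
        return f"CPR_{call.subfamily}"
    return call.family


@dataclass
class ExpressionMatrix:
    """Gene x tissue FPKM values (non-negative), as a pandas DataFrame."""

    data: pd.DataFrame  # index: gene ids; columns: tissue names

    def __post_init__(self):
        if (self.data.values < 0).any():
            bad = self.data.index[(self.data < 0).any(axis=1)].tolist()
            raise ValueError(f"negative FPKM values for gene(s): {bad}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.data.columns)

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls(df.astype(float))

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene")


def bin_fpkm(value: float) -> str:
    """Map an FPKM value to its expression category (left-closed bins)."""
    if value < 0:
        raise ValueError(f"FPKM must be non-negative, got {value}")
    idx = int(np.searchsorted(BIN_EDGES, value, side="right")) - 1
    return EXPRESSION_BINS[idx]


def expressed_call(value: float, threshold: float = 1.0) -> bool:
    """True iff the gene counts as expressed (FPKM >= threshold)."""
    if value < 0:
        raise ValueError(f"FPKM must be non-negative, got {value}")
    return value >= threshold


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention used for printed percentages)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_pct(numerator: float, denominator: float, decimals: int = 1) -> str:
    """Percentage string, e.g. format_pct(132, 217) -> '60.8%'."""
    if denominator == 0:
        return "NA"
    value = round_half_up(100.0 * numerator / denominator, decimals)
    return f"{value:.{decimals}f}%"


def summarize_counts(counts: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Append a Total row and per-tissue percentage columns to a counts table.

    `counts` must have a "Genome" column and one column per tissue; rows
    are family strata. Percentages are per row: expressed count over the
    stratum's genome count, rounded half away from zero.
    """
    if "Genome" not in counts.columns:
        raise ValueError('counts table needs a "Genome" column')
    table = counts.copy()
    table.loc["Total"] = table.sum(axis=0)
    for tissue in [c for c in counts.columns if c != "Genome"]:
        table[f"{tissue}_pct"] = [
            round_half_up(100.0 * row[tissue] / row["Genome"], decimals)
            if row["Genome"] else float("nan")
            for _, row in table.iterrows()
        ]
    return table


def family_tissue_table(matrix: ExpressionMatrix, calls: list[FamilyCall],
                        config: RunConfig = _DEFAULT,
                        decimals: int = 1) -> pd.DataFrame:
    """Counts of genes per family stratum: genome total and expressed per
    tissue, with a Total row and percentage columns.

    Every gene in the matrix must have a classification; not-CP genes are
    excluded from the table. Genome counts come from the calls (all
    classified CPs, whether or not present in the matrix).
    """
    call_by_id = {c.protein_id: c for c in calls}
    missing = [g for g in matrix.genes if g not in call_by_id]
    if missing:
        raise ValueError(f"matrix gene(s) without a family call: {missing}")

    strata = [s for s in STRATA]
    counts = pd.DataFrame(0, index=strata, columns=["Genome"] + matrix.tissues)
    for call in calls:
        if call.family == "not-CP":
            continue
        counts.loc[stratum_of(call), "Genome"] += 1
    for gene in matrix.genes:
        call = call_by_id[gene]
        if call.family == "not-CP":
            continue
        stratum = stratum_of(call)
        for tissue in matrix.tissues:
            if expressed_call(matrix.data.at[gene, tissue],
                              config.expressed_min_fpkm):
                counts.loc[stratum, tissue] += 1
    counts = counts.loc[counts.sum(axis=1) > 0]  # drop empty strata
    return summarize_counts(counts, decimals)


def not_expressed_count(matrix: ExpressionMatrix, calls: list[FamilyCall],
                        family: str, subfamily: str | None, tissue: str,
                        config: RunConfig = _DEFAULT) -> int:
    """Genome count minus expressed count for one family stratum/tissue."""
    if tissue not in matrix.tissues:
        raise ValueError(f"unknown tissue {tissue!r}; have {matrix.tissues}")
    target = f"CPR_{subfamily}" if family == "CPR" else family
    if target not in STRATA:
        raise ValueError(f"unknown family stratum {target!r}")
    genome = expressed = 0
    for call in calls:
        if call.family == "not-CP" or stratum_of(call) != target:
            continue
        genome += 1
        gene = call.protein_id
        if gene in matrix.data.index and expressed_call(
                matrix.data.at[gene, tissue], config.expressed_min_fpkm):
            expressed += 1
    return genome - expressed


def heatmap_matrix(matrix: ExpressionMatrix, config: RunConfig = _DEFAULT,
                   genomic_order: list[str] | None = None) -> pd.DataFrame:
    """log10(FPKM + pseudocount) matrix with deterministic row ordering.

    Rows are ordered by average-linkage hierarchical clustering of the
    transformed profiles (Euclidean distance) or, with
    ``config.heatmap_order == "genomic"``, by the supplied genomic order.
    """
    log = np.log10(matrix.data + config.heatmap_pseudocount)
    if config.heatmap_order == "genomic":
        if genomic_order is None:
            raise ValueError("genomic ordering requested but no order given")
        order = [g for g in genomic_order if g in log.index]
        leftover = [g for g in log.index if g not in set(order)]
        return log.loc[order + leftover]
    if len(log) < 3:
        return log.sort_index()
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import pdist
    linkage = hierarchy.linkage(pdist(log.values), method="average")
    leaves = hierarchy.leaves_list(linkage)
    return log.iloc[leaves]


def tissue_specificity(matrix: ExpressionMatrix,
                       config: RunConfig = _DEFAULT) -> pd.DataFrame:
    """Per-gene dominant tissue and dominance ratio (max / row sum).

    Genes whose dominance ratio reaches ``tissue_specific_min_ratio`` are
    flagged tissue-specific; all-zero rows are flagged silent.
    """
    if len(matrix.tissues) < 2:
        raise ValueError("tissue specificity needs at least 2 tissues")
    rows = []
    for gene in matrix.genes:
        values = matrix.data.loc[gene]
        total = float(values.sum())
        if total == 0:
            rows.append({"gene": gene, "dominant_tissue": None,
                         "dominance_ratio": float("nan"),
                         "tissue_specific": False, "silent": True})
            continue
        dominant = values.idxmax()
        ratio = float(values.max()) / total
        rows.append({"gene": gene, "dominant_tissue": dominant,
                     "dominance_ratio": ratio,
                     "tissue_specific": ratio >= config.tissue_specific_min_ratio,
                     "silent": False})
    return pd.DataFrame(rows).set_index("gene")


def write_table_report(table: pd.DataFrame, path,
                       config: RunConfig = _DEFAULT) -> None:
    with open(path, "w") as fh:
        fh.write(f"# expressed threshold: FPKM >= {config.expressed_min_fpkm}\n")
        table.to_csv(fh, sep="\t", index_label="family")
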