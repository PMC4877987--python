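"""Transcriptional activity from paired metagenome/metatranscriptome counts.

RPKM (reads per kilobase of gene per million mapped reads) normalizes a
raw count for gene length and library depth:

    RPKM = 1e9 * count / (length_bp * total_mapped_reads)

MRPKM — the ratio of RPKM from RNA to RPKM from DNA — measures per-gene
transcriptional activity normalized for gene dosage: gene length cancels,
and DNA coverage corrects for how abundant the genome is. MRPKM is
undefined (not zero, not infinite) where the DNA RPKM is zero; undefined
values carry a flag and are never silently coerced.
"""

from __future__ import annotations

import math
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from ._util import round_half_away


def rpkm(count: int, length_bp: int, total_mapped_reads: int) -> float:
    """Reads per kilobase per million mapped reads."""
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    return 1e9 * count / (length_bp * total_mapped_reads)


def mrpkm(dna_count: int, rna_count: int, length_bp: int,
          dna_total: int, rna_total: int) -> float | None:
    """RPKM-RNA / RPKM-DNA for one gene; None when DNA RPKM is zero.

    Algebraically (rna_count/dna_count) * (dna_total/rna_total); the gene
    length cancels exactly.
    """
    d = rpkm(dna_count, length_bp, dna_total)
    r = rpkm(rna_count, length_bp, rna_total)
    if d == 0.0:
        return None
    return r / d


def activity_table(expression: pd.DataFrame, lengths: pd.Series | dict,
                   dna_total: int | None = None,
                   rna_total: int | None = None) -> pd.DataFrame:
    """Per-gene activity table from count data.

    ``expression`` needs gene_id, dna_count, rna_count; ``lengths`` maps
    gene_id to length in bp. Library totals default to the column sums.
    Output columns: gene_id, length_bp, rpkm_dna, rpkm_rna, mrpkm (NaN
    where undefined) and ``defined`` (False where DNA RPKM is zero).
    """
    df = expression.copy()
    if isinstance(lengths, dict):
        lengths = pd.Series(lengths)
    df["length_bp"] = df["gene_id"].map(lengths)
    if df["length_bp"].isna().any():
        bad = df.loc[df["length_bp"].isna(), "gene_id"].head(5).tolist()
        raise KeyError(f"genes with unknown length: {bad}")
    dna_total = int(dna_total if dna_total is not None
                    else df["dna_count"].sum())
    rna_total = int(rna_total if rna_total is not None
                    else df["rna_count"].sum())
    if dna_total <= 0 or rna_total <= 0:
        raise ValueError("library totals must be positive")
    ln = df["length_bp"].to_numpy(dtype=float)
    df["rpkm_dna"] = 1e9 * df["dna_count"].to_numpy(float) / (ln * dna_total)
    df["rpkm_rna"] = 1e9 * df["rna_count"].to_numpy(float) / (ln * rna_total)
    defined = df["rpkm_dna"] > 0
    df["mrpkm"] = np.where(defined, df["rpkm_rna"] / df["rpkm_dna"].where(defined, 1.0),
                           np.nan)
    df["defined"] = defined
    return df[["gene_id", "length_bp", "dna_count", "rna_count",
               "rpkm_dna", "rpkm_rna", "mrpkm", "defined"]]


def bin_activity_summary(gene_ids: Iterable[str], activity: pd.DataFrame,
                         active_threshold: float = 0.0
                         ) -> tuple[float, pd.DataFrame]:
    """Percentage of a bin's genes with MRPKM above the threshold.

    With the default threshold 0 this is "genes with any detected
    transcript". Genes with undefined MRPKM never count as active. The
    denominator is all of the bin's genes found in the table. Returns the
    percentage (one decimal) and the per-gene sub-table.
    """
    wanted = set(gene_ids)
    if not wanted:
        raise ValueError("empty gene group")
    sub = activity[activity["gene_id"].isin(wanted)]
    if sub.empty:
        raise KeyError("none of the bin's genes are present in the table")
    active = sub["defined"] & (sub["mrpkm"] > active_threshold)
    pct = round_half_away(100.0 * int(active.sum()) / len(sub), 1)
    return pct, sub


def gene_group_activity(gene_ids: Iterable[str], activity: pd.DataFrame,
                        aggregation: Literal["sum", "mean"] = "sum"
                        ) -> tuple[float | None, int]:
    """Aggregate MRPKM over a gene group (e.g. all pilA homolog copies).

    Undefined members are excluded from the aggregate and counted in the
    second return value; a group with no defined member returns
    (None, n_undefined) rather than a silent zero.
    """
    wanted = set(gene_ids)
    if not wanted:
        raise ValueError("empty gene group")
    sub = activity[activity["gene_id"].isin(wanted)]
    if sub.empty:
        raise KeyError("none of the group's genes are present in the table")
    defined = sub[sub["defined"]]
    n_undef = len(sub) - len(defined)
    if defined.empty:
        return None, n_undef
    vals = defined["mrpkm"].to_numpy(dtype=float)
    agg = float(vals.sum()) if aggregation == "sum" else float(vals.mean())
    if math.isnan(agg):
        return None, n_undef
    return agg, n_undef
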