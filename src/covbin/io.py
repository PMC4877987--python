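"""Readers and writers for the plain-text formats the pipeline exchanges.

Everything is FASTA or tab-separated text with a header row, so outputs
can be inspected, diffed and versioned. The mapping summary carries its
library size in a ``# total_reads=`` comment line above the header.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coverage import MappingSummary


# --- FASTA ----------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Scaffold sequences keyed by ID, uppercased."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path,
                width: int = 80) -> None:
    records = [SeqRecord(Seq(seq), id=sid, description="")
               for sid, seq in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# --- mapping summaries ----------------------------------------------------

def write_mapping_tsv(mapping: MappingSummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# total_reads={mapping.total_reads}\n")
        fh.write("scaffold_id\tmapped_reads\tmapped_bases\n")
        for sid in sorted(mapping.mapped_reads):
            fh.write(f"{sid}\t{mapping.mapped_reads[sid]}"
                     f"\t{mapping.mapped_bases[sid]}\n")


def read_mapping_tsv(path: str | Path, sample_id: str | None = None
                     ) -> MappingSummary:
    path = Path(path)
    total = 0
    with open(path) as fh:
        first = fh.readline().strip()
        if first.startswith("# total_reads="):
            total = int(first.split("=", 1)[1])
        else:
            raise ValueError(f"{path}: missing '# total_reads=' header line")
    df = pd.read_csv(path, sep="\t", comment="#")
    return MappingSummary(
        sample_id=sample_id or path.stem.replace("mapping_", ""),
        mapped_reads=dict(zip(df["scaffold_id"], df["mapped_reads"].astype(int))),
        mapped_bases=dict(zip(df["scaffold_id"], df["mapped_bases"].astype(int))),
        total_reads=total,
    )


# --- simple TSV tables ----------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_markers_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"gene_id", "scaffold_id", "marker_id"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    return df


def read_genes_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"gene_id", "scaffold_id", "start", "end", "strand"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    return df


def read_links_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"scaffold_a", "scaffold_b", "n_links"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    return df


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"gene_id", "dna_count", "rna_count"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    return df


def read_tnf_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="scaffold_id")


# --- BLAST tabular --------------------------------------------------------

BLAST12_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch",
                   "gapopen", "qstart", "qend", "sstart", "send",
                   "evalue", "bitscore"]


def read_blast_tab(path: str | Path,
                   query_lengths: Mapping[str, int] | None = None
                   ) -> pd.DataFrame:
    """Read 12-column BLAST tabular output (optional qlen/slen columns 13-14).

    Returns the canonical alignment-hit table used by the comparison
    operations: query_id, subject_id, percent_identity, alignment_length,
    bitscore, query_length, query_aligned. Query length comes from a qlen
    column when present, else from ``query_lengths``.
    """
    raw = pd.read_csv(path, sep="\t", header=None, comment="#")
    if raw.shape[1] < 12:
        raise ValueError(f"{path}: expected >= 12 tab-separated columns")
    cols = BLAST12_COLUMNS + ["qlen", "slen"][: raw.shape[1] - 12]
    raw.columns = cols + list(raw.columns[len(cols):])
    out = pd.DataFrame({
        "query_id": raw["qseqid"],
        "subject_id": raw["sseqid"],
        "percent_identity": raw["pident"].astype(float),
        "alignment_length": raw["length"].astype(int),
        "bitscore": raw["bitscore"].astype(float),
        "query_aligned": (raw["qend"] - raw["qstart"]).abs().astype(int) + 1,
    })
    if "qlen" in raw.columns:
        out["query_length"] = raw["qlen"].astype(int)
    elif query_lengths is not None:
        out["query_length"] = out["query_id"].map(query_lengths).astype(int)
    else:
        raise ValueError(
            f"{path}: no qlen column; supply query_lengths to resolve "
            "query coverage")
    return out


# --- JSON helpers ---------------------------------------------------------

def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
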