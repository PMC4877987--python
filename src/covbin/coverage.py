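"""Per-scaffold coverage profiles and bin-level relative abundance.

Coverage of a scaffold in one sample is defined as the total base pairs of
mapped reads divided by the scaffold length. Binning operates on the pair
of coverages a scaffold shows across two metagenomes sequenced from the
same community at different times, so the central product here is a table
with one row per scaffold and one coverage column per sample.

Mapping evidence enters either as a plain per-scaffold summary table
(scaffold_id, mapped_reads, mapped_bases, plus the library size) or as a
SAM/BAM file, from which primary mapped records are counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_away

#: coverage assigned the pseudo-count floor before log10 at plot/selection time
LOG_PSEUDOCOUNT = 0.01


@dataclass
class MappingSummary:
    """Read-mapping evidence for one sample against the scaffold set."""

    sample_id: str
    mapped_reads: dict[str, int] = field(default_factory=dict)
    mapped_bases: dict[str, int] = field(default_factory=dict)
    total_reads: int = 0

    def __post_init__(self) -> None:
        if self.total_reads < 0:
            raise ValueError("total_reads must be non-negative")
        if self.mapped_reads and self.total_reads < max(self.mapped_reads.values()):
            raise ValueError(
                "total_reads smaller than a single scaffold's mapped_reads")


def parse_sam(path: str | Path, min_mapped_fraction: float = 0.0,
              sample_id: str | None = None) -> MappingSummary:
    """Build a MappingSummary from a SAM/BAM file.

    Counts primary, mapped records per reference sequence; mapped bases are
    the reference-consuming cigar lengths (M/=/X/D) of those records.
    Secondary and supplementary records are ignored so each read is counted
    once, at its primary placement. ``total_reads`` is the number of
    distinct read names in the file, mapped or not. Records whose aligned
    query fraction falls below ``min_mapped_fraction`` are skipped.
    """
    import pysam

    path = Path(path)
    reads: dict[str, int] = {}
    bases: dict[str, int] = {}
    names: set[str] = set()
    # M=0, I=1, D=2, N=3, S=4, H=5, P=6, ==7, X=8
    ref_ops = {0, 2, 7, 8}
    query_ops = {0, 1, 4, 7, 8}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            names.add(rec.query_name)
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            cig = rec.cigartuples or []
            qlen = sum(n for op, n in cig if op in query_ops) or (
                rec.query_length or 0)
            aligned_q = sum(n for op, n in cig if op in {0, 7, 8})
            if qlen and aligned_q / qlen < min_mapped_fraction:
                continue
            ref = rec.reference_name
            reads[ref] = reads.get(ref, 0) + 1
            bases[ref] = bases.get(ref, 0) + sum(
                n for op, n in cig if op in ref_ops)
    return MappingSummary(sample_id=sample_id or path.stem,
                          mapped_reads=reads, mapped_bases=bases,
                          total_reads=len(names))


def coverage_from_mapping(
    mappings: Sequence[MappingSummary],
    lengths: Mapping[str, int],
) -> pd.DataFrame:
    """Per-scaffold coverage table from per-sample mapping summaries.

    Returns a DataFrame indexed by scaffold_id with columns ``length``,
    ``cov_<sample>`` (mapped_bases / length) and ``reads_<sample>`` for
    every sample. Scaffolds absent from a mapping get zero. A mapping that
    mentions a scaffold with no known length is an error naming the
    offenders.
    """
    ids = sorted(lengths)
    known = set(ids)
    for m in mappings:
        unknown = sorted(set(m.mapped_reads) - known)
        if unknown:
            raise KeyError(
                f"sample {m.sample_id!r} maps to unknown scaffolds: "
                f"{', '.join(unknown[:10])}"
                + ("..." if len(unknown) > 10 else ""))
    lens = np.array([lengths[s] for s in ids], dtype=float)
    if (lens <= 0).any():
        raise ValueError("all scaffold lengths must be positive")
    out = pd.DataFrame({"length": lens.astype(int)},
                       index=pd.Index(ids, name="scaffold_id"))
    for m in mappings:
        bases = np.array([m.mapped_bases.get(s, 0) for s in ids], dtype=float)
        nreads = np.array([m.mapped_reads.get(s, 0) for s in ids], dtype=int)
        out[f"cov_{m.sample_id}"] = bases / lens
        out[f"reads_{m.sample_id}"] = nreads
    return out


def log10_coverage(values: np.ndarray | pd.Series,
                   pseudocount: float = LOG_PSEUDOCOUNT) -> np.ndarray:
    """log10 of coverage with zeros floored at the pseudo-count."""
    v = np.asarray(values, dtype=float)
    return np.log10(np.maximum(v, pseudocount))


def relative_abundance(bin_scaffolds: Iterable[str],
                       mappings: Sequence[MappingSummary],
                       ndigits: int = 1) -> dict[str, float]:
    """Bin abundance per sample: mapped reads over bin scaffolds as a
    percentage of the library's total reads, rounded to one decimal."""
    members = set(bin_scaffolds)
    out: dict[str, float] = {}
    for m in mappings:
        if m.total_reads <= 0:
            raise ValueError(f"sample {m.sample_id!r} has total_reads=0")
        hit = sum(n for s, n in m.mapped_reads.items() if s in members)
        out[m.sample_id] = round_half_away(100.0 * hit / m.total_reads, ndigits)
    return out
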