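"""Bin quality estimation from single-copy marker genes.

A set of genes expected exactly once per genome (107 essential
single-copy genes, or 35 conserved single-copy COGs as a cross-check)
turns marker detection into two quality numbers for a genome bin:

* completeness — the percentage of the marker set identified in the bin;
* redundancy (contamination) — duplicated markers (present in two or more
  copies) as a percentage of the markers identified.

"Duplicated" counts markers occurring >= 2 times, not the number of extra
copies: a marker seen three times contributes one duplicated marker.
Percentages are reported rounded half-away-from-zero to one decimal;
full precision is retained internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from ._util import round_half_away
from .binning import GenomeBin

_PACKAGED_SETS = {
    "ESCG107": ("escg107_markers.txt", 107),
    "COG35": ("cog35_markers.txt", 35),
}


@dataclass(frozen=True)
class MarkerSet:
    set_id: str
    marker_ids: frozenset[str]

    @property
    def expected_size(self) -> int:
        return len(self.marker_ids)


def load_marker_set(set_id: str) -> MarkerSet:
    """Load a packaged marker set ('ESCG107' or 'COG35') from its data file."""
    if set_id not in _PACKAGED_SETS:
        raise KeyError(f"unknown marker set {set_id!r}; "
                       f"choose from {sorted(_PACKAGED_SETS)}")
    fname, expected = _PACKAGED_SETS[set_id]
    text = resources.files("covbin").joinpath("data", fname).read_text()
    ids = frozenset(line.strip() for line in text.splitlines()
                    if line.strip() and not line.startswith("#"))
    if len(ids) != expected:
        raise ValueError(f"{fname}: expected {expected} markers, got {len(ids)}")
    return MarkerSet(set_id=set_id, marker_ids=ids)


def marker_set_from_file(path: str | Path, set_id: str | None = None
                         ) -> MarkerSet:
    """A marker set from a plain text file of IDs (one per line, # comments)."""
    path = Path(path)
    ids = frozenset(line.strip() for line in path.read_text().splitlines()
                    if line.strip() and not line.startswith("#"))
    if not ids:
        raise ValueError(f"{path}: no marker IDs found")
    return MarkerSet(set_id=set_id or path.stem, marker_ids=ids)


def _marker_counts(hits: pd.DataFrame, marker_set: MarkerSet) -> pd.Series:
    """Hits per marker of the set (one gene counts once per marker)."""
    if hits.empty:
        return pd.Series(dtype=int)
    sub = hits[hits["marker_id"].isin(marker_set.marker_ids)]
    if "score" in sub.columns and sub["score"].notna().any():
        # best-hit-per-gene so one gene cannot inflate two markers
        sub = (sub.sort_values(["gene_id", "score", "marker_id"],
                               ascending=[True, False, True])
                  .drop_duplicates(subset="gene_id", keep="first"))
    else:
        sub = sub.drop_duplicates(subset=["gene_id", "marker_id"])
    return sub.groupby("marker_id").size()


def completeness(hits: pd.DataFrame, marker_set: MarkerSet) -> float:
    """Percentage of the marker set with at least one hit (full precision)."""
    counts = _marker_counts(hits, marker_set)
    return 100.0 * len(counts) / marker_set.expected_size


def redundancy(hits: pd.DataFrame, marker_set: MarkerSet) -> float:
    """Duplicated markers over identified markers, as a percentage.

    Zero when no marker is identified (logged via a warning so the
    convention is auditable)."""
    counts = _marker_counts(hits, marker_set)
    if len(counts) == 0:
        warnings.warn("no markers identified; redundancy reported as 0.0 "
                      "by convention", stacklevel=2)
        return 0.0
    return 100.0 * int((counts >= 2).sum()) / len(counts)


@dataclass
class QCReport:
    bin_id: str
    marker_set_id: str
    n_identified: int
    n_duplicated: int
    completeness_pct: float  # rounded, 1 decimal
    redundancy_pct: float    # rounded, 1 decimal
    passes_quality: bool

    def to_dict(self) -> dict:
        return self.__dict__.copy()

    def to_table_row(self) -> str:
        return (f"{self.bin_id}\t{self.marker_set_id}\t{self.n_identified}"
                f"\t{self.n_duplicated}\t{self.completeness_pct}"
                f"\t{self.redundancy_pct}\t{self.passes_quality}")


def qc_report(bin_: GenomeBin | Iterable[str], hits: pd.DataFrame,
              marker_set: MarkerSet,
              min_completeness: float = 96.0,
              max_redundancy: float = 5.0) -> QCReport:
    """Quality report for a bin: restrict hits to the bin's scaffolds,
    compute both metrics, and flag whether the bin clears the quality bar
    (completeness > 96 and redundancy < 5 by default, configurable)."""
    if isinstance(bin_, GenomeBin):
        bin_id, members = bin_.bin_id, bin_.scaffold_ids
    else:
        members = set(bin_)
        bin_id = "bin"
    sub = hits[hits["scaffold_id"].isin(members)]
    counts = _marker_counts(sub, marker_set)
    n_ident = len(counts)
    n_dup = int((counts >= 2).sum())
    comp = 100.0 * n_ident / marker_set.expected_size
    red = (100.0 * n_dup / n_ident) if n_ident else 0.0
    if n_ident == 0:
        warnings.warn(f"bin {bin_id!r}: no markers identified", stacklevel=2)
    return QCReport(
        bin_id=bin_id,
        marker_set_id=marker_set.set_id,
        n_identified=n_ident,
        n_duplicated=n_dup,
        completeness_pct=round_half_away(comp, 1),
        redundancy_pct=round_half_away(red, 1),
        passes_quality=(comp > min_completeness) and (red < max_redundancy),
    )


def load_hmmer_tblout(path: str | Path, score_threshold: float = 0.0,
                      gene_to_scaffold: dict[str, str] | None = None
                      ) -> pd.DataFrame:
    """Marker hits from HMMER3 --tblout output (best marker per gene).

    Columns used: target name (the gene), query name (the marker profile)
    and the full-sequence score. Hits below ``score_threshold`` are
    dropped; each gene keeps only its best-scoring marker. Scaffold IDs
    are resolved through ``gene_to_scaffold`` when given, else left empty.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: malformed tblout line")
            try:
                score = float(parts[5])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: bad score field {parts[5]!r}") from exc
            rows.append((parts[0], parts[2], score))
    df = pd.DataFrame(rows, columns=["gene_id", "marker_id", "score"])
    df = df[df["score"] >= score_threshold]
    df = (df.sort_values(["gene_id", "score", "marker_id"],
                         ascending=[True, False, True])
            .drop_duplicates(subset="gene_id", keep="first")
            .reset_index(drop=True))
    df.insert(1, "scaffold_id",
              df["gene_id"].map(gene_to_scaffold or {}).fillna(""))
    return df[["gene_id", "scaffold_id", "marker_id", "score"]]
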