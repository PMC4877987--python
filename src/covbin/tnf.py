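"""Tetranucleotide-frequency (TNF) signatures and composition-based bin refinement.

The 4-mer composition of an assembled scaffold is approximately constant
along a genome and differs between genomes, which makes it a useful
signature for spotting contamination inside a coverage-defined bin. Since
assembled scaffolds have arbitrary strand, each 4-mer is collapsed with its
reverse complement onto a canonical representative; of the 256 raw 4-mers,
16 are their own reverse complement, leaving 16 + 240/2 = 136 canonical
dimensions. Frequencies are fractions of valid windows and sum to one.

Refinement clusters the scaffold signatures hierarchically and cuts the
tree at a fixed height (0.1 by default); the cluster carrying the greatest
total scaffold length is the bin core and everything else is flagged as
contamination.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform

from ._util import reverse_complement

_BASES = "ACGT"

#: All 136 canonical (reverse-complement collapsed) 4-mers, lexicographic.
CANONICAL_KMERS: tuple[str, ...] = tuple(
    sorted(
        {
            min(k, reverse_complement(k))
            for k in ("".join(p) for p in itertools.product(_BASES, repeat=4))
        }
    )
)

N_CANONICAL = len(CANONICAL_KMERS)  # 136

_CANONICAL_INDEX = {k: i for i, k in enumerate(CANONICAL_KMERS)}

# code (base-4 integer of a raw 4-mer) -> canonical dimension, as an array
_CODE_TO_CANONICAL = np.empty(256, dtype=np.int64)
for _code in range(256):
    _kmer = "".join(_BASES[(_code >> (2 * (3 - _j))) & 3] for _j in range(4))
    _CODE_TO_CANONICAL[_code] = _CANONICAL_INDEX[min(_kmer, reverse_complement(_kmer))]

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def canonical_kmer(kmer: str) -> str:
    """Return the canonical form of a 4-mer: min(kmer, reverse complement).

    Idempotent. Raises ValueError for anything that is not a 4-letter
    unambiguous DNA string; callers counting windows skip such windows.
    """
    if len(kmer) != 4:
        raise ValueError(f"expected a 4-mer, got {kmer!r}")
    kmer = kmer.upper()
    if any(c not in _BASES for c in kmer):
        raise ValueError(f"ambiguous or non-DNA base in {kmer!r}")
    return min(kmer, reverse_complement(kmer))


def tnf_vector(sequence: str) -> np.ndarray:
    """Canonical tetranucleotide frequency vector of a sequence.

    Every length-4 window (step 1) free of ambiguous bases contributes one
    count to its canonical 4-mer; frequencies are counts over total valid
    windows, so the vector sums to 1. Raises ValueError when no valid
    window exists.
    """
    codes = _BASE_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if codes.size < 4:
        raise ValueError("sequence shorter than 4 bases")
    # rolling 4-mer codes; windows touching an ambiguous base are invalid
    valid = codes >= 0
    win_valid = valid[:-3] & valid[1:-2] & valid[2:-1] & valid[3:]
    if not win_valid.any():
        raise ValueError("no valid 4-mer window in sequence")
    c = np.where(valid, codes, 0)
    win_codes = (c[:-3] << 6) | (c[1:-2] << 4) | (c[2:-1] << 2) | c[3:]
    dims = _CODE_TO_CANONICAL[win_codes[win_valid]]
    counts = np.bincount(dims, minlength=N_CANONICAL).astype(float)
    return counts / counts.sum()


def tnf_table(sequences: Mapping[str, str]) -> "pd.DataFrame":
    """TNF vectors for many scaffolds as a DataFrame (rows=scaffolds)."""
    import pandas as pd

    ids = list(sequences)
    mat = np.vstack([tnf_vector(sequences[s]) for s in ids])
    return pd.DataFrame(mat, index=pd.Index(ids, name="scaffold_id"),
                        columns=list(CANONICAL_KMERS))


def tnf_distance(v1: np.ndarray, v2: np.ndarray) -> float:
    """Euclidean distance between two TNF vectors."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != (N_CANONICAL,) or v2.shape != (N_CANONICAL,):
        raise ValueError(f"TNF vectors must have length {N_CANONICAL}")
    return float(np.linalg.norm(v1 - v2))


@dataclass
class RefinementResult:
    """Outcome of composition-based refinement of one bin."""

    kept: set[str]
    removed: set[str]
    #: one entry per removed scaffold: (scaffold_id, height at which its
    #: cluster would merge with the kept core)
    removals: list[dict] = field(default_factory=list)
    #: scipy linkage matrix of the clustering, for audit/plotting
    linkage_matrix: np.ndarray | None = None
    cutoff: float = 0.1


def _scale_vectors(mat: np.ndarray, scaling: str) -> np.ndarray:
    if scaling == "fraction":
        return mat
    if scaling == "percent":
        return mat * 100.0
    if scaling == "zscore":
        sd = mat.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        return (mat - mat.mean(axis=0)) / sd
    raise ValueError(f"unknown TNF scaling {scaling!r}")


def tnf_refine(
    scaffold_ids: Sequence[str],
    vectors: Mapping[str, np.ndarray],
    lengths: Mapping[str, int],
    cutoff: float = 0.1,
    linkage: str = "average",
    min_keep_fraction: float = 0.5,
    scaling: str = "fraction",
) -> RefinementResult:
    """Split a bin into a kept core and removed putative contamination.

    Scaffold TNF vectors are clustered agglomeratively (average linkage by
    default) and the tree is cut at ``cutoff``; the cluster with the
    greatest total scaffold length is kept. If that cluster holds less than
    ``min_keep_fraction`` of the bin's length the refinement is considered
    unsafe and nothing is removed (recorded in the result).

    All scaffolds in a single cluster is a valid outcome with an empty
    removed set. Kept and removed sets partition the input exactly.
    """
    ids = list(scaffold_ids)
    if len(ids) < 2:
        raise ValueError("refinement needs at least 2 scaffolds")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    mat = np.vstack([np.asarray(vectors[s], dtype=float) for s in ids])
    mat = _scale_vectors(mat, scaling)
    Z = scipy_linkage(mat, method=linkage, metric="euclidean")
    labels = fcluster(Z, t=cutoff, criterion="distance")

    by_cluster: dict[int, list[str]] = {}
    for sid, lab in zip(ids, labels):
        by_cluster.setdefault(int(lab), []).append(sid)

    # larger total length wins; ties: more scaffolds, then smallest member id
    stats = {
        lab: (sum(lengths[s] for s in members), len(members))
        for lab, members in by_cluster.items()
    }
    best = max(stats.values())
    kept_label = min(
        (lab for lab, st in stats.items() if st == best),
        key=lambda lab: min(by_cluster[lab]),
    )
    kept = set(by_cluster[kept_label])
    removed = set(ids) - kept

    total_len = sum(lengths[s] for s in ids)
    kept_len = sum(lengths[s] for s in kept)
    if removed and total_len > 0 and kept_len / total_len < min_keep_fraction:
        # refusing to throw away most of the bin; keep everything
        return RefinementResult(
            kept=set(ids), removed=set(),
            removals=[{
                "note": "refinement skipped: largest cluster holds "
                        f"{kept_len / total_len:.2f} < min_keep_fraction="
                        f"{min_keep_fraction} of total length",
            }],
            linkage_matrix=Z, cutoff=cutoff,
        )

    # replay merges to find, for each removed scaffold, the height at which
    # its cluster first joins a cluster containing kept-core members
    removals: list[dict] = []
    if removed:
        n = len(ids)
        comp: list[set[int]] = [{i} for i in range(n)]
        has_kept = [ids[i] in kept for i in range(n)]
        join_height: dict[str, float] = {}
        nodes: list[set[int]] = [set() for _ in range(n - 1)]
        node_kept: list[bool] = [False] * (n - 1)
        for m, (a, b, h, _cnt) in enumerate(Z):
            a, b = int(a), int(b)
            sa = comp[a] if a < n else nodes[a - n]
            sb = comp[b] if b < n else nodes[b - n]
            ka = has_kept[a] if a < n else node_kept[a - n]
            kb = has_kept[b] if b < n else node_kept[b - n]
            merged = sa | sb
            nodes[m] = merged
            node_kept[m] = ka or kb
            if ka != kb:  # one side gains kept members now
                newly = sb if ka else sa
                for i in newly:
                    sid = ids[i]
                    if sid in removed and sid not in join_height:
                        join_height[sid] = float(h)
        removals = [
            {"scaffold_id": s, "merge_height": join_height.get(s, float("inf"))}
            for s in sorted(removed)
        ]
    return RefinementResult(kept=kept, removed=removed, removals=removals,
                            linkage_matrix=Z, cutoff=cutoff)


def pairwise_distance_matrix(vectors: Mapping[str, np.ndarray],
                             ids: Iterable[str] | None = None) -> np.ndarray:
    """Dense Euclidean distance matrix over the given scaffolds (audit aid)."""
    ids = list(ids) if ids is not None else list(vectors)
    mat = np.vstack([vectors[s] for s in ids])
    return squareform(pdist(mat, metric="euclidean"))
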