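"""Pairwise genome comparison: fragment ANI, shared and duplicated genes,
and species-level classification.

Average nucleotide identity (ANI) follows the classical fragment recipe:
one genome is cut into consecutive fragments (1,020 bp by default), each
fragment is aligned to the best-matching stretch of the other genome on
either strand, and ANI is the mean identity of fragments aligning at or
above the similarity cutoff (60 % by default). The headline number is the
symmetric mean of both directions. Fragment alignment uses edlib's infix
mode (best edit-distance placement of the whole fragment), so identity is
1 - edits/fragment_length; precomputed tabular alignments can be ingested
instead.

Shared genes between two genomes are bidirectional best hits (BBH) of
their protein sets under the filter triple bitscore >= 70, identity >=
30 %, and alignment covering >= 70 % of the query — the same filters used
to flag duplicated genes within one genome. Species delineation applies
the conventional thresholds: ANI < 94 % (corroborated by in-silico DDH <
70 % when available) separates species.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from ._util import reverse_complement, round_half_away


# --- ANI ------------------------------------------------------------------

@dataclass
class ANIResult:
    ani: float | None          # symmetric mean, percent
    ani_ab: float | None       # A fragments vs B
    ani_ba: float | None
    n_fragments_ab: int        # retained fragments
    n_fragments_ba: int
    indeterminate: bool = False


def _fragments(sequences: Sequence[str], fragment_len: int) -> list[str]:
    frags = []
    for seq in sequences:
        for i in range(0, len(seq) - fragment_len + 1, fragment_len):
            frags.append(seq[i:i + fragment_len])
    return frags


def _one_way_ani(frags: list[str], targets: Sequence[str],
                 min_identity_pct: float) -> tuple[float | None, int]:
    # k bounds the search: fragments below the identity cutoff are
    # discarded anyway, so edits beyond (1 - cutoff) * len need not be found
    idents = []
    both_strands = [t for t in targets] + [reverse_complement(t)
                                           for t in targets]
    for frag in frags:
        k = int(len(frag) * (1.0 - min_identity_pct / 100.0))
        best = None
        for t in both_strands:
            res = edlib.align(frag, t, mode="HW", task="distance", k=k)
            d = res["editDistance"]
            if d >= 0 and (best is None or d < best):
                best = d
                if best == 0:
                    break
        if best is None:
            continue
        ident = 100.0 * (1.0 - best / len(frag))
        if ident >= min_identity_pct:
            idents.append(ident)
    if not idents:
        return None, 0
    return float(np.mean(idents)), len(idents)


def ani(genome_a: Mapping[str, str] | Sequence[str],
        genome_b: Mapping[str, str] | Sequence[str],
        fragment_len: int = 1020,
        min_identity_pct: float = 60.0,
        min_frag_cov: float = 0.70) -> ANIResult:
    """Fragment-based ANI between two genomes (sets of sequences).

    Fragments shorter than ``fragment_len`` (trailing ends) are skipped.
    With the internal aligner every fragment is aligned end-to-end, so
    ``min_frag_cov`` only applies when ingesting tabular alignments via
    :func:`ani_from_alignments`. A genome pair with no retained fragment
    in either direction yields an indeterminate (flagged) result.
    """
    seqs_a = list(genome_a.values()) if isinstance(genome_a, Mapping) else list(genome_a)
    seqs_b = list(genome_b.values()) if isinstance(genome_b, Mapping) else list(genome_b)
    if not seqs_a or not seqs_b:
        raise ValueError("both genomes must be non-empty")
    if fragment_len < 100:
        raise ValueError("fragment_len must be >= 100")
    frags_a = _fragments(seqs_a, fragment_len)
    frags_b = _fragments(seqs_b, fragment_len)
    if not frags_a or not frags_b:
        raise ValueError("a genome is shorter than one fragment")
    ab, n_ab = _one_way_ani(frags_a, seqs_b, min_identity_pct)
    ba, n_ba = _one_way_ani(frags_b, seqs_a, min_identity_pct)
    vals = [v for v in (ab, ba) if v is not None]
    sym = float(np.mean(vals)) if vals else None
    return ANIResult(ani=sym, ani_ab=ab, ani_ba=ba,
                     n_fragments_ab=n_ab, n_fragments_ba=n_ba,
                     indeterminate=sym is None)


def ani_from_alignments(hits: pd.DataFrame,
                        min_identity_pct: float = 60.0,
                        min_frag_cov: float = 0.70) -> ANIResult:
    """One-directional ANI from a precomputed fragment alignment table
    (canonical alignment-hit columns, one best hit per fragment)."""
    ok = hits[
        (hits["percent_identity"] >= min_identity_pct)
        & (hits["query_aligned"] / hits["query_length"] >= min_frag_cov)
    ]
    if ok.empty:
        return ANIResult(ani=None, ani_ab=None, ani_ba=None,
                         n_fragments_ab=0, n_fragments_ba=0,
                         indeterminate=True)
    val = float(ok["percent_identity"].mean())
    return ANIResult(ani=val, ani_ab=val, ani_ba=None,
                     n_fragments_ab=len(ok), n_fragments_ba=0)


# --- gene-level comparison ------------------------------------------------

@dataclass(frozen=True)
class HitFilters:
    min_bitscore: float = 70.0
    min_identity: float = 30.0   # percent
    min_query_cov: float = 0.70  # fraction of query length aligned


def _apply_filters(hits: pd.DataFrame, f: HitFilters) -> pd.DataFrame:
    return hits[
        (hits["bitscore"] >= f.min_bitscore)
        & (hits["percent_identity"] >= f.min_identity)
        & (hits["query_aligned"] / hits["query_length"] >= f.min_query_cov)
    ]


def _best_per_query(hits: pd.DataFrame) -> dict[str, str]:
    """Best subject per query: bitscore, tie -> identity, tie -> smallest
    subject id."""
    best: dict[str, tuple[float, float, str]] = {}
    for r in hits.itertuples(index=False):
        # sort key: higher bitscore, higher identity, lexicographically
        # smaller subject (encoded by negating comparison at the end)
        cand = (r.bitscore, r.percent_identity, r.subject_id)
        cur = best.get(r.query_id)
        if cur is None:
            best[r.query_id] = cand
        else:
            if (cand[0], cand[1]) > (cur[0], cur[1]) or (
                    (cand[0], cand[1]) == (cur[0], cur[1])
                    and cand[2] < cur[2]):
                best[r.query_id] = cand
    return {q: v[2] for q, v in best.items()}


def bbh_shared_genes(hits_ab: pd.DataFrame, hits_ba: pd.DataFrame,
                     filters: HitFilters = HitFilters()
                     ) -> tuple[int, list[tuple[str, str]]]:
    """Bidirectional best hits between gene sets A and B.

    Both tables are filtered, each query keeps its best hit, and a pair
    (a, b) is shared iff best(a) = b and best(b) = a. Returns the count
    and the sorted pair list.
    """
    best_ab = _best_per_query(_apply_filters(hits_ab, filters))
    best_ba = _best_per_query(_apply_filters(hits_ba, filters))
    pairs = sorted((a, b) for a, b in best_ab.items()
                   if best_ba.get(b) == a)
    return len(pairs), pairs


def duplicated_genes(self_hits: pd.DataFrame, n_genes: int,
                     filters: HitFilters = HitFilters()
                     ) -> tuple[int, float]:
    """Putatively duplicated genes within one genome.

    A gene is duplicated iff it has at least one non-self hit passing the
    filters. Returns (count, percentage of all ``n_genes`` protein-coding
    genes, one decimal)."""
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    ok = _apply_filters(self_hits, filters)
    ok = ok[ok["query_id"] != ok["subject_id"]]
    count = int(ok["query_id"].nunique())
    return count, round_half_away(100.0 * count / n_genes, 1)


# --- species classification ----------------------------------------------

class Verdict(str, Enum):
    SAME_SPECIES = "same_species"
    DIFFERENT_SPECIES = "different_species"
    INDETERMINATE = "indeterminate"


@dataclass
class SpeciesCall:
    ani_pct: float
    ddh_pct: float | None
    verdict: Verdict


def classify_species(ani_pct: float, ddh_pct: float | None = None,
                     ani_threshold: float = 94.0,
                     ddh_threshold: float = 70.0) -> SpeciesCall:
    """Species delineation from ANI (and optionally in-silico DDH).

    Different species when ANI < 94 % — corroborated by DDH < 70 % when
    provided; same species when ANI >= 94 % and DDH (if given) >= 70 %;
    conflicting evidence yields an indeterminate call. DDH itself is never
    computed here; it is an externally supplied value.
    """
    if not 0.0 <= ani_pct <= 100.0:
        raise ValueError("ani_pct must lie in [0, 100]")
    if ddh_pct is not None and not 0.0 <= ddh_pct <= 100.0:
        raise ValueError("ddh_pct must lie in [0, 100]")
    ani_low = ani_pct < ani_threshold
    if ddh_pct is None:
        verdict = Verdict.DIFFERENT_SPECIES if ani_low else Verdict.SAME_SPECIES
    else:
        ddh_low = ddh_pct < ddh_threshold
        if ani_low and ddh_low:
            verdict = Verdict.DIFFERENT_SPECIES
        elif not ani_low and not ddh_low:
            verdict = Verdict.SAME_SPECIES
        else:
            verdict = Verdict.INDETERMINATE
    return SpeciesCall(ani_pct=ani_pct, ddh_pct=ddh_pct, verdict=verdict)
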