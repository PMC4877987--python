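"""Genome-bin extraction from two-dimensional coverage space.

Scaffolds of one genome share a characteristic pair of coverages across
two metagenomes of the same community, so they cluster in the plane of
(log10 coverage in sample 1, log10 coverage in sample 2). A bin is built
in three fixed stages, each recorded in the bin's provenance log:

1. ``coverage_select`` — scaffolds of sufficient length whose log-coverage
   point falls inside a selection region (polygon or ellipse);
2. ``tnf_removed`` — composition refinement drops scaffolds whose
   tetranucleotide signature separates from the bin core;
3. ``pe_rescued`` — paired-end links pull back scaffolds connected to the
   bin, recovering members excluded by coverage anomalies such as
   multi-copy elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .coverage import log10_coverage
from . import tnf as tnf_mod


@dataclass
class SelectionRegion:
    """A region in log10-coverage space plus a length floor for members.

    Either ``polygon`` (list of (x, y) vertices, closing edge implied,
    boundary inclusive) or ``ellipse`` ((cx, cy), (rx, ry)).
    """

    polygon: Sequence[tuple[float, float]] | None = None
    ellipse: tuple[tuple[float, float], tuple[float, float]] | None = None
    min_scaffold_len: int = 1000

    def __post_init__(self) -> None:
        if (self.polygon is None) == (self.ellipse is None):
            raise ValueError("provide exactly one of polygon or ellipse")
        if self.polygon is not None and len(self.polygon) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        if self.ellipse is not None:
            (_, _), (rx, ry) = self.ellipse
            if rx <= 0 or ry <= 0:
                raise ValueError("ellipse radii must be positive")

    def contains(self, x: float, y: float) -> bool:
        if self.polygon is not None:
            return Polygon(self.polygon).covers(Point(x, y))
        (cx, cy), (rx, ry) = self.ellipse
        return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 <= 1.0

    def to_dict(self) -> dict:
        d: dict = {"min_scaffold_len": self.min_scaffold_len}
        if self.polygon is not None:
            d["polygon"] = [list(v) for v in self.polygon]
        else:
            d["ellipse"] = {"center": list(self.ellipse[0]),
                            "radii": list(self.ellipse[1])}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SelectionRegion":
        if "polygon" in d:
            return cls(polygon=[tuple(v) for v in d["polygon"]],
                       min_scaffold_len=d.get("min_scaffold_len", 1000))
        e = d["ellipse"]
        return cls(ellipse=(tuple(e["center"]), tuple(e["radii"])),
                   min_scaffold_len=d.get("min_scaffold_len", 1000))


@dataclass
class GenomeBin:
    """A named scaffold set with a full inclusion/exclusion audit trail."""

    bin_id: str
    scaffold_ids: set[str] = field(default_factory=set)
    provenance: list[dict] = field(default_factory=list)

    def log(self, stage: str, scaffold_id: str, detail: str) -> None:
        self.provenance.append({"stage": stage, "scaffold_id": scaffold_id,
                                "detail": detail})

    def replay(self) -> set[str]:
        """Reconstruct membership from the provenance log."""
        members: set[str] = set()
        for ev in self.provenance:
            if ev["stage"] in ("coverage_select", "pe_rescued"):
                members.add(ev["scaffold_id"])
            elif ev["stage"] == "tnf_removed":
                members.discard(ev["scaffold_id"])
        return members

    def to_dict(self) -> dict:
        return {"bin_id": self.bin_id,
                "scaffold_ids": sorted(self.scaffold_ids),
                "provenance": list(self.provenance)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "GenomeBin":
        return cls(bin_id=d["bin_id"], scaffold_ids=set(d["scaffold_ids"]),
                   provenance=list(d.get("provenance", [])))


def _log_cov_points(profiles: pd.DataFrame,
                    sample_pair: tuple[str, str]) -> np.ndarray:
    cols = [f"cov_{sample_pair[0]}", f"cov_{sample_pair[1]}"]
    missing = [c for c in cols if c not in profiles.columns]
    if missing:
        raise KeyError(f"samples missing from coverage table: {missing}")
    return np.column_stack([log10_coverage(profiles[c]) for c in cols])


def select_by_coverage(profiles: pd.DataFrame, region: SelectionRegion,
                       sample_pair: tuple[str, str],
                       bin_id: str = "bin") -> GenomeBin:
    """Recruit scaffolds whose log10 coverage pair lies inside the region.

    Only scaffolds at least ``region.min_scaffold_len`` long are eligible;
    points on the region boundary are included. An empty selection is an
    error (the region likely needs widening).
    """
    pts = _log_cov_points(profiles, sample_pair)
    b = GenomeBin(bin_id=bin_id)
    for (sid, row), (x, y) in zip(profiles.iterrows(), pts):
        if row["length"] < region.min_scaffold_len:
            continue
        if region.contains(float(x), float(y)):
            b.scaffold_ids.add(sid)
            b.log("coverage_select", sid,
                  f"log10cov=({x:.3f},{y:.3f}) len={int(row['length'])}")
    if not b.scaffold_ids:
        raise ValueError(
            f"region selected no scaffolds for {bin_id}; widen the region")
    return b


def auto_seed_regions(profiles: pd.DataFrame,
                      sample_pair: tuple[str, str],
                      min_len: int = 10_000,
                      bandwidth: float = 0.2,
                      member_min_len: int = 1000,
                      min_cluster_weight: float = 10.0) -> list[SelectionRegion]:
    """Propose one selection region per coverage cluster.

    Density-based clustering (DBSCAN, eps = ``bandwidth`` in log10 units)
    of the log-coverage points of scaffolds >= ``min_len``, weighted by
    scaffold length in kb; each cluster yields its bounding box expanded
    by half a bandwidth. This automates what is otherwise drawn by eye on
    the coverage plot. Deterministic given inputs.
    """
    from sklearn.cluster import DBSCAN

    sel = profiles[profiles["length"] >= min_len]
    if sel.empty:
        raise ValueError(f"no scaffolds >= {min_len} bp to seed regions from")
    pts = _log_cov_points(sel, sample_pair)
    w = sel["length"].to_numpy(dtype=float) / 1000.0
    labels = DBSCAN(eps=bandwidth, min_samples=int(min_cluster_weight)).fit(
        pts, sample_weight=w).labels_
    regions: list[SelectionRegion] = []
    pad = bandwidth / 2.0
    for lab in sorted(set(labels) - {-1}):
        p = pts[labels == lab]
        x0, y0 = p.min(axis=0) - pad
        x1, y1 = p.max(axis=0) + pad
        regions.append(SelectionRegion(
            polygon=[(x0, y0), (x1, y0), (x1, y1), (x0, y1)],
            min_scaffold_len=member_min_len))
    return regions


def pe_rescue(bin_: GenomeBin, links: pd.DataFrame,
              coverage_profiles: pd.DataFrame,
              sample_pair: tuple[str, str],
              min_links: int = 2,
              max_cov_fold: float = 3.0) -> GenomeBin:
    """Re-attach scaffolds linked to the bin by paired-end evidence.

    A candidate joins when some current member is connected to it by at
    least ``min_links`` read pairs (the threshold applies per scaffold
    pair, so several independent single chimeric links never add up to an
    admission) and, in at least one sample, its coverage is no less than
    the bin's length-weighted median divided by ``max_cov_fold`` —
    coverage above the median is always admissible, because multi-copy
    elements legitimately exceed it. Iterates to a fixpoint; never
    removes members.
    """
    if min_links < 1:
        raise ValueError("min_links must be >= 1")
    out = GenomeBin(bin_id=bin_.bin_id,
                    scaffold_ids=set(bin_.scaffold_ids),
                    provenance=list(bin_.provenance))
    cols = [f"cov_{t}" for t in sample_pair]
    lengths = coverage_profiles["length"]

    def weighted_median(col: str) -> float:
        members = sorted(out.scaffold_ids & set(coverage_profiles.index))
        vals = coverage_profiles.loc[members, col].to_numpy(dtype=float)
        w = lengths.loc[members].to_numpy(dtype=float)
        order = np.argsort(vals)
        cw = np.cumsum(w[order])
        return float(vals[order][np.searchsorted(cw, cw[-1] / 2.0)])

    # adjacency with accumulated link counts
    neigh: dict[str, dict[str, int]] = {}
    for _, r in links.iterrows():
        a, b, n = r["scaffold_a"], r["scaffold_b"], int(r["n_links"])
        neigh.setdefault(a, {})[b] = neigh.setdefault(a, {}).get(b, 0) + n
        neigh.setdefault(b, {})[a] = neigh.setdefault(b, {}).get(a, 0) + n

    changed = True
    while changed:
        changed = False
        med = {c: weighted_median(c) for c in cols}
        candidates: dict[str, int] = {}  # best single pair-link count
        for m in out.scaffold_ids:
            for other, n in neigh.get(m, {}).items():
                if other in out.scaffold_ids:
                    continue
                candidates[other] = max(candidates.get(other, 0), n)
        for sid in sorted(candidates):
            n = candidates[sid]
            if n < min_links or sid not in coverage_profiles.index:
                continue
            covs = coverage_profiles.loc[sid, cols].to_numpy(dtype=float)
            ok = any(c >= med[col] / max_cov_fold
                     for c, col in zip(covs, cols))
            if ok:
                out.scaffold_ids.add(sid)
                out.log("pe_rescued", sid,
                        f"links={n} cov={covs.round(2).tolist()} "
                        f"median={[round(med[c], 2) for c in cols]}")
                changed = True
    return out


def extract_bin(profiles: pd.DataFrame,
                tnf_vectors: Mapping[str, np.ndarray],
                links: pd.DataFrame,
                region: SelectionRegion,
                sample_pair: tuple[str, str],
                bin_id: str = "bin",
                tnf_cutoff: float = 0.1,
                tnf_linkage: str = "average",
                tnf_scaling: str = "fraction",
                min_keep_fraction: float = 0.5,
                min_links: int = 2,
                max_cov_fold: float = 3.0) -> GenomeBin:
    """The full three-stage recruitment: coverage selection, composition
    refinement, paired-end rescue. Stage order is fixed; provenance is
    preserved across stages so membership can be replayed."""
    b = select_by_coverage(profiles, region, sample_pair, bin_id=bin_id)
    lengths = profiles["length"].to_dict()
    if len(b.scaffold_ids) >= 2:
        ref = tnf_mod.tnf_refine(sorted(b.scaffold_ids), tnf_vectors,
                                 lengths, cutoff=tnf_cutoff,
                                 linkage=tnf_linkage,
                                 min_keep_fraction=min_keep_fraction,
                                 scaling=tnf_scaling)
        for ev in ref.removals:
            if "scaffold_id" in ev:
                b.scaffold_ids.discard(ev["scaffold_id"])
                b.log("tnf_removed", ev["scaffold_id"],
                      f"merge_height={ev['merge_height']:.4f} "
                      f"cutoff={tnf_cutoff}")
    b = pe_rescue(b, links, profiles, sample_pair,
                  min_links=min_links, max_cov_fold=max_cov_fold)
    return b
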