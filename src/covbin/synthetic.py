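"""Fully labeled synthetic metagenome communities for pipeline testing.

The generator emulates the statistical structure differential-coverage
binning relies on, with ground truth attached to every object:

* genomes with distinct per-sample mean coverages (the two-sample
  "enrichment time points" design) and distinct base composition;
* fragmentation into scaffolds of at least 1 kb, recording adjacency;
* per-sample read-mapping summaries with Poisson read counts;
* single-copy marker genes planted with controlled dropout/duplication
  against the 107-member marker set;
* paired-end links between adjacent same-genome scaffolds plus optional
  cross-genome noise links;
* per-gene DNA/RNA read counts with a controlled active-gene fraction.

Composition model: an order-``k`` Markov chain whose conditional base
distributions are Dirichlet-perturbed per genome while the G+C mass of
every conditional is pinned to the genome's GC target. GC-only (order 0)
sequences of realistic divergence sit too close in tetranucleotide space
to exercise composition-based refinement at its conventional 0.1 cutoff
(expected distance 0.088 between GC 0.54 and 0.30), so genome-specific
k-mer usage bias is the default, as in real genomes; ``order=0`` gives the
plain GC model.

Every operation is a pure function of its inputs and seed.
"""

from __future__ import annotations

import json
import zlib
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import MappingSummary
from . import io as cio

_BASES = "ACGT"

#: fraction of library reads assumed to map back to the assembly; the
#: remainder models reads from unassembled community members
DEFAULT_MAPPED_FRACTION = 0.87


def _rng(seed: int, *keys: str | int) -> np.random.Generator:
    """Deterministic child generator for (seed, keys...)."""
    entropy = [int(seed)] + [
        k if isinstance(k, int) else zlib.crc32(k.encode()) for k in keys
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass
class GenomeModel:
    """Parameters of one synthetic genome."""

    genome_id: str
    length: int
    gc_content: float
    mean_coverage_by_sample: dict[str, float]
    n_marker_copies: dict[str, int] = field(default_factory=dict)
    active_gene_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.length < 10_000:
            raise ValueError("genome length must be >= 10,000 bp")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must lie strictly inside (0, 1)")
        if any(c <= 0 for c in self.mean_coverage_by_sample.values()):
            raise ValueError("coverage means must be positive")
        if not 0.0 <= self.active_gene_fraction <= 1.0:
            raise ValueError("active_gene_fraction must lie in [0, 1]")


@dataclass
class TruthTable:
    """Ground truth mapping every scaffold and gene to its genome."""

    scaffold_to_genome: dict[str, str]
    genes: pd.DataFrame  # gene_id, scaffold_id, start, end, strand,
    #                      genome_id, marker_id (or None), active (bool)
    adjacency: list[tuple[str, str]] = field(default_factory=list)

    def genome_of(self, scaffold_id: str) -> str:
        return self.scaffold_to_genome[scaffold_id]

    def to_json(self, path: str | Path) -> None:
        obj = {
            "scaffold_to_genome": self.scaffold_to_genome,
            "adjacency": [list(p) for p in self.adjacency],
            # round-trip through pandas JSON for native scalar types
            "genes": json.loads(self.genes.to_json(orient="records")),
        }
        cio.write_json(obj, path)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        obj = cio.read_json(path)
        genes = pd.DataFrame(obj["genes"])
        return cls(scaffold_to_genome=obj["scaffold_to_genome"],
                   genes=genes,
                   adjacency=[tuple(p) for p in obj["adjacency"]])


# --- sequence simulation --------------------------------------------------

def simulate_genome(genome_id: str, length: int, gc_content: float,
                    seed: int, order: int = 3,
                    concentration: float = 1.0) -> str:
    """Simulate a genome sequence with the given GC content.

    ``order=0`` draws bases i.i.d. with P(G)+P(C)=gc_content. For
    ``order>=1`` the conditionals of an order-``order`` Markov chain are
    sampled from a Dirichlet centered on the GC model (lower
    ``concentration`` = stronger genome-specific k-mer bias), then each
    conditional's G+C mass is renormalized back to gc_content so GC stays
    on target while k-mer usage varies between genomes.
    """
    if not 0.0 < gc_content < 1.0:
        raise ValueError("gc_content must lie strictly inside (0, 1)")
    if length < 10_000:
        raise ValueError("genome length must be >= 10,000 bp")
    rng = _rng(seed, "genome", genome_id)
    base = np.array([(1 - gc_content) / 2, gc_content / 2,
                     gc_content / 2, (1 - gc_content) / 2])
    if order == 0:
        draws = rng.choice(4, size=length, p=base)
        return "".join(_BASES[i] for i in draws)
    nctx = 4**order
    T = rng.dirichlet(4.0 * concentration * base + 1e-2, size=nctx)
    gc_mass = T[:, 1] + T[:, 2]
    at_mass = T[:, 0] + T[:, 3]
    T[:, 1] *= gc_content / gc_mass
    T[:, 2] *= gc_content / gc_mass
    T[:, 0] *= (1 - gc_content) / at_mass
    T[:, 3] *= (1 - gc_content) / at_mass
    cum = [row.cumsum().tolist() for row in T]
    out = [int(b) for b in rng.choice(4, size=order, p=base)]
    ctx = 0
    for b in out:
        ctx = ctx * 4 + b
    mask = nctx // 4 if order > 1 else 1
    u = rng.random(length).tolist()
    for j in range(order, length):
        row = cum[ctx]
        b = bisect_left(row, u[j])
        if b > 3:
            b = 3
        out.append(b)
        ctx = (ctx % mask) * 4 + b if order > 1 else b
    return "".join(_BASES[i] for i in out)


def mutate_sequence(sequence: str, rate: float, seed: int) -> str:
    """Substitute each base independently with probability ``rate``
    (always to a different base); a simple divergence model for ANI tests."""
    rng = _rng(seed, "mutate")
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    code = {ord(b): i for i, b in enumerate(_BASES)}
    lut = np.array([ord(b) for b in _BASES], dtype=np.uint8)
    for i in hit:
        cur = code.get(int(arr[i]))
        if cur is None:
            continue
        arr[i] = lut[(cur + rng.integers(1, 4)) % 4]
    return arr.tobytes().decode("ascii")


def fragment_genome(sequence: str, min_len: int = 1000,
                    mean_len: int = 10_000, seed: int = 0,
                    id_prefix: str = "s") -> tuple[dict[str, str],
                                                   list[tuple[str, str]]]:
    """Tile a genome into non-overlapping scaffolds of at least ``min_len``.

    Scaffold lengths are exponential around ``mean_len`` (clipped below at
    ``min_len``); a too-short terminal remainder is absorbed into the last
    scaffold, so concatenating the scaffolds in order reproduces the
    genome byte-for-byte. Returns the ordered scaffolds and the list of
    adjacent pairs (used to simulate paired-end links).
    """
    if min_len < 1000:
        raise ValueError("min_len must be >= 1000 bp")
    n = len(sequence)
    if n < min_len:
        raise ValueError(f"genome of {n} bp is shorter than min_len={min_len}")
    rng = _rng(seed, "fragment", id_prefix)
    cuts: list[int] = []
    pos = 0
    while n - pos >= min_len:
        ln = max(min_len, int(round(rng.exponential(mean_len))))
        if n - pos - ln < min_len:  # absorb the remainder
            ln = n - pos
        cuts.append(ln)
        pos += ln
    scaffolds: dict[str, str] = {}
    start = 0
    for i, ln in enumerate(cuts):
        scaffolds[f"{id_prefix}_{i:04d}"] = sequence[start:start + ln]
        start += ln
    ids = list(scaffolds)
    adjacency = list(zip(ids[:-1], ids[1:]))
    return scaffolds, adjacency


# --- mapping --------------------------------------------------------------

def simulate_mapping(
    scaffold_lengths: Mapping[str, int],
    scaffold_to_genome: Mapping[str, str],
    models: Mapping[str, GenomeModel],
    sample_ids: Sequence[str],
    read_len: int = 100,
    seed: int = 0,
    mapped_fraction: float = DEFAULT_MAPPED_FRACTION,
) -> dict[str, MappingSummary]:
    """Per-sample mapping summaries with Poisson read counts.

    For scaffold s of genome g in sample t, mapped reads ~
    Poisson(mean_coverage[g][t] * len(s) / read_len) and mapped bases =
    count * read_len, so the realized coverage fluctuates around the
    generating mean. The library size inflates the mapped total by
    1/mapped_fraction, modelling reads from unassembled genomes.
    """
    if read_len <= 0:
        raise ValueError("read_len must be positive")
    unknown = sorted(s for s in scaffold_lengths
                     if scaffold_to_genome.get(s) not in models)
    if unknown:
        raise KeyError(f"scaffolds with unknown genome: {unknown[:10]}")
    out: dict[str, MappingSummary] = {}
    for t in sample_ids:
        rng = _rng(seed, "mapping", t)
        reads: dict[str, int] = {}
        bases: dict[str, int] = {}
        for sid in sorted(scaffold_lengths):
            g = models[scaffold_to_genome[sid]]
            cov = g.mean_coverage_by_sample.get(t, 0.0)
            lam = cov * scaffold_lengths[sid] / read_len
            count = int(rng.poisson(lam)) if lam > 0 else 0
            reads[sid] = count
            bases[sid] = count * read_len
        total = int(np.ceil(sum(reads.values()) / mapped_fraction))
        out[t] = MappingSummary(sample_id=t, mapped_reads=reads,
                                mapped_bases=bases, total_reads=max(total, 1))
    return out


# --- genes, markers, links, expression ------------------------------------

def lay_genes(
    scaffold_lengths: Mapping[str, int],
    scaffold_to_genome: Mapping[str, str],
    models: Mapping[str, GenomeModel],
    gene_length: int = 900,
    gene_spacing: int = 1100,
    seed: int = 0,
) -> pd.DataFrame:
    """Tile genes onto scaffolds and assign active flags per genome.

    Genes are ``gene_length`` bp at a fixed ``gene_spacing`` period
    (1-based inclusive coordinates, strand random). Exactly
    round(active_gene_fraction * n_genes) genes per genome are marked
    active, so the planted fraction is controlled rather than binomially
    sampled.
    """
    rows = []
    for sid in sorted(scaffold_lengths):
        gid = scaffold_to_genome[sid]
        ln = scaffold_lengths[sid]
        n = max(0, (ln - 100) // gene_spacing)
        rng = _rng(seed, "genes", sid)
        strands = rng.choice(["+", "-"], size=n)
        for i in range(n):
            start = 101 + i * gene_spacing
            end = start + gene_length - 1
            if end > ln:
                break
            rows.append((f"{sid}_g{i:03d}", sid, start, end, strands[i],
                         gid, None, False))
    genes = pd.DataFrame(rows, columns=["gene_id", "scaffold_id", "start",
                                        "end", "strand", "genome_id",
                                        "marker_id", "active"])
    for gid, model in models.items():
        idx = genes.index[genes["genome_id"] == gid]
        n_active = int(round(model.active_gene_fraction * len(idx)))
        rng = _rng(seed, "active", gid)
        chosen = rng.choice(idx, size=n_active, replace=False)
        genes.loc[chosen, "active"] = True
    return genes


def plant_markers(
    genes: pd.DataFrame,
    marker_ids: Sequence[str],
    dropout_map: Mapping[str, Sequence[str]] | None = None,
    duplication_map: Mapping[str, Sequence[str] | Mapping[str, int]] | None = None,
    seed: int = 0,
    genomes: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, dict[str, float]]]:
    """Plant single-copy marker genes with controlled dropout/duplication.

    Each genome gets one copy of every marker in the set, minus the
    markers listed in ``dropout_map[genome]``, plus extra copies for the
    markers in ``duplication_map[genome]`` (a list means one extra copy
    each). Copies are assigned to distinct existing genes of the genome.

    Returns (marker hit table, updated gene table, truth QC per genome):
    truth completeness = 100*(|set|-dropouts)/|set| and truth redundancy =
    100*duplicated/(|set|-dropouts). A marker both dropped and duplicated
    in the same genome is an error.
    """
    dropout_map = dropout_map or {}
    duplication_map = duplication_map or {}
    marker_set = list(marker_ids)
    genes = genes.copy()
    target_genomes = sorted(set(genomes) if genomes is not None
                            else set(genes["genome_id"]))
    hit_rows = []
    truth: dict[str, dict[str, float]] = {}
    for gid in target_genomes:
        drops = set(dropout_map.get(gid, ()))
        dups_in = duplication_map.get(gid, ())
        dups: dict[str, int] = (dict(dups_in) if isinstance(dups_in, Mapping)
                                else {m: 1 for m in dups_in})
        bad = drops & set(dups)
        if bad:
            raise ValueError(
                f"genome {gid}: markers both dropped and duplicated: {sorted(bad)}")
        unknown = (drops | set(dups)) - set(marker_set)
        if unknown:
            raise ValueError(
                f"genome {gid}: markers not in the set: {sorted(unknown)}")
        present = [m for m in marker_set if m not in drops]
        copies = [(m, 1 + dups.get(m, 0)) for m in present]
        total_copies = sum(c for _, c in copies)
        pool = genes.index[(genes["genome_id"] == gid)
                           & genes["marker_id"].isna()]
        if len(pool) < total_copies:
            raise ValueError(
                f"genome {gid}: {len(pool)} genes available but "
                f"{total_copies} marker copies requested")
        rng = _rng(seed, "markers", gid)
        chosen = rng.choice(pool, size=total_copies, replace=False)
        k = 0
        for m, c in copies:
            for _ in range(c):
                gi = chosen[k]
                k += 1
                genes.loc[gi, "marker_id"] = m
                hit_rows.append((genes.loc[gi, "gene_id"],
                                 genes.loc[gi, "scaffold_id"], m))
        n_ident = len(present)
        n_dup = len(dups)
        truth[gid] = {
            "n_identified": n_ident,
            "n_duplicated": n_dup,
            "completeness_pct": 100.0 * n_ident / len(marker_set),
            "redundancy_pct": (100.0 * n_dup / n_ident) if n_ident else 0.0,
        }
    hits = pd.DataFrame(hit_rows,
                        columns=["gene_id", "scaffold_id", "marker_id"])
    return hits, genes, truth


def simulate_pe_links(
    adjacency: Sequence[tuple[str, str]],
    scaffold_to_genome: Mapping[str, str],
    n_links_adjacent: int = 5,
    n_noise_links: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired-end link table: adjacent same-genome scaffolds share
    ``n_links_adjacent`` links; ``n_noise_links`` single links are added
    between distinct random cross-genome scaffold pairs (one link each,
    modelling isolated chimeric read pairs)."""
    if n_links_adjacent < 1:
        raise ValueError("n_links_adjacent must be >= 1")
    counts: dict[tuple[str, str], int] = {}
    for a, b in adjacency:
        key = (min(a, b), max(a, b))
        counts[key] = counts.get(key, 0) + n_links_adjacent
    ids = sorted(scaffold_to_genome)
    rng = _rng(seed, "links")
    added = 0
    guard = 0
    while added < n_noise_links and guard < 1000 * max(1, n_noise_links):
        guard += 1
        a, b = rng.choice(ids, size=2, replace=False)
        if scaffold_to_genome[a] == scaffold_to_genome[b]:
            continue
        key = (min(a, b), max(a, b))
        if key in counts:
            continue
        counts[key] = 1
        added += 1
    rows = [(a, b, n) for (a, b), n in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["scaffold_a", "scaffold_b", "n_links"])


def simulate_expression(
    genes: pd.DataFrame,
    models: Mapping[str, GenomeModel],
    rna_library_size: int = 200_000,
    dna_library_size: int = 500_000,
    seed: int = 0,
    dna_sample: str | None = None,
) -> pd.DataFrame:
    """Per-gene DNA and RNA read counts.

    DNA counts are Poisson with rate proportional to gene length times the
    genome's coverage (in ``dna_sample``, or the mean over samples);
    inactive genes get zero RNA, active genes get Poisson RNA counts with
    rate proportional to length times a genome-specific activity
    multiplier. Rates are scaled so expected totals match the library
    sizes.
    """
    if rna_library_size <= 0 or dna_library_size <= 0:
        raise ValueError("library sizes must be positive")
    rng = _rng(seed, "expression")
    glen = (genes["end"] - genes["start"] + 1).to_numpy(dtype=float)

    def genome_cov(gid: str) -> float:
        m = models[gid]
        if dna_sample is not None:
            return m.mean_coverage_by_sample[dna_sample]
        return float(np.mean(list(m.mean_coverage_by_sample.values())))

    cov = genes["genome_id"].map(genome_cov).to_numpy(dtype=float)
    dna_w = glen * cov
    dna_counts = rng.poisson(dna_library_size * dna_w / dna_w.sum())

    mult = {gid: float(_rng(seed, "activity_mult", gid).lognormal(0.0, 0.5))
            for gid in models}
    rna_w = np.where(genes["active"].to_numpy(bool),
                     glen * genes["genome_id"].map(mult).to_numpy(float), 0.0)
    if rna_w.sum() > 0:
        rna_counts = rng.poisson(rna_library_size * rna_w / rna_w.sum())
    else:
        rna_counts = np.zeros(len(genes), dtype=int)
    return pd.DataFrame({"gene_id": genes["gene_id"],
                         "dna_count": dna_counts.astype(int),
                         "rna_count": rna_counts.astype(int)})


# --- whole communities ----------------------------------------------------

@dataclass
class Community:
    """A simulated community plus all derived evidence tables and truth."""

    models: dict[str, GenomeModel]
    scaffolds: dict[str, str]
    truth: TruthTable
    mappings: dict[str, MappingSummary]
    markers: pd.DataFrame
    links: pd.DataFrame
    expression: pd.DataFrame
    truth_qc: dict[str, dict[str, float]]
    marker_set_id: str = "ESCG107"

    @property
    def scaffold_lengths(self) -> dict[str, int]:
        return {s: len(seq) for s, seq in self.scaffolds.items()}

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the community through its public file formats."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["scaffolds"] = outdir / "scaffolds.fasta"
        cio.write_fasta(self.scaffolds, paths["scaffolds"])
        for t, m in self.mappings.items():
            p = outdir / f"mapping_{t}.tsv"
            cio.write_mapping_tsv(m, p)
            paths[f"mapping_{t}"] = p
        paths["markers"] = outdir / "markers.tsv"
        cio.write_tsv(self.markers, paths["markers"])
        paths["genes"] = outdir / "genes.tsv"
        cio.write_tsv(self.truth.genes[["gene_id", "scaffold_id", "start",
                                        "end", "strand"]], paths["genes"])
        paths["links"] = outdir / "links.tsv"
        cio.write_tsv(self.links, paths["links"])
        paths["expression"] = outdir / "expression.tsv"
        cio.write_tsv(self.expression, paths["expression"])
        paths["truth"] = outdir / "truth.json"
        self.truth.to_json(paths["truth"])
        return paths


def default_models(sample_ids: Sequence[str] = ("SE", "LE")
                   ) -> dict[str, GenomeModel]:
    """The standard four-genome community: coverage pairs separated at
    least five-fold in one sample, GC contents 0.40/0.54/0.65/0.54, and
    active-gene fractions spanning the range seen in curated genome bins,
    plus a low-GC contaminant whose coverage pair coincides with g2's."""
    se, le = sample_ids
    spec = [
        ("g1", 350_000, 0.54, {se: 100.0, le: 60.0}, 0.278),
        ("g2", 300_000, 0.40, {se: 20.0, le: 5.0}, 0.354),
        ("g3", 300_000, 0.65, {se: 4.0, le: 40.0}, 0.181),
        ("g4", 250_000, 0.54, {se: 400.0, le: 4.0}, 0.018),
        # coverage pair coincides with g1 so the contaminant scaffolds are
        # recruited into g1's region; composition (GC 0.30 vs 0.54) is what
        # must expose them
        ("contam", 16_000, 0.30, {se: 100.0, le: 60.0}, 0.10),
    ]
    return {gid: GenomeModel(genome_id=gid, length=ln, gc_content=gc,
                             mean_coverage_by_sample=cov,
                             active_gene_fraction=act)
            for gid, ln, gc, cov, act in spec}


#: Table-1-style dropout/duplication patterns for the default community
DEFAULT_DROPOUT = {"g1": 1, "g2": 2, "g3": 0, "g4": 1}
DEFAULT_DUPLICATION = {"g1": 4, "g2": 2, "g3": 4, "g4": 3}


def simulate_community(
    models: Mapping[str, GenomeModel] | None = None,
    seed: int = 0,
    marker_ids: Sequence[str] | None = None,
    marker_set_id: str = "ESCG107",
    dropout_counts: Mapping[str, int] | None = None,
    duplication_counts: Mapping[str, int] | None = None,
    min_scaffold_len: int = 1000,
    mean_scaffold_len: int = 10_000,
    read_len: int = 100,
    n_links_adjacent: int = 5,
    n_noise_links: int = 20,
    rna_library_size: int = 200_000,
    dna_library_size: int = 500_000,
) -> Community:
    """Generate a complete labeled community under the default conditions.

    Marker dropout/duplication counts follow the patterns of curated-bin
    QC (e.g. one marker missing and four duplicated). The genome named
    ``contam`` is split into exactly two scaffolds planted as composition
    contaminants and receives no markers.
    """
    if models is None:
        models = default_models()
    if marker_ids is None:
        from .markers import load_marker_set
        marker_ids = sorted(load_marker_set(marker_set_id).marker_ids)
    if dropout_counts is None:
        dropout_counts = DEFAULT_DROPOUT
    if duplication_counts is None:
        duplication_counts = DEFAULT_DUPLICATION

    sample_ids = sorted({t for m in models.values()
                         for t in m.mean_coverage_by_sample})

    scaffolds: dict[str, str] = {}
    scaffold_to_genome: dict[str, str] = {}
    adjacency: list[tuple[str, str]] = []
    for gid in sorted(models):
        m = models[gid]
        seq = simulate_genome(gid, m.length, m.gc_content, seed=seed)
        if gid == "contam":
            # two planted contaminant scaffolds, deliberate and exact
            half = len(seq) // 2
            frags = {f"{gid}_0000": seq[:half], f"{gid}_0001": seq[half:]}
            adj = [(f"{gid}_0000", f"{gid}_0001")]
        else:
            frags, adj = fragment_genome(seq, min_len=min_scaffold_len,
                                         mean_len=mean_scaffold_len,
                                         seed=seed, id_prefix=gid)
        scaffolds.update(frags)
        scaffold_to_genome.update({s: gid for s in frags})
        adjacency.extend(adj)

    lengths = {s: len(q) for s, q in scaffolds.items()}
    mappings = simulate_mapping(lengths, scaffold_to_genome, models,
                                sample_ids, read_len=read_len, seed=seed)
    genes = lay_genes(lengths, scaffold_to_genome, models, seed=seed)

    marker_list = list(marker_ids)
    pick = _rng(seed, "qc_patterns")
    dropout_map: dict[str, list[str]] = {}
    duplication_map: dict[str, list[str]] = {}
    marker_genomes = [g for g in sorted(models) if g != "contam"]
    for gid in marker_genomes:
        n_drop = int(dropout_counts.get(gid, 0))
        n_dup = int(duplication_counts.get(gid, 0))
        chosen = pick.choice(marker_list, size=n_drop + n_dup, replace=False)
        dropout_map[gid] = list(chosen[:n_drop])
        duplication_map[gid] = list(chosen[n_drop:])
    hits, genes, truth_qc = plant_markers(
        genes, marker_list, dropout_map, duplication_map, seed=seed,
        genomes=marker_genomes)

    links = simulate_pe_links(adjacency, scaffold_to_genome,
                              n_links_adjacent=n_links_adjacent,
                              n_noise_links=n_noise_links, seed=seed)
    expression = simulate_expression(genes, models,
                                     rna_library_size=rna_library_size,
                                     dna_library_size=dna_library_size,
                                     seed=seed, dna_sample=sample_ids[0])
    truth = TruthTable(scaffold_to_genome=scaffold_to_genome, genes=genes,
                       adjacency=adjacency)
    return Community(models=dict(models), scaffolds=scaffolds, truth=truth,
                     mappings=mappings, markers=hits, links=links,
                     expression=expression, truth_qc=truth_qc,
                     marker_set_id=marker_set_id)
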