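"""Genome comparison: fragment ANI, BBH shared genes, species calls."""

import numpy as np
import pandas as pd
import pytest

from covbin.compare import (HitFilters, Verdict, ani, ani_from_alignments,
                            bbh_shared_genes, classify_species,
                            duplicated_genes)
from covbin.synthetic import mutate_sequence, simulate_genome


@pytest.fixture(scope="module")
def genome():
    return simulate_genome("ref", 40_000, 0.5, seed=1)


class TestAni:
    def test_self_identity_is_exactly_100(self, genome):
        res = ani([genome], [genome], fragment_len=1020)
        assert res.ani == 100.0
        assert not res.indeterminate

    def test_mutation_rate_oracle(self, genome):
        """5 % per-base substitutions should yield ANI near 95 %."""
        mut = mutate_sequence(genome, 0.05, seed=2)
        res = ani([genome], [mut], fragment_len=1020)
        assert res.ani == pytest.approx(95.0, abs=1.0)

    def test_low_identity_fragments_excluded(self, genome):
        """A genome half-replaced by unrelated sequence keeps its ANI from
        the surviving fragments; the scrambled half is excluded rather
        than dragging the mean down toward 50 %."""
        unrelated = simulate_genome("x", 20_000, 0.5, seed=9)
        chimera = genome[:20_000] + unrelated
        res = ani([chimera], [genome], fragment_len=1020,
                  min_identity_pct=60.0)
        # ~19 of 39 fragments retained, all near-identical
        assert res.n_fragments_ab < 39
        assert res.ani_ab > 95.0

    def test_unrelated_genomes_flagged_indeterminate(self):
        a = simulate_genome("a", 15_000, 0.5, seed=3)
        b = simulate_genome("b", 15_000, 0.5, seed=4)
        res = ani([a], [b], fragment_len=1020, min_identity_pct=80.0)
        assert res.indeterminate
        assert res.ani is None

    def test_empty_genome_rejected(self, genome):
        with pytest.raises(ValueError):
            ani([], [genome])

    def test_tabular_ingestion_applies_cutoffs(self):
        hits = pd.DataFrame({
            "query_id": ["f1", "f2", "f3"],
            "subject_id": ["g", "g", "g"],
            "percent_identity": [95.0, 50.0, 70.0],
            "alignment_length": [1020, 1020, 1020],
            "bitscore": [100.0, 100.0, 100.0],
            "query_length": [1020, 1020, 1020],
            "query_aligned": [1020, 1020, 500],
        })
        res = ani_from_alignments(hits, min_identity_pct=60.0,
                                  min_frag_cov=0.70)
        # f2 fails identity, f3 fails coverage
        assert res.ani == 95.0
        assert res.n_fragments_ab == 1


def _hit(q, s, bits=100.0, ident=90.0, qlen=300, qal=300):
    return {"query_id": q, "subject_id": s, "percent_identity": ident,
            "alignment_length": qal, "bitscore": bits,
            "query_length": qlen, "query_aligned": qal}


def _bbh_oracle(hits_ab, hits_ba, f):
    """Exhaustive double loop, independent of the implementation."""
    def passes(h):
        return (h["bitscore"] >= f.min_bitscore
                and h["percent_identity"] >= f.min_identity
                and h["query_aligned"] / h["query_length"] >= f.min_query_cov)

    def best(hits):
        out = {}
        for h in hits:
            if not passes(h):
                continue
            q = h["query_id"]
            cur = out.get(q)
            if cur is None or (h["bitscore"], h["percent_identity"],
                               [-ord(c) for c in h["subject_id"]]) > (
                    cur["bitscore"], cur["percent_identity"],
                    [-ord(c) for c in cur["subject_id"]]):
                out[q] = h
        return {q: h["subject_id"] for q, h in out.items()}

    ba = best(hits_ba)
    return sorted((a, b) for a, b in best(hits_ab).items()
                  if ba.get(b) == a)


class TestBbh:
    def test_bitscore_boundary_inclusive_at_70(self):
        ab = [_hit("a1", "b1", bits=69.9)]
        ba = [_hit("b1", "a1", bits=70.0)]
        n, pairs = bbh_shared_genes(pd.DataFrame(ab), pd.DataFrame(ba))
        assert n == 0
        ab[0]["bitscore"] = 70.0
        n, pairs = bbh_shared_genes(pd.DataFrame(ab), pd.DataFrame(ba))
        assert pairs == [("a1", "b1")]

    def test_identical_gene_sets_all_shared(self):
        ab = [_hit(f"a{i}", f"b{i}") for i in range(20)]
        ba = [_hit(f"b{i}", f"a{i}") for i in range(20)]
        n, _ = bbh_shared_genes(pd.DataFrame(ab), pd.DataFrame(ba))
        assert n == 20

    def test_random_tables_match_double_loop_oracle(self):
        rng = np.random.default_rng(13)
        a_genes = [f"a{i}" for i in range(15)]
        b_genes = [f"b{i}" for i in range(12)]
        ab, ba = [], []
        for _ in range(120):
            ab.append(_hit(rng.choice(a_genes), rng.choice(b_genes),
                           bits=float(rng.uniform(40, 150)),
                           ident=float(rng.uniform(20, 100)),
                           qal=int(rng.uniform(120, 300))))
            ba.append(_hit(rng.choice(b_genes), rng.choice(a_genes),
                           bits=float(rng.uniform(40, 150)),
                           ident=float(rng.uniform(20, 100)),
                           qal=int(rng.uniform(120, 300))))
        f = HitFilters()
        n, pairs = bbh_shared_genes(pd.DataFrame(ab), pd.DataFrame(ba), f)
        assert pairs == _bbh_oracle(ab, ba, f)
        assert n <= min(len(a_genes), len(b_genes))

    def test_filters_are_monotone(self):
        rng = np.random.default_rng(29)
        ab = [_hit(f"a{i % 10}", f"b{rng.integers(10)}",
                   bits=float(rng.uniform(40, 150)),
                   ident=float(rng.uniform(20, 100))) for i in range(60)]
        ba = [_hit(f"b{i % 10}", f"a{rng.integers(10)}",
                   bits=float(rng.uniform(40, 150)),
                   ident=float(rng.uniform(20, 100))) for i in range(60)]
        loose = HitFilters(min_bitscore=50, min_identity=20,
                           min_query_cov=0.5)
        for tight in (HitFilters(min_bitscore=90, min_identity=20,
                                 min_query_cov=0.5),
                      HitFilters(min_bitscore=50, min_identity=60,
                                 min_query_cov=0.5),
                      HitFilters(min_bitscore=50, min_identity=20,
                                 min_query_cov=0.9)):
            n_loose, _ = bbh_shared_genes(pd.DataFrame(ab),
                                          pd.DataFrame(ba), loose)
            n_tight, _ = bbh_shared_genes(pd.DataFrame(ab),
                                          pd.DataFrame(ba), tight)
            assert n_tight <= n_loose


class TestDuplicatedGenes:
    def test_self_hit_only_not_duplicated(self):
        hits = pd.DataFrame([_hit("g1", "g1")])
        count, pct = duplicated_genes(hits, n_genes=10)
        assert (count, pct) == (0, 0.0)

    def test_identical_pair_both_counted(self):
        hits = pd.DataFrame([_hit("g1", "g1"), _hit("g1", "g2"),
                             _hit("g2", "g2"), _hit("g2", "g1")])
        count, pct = duplicated_genes(hits, n_genes=8)
        assert (count, pct) == (2, 25.0)

    def test_planted_fraction_recovered(self):
        """30 of 200 genes planted as duplicates come back exactly."""
        rows = []
        for i in range(200):
            rows.append(_hit(f"g{i}", f"g{i}"))
        for i in range(30):
            rows.append(_hit(f"g{i}", f"g{i + 500}"))
        count, pct = duplicated_genes(pd.DataFrame(rows), n_genes=200)
        assert (count, pct) == (30, 15.0)

    def test_filters_exclude_weak_hits(self):
        hits = pd.DataFrame([_hit("g1", "g2", ident=25.0)])
        assert duplicated_genes(hits, n_genes=4)[0] == 0


class TestClassifySpecies:
    @pytest.mark.parametrize("ani_pct,ddh,verdict", [
        (79.3, 17.7, Verdict.DIFFERENT_SPECIES),  # the curated-bin pair
        (100.0, 100.0, Verdict.SAME_SPECIES),
        (95.0, 60.0, Verdict.INDETERMINATE),
        (90.0, None, Verdict.DIFFERENT_SPECIES),
        (96.0, None, Verdict.SAME_SPECIES),
        (93.9, 80.0, Verdict.INDETERMINATE),
    ])
    def test_threshold_logic(self, ani_pct, ddh, verdict):
        assert classify_species(ani_pct, ddh).verdict == verdict

    @pytest.mark.parametrize("bad", [-1.0, 101.0])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            classify_species(bad)
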