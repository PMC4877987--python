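"""The community generator: determinism, conservation, parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from covbin.markers import MarkerSet, qc_report
from covbin.synthetic import (GenomeModel, fragment_genome, lay_genes,
                              mutate_sequence, plant_markers,
                              simulate_expression, simulate_genome,
                              simulate_mapping, simulate_pe_links)
from covbin.tnf import tnf_distance, tnf_vector


class TestSimulateGenome:
    def test_gc_content_on_target(self):
        seq = simulate_genome("g1", 100_000, 0.54, seed=1)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.52 <= gc <= 0.56

    def test_seed_determinism(self):
        a = simulate_genome("g1", 100_000, 0.54, seed=1)
        b = simulate_genome("g1", 100_000, 0.54, seed=1)
        assert a == b
        assert a != simulate_genome("g1", 100_000, 0.54, seed=2)

    @pytest.mark.parametrize("kw", [
        {"gc_content": 0.0}, {"gc_content": 1.2}, {"length": 500},
    ])
    def test_invalid_parameters(self, kw):
        args = {"genome_id": "g", "length": 50_000, "gc_content": 0.5,
                "seed": 0}
        args.update(kw)
        with pytest.raises(ValueError):
            simulate_genome(**args)

    def test_composition_separates_genomes(self):
        """Two genomes at GC 0.40 vs 0.65 are further apart in TNF space
        than the two halves of either genome are from each other — the
        premise of composition-based refinement."""
        a = simulate_genome("a", 100_000, 0.40, seed=1)
        b = simulate_genome("b", 100_000, 0.65, seed=2)
        between = tnf_distance(tnf_vector(a), tnf_vector(b))
        half_a = tnf_distance(tnf_vector(a[:50_000]), tnf_vector(a[50_000:]))
        half_b = tnf_distance(tnf_vector(b[:50_000]), tnf_vector(b[50_000:]))
        assert between > half_a
        assert between > half_b


class TestFragmentGenome:
    def test_conservation_and_length_floor(self):
        seq = simulate_genome("g", 100_000, 0.5, seed=3)
        frags, adjacency = fragment_genome(seq, min_len=1000, mean_len=10_000,
                                           seed=3, id_prefix="g")
        assert "".join(frags.values()) == seq
        assert sum(len(s) for s in frags.values()) == 100_000
        assert all(len(s) >= 1000 for s in frags.values())
        assert len(adjacency) == len(frags) - 1

    def test_breakpoint_determinism(self):
        seq = simulate_genome("g", 60_000, 0.5, seed=4)
        f1, _ = fragment_genome(seq, seed=5)
        f2, _ = fragment_genome(seq, seed=5)
        assert f1 == f2

    def test_short_genome_rejected(self):
        with pytest.raises(ValueError):
            fragment_genome("ACGT" * 100, min_len=1000)


def _toy_models():
    return {
        "a": GenomeModel("a", 50_000, 0.5, {"S": 100.0, "T": 10.0}),
        "b": GenomeModel("b", 50_000, 0.5, {"S": 5.0}),  # absent from T
    }


class TestSimulateMapping:
    def test_poisson_mean(self):
        models = _toy_models()
        lengths = {"a_0": 10_000}
        mapped = simulate_mapping(lengths, {"a_0": "a"}, models, ["S"],
                                  read_len=100, seed=1)
        count = mapped["S"].mapped_reads["a_0"]
        # expected 10,000 reads, sd 100
        assert abs(count - 10_000) < 5 * 100
        assert mapped["S"].mapped_bases["a_0"] == count * 100

    def test_zero_coverage_sample(self):
        models = _toy_models()
        mapped = simulate_mapping({"b_0": 20_000}, {"b_0": "b"}, models,
                                  ["T"], seed=1)
        assert mapped["T"].mapped_reads["b_0"] == 0

    def test_unknown_genome_is_an_error(self):
        with pytest.raises(KeyError):
            simulate_mapping({"x_0": 5000}, {"x_0": "nope"}, _toy_models(),
                             ["S"], seed=0)


def _genes_for(n_genomes=1, scaffolds_per_genome=4, seed=0, active=0.25):
    models = {}
    lengths = {}
    owner = {}
    for gi in range(n_genomes):
        gid = f"g{gi}"
        models[gid] = GenomeModel(gid, 200_000, 0.5, {"S": 10.0},
                                  active_gene_fraction=active)
        for si in range(scaffolds_per_genome):
            sid = f"{gid}_{si:04d}"
            lengths[sid] = 50_000
            owner[sid] = gid
    genes = lay_genes(lengths, owner, models, seed=seed)
    return models, lengths, owner, genes


class TestPlantMarkers:
    @pytest.mark.parametrize("size,n_drop,n_dup,comp,red", [
        (107, 1, 4, 106 / 107 * 100, 4 / 106 * 100),
        (107, 0, 0, 100.0, 0.0),
        (35, 2, 1, 33 / 35 * 100, 1 / 33 * 100),
    ])
    def test_truth_matches_forced_counts(self, size, n_drop, n_dup, comp,
                                         red):
        _, _, _, genes = _genes_for()
        markers = [f"M{i:03d}" for i in range(size)]
        hits, genes2, truth = plant_markers(
            genes, markers,
            dropout_map={"g0": markers[:n_drop]},
            duplication_map={"g0": markers[n_drop:n_drop + n_dup]},
            seed=1)
        assert truth["g0"]["completeness_pct"] == pytest.approx(comp)
        assert truth["g0"]["redundancy_pct"] == pytest.approx(red)
        assert len(hits) == size - n_drop + n_dup

    @pytest.mark.parametrize("size", [35, 107])
    def test_qc_round_trip_recovers_truth_exactly(self, size):
        """The marker-QC operations applied to the emitted hit table must
        reproduce the planted truth for any dropout/duplication pattern."""
        _, lengths, _, genes = _genes_for()
        markers = [f"M{i:03d}" for i in range(size)]
        hits, _, truth = plant_markers(
            genes, markers, dropout_map={"g0": markers[:3]},
            duplication_map={"g0": {markers[5]: 2, markers[6]: 1}}, seed=2)
        mset = MarkerSet("toy", frozenset(markers))
        report = qc_report(set(lengths), hits, mset)
        assert report.n_identified == truth["g0"]["n_identified"]
        assert report.n_duplicated == truth["g0"]["n_duplicated"]

    def test_conflicting_dropout_and_duplication(self):
        _, _, _, genes = _genes_for()
        with pytest.raises(ValueError, match="dropped and duplicated"):
            plant_markers(genes, ["M0", "M1"], dropout_map={"g0": ["M0"]},
                          duplication_map={"g0": ["M0"]}, seed=0)


class TestPeLinks:
    def test_link_graph_components_equal_genomes_without_noise(self):
        import networkx as nx

        _, lengths, owner, _ = _genes_for(n_genomes=3)
        adjacency = []
        for gid in {"g0", "g1", "g2"}:
            mine = sorted(s for s in owner if owner[s] == gid)
            adjacency += list(zip(mine[:-1], mine[1:]))
        links = simulate_pe_links(adjacency, owner, n_links_adjacent=4,
                                  n_noise_links=0, seed=0)
        g = nx.Graph()
        g.add_nodes_from(owner)
        g.add_edges_from(zip(links["scaffold_a"], links["scaffold_b"]))
        comps = list(nx.connected_components(g))
        assert len(comps) == 3
        assert all(len({owner[s] for s in c}) == 1 for c in comps)

    def test_adjacent_pair_link_count(self):
        owner = {"a_0": "a", "a_1": "a"}
        links = simulate_pe_links([("a_0", "a_1")], owner,
                                  n_links_adjacent=7, seed=0)
        assert links.loc[0, "n_links"] == 7

    def test_noise_links_cross_genomes(self):
        _, _, owner, _ = _genes_for(n_genomes=2)
        links = simulate_pe_links([], owner, n_links_adjacent=1,
                                  n_noise_links=10, seed=1)
        assert len(links) == 10
        for r in links.itertuples():
            assert owner[r.scaffold_a] != owner[r.scaffold_b]


class TestSimulateExpression:
    def test_inactive_genes_have_zero_rna(self):
        models, _, _, genes = _genes_for(active=0.3)
        expr = simulate_expression(genes, models, seed=1)
        merged = genes.merge(expr, on="gene_id")
        assert (merged.loc[~merged["active"], "rna_count"] == 0).all()

    def test_active_fraction_is_controlled(self):
        models, _, _, genes = _genes_for(n_genomes=2, scaffolds_per_genome=6,
                                         active=0.3)
        expr = simulate_expression(genes, models, seed=1)
        merged = genes.merge(expr, on="gene_id")
        frac = (merged["rna_count"] > 0).mean()
        assert abs(frac - 0.3) < 0.02

    def test_invalid_library_sizes(self):
        models, _, _, genes = _genes_for()
        with pytest.raises(ValueError):
            simulate_expression(genes, models, rna_library_size=0)


class TestMutate:
    def test_rate_and_determinism(self):
        seq = simulate_genome("g", 50_000, 0.5, seed=1)
        mut = mutate_sequence(seq, 0.05, seed=2)
        assert mut == mutate_sequence(seq, 0.05, seed=2)
        diff = sum(a != b for a, b in zip(seq, mut)) / len(seq)
        assert abs(diff - 0.05) < 0.005


class TestCommunityFixture:
    def test_truth_qc_matches_planted_patterns(self, community):
        got = {g: (round(v["completeness_pct"], 1),
                   round(v["redundancy_pct"], 1))
               for g, v in community.truth_qc.items()}
        assert got == {"g1": (99.1, 3.8), "g2": (98.1, 1.9),
                       "g3": (100.0, 3.7), "g4": (99.1, 2.8)}

    def test_every_scaffold_and_gene_has_one_genome(self, community):
        truth = community.truth
        assert set(truth.scaffold_to_genome) == set(community.scaffolds)
        genes = truth.genes
        assert genes["gene_id"].is_unique
        # gene intervals lie within scaffold bounds
        lens = pd.Series(community.scaffold_lengths)
        assert (genes["start"] >= 1).all()
        assert (genes["end"] <= genes["scaffold_id"].map(lens)).all()

    def test_write_round_trips_through_public_formats(self, community,
                                                      tmp_path):
        from covbin import io as cio
        from covbin.synthetic import TruthTable

        paths = community.write(tmp_path)
        seqs = cio.read_fasta(paths["scaffolds"])
        assert seqs == community.scaffolds
        m = cio.read_mapping_tsv(paths["mapping_SE"], sample_id="SE")
        assert m.total_reads == community.mappings["SE"].total_reads
        assert m.mapped_reads == community.mappings["SE"].mapped_reads
        truth = TruthTable.from_json(paths["truth"])
        assert truth.scaffold_to_genome == community.truth.scaffold_to_genome
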