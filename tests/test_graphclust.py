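"""Read-similarity graph construction, clustering, and annotation."""

import numpy as np
import pytest

from conftest import mutate, random_dna, reads_from, tile_reads
from repskim import synthgen as sg
from repskim.core import Read, ReadSet, revcomp
from repskim.graphclust import (LINEAGE_VOCAB, annotate_cluster, cluster_graph,
                                comparative_cluster, find_overlaps,
                                genome_proportion)


class TestFindOverlaps:
    def test_identical_reads_full_edge(self, rng):
        s = random_dna(rng, 140)
        sim = find_overlaps(reads_from([s, s]))
        assert sim.graph.number_of_edges() == 1
        (_, _, data), = sim.graph.edges(data=True)
        assert data["identity"] == 1.0
        assert data["overlap"] == 1.0

    def test_reverse_complement_detected(self, rng):
        s = random_dna(rng, 140)
        sim = find_overlaps(reads_from([s, revcomp(s)]))
        assert sim.graph.number_of_edges() == 1

    def test_exact_77bp_block_is_boundary_inclusive(self, rng):
        # 77 = ceil(0.55 * 140): an exact shared block of exactly that
        # length must produce an edge
        block = random_dna(rng, 77)
        a = block + random_dna(rng, 63)
        b = random_dna(rng, 63) + block
        sim = find_overlaps(reads_from([a, b]))
        assert sim.graph.number_of_edges() == 1
        (_, _, data), = sim.graph.edges(data=True)
        assert data["overlap"] >= 77 / 140

    def test_dissimilar_reads_no_edge(self, rng):
        sim = find_overlaps(reads_from([random_dna(rng, 140) for _ in range(10)]))
        assert sim.graph.number_of_edges() == 0

    def test_low_identity_no_edge(self, rng):
        a = random_dna(rng, 140)
        b = mutate(a, 56, rng)  # 60% identity
        sim = find_overlaps(reads_from([a, b]))
        assert sim.graph.number_of_edges() == 0

    def test_identity_just_below_threshold_rejected(self, rng):
        a = random_dna(rng, 140)
        b = mutate(a, 18, rng)  # ~87% ungapped identity
        sim = find_overlaps(reads_from([a, b]))
        assert sim.graph.number_of_edges() == 0

    def test_identity_above_threshold_accepted(self, rng):
        a = random_dna(rng, 140)
        b = mutate(a, 7, rng)  # 95% identity
        sim = find_overlaps(reads_from([a, b]))
        assert sim.graph.number_of_edges() == 1

    def test_non_uniform_lengths_rejected(self, rng):
        rs = reads_from([random_dna(rng, 140), random_dna(rng, 120)])
        with pytest.raises(ValueError):
            find_overlaps(rs)


class TestClusterGraph:
    def planted_readsets(self, rng, n_families=2, reads_per_family=40):
        # ~14x coverage keeps each family's overlap chain connected
        seqs, truth = [], []
        for f in range(n_families):
            template = random_dna(rng, 400)
            for s in tile_reads(template, 140, reads_per_family, rng):
                seqs.append(s)
                truth.append(f)
        return seqs, truth

    def test_two_planted_families_two_pure_clusters(self, rng):
        seqs, truth = self.planted_readsets(rng)
        rs = reads_from(seqs)
        clusters, _ = cluster_graph(find_overlaps(rs))
        assert len(clusters) == 2
        id2truth = {r.id: t for r, t in zip(rs, truth)}
        for c in clusters:
            fams = {id2truth[rid] for rid in c.read_ids}
            assert len(fams) == 1

    def test_complete_graph_single_cluster(self, rng):
        s = random_dna(rng, 140)
        rs = reads_from([s] * 50)
        clusters, unclustered = cluster_graph(find_overlaps(rs))
        assert len(clusters) == 1 and clusters[0].size == 50
        assert unclustered == []

    def test_singletons_pooled_unclustered(self, rng):
        rs = reads_from([random_dna(rng, 140) for _ in range(5)])
        clusters, unclustered = cluster_graph(find_overlaps(rs))
        assert clusters == [] and len(unclustered) == 5

    def test_clusters_ordered_by_size(self, rng):
        a = random_dna(rng, 140)
        b = random_dna(rng, 140)
        rs = reads_from([a] * 10 + [b] * 30)
        clusters, _ = cluster_graph(find_overlaps(rs))
        assert [c.size for c in clusters] == [30, 10]
        assert [c.cluster_id for c in clusters] == [1, 2]

    def test_invariant_under_read_order_permutation(self, rng):
        seqs, _ = self.planted_readsets(rng, 3, 30)
        rs1 = reads_from(seqs)
        order = rng.permutation(len(seqs))
        rs2 = reads_from([seqs[i] for i in order], prefix="q")
        part1 = {frozenset(sorted(rs1[int(i)].seq for i in range(len(rs1))
                                  if rs1[int(i)].id in set(c.read_ids)))
                 for c in cluster_graph(find_overlaps(rs1))[0]}
        part2 = {frozenset(sorted(rs2[int(i)].seq for i in range(len(rs2))
                                  if rs2[int(i)].id in set(c.read_ids)))
                 for c in cluster_graph(find_overlaps(rs2))[0]}
        assert part1 == part2

    def test_proportions_sum_to_100(self, rng):
        seqs, _ = self.planted_readsets(rng, 2, 25)
        seqs += [random_dna(rng, 140) for _ in range(10)]
        rs = reads_from(seqs)
        clusters, unclustered = cluster_graph(find_overlaps(rs))
        total = sum(c.genome_proportion for c in clusters)
        total += 100.0 * len(unclustered) / len(rs)
        assert total == pytest.approx(100.0)


class TestGenomeProportion:
    def test_above_threshold_flagged(self):
        p, flag = genome_proportion(150, 1_000_000)
        assert p == pytest.approx(0.015) and flag

    def test_zero_cluster(self):
        p, flag = genome_proportion(0, 100)
        assert p == 0.0 and not flag

    def test_threshold_is_strict(self):
        # exactly 0.01% is NOT annotated ("higher than" semantics)
        p, flag = genome_proportion(1, 10_000)
        assert p == pytest.approx(0.01) and not flag

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            genome_proportion(1, 0)


class TestAnnotateCluster:
    def make_cluster_and_reads(self, rng, template, n=40):
        seqs = tile_reads(template, 140, n, rng)
        rs = reads_from(seqs)
        clusters, _ = cluster_graph(find_overlaps(rs))
        assert len(clusters) == 1
        return clusters[0], {r.id: r.seq for r in rs}

    def test_reads_from_reference_get_its_lineage(self, rng):
        ref = random_dna(rng, 500)
        cluster, by_id = self.make_cluster_and_reads(rng, ref)
        label = annotate_cluster(cluster, by_id, [("ref1", "Ty3/gypsy: Athila", ref)])
        assert label == "Ty3/gypsy: Athila"

    def test_no_hits_unclassified(self, rng):
        cluster, by_id = self.make_cluster_and_reads(rng, random_dna(rng, 500))
        label = annotate_cluster(cluster, by_id,
                                 [("ref1", "Ty1/copia: Ale", random_dna(rng, 900))])
        assert label == "unclassified"

    def test_majority_vote_wins(self, rng):
        ref_a = random_dna(rng, 600)
        ref_b = random_dna(rng, 600)
        # build one cluster whose reads hit A (60%) or B (40%); join the
        # two read groups with a shared linker block so they cluster
        linker = random_dna(rng, 140)
        seqs = (tile_reads(ref_a, 140, 12, rng, both_strands=False)
                + tile_reads(ref_b, 140, 8, rng, both_strands=False)
                + [ref_a[:70] + linker[:70], linker[:70] + ref_b[-70:]])
        rs = reads_from(seqs + [linker])
        clusters, _ = cluster_graph(find_overlaps(rs))
        biggest = clusters[0]
        by_id = {r.id: r.seq for r in rs}
        label = annotate_cluster(
            biggest, by_id,
            [("a", "Ty3/gypsy: Athila", ref_a), ("b", "Ty3/gypsy: CRM", ref_b)])
        assert label == "Ty3/gypsy: Athila"

    def test_unknown_lineage_rejected(self, rng):
        cluster, by_id = self.make_cluster_and_reads(rng, random_dna(rng, 500))
        with pytest.raises(ValueError):
            annotate_cluster(cluster, by_id, [("x", "Made/Up: Thing", random_dna(rng, 500))])

    def test_vocabulary_is_controlled(self):
        assert "Ty3/gypsy: Athila" in LINEAGE_VOCAB
        assert "tandem" in LINEAGE_VOCAB
        assert len(LINEAGE_VOCAB) == 24


class TestComparativeCluster:
    def two_species_readsets(self, rng, shared=True):
        t = sg.make_species_tree(2, [1, 1], 0.1, 0, species_ids=["SPA1", "SPB1"])
        sharing = frozenset(["SPA1", "SPB1"]) if shared else frozenset(["SPA1"])
        fams = [sg.RepeatFamilySpec("SAT1", "tandem", 180, sharing)]
        lib = sg.evolve_repeat_library(t, fams, seed=1)
        readsets = {}
        for sid in ("SPA1", "SPB1"):
            fr = {"SAT1": 0.2} if sid in sharing else {}
            g = sg.build_genome(sg.SpeciesSpec(sid, sid[2], 0.05, fr), lib, seed=3)
            rs = sg.simulate_reads(g, 140, 0.3, 0.0, seed=4)
            readsets[sid] = rs
        return readsets

    def test_shared_family_has_both_species_and_cross_edges(self, rng):
        res = comparative_cluster(self.two_species_readsets(rng, True),
                                  {"SPA1": 0.05, "SPB1": 0.05})
        big = res.clusters[0]
        assert big.species_counts.get("SPA1", 0) > 0
        assert big.species_counts.get("SPB1", 0) > 0
        assert big.inter_species_edges.get(("SPA1", "SPB1"), 0) > 0

    def test_species_specific_family_single_species(self, rng):
        res = comparative_cluster(self.two_species_readsets(rng, False),
                                  {"SPA1": 0.05, "SPB1": 0.05})
        big = res.clusters[0]
        assert set(big.species_counts) == {"SPA1"}

    def test_abundance_matrix_percent_of_species_reads(self, rng):
        res = comparative_cluster(self.two_species_readsets(rng, True),
                                  {"SPA1": 0.05, "SPB1": 0.05})
        col = res.abundance["SPA1"]
        assert col.sum() <= 100.0 + 1e-9
        big = res.clusters[0]
        expected = 100.0 * big.species_counts["SPA1"] / res.sampled_counts["SPA1"]
        assert res.abundance.loc[big.cluster_id, "SPA1"] == pytest.approx(expected)

    def test_single_species_rejected(self, rng):
        with pytest.raises(ValueError):
            comparative_cluster({"SPA1": reads_from(["ACGT" * 35])}, {"SPA1": 1.0})


def test_planted_family_clustering_matches_truth_ari(rng):
    """Five well-separated families cluster with ARI >= 0.95 vs truth."""
    from sklearn.metrics import adjusted_rand_score

    seqs, truth = [], []
    for f in range(5):
        template = random_dna(rng, 600)
        for s in tile_reads(template, 140, 60, rng, error_rate=0.01):
            seqs.append(s)
            truth.append(f)
    rs = reads_from(seqs)
    clusters, unclustered = cluster_graph(find_overlaps(rs))
    id2cluster = {}
    for c in clusters:
        for rid in c.read_ids:
            id2cluster[rid] = c.cluster_id
    for i, rid in enumerate(unclustered):
        id2cluster[rid] = -(i + 1)
    labels = [id2cluster[r.id] for r in rs]
    assert adjusted_rand_score(truth, labels) >= 0.95
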