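"""The synthetic-data generator: trees, repeat evolution, genomes, reads."""

import io
import math

import numpy as np
import pytest

from repskim import synthgen as sg
from repskim.core import revcomp, write_fastq


def newick(tree):
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue()


class TestMakeSpeciesTree:
    def test_two_leaf_tree(self):
        t = sg.make_species_tree(2, [1, 1], 0.1, 7)
        tips = list(t.tips())
        assert len(tips) == 2
        assert all(tip.length > 0 for tip in tips)

    def test_four_clades_monophyletic(self):
        t = sg.make_species_tree(15, [6, 2, 6, 1], 0.1, 1)
        clades = sg.clade_map(t)
        by_clade = {}
        for sid, cid in clades.items():
            by_clade.setdefault(cid, set()).add(sid)
        assert sorted(len(v) for v in by_clade.values()) == [1, 2, 6, 6]
        # each multi-species clade is a monophyletic subtree
        for members in by_clade.values():
            if len(members) < 2:
                continue
            lca = t.lca([n for n in t.tips() if n.name in members])
            assert {x.name for x in lca.tips()} == members

    def test_seeded_determinism(self):
        a = sg.make_species_tree(8, [4, 4], 0.05, 3)
        b = sg.make_species_tree(8, [4, 4], 0.05, 3)
        assert newick(a) == newick(b)

    def test_all_branch_lengths_positive(self):
        t = sg.make_species_tree(15, [6, 2, 6, 1], 0.1, 5)
        for node in t.postorder(include_self=False):
            assert node.length is not None and node.length > 0

    def test_roughly_ultrametric_at_depth(self):
        t = sg.make_species_tree(10, [5, 5], 0.2, 2)
        depths = [sum(a.length for a in tip.ancestors() if a.length) + tip.length
                  for tip in t.tips()]
        assert all(0.1 < d <= 0.2 + 1e-9 for d in depths)
        assert max(depths) - min(depths) < 1e-9  # ultrametric

    def test_mismatched_clade_sizes_rejected(self):
        with pytest.raises(ValueError):
            sg.make_species_tree(5, [2, 2], 0.1, 0)


class TestEvolveRepeatLibrary:
    def test_zero_divergence_copies_identical(self):
        t = sg.make_species_tree(4, [2, 2], 0.1, 0)
        ids = frozenset(x.name for x in t.tips())
        spec = sg.RepeatFamilySpec("F1", "tandem", 180, ids, divergence=0.0)
        lib = sg.evolve_repeat_library(t, [spec], seed=1)
        root = lib.root_consensus["F1"]
        assert all(seq == root for seq in lib.species_consensus["F1"].values())

    def test_single_species_sharing(self):
        t = sg.make_species_tree(3, [2, 1], 0.1, 0)
        sid = sorted(x.name for x in t.tips())[0]
        spec = sg.RepeatFamilySpec("F1", "tandem", 100, frozenset([sid]))
        lib = sg.evolve_repeat_library(t, [spec], seed=1)
        assert set(lib.species_consensus["F1"]) == {sid}

    def test_unknown_species_rejected(self):
        t = sg.make_species_tree(2, [1, 1], 0.1, 0)
        spec = sg.RepeatFamilySpec("F1", "tandem", 100, frozenset(["NOPE"]))
        with pytest.raises(ValueError):
            sg.evolve_repeat_library(t, [spec], seed=1)

    def test_sister_pair_identity_matches_jc_expectation(self):
        # per-branch divergence 0.05 on each of two sister edges: the
        # pair is separated by d = 0.10 and expected per-site identity
        # is 1/4 + 3/4 exp(-4d/3)
        d_total = 0.10
        p_same = 0.25 + 0.75 * math.exp(-4 * d_total / 3)
        L, reps = 180, 100
        t = sg.make_species_tree(2, [1, 1], 0.1, 0)
        # two tips joined at the root: each root-child edge is one branch
        obs = []
        for seed in range(reps):
            spec = sg.RepeatFamilySpec(
                "F1", "tandem", L, frozenset(x.name for x in t.tips()),
                divergence=0.05)
            lib = sg.evolve_repeat_library(t, [spec], seed=seed)
            a, b = lib.species_consensus["F1"].values()
            obs.append(sum(x == y for x, y in zip(a, b)) / L)
        se = math.sqrt(p_same * (1 - p_same) / L / reps)
        assert abs(np.mean(obs) - p_same) < 3 * se

    def test_identity_decreases_with_tree_distance(self):
        # clock-like rates: sister species stay more similar than
        # cross-clade species, monotonically in tree distance
        t = sg.make_species_tree(6, [3, 3], 0.1, 4)
        ids = frozenset(x.name for x in t.tips())
        spec = sg.RepeatFamilySpec("F1", "TE", 1000, ids, rate=0.5)
        lib = sg.evolve_repeat_library(t, [spec], seed=2)
        tips = {x.name: x for x in t.tips()}
        dists, idents = [], []
        names = sorted(tips)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                dists.append(tips[a].distance(tips[b]))
                sa, sb = lib.species_consensus["F1"][a], lib.species_consensus["F1"][b]
                idents.append(sum(x == y for x, y in zip(sa, sb)) / len(sa))
        # correlation between distance and identity strongly negative
        r = np.corrcoef(dists, idents)[0, 1]
        assert r < -0.8


class TestBuildGenome:
    @pytest.fixture
    def simple_library(self):
        t = sg.make_species_tree(2, [1, 1], 0.1, 0, species_ids=["SP01", "SP02"])
        fams = [
            sg.RepeatFamilySpec("SAT1", "tandem", 180, frozenset(["SP01", "SP02"])),
            sg.RepeatFamilySpec("TE1", "TE", 500, frozenset(["SP01", "SP02"])),
        ]
        return sg.evolve_repeat_library(t, fams, seed=1)

    def test_tandem_array_copy_number_and_fraction(self, simple_library):
        spec = sg.SpeciesSpec("SP01", "A", 1.0, {"SAT1": 0.10})
        g = sg.build_genome(spec, simple_library, seed=2)
        assert len(g) == 1_000_000
        monomer = simple_library.species_consensus["SAT1"]["SP01"]
        n_copies = g.sequence.count(monomer)
        assert n_copies == round(0.10 * 1e6 / 180)  # ~555
        assert 0.099 <= g.realized_fractions["SAT1"] <= 0.101

    def test_zero_fractions_pure_background(self, simple_library):
        spec = sg.SpeciesSpec("SP01", "A", 0.1, {})
        g = sg.build_genome(spec, simple_library, seed=3)
        assert g.intervals == [] and g.realized_fractions == {}
        reads = sg.simulate_reads(g, 140, 0.2, 0.0, seed=1)
        assert all(r.family == "" for r in reads)

    def test_table_like_fractions_recovered(self, simple_library):
        spec = sg.SpeciesSpec("SP01", "A", 0.5, {"SAT1": 0.0444, "TE1": 0.17})
        g = sg.build_genome(spec, simple_library, seed=4)
        assert abs(g.realized_fractions["SAT1"] - 0.0444) < 0.002
        assert abs(g.realized_fractions["TE1"] - 0.17) < 0.002

    def test_too_small_tandem_fraction_dropped_with_warning(self, simple_library):
        spec = sg.SpeciesSpec("SP01", "A", 0.001, {"SAT1": 0.0001})
        g = sg.build_genome(spec, simple_library, seed=5)
        assert "SAT1" not in g.realized_fractions
        assert any("SAT1" in w for w in g.warnings)

    def test_intervals_disjoint_and_sorted(self, simple_library):
        spec = sg.SpeciesSpec("SP01", "A", 0.3, {"SAT1": 0.05, "TE1": 0.08})
        g = sg.build_genome(spec, simple_library, seed=6)
        prev_end = 0
        for s, e, _ in g.intervals:
            assert s >= prev_end and e > s
            prev_end = e


class TestSimulateReads:
    @pytest.fixture
    def genome(self):
        t = sg.make_species_tree(2, [1, 1], 0.1, 0, species_ids=["SP01", "SP02"])
        lib = sg.evolve_repeat_library(
            t, [sg.RepeatFamilySpec("SAT1", "tandem", 180, frozenset(["SP01"]))], 1)
        return sg.build_genome(sg.SpeciesSpec("SP01", "A", 1.0, {"SAT1": 0.1}), lib, 2)

    def test_read_count_formula(self, genome):
        rs = sg.simulate_reads(genome, 140, 0.5, 0.0, seed=1)
        assert len(rs) == round(0.5 * 1e6 / 140) == 3571

    def test_error_free_reads_are_substrings(self, genome):
        rs = sg.simulate_reads(genome, 140, 0.05, 0.0, seed=2)
        for r in list(rs)[:100]:
            assert r.seq in genome.sequence or revcomp(r.seq) in genome.sequence

    def test_same_seed_byte_identical_fastq(self, genome, tmp_path):
        for name in ("a", "b"):
            rs = sg.simulate_reads(genome, 140, 0.1, 0.01, seed=3)
            write_fastq(rs, tmp_path / f"{name}.fastq")
        assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()

    def test_zero_reads_rejected(self, genome):
        with pytest.raises(ValueError):
            sg.simulate_reads(genome, 140, 1e-7, 0.0, seed=1)

    def test_quality_encodes_error_rate(self, genome):
        rs = sg.simulate_reads(genome, 140, 0.01, 0.001, seed=4)
        assert int(rs[0].qual[0]) == 30  # -10 log10(0.001)

    def test_truth_families_roughly_match_fraction(self, genome):
        rs = sg.simulate_reads(genome, 140, 0.5, 0.0, seed=5)
        frac = sum(1 for r in rs if r.family == "SAT1") / len(rs)
        assert 0.07 < frac < 0.14


class TestScenario:
    def test_roundtrip_via_yaml_dict(self):
        sc = sg.four_clade_scenario(seed=3)
        d = sg.scenario_to_dict(sc)
        sc2 = sg.scenario_from_dict(d)
        assert [s.species_id for s in sc2.species] == [s.species_id for s in sc.species]
        assert {f.family_id for f in sc2.families} == {f.family_id for f in sc.families}

    def test_truth_fractions_match_requests(self):
        sc = sg.four_clade_scenario(seed=2)
        sc.species = sc.species[:3]
        keep = {s.species_id for s in sc.species}
        sc.families = [f for f in sc.families
                       if f.sharing & keep]
        for f in sc.families:
            f.sharing = frozenset(f.sharing & keep)
        sc.clade_sizes = [3]
        for s in sc.species:
            s.clade_id = "A"
        res = sg.run_scenario(sc)
        for s in sc.species:
            g = res.genomes[s.species_id]
            for fam, req in s.repeat_fractions.items():
                if fam in g.realized_fractions:
                    assert abs(g.realized_fractions[fam] - req) < 0.005

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            sg.SpeciesSpec("toolongid", "A", 1.0, {})
        with pytest.raises(ValueError):
            sg.SpeciesSpec("SP01", "A", 1.0, {"F": 1.2})
        with pytest.raises(ValueError):
            sg.RepeatFamilySpec("F", "tandem", 5, frozenset(["a"]))
        with pytest.raises(ValueError):
            sg.RepeatFamilySpec("F", "tandem", 100, frozenset())
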