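"""ANI estimation, single-linkage dereplication, representative
selection by the provenance priority ladder, and catalog comparison."""

import numpy as np
import pytest

from curdcat.dereplicate import (
    cluster_genomes,
    compare_catalogs,
    dereplicate,
    estimate_ani,
    select_representative,
)
from curdcat.records import ContigRecord, GenomeRecord, Provenance, Thresholds
from curdcat.simulate import (
    make_catalog_scenario,
    make_shared_catalogs,
    mutate_sequence,
    random_genome_sequence,
)

from conftest import make_genome


class TestEstimateAni:
    def test_self_identity_is_100(self):
        g = make_genome("g", length=10_000)
        assert estimate_ani(g, g) == 100.0

    def test_reverse_complement_is_100(self, rng):
        seq = random_genome_sequence(20_000, 0.5, rng)
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        a = make_genome("a", sequence=seq)
        b = make_genome("b", sequence=rc)
        assert estimate_ani(a, b) == pytest.approx(100.0, abs=1e-9)

    def test_matches_alignment_oracle_on_planted_variant(self, strain_pair):
        parent, variant, oracle = strain_pair
        a = make_genome("a", sequence=parent)
        b = make_genome("b", sequence=variant)
        assert estimate_ani(a, b) == pytest.approx(oracle, abs=0.5)

    def test_symmetric_and_contig_order_invariant(self, rng):
        seq = random_genome_sequence(20_000, 0.5, rng)
        var = mutate_sequence(seq, 0.01, rng)
        a = make_genome("a", sequence=seq, n_contigs=2)
        b = make_genome("b", sequence=var, n_contigs=3)
        b_shuffled = GenomeRecord("b2", list(reversed(b.contigs)))
        assert estimate_ani(a, b) == pytest.approx(estimate_ani(b, a), abs=1e-9)
        assert estimate_ani(a, b_shuffled) == pytest.approx(estimate_ani(a, b), abs=1e-9)

    def test_sketch_estimate_close_to_exact(self, strain_pair):
        parent, variant, _ = strain_pair
        a = make_genome("a", sequence=parent)
        b = make_genome("b", sequence=variant)
        exact = estimate_ani(a, b)
        sketched = estimate_ani(a, b, sketch_size=2000)
        assert sketched == pytest.approx(exact, abs=0.2)

    def test_bad_k_rejected(self):
        g = make_genome("g", length=1000)
        with pytest.raises(ValueError, match="odd"):
            estimate_ani(g, g, k=20)

    def test_genome_shorter_than_k_rejected(self):
        a = GenomeRecord("a", [ContigRecord("c", "ACGTACGTAC")])
        with pytest.raises(ValueError, match="shorter than k"):
            estimate_ani(a, a.__class__("b", [ContigRecord("d", "ACGTACGTAC")]))


class TestClusterGenomes:
    def test_identical_copies_form_one_cluster(self, rng):
        seq = random_genome_sequence(10_000, 0.5, rng)
        genomes = [make_genome(f"g{i}", sequence=seq) for i in range(3)]
        clusters = cluster_genomes(genomes)
        assert len(clusters) == 1
        assert clusters[0].member_ids == ["g0", "g1", "g2"]

    def test_planted_ani_95_splits_at_threshold_99(self, rng):
        seq = random_genome_sequence(50_000, 0.5, rng)
        var = mutate_sequence(seq, 0.05, rng)  # oracle ANI ~ 95
        genomes = [make_genome("a", sequence=seq), make_genome("b", sequence=var)]
        assert len(cluster_genomes(genomes)) == 2
        assert len(cluster_genomes(genomes, Thresholds(ani_same_genome=90.0))) == 1

    def test_single_linkage_chains_transitively(self, rng):
        # A~B and B~C above threshold but A~C below: one cluster of 3
        base = random_genome_sequence(60_000, 0.5, rng)
        b = mutate_sequence(base, 0.004, rng)   # ANI(A,B) ~ 99.6
        c = mutate_sequence(b, 0.004, rng)      # ANI(B,C) ~ 99.6, ANI(A,C) ~ 99.2
        genomes = [make_genome(g, sequence=s) for g, s in [("A", base), ("B", b), ("C", c)]]
        t = Thresholds(ani_same_genome=99.4)
        clusters = cluster_genomes(genomes, t)
        assert len(clusters) == 1
        assert clusters[0].pairwise_ani[frozenset(("A", "C"))] < 99.4

    def test_distinct_random_genomes_stay_singletons(self, rng):
        genomes = [make_genome(f"g{i}", length=10_000, seed=i) for i in range(4)]
        assert len(cluster_genomes(genomes)) == 4

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cluster_genomes([])


class TestSelectRepresentative:
    def _cluster(self, genomes):
        clusters = cluster_genomes(genomes, Thresholds(ani_same_genome=0.001))
        assert len(clusters) == 1
        return clusters[0]

    def test_isolate_beats_better_quality_mag(self, rng):
        seq = random_genome_sequence(10_000, 0.5, rng)
        isolate = make_genome("iso", sequence=seq, provenance=Provenance.ISOLATE,
                              completeness=85.0)
        circ = make_genome("circ", sequence=mutate_sequence(seq, 0.001, rng),
                           provenance=Provenance.TIMEPOINT, circular=True,
                           completeness=99.0)
        cluster = self._cluster([circ, isolate])
        assert select_representative(cluster, [circ, isolate]) == "iso"

    def test_priority_ladder_order(self, rng):
        seq = random_genome_sequence(10_000, 0.5, rng)
        mk = lambda gid, prov, circ: make_genome(
            gid, sequence=mutate_sequence(seq, 0.001, rng), provenance=prov,
            circular=circ, completeness=90.0, contamination=1.0)
        ladder = [
            mk("e_coasm_flat", Provenance.COASSEMBLY, False),
            mk("d_tp_flat", Provenance.TIMEPOINT, False),
            mk("c_coasm_circ", Provenance.COASSEMBLY, True),
            mk("b_tp_circ", Provenance.TIMEPOINT, True),
            mk("a_iso", Provenance.ISOLATE, False),
        ]
        genomes = list(ladder)
        while genomes:
            cluster = self._cluster(genomes)
            assert select_representative(cluster, genomes) == genomes[-1].genome_id
            genomes = genomes[:-1]

    def test_quality_score_tiebreak_completeness_minus_5x_contamination(self, rng):
        # (comp 98, cont 1) scores 93 and beats (comp 95, cont 0.5) at 92.5
        seq = random_genome_sequence(10_000, 0.5, rng)
        a = make_genome("a", sequence=seq, provenance=Provenance.COASSEMBLY,
                        completeness=98.0, contamination=1.0)
        b = make_genome("b", sequence=mutate_sequence(seq, 0.001, rng),
                        provenance=Provenance.COASSEMBLY,
                        completeness=95.0, contamination=0.5)
        cluster = self._cluster([b, a])
        assert select_representative(cluster, [a, b]) == "a"

    def test_singleton_returns_its_member(self):
        g = make_genome("only")
        clusters = cluster_genomes([g])
        assert select_representative(clusters[0], [g]) == "only"

    def test_invariant_to_member_order(self, rng):
        seq = random_genome_sequence(10_000, 0.5, rng)
        genomes = [
            make_genome(f"g{i}", sequence=mutate_sequence(seq, 0.001, rng),
                        provenance=Provenance.TIMEPOINT,
                        completeness=90.0 + i, contamination=1.0)
            for i in range(4)
        ]
        cluster = self._cluster(genomes)
        picks = {
            select_representative(cluster, order)
            for order in (genomes, genomes[::-1], genomes[2:] + genomes[:2])
        }
        assert picks == {"g3"}


class TestCatalogRecovery:
    def test_planted_clusters_recovered_exactly(self):
        genomes, truth = make_catalog_scenario(n_base=6, n_variants=2, rate=0.002,
                                               genome_length_bp=20_000, seed=77)
        clusters = dereplicate(genomes)
        assert len(clusters) == 6
        got = {frozenset(c.member_ids) for c in clusters}
        expected = {frozenset(v["members"]) for v in truth.values()}
        assert got == expected
        by_members = {frozenset(c.member_ids): c for c in clusters}
        for v in truth.values():
            if v["isolate"] is not None:
                assert by_members[frozenset(v["members"])].representative_id == v["isolate"]


class TestCompareCatalogs:
    def test_identical_genome_across_three_catalogs(self, rng):
        seq = random_genome_sequence(10_000, 0.5, rng)
        catalogs = {
            name: [make_genome(f"{name}.shared", sequence=seq),
                   make_genome(f"{name}.own", length=10_000, seed=ord(name))]
            for name in "ABC"
        }
        cmp = compare_catalogs(catalogs)
        assert len(cmp.shared_all) == 1
        assert cmp.unique == {"A": 1, "B": 1, "C": 1}

    def test_disjoint_catalogs_have_no_shared_groups(self, rng):
        catalogs = {
            "A": [make_genome("A.g1", length=8000, seed=1)],
            "B": [make_genome("B.g1", length=8000, seed=2),
                  make_genome("B.g2", length=8000, seed=3)],
        }
        cmp = compare_catalogs(catalogs)
        assert cmp.pairwise_shared == {}
        assert cmp.unique == {"A": 1, "B": 2}

    def test_planted_venn_structure_recovered(self):
        # mirrors the three-community overlap design: 6 groups in all
        # three catalogs, 8 in A and B only
        catalogs, truth = make_shared_catalogs(seed=5)
        cmp = compare_catalogs(catalogs)
        assert len(cmp.shared_all) == truth["shared_all"]
        assert cmp.pairwise_shared.get(frozenset(("A", "B"))) == truth["shared_ab_only"]
        assert cmp.unique == truth["unique"]
        # invariant: every genome accounted for exactly once
        for name, size in cmp.catalog_sizes.items():
            n = sum(
                sum(1 for m in group if m.startswith(f"{name}."))
                for groups in cmp.regions.values()
                for group in groups
            )
            assert n == size
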