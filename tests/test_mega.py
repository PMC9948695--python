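"""Overlap detection, the 90%-containment redundancy rule, mega-assembly
merging, and MGE candidate length selection — checked against an
independent edlib infix-alignment oracle."""

import edlib
import pytest

from curdcat.mega import (
    build_mega_assembly,
    find_overlaps,
    remove_redundant,
    select_mge_candidates,
)
from curdcat.records import ContigRecord, Thresholds
from curdcat.simulate import make_redundancy_scenario, random_genome_sequence

from conftest import make_genome

_RC = str.maketrans("ACGT", "TGCA")


def oracle_redundant(contigs, frac=0.90, max_sub_rate=0.01):
    """Independent containment oracle: a contig is redundant iff >= frac
    of it aligns (edlib infix mode, either strand) into a longer retained
    contig at <= max_sub_rate errors, resolved shortest-first as the
    removal rule prescribes. Valid for substitution-only planted data."""
    retained = {c.contig_id for c in contigs}
    by_len = sorted(contigs, key=lambda c: (c.length_bp, c.contig_id))
    for q in by_len:
        budget = int(max_sub_rate * q.length_bp * frac + 0.5)
        for s in contigs:
            if s.contig_id == q.contig_id or s.contig_id not in retained:
                continue
            if not (s.length_bp > q.length_bp or
                    (s.length_bp == q.length_bp and s.contig_id < q.contig_id)):
                continue
            for target in (s.sequence, s.sequence.translate(_RC)[::-1]):
                # infix alignment of the covered prefix of q (>= frac of it)
                core = q.sequence[: int(frac * q.length_bp)]
                d = edlib.align(core, target, mode="HW", task="distance")["editDistance"]
                if d >= 0 and d <= budget:
                    retained.discard(q.contig_id)
                    break
            if q.contig_id not in retained:
                break
    return {c.contig_id for c in contigs} - retained


class TestFindOverlaps:
    def test_exact_containment_hit(self, rng):
        a = ContigRecord("A", random_genome_sequence(10_000, 0.5, rng))
        b = ContigRecord("B", a.sequence[200:9700])  # 95% of A
        hits = {(h.query_id, h.subject_id): h for h in find_overlaps([a, b])}
        h = hits[("B", "A")]
        assert h.identity == pytest.approx(100.0)
        assert h.query_coverage >= 0.99
        assert hits[("A", "B")].query_coverage >= 0.94

    def test_unrelated_contigs_share_no_20mer(self, rng):
        a = ContigRecord("A", random_genome_sequence(10_000, 0.5, rng))
        b = ContigRecord("B", random_genome_sequence(10_000, 0.5, rng))
        # oracle: exhaustive word intersection of the generated pair
        words = lambda s: {s[i:i + 20] for i in range(len(s) - 19)}
        rc = b.sequence.translate(_RC)[::-1]
        assert not (words(a.sequence) & (words(b.sequence) | words(rc)))
        assert find_overlaps([a, b]) == []

    def test_reverse_complement_half_covered(self, rng):
        a = ContigRecord("A", random_genome_sequence(8_000, 0.5, rng))
        b = ContigRecord("B", a.sequence[:4000].translate(_RC)[::-1])
        hits = {(h.query_id, h.subject_id): h for h in find_overlaps([a, b])}
        assert hits[("B", "A")].query_coverage == pytest.approx(1.0, abs=0.01)
        assert hits[("A", "B")].query_coverage == pytest.approx(0.5, abs=0.01)

    def test_no_self_hits(self, rng):
        a = ContigRecord("A", random_genome_sequence(5_000, 0.5, rng))
        assert all(h.query_id != h.subject_id for h in find_overlaps([a, a.__class__("B", a.sequence)]))


class TestRemoveRedundant:
    def test_contained_smaller_contig_removed(self, rng):
        a = ContigRecord("A", random_genome_sequence(10_000, 0.5, rng))
        b = ContigRecord("B", a.sequence[1000:6000])
        kept = remove_redundant([a, b])
        assert [c.contig_id for c in kept] == ["A"]

    def test_85_percent_overlap_keeps_both(self, rng):
        a = ContigRecord("A", random_genome_sequence(10_000, 0.5, rng))
        shared = a.sequence[:3400]  # 85% of B's 4000 bp
        b = ContigRecord("B", shared + random_genome_sequence(600, 0.5, rng))
        kept = remove_redundant([a, b])
        assert {c.contig_id for c in kept} == {"A", "B"}

    def test_containment_chain_cascades_to_largest(self, rng):
        a = ContigRecord("A", random_genome_sequence(10_000, 0.5, rng))
        b = ContigRecord("B", a.sequence[2000:7000])
        c = ContigRecord("C", b.sequence[1000:3000])
        kept = remove_redundant([c, a, b])
        assert [k.contig_id for k in kept] == ["A"]

    def test_equal_length_duplicates_keep_lexicographic_smaller(self, rng):
        seq = random_genome_sequence(5_000, 0.5, rng)
        kept = remove_redundant([ContigRecord("zeta", seq), ContigRecord("alpha", seq)])
        assert [c.contig_id for c in kept] == ["alpha"]

    def test_planted_scenario_recovers_exactly_the_redundants(self):
        contigs, truth = make_redundancy_scenario(
            n_unique=12, n_contained=6, n_partial=3, seed=101)
        kept = remove_redundant(contigs)
        removed = {c.contig_id for c in contigs} - {c.contig_id for c in kept}
        assert removed == truth

    def test_idempotent_and_no_residual_redundancy(self):
        contigs, _ = make_redundancy_scenario(
            n_unique=8, n_contained=4, n_partial=2, seed=7)
        t = Thresholds()
        kept = remove_redundant(contigs, t=t)
        again = remove_redundant(kept, t=t)
        assert [c.contig_id for c in again] == [c.contig_id for c in kept]
        residual = [
            h for h in find_overlaps(kept, t)
            if h.query_coverage >= t.overlap_redundant_frac
        ]
        by_id = {c.contig_id: c for c in kept}
        assert not [
            h for h in residual
            if by_id[h.subject_id].length_bp > by_id[h.query_id].length_bp
        ]

    def test_agrees_with_edlib_alignment_oracle(self):
        # desk-scale instances: <= 20 contigs of <= 5 kb
        for seed in (1, 2, 3):
            contigs, _ = make_redundancy_scenario(
                n_unique=10, n_contained=6, n_partial=4,
                contig_bp=(2000, 5000), seed=seed)
            kept = remove_redundant(contigs)
            removed = {c.contig_id for c in contigs} - {c.contig_id for c in kept}
            assert removed == oracle_redundant(contigs), f"seed {seed}"


class TestBuildMegaAssembly:
    def _contigs(self, rng, n, length, prefix):
        return [
            ContigRecord(f"{prefix}{i}", random_genome_sequence(length, 0.5, rng))
            for i in range(n)
        ]

    def test_three_sources_counted(self, rng):
        unb = self._contigs(rng, 5, 2000, "u")
        unm = self._contigs(rng, 3, 2000, "m")
        cat = [make_genome("g1", length=6000, n_contigs=2, seed=1),
               make_genome("g2", length=6000, n_contigs=1, seed=2)]
        mega = build_mega_assembly(unb, unm, cat)
        assert mega.source_counts == {
            "nonredundant_unbinned": 5,
            "unmapped_read_assembly": 3,
            "catalog_mag": 3,
        }
        assert len(mega.contigs) == 11

    def test_short_contigs_dropped(self, rng):
        unb = [ContigRecord("short", random_genome_sequence(800, 0.5, rng)),
               ContigRecord("long", random_genome_sequence(1500, 0.5, rng))]
        mega = build_mega_assembly(unb, [], [])
        assert [c.contig_id for c in mega.contigs] == ["nonredundant_unbinned|long"]

    def test_empty_middle_source_is_fine(self, rng):
        mega = build_mega_assembly(self._contigs(rng, 2, 2000, "u"), [],
                                   [make_genome("g", length=4000)])
        assert mega.source_counts["unmapped_read_assembly"] == 0

    def test_duplicate_id_within_source_rejected(self, rng):
        c = ContigRecord("dup", random_genome_sequence(2000, 0.5, rng))
        with pytest.raises(ValueError, match="duplicate"):
            build_mega_assembly([c, ContigRecord("dup", c.sequence)], [], [])


class TestSelectMgeCandidates:
    @pytest.mark.parametrize("length,included", [(5000, False), (5001, True)])
    def test_strict_length_boundary(self, rng, length, included):
        mega = build_mega_assembly(
            [ContigRecord("c", random_genome_sequence(length, 0.5, rng))], [], [])
        got = select_mge_candidates(mega)
        assert (len(got) == 1) is included

    def test_empty_assembly_gives_empty_list(self):
        mega = build_mega_assembly([], [], [])
        assert select_mge_candidates(mega) == []
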