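"""MGE-host association calls, persistence bookkeeping, host-change
(putative HGT) detection and the bipartite association graph."""

import networkx as nx
import pytest

from curdcat.hostlink import (
    associate,
    count_association_persistence,
    detect_host_changes,
    export_association_graph,
    persistence_histogram,
)
from curdcat.records import ContactTable, ContigRecord
from curdcat.simulate import ContactSpec, make_association_scenario, simulate_contacts

from conftest import make_genome


def _bins():
    return [
        make_genome("binX", length=6000, n_contigs=3, seed=1,
                    taxonomy=("Bacteria", "", "", "", "", "Psychrobacter", "")),
        make_genome("binY", length=6000, n_contigs=2, seed=2,
                    taxonomy=("Bacteria", "", "", "", "", "Halomonas", "")),
        make_genome("binZ", length=6000, n_contigs=2, seed=3,
                    taxonomy=("Bacteria", "", "", "", "", "Psychrobacter", "")),
    ]


def _mge(mge_id="mge1"):
    return ContigRecord(mge_id, "ACGT" * 1500)


def _table(tp, entries):
    t = ContactTable(tp)
    for a, b, n in entries:
        t.add(a, b, n)
    return t


class TestAssociate:
    def test_dominant_host_reported_alone(self):
        bins = _bins()
        table = _table("t1", [("mge1", "binX.c001", 12), ("mge1", "binX.c002", 8),
                              ("mge1", "binY.c001", 2)])
        recs = associate(table, [_mge()], bins, min_links=5, dominance_ratio=3)
        assert len(recs) == 1
        assert recs[0].host_id == "binX" and recs[0].n_links == 20
        assert recs[0].host_kind == "mag"

    def test_comparable_hosts_give_multi_host_call(self):
        bins = _bins()
        table = _table("t1", [("mge1", "binX.c001", 20), ("mge1", "binY.c001", 15)])
        recs = associate(table, [_mge()], bins, min_links=5, dominance_ratio=3)
        assert {r.host_id for r in recs} == {"binX", "binY"}

    def test_below_min_links_unassociated(self):
        bins = _bins()
        table = _table("t1", [("mge1", "binX.c001", 4)])
        assert associate(table, [_mge()], bins, min_links=5) == []

    def test_monotone_in_min_links(self):
        bins, mges, cspec, tables = make_association_scenario(seed=11)
        prev = None
        for ml in (1, 3, 5, 10, 30):
            recs = associate(tables[0], mges, bins, min_links=ml, dominance_ratio=3)
            keys = {(r.mge_id, r.host_id) for r in recs}
            if prev is not None:
                assert keys <= prev
            prev = keys

    def test_zero_background_gives_exact_recovery(self):
        cspec = ContactSpec(mge_link_rate=30, background_rate=0.0)
        bins, mges, cspec, tables = make_association_scenario(
            cspec=cspec, n_switching=0, seed=5)
        for table in tables:
            recs = associate(table, mges, bins, min_links=5, dominance_ratio=3)
            assert {r.mge_id for r in recs} == {m.contig_id for m in mges}
            for r in recs:
                assert r.host_id == cspec.host_schedule[r.mge_id][table.timepoint]

    def test_unknown_contig_rejected_when_universe_given(self):
        bins = _bins()
        table = _table("t1", [("mge1", "mystery", 10)])
        with pytest.raises(ValueError, match="unknown contigs"):
            associate(table, [_mge()], bins, known_contigs=set())

    def test_unbinned_candidate_reported_as_such(self):
        bins = _bins()
        table = _table("t1", [("mge1", "loose.c1", 9)])
        recs = associate(table, [_mge()], bins, min_links=5)
        assert recs[0].host_kind == "unbinned_contig"

    def test_mge_id_collision_with_bin_contig_rejected(self):
        bins = _bins()
        table = _table("t1", [])
        with pytest.raises(ValueError, match="also appear"):
            associate(table, [ContigRecord("binX.c001", "ACGT" * 300)], bins)


class TestPersistence:
    def _recs(self):
        bins = _bins()
        out = []
        for tp, host in [("t1", "binX"), ("t3", "binX")]:
            table = _table(tp, [("mge1", f"{host}.c001", 10)])
            out += associate(table, [_mge()], bins)
        return out

    def test_same_host_two_timepoints_counts_two(self):
        assert count_association_persistence(self._recs()) == {("mge1", "binX"): 2}
        assert persistence_histogram(self._recs()) == {2: 1}

    def test_unassociated_mge_absent(self):
        assert persistence_histogram([]) == {}

    def test_planted_schedule_histogram(self):
        # every MGE associated at all three time points; switchers split
        # their persistence across two hosts (2 + 1)
        bins, mges, cspec, tables = make_association_scenario(
            n_mges=10, n_switching=2, seed=19)
        recs = []
        for t in tables:
            recs += associate(t, mges, bins, min_links=5, dominance_ratio=3)
        hist = persistence_histogram(recs)
        assert hist.get(3, 0) == 8
        assert hist.get(2, 0) == 2
        assert hist.get(1, 0) == 2


class TestDetectHostChanges:
    def test_mag_level_switch_within_same_genus(self):
        # a plasmid moving between two same-genus MAGs: one MAG-level
        # event flagged as putative HGT, no genus-level event
        bins = _bins()
        recs = []
        for tp, host in [("t1", "binX"), ("t2", "binZ")]:
            table = _table(tp, [("mge1", f"{host}.c001", 10)])
            recs += associate(table, [_mge()], bins)
        events = detect_host_changes(recs, timepoint_order=["t1", "t2"])
        assert len(events) == 1
        e = events[0]
        assert e.level == "mag" and e.flagged_hgt
        assert (e.host_from, e.host_to) == ("binX", "binZ")

    def test_genus_change_also_reported(self):
        bins = _bins()
        recs = []
        for tp, host in [("t1", "binX"), ("t2", "binY")]:
            table = _table(tp, [("mge1", f"{host}.c001", 10)])
            recs += associate(table, [_mge()], bins)
        events = detect_host_changes(recs, timepoint_order=["t1", "t2"])
        levels = {e.level for e in events}
        assert levels == {"mag", "genus"}
        genus_event = next(e for e in events if e.level == "genus")
        assert (genus_event.host_from, genus_event.host_to) == ("Psychrobacter", "Halomonas")
        assert not genus_event.flagged_hgt

    def test_constant_host_schedule_emits_nothing(self):
        cspec = ContactSpec(mge_link_rate=30, background_rate=0.0)
        bins, mges, cspec, tables = make_association_scenario(
            cspec=cspec, n_switching=0, seed=23)
        recs = []
        for t in tables:
            recs += associate(t, mges, bins)
        assert detect_host_changes(recs, timepoint_order=["t1", "t2", "t3"]) == []

    def test_planted_switches_recovered(self):
        bins, mges, cspec, tables = make_association_scenario(
            n_mges=30, n_switching=4, seed=29)
        recs = []
        for t in tables:
            recs += associate(t, mges, bins, min_links=5, dominance_ratio=3)
        events = detect_host_changes(recs, timepoint_order=["t1", "t2", "t3"])
        switched = {m for m, sched in cspec.host_schedule.items()
                    if len(set(sched.values())) > 1}
        mag_events = {e.mge_id for e in events if e.level == "mag"}
        assert mag_events == switched


class TestExportGraph:
    def test_empty_records_graph_has_no_edges(self):
        g = export_association_graph([])
        assert g.number_of_nodes() == 0 and g.number_of_edges() == 0

    def test_single_association_edge_attributes(self):
        bins = _bins()
        table = _table("t1", [("mge1", "binX.c001", 10)])
        recs = associate(table, [_mge()], bins)
        g = export_association_graph(recs, bins)
        assert g.number_of_edges() == 1
        (_, _, data), = g.edges(data=True)
        assert data["n_links"] == 10 and data["timepoint"] == "t1"
        assert g.nodes["binX"]["genus"] == "Psychrobacter"

    def test_multi_host_mge_has_degree_two(self):
        bins = _bins()
        table = _table("t1", [("mge1", "binX.c001", 20), ("mge1", "binY.c001", 15)])
        recs = associate(table, [_mge()], bins)
        g = export_association_graph(recs)
        assert g.degree("mge1") == 2
        assert nx.is_bipartite(g)
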