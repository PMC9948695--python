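"""MGE-host association from Hi-C contact evidence, and longitudinal
host-change (putative HGT) detection.

Each extrachromosomal MGE's link counts are aggregated per candidate
host: summed over a MAG's contigs, or per contig for unbinned
candidates. Candidates with at least ``min_links`` links qualify; when
the top candidate dominates the runner-up by a factor of
``dominance_ratio`` only the top is reported, otherwise every
qualifying candidate is (multi-host association). Associations tracked
across time points yield persistence histograms and host-change events:
a MAG-level change (same MGE, different host MAG at two time points) is
flagged as a putative HGT candidate; genus-level changes are reported
when the host genus differs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .records import ContactTable, ContigRecord, GenomeRecord, RANKS

log = logging.getLogger("curdcat")

DEFAULT_MIN_LINKS = 5
DEFAULT_DOMINANCE_RATIO = 3.0

__all__ = [
    "AssociationRecord",
    "HostChangeEvent",
    "associate",
    "count_association_persistence",
    "persistence_histogram",
    "detect_host_changes",
    "export_association_graph",
]


@dataclass
class AssociationRecord:
    mge_id: str
    host_id: str
    host_kind: str  # "mag" | "unbinned_contig"
    timepoint: str
    n_links: int
    evidence: set[str] = field(default_factory=lambda: {"hic"})
    host_taxonomy: tuple[str, ...] = ()

    @property
    def host_genus(self) -> str:
        idx = RANKS.index("genus")
        return self.host_taxonomy[idx] if len(self.host_taxonomy) > idx else ""


@dataclass
class HostChangeEvent:
    mge_id: str
    timepoint_from: str
    timepoint_to: str
    host_from: str
    host_to: str
    level: str  # "mag" | "genus"
    flagged_hgt: bool


def associate(
    contacts: ContactTable,
    mges: list[ContigRecord],
    bins: list[GenomeRecord],
    min_links: int = DEFAULT_MIN_LINKS,
    dominance_ratio: float = DEFAULT_DOMINANCE_RATIO,
    allow_unbinned: bool = True,
    known_contigs: set[str] | None = None,
) -> list[AssociationRecord]:
    """Assign each MGE to its host candidate(s) at one time point.

    MGEs with no candidate reaching min_links are reported unassociated
    (i.e. absent from the result). When ``known_contigs`` names the
    assembly's contig universe, contacts referencing anything outside it
    are an error so mislabelled inputs fail fast; contigs outside any
    bin are unbinned association candidates when allow_unbinned is set.
    """
    if min_links < 1:
        raise ValueError("min_links must be >= 1")
    if dominance_ratio < 1:
        raise ValueError("dominance_ratio must be >= 1")
    contig_to_bin: dict[str, GenomeRecord] = {}
    for g in bins:
        for c in g.contigs:
            contig_to_bin[c.contig_id] = g
    mge_ids = {m.contig_id for m in mges}
    overlap = mge_ids & set(contig_to_bin)
    if overlap:
        raise ValueError(f"MGE ids also appear as bin contigs: {sorted(overlap)[:5]}")
    known = mge_ids | set(contig_to_bin)
    if known_contigs is not None:
        unknown = contacts.contig_ids() - known - set(known_contigs)
        if unknown:
            raise ValueError(
                f"contact table references unknown contigs: {sorted(unknown)[:5]}"
            )
    elif not allow_unbinned:
        unknown = contacts.contig_ids() - known
        if unknown:
            raise ValueError(
                f"contact table references unknown contigs: {sorted(unknown)[:5]}"
            )

    bins_by_id = {g.genome_id: g for g in bins}
    records: list[AssociationRecord] = []
    for mge_id in sorted(mge_ids):
        links: dict[str, int] = {}
        evidence: dict[str, set[str]] = {}
        kinds: dict[str, str] = {}
        for other, n, ev in contacts.neighbours(mge_id):
            if other in mge_ids:
                continue  # MGE-MGE contacts carry no host information
            g = contig_to_bin.get(other)
            if g is not None:
                cand, kind = g.genome_id, "mag"
            elif allow_unbinned:
                cand, kind = other, "unbinned_contig"
            else:
                continue
            links[cand] = links.get(cand, 0) + n
            evidence.setdefault(cand, set()).update(ev)
            kinds[cand] = kind
        qualifying = {c: n for c, n in links.items() if n >= min_links}
        if not qualifying:
            continue
        ranked = sorted(qualifying.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ranked) > 1 and ranked[0][1] >= dominance_ratio * ranked[1][1]:
            ranked = ranked[:1]
        for cand, n in ranked:
            g = bins_by_id.get(cand)
            records.append(
                AssociationRecord(
                    mge_id=mge_id,
                    host_id=cand,
                    host_kind=kinds[cand],
                    timepoint=contacts.timepoint,
                    n_links=n,
                    evidence=set(evidence[cand]),
                    host_taxonomy=g.taxonomy if g is not None else (),
                )
            )
    return records


def count_association_persistence(
    records: list[AssociationRecord],
) -> dict[tuple[str, str], int]:
    """Per (mge, host): the number of time points with an association."""
    seen: dict[tuple[str, str], set[str]] = {}
    for r in records:
        seen.setdefault((r.mge_id, r.host_id), set()).add(r.timepoint)
    return {k: len(v) for k, v in seen.items()}


def persistence_histogram(records: list[AssociationRecord]) -> dict[int, int]:
    """How many (mge, host) pairs persist for 1, 2, 3, ... time points."""
    hist: dict[int, int] = {}
    for n in count_association_persistence(records).values():
        hist[n] = hist.get(n, 0) + 1
    return dict(sorted(hist.items()))


def detect_host_changes(
    records: list[AssociationRecord],
    timepoint_order: list[str] | None = None,
) -> list[HostChangeEvent]:
    """Flag MGEs whose host differs between time points.

    For each MGE, consecutive associated time points are compared (the
    earliest transition is reported once, not every ordered pair). A
    MAG-level event fires when the host set changes to a disjoint MAG
    set; since every association already passed min_links, MAG-level
    events are flagged as putative HGT. A genus-level event additionally
    fires when the host genus set becomes disjoint. Comparison uses MAG
    associations only (unbinned hosts have no stable identity).
    """
    by_mge: dict[str, dict[str, list[AssociationRecord]]] = {}
    tps: set[str] = set()
    for r in records:
        if r.host_kind != "mag":
            continue
        by_mge.setdefault(r.mge_id, {}).setdefault(r.timepoint, []).append(r)
        tps.add(r.timepoint)
    order = timepoint_order or sorted(tps)
    rank = {tp: i for i, tp in enumerate(order)}

    events: list[HostChangeEvent] = []
    for mge_id in sorted(by_mge):
        per_tp = by_mge[mge_id]
        assoc_tps = sorted(per_tp, key=lambda tp: rank.get(tp, len(rank)))
        for tp_a, tp_b in zip(assoc_tps, assoc_tps[1:]):
            hosts_a = {r.host_id for r in per_tp[tp_a]}
            hosts_b = {r.host_id for r in per_tp[tp_b]}
            if hosts_a.isdisjoint(hosts_b):
                top_a = max(per_tp[tp_a], key=lambda r: r.n_links)
                top_b = max(per_tp[tp_b], key=lambda r: r.n_links)
                events.append(
                    HostChangeEvent(
                        mge_id=mge_id,
                        timepoint_from=tp_a,
                        timepoint_to=tp_b,
                        host_from=top_a.host_id,
                        host_to=top_b.host_id,
                        level="mag",
                        flagged_hgt=True,
                    )
                )
                genera_a = {r.host_genus for r in per_tp[tp_a] if r.host_genus}
                genera_b = {r.host_genus for r in per_tp[tp_b] if r.host_genus}
                if genera_a and genera_b and genera_a.isdisjoint(genera_b):
                    events.append(
                        HostChangeEvent(
                            mge_id=mge_id,
                            timepoint_from=tp_a,
                            timepoint_to=tp_b,
                            host_from=top_a.host_genus,
                            host_to=top_b.host_genus,
                            level="genus",
                            flagged_hgt=False,
                        )
                    )
    return events


def export_association_graph(
    records: list[AssociationRecord], bins: list[GenomeRecord] | None = None
) -> nx.MultiGraph:
    """Bipartite MGE-host graph; edges carry timepoint/evidence/n_links.

    Node insertion order is deterministic (sorted), so GraphML output is
    reproducible.
    """
    g = nx.MultiGraph()
    mge_nodes = sorted({r.mge_id for r in records})
    host_nodes = sorted({r.host_id for r in records})
    for n in mge_nodes:
        g.add_node(n, kind="mge", bipartite=0)
    for n in host_nodes:
        g.add_node(n, kind="host", bipartite=1)
    if bins:
        for b in bins:
            if b.genome_id in g.nodes:
                g.nodes[b.genome_id]["genus"] = b.genus
    for r in sorted(records, key=lambda r: (r.mge_id, r.host_id, r.timepoint)):
        g.add_edge(
            r.mge_id,
            r.host_id,
            timepoint=r.timepoint,
            n_links=r.n_links,
            evidence="+".join(sorted(r.evidence)),
        )
    return g


def associations_to_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mge_id": r.mge_id,
                "host_id": r.host_id,
                "host_kind": r.host_kind,
                "timepoint": r.timepoint,
                "n_links": r.n_links,
                "evidence": "+".join(sorted(r.evidence)),
                "host_taxonomy": ";".join(r.host_taxonomy),
            }
            for r in records
        ],
        columns=[
            "mge_id",
            "host_id",
            "host_kind",
            "timepoint",
            "n_links",
            "evidence",
            "host_taxonomy",
        ],
    )
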