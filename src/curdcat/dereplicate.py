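"""Genome dereplication: ANI estimation, clustering, representative
selection by the provenance priority hierarchy, and cross-community
catalog comparison.

ANI between two genomes is estimated from canonical k-mer containment:
with per-base identity p, a k-mer survives mutation with probability
p^k, so the containment c of the smaller genome's k-mer set in the
larger one satisfies ANI ~ 100 * c^(1/k). An optional bottom-sketch
(MinHash) subsamples the smaller set for speed. Clustering is
single-linkage over pairs at ANI >= the threshold (genomes above the
threshold are "the same genome"); one representative per cluster is
chosen by the priority ladder isolate > circular time-point MAG >
circular co-assembly MAG > high-quality noncircular time-point MAG >
high-quality noncircular co-assembly MAG, with ties broken by the
quality score completeness - 5*contamination, then fewer contigs, then
genome id.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._kmers import hashed_kmer_set
from .records import GenomeRecord, Provenance, Thresholds, is_high_quality

log = logging.getLogger("curdcat")

__all__ = [
    "DereplicationCluster",
    "CatalogComparison",
    "estimate_ani",
    "ani_matrix",
    "cluster_genomes",
    "select_representative",
    "dereplicate",
    "compare_catalogs",
]


@dataclass
class DereplicationCluster:
    cluster_id: str
    member_ids: list[str]
    representative_id: str | None = None
    pairwise_ani: dict[frozenset, float] = field(default_factory=dict)

    def ani(self, a: str, b: str) -> float:
        if a == b:
            return 100.0
        return self.pairwise_ani[frozenset((a, b))]


@dataclass
class CatalogComparison:
    """Venn-region bookkeeping of genome groups across communities.

    regions maps a frozenset of community names to the list of genome
    groups (tuples of genome ids) present in exactly that community set.
    """

    communities: list[str]
    catalog_sizes: dict[str, int]
    regions: dict[frozenset, list[tuple[str, ...]]]

    @property
    def shared_all(self) -> list[tuple[str, ...]]:
        return self.regions.get(frozenset(self.communities), [])

    @property
    def pairwise_shared(self) -> dict[frozenset, int]:
        return {
            region: len(groups)
            for region, groups in self.regions.items()
            if len(region) == 2
        }

    @property
    def unique(self) -> dict[str, int]:
        out = {c: 0 for c in self.communities}
        for region, groups in self.regions.items():
            if len(region) == 1:
                (c,) = region
                out[c] = len(groups)
        return out

    def region_counts(self) -> dict[frozenset, int]:
        return {r: len(g) for r, g in self.regions.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for region in sorted(self.regions, key=lambda r: (-len(r), sorted(r))):
            label = "∩".join(sorted(region))
            for group in self.regions[region]:
                rows.append(
                    {"region": label, "n_communities": len(region), "members": ",".join(group)}
                )
        return pd.DataFrame(rows, columns=["region", "n_communities", "members"])


def _kmer_profile(g: GenomeRecord, k: int) -> np.ndarray:
    seqs = [c.sequence for c in g.contigs]
    if max((len(s) for s in seqs), default=0) < k:
        raise ValueError(f"genome {g.genome_id!r}: every contig shorter than k={k}")
    return hashed_kmer_set(seqs, k)


def _containment_ani(
    small: np.ndarray, large: np.ndarray, k: int, sketch_size: int | None
) -> float:
    if small.size == 0 or large.size == 0:
        return 0.0
    if sketch_size is not None and small.size > sketch_size:
        sample = small[:sketch_size]  # arrays are hash-sorted: bottom sketch
    else:
        sample = small
    idx = np.searchsorted(large, sample)
    idx[idx == large.size] = large.size - 1
    matches = int(np.count_nonzero(large[idx] == sample))
    c = matches / sample.size
    if c <= 0.0:
        return 0.0
    return float(min(100.0, 100.0 * c ** (1.0 / k)))


def estimate_ani(
    a: GenomeRecord,
    b: GenomeRecord,
    k: int = 21,
    sketch_size: int | None = None,
) -> float:
    """Strand-independent k-mer containment ANI estimate in [0, 100].

    Symmetric by construction (containment of the smaller k-mer set in
    the larger). k must be odd in 15..31 so canonical k-mers are
    well-defined.
    """
    if k % 2 == 0 or not (15 <= k <= 31):
        raise ValueError("k must be odd and within 15..31")
    if a.genome_id == b.genome_id:
        return 100.0
    ka = _kmer_profile(a, k)
    kb = _kmer_profile(b, k)
    small, large = (ka, kb) if ka.size <= kb.size else (kb, ka)
    return _containment_ani(small, large, k, sketch_size)


def ani_matrix(
    genomes: list[GenomeRecord], k: int = 21, sketch_size: int | None = None
) -> pd.DataFrame:
    """All-vs-all ANI; k-mer profiles computed once per genome."""
    profiles = {g.genome_id: _kmer_profile(g, k) for g in genomes}
    ids = [g.genome_id for g in genomes]
    mat = np.full((len(ids), len(ids)), 100.0)
    for (i, gi), (j, gj) in itertools.combinations(enumerate(ids), 2):
        pi, pj = profiles[gi], profiles[gj]
        small, large = (pi, pj) if pi.size <= pj.size else (pj, pi)
        mat[i, j] = mat[j, i] = _containment_ani(small, large, k, sketch_size)
    return pd.DataFrame(mat, index=ids, columns=ids)


def cluster_genomes(
    genomes: list[GenomeRecord],
    t: Thresholds | None = None,
    k: int = 21,
    sketch_size: int | None = None,
    ani: pd.DataFrame | None = None,
) -> list[DereplicationCluster]:
    """Single-linkage clusters over pairs with ANI >= t.ani_same_genome.

    Cluster ids are assigned deterministically in order of each
    cluster's smallest member genome_id.
    """
    if not genomes:
        raise ValueError("need at least one genome")
    t = t or Thresholds()
    ids = [g.genome_id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids")
    if ani is None:
        ani = ani_matrix(genomes, k=k, sketch_size=sketch_size)
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    for a, b in itertools.combinations(ids, 2):
        if ani.at[a, b] >= t.ani_same_genome:
            graph.add_edge(a, b)
    components = sorted(nx.connected_components(graph), key=min)
    clusters = []
    for i, comp in enumerate(components, start=1):
        members = sorted(comp)
        pairwise = {
            frozenset((a, b)): float(ani.at[a, b])
            for a, b in itertools.combinations(members, 2)
        }
        clusters.append(
            DereplicationCluster(
                cluster_id=f"C{i:03d}", member_ids=members, pairwise_ani=pairwise
            )
        )
    return clusters


def _priority_class(g: GenomeRecord, t: Thresholds) -> int:
    if g.provenance is Provenance.ISOLATE:
        return 0
    if g.circular and g.provenance is Provenance.TIMEPOINT:
        return 1
    if g.circular and g.provenance is Provenance.COASSEMBLY:
        return 2
    hq = (
        g.completeness is not None
        and g.contamination is not None
        and is_high_quality(g, t)
    )
    if hq and g.provenance is Provenance.TIMEPOINT:
        return 3
    if hq and g.provenance is Provenance.COASSEMBLY:
        return 4
    return 5


def _quality_score(g: GenomeRecord) -> float:
    comp = g.completeness if g.completeness is not None else 0.0
    cont = g.contamination if g.contamination is not None else 100.0
    return comp - 5.0 * cont


def select_representative(
    cluster: DereplicationCluster,
    genomes: dict[str, GenomeRecord] | list[GenomeRecord],
    t: Thresholds | None = None,
) -> str:
    """Pick the cluster representative by the priority ladder; within a
    class, higher quality score (completeness - 5*contamination), then
    fewer contigs, then lexicographic genome id. Total order, so the
    choice is deterministic and order-independent."""
    t = t or Thresholds()
    if not cluster.member_ids:
        raise ValueError(f"cluster {cluster.cluster_id!r} is empty")
    by_id = (
        genomes
        if isinstance(genomes, dict)
        else {g.genome_id: g for g in genomes}
    )
    members = [by_id[m] for m in cluster.member_ids]
    best = min(
        members,
        key=lambda g: (_priority_class(g, t), -_quality_score(g), g.n_contigs, g.genome_id),
    )
    return best.genome_id


def dereplicate(
    genomes: list[GenomeRecord],
    t: Thresholds | None = None,
    k: int = 21,
    sketch_size: int | None = None,
) -> list[DereplicationCluster]:
    """cluster_genomes + select_representative in one call."""
    t = t or Thresholds()
    clusters = cluster_genomes(genomes, t, k=k, sketch_size=sketch_size)
    by_id = {g.genome_id: g for g in genomes}
    for c in clusters:
        c.representative_id = select_representative(c, by_id, t)
    return clusters


def clusters_to_frame(clusters: list[DereplicationCluster]) -> pd.DataFrame:
    rows = []
    for c in clusters:
        for m in c.member_ids:
            rows.append(
                {
                    "cluster_id": c.cluster_id,
                    "genome_id": m,
                    "is_representative": m == c.representative_id,
                    "ani_to_representative": (
                        100.0
                        if m == c.representative_id
                        else c.ani(m, c.representative_id)
                    ),
                }
            )
    return pd.DataFrame(
        rows, columns=["cluster_id", "genome_id", "is_representative", "ani_to_representative"]
    )


def compare_catalogs(
    catalogs: dict[str, list[GenomeRecord]],
    t: Thresholds | None = None,
    k: int = 21,
    sketch_size: int | None = None,
) -> CatalogComparison:
    """Group genomes across communities at ANI >= the threshold (single
    linkage) and report Venn-region counts: a group is shared by exactly
    the set of communities its members come from."""
    t = t or Thresholds()
    if len(catalogs) < 2:
        raise ValueError("need at least two communities to compare")
    pooled: list[GenomeRecord] = []
    community_of: dict[str, str] = {}
    for community, genomes in catalogs.items():
        for g in genomes:
            if g.genome_id in community_of:
                raise ValueError(f"genome id {g.genome_id!r} appears in two catalogs")
            community_of[g.genome_id] = community
            pooled.append(g)
    clusters = cluster_genomes(pooled, t, k=k, sketch_size=sketch_size)
    regions: dict[frozenset, list[tuple[str, ...]]] = {}
    for c in clusters:
        present = frozenset(community_of[m] for m in c.member_ids)
        regions.setdefault(present, []).append(tuple(c.member_ids))
    return CatalogComparison(
        communities=sorted(catalogs),
        catalog_sizes={c: len(g) for c, g in catalogs.items()},
        regions=regions,
    )
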