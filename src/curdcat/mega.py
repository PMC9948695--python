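"""Mega-assembly construction: overlap detection, redundancy removal,
source merging and MGE-candidate selection.

A contig is redundant when another, strictly longer retained contig
covers at least ``overlap_redundant_frac`` (default 90%) of it at
``overlap_identity`` (default 99%) percent identity; the smaller contig
is removed. Overlaps are found seed-and-merge style: exact shared words
of 20 bp on either strand are grouped by diagonal and merged into
ungapped aligned segments that are then identity-scored base by base.
The mega-assembly concatenates nonredundant unbinned contigs, the
unmapped-read assembly, and the catalog MAG contigs, then drops contigs
shorter than ``min_contig_bp``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._kmers import forward_kmers
from .records import ContigRecord, GenomeRecord, Thresholds

log = logging.getLogger("curdcat")

WORD_SIZE = 20
_MAX_SEED_GAP = 200  # merge same-diagonal seeds separated by short mismatch runs
_COMP = str.maketrans("ACGTN", "TGCAN")

__all__ = [
    "OverlapHit",
    "MegaAssembly",
    "find_overlaps",
    "remove_redundant",
    "build_mega_assembly",
    "select_mge_candidates",
]


@dataclass
class OverlapHit:
    """Aggregate local-alignment evidence of one contig against another.

    query_coverage is the union of aligned query intervals divided by
    the query length; identity is the aligned-bp-weighted mean percent
    identity of the kept segments.
    """

    query_id: str
    subject_id: str
    identity: float
    query_coverage: float
    aligned_bp: int


@dataclass
class MegaAssembly:
    contigs: list[ContigRecord]
    source_counts: dict[str, int]

    def __post_init__(self) -> None:
        ids = [c.contig_id for c in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate contig ids in mega-assembly")
        if sum(self.source_counts.values()) != len(self.contigs):
            raise ValueError("source_counts do not sum to the number of contigs")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _matched_segments(query: str, subject: str, min_identity: float):
    """Yield (q_start, q_end, n_match) ungapped segments of query against
    subject (one strand) at identity >= min_identity, via shared exact
    words merged along diagonals."""
    w = WORD_SIZE
    if len(query) < w or len(subject) < w:
        return
    qk = forward_kmers(query, w)
    sk = forward_kmers(subject, w)
    order = np.argsort(sk, kind="stable")
    s_sorted = sk[order]
    left = np.searchsorted(s_sorted, qk, side="left")
    right = np.searchsorted(s_sorted, qk, side="right")
    counts = right - left
    hit = np.flatnonzero(counts)
    if hit.size == 0:
        return
    lens = counts[hit]
    total = int(lens.sum())
    if total > 2_000_000:  # pathological repeat blowup guard
        keep = lens <= 50
        hit, lens = hit[keep], lens[keep]
        total = int(lens.sum())
        if total == 0:
            return
    qpos = np.repeat(hit, lens)
    starts = np.repeat(left[hit], lens)
    offs = np.arange(total) - np.repeat(np.cumsum(lens) - lens, lens)
    spos = order[starts + offs]
    diag = qpos.astype(np.int64) - spos.astype(np.int64)
    key = np.lexsort((qpos, diag))
    diag, qpos, spos = diag[key], qpos[key], spos[key]

    qa = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
    sa = np.frombuffer(subject.encode("ascii"), dtype=np.uint8)

    def _emit(d: int, q0: int, q1: int):
        # ungapped segment on diagonal d spanning query [q0, q1)
        s0 = q0 - d
        seg_q = qa[q0:q1]
        seg_s = sa[s0 : s0 + (q1 - q0)]
        n_match = int(np.count_nonzero(seg_q == seg_s))
        ident = 100.0 * n_match / (q1 - q0)
        if ident >= min_identity:
            return (q0, q1, n_match)
        return None

    i = 0
    n = diag.size
    while i < n:
        d = diag[i]
        run_start = qpos[i]
        prev = qpos[i]
        j = i + 1
        while j < n and diag[j] == d and qpos[j] - prev <= _MAX_SEED_GAP:
            prev = qpos[j]
            j += 1
        seg = _emit(int(d), int(run_start), int(prev) + w)
        if seg is not None:
            yield seg
        i = j


def _union_length(intervals: list[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total = 0
    cur_a, cur_b = intervals[0]
    for a, b in intervals[1:]:
        if a > cur_b:
            total += cur_b - cur_a
            cur_a, cur_b = a, b
        else:
            cur_b = max(cur_b, b)
    return total + (cur_b - cur_a)


def _query_hit(query: ContigRecord, subject: ContigRecord, min_identity: float):
    segments = []
    for strand_subject in (subject.sequence, _revcomp(subject.sequence)):
        segments.extend(
            _matched_segments(query.sequence, strand_subject, min_identity)
        )
    if not segments:
        return None
    intervals = [(q0, q1) for q0, q1, _ in segments]
    aligned = _union_length(intervals)
    span = sum(q1 - q0 for q0, q1, _ in segments)
    matches = sum(m for _, _, m in segments)
    return OverlapHit(
        query_id=query.contig_id,
        subject_id=subject.contig_id,
        identity=100.0 * matches / span,
        query_coverage=aligned / query.length_bp,
        aligned_bp=aligned,
    )


def find_overlaps(
    contigs: list[ContigRecord], t: Thresholds | None = None
) -> list[OverlapHit]:
    """All-vs-all overlap hits (both strands, self-pairs excluded).

    One hit per ordered (query, subject) pair that shares at least one
    qualifying aligned segment.
    """
    t = t or Thresholds()
    hits: list[OverlapHit] = []
    for i, q in enumerate(contigs):
        for j, s in enumerate(contigs):
            if i == j:
                continue
            hit = _query_hit(q, s, t.overlap_identity)
            if hit is not None:
                hits.append(hit)
    return hits


def remove_redundant(
    contigs: list[ContigRecord],
    hits: list[OverlapHit] | None = None,
    t: Thresholds | None = None,
) -> list[ContigRecord]:
    """Drop contigs covered >= overlap_redundant_frac by a longer retained
    contig; the smaller contig is always the one removed.

    Resolution runs shortest-to-longest so cascading removals are
    deterministic; equal-length mutual redundancy keeps the
    lexicographically smaller id. Returns survivors in input order.
    """
    t = t or Thresholds()
    if hits is None:
        hits = find_overlaps(contigs, t)
    by_id = {c.contig_id: c for c in contigs}
    hits_by_query: dict[str, list[OverlapHit]] = {}
    for h in hits:
        hits_by_query.setdefault(h.query_id, []).append(h)
    removed: set[str] = set()
    order = sorted(contigs, key=lambda c: (c.length_bp, c.contig_id))
    for c in order:
        for h in hits_by_query.get(c.contig_id, []):
            if h.query_coverage < t.overlap_redundant_frac:
                continue
            if h.identity < t.overlap_identity:
                continue
            subj = by_id[h.subject_id]
            if subj.contig_id in removed:
                continue
            longer = subj.length_bp > c.length_bp or (
                subj.length_bp == c.length_bp and subj.contig_id < c.contig_id
            )
            if longer:
                removed.add(c.contig_id)
                break
    return [c for c in contigs if c.contig_id not in removed]


def build_mega_assembly(
    nonredundant_unbinned: list[ContigRecord],
    unmapped_assembly_contigs: list[ContigRecord],
    catalog_genomes: list[GenomeRecord],
    t: Thresholds | None = None,
) -> MegaAssembly:
    """Concatenate the three contig sources (ids prefixed by source),
    then drop contigs shorter than min_contig_bp."""
    t = t or Thresholds()
    sources = {
        "nonredundant_unbinned": list(nonredundant_unbinned),
        "unmapped_read_assembly": list(unmapped_assembly_contigs),
        "catalog_mag": [c for g in catalog_genomes for c in g.contigs],
    }
    contigs: list[ContigRecord] = []
    counts: dict[str, int] = {}
    seen: set[str] = set()
    for source, items in sources.items():
        kept = 0
        for c in items:
            if c.length_bp < t.min_contig_bp:
                continue
            new_id = f"{source}|{c.contig_id}"
            if new_id in seen:
                raise ValueError(f"duplicate contig id after prefixing: {new_id!r}")
            seen.add(new_id)
            contigs.append(
                ContigRecord(new_id, c.sequence, source_genome=c.source_genome)
            )
            kept += 1
        counts[source] = kept
    log.info(
        "mega-assembly: %d contigs (%s)",
        len(contigs),
        ", ".join(f"{k}={v}" for k, v in counts.items()),
    )
    return MegaAssembly(contigs=contigs, source_counts=counts)


def select_mge_candidates(
    mega: MegaAssembly, t: Thresholds | None = None
) -> list[ContigRecord]:
    """Contigs strictly longer than min_mge_candidate_bp, the substrate
    for MGE prediction."""
    t = t or Thresholds()
    return [c for c in mega.contigs if c.length_bp > t.min_mge_candidate_bp]
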