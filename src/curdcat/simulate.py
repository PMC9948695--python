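"""Synthetic communities with known ground truth.

Every downstream stage is exercised against data generated here: base
genomes are i.i.d. DNA at a stated GC content, strain variants derive
from a parent by i.i.d. substitutions (so expected ANI has the closed
form 100*(1-rate)), per-position depth follows an overdispersed
negative-binomial count model with planted outlier positions, Hi-C
contact counts are Poisson at three rates (intra-genome, MGE-to-host,
background) with scheduled host switches across time points, and
presence/absence matrices carry planted group-enriched functions.

All generators are deterministic under their seed, and ground-truth
labels travel on the artifacts (``source_genome`` on contigs, ``truth``
on matrices, explicit schedule/label returns from scenario builders).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pangenome import COG_CATEGORIES, GeneClusterMatrix
from .records import ContactTable, ContigRecord, DepthProfile, GenomeRecord, Provenance

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

__all__ = [
    "CommunitySpec",
    "ContactSpec",
    "random_genome_sequence",
    "mutate_sequence",
    "fragment_sequence",
    "make_community",
    "simulate_depth",
    "simulate_contacts",
    "simulate_pangenome",
    "make_catalog_scenario",
    "make_shared_catalogs",
    "make_redundancy_scenario",
    "make_association_scenario",
    "make_abundance_scenario",
]


@dataclass
class CommunitySpec:
    """Parameters of one synthetic community.

    strain_groups lists (parent index, substitution rate) pairs; each
    entry adds one variant genome derived from the indexed base genome.
    """

    n_genomes: int = 10
    genome_length_bp: int = 50_000
    gc_content: float = 0.5
    strain_groups: list[tuple[int, float]] = field(default_factory=list)
    n_timepoints: int = 1
    seed: int = 0
    max_contigs_per_genome: int = 4
    min_fragment_bp: int = 1000

    def __post_init__(self) -> None:
        if self.n_timepoints < 1:
            raise ValueError("n_timepoints must be >= 1")
        if not (0.0 < self.gc_content < 1.0):
            raise ValueError("gc_content must be in (0, 1)")
        for parent, rate in self.strain_groups:
            if not (0 <= parent < self.n_genomes):
                raise ValueError(f"strain parent index {parent} out of range")
            if not (0.0 <= rate <= 0.3):
                raise ValueError(
                    f"substitution rate {rate} outside [0, 0.3] (ANI model breaks down)"
                )


@dataclass
class ContactSpec:
    """Rates of the Hi-C contact model plus the MGE host schedule.

    host_schedule maps mge_id -> {timepoint -> host genome_id or "none"}.
    """

    intra_genome_rate: float = 10.0
    mge_link_rate: float = 30.0
    background_rate: float = 0.5
    host_schedule: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for r in (self.intra_genome_rate, self.mge_link_rate, self.background_rate):
            if r < 0:
                raise ValueError("contact rates must be >= 0")


def random_genome_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    p_at = (1.0 - gc) / 2.0
    p_gc = gc / 2.0
    codes = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at])
    return _BASES[codes].tobytes().decode("ascii")


def mutate_sequence(sequence: str, rate: float, rng: np.random.Generator) -> str:
    """i.i.d. substitutions at the given per-base rate (no indels)."""
    if not (0.0 <= rate <= 0.3):
        raise ValueError(f"substitution rate {rate} outside [0, 0.3]")
    codes = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    two_bit = lut[codes]
    hit = np.flatnonzero(rng.random(codes.size) < rate)
    if hit.size:
        shift = rng.integers(1, 4, size=hit.size)
        two_bit[hit] = (two_bit[hit] + shift) % 4
    return _BASES[two_bit].tobytes().decode("ascii")


def fragment_sequence(
    sequence: str, n_contigs: int, min_fragment_bp: int, rng: np.random.Generator
) -> list[str]:
    """Split at uniform random breakpoints, each fragment >= min_fragment_bp."""
    n = len(sequence)
    if n_contigs <= 1 or n < 2 * min_fragment_bp:
        return [sequence]
    n_contigs = min(n_contigs, n // min_fragment_bp)
    for _ in range(200):  # rejection-sample breakpoints honouring the minimum
        cuts = np.sort(rng.integers(min_fragment_bp, n - min_fragment_bp + 1, size=n_contigs - 1))
        bounds = np.concatenate(([0], cuts, [n]))
        if np.all(np.diff(bounds) >= min_fragment_bp):
            return [sequence[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
    return [sequence]


def make_community(spec: CommunitySpec) -> list[GenomeRecord]:
    """Base genomes plus derived strain variants, fragmented into contigs.

    Ground truth is recorded in ``source_genome`` on every contig (the id
    of the base genome a variant derives from). Quality metrics are drawn
    from ranges typical of high-quality MAGs so the catalog stages have
    realistic inputs.
    """
    rng = np.random.default_rng(spec.seed)
    genomes: list[GenomeRecord] = []
    base_seqs: list[str] = []

    def _build(genome_id: str, sequence: str, truth_id: str) -> GenomeRecord:
        n_frag = int(rng.integers(1, spec.max_contigs_per_genome + 1))
        frags = fragment_sequence(sequence, n_frag, spec.min_fragment_bp, rng)
        contigs = [
            ContigRecord(f"{genome_id}.c{i:03d}", s, source_genome=truth_id)
            for i, s in enumerate(frags, start=1)
        ]
        circular = len(contigs) == 1 and bool(rng.random() < 0.7)
        return GenomeRecord(
            genome_id=genome_id,
            contigs=contigs,
            provenance=Provenance.TIMEPOINT,
            circular=circular,
            completeness=float(np.round(rng.uniform(75, 100), 2)),
            contamination=float(np.round(rng.uniform(0, 5), 2)),
            taxonomy=("Bacteria", "", "", "", "", f"Genus{genomes_index(genome_id)}", ""),
        )

    def genomes_index(genome_id: str) -> str:
        return genome_id.split("_")[0].lstrip("g")

    for i in range(spec.n_genomes):
        gid = f"g{i:02d}"
        seq = random_genome_sequence(spec.genome_length_bp, spec.gc_content, rng)
        base_seqs.append(seq)
        genomes.append(_build(gid, seq, gid))
    counters: dict[int, int] = {}
    for parent, rate in spec.strain_groups:
        counters[parent] = counters.get(parent, 0) + 1
        gid = f"g{parent:02d}_v{counters[parent]}"
        variant = mutate_sequence(base_seqs[parent], rate, rng)
        genomes.append(_build(gid, variant, f"g{parent:02d}"))
    return genomes


def simulate_depth(
    contig: ContigRecord,
    mean_depth: float,
    dispersion: float = 5.0,
    outlier_frac: float = 0.0,
    outlier_mult: float = 1.0,
    seed: int = 0,
) -> DepthProfile:
    """Overdispersed per-position depth (variance = mean + mean^2/dispersion)
    with a planted fraction of positions multiplied by outlier_mult,
    emulating repeats and mobile regions."""
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    if not (0.0 <= outlier_frac <= 1.0):
        raise ValueError("outlier_frac must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = contig.length_bp
    p = dispersion / (dispersion + mean_depth)
    depths = rng.negative_binomial(dispersion, p, size=n).astype(np.int64)
    if outlier_frac > 0 and outlier_mult != 1.0:
        n_out = int(round(outlier_frac * n))
        if n_out:
            idx = rng.choice(n, size=n_out, replace=False)
            depths[idx] = np.round(depths[idx] * outlier_mult).astype(np.int64)
    return DepthProfile(contig_id=contig.contig_id, depths=depths)


def simulate_contacts(
    bins: list[GenomeRecord],
    mges: list[ContigRecord],
    cspec: ContactSpec,
    timepoint: str,
    seed: int = 0,
) -> ContactTable:
    """Poisson link counts per contig pair at the three planted rates.

    MGE links target the scheduled host at this time point (rate applies
    per host contig, so a host with 5 contigs expects 5x mge_link_rate
    links in total); everything else gets background.
    """
    rng = np.random.default_rng(seed)
    bin_ids = {g.genome_id for g in bins}
    for mge_id, sched in cspec.host_schedule.items():
        for tp, host in sched.items():
            if host != "none" and host not in bin_ids:
                raise ValueError(
                    f"host schedule for {mge_id!r} at {tp!r} references unknown genome {host!r}"
                )
    contig_genome: dict[str, str] = {}
    contig_ids: list[str] = []
    for g in bins:
        for c in g.contigs:
            contig_genome[c.contig_id] = g.genome_id
            contig_ids.append(c.contig_id)
    mge_ids = [m.contig_id for m in mges]
    dup = set(mge_ids) & set(contig_ids)
    if dup:
        raise ValueError(f"MGE ids collide with bin contig ids: {sorted(dup)[:5]}")

    all_ids = contig_ids + mge_ids
    hosts_now = {
        m: cspec.host_schedule.get(m, {}).get(timepoint, "none") for m in mge_ids
    }
    pairs: list[tuple[str, str]] = []
    rates: list[float] = []
    for i, a in enumerate(all_ids):
        for b in all_ids[i + 1 :]:
            ga = contig_genome.get(a)
            gb = contig_genome.get(b)
            if ga is not None and ga == gb:
                rate = cspec.intra_genome_rate
            elif ga is None and gb is not None and hosts_now.get(a) == gb:
                rate = cspec.mge_link_rate
            elif gb is None and ga is not None and hosts_now.get(b) == ga:
                rate = cspec.mge_link_rate
            else:
                rate = cspec.background_rate
            pairs.append((a, b))
            rates.append(rate)
    counts = rng.poisson(np.asarray(rates))
    table = ContactTable(timepoint=timepoint)
    for (a, b), n in zip(pairs, counts):
        if n > 0:
            table.add(a, b, int(n), "hic")
    return table


def simulate_pangenome(
    n_group_a: int = 20,
    n_group_b: int = 20,
    n_core: int = 50,
    n_enriched: int = 20,
    p_present_a: float = 0.9,
    p_present_b: float = 0.1,
    n_null: int = 500,
    seed: int = 0,
    p_null: float = 0.5,
    group_a_label: str = "cheese",
    group_b_label: str = "other",
) -> GeneClusterMatrix:
    """Presence/absence matrix with planted structure.

    Core clusters are present in every genome; enriched clusters are
    present with probability p_present_a in group A and p_present_b in
    group B; null clusters share one probability in both groups. The
    planted label of each cluster ("core"/"enriched"/"null") is carried
    in the matrix's ``truth`` field; each cluster gets its own function
    accession so function-level tests see the planted unit directly.
    """
    for p in (p_present_a, p_present_b, p_null):
        if not (0.0 <= p <= 1.0):
            raise ValueError("presence probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_g = n_group_a + n_group_b
    genome_ids = [f"A{i:03d}" for i in range(n_group_a)] + [
        f"B{i:03d}" for i in range(n_group_b)
    ]
    group_labels = [group_a_label] * n_group_a + [group_b_label] * n_group_b
    in_a = np.array([True] * n_group_a + [False] * n_group_b)

    blocks = []
    truth: dict[str, str] = {}
    cluster_ids: list[str] = []

    def _add(label: str, count: int, col_fn):
        for _ in range(count):
            j = len(cluster_ids)
            cid = f"gc{j:05d}"
            cluster_ids.append(cid)
            truth[cid] = label
            col = col_fn()
            if not col.any():  # invariant: no all-absent cluster
                col[rng.integers(0, n_g)] = True
            blocks.append(col)

    _add("core", n_core, lambda: np.ones(n_g, dtype=bool))
    _add(
        "enriched",
        n_enriched,
        lambda: np.where(in_a, rng.random(n_g) < p_present_a, rng.random(n_g) < p_present_b),
    )
    _add("null", n_null, lambda: rng.random(n_g) < p_null)

    presence = np.column_stack(blocks) if blocks else np.zeros((n_g, 0), dtype=bool)
    functions = {cid: f"FN{j:05d}" for j, cid in enumerate(cluster_ids)}
    categories = {
        cid: COG_CATEGORIES[int(rng.integers(0, len(COG_CATEGORIES)))]
        for cid in cluster_ids
    }
    return GeneClusterMatrix(
        genome_ids=genome_ids,
        group_labels=group_labels,
        cluster_ids=cluster_ids,
        functions=functions,
        categories=categories,
        presence=presence,
        truth=truth,
    )


# --------------------------------------------------------------- scenarios


def make_catalog_scenario(
    n_base: int = 10,
    n_variants: int = 2,
    rate: float = 0.002,
    genome_length_bp: int = 50_000,
    seed: int = 0,
):
    """Dereplication test bed: n_base unrelated genomes, each expanded to a
    cluster of (1 + n_variants) strain variants at the planted rate.

    Members are assigned provenance classes covering the priority
    hierarchy; in roughly half the clusters one member is an isolate.
    Returns (genomes, truth) where truth maps base id -> dict with
    'members' (ids) and 'isolate' (the planted isolate id or None).
    """
    rng = np.random.default_rng(seed)
    genomes: list[GenomeRecord] = []
    truth: dict[str, dict] = {}
    classes = [
        (Provenance.TIMEPOINT, True),
        (Provenance.COASSEMBLY, True),
        (Provenance.TIMEPOINT, False),
        (Provenance.COASSEMBLY, False),
    ]
    for i in range(n_base):
        base_id = f"g{i:02d}"
        seq = random_genome_sequence(genome_length_bp, 0.5, rng)
        member_ids = []
        has_isolate = bool(rng.random() < 0.5)
        isolate_slot = int(rng.integers(0, n_variants + 1)) if has_isolate else -1
        isolate_id = None
        for v in range(n_variants + 1):
            gid = base_id if v == 0 else f"{base_id}_v{v}"
            s = seq if v == 0 else mutate_sequence(seq, rate, rng)
            if v == isolate_slot:
                prov, circ = Provenance.ISOLATE, False
                isolate_id = gid
            else:
                prov, circ = classes[int(rng.integers(0, len(classes)))]
            n_frag = 1 if circ else int(rng.integers(1, 4))
            frags = fragment_sequence(s, n_frag, 1000, rng)
            contigs = [
                ContigRecord(f"{gid}.c{j:03d}", f, source_genome=base_id)
                for j, f in enumerate(frags, start=1)
            ]
            genomes.append(
                GenomeRecord(
                    genome_id=gid,
                    contigs=contigs,
                    provenance=prov,
                    circular=circ and len(contigs) == 1,
                    completeness=float(np.round(rng.uniform(75, 100), 2)),
                    contamination=float(np.round(rng.uniform(0, 5), 2)),
                )
            )
            member_ids.append(gid)
        truth[base_id] = {"members": member_ids, "isolate": isolate_id}
    return genomes, truth


def make_shared_catalogs(
    n_all: int = 6,
    n_ab: int = 8,
    n_unique: tuple[int, int, int] = (2, 3, 4),
    genome_length_bp: int = 20_000,
    rate: float = 0.001,
    seed: int = 0,
):
    """Three per-community catalogs with planted Venn structure: n_all
    genome groups shared by all three communities, n_ab shared by A and B
    only, and per-community unique genomes. Shared copies differ by the
    planted substitution rate (ANI ~ 99.9). Returns (catalogs, truth)."""
    rng = np.random.default_rng(seed)
    names = ("A", "B", "C")
    catalogs: dict[str, list[GenomeRecord]] = {n: [] for n in names}

    def _genome(community: str, tag: str, seq: str) -> GenomeRecord:
        gid = f"{community}.{tag}"
        return GenomeRecord(
            genome_id=gid,
            contigs=[ContigRecord(f"{gid}.c001", seq, source_genome=tag)],
            provenance=Provenance.TIMEPOINT,
            completeness=95.0,
            contamination=1.0,
        )

    for i in range(n_all):
        base = random_genome_sequence(genome_length_bp, 0.5, rng)
        for n in names:
            catalogs[n].append(_genome(n, f"all{i:02d}", mutate_sequence(base, rate, rng)))
    for i in range(n_ab):
        base = random_genome_sequence(genome_length_bp, 0.5, rng)
        for n in ("A", "B"):
            catalogs[n].append(_genome(n, f"ab{i:02d}", mutate_sequence(base, rate, rng)))
    for n, k in zip(names, n_unique):
        for i in range(k):
            seq = random_genome_sequence(genome_length_bp, 0.5, rng)
            catalogs[n].append(_genome(n, f"uniq{i:02d}", seq))
    truth = {
        "shared_all": n_all,
        "shared_ab_only": n_ab,
        "unique": dict(zip(names, n_unique)),
    }
    return catalogs, truth


def make_redundancy_scenario(
    n_unique: int = 20,
    n_contained: int = 10,
    n_partial: int = 5,
    contig_bp: tuple[int, int] = (3000, 8000),
    partial_frac: float = 0.85,
    seed: int = 0,
):
    """Plant containment redundancy among unique contigs.

    Contained contigs are substrings (sometimes reverse-complemented, at
    up to 0.3% substitutions) of a unique parent, so >= 90% of the
    smaller contig aligns; partial contigs share only partial_frac of
    their length with a parent (below the removal cutoff). Returns
    (contigs, truth_redundant_ids)."""
    rng = np.random.default_rng(seed)
    comp = str.maketrans("ACGT", "TGCA")
    contigs: list[ContigRecord] = []
    for i in range(n_unique):
        length = int(rng.integers(contig_bp[0], contig_bp[1] + 1))
        contigs.append(
            ContigRecord(f"u{i:03d}", random_genome_sequence(length, 0.5, rng))
        )
    redundant: list[str] = []
    for i in range(n_contained):
        parent = contigs[int(rng.integers(0, n_unique))]
        sub_len = int(rng.integers(int(0.4 * parent.length_bp), int(0.8 * parent.length_bp)))
        start = int(rng.integers(0, parent.length_bp - sub_len + 1))
        seq = parent.sequence[start : start + sub_len]
        seq = mutate_sequence(seq, float(rng.uniform(0, 0.003)), rng)
        if rng.random() < 0.5:
            seq = seq.translate(comp)[::-1]
        cid = f"r{i:03d}"
        contigs.append(ContigRecord(cid, seq))
        redundant.append(cid)
    for i in range(n_partial):
        # keep the partial contig no longer than its parent so neither side
        # of the pair reaches the containment cutoff
        candidates = [c for c in contigs[:n_unique] if c.length_bp >= 3000]
        parent = candidates[int(rng.integers(0, len(candidates)))]
        total = int(rng.integers(3000, parent.length_bp + 1))
        shared = int(partial_frac * total)
        start = int(rng.integers(0, parent.length_bp - shared + 1))
        seq = parent.sequence[start : start + shared] + random_genome_sequence(
            total - shared, 0.5, rng
        )
        contigs.append(ContigRecord(f"p{i:03d}", seq))
    return contigs, set(redundant)


def make_association_scenario(
    n_bins: int = 8,
    n_mges: int = 30,
    n_switching: int = 4,
    timepoints: tuple[str, ...] = ("t1", "t2", "t3"),
    cspec: ContactSpec | None = None,
    mge_bp: int = 6000,
    genome_bp: int = 12_000,
    seed: int = 0,
):
    """MGE-host test bed: bins with distinct genera, MGEs with a host
    schedule in which n_switching MGEs switch to a different-genus host
    at the final time point. Returns (bins, mges, cspec, tables) with the
    ground-truth schedule inside cspec.host_schedule."""
    rng = np.random.default_rng(seed)
    bins: list[GenomeRecord] = []
    for i in range(n_bins):
        gid = f"bin{i:02d}"
        seq = random_genome_sequence(genome_bp, 0.5, rng)
        frags = fragment_sequence(seq, int(rng.integers(2, 5)), 1000, rng)
        bins.append(
            GenomeRecord(
                genome_id=gid,
                contigs=[
                    ContigRecord(f"{gid}.c{j:03d}", f, source_genome=gid)
                    for j, f in enumerate(frags, start=1)
                ],
                provenance=Provenance.TIMEPOINT,
                completeness=95.0,
                contamination=1.0,
                taxonomy=("Bacteria", "", "", "", "", f"Genus{i:02d}", ""),
            )
        )
    mges = [
        ContigRecord(f"mge{i:02d}", random_genome_sequence(mge_bp, 0.5, rng))
        for i in range(n_mges)
    ]
    schedule: dict[str, dict[str, str]] = {}
    switchers = rng.choice(n_mges, size=n_switching, replace=False)
    for i, m in enumerate(mges):
        home = int(rng.integers(0, n_bins))
        sched = {tp: bins[home].genome_id for tp in timepoints}
        if i in switchers:
            other = int((home + 1 + rng.integers(0, n_bins - 1)) % n_bins)
            sched[timepoints[-1]] = bins[other].genome_id
        schedule[m.contig_id] = sched
    base = cspec or ContactSpec()
    cspec = ContactSpec(
        intra_genome_rate=base.intra_genome_rate,
        mge_link_rate=base.mge_link_rate,
        background_rate=base.background_rate,
        host_schedule=schedule,
    )
    tables = [
        simulate_contacts(bins, mges, cspec, tp, seed=int(seed) * 1000 + j)
        for j, tp in enumerate(timepoints)
    ]
    return bins, mges, cspec, tables


def make_abundance_scenario(
    weights: tuple[float, ...] = (0.4, 0.25, 0.15, 0.12, 0.08),
    total_depth: float = 100.0,
    contig_bp: int = 5000,
    n_contigs: int = 2,
    dispersion: float = 20.0,
    outlier_frac: float = 0.02,
    outlier_mult: float = 20.0,
    seed: int = 0,
):
    """Genomes at planted relative abundances: each genome's per-position
    depth is drawn at mean total_depth * weight, with outlier positions
    planted so the IQR filter has work to do. Returns (profiles_by_genome,
    weights) where profiles_by_genome maps genome id -> list of
    (ContigRecord, DepthProfile)."""
    rng = np.random.default_rng(seed)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    out: dict[str, list[tuple[ContigRecord, DepthProfile]]] = {}
    for i, w in enumerate(weights):
        gid = f"g{i:02d}"
        items = []
        for j in range(n_contigs):
            contig = ContigRecord(
                f"{gid}.c{j:03d}",
                random_genome_sequence(contig_bp, 0.5, rng),
                source_genome=gid,
            )
            prof = simulate_depth(
                contig,
                mean_depth=total_depth * w,
                dispersion=dispersion,
                outlier_frac=outlier_frac,
                outlier_mult=outlier_mult,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            items.append((contig, prof))
        out[gid] = items
    return out, dict(zip(out.keys(), weights))
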