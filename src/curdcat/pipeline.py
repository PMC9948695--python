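"""End-to-end orchestration of the pipeline stages on one JSON config.

The workflow mirrors the longitudinal study design: simulate a community
with ground truth, dereplicate its genomes into a catalog, build a
mega-assembly after redundancy removal, profile coverage-based
abundances and taxonomic composition, associate MGEs with hosts across
time points and flag host changes, and partition/enrich the pangenome.
Each stage writes plain-text outputs under its own directory and the
run manifest records parameters and content digests, so a rerun with
the same config and seed reproduces identical digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import dereplicate as derep  # noqa: F401
from .dereplicate import dereplicate as _dereplicate, clusters_to_frame as _clusters_to_frame, compare_catalogs as _compare_catalogs
from . import hostlink, io, mega, pangenome, profiles, simulate
from .records import TaxProfile, Thresholds

log = logging.getLogger("curdcat")

STAGES = [
    "simulate",
    "dereplicate",
    "mega_assemble",
    "abundance",
    "ordinate",
    "associate",
    "track",
    "pangenome",
    "enrich",
]

DEFAULT_CONFIG = {
    "seed": 1,
    "outdir": "curdcat_run",
    "thresholds": {},
    "stages": STAGES,
    "simulate": {
        "n_genomes": 6,
        "genome_length_bp": 20_000,
        "n_variants": 1,
        "strain_rate": 0.002,
        "timepoints": ["t1", "t2", "t3"],
        "n_mges": 12,
        "n_switching": 2,
        "n_bins": 6,
        "redundancy": {"n_unique": 10, "n_contained": 4, "n_partial": 2},
        "pangenome": {
            "n_group_a": 12,
            "n_group_b": 12,
            "n_core": 30,
            "n_enriched": 10,
            "n_null": 100,
        },
    },
    "associate": {"min_links": 5, "dominance_ratio": 3.0},
    "dereplicate": {"kmer": 21, "sketch_size": None},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = json.load(fh)
    else:
        user = dict(path_or_dict or {})
    return _merge(DEFAULT_CONFIG, user)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def run_pipeline(config, seed: int | None = None) -> dict:
    """Execute the configured stages in dependency order.

    Returns the run manifest (also written to <outdir>/manifest.json):
    per stage the inputs, parameters, output paths and sha256 digests.
    A stage failure aborts the run with the failing stage named; partial
    outputs are kept next to a ``<stage>.partial`` marker file.
    """
    cfg = load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    rng_seed = int(cfg["seed"])
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    t = Thresholds.from_dict(cfg.get("thresholds", {}))
    stages = [s for s in STAGES if s in cfg["stages"]]
    unknown_stages = set(cfg["stages"]) - set(STAGES)
    if unknown_stages:
        raise ValueError(f"unknown stages: {sorted(unknown_stages)}")

    # every externally referenced input must exist before any stage runs
    for name, path in cfg.get("inputs", {}).items():
        if not Path(path).exists():
            raise FileNotFoundError(f"configured input {name!r} not found: {path}")

    manifest: dict = {"config": cfg, "stages": {}}
    state: dict = {}

    for stage in stages:
        marker = outdir / f"{stage}.partial"
        marker.touch()
        started = time.perf_counter()
        try:
            outputs = _STAGE_FNS[stage](cfg, t, rng_seed, outdir, state)
        except Exception as e:
            log.error("stage %r failed: %s", stage, e)
            raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
        marker.unlink()
        elapsed = time.perf_counter() - started
        manifest["stages"][stage] = {
            "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in outputs},
            "seconds": round(elapsed, 3),
        }
        log.info("stage %-13s done in %.2fs (%d outputs)", stage, elapsed, len(outputs))

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str, sort_keys=True)
    return manifest


# ------------------------------------------------------------------ stages


def _simulate_state(cfg, seed, state):
    """Populate the in-memory simulation state (pure compute, no writes)."""
    p = cfg["simulate"]
    rng = np.random.default_rng(seed)

    spec = simulate.CommunitySpec(
        n_genomes=p["n_genomes"],
        genome_length_bp=p["genome_length_bp"],
        strain_groups=[
            (i, p["strain_rate"]) for i in range(p["n_genomes"]) for _ in range(p["n_variants"])
        ],
        n_timepoints=len(p["timepoints"]),
        seed=seed,
    )
    state["genomes"] = simulate.make_community(spec)

    contigs, truth_red = simulate.make_redundancy_scenario(seed=seed, **p["redundancy"])
    state["unbinned"] = contigs
    state["truth_redundant"] = truth_red

    bins, mges, cspec, tables = simulate.make_association_scenario(
        n_bins=p["n_bins"],
        n_mges=p["n_mges"],
        n_switching=p["n_switching"],
        timepoints=tuple(p["timepoints"]),
        seed=seed,
    )
    state.update(bins=bins, mges=mges, cspec=cspec, contact_tables=tables)

    depth_items, weights = simulate.make_abundance_scenario(seed=seed)
    state["depth_items"] = depth_items
    state["planted_weights"] = weights

    # taxonomic profiles per time point: stable genus weights + noise,
    # plus rare genera under the "Rest" cutoff
    genera = [f"Genus{i:02d}" for i in range(p["n_genomes"])]
    base_w = rng.dirichlet(np.full(len(genera), 2.0))
    tax = []
    for tp in p["timepoints"]:
        w = base_w * rng.lognormal(0, 0.3, size=len(genera))
        counts = {g: float(np.round(1e5 * x / w.sum(), 3)) for g, x in zip(genera, w)}
        counts["RareGenusX"] = 10.0
        counts["RareGenusY"] = 5.0
        tax.append(TaxProfile(sample_id="community", timepoint=str(tp), counts=counts))
    state["tax_profiles"] = tax

    state["pangenome_matrix"] = simulate.simulate_pangenome(seed=seed, **p["pangenome"])
    return state


def _ensure_sim(cfg, seed, state):
    if "genomes" not in state:
        log.info("simulate stage not selected; regenerating inputs in memory from seed")
        _simulate_state(cfg, seed, state)


def _stage_simulate(cfg, t, seed, outdir, state):
    _simulate_state(cfg, seed, state)
    d = outdir / "simulated"
    d.mkdir(parents=True, exist_ok=True)
    io.write_genomes(state["genomes"], d / "genomes")
    io.write_contigs_fasta(state["unbinned"], d / "unbinned.fasta")
    io.write_contigs_fasta(state["mges"], d / "mges.fasta")
    io.write_contacts(state["contact_tables"], d / "contacts.tsv")
    io.write_depth_profiles(
        [prof for items in state["depth_items"].values() for _, prof in items],
        d / "depth.tsv",
    )
    io.write_tax_profiles(state["tax_profiles"], d / "tax_profiles.tsv")
    matrix = state["pangenome_matrix"]
    pres = pd.DataFrame(
        matrix.presence.astype(int), index=matrix.genome_ids, columns=matrix.cluster_ids
    )
    pres.insert(0, "genome_id", pres.index)
    _write_tsv(pres, d / "presence.tsv")

    return [
        d / "genomes" / "bin_metadata.tsv",
        d / "unbinned.fasta",
        d / "mges.fasta",
        d / "contacts.tsv",
        d / "depth.tsv",
        d / "tax_profiles.tsv",
        d / "presence.tsv",
    ]


def _stage_dereplicate(cfg, t, seed, outdir, state):
    _ensure_sim(cfg, seed, state)
    p = cfg["dereplicate"]
    clusters = _dereplicate(
        state["genomes"], t, k=p["kmer"], sketch_size=p["sketch_size"]
    )
    state["clusters"] = clusters
    reps = {c.representative_id for c in clusters}
    state["catalog"] = [g for g in state["genomes"] if g.genome_id in reps]
    return [_write_tsv(_clusters_to_frame(clusters), outdir / "catalog" / "clusters.tsv")]


def _stage_mega(cfg, t, seed, outdir, state):
    _ensure_sim(cfg, seed, state)
    hits = mega.find_overlaps(state["unbinned"], t)
    nonredundant = mega.remove_redundant(state["unbinned"], hits, t)
    assembly = mega.build_mega_assembly(nonredundant, [], state["catalog"], t)
    state["mega"] = assembly
    d = outdir / "mega"
    d.mkdir(parents=True, exist_ok=True)
    hits_df = pd.DataFrame(
        [
            {
                "qseqid": h.query_id,
                "sseqid": h.subject_id,
                "pident": round(h.identity, 3),
                "qcovs": round(100 * h.query_coverage, 2),
                "length": h.aligned_bp,
            }
            for h in hits
        ],
        columns=["qseqid", "sseqid", "pident", "qcovs", "length"],
    )
    _write_tsv(hits_df, d / "overlaps.tsv")
    io.write_contigs_fasta(assembly.contigs, d / "mega_assembly.fasta")
    candidates = mega.select_mge_candidates(assembly, t)
    _write_tsv(
        pd.DataFrame(
            {"contig_id": [c.contig_id for c in candidates],
             "length_bp": [c.length_bp for c in candidates]}
        ),
        d / "mge_candidates.tsv",
    )
    return [d / "overlaps.tsv", d / "mega_assembly.fasta", d / "mge_candidates.tsv"]


def _stage_abundance(cfg, t, seed, outdir, state):
    _ensure_sim(cfg, seed, state)
    d = outdir / "abundance"
    coverages = {
        gid: profiles.genome_coverage([prof for _, prof in items])
        for gid, items in state["depth_items"].items()
    }
    rel = profiles.relative_abundance(coverages)
    df = pd.DataFrame(
        {
            "genome_id": list(coverages),
            "iqr_coverage": [coverages[g] for g in coverages],
            "relative_abundance": [rel[g] for g in coverages],
        }
    )
    out = [_write_tsv(df, d / "abundance.tsv")]
    collapsed = [profiles.collapse_profile(p, t) for p in state["tax_profiles"]]
    state["collapsed_profiles"] = collapsed
    out.append(io.write_tax_profiles(collapsed, d / "collapsed_profiles.tsv"))
    return out


def _stage_ordinate(cfg, t, seed, outdir, state):
    _ensure_sim(cfg, seed, state)
    d = outdir / "ordination"
    coords, explained = profiles.bray_curtis_ordination(state["tax_profiles"], n_axes=2)
    coords = coords.round(9)
    coords.insert(0, "sample", coords.index)
    out = [_write_tsv(coords, d / "coordinates.tsv")]
    ev = pd.DataFrame(
        {"axis": [f"PC{i+1}" for i in range(len(explained))],
         "explained_proportion": np.round(explained, 9)}
    )
    out.append(_write_tsv(ev, d / "explained.tsv"))
    return out


def _stage_associate(cfg, t, seed, outdir, state):
    _ensure_sim(cfg, seed, state)
    p = cfg["associate"]
    records = []
    for table in state["contact_tables"]:
        records.extend(
            hostlink.associate(
                table,
                state["mges"],
                state["bins"],
                min_links=p["min_links"],
                dominance_ratio=p["dominance_ratio"],
            )
        )
    state["associations"] = records
    return [
        _write_tsv(
            hostlink.associations_to_frame(records),
            outdir / "associations" / "associations.tsv",
        )
    ]


def _stage_track(cfg, t, seed, outdir, state):
    if "associations" not in state:
        raise RuntimeError("stage 'track' requires stage 'associate' in the same run")
    d = outdir / "associations"
    records = state["associations"]
    hist = hostlink.persistence_histogram(records)
    out = [
        _write_tsv(
            pd.DataFrame(
                {"n_timepoints": list(hist), "n_mge_host_pairs": list(hist.values())}
            ),
            d / "persistence.tsv",
        )
    ]
    tps = [t.timepoint for t in state["contact_tables"]]
    events = hostlink.detect_host_changes(records, timepoint_order=tps)
    out.append(
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "mge_id": e.mge_id,
                        "timepoint_from": e.timepoint_from,
                        "timepoint_to": e.timepoint_to,
                        "host_from": e.host_from,
                        "host_to": e.host_to,
                        "level": e.level,
                        "flagged_hgt": e.flagged_hgt,
                    }
                    for e in events
                ],
                columns=[
                    "mge_id", "timepoint_from", "timepoint_to",
                    "host_from", "host_to", "level", "flagged_hgt",
                ],
            ),
            d / "host_changes.tsv",
        )
    )
    graph = hostlink.export_association_graph(records, state["bins"])
    graph_path = d / "association_graph.graphml"
    nx.write_graphml(graph, graph_path)
    out.append(graph_path)
    return out


def _stage_pangenome(cfg, t, seed, outdir, state):
    _ensure_sim(cfg, seed, state)
    d = outdir / "pangenome"
    m = state["pangenome_matrix"]
    soft = pangenome.partition_soft_core(m, t)
    strict = pangenome.partition_strict(m)
    df = pd.DataFrame(
        {
            "cluster_id": m.cluster_ids,
            "soft_core": [soft[c] for c in m.cluster_ids],
            "strict": [strict[c] for c in m.cluster_ids],
            "category": [m.categories[c] for c in m.cluster_ids],
        }
    )
    out = [_write_tsv(df, d / "partition.tsv")]
    out.append(_write_tsv(pangenome.partition_summary(m, strict), d / "category_composition.tsv"))
    return out


def _stage_enrich(cfg, t, seed, outdir, state):
    _ensure_sim(cfg, seed, state)
    d = outdir / "pangenome"
    m = state["pangenome_matrix"]
    group_a = sorted(set(m.group_labels))[0]
    results = pangenome.enrich(m, group_a, t)
    return [_write_tsv(pangenome.enrichment_table(results).round(9), d / "enrichment.tsv")]


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "dereplicate": _stage_dereplicate,
    "mega_assemble": _stage_mega,
    "abundance": _stage_abundance,
    "ordinate": _stage_ordinate,
    "associate": _stage_associate,
    "track": _stage_track,
    "pangenome": _stage_pangenome,
    "enrich": _stage_enrich,
}
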