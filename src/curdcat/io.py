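"""Readers and writers for the plain-text formats the pipeline consumes.

Sequences travel as FASTA (one file per genome, parsed with Bio.SeqIO),
tabular data as TSV (pandas): bin metadata, per-position depth profiles,
Hi-C contact pairs, taxonomic count profiles, MGE labels, and gene-cluster
presence/absence matrices with annotations and group labels.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (
    ContactTable,
    ContigRecord,
    DepthProfile,
    GenomeRecord,
    Provenance,
    TaxProfile,
    Thresholds,
)

log = logging.getLogger("curdcat")

METADATA_COLUMNS = [
    "genome_id",
    "provenance",
    "circular",
    "completeness",
    "contamination",
    "taxonomy",
]


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str})
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: metadata table missing columns {sorted(missing)}")
    if df["genome_id"].duplicated().any():
        dups = df.loc[df["genome_id"].duplicated(), "genome_id"].tolist()
        raise ValueError(f"{path}: duplicate genome_id rows {dups}")
    return df


def _parse_fasta(path: Path) -> list[ContigRecord]:
    contigs = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            contigs.append(ContigRecord(contig_id=rec.id, sequence=str(rec.seq)))
    except ValueError as e:  # Bio.SeqIO signals malformed records with ValueError
        raise ValueError(f"{path}: malformed FASTA ({e})") from e
    if not contigs:
        raise ValueError(f"{path}: empty or non-FASTA file")
    return contigs


def read_genomes(paths, metadata: pd.DataFrame | str | Path | None = None) -> list[GenomeRecord]:
    """Read one genome per FASTA file; join bin metadata by genome_id.

    The genome_id is the FASTA file stem. Genomes without a metadata row
    default to provenance=coassembly with quality fields flagged missing
    (None); they can be inspected but not quality-filtered.
    """
    if metadata is not None and not isinstance(metadata, pd.DataFrame):
        metadata = read_metadata(metadata)
    meta_by_id = (
        {} if metadata is None else {r.genome_id: r for r in metadata.itertuples()}
    )
    genomes: list[GenomeRecord] = []
    seen: set[str] = set()
    for p in map(Path, paths):
        gid = p.stem
        if gid in seen:
            raise ValueError(f"duplicate genome_id {gid!r} (from {p})")
        seen.add(gid)
        contigs = _parse_fasta(p)
        row = meta_by_id.get(gid)
        if row is None:
            genomes.append(GenomeRecord(genome_id=gid, contigs=contigs))
            continue
        genomes.append(
            GenomeRecord(
                genome_id=gid,
                contigs=contigs,
                provenance=Provenance(row.provenance),
                circular=_parse_bool(row.circular),
                completeness=_opt_float(row.completeness),
                contamination=_opt_float(row.contamination),
                taxonomy=row.taxonomy if isinstance(row.taxonomy, str) else "",
            )
        )
    return genomes


def _parse_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in {"true", "1", "yes"}
    return bool(v)


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return None
    return float(v)


def write_genomes(genomes: list[GenomeRecord], outdir) -> Path:
    """Write one FASTA per genome plus a bin-metadata TSV; returns outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for g in genomes:
        recs = [
            SeqRecord(Seq(c.sequence), id=c.contig_id, description="")
            for c in g.contigs
        ]
        SeqIO.write(recs, str(outdir / f"{g.genome_id}.fasta"), "fasta")
        rows.append(
            {
                "genome_id": g.genome_id,
                "provenance": g.provenance.value,
                "circular": g.circular,
                "completeness": g.completeness,
                "contamination": g.contamination,
                "taxonomy": g.taxonomy_string(),
            }
        )
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(
        outdir / "bin_metadata.tsv", sep="\t", index=False
    )
    return outdir


def write_contigs_fasta(contigs: list[ContigRecord], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    recs = [SeqRecord(Seq(c.sequence), id=c.contig_id, description="") for c in contigs]
    SeqIO.write(recs, str(path), "fasta")
    return path


def read_contigs_fasta(path) -> list[ContigRecord]:
    return _parse_fasta(Path(path))


# ---------------------------------------------------------------- depth TSV

def write_depth_profiles(profiles: list[DepthProfile], path) -> Path:
    """TSV with columns contig_id, position (1-based), depth."""
    path = Path(path)
    frames = [
        pd.DataFrame(
            {
                "contig_id": p.contig_id,
                "position": range(1, p.depths.size + 1),
                "depth": p.depths,
            }
        )
        for p in profiles
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
    return path


def read_depth_profiles(path) -> list[DepthProfile]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for cid, grp in df.groupby("contig_id", sort=False):
        grp = grp.sort_values("position")
        out.append(DepthProfile(contig_id=str(cid), depths=grp["depth"].to_numpy()))
    return out


# ------------------------------------------------------------- contacts TSV

def write_contacts(tables: list[ContactTable], path) -> Path:
    """Pairs TSV: contig_a, contig_b, timepoint, evidence, n_links."""
    rows = []
    for t in tables:
        for (a, b), n in sorted(t.links.items()):
            ev = "+".join(sorted(t.evidence[(a, b)]))
            rows.append((a, b, t.timepoint, ev, n))
    pd.DataFrame(
        rows, columns=["contig_a", "contig_b", "timepoint", "evidence", "n_links"]
    ).to_csv(path, sep="\t", index=False)
    return Path(path)


def read_contacts(path) -> list[ContactTable]:
    df = pd.read_csv(path, sep="\t", dtype={"timepoint": str})
    tables = []
    for tp, grp in df.groupby("timepoint", sort=True):
        t = ContactTable(timepoint=str(tp))
        for r in grp.itertuples():
            evs = str(r.evidence).split("+")
            t.add(r.contig_a, r.contig_b, int(r.n_links), evs[0])
            key = t._key(r.contig_a, r.contig_b)
            for ev in evs[1:]:  # extra evidence types tag the pair, count stored once
                if ev not in ContactTable.EVIDENCE:
                    raise ValueError(f"unknown evidence type {ev!r}")
                t.evidence[key].add(ev)
        tables.append(t)
    return tables


# ------------------------------------------------------------- profiles TSV

def write_tax_profiles(profiles: list[TaxProfile], path) -> Path:
    rows = [
        (p.sample_id, p.timepoint, taxon, count)
        for p in profiles
        for taxon, count in sorted(p.counts.items())
    ]
    pd.DataFrame(rows, columns=["sample_id", "timepoint", "taxon", "count"]).to_csv(
        path, sep="\t", index=False
    )
    return Path(path)


def read_tax_profiles(path) -> list[TaxProfile]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "timepoint": str})
    out = []
    for (sid, tp), grp in df.groupby(["sample_id", "timepoint"], sort=False):
        out.append(
            TaxProfile(
                sample_id=str(sid),
                timepoint=str(tp),
                counts=dict(zip(grp["taxon"], grp["count"].astype(float))),
            )
        )
    return out


# ---------------------------------------------------------------- config

def load_thresholds(path) -> Thresholds:
    """JSON config mirroring Thresholds; unknown keys are an error."""
    with open(path) as fh:
        return Thresholds.from_dict(json.load(fh))
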