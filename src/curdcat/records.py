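"""Core domain types shared by every pipeline stage.

The central objects are :class:`GenomeRecord` (a MAG or isolate assembly
with provenance and CheckM-style quality metrics), :class:`ContigRecord`,
the per-position :class:`DepthProfile`, the Hi-C :class:`ContactTable`,
taxonomic count profiles, and the :class:`Thresholds` bundle that houses
every numeric cutoff used across the pipeline.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields

import numpy as np

__all__ = [
    "Provenance",
    "RANKS",
    "ContigRecord",
    "GenomeRecord",
    "Thresholds",
    "DepthProfile",
    "TaxProfile",
    "ContactTable",
    "filter_high_quality",
    "is_high_quality",
]

#: Taxonomic ranks carried on a genome, ordered domain -> species.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

_VALID_BASES = frozenset("ACGTN")


class Provenance(str, enum.Enum):
    """Where an assembly came from; drives representative selection."""

    ISOLATE = "isolate"
    TIMEPOINT = "timepoint_assembly"
    COASSEMBLY = "coassembly"
    SHORT_READ = "short_read_assembly"


@dataclass
class ContigRecord:
    """A single contig: id, uppercase DNA over {A,C,G,T,N}.

    ``source_genome`` carries the simulator's ground-truth origin and is
    absent (None) for real data.
    """

    contig_id: str
    sequence: str
    source_genome: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"contig {self.contig_id!r}: empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(
                f"contig {self.contig_id!r}: non-ACGTN characters {sorted(bad)}"
            )

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


def _norm_taxonomy(taxonomy) -> tuple[str, ...]:
    """Normalise taxonomy input to a 7-tuple of rank names.

    Accepts a sequence of up to 7 ranks or a semicolon-joined string;
    GTDB-style ``d__`` / ``g__`` prefixes are stripped. Missing trailing
    ranks become empty strings.
    """
    if taxonomy is None:
        ranks: list[str] = []
    elif isinstance(taxonomy, str):
        ranks = [r.strip() for r in taxonomy.split(";")] if taxonomy else []
    else:
        ranks = [str(r) for r in taxonomy]
    out = []
    for r in ranks:
        if len(r) >= 3 and r[1:3] == "__":
            r = r[3:]
        out.append(r)
    if len(out) > len(RANKS):
        raise ValueError(f"taxonomy has {len(out)} ranks; at most {len(RANKS)} allowed")
    out.extend([""] * (len(RANKS) - len(out)))
    return tuple(out)


@dataclass
class GenomeRecord:
    """A genome/MAG/isolate assembly plus provenance, quality and taxonomy.

    Quality fields (completeness, contamination) may be None when the
    metadata table had no row for this genome; such genomes survive
    reading but are rejected by :func:`filter_high_quality`.
    """

    genome_id: str
    contigs: list[ContigRecord]
    provenance: Provenance = Provenance.COASSEMBLY
    circular: bool = False
    completeness: float | None = None
    contamination: float | None = None
    taxonomy: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError(f"genome {self.genome_id!r}: no contigs")
        self.provenance = Provenance(self.provenance)
        self.taxonomy = _norm_taxonomy(self.taxonomy)
        # circularity only meaningful for single-contig assemblies
        if self.circular and len(self.contigs) != 1:
            self.circular = False
        for name in ("completeness", "contamination"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= float(v) <= 100.0):
                raise ValueError(
                    f"genome {self.genome_id!r}: {name}={v} outside [0, 100]"
                )

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)

    @property
    def length_bp(self) -> int:
        return sum(c.length_bp for c in self.contigs)

    @property
    def genus(self) -> str:
        return self.taxonomy[RANKS.index("genus")] if self.taxonomy else ""

    def taxonomy_string(self) -> str:
        return ";".join(self.taxonomy)


@dataclass
class Thresholds:
    """Every numeric cutoff used by the pipeline, with its default.

    ani_same_genome        ANI (%) above which two genomes are "the same"
    overlap_redundant_frac fraction of a contig that must be covered for
                           it to count as redundant
    overlap_identity       percent identity required of overlap alignments
    min_contig_bp          contigs below this are dropped from assemblies
    min_mge_candidate_bp   MGE prediction considers contigs strictly longer
    hq_completeness        high-quality requires completeness strictly >
    hq_contamination       ... contamination strictly <
    hq_max_contigs         ... contig count strictly <
    soft_core_frac         soft-core = present in at least this fraction
    enrichment_q           BH-corrected q-value cutoff for enrichment
    rest_frac              taxa below this relative abundance fold into
                           the "Rest" category
    """

    ani_same_genome: float = 99.0
    overlap_redundant_frac: float = 0.90
    overlap_identity: float = 99.0
    min_contig_bp: int = 1000
    min_mge_candidate_bp: int = 5000
    hq_completeness: float = 70.0
    hq_contamination: float = 10.0
    hq_max_contigs: int = 20
    soft_core_frac: float = 0.95
    enrichment_q: float = 0.10
    rest_frac: float = 0.01

    def __post_init__(self) -> None:
        for name in ("overlap_redundant_frac", "soft_core_frac", "enrichment_q", "rest_frac"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name}={v} outside (0, 1]")
        for name in ("ani_same_genome", "overlap_identity", "hq_completeness", "hq_contamination"):
            v = getattr(self, name)
            if not (0.0 < v <= 100.0):
                raise ValueError(f"{name}={v} outside (0, 100]")

    @classmethod
    def from_dict(cls, d: dict) -> "Thresholds":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown threshold names: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class DepthProfile:
    """Per-position read depth of one contig."""

    contig_id: str
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths)
        if self.depths.ndim != 1 or self.depths.size < 1:
            raise ValueError(f"profile {self.contig_id!r}: need a 1-D vector of length >= 1")
        if np.any(self.depths < 0):
            raise ValueError(f"profile {self.contig_id!r}: negative depths")


@dataclass
class TaxProfile:
    """Taxonomic counts for one sample at one time point."""

    sample_id: str
    timepoint: str
    counts: dict[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError(f"profile {self.sample_id!r}: negative counts")

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))


class ContactTable:
    """Hi-C / long-read link counts between contig pairs at one time point.

    Pairs are unordered (stored as sorted tuples) so the table is symmetric
    by construction. Each pair carries a count and the set of evidence
    types ({"hic", "long_read"}) that contributed.
    """

    EVIDENCE = frozenset({"hic", "long_read"})

    def __init__(self, timepoint: str):
        self.timepoint = timepoint
        self.links: dict[tuple[str, str], int] = {}
        self.evidence: dict[tuple[str, str], set[str]] = {}

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, n: int, evidence: str = "hic") -> None:
        if n < 0:
            raise ValueError("link count must be >= 0")
        if evidence not in self.EVIDENCE:
            raise ValueError(f"unknown evidence type {evidence!r}")
        if n == 0:
            return
        k = self._key(a, b)
        self.links[k] = self.links.get(k, 0) + int(n)
        self.evidence.setdefault(k, set()).add(evidence)

    def count(self, a: str, b: str) -> int:
        return self.links.get(self._key(a, b), 0)

    def neighbours(self, contig: str):
        """Yield (other_contig, count, evidence) for every linked partner."""
        for (a, b), n in self.links.items():
            if a == contig:
                yield b, n, self.evidence[(a, b)]
            elif b == contig:
                yield a, n, self.evidence[(a, b)]

    def contig_ids(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.links:
            out.add(a)
            out.add(b)
        return out

    def __len__(self) -> int:
        return len(self.links)


def is_high_quality(g: GenomeRecord, t: Thresholds) -> bool:
    """True iff the genome passes the high-quality MAG thresholds
    (completeness strictly above, contamination strictly below, contig
    count strictly below — all three inequalities are strict)."""
    if g.completeness is None or g.contamination is None:
        raise ValueError(f"genome {g.genome_id!r}: missing quality metrics")
    return (
        g.completeness > t.hq_completeness
        and g.contamination < t.hq_contamination
        and g.n_contigs < t.hq_max_contigs
    )


def filter_high_quality(
    genomes: list[GenomeRecord], t: Thresholds | None = None
) -> list[GenomeRecord]:
    """Keep exactly the high-quality genomes, preserving input order."""
    t = t or Thresholds()
    return [g for g in genomes if is_high_quality(g, t)]
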