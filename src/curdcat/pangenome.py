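"""Pangenome partitioning and group functional enrichment.

Gene clusters are partitioned either by the soft-core rule (core =
present in at least a fraction ``soft_core_frac`` of genomes, default
95%) or strictly into core (all genomes), shell (2+ but not all) and
cloud (exactly one genome). Functional enrichment between two genome
groups (e.g. cheese vs non-cheese isolates) uses a two-sided Fisher
exact test per function with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .records import Thresholds

log = logging.getLogger("curdcat")

#: COG functional category letters used for annotation bookkeeping.
COG_CATEGORIES = "JKLDVTMNUOCGEFHIPQRS"


@dataclass
class GeneClusterMatrix:
    """Genomes x gene-clusters presence/absence with annotations.

    presence[i, j] is True iff genome i carries cluster j. Each cluster
    has a function annotation (accession such as ``COG0001`` plus a
    one-letter category); each genome has a group label (e.g. "cheese" /
    "other"). ``truth`` optionally carries simulator ground-truth labels
    per cluster ("core" / "enriched" / "null").
    """

    genome_ids: list[str]
    group_labels: list[str]
    cluster_ids: list[str]
    functions: dict[str, str]  # cluster_id -> function accession
    categories: dict[str, str]  # cluster_id -> COG category letter
    presence: np.ndarray
    truth: dict[str, str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        n_g, n_c = self.presence.shape
        if n_g != len(self.genome_ids) or n_c != len(self.cluster_ids):
            raise ValueError("presence matrix shape does not match genome/cluster lists")
        if len(self.group_labels) != n_g:
            raise ValueError("group labels must cover all genomes")
        empty = ~self.presence.any(axis=0)
        if empty.any():
            bad = [self.cluster_ids[j] for j in np.flatnonzero(empty)]
            raise ValueError(f"all-absent clusters not allowed: {bad[:5]}")

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)

    def presence_fraction(self) -> np.ndarray:
        return self.presence.mean(axis=0)


@dataclass
class EnrichmentResult:
    """One function's 2x2 test: genomes with/without the function x group."""

    function_id: str
    a_with: int
    a_without: int
    b_with: int
    b_without: int
    p_value: float
    q_value: float
    enriched_group: str

    @property
    def table(self) -> list[list[int]]:
        return [[self.a_with, self.a_without], [self.b_with, self.b_without]]


def partition_soft_core(m: GeneClusterMatrix, t: Thresholds | None = None) -> dict[str, str]:
    """Label each cluster core/accessory by the soft-core rule
    (present in >= soft_core_frac of genomes)."""
    t = t or Thresholds()
    if m.n_genomes < 2:
        raise ValueError("need at least 2 genomes to partition a pangenome")
    frac = m.presence_fraction()
    return {
        cid: ("core" if f >= t.soft_core_frac else "accessory")
        for cid, f in zip(m.cluster_ids, frac)
    }


def partition_strict(m: GeneClusterMatrix) -> dict[str, str]:
    """Label clusters core (all genomes) / shell (2..n-1) / cloud (1)."""
    if m.n_genomes < 2:
        raise ValueError("need at least 2 genomes to partition a pangenome")
    n_present = m.presence.sum(axis=0)
    labels = {}
    for cid, k in zip(m.cluster_ids, n_present):
        if k == m.n_genomes:
            labels[cid] = "core"
        elif k == 1:
            labels[cid] = "cloud"
        else:
            labels[cid] = "shell"
    return labels


def partition_summary(m: GeneClusterMatrix, labels: dict[str, str]) -> pd.DataFrame:
    """Per-partition COG-category composition (counts of clusters)."""
    rows = [
        {"cluster_id": cid, "label": labels[cid], "category": m.categories.get(cid, "")}
        for cid in m.cluster_ids
    ]
    df = pd.DataFrame(rows)
    return (
        df.groupby(["label", "category"]).size().rename("n_clusters").reset_index()
    )


def enrich(
    m: GeneClusterMatrix,
    group_a_label: str,
    t: Thresholds | None = None,
    per_cluster: bool = False,
) -> list[EnrichmentResult]:
    """Test every function for differential presence between two groups.

    A genome "has" a function iff any of its gene clusters carries that
    annotation (set per_cluster=True to test clusters individually).
    Two-sided Fisher exact p-values are BH-adjusted across all tested
    functions; results are returned for every function, sorted by q then
    p, with enriched_group set to the group with the higher presence
    fraction. Callers filter at q < t.enrichment_q.
    """
    t = t or Thresholds()
    groups = sorted(set(m.group_labels))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    if group_a_label not in groups:
        raise ValueError(f"unknown group {group_a_label!r}")
    group_b_label = next(g for g in groups if g != group_a_label)
    in_a = np.array([g == group_a_label for g in m.group_labels])
    n_a, n_b = int(in_a.sum()), int((~in_a).sum())
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 genomes")

    if per_cluster:
        units = {cid: [j] for j, cid in enumerate(m.cluster_ids)}
    else:
        units = {}
        for j, cid in enumerate(m.cluster_ids):
            units.setdefault(m.functions.get(cid, cid), []).append(j)

    names = sorted(units)
    pvals = np.empty(len(names))
    tables = []
    for i, fn in enumerate(names):
        has = m.presence[:, units[fn]].any(axis=1)
        a_with = int((has & in_a).sum())
        b_with = int((has & ~in_a).sum())
        tab = [[a_with, n_a - a_with], [b_with, n_b - b_with]]
        pvals[i] = fisher_exact(tab, alternative="two-sided")[1]
        tables.append(tab)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")

    results = []
    for fn, tab, p, q in zip(names, tables, pvals, qvals):
        frac_a = tab[0][0] / n_a
        frac_b = tab[1][0] / n_b
        enriched = group_a_label if frac_a >= frac_b else group_b_label
        results.append(
            EnrichmentResult(
                function_id=fn,
                a_with=tab[0][0],
                a_without=tab[0][1],
                b_with=tab[1][0],
                b_without=tab[1][1],
                p_value=float(p),
                q_value=float(max(q, p)),
                enriched_group=enriched,
            )
        )
    results.sort(key=lambda r: (r.q_value, r.p_value, r.function_id))
    return results


def significant(results: list[EnrichmentResult], t: Thresholds | None = None):
    t = t or Thresholds()
    return [r for r in results if r.q_value < t.enrichment_q]


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "function_id": r.function_id,
                "a_with": r.a_with,
                "a_without": r.a_without,
                "b_with": r.b_with,
                "b_without": r.b_without,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "enriched_group": r.enriched_group,
            }
            for r in results
        ]
    )
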