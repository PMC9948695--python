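"""Coverage and community-profile statistics.

The central statistic is the IQR-filtered mean coverage: per contig,
positions whose depth lies within the interquartile range (25th-75th
percentile, closed interval, linear-interpolation percentiles) are kept
and averaged, which robustly discounts repeat/mobile-region pileups.
Contig values are combined per genome as a length-weighted mean, and
genome coverages normalised to relative abundances. Taxonomic profiles
are collapsed with the "Rest" rule (taxa under 1% fold into one
category) and ordinated by principal coordinate analysis of Bray-Curtis
dissimilarities.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import pcoa

from .records import DepthProfile, TaxProfile, Thresholds

log = logging.getLogger("curdcat")

__all__ = [
    "iqr_mean_coverage",
    "genome_coverage",
    "relative_abundance",
    "mapped_fraction",
    "collapse_profile",
    "bray_curtis",
    "bray_curtis_ordination",
]


def iqr_mean_coverage(p: DepthProfile, percentile_method: str = "linear") -> float:
    """Mean depth over positions with q1 <= depth <= q3.

    q1/q3 are the 25th/75th percentiles of the depth values (linear
    interpolation between order statistics by default). The closed
    interval means positions equal to a percentile are kept, so the
    filter never empties a profile; the plain mean is a pure fallback.
    """
    depths = p.depths
    if depths.size == 0:
        raise ValueError(f"profile {p.contig_id!r} is empty")
    q1, q3 = np.percentile(depths, [25, 75], method=percentile_method)
    kept = depths[(depths >= q1) & (depths <= q3)]
    if kept.size == 0:
        return float(depths.mean())
    return float(kept.mean())


def genome_coverage(
    profiles: list[DepthProfile],
    lengths: dict[str, int] | None = None,
    percentile_method: str = "linear",
) -> float:
    """Length-weighted mean of per-contig IQR coverages:
    sum(len_i * iqr_mean_i) / sum(len_i).

    Contig lengths default to the profile lengths; pass ``lengths`` when
    profiles were subsampled.
    """
    if not profiles:
        raise ValueError("no depth profiles supplied")
    num = 0.0
    den = 0.0
    for p in profiles:
        if lengths is not None:
            if p.contig_id not in lengths:
                raise ValueError(f"no contig length for profile {p.contig_id!r}")
            w = lengths[p.contig_id]
        else:
            w = p.depths.size
        num += w * iqr_mean_coverage(p, percentile_method)
        den += w
    return num / den


def relative_abundance(coverages: dict[str, float]) -> dict[str, float]:
    """Divide each genome's coverage by the total; zero coverage maps to 0."""
    if any(v < 0 for v in coverages.values()):
        raise ValueError("negative coverage")
    total = sum(coverages.values())
    if total <= 0:
        raise ValueError("all coverages are zero: relative abundance undefined")
    return {g: v / total for g, v in coverages.items()}


def mapped_fraction(n_mapped: int, n_total: int) -> float:
    """Percent of reads mapped, flagstat-style."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not (0 <= n_mapped <= n_total):
        raise ValueError("need 0 <= n_mapped <= n_total")
    return 100.0 * n_mapped / n_total


def collapse_profile(p: TaxProfile, t: Thresholds | None = None) -> TaxProfile:
    """Fold taxa with relative abundance < rest_frac into "Rest".

    Counts are conserved exactly; a taxon at exactly the cutoff is
    retained (strict <). Idempotent: "Rest" itself is exempt from
    re-collapsing.
    """
    t = t or Thresholds()
    total = p.total
    if total <= 0:
        return TaxProfile(p.sample_id, p.timepoint, dict(p.counts))
    kept: dict[str, float] = {}
    rest = 0.0
    for taxon, count in p.counts.items():
        if taxon != "Rest" and count / total < t.rest_frac:
            rest += count
        else:
            kept[taxon] = kept.get(taxon, 0.0) + count
    if rest > 0:
        kept["Rest"] = kept.get("Rest", 0.0) + rest
    return TaxProfile(p.sample_id, p.timepoint, kept)


def _profiles_to_matrix(profiles: list[TaxProfile]) -> pd.DataFrame:
    taxa = sorted({t for p in profiles for t in p.counts})
    ids = [f"{p.sample_id}|{p.timepoint}" for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate (sample_id, timepoint) pairs")
    data = np.array(
        [[p.counts.get(t, 0.0) for t in taxa] for p in profiles], dtype=float
    )
    return pd.DataFrame(data, index=ids, columns=taxa)


def bray_curtis(u: dict[str, float], v: dict[str, float]) -> float:
    """Bray-Curtis dissimilarity between two count profiles:
    1 - 2*sum(min(u_i, v_i)) / (sum u + sum v)."""
    taxa = sorted(set(u) | set(v))
    a = np.array([u.get(t, 0.0) for t in taxa])
    b = np.array([v.get(t, 0.0) for t in taxa])
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("profiles must have positive totals")
    return float(np.abs(a - b).sum() / (a + b).sum())


def bray_curtis_ordination(profiles: list[TaxProfile], n_axes: int = 2):
    """Principal coordinate analysis of pairwise Bray-Curtis distances.

    Classical metric scaling (double-centred distance matrix,
    eigendecomposition). Axis signs are fixed by making each axis's
    largest-magnitude coordinate positive; negative eigenvalues (BC is
    non-Euclidean) are truncated to zero for the explained proportions.

    Returns (coordinates DataFrame indexed by "sample|timepoint",
    explained-proportion array of length n_axes).
    """
    if len(profiles) < 3:
        raise ValueError("need at least 3 samples to ordinate")
    matrix = _profiles_to_matrix(profiles)
    totals = matrix.sum(axis=1)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"samples with zero total counts: {bad}")
    dm = DistanceMatrix(
        squareform(pdist(matrix.to_numpy(), metric="braycurtis")), ids=list(matrix.index)
    )
    result = pcoa(dm, number_of_dimensions=min(n_axes, len(profiles) - 1))
    coords = result.samples.iloc[:, :n_axes].copy()
    coords.columns = [f"PC{i + 1}" for i in range(coords.shape[1])]
    for col in coords.columns:  # deterministic sign convention
        vals = coords[col].to_numpy()
        if vals[np.argmax(np.abs(vals))] < 0:
            coords[col] = -vals
    eig = result.eigvals.to_numpy()
    neg = eig < 0
    if neg.any():
        log.warning(
            "PCoA produced %d negative eigenvalues (Bray-Curtis is non-Euclidean); "
            "truncating to zero for explained proportions",
            int(neg.sum()),
        )
        eig = np.clip(eig, 0, None)
    explained = eig / eig.sum() if eig.sum() > 0 else np.zeros_like(eig)
    return coords, explained[: coords.shape[1]]
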