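# Methods

`curdcat` implements the bespoke computational stages of a longitudinal,
multi-platform metagenomics workflow for washed-rind cheese surface
communities, together with a synthetic-community generator that makes
every stage testable against known ground truth. This note records the
models, the parameters that matter, the numerical conventions, and the
design choices that were genuinely open.

## ANI estimation and dereplication

Average nucleotide identity between two genomes is estimated from
canonical k-mer containment. Under an i.i.d. substitution model with
per-base identity p, a k-mer survives unmutated with probability p^k,
so the containment c of the smaller genome's distinct canonical k-mer
set in the larger one satisfies p ≈ c^(1/k); we report
ANI = 100·c^(1/k). Defaults: k = 21 (odd, so canonical k-mers are
well-defined; long enough that random 21-mer collisions are negligible
at desk scale), exact k-mer sets by default with an optional
bottom-sketch MinHash (`sketch_size`) that subsamples the smaller set —
at sketch size s the containment standard error is ≈ sqrt(c(1−c)/s),
i.e. ~0.01 ANI points at s = 2000 for near-identical genomes. k-mers
are hashed through splitmix64 so the bottom sketch is a uniform sample.
The estimator is validated in the tests against an independent oracle:
alignment identity on the planted homologous coordinates of simulated
strain pairs (exact for the substitution-only strain model).

Dereplication is single-linkage over the graph of genome pairs with
ANI ≥ `ani_same_genome` (default 99, the "same genome" convention).
Single linkage is deliberate: near-identical strain variants must end
up in one cluster even when the most distant pair dips just below the
cutoff. A two-stage pre-filter (as genome-scale dereplication tools use
for thousands of genomes) is unnecessary at the catalog sizes this
package targets.

One representative per cluster is chosen by the provenance priority
ladder: isolate genome > circular MAG from an individual time-point
assembly > circular MAG from a co-assembly > high-quality noncircular
time-point MAG > high-quality noncircular co-assembly MAG. "Complete,
noncircular" is interpreted as passing the high-quality MAG thresholds
(completeness > 70 %, contamination < 10 %, contigs < 20 — all strict
inequalities, matching the printed directions). Ties within a class are
broken by the quality score completeness − 5·contamination (the
convention of genome-dereplication tooling; the source workflow states
only "low contamination and high completeness"), then by fewer contigs,
then lexicographically by genome id, giving a total order and therefore
deterministic, input-order-invariant selection.

Catalog comparison pools the genomes of several communities, clusters
them the same way, and reports Venn-region counts: a genome group is
"shared by S" iff its members come from exactly the community set S.

## Mega-assembly redundancy removal

An unbinned contig is redundant when ≥ `overlap_redundant_frac`
(default 0.90) of it is covered by local alignments at
≥ `overlap_identity` (default 99 %) identity against a strictly longer
retained contig; the smaller contig is always the one removed. Coverage
is the union of aligned query intervals, not a single best alignment,
so a containment fragmented into several local alignments still
triggers removal. Resolution runs shortest-to-longest, which makes
cascading removals (C ⊂ B ⊂ A keeps only A) deterministic; equal-length
mutual containment keeps the lexicographically smaller id.

Overlaps are found seed-and-merge style: exact shared 20 bp words
(both strands) are grouped by alignment diagonal, same-diagonal seeds
within 200 bp are merged into one ungapped segment, and each segment is
identity-scored base by base. No gapped extension is performed — the
synthetic strain model is substitution-only, so true containments lie
on single diagonals; on real data with indels the estimator would
fragment across nearby diagonals and undercount coverage (a known
limitation; the 90 % threshold leaves headroom for small indel counts).
E-value statistics are not reimplemented: at desk scale the identity
and coverage thresholds subsume them. The test suite checks the whole
removal decision against an independent infix-alignment oracle (edlib)
on instances of ≤ 20 contigs.

The mega-assembly concatenates three sources — nonredundant unbinned
contigs, contigs assembled from unmapped short reads, and the catalog
MAG contigs — with ids prefixed by source, then drops contigs shorter
than `min_contig_bp` (1000). MGE candidates are the contigs strictly
longer than `min_mge_candidate_bp` (5000).

## Coverage statistic and abundance

Per contig, the IQR-filtered mean coverage keeps positions whose depth
lies in the closed interval [q1, q3], where q1/q3 are the 25th/75th
percentiles of the depth values under the linear-interpolation
percentile convention (the default of mainstream numerical stacks; the
convention is a function argument and the test oracle recomputes it the
same way). The closed interval means values equal to a percentile
qualify, so the filter can never empty a profile; the plain mean
remains as a pure fallback. A consequence of the literal rule: when
more than 25 % of positions have zero depth, q1 = 0 and zeros are kept,
deflating the statistic for very patchily covered contigs. Per genome,
contig values combine as the length-weighted mean
Σ(len_i · iqr_i)/Σ len_i, and relative abundance divides each genome's
coverage by the community total.

Taxonomic profiles collapse taxa with relative abundance strictly
below `rest_frac` (1 %) into a "Rest" category; totals are conserved
exactly and the operation is idempotent ("Rest" is exempt from
re-collapsing). Ordination is classical PCoA (double-centred distance
matrix, eigendecomposition, via scikit-bio) of Bray-Curtis
dissimilarities on counts — metric scaling of BC distances rather than
PCA of raw abundances, following the workflow's stated ordination
method. Axis signs are fixed by making each axis's largest-magnitude
coordinate positive; negative eigenvalues (BC is non-Euclidean) are
truncated to zero for explained-proportion reporting, with a logged
warning.

## MGE–host association and host-change detection

The association stage consumes pre-aggregated uniquely-mapping contact
counts per contig pair (pairs TSV), not alignment files; read mapping
and multi-mapper removal happen upstream. Per MGE, links are summed
over each candidate host's contigs (MAGs) or kept per contig (unbinned
candidates); MGE–MGE links carry no host information and are ignored.
Candidates with ≥ `min_links` links qualify. When the top candidate has
at least `dominance_ratio` times the runner-up's links only the top is
reported; otherwise all qualifying candidates are reported (multi-host
association, which real data shows). Defaults min_links = 5 and
dominance_ratio = 3 are calibrated on the reference simulation
(mge_link_rate 30, background 0.5) to hold precision and recall ≥ 0.9;
both are exposed as CLI flags. Link counts are not size-normalised by
default — association is reported on raw evidence.

Across time points, persistence counts the time points each (MGE,
host) pair stays associated. Host-change detection compares consecutive
associated time points per MGE (the earliest transition is reported
once): a MAG-level event fires when the MAG host sets become disjoint
and is flagged as a putative HGT candidate (both endpoints already
passed min_links); a genus-level event additionally fires when the
host genus sets are disjoint. An MGE associated with two MAGs at the
same time point is reported as multi-host but not flagged as HGT.
Unbinned hosts are excluded from change detection (no stable identity).

## Pangenome partitioning and enrichment

The soft-core rule labels a gene cluster core when present in at least
`soft_core_frac` (95 %) of genomes; the strict rule labels clusters
core (all genomes), shell (2 to n−1) or cloud (exactly one). Functional
enrichment between two genome groups builds, per function, the 2×2
table of genomes with/without the function (a genome "has" a function
iff any of its clusters carries that annotation; per-cluster testing is
available behind a flag), computes a two-sided Fisher exact p-value,
and adjusts across all tested functions with Benjamini–Hochberg,
reporting functions with q < `enrichment_q` (0.1). The source workflow
used a pangenomics suite's logistic-score enrichment; the Fisher+BH
substitution ranks by the same group-presence imbalance, is exactly
reproducible without iterative fitting, and is evaluated here on
planted-signal recovery and FDR calibration, not on replicating the
other tool's scores. The BH adjustment is an assumption — the method
behind the workflow's "corrected q-value" is not specified.

## The synthetic-data generator

What it emulates, and the defaults that define the reference study
conditions:

- **Genomes.** Base genomes are i.i.d. DNA at a stated GC content
  (default 0.5); strain variants apply i.i.d. substitutions at a stated
  rate (no indels), so expected ANI has the closed form 100·(1−rate)
  and an exact alignment oracle exists. Rates above 0.3 are rejected —
  the k-mer ANI model breaks down. Default genome length is 50 kb:
  orders of magnitude below real MAGs, but every statistic exercised
  (k-mer containment, coverage means, link counts) is scale-free in
  length once k-mer sampling noise is far below the decision margins,
  which it is at 50 kb. Genomes fragment into 1–4 contigs at uniform
  random breakpoints with a 1 kb minimum fragment, so the length filter
  has work to do.
- **Depth.** Per-position counts are negative binomial with
  variance = mean + mean²/dispersion (default dispersion 5–20;
  real metagenomic depth is overdispersed), with a planted fraction of
  positions multiplied by an outlier factor to emulate repeat/mobile
  pileups — the feature the IQR filter exists to discount.
- **Contacts.** Independent Poisson counts per contig pair at three
  rates: intra-genome (default 10), MGE-to-scheduled-host per host
  contig (default 30), background (default 0.5). The host schedule maps
  each MGE to a host (or "none") per time point; switch scenarios move
  a set fraction of MGEs to a different-genus host at the final time
  point.
- **Pangenome matrices.** Core clusters present everywhere; enriched
  clusters present at p_a vs p_b (reference 0.9 vs 0.1 in 20 vs 20
  genomes); nulls at one shared probability (0.5); every cluster gets
  its own function accession and a random COG category letter. An
  all-absent sample is repaired by forcing one presence (the matrix
  invariant forbids empty clusters).

Everything is deterministic under (spec, seed) and ground-truth labels
travel on the artifacts (`source_genome` on contigs, `truth` on
matrices, the schedule inside the contact spec), so recovery metrics
never re-derive truth.

What the generator does **not** model: indels and rearrangements,
read-level errors (no FASTQ), Hi-C ligation-junction chemistry and
distance decay, GC-coverage bias, fungal genomes, real taxonomies.
Passing tests therefore demonstrate that the *decision logic* of each
stage is correct under its stated evidence model, not that the stages
are robust to every artefact of real sequencing data.

## Problem sizes in tests and the acceptance script

Monte-Carlo checks run at the reference conditions: catalog recovery
(10 base genomes × 3 variants at rate 0.002) over 100 seeds, ANI-oracle
agreement over 50 seeds per rate on 100 kb genomes, abundance recovery
over 200 seeds, association precision/recall and switch recovery over
100 seeds, enrichment recovery over 200 seeds and all-null calibration
over 500 replicates. `scripts/acceptance.py` recomputes the same
quantities at moderately reduced seed counts (30–100 per quantity,
chosen so the whole script completes in about a minute on one CPU) with
seeds derived from its `--seed` argument.

## Known limitations

- The overlap finder assumes substitution-only divergence between
  redundant contigs; indel-rich containments would be under-covered.
- ANI is containment-based without an alignment-fraction filter, so a
  perfect subset genome reports high ANI to its superset (intended for
  dereplication, but not a general-purpose ANI).
- Enrichment drops no genomes for missing annotations unless a function
  is entirely unannotated in a genome set; unannotated clusters fall
  back to their own cluster id as a singleton "function".
- Host-change detection reports the earliest transition between
  consecutive associated time points; an MGE that leaves and later
  returns to a host is two events, not one round trip.
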