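# Methods

This note documents the models, defaults and design decisions behind each
stage of the pipeline, what the synthetic-data generator does and does not
emulate, and the numerical conventions that make runs reproducible.

## Single-cell consensus genotyping (`scgeno`)

**Cell QC.** A cell is kept iff its covered target fraction is ≥ 0.75
(exclusion is strict: "< 75%") and its mean target depth is ≥ 10x. When
per-cell summaries are not supplied they are computed from the read table:
covered fraction = sites with ≥ 1 read / target size, mean depth = total
reads / target size (absent sites count as depth 0).

**Consensus call.** Per cell x site with depth d and alt count a:

| stratum        | call mutant iff |
|----------------|-----------------|
| d < 10         | NA (missing)    |
| 10 ≤ d ≤ 20    | a ≥ 10          |
| 20 < d ≤ 100   | a/d ≥ 0.30      |
| d > 100        | a/d ≥ 0.20      |

Boundary conventions: the overlap of the printed ranges at depth 20 resolves
to the lower stratum; depth exactly 100 uses the 30% rule; all comparisons
are inclusive as written. Note the 10–20x stratum is deliberately harsh — at
depth 10 it demands every read be mutant — so even error-free reads at
moderate depth under-call heterozygous sites. This is why the "noiseless
limit" used in recovery tests is the joint limit α = β = 0 *and* large depth
(10⁴): with moderate depth the stratum itself, not the error model, is the
binding constraint.

**Site filters**, applied in the fixed order min-cells → clustered →
germline, each idempotent, with every removal recorded as (snv, reason):

* *min_cells*: SNVs mutant in fewer than 3 cells are removed.
* *clustered*: on the retained site list (cohort level, not per cell), any
  SNV whose nearest retained neighbour on the same chromosome is ≤ 10 bp
  away is removed; all members of a proximal chain go. Window membership at
  exactly 10 bp removes; 11 bp keeps.
* *germline*: exact (chrom, pos, ref, alt) matches against the supplied
  germline set; the set can be augmented by sites mutant in ≥ 50% of
  normal-tissue cells (`germline_from_normals`).

**Mutation frequency** of an SNV is 100 x mutant cells / all QC-passing
cells; missing observations stay in the denominator (an NA-excluded variant
is available behind a flag). Keeping NA cells in the denominator makes
frequencies comparable across SNVs with different missingness.

**Calibration, not per-entry perfection.** At β = 0.2 every dropped-out
mutant entry is observed reference, so single-entry agreement with truth is
bounded by 1 − β x (mutant share) — about 0.90 for the default 4-clone
structure. The tests therefore assert the derived calibration (reference
entries ≥ 99.5% correct; mutant entries recovered at ≈ (1 − β) x stratum
pass rate, i.e. 0.68–0.82; overall ≥ 0.85) rather than an unattainable
constant. Clone-level consensus genotypes, which pool cells, recover ≥ 99%
of entries (see below).

## Bulk concordance (`bulkcmp`)

**Caller consensus.** Only variants reported by both callers are kept, then
depth < 10x and off-target sites are dropped (targets are half-open 0-based
BED intervals). Because the operation is required to be symmetric in its
two arguments, the depth and alt count of a shared variant are the mean of
the two callers' values.

**Categories and low-MAF rescue.** Over the union of bulk-called and
matrix-retained SNVs: common, bulk-specific, sc-specific. An sc-specific
SNV is rescued as *low-MAF* iff the bulk pileup shows ≥ 2 mutant reads at
VAF < 0.05 — present in the tissue but below somatic-caller sensitivity.
Both knobs are config-exposed; they are this package's own explicit
definition of "below caller sensitivity", for which no community standard
exists. Sites absent from the
pileup are marked unresolvable, never rescued. Rescue never alters common
or bulk-specific rows.

**Concordance** is the Pearson r between single-cell mutation frequency and
bulk MAF over common ∪ low-MAF SNVs (≥ 3 pairs required).

**Purity.** VAFs are split by 1-D 2-means (skipped below 10 variants or at
zero variance); the component with the higher mean is the clonal cluster
and purity = min(1, 2 x median clonal VAF), the diploid-heterozygous moment
estimate. This is a deterministic, dependency-light replacement for a full
Bayesian mixture; on unimodal clonal-only data the upper-half median biases
the estimate up by ≈ +0.03–0.04 at 300x, inside the ±0.05 acceptance band.
It is scale-equivariant in the VAFs until the clip at 1.

## Clone discovery (`clones`)

**Distance.** d(i,j) = 1 − |both mutant| / |either mutant| over sites
non-missing in both cells; a pair with no mutation among co-observed sites
has d = 0 (two clean normal cells are identical, not undefined). Pairs with
fewer than `min_support` (default 10) co-observed sites are imputed at the
mean of supported entries and flagged. Jaccard-complement on presence data
is robust to the dominant error (dropout deflates the intersection and the
union together); the distance and linkage are config-exposed.

**Clustering** is average-linkage agglomeration; k is either given or
chosen by maximal silhouette over k ∈ [2, 10] (ties to the smaller k).
Silhouette under-fits nested clones — a parent clone and its descendant
share their trunk and may merge at the silhouette optimum — so evaluations
that know the generative clone count pass it explicitly; automatic k is the
honest default for unknown data.

**MDS** is classical Torgerson scaling (eigendecomposition of the
double-centred squared-distance matrix), exact on Euclidean inputs; signs
are fixed by making each axis's largest-magnitude loading positive, so
coordinates are fully deterministic. A warning fires when negative
eigenvalue mass exceeds 20% of the spectrum.

**SNV clusters** use the same machinery on the transposed matrix (distance
between SNVs = Jaccard complement of their cell-presence sets), reported
with each cluster's cell-prevalence range. Cluster counts depend on the cut
criterion; the package reports counts under its documented silhouette rule
only.

## Lineage (`lineage`)

**Error model.** α = P(observe mutant | true reference) = 0.002 and
β = P(observe reference | true mutant) = 0.2 by default, the
false-positive and allelic-dropout rates conventionally assumed when
inferring trees from MDA single-cell genotypes. Both must lie in [0, 0.5).

**Consensus genotypes.** Per clone and SNV, with k cells observed mutant
and n observed reference (missing ignored), the genotype maximises
L(1) = k log(1−β) + n log β versus L(0) = k log α + n log(1−α); ties (also
the all-NA case, which is flagged) resolve to reference. Sites are
independent; there is no doublet model. With α = β the rule reduces to
simple majority. The brute-force oracle equivalence is tested over the full
(k, n, α, β) grid.

**Tree.** Neighbor-joining (Biopython) on pairwise Hamming distances
between clone genotype vectors, with an all-reference outgroup taxon
appended and the tree rooted on it; negative NJ branch lengths are clamped
to 0. Duplicate genotype rows raise, or merge into their first
representative under a flag (a normal-cell population merges into the
outgroup this way). Internal states come from binary Fitch parsimony with
ambiguities resolved toward reference on the downward pass; a branch's
acquired SNVs are its 0→1 switches. Branch labels: a branch whose
descendant tumour clones are all tumour clones is *trunk*; one whose
descendant tumour clones share a tissue is *primary*/*metastatic*; anything
else is *unlabeled*. This two-stage procedure (clusters, then ML genotypes
+ NJ) deliberately replaces joint MCMC clustering-and-tree inference: it is
deterministic, auditable, and sufficient for trunk/branch structure at
clone resolution.

**Tree comparison.** Robinson–Foulds distance is computed on nontrivial
bipartitions with (near-)zero-length internal edges collapsed first, so a
force-resolved polytomy does not count as a difference; the truth tree,
whose clones may sit at internal nodes, is converted to pendant-leaf form.
The routine is cross-checked against dendropy.

## Clone-specific genes (`genesel`)

A cell is mutated for a gene iff it is mutant at ≥ 1 nonsynonymous SNV of
that gene; cells with no observation over the gene's SNVs leave that gene's
denominator; synonymous-only genes are never tested. Genes mutated in < 3
cells overall are not tested (configurable). Each tested gene forms a 2x2
table [mutated, not] x [metastatic, primary] analysed with the uncorrected
Pearson chi-squared test, replaced by Fisher's exact test (and flagged)
when any expected count is < 5. The counting unit is the cell, matching
per-cell mutation profiles within clone groups. log2 fold change uses a
pseudocount ε = 0.5/max(group size) and is computed as a difference of
logs so that swapping groups negates it exactly. BH adjustment is
implemented in-package as q(i) = min over j ≥ i of p(j)·m/j (clipped at 1)
so that exact-equality testing against a brute-force oracle is meaningful;
it agrees with statsmodels to 1e-12. Selection: FDR < 0.05 and
|log2 fold| > 1. High-risk: ≥ 1 contributing nonsynonymous SNV with
SIFT < 0.05 *and* PolyPhen > 0.85; missing scores never qualify.

## Synthetic cohorts (`sim`)

The generator emulates, with known truth: a uniform random recursive clone
tree rooted at an all-reference normal clone (non-root clones tagged
primary/metastatic, first half/second half); SNVs multinomially distributed
over edges with every edge ≥ 1 marker (a perfect phylogeny by
construction); negative-binomial per-site depths (default mean 80x, shape
3 — strongly over-dispersed, as MDA coverage is); site-level missingness
(default 0.1); whole-allele dropout at β = 0.2 (a dropped site draws its
alt count as a reference site would) and false positives at α = 0.002;
het VAF 0.5 (diploid heterozygous; copy number is ignored by design, since
MDA priming bias makes single-cell CNA estimates unreliable anyway); bulk
samples as purity-weighted clone mixtures at 300x;
and 2% of clonal SNVs planted within 10 bp of another to exercise the
clustered-site filter.

Normal cells carry Poisson(3) private mutations drawn from a reserved
background-site pool in the catalogue (background sites are reference in
every clone, so catalogue conservation and the perfect-phylogeny structure
hold). Placing them at dedicated sites matters: the ≥ 3-cell filter then
removes them, exactly as the real filter disposes of stray normal-cell
mutations, and normal cells correctly collapse to a zero-distance cluster.

Not emulated: read-level data (FASTQ/alignment), doublets, copy-number
events, sequencing-error base miscalls distinct from α, or site-specific
amplification bias. Passing tests therefore demonstrate correctness of the
analysis logic under the stated noise model, not robustness to artefacts
outside it. The NB(80, 3) depth default is a plausibility choice for
high-depth MDA exomes, not a fit to any particular dataset.

Determinism: every stage draws from `SeedSequence(seed, spawn_key=(stage,))`
streams, so one run seed reproduces each stage independently and the full
`run` summary is byte-identical across repeats.

## Evaluation experiment sizes

The acceptance harness (`scripts/acceptance.py`, `tests/test_acceptance.py`)
uses: 60 cells x 200 clonal SNVs for clustering/genotype/topology recovery
(with the error-free limit at depth 10⁴); 100 cells x 200 SNVs with a
4-cell, 5%-mixture leaf subclone for concordance and low-MAF rescue
(sensitivity is measured over planted private SNVs that survive to the
sc-specific category — rescue operates on the category table; upstream
detection loss of a 4-cell subclone against the 3-cell rule is a filter
property, visible in `n_private_detected`); 1000 equal-rate binomial null
genes for calibration and 100 replicates of a 0.6-vs-0.05 planted gene
(among 20 nulls, 30 cells/group) for power; 200 clonal SNVs at 300x for
purity; and two full pipeline runs for determinism. These sizes keep the
whole harness under ten seconds while leaving every check comfortably
powered.
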