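# Methods

`readclust` clusters short metagenomic reads by genome of origin in two
stages: a **local** stage that groups reads by sequence overlap, and a
**global** stage that merges the resulting small clusters using the
covariation of their sequencing coverage across samples. This note
documents the model behind each stage, the parameters that matter, the
numerical choices that were genuinely open, and what the synthetic
communities used for testing do and do not demonstrate.

## Local clustering

### Seeds

Two reads are candidate overlaps when they share *seeds*. In `kmer` mode
the seeds of a read are all of its canonical k-mers (lexicographic minimum
of the k-mer and its reverse complement, byte order A<C<G<T; default
k = 41). In `minimizer` mode (the default) each k-length window is
represented by its smallest canonical m-mer (default m = 22), and the
read's seed set is the set of window minimizers. Runs of adjacent windows
usually share their minimum, so the minimizer set is several-fold smaller
than the k-mer set while an exact shared stretch of length ≥ k still
guarantees a shared window and hence a shared seed. Each m-mer is
canonicalized *before* the window minimum is taken, making seed sets
strand-invariant — required to detect overlaps between reads sequenced
from opposite strands. Windows containing `N` are skipped entirely.

### Graph construction

Reads are grouped by seed; every read pair co-occurring under a seed gets
an edge weighted by the number of *distinct* shared seeds, and edges with
weight below `min_shared_kmers` (default 2) are dropped. Two density
controls apply:

* `repeat_seed_limit` (default 300): a seed present in more reads than
  this is discarded as repetitive before any pair is emitted. This masks
  genomic repeats and bounds the quadratic per-seed pair generation.
* `max_degree` (default 25): with `max_degree_mode="node"` (default),
  each read ranks its incident edges by (weight desc, neighbor id asc) and
  an edge survives if it is within the top `max_degree` at either
  endpoint. Deeper sequencing then adds reads without shredding the
  graph, and clustering quality improves with coverage. The alternative
  `max_degree_mode="seed"` discards any seed shared by more than
  `max_degree` reads; it is cheaper but self-defeating above modest
  coverage — once a genome's pooled coverage makes typical seed occupancy
  exceed the bound, every genomic seed is discarded and the graph empties.
  We measured the fraction of reads ending up in ≥50-read clusters on the
  default community under seed mode: 0.37 at 30× pooled coverage, 0.08 at
  45×, 0.00 at ≥60×, versus 0.32/0.49/0.65/0.78 at 30/60/100/200× under
  node mode. Node mode is therefore the default.

### Partitioning

The graph is partitioned by asynchronous label propagation (LPA): each
node starts with its own label; per sweep, nodes are visited in a
seeded-shuffled order and adopt the label with the greatest total support
among their neighbors (neighbor count for the read graph, summed edge
weight for the cluster graph), ties broken toward the smallest label. The
sweep loop stops when a sweep changes nothing or after `lpa_max_iters`
(default 20) sweeps. The schedule, tie-break and termination rule are
pinned because LPA is order- and tie-sensitive; given the seed, the
partition is deterministic. Labels cannot cross connected components.

Clusters smaller than `min_reads_per_cluster` (default 50) are discarded:
small clusters do not yield reliable k-mer spectra for the global stage.
The threshold is inclusive (size ≥ 50 survives); set 51 for a strict
"more than 50".

A structural property of asynchronous LPA worth knowing: on the band-like
overlap graphs that contiguous genome coverage produces, LPA freezes into
local domains of roughly 2–3× the mean degree. With the default
`max_degree` of 25 the capped mean degree is ~35, so local clusters are
typically ~60–120 reads no matter how deep the sequencing, and the
fraction of reads in ≥50-read clusters plateaus around 0.65–0.8. This is
the method's intrinsic under-clustering — exactly what the global stage
exists to repair — but it also caps the completeness any downstream merge
can reach, since discarded sub-threshold clusters never re-enter.

## Coverage estimation

A cluster drawn from one genome shows a peak in its k-mer frequency
spectrum near coverage × (L−k+1)/L (L = read length; each genomic k-mer is
seen once per read spanning it), while sequencing-error k-mers concentrate
at count 1. With substitution error rate e, a further attrition factor
(1−e)^k applies (≈ 0.81 at e = 0.005, k = 41) because only error-free
copies of a k-mer count; this cancels in cross-sample ratios, which are
all the global stage uses.

Per cluster we: (1) pool the cluster's reads over all samples and build
the spectrum; (2) drop counts below `error_count_floor` (default 2);
(3) find the peak; (4) select up to `representative_kmer_count` (default
100) k-mers with pooled counts within `peak_window` (default 2) of the
peak, ordered by (|count − peak|, lexicographic) for determinism; and
(5) estimate the cluster's coverage in each sample as the median of the
representative k-mers' per-sample counts over the whole dataset, absent
counts as 0. The median tolerates the minority of representative k-mers
hit by errors or repeats. Clusters whose floored spectrum is empty are
excluded from the global stage (and reported); their reads keep their
local cluster.

Peak finding maximizes total k-mer mass c·hist[c] rather than raw bin
height hist[c]. For the ~100-read clusters the local stage produces, true
counts spread thinly over many adjacent values (3–8 k-mers per count bin)
while residual error k-mers concentrate at the floor, so the raw mode can
land on the error bin; mass weighting keeps the genuine coverage peak
ahead without a smoothing bandwidth parameter. For large clusters with
sharp spectra the two rules agree.

Coverages are reported in k-mer-count units (no conversion to base
coverage) and no per-sample depth normalization is applied: cosine
similarity only compares directions, so a global per-sample scale factor
is harmless as long as it is shared by all clusters.

## Global clustering

Stacking the per-cluster vectors gives the samples × clusters coverage
matrix. Clusters from one genome share that genome's abundance profile
across samples, so their columns point in the same direction regardless of
cluster size (peak *height* scales with cluster size; peak *position* per
sample does not). All pairwise cosine similarities are computed exactly
(no approximate nearest-neighbor shortcuts — determinism and
oracle-testability matter more at this scale), and pairs with similarity ≥
`cosine_threshold` (default 0.925, inclusive) become weighted edges of a
cluster graph. Zero columns are excluded from comparison and carried as
isolated nodes. The graph is partitioned with the same LPA, weighted by
similarity; member clusters of a partition merge by read-set union, so the
multiset of clustered reads is conserved exactly. Local clusters excluded
from the matrix map to themselves.

Lower thresholds merge more aggressively (risking mixed, impure merged
clusters); higher ones under-merge. Edge sets are nested in the
threshold, so the connected-component count is nondecreasing in it.

## Evaluation

With truth labels (genome and species per read), a cluster's
**purity** is the fraction of its reads from its predominant genome
(argmax count, ties to the smallest label), computed at genome and at
species level; species purity ≥ genome purity because near-identical
strains split genome-level counts. **Completeness** is the fraction of
*all* the predominant genome's reads in the dataset — clustered or not —
captured by the cluster; this makes local/global comparisons fair and
penalizes discarded reads. A genome is **recovered** when some cluster
predominated by it has purity > 0.95 and completeness > 0.80 (both
strict). Cluster-size distributions are reported read-weighted over log10
decade bins. Reported medians are over clusters; read-weighted medians
are also available in the JSON summary.

## Synthetic communities

The simulator generates what the method assumes and nothing more: each
genome is an i.i.d. uniform ACGT sequence (default 50 kb), so distinct
genomes share essentially no 41-mers and cross-genome impurity isolates
failures of the method rather than biological ambiguity. Relative
abundances per (genome, sample) are lognormal (μ = 0, σ = 1), column
normalized — giving each genome its own cross-sample profile, the signal
the global stage exploits. Reads (default 150 bp) start uniformly on the
circularized genome (no edge-coverage artifacts), strands are fair, and
errors are i.i.d. substitutions (default 0.005); indels are omitted
because they would exercise nothing the spectrum/error-floor machinery
does not already face. Optional strain pairs differ by Bernoulli
substitutions and share a species label. `mean_base_coverage` (default
10 per genome per sample — ~100× pooled over the default 10 samples, the
regime where coverage-based merging operates well) may be a scalar or a
per-sample vector for unequal sequencing depth. Everything is
deterministic given `rng_seed`.

What passing tests on these communities does **not** show: tolerance to
shared sequence between genomes (conserved regions, mobile elements),
GC-dependent coverage bias, indels or chimeras, real abundance
distributions, or genome sizes beyond tens of kb. Species-level purity
with real strain mixtures is exercised only by the idealized strain-pair
model.

## Problem sizes and defaults

The default end-to-end study is 3 genomes × 50 kb × 10 samples at ~100×
pooled coverage per genome (~100k reads, ~36 s single-core for the whole
pipeline). The sample-count comparison holds per-sample depth fixed while
varying the number of samples, so more samples also mean more total data —
the way cohort growth behaves in practice. On these communities the
pipeline typically clusters ~60–65% of reads into ≥50-read local clusters
(median local completeness ~0.2%), and global merging reassembles them
into one merged cluster per genome at purity 1.0 with per-genome
completeness ~0.55–0.70 — a several-hundred-fold median completeness gain,
bounded by the local-stage plateau described above. At very low per-sample
coverage (λ ≲ 2 expected counts) the per-sample medians are coarse
integers and same-genome cosine similarity degrades; the estimator is
meant for the ≥5×-per-sample regime.

## Known limitations

* Asynchronous LPA's frozen-domain behavior caps the clustered-read
  fraction (see above); a different partitioner (e.g. synchronous LPA or
  modularity-based methods) would trade determinism guarantees for larger
  local clusters.
* Coverage vectors use integer count medians; with few samples or shallow
  per-sample depth, cosine separation between genomes weakens (2-sample
  profiles are nearly always similar in direction).
* The seed-occupancy repeat filter assumes repeats are rare; repeat-dense
  genomes will lose seeds and fragment.
* Paired-end mates are treated as independent reads; mate linkage is
  deliberately unused as clustering evidence.
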