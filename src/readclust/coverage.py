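"""Per-sample coverage estimation for read clusters.

A read cluster drawn from one genome shows a peak in its k-mer frequency
spectrum at roughly coverage × (L−k+1)/L (L = read length): most genomic
k-mers are seen once per read spanning them, while sequencing-error k-mers
pile up at count 1. We locate the peak of the pooled (all samples combined)
spectrum after discarding counts below an error floor, pick up to ``rp``
representative k-mers whose pooled counts lie within ``peak_window`` of the
peak, and read the cluster's coverage in each sample as the median of the
representative k-mers' per-sample counts. The median makes the estimate
robust to the minority of representative k-mers hit by errors or repeats.

Stacking the per-cluster vectors gives the samples × clusters coverage
matrix whose columns are compared by cosine similarity in the global stage.
Coverages are reported in k-mer-count units; only the relative profile
across samples matters downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .local_clustering import ReadCluster
from .seeds import SampleKmerCounts, count_kmers_by_sample, kmers
from .sequence_io import Read


class UnreliableSpectrumError(ValueError):
    """Spectrum empty after error-flooring: no peak can be located."""


@dataclass(frozen=True)
class GlobalParams:
    """Coverage-estimation knobs.

    representative_kmer_count: maximum representative k-mers per cluster.
    error_count_floor: pooled counts below this are ignored for peak
        finding (error k-mers dominate count 1).
    peak_window: representative candidates come from pooled counts within
        ± this window of the peak.
    """

    representative_kmer_count: int = 100
    error_count_floor: int = 2
    peak_window: int = 2

    def __post_init__(self) -> None:
        if self.representative_kmer_count < 1:
            raise ValueError("representative_kmer_count must be ≥ 1")
        if self.error_count_floor < 1:
            raise ValueError("error_count_floor must be ≥ 1")
        if self.peak_window < 0:
            raise ValueError("peak_window must be ≥ 0")


@dataclass
class KmerSpectrum:
    """Histogram: pooled occurrence count -> number of distinct k-mers."""

    histogram: Dict[int, int]


@dataclass
class RepresentativeKmers:
    cluster_id: str
    kmers: List[str]


@dataclass
class CoverageMatrix:
    """samples × clusters matrix of estimated coverages."""

    samples: List[str]
    clusters: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.clusters)):
            raise ValueError(
                f"coverage matrix shape {self.values.shape} inconsistent with "
                f"{len(self.samples)} samples × {len(self.clusters)} clusters"
            )
        if (self.values < 0).any():
            raise ValueError("coverage values must be nonnegative")

    def column(self, cluster_id: str) -> np.ndarray:
        return self.values[:, self.clusters.index(cluster_id)]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\t" + "\t".join(self.clusters) + "\n")
            for i, s in enumerate(self.samples):
                cells = "\t".join(f"{v:.10g}" for v in self.values[i])
                fh.write(f"{s}\t{cells}\n")

    @classmethod
    def read_tsv(cls, path) -> "CoverageMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[0] != "sample_id":
                raise ValueError(f"{path}: bad coverage header")
            clusters = header[1:]
            samples: List[str] = []
            rows: List[List[float]] = []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                samples.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        return cls(samples, clusters, np.array(rows, dtype=float))


def cluster_kmer_counts(
    cluster: ReadCluster, reads_by_id: Mapping[str, Read], k: int
) -> Dict[str, int]:
    """Pooled (all samples combined) occurrence count of each canonical
    k-mer across the cluster's reads."""
    counts: Dict[str, int] = {}
    for rid in cluster.read_ids:
        for km in kmers(reads_by_id[rid].sequence, k):
            counts[km] = counts.get(km, 0) + 1
    return counts


def cluster_spectrum(
    cluster: ReadCluster, reads_by_id: Mapping[str, Read], k: int
) -> KmerSpectrum:
    """The cluster's pooled k-mer frequency spectrum."""
    if not cluster.read_ids:
        raise ValueError("cluster is empty")
    hist: Dict[int, int] = {}
    for c in cluster_kmer_counts(cluster, reads_by_id, k).values():
        hist[c] = hist.get(c, 0) + 1
    return KmerSpectrum(hist)


def find_peak(spectrum: KmerSpectrum, error_count_floor: int) -> int:
    """Peak of the floored spectrum, by total k-mer mass.

    Among counts ≥ floor, returns the count c maximizing c·histogram[c]
    (ties toward the larger count). Mass weighting rather than raw bin
    height keeps the genuine coverage peak ahead of residual low-count
    error k-mers when the cluster is small and its true counts spread
    thinly over many adjacent count values.
    """
    best: Optional[Tuple[int, int]] = None
    for count, n_kmers in spectrum.histogram.items():
        if count < error_count_floor:
            continue
        key = (count * n_kmers, count)
        if best is None or key > best:
            best = key
    if best is None:
        raise UnreliableSpectrumError(
            f"spectrum empty after flooring at {error_count_floor}"
        )
    return best[1]


def select_representative_kmers(
    cluster: ReadCluster,
    kmer_counts: Mapping[str, int],
    peak: int,
    params: GlobalParams,
) -> RepresentativeKmers:
    """Up to ``rp`` k-mers with pooled count within ``peak_window`` of the
    peak, chosen deterministically by (|count − peak|, lexicographic)."""
    lo, hi = peak - params.peak_window, peak + params.peak_window
    candidates = [(abs(c - peak), km) for km, c in kmer_counts.items() if lo <= c <= hi]
    candidates.sort()
    chosen = [km for _, km in candidates[: params.representative_kmer_count]]
    return RepresentativeKmers(cluster.cluster_id, chosen)


def coverage_vector(
    rep: RepresentativeKmers, counts: SampleKmerCounts, samples: Sequence[str]
) -> np.ndarray:
    """Per-sample median of the representative k-mers' counts (absent
    counts are 0; even-cardinality median is the mean of the central two)."""
    if not rep.kmers:
        raise ValueError("no representative k-mers")
    return np.array(
        [np.median([counts.get(km, s) for km in rep.kmers]) for s in samples],
        dtype=float,
    )


def build_coverage_matrix(
    clusters: Sequence[ReadCluster],
    reads: Iterable[Read] | Mapping[str, Read],
    samples: Sequence[str],
    params: GlobalParams,
    k: int,
    sample_counts: Optional[SampleKmerCounts] = None,
) -> Tuple[CoverageMatrix, List[str]]:
    """One coverage column per cluster with a reliable spectrum.

    Returns the matrix plus the ids of clusters excluded for unreliable
    spectra. When ``sample_counts`` is not supplied, per-sample counts are
    computed over all reads restricted to the union of representative
    k-mers (identical results, far less memory).
    """
    if isinstance(reads, Mapping):
        reads_by_id: Mapping[str, Read] = reads
    else:
        reads_by_id = {r.read_id: r for r in reads}

    reps: List[RepresentativeKmers] = []
    excluded: List[str] = []
    for cluster in clusters:
        counts = cluster_kmer_counts(cluster, reads_by_id, k)
        hist: Dict[int, int] = {}
        for c in counts.values():
            hist[c] = hist.get(c, 0) + 1
        try:
            peak = find_peak(KmerSpectrum(hist), params.error_count_floor)
        except UnreliableSpectrumError:
            excluded.append(cluster.cluster_id)
            continue
        reps.append(select_representative_kmers(cluster, counts, peak, params))

    if sample_counts is None:
        union: Set[str] = set()
        for rep in reps:
            union.update(rep.kmers)
        sample_counts = count_kmers_by_sample(reads_by_id.values(), k, restrict_to=union)

    cols = [coverage_vector(rep, sample_counts, samples) for rep in reps]
    values = (
        np.column_stack(cols) if cols else np.zeros((len(samples), 0), dtype=float)
    )
    matrix = CoverageMatrix(list(samples), [rep.cluster_id for rep in reps], values)
    return matrix, excluded
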