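"""Canonical k-mer and minimizer seed machinery.

Seeds are the currency of the overlap stage: two reads are candidate
overlaps when they share seeds. In k-mer mode the seeds are all canonical
k-mers of a read; in minimizer mode each k-length window is represented by
its lexicographically smallest canonical m-mer, which compresses runs of
adjacent shared k-mers into a single shared seed without losing overlap
sensitivity (an exact shared stretch of length ≥ k still guarantees a
shared window, hence a shared minimizer).

Canonicalization (lexicographic minimum of a sequence and its reverse
complement, byte order A<C<G<T) happens per m-mer *before* the window
minimum is taken, so minimizer sets are invariant under reverse
complementing a read — required for detecting overlaps between reads
sequenced from opposite strands.

Windows containing ``N`` are skipped entirely.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Optional, Set, Tuple

from .sequence_io import Read

_RC = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def canonical(seq: str) -> str:
    """Lexicographic minimum of ``seq`` and its reverse complement.

    Idempotent; rejects characters outside ACGT (callers must pre-filter
    N-containing windows).
    """
    if not _VALID.issuperset(seq):
        bad = sorted(set(seq) - _VALID)
        raise ValueError(f"non-ACGT characters in sequence: {bad}")
    rc = revcomp(seq)
    return seq if seq <= rc else rc


@dataclass(frozen=True)
class SeedParams:
    """Seed configuration: k-mer length, minimizer length and mode."""

    k: int = 41
    m: int = 22
    mode: str = "kmer"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"k must be ≥ 2, got {self.k}")
        if not (1 <= self.m <= self.k):
            raise ValueError(f"require 1 ≤ m ≤ k, got m={self.m}, k={self.k}")
        if self.mode not in ("kmer", "minimizer"):
            raise ValueError(f"mode must be 'kmer' or 'minimizer', got {self.mode!r}")


def _clean_segments(seq: str, minlen: int) -> Iterator[str]:
    """Maximal N-free segments of length ≥ minlen (uppercased input)."""
    for seg in seq.split("N"):
        if len(seg) >= minlen:
            yield seg


def kmers(seq: str, k: int) -> List[str]:
    """All canonical k-mers of ``seq``, one per N-free window, in order."""
    out: List[str] = []
    for seg in _clean_segments(seq, k):
        n = len(seg)
        rc = revcomp(seg)
        for i in range(n - k + 1):
            f = seg[i : i + k]
            r = rc[n - k - i : n - i]
            out.append(f if f <= r else r)
    return out


def _canonical_mmers(seg: str, m: int) -> List[str]:
    n = len(seg)
    rc = revcomp(seg)
    return [
        f if f <= (r := rc[n - m - i : n - i]) else r
        for i in range(n - m + 1)
        for f in (seg[i : i + m],)
    ]


def minimizers(seq: str, params: SeedParams) -> Set[str]:
    """Window minimizers: for each k-length N-free window, the smallest
    canonical m-mer among its k−m+1 constituent m-mers.

    Returns the set over all windows (adjacent windows usually share their
    minimum, so the set is much smaller than the k-mer set).
    """
    k, m = params.k, params.m
    out: Set[str] = set()
    for seg in _clean_segments(seq, k):
        mm = _canonical_mmers(seg, m)
        w = k - m + 1
        # sliding minimum over mm with window size w (monotonic deque)
        dq: deque[int] = deque()
        for i, s in enumerate(mm):
            while dq and mm[dq[-1]] >= s:
                dq.pop()
            dq.append(i)
            if dq[0] <= i - w:
                dq.popleft()
            if i >= w - 1:
                out.add(mm[dq[0]])
    return out


def seeds_of(read_seq: str, params: SeedParams) -> Set[str]:
    """The distinct seeds of a read under the configured mode."""
    if params.mode == "minimizer":
        return minimizers(read_seq, params)
    return set(kmers(read_seq, params.k))


class SampleKmerCounts:
    """Per-sample canonical k-mer occurrence counts.

    Absent keys mean count 0. Backed by a flat dict keyed by
    (kmer, sample_id).
    """

    def __init__(self, counts: Optional[Dict[Tuple[str, str], int]] = None) -> None:
        self.counts: Dict[Tuple[str, str], int] = counts or {}

    def get(self, kmer: str, sample_id: str) -> int:
        return self.counts.get((kmer, sample_id), 0)

    def __len__(self) -> int:
        return len(self.counts)

    def __eq__(self, other) -> bool:
        return isinstance(other, SampleKmerCounts) and self.counts == other.counts

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("kmer\tsample_id\tcount\n")
            for (kmer, sample), c in sorted(self.counts.items()):
                fh.write(f"{kmer}\t{sample}\t{c}\n")

    @classmethod
    def read_tsv(cls, path) -> "SampleKmerCounts":
        counts: Dict[Tuple[str, str], int] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
            if header != "kmer\tsample_id\tcount":
                raise ValueError(f"{path}: bad header {header!r}")
            for line in fh:
                kmer, sample, c = line.rstrip("\n").split("\t")
                counts[(kmer, sample)] = int(c)
        return cls(counts)


def count_kmers_by_sample(
    reads: Iterable[Read], k: int, restrict_to: Optional[Set[str]] = None
) -> SampleKmerCounts:
    """Count occurrences of every canonical k-mer per sample.

    ``restrict_to`` limits accounting to a given k-mer set (used to count
    only representative k-mers over a large dataset); counts for the
    retained k-mers are identical to an unrestricted run.
    """
    counts: Dict[Tuple[str, str], int] = {}
    for read in reads:
        sample = read.sample_id
        for km in kmers(read.sequence, k):
            if restrict_to is not None and km not in restrict_to:
                continue
            key = (km, sample)
            counts[key] = counts.get(key, 0) + 1
    return SampleKmerCounts(counts)
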