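"""Sequence and artifact I/O.

Reads are bound to samples through a tab-separated manifest
(``sample_id\tpath\tformat``); every intermediate artifact of the pipeline
(cluster assignments, coverage matrices, edge lists, merge maps) is a plain
TSV so that runs are diffable and byte-reproducible.

Ground-truth labels for simulated communities travel either inside read
names as ``genome=<id> species=<id>`` tokens or in a sidecar TSV; both are
supported here.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

FORMATS = ("fastq", "fasta")


class ManifestError(ValueError):
    """Raised when a sample manifest is malformed or references bad files."""


class ReadParseError(ValueError):
    """Raised on malformed sequence records."""


class AssignmentError(ValueError):
    """Raised on malformed or inconsistent cluster-assignment files."""


@dataclass(frozen=True)
class ManifestEntry:
    sample_id: str
    path: Path
    format: str


@dataclass(frozen=True)
class SampleManifest:
    """Declares which sequence files belong to which sample.

    A sample may span several files (one entry per file); the same
    (sample_id, path) pair may not appear twice.
    """

    entries: Tuple[ManifestEntry, ...]

    @property
    def sample_ids(self) -> List[str]:
        seen: Dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.sample_id)
        return list(seen)


@dataclass
class Read:
    """A short read bound to its sample, optionally truth-labeled."""

    read_id: str
    sample_id: str
    sequence: str
    truth_genome: Optional[str] = None
    truth_species: Optional[str] = None


@dataclass
class ClusterAssignment:
    """Disjoint mapping read_id -> cluster_id; unassigned reads are absent."""

    mapping: Dict[str, str] = field(default_factory=dict)

    def __eq__(self, other) -> bool:  # order-insensitive
        return isinstance(other, ClusterAssignment) and self.mapping == other.mapping


def load_manifest(path: str | Path) -> SampleManifest:
    """Parse and validate a sample manifest.

    Relative paths are resolved against the manifest's own directory.
    Errors name the offending line number or path.
    """
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"manifest not found: {path}")
    base = path.parent
    entries: List[ManifestEntry] = []
    seen: set[Tuple[str, str]] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header.split("\t") != ["sample_id", "path", "format"]:
            raise ManifestError(
                f"{path}: line 1: expected header 'sample_id\\tpath\\tformat', got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ManifestError(f"{path}: line {lineno}: expected 3 columns, got {len(parts)}")
            sample_id, raw_path, fmt = parts
            if fmt not in FORMATS:
                raise ManifestError(
                    f"{path}: line {lineno}: unknown format {fmt!r} (expected one of {FORMATS})"
                )
            key = (sample_id, raw_path)
            if key in seen:
                raise ManifestError(
                    f"{path}: line {lineno}: duplicate entry ({sample_id}, {raw_path})"
                )
            seen.add(key)
            p = Path(raw_path)
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise ManifestError(f"{path}: line {lineno}: file not found: {p}")
            entries.append(ManifestEntry(sample_id, p, fmt))
    if not entries:
        raise ManifestError(f"{path}: manifest has no entries")
    return SampleManifest(tuple(entries))


def _open_text(path: Path) -> io.TextIOBase:
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _parse_truth(title: str) -> Tuple[str, Optional[str], Optional[str]]:
    """Split a record title into (read_id, truth_genome, truth_species).

    Truth labels follow the ``genome=<id> species=<id>`` convention in the
    whitespace-separated description; absent tokens yield None.
    """
    tokens = title.split()
    read_id = tokens[0]
    genome = species = None
    for tok in tokens[1:]:
        if tok.startswith("genome="):
            genome = tok[len("genome="):]
        elif tok.startswith("species="):
            species = tok[len("species="):]
    return read_id, genome, species


def load_reads(manifest: SampleManifest) -> Iterator[Read]:
    """Stream every record of every manifest file, tagged with its sample.

    Read ids colliding across samples are disambiguated by prefixing the
    sample id; a collision surviving that is a hard error.
    """
    seen_ids: set[str] = set()
    for entry in manifest.entries:
        with _open_text(entry.path) as fh:
            if entry.format == "fastq":
                records: Iterable[Tuple[str, str]] = (
                    (title, seq) for title, seq, _qual in _iter_fastq(fh, entry.path)
                )
            else:
                records = SimpleFastaParser(fh)
            for title, seq in records:
                read_id, genome, species = _parse_truth(title)
                if read_id in seen_ids:
                    read_id = f"{entry.sample_id}:{read_id}"
                    if read_id in seen_ids:
                        raise ReadParseError(
                            f"{entry.path}: duplicate read id {read_id!r} within sample"
                        )
                seen_ids.add(read_id)
                yield Read(read_id, entry.sample_id, seq.upper(), genome, species)


def _iter_fastq(fh, path: Path):
    idx = 0
    try:
        for idx, rec in enumerate(FastqGeneralIterator(fh), start=1):
            yield rec
    except ValueError as exc:
        raise ReadParseError(f"{path}: malformed FASTQ near record {idx + 1}: {exc}") from exc


# ---------------------------------------------------------------------------
# Tabular artifacts


def write_assignment(assignment: ClusterAssignment, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("read_id\tcluster_id\n")
        for read_id in sorted(assignment.mapping):
            fh.write(f"{read_id}\t{assignment.mapping[read_id]}\n")


def read_assignment(path: str | Path) -> ClusterAssignment:
    path = Path(path)
    mapping: Dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != "read_id\tcluster_id":
            raise AssignmentError(f"{path}: bad header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise AssignmentError(f"{path}: line {lineno}: expected 2 columns")
            read_id, cluster_id = parts
            if read_id in mapping:
                raise AssignmentError(
                    f"{path}: line {lineno}: read {read_id!r} assigned to two clusters"
                )
            mapping[read_id] = cluster_id
    return ClusterAssignment(mapping)


def write_truth_table(truth: Dict[str, Tuple[str, str, str]], path: str | Path) -> None:
    """Write read_id -> (genome, species, sample) as TSV."""
    with open(path, "w") as fh:
        fh.write("read_id\tgenome\tspecies\tsample_id\n")
        for read_id in sorted(truth):
            g, s, samp = truth[read_id]
            fh.write(f"{read_id}\t{g}\t{s}\t{samp}\n")


def read_truth_table(path: str | Path) -> Dict[str, Tuple[str, str, str]]:
    path = Path(path)
    truth: Dict[str, Tuple[str, str, str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["read_id", "genome", "species"]:
            raise AssignmentError(f"{path}: bad truth-table header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise AssignmentError(f"{path}: line {lineno}: expected ≥3 columns")
            sample = parts[3] if len(parts) > 3 else ""
            truth[parts[0]] = (parts[1], parts[2], sample)
    return truth


def write_edge_list(
    edges: Iterable[Tuple[str, str, float]], path: str | Path, columns: Tuple[str, str, str]
) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for a, b, w in sorted(edges):
            fh.write(f"{a}\t{b}\t{w:.10g}\n")
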