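"""Truth-labeled multi-sample community simulator.

Emulates the statistical structure the global stage exploits: each genome
has its own relative-abundance profile across samples (lognormal by
default), reads are drawn from genomes in proportion to abundance with
uniform start positions on a circularized genome, a fair strand coin and
i.i.d. substitution errors. Genomes are i.i.d. uniform ACGT sequences, so
at the default 50 kb length they share essentially no 41-mers and provide
controlled separability; optional near-identical strain pairs within a
species exercise the strain/purity machinery.

Circularization removes coverage dropoff at genome ends, which keeps
coverage-recovery tests clean. The error model is substitution-only:
indels would add nothing the spectrum/error-floor machinery does not
already face.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .sequence_io import ManifestEntry, SampleManifest, write_truth_table

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

TruthTable = Dict[str, Tuple[str, str, str]]  # read_id -> (genome, species, sample)


@dataclass(frozen=True)
class Lognormal:
    """Lognormal relative-abundance model (natural-log parameters)."""

    mu: float = 0.0
    sigma: float = 1.0


@dataclass
class CommunitySpec:
    """Study conditions for one simulated community.

    mean_base_coverage is the expected per-genome base coverage in one
    sample at uniform abundance (scalar), or a per-sample sequence of such
    depths for unequal sequencing depth across samples.
    """

    n_genomes: int = 3
    genome_length: int = 50_000
    n_samples: int = 10
    read_length: int = 150
    abundance_model: Union[Lognormal, np.ndarray] = field(default_factory=Lognormal)
    mean_base_coverage: Union[float, Sequence[float]] = 10.0
    substitution_error_rate: float = 0.005
    strain_divergence: Optional[float] = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genomes", "genome_length", "n_samples", "read_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be ≥ 1")
        if self.read_length > self.genome_length:
            raise ValueError("read_length must be ≤ genome_length")
        if not (0.0 <= self.substitution_error_rate < 1.0):
            raise ValueError("substitution_error_rate must be in [0, 1)")
        if self.strain_divergence is not None and not (
            0.0 <= self.strain_divergence < 1.0
        ):
            raise ValueError("strain_divergence must be in [0, 1)")

    def per_sample_depths(self) -> np.ndarray:
        if np.isscalar(self.mean_base_coverage):
            return np.full(self.n_samples, float(self.mean_base_coverage))
        depths = np.asarray(self.mean_base_coverage, dtype=float)
        if depths.shape != (self.n_samples,):
            raise ValueError(
                f"mean_base_coverage vector length {depths.size} != n_samples {self.n_samples}"
            )
        return depths


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def generate_genomes(spec: CommunitySpec) -> List[Tuple[str, str, str]]:
    """(genome_id, species_id, sequence) triples.

    Without strains every genome is its own species. With
    ``strain_divergence`` set, genomes come in within-species pairs: the
    second of each pair is a copy of the first with Bernoulli(divergence)
    substitutions (an odd trailing genome stays unpaired).
    """
    rng = np.random.default_rng(spec.rng_seed)
    out: List[Tuple[str, str, str]] = []
    L = spec.genome_length
    i = 0
    species_idx = 0
    while i < spec.n_genomes:
        species_idx += 1
        codes = rng.integers(0, 4, size=L, dtype=np.uint8)
        if spec.strain_divergence is None:
            out.append((f"G{i + 1}", f"S{species_idx}", _codes_to_str(codes)))
            i += 1
            continue
        sid = f"S{species_idx}"
        out.append((f"G{i + 1}", sid, _codes_to_str(codes)))
        i += 1
        if i < spec.n_genomes:
            mutated = codes.copy()
            hits = np.flatnonzero(rng.random(L) < spec.strain_divergence)
            # substitute to a different base: add 1..3 mod 4
            mutated[hits] = (mutated[hits] + rng.integers(1, 4, size=hits.size)) % 4
            out.append((f"G{i + 1}", sid, _codes_to_str(mutated)))
            i += 1
    return out


def sample_abundance_matrix(spec: CommunitySpec) -> np.ndarray:
    """genomes × samples relative abundances; columns sum to 1."""
    if isinstance(spec.abundance_model, Lognormal):
        rng = np.random.default_rng(spec.rng_seed + 1)
        model = spec.abundance_model
        a = rng.lognormal(model.mu, model.sigma, size=(spec.n_genomes, spec.n_samples))
    else:
        a = np.asarray(spec.abundance_model, dtype=float)
        if a.shape != (spec.n_genomes, spec.n_samples):
            raise ValueError(
                f"explicit abundance matrix shape {a.shape} != "
                f"({spec.n_genomes}, {spec.n_samples})"
            )
        if (a < 0).any():
            raise ValueError("abundance matrix entries must be nonnegative")
    return a / a.sum(axis=0, keepdims=True)


def simulate_reads(
    genomes: Sequence[Tuple[str, str, str]],
    abundances: np.ndarray,
    spec: CommunitySpec,
    outdir: str | Path,
    gzip_fastq: bool = False,
) -> Tuple[SampleManifest, TruthTable]:
    """Write one FASTQ per sample plus manifest and truth TSVs.

    Per (genome, sample) the read count targets an expected base coverage
    of depth_s × n_genomes × abundance; starts are uniform on the forward
    strand of the circularized genome, strands are fair, and substitution
    errors are i.i.d. Deterministic given the spec's rng_seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.rng_seed + 2)
    depths = spec.per_sample_depths()
    rl = spec.read_length
    err = spec.substitution_error_rate
    comp = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G in code space

    truth: TruthTable = {}
    entries: List[ManifestEntry] = []
    genome_codes = [
        np.frombuffer(seq.encode(), dtype=np.uint8) for _, _, seq in genomes
    ]
    lut = np.zeros(256, dtype=np.uint8)
    lut[ord("C")] = 1
    lut[ord("G")] = 2
    lut[ord("T")] = 3
    genome_codes = [np.concatenate([lut[g], lut[g][: rl - 1]]) for g in genome_codes]

    for s in range(spec.n_samples):
        sample_id = f"sample{s + 1}"
        suffix = ".fastq.gz" if gzip_fastq else ".fastq"
        fq_path = outdir / f"{sample_id}{suffix}"
        opener = gzip.open if gzip_fastq else open
        with opener(fq_path, "wt") as fh:
            for g, (gid, sid, _seq) in enumerate(genomes):
                L = spec.genome_length
                cov = depths[s] * spec.n_genomes * abundances[g, s]
                n_reads = int(round(cov * L / rl))
                if n_reads == 0:
                    continue
                starts = rng.integers(0, L, size=n_reads)
                strands = rng.random(n_reads) < 0.5
                err_mask = (
                    rng.random((n_reads, rl)) < err if err > 0 else None
                )
                doubled = genome_codes[g]
                for i in range(n_reads):
                    codes = doubled[starts[i] : starts[i] + rl]
                    if err_mask is not None and err_mask[i].any():
                        codes = codes.copy()
                        hits = np.flatnonzero(err_mask[i])
                        codes[hits] = (
                            codes[hits] + rng.integers(1, 4, size=hits.size)
                        ) % 4
                    if strands[i]:
                        codes = comp[codes[::-1]]
                    seq = _codes_to_str(codes)
                    rid = f"{gid}_{sample_id}_r{i + 1}"
                    fh.write(
                        f"@{rid} genome={gid} species={sid}\n{seq}\n+\n{'I' * rl}\n"
                    )
                    truth[rid] = (gid, sid, sample_id)
        entries.append(ManifestEntry(sample_id, fq_path, "fastq"))

    manifest = SampleManifest(tuple(entries))
    with open(outdir / "manifest.tsv", "w") as fh:
        fh.write("sample_id\tpath\tformat\n")
        for e in entries:
            fh.write(f"{e.sample_id}\t{e.path.name}\t{e.format}\n")
    write_truth_table(truth, outdir / "truth.tsv")
    return manifest, truth


def simulate_community(
    spec: CommunitySpec, outdir: str | Path, gzip_fastq: bool = False
) -> Tuple[SampleManifest, TruthTable]:
    """Genomes + abundances + reads in one call."""
    genomes = generate_genomes(spec)
    abundances = sample_abundance_matrix(spec)
    return simulate_reads(genomes, abundances, spec, outdir, gzip_fastq=gzip_fastq)
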