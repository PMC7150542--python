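"""Purity/completeness scoring of clusterings against truth labels.

purity(cluster) = fraction of the cluster's reads from its predominant
genome (or species); completeness(cluster) = fraction of *all* reads of
that predominant genome in the dataset that the cluster captures
(unclustered reads count in the denominator). A genome is "recovered" when
some cluster predominated by it has purity > 0.95 and completeness > 0.80
(both strict), a deliberately demanding criterion: strain heterogeneity
depresses genome-level purity, and a single uncovered region longer than a
read caps completeness.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .local_clustering import ReadCluster

TruthMap = Mapping[str, Tuple[str, str]]  # read_id -> (genome, species)


@dataclass(frozen=True)
class RecoveryCriteria:
    min_purity: float = 0.95
    min_completeness: float = 0.80

    def __post_init__(self) -> None:
        for name in ("min_purity", "min_completeness"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass
class ClusterScore:
    cluster_id: str
    size: int
    predominant_genome: str
    purity_genome: float
    purity_species: float
    completeness: float


def _predominant(counter: Counter) -> Tuple[str, int]:
    # argmax count, ties toward lexicographically smallest label
    best = min(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    return best


def score_cluster(
    cluster: ReadCluster, truth: TruthMap, _genome_totals: Counter | None = None
) -> ClusterScore:
    """Score one cluster; completeness is relative to the genome's reads in
    the whole truth table, clustered or not."""
    genomes: Counter = Counter()
    species: Counter = Counter()
    for rid in cluster.read_ids:
        if rid not in truth:
            raise KeyError(f"read {rid!r} has no truth label")
        g, s = truth[rid]
        genomes[g] += 1
        species[s] += 1
    size = len(cluster.read_ids)
    top_genome, g_count = _predominant(genomes)
    _, s_count = _predominant(species)
    if _genome_totals is None:
        _genome_totals = Counter(g for g, _ in truth.values())
    return ClusterScore(
        cluster_id=cluster.cluster_id,
        size=size,
        predominant_genome=top_genome,
        purity_genome=g_count / size,
        purity_species=s_count / size,
        completeness=g_count / _genome_totals[top_genome],
    )


def score_clusters(clusters: Sequence[ReadCluster], truth: TruthMap) -> List[ClusterScore]:
    totals = Counter(g for g, _ in truth.values())
    return [score_cluster(c, truth, totals) for c in clusters]


def recovered_genomes(
    scores: Sequence[ClusterScore], criteria: RecoveryCriteria = RecoveryCriteria()
) -> Set[str]:
    """Genomes with a cluster strictly exceeding both thresholds."""
    return {
        sc.predominant_genome
        for sc in scores
        if sc.purity_genome > criteria.min_purity
        and sc.completeness > criteria.min_completeness
    }


def size_distribution(clusters: Sequence[ReadCluster]) -> pd.DataFrame:
    """Read-weighted cluster-size histogram over log10 decade bins.

    Rows: (log10_bin b meaning sizes in [10^b, 10^(b+1)), fraction of
    clustered reads in clusters of that size). Fractions sum to 1.
    """
    if not clusters:
        return pd.DataFrame(columns=["log10_bin", "fraction"])
    sizes = np.array([len(c) for c in clusters])
    bins = np.floor(np.log10(sizes)).astype(int)
    total = sizes.sum()
    rows = [
        (int(b), float(sizes[bins == b].sum() / total)) for b in np.unique(bins)
    ]
    return pd.DataFrame(rows, columns=["log10_bin", "fraction"])


def per_genome_best_completeness(scores: Sequence[ClusterScore]) -> Dict[str, float]:
    """Best (max-completeness) cluster per predominant genome."""
    best: Dict[str, float] = {}
    for sc in scores:
        cur = best.get(sc.predominant_genome, -1.0)
        if sc.completeness > cur:
            best[sc.predominant_genome] = sc.completeness
    return best


def summarize(
    clusters: Sequence[ReadCluster],
    truth: TruthMap,
    criteria: RecoveryCriteria = RecoveryCriteria(),
) -> Dict:
    """JSON-ready summary: medians, recovered genomes, size distribution."""
    scores = score_clusters(clusters, truth)
    dist = size_distribution(clusters)
    n_clustered = sum(len(c) for c in clusters)

    def med(vals: List[float]) -> float:
        return float(np.median(vals)) if vals else float("nan")

    read_weights = [sc.size for sc in scores]
    return {
        "n_clusters": len(scores),
        "n_reads_clustered": n_clustered,
        "n_reads_total": len(truth),
        "median_purity_genome": med([sc.purity_genome for sc in scores]),
        "median_purity_species": med([sc.purity_species for sc in scores]),
        "median_completeness": med([sc.completeness for sc in scores]),
        "read_weighted_median_completeness": _weighted_median(
            [sc.completeness for sc in scores], read_weights
        ),
        "recovered_genomes": sorted(recovered_genomes(scores, criteria)),
        "per_genome_best_completeness": per_genome_best_completeness(scores),
        "size_distribution": dist.to_dict(orient="records"),
    }


def _weighted_median(values: List[float], weights: List[float]) -> float:
    if not values:
        return float("nan")
    order = np.argsort(values)
    v = np.asarray(values)[order]
    w = np.asarray(weights, dtype=float)[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * cum[-1])])


def write_report(
    clusters: Sequence[ReadCluster],
    truth: TruthMap,
    json_path,
    tsv_path=None,
    criteria: RecoveryCriteria = RecoveryCriteria(),
) -> Dict:
    summary = summarize(clusters, truth, criteria)
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if tsv_path is not None:
        scores = score_clusters(clusters, truth)
        df = pd.DataFrame(
            [
                (
                    sc.cluster_id,
                    sc.size,
                    sc.predominant_genome,
                    sc.purity_genome,
                    sc.purity_species,
                    sc.completeness,
                )
                for sc in sorted(scores, key=lambda s: s.cluster_id)
            ],
            columns=[
                "cluster_id",
                "size",
                "predominant_genome",
                "purity_genome",
                "purity_species",
                "completeness",
            ],
        )
        df.to_csv(tsv_path, sep="\t", index=False, float_format="%.6f")
    return summary
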