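"""Global merging of read clusters by cross-sample coverage covariation.

Clusters originating from one genome share that genome's abundance profile
across samples, so their coverage-matrix columns point in the same
direction regardless of cluster size. Pairwise cosine similarities above a
threshold become weighted edges of a cluster graph, which is partitioned
with weighted label propagation; member clusters of a partition are merged
by unioning their read sets, conserving every read.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import networkx as nx
import numpy as np

from .coverage import CoverageMatrix
from .local_clustering import ReadCluster, label_propagation


class NoSignalClusterError(ValueError):
    """A zero coverage vector carries no direction to compare."""


@dataclass(frozen=True)
class GlobalGraphParams:
    """Cluster-graph construction and partitioning knobs."""

    cosine_threshold: float = 0.925
    lpa_max_iters: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.cosine_threshold <= 1.0):
            raise ValueError(
                f"cosine_threshold must be in [0, 1], got {self.cosine_threshold}"
            )
        if self.lpa_max_iters < 1:
            raise ValueError("lpa_max_iters must be ≥ 1")


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """dot(u,v)/(‖u‖·‖v‖); in [0,1] for nonnegative inputs."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"vector shapes differ: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise NoSignalClusterError("cosine similarity undefined for zero vector")
    return float(np.dot(u, v) / (nu * nv))


def build_cluster_graph(matrix: CoverageMatrix, params: GlobalGraphParams) -> nx.Graph:
    """Edges for every unordered cluster pair with similarity ≥ threshold.

    Zero-coverage columns join the graph as isolated nodes (no direction to
    compare) so downstream merge maps stay total.
    """
    graph = nx.Graph()
    graph.add_nodes_from(matrix.clusters)
    x = matrix.values
    norms = np.linalg.norm(x, axis=0)
    live = norms > 0.0
    idx = np.flatnonzero(live)
    if idx.size >= 2:
        xn = x[:, idx] / norms[idx]
        sim = xn.T @ xn
        cs = params.cosine_threshold
        n = idx.size
        for a in range(n - 1):
            row = sim[a]
            for b in range(a + 1, n):
                if row[b] >= cs:
                    graph.add_edge(
                        matrix.clusters[idx[a]],
                        matrix.clusters[idx[b]],
                        weight=float(row[b]),
                    )
    return graph


def global_merge(
    local_clusters: Sequence[ReadCluster],
    matrix: CoverageMatrix,
    params: GlobalGraphParams,
) -> Tuple[Dict[str, str], List[ReadCluster]]:
    """Partition the cluster graph and union member read sets.

    Local clusters absent from the coverage matrix (unreliable spectra) map
    to themselves. Returns (merge map local_id -> global_id, merged
    clusters); the multiset of read ids is unchanged by merging.
    """
    known = {c.cluster_id for c in local_clusters}
    unknown = [cid for cid in matrix.clusters if cid not in known]
    if unknown:
        raise ValueError(f"coverage matrix columns not among local clusters: {unknown}")

    graph = build_cluster_graph(matrix, params)
    labels = label_propagation(
        graph, max_iters=params.lpa_max_iters, rng_seed=params.rng_seed, weighted=True
    )

    groups: Dict[str, List[str]] = {}
    for cid in (c.cluster_id for c in local_clusters):
        lab = labels.get(cid, cid)  # clusters outside the graph stay alone
        groups.setdefault(lab, []).append(cid)

    by_id = {c.cluster_id: c for c in local_clusters}
    ordered = sorted(groups.values(), key=lambda mem: min(mem))
    width = max(5, len(str(len(ordered))))
    merge_map: Dict[str, str] = {}
    merged: List[ReadCluster] = []
    for i, members in enumerate(ordered, start=1):
        gid = f"g{i:0{width}d}"
        read_ids: set[str] = set()
        for cid in members:
            merge_map[cid] = gid
            read_ids.update(by_id[cid].read_ids)
        merged.append(ReadCluster(gid, read_ids))
    return merge_map, merged


def write_merge_map(merge_map: Dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("local_cluster\tglobal_cluster\n")
        for local_id in sorted(merge_map):
            fh.write(f"{local_id}\t{merge_map[local_id]}\n")


def read_merge_map(path) -> Dict[str, str]:
    out: Dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != "local_cluster\tglobal_cluster":
            raise ValueError(f"{path}: bad merge-map header")
        for line in fh:
            local_id, global_id = line.rstrip("\n").split("\t")
            out[local_id] = global_id
    return out
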