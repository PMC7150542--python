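"""Overlap-based local clustering of reads.

Reads sharing seeds (canonical k-mers or minimizers) are joined into an
undirected graph whose edge weights count distinct shared seeds; the graph
is partitioned with a deterministic asynchronous label propagation (LPA)
and small clusters are discarded, because clusters with too few reads do
not produce reliable k-mer frequency spectra downstream.

``max_degree`` limits graph density. Two semantics are provided:

* ``node`` (default): all shared-seed edges are counted, then each node
  keeps only its ``max_degree`` strongest edges (largest shared-seed
  count, ties to the smaller neighbor); an edge survives if either
  endpoint keeps it. Coverage then adds reads without shredding
  connectivity, so clustering improves with sequencing depth.
* ``seed``: a seed occurring in more than ``max_degree`` reads is dropped
  before any pair is emitted. Cheap and aggressive, but above modest
  coverage every genomic seed exceeds the bound and the graph empties.

Independently of either mode, seeds occurring in more than
``repeat_seed_limit`` reads are discarded as repeats, which also bounds
per-seed pair generation.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Hashable, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .seeds import SeedParams, seeds_of
from .sequence_io import Read

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


@dataclass(frozen=True)
class LocalParams:
    """Knobs of the overlap stage.

    min_shared_kmers: minimum distinct shared seeds for an edge to exist.
    max_degree: density bound, interpreted per ``max_degree_mode``.
    min_reads_per_cluster: clusters below this size are dropped after
        partitioning (size ≥ threshold survives; pass 51 to reproduce a
        strict "more than 50").
    repeat_seed_limit: seeds in more reads than this are dropped as
        repetitive regardless of mode (None disables).
    """

    seed_params: SeedParams = field(default_factory=SeedParams)
    min_shared_kmers: int = 2
    max_degree: int = 25
    max_degree_mode: str = "node"
    min_reads_per_cluster: int = 50
    repeat_seed_limit: Optional[int] = 300
    lpa_max_iters: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_shared_kmers", "max_degree", "min_reads_per_cluster"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be ≥ 1")
        if self.max_degree_mode not in ("node", "seed"):
            raise ValueError(f"max_degree_mode must be 'node' or 'seed'")
        if self.repeat_seed_limit is not None and self.repeat_seed_limit < 1:
            raise ValueError("repeat_seed_limit must be ≥ 1 or None")
        if self.lpa_max_iters < 1:
            raise ValueError("lpa_max_iters must be ≥ 1")


@dataclass
class ReadCluster:
    cluster_id: str
    read_ids: Set[str]

    def __len__(self) -> int:
        return len(self.read_ids)


# ---------------------------------------------------------------------------
# Graph construction


def _merge_sorted_counts(
    agg: Optional[Tuple[np.ndarray, np.ndarray]], codes: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    uniq, cnt = np.unique(codes, return_counts=True)
    if agg is None:
        return uniq, cnt
    allc = np.concatenate([agg[0], uniq])
    allw = np.concatenate([agg[1], cnt])
    order = np.argsort(allc, kind="stable")
    allc, allw = allc[order], allw[order]
    out_c, first = np.unique(allc, return_index=True)
    out_w = np.add.reduceat(allw, first)
    return out_c, out_w


def _pair_weights(
    seed_lists: Iterable[List[int]], n_reads: int, params: LocalParams
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distinct-shared-seed count for every read pair co-occurring under a
    surviving seed. Returns (a, b, weight) index arrays with a < b."""
    limit = params.repeat_seed_limit
    drop_over = params.max_degree if params.max_degree_mode == "seed" else None
    chunks: List[np.ndarray] = []
    pending = 0
    agg: Optional[Tuple[np.ndarray, np.ndarray]] = None
    for rids in seed_lists:
        s = len(rids)
        if s < 2:
            continue
        if drop_over is not None and s > drop_over:
            continue
        if limit is not None and s > limit:
            continue
        a = np.asarray(rids, dtype=np.int64)
        iu, ju = np.triu_indices(s, 1)
        x, y = a[iu], a[ju]
        lo = np.minimum(x, y)
        hi = np.maximum(x, y)
        chunks.append(lo * n_reads + hi)
        pending += lo.size
        if pending > 4_000_000:  # bound peak memory of the aggregation
            agg = _merge_sorted_counts(agg, np.concatenate(chunks))
            chunks, pending = [], 0
    if chunks:
        agg = _merge_sorted_counts(agg, np.concatenate(chunks))
    if agg is None:
        z = np.zeros(0, dtype=np.int64)
        return z, z, z
    codes, weights = agg
    keep = weights >= params.min_shared_kmers
    codes, weights = codes[keep], weights[keep]
    return codes // n_reads, codes % n_reads, weights


def _cap_node_degree(
    ea: np.ndarray, eb: np.ndarray, w: np.ndarray, max_degree: int
) -> np.ndarray:
    """Boolean mask keeping edges ranked ≤ max_degree at either endpoint.

    Per-node ranking is by (weight desc, neighbor asc) — deterministic.
    """
    n_edges = ea.size
    if n_edges == 0:
        return np.ones(0, dtype=bool)
    node = np.concatenate([ea, eb])
    nbr = np.concatenate([eb, ea])
    ww = np.concatenate([w, w])
    eid = np.concatenate([np.arange(n_edges), np.arange(n_edges)])
    order = np.lexsort((nbr, -ww, node))
    node_sorted = node[order]
    starts = np.flatnonzero(np.r_[True, node_sorted[1:] != node_sorted[:-1]])
    rank = np.arange(node.size) - np.repeat(starts, np.diff(np.r_[starts, node.size]))
    keep_eids = np.unique(eid[order][rank < max_degree])
    mask = np.zeros(n_edges, dtype=bool)
    mask[keep_eids] = True
    return mask


def _build_edge_arrays(
    reads: Sequence[Read], params: LocalParams
) -> Tuple[List[str], np.ndarray, np.ndarray, np.ndarray]:
    seed_to_reads: Dict[str, List[int]] = defaultdict(list)
    node_ids: List[str] = []
    sp = params.seed_params
    for idx, read in enumerate(reads):
        node_ids.append(read.read_id)
        for s in seeds_of(read.sequence, sp):
            seed_to_reads[s].append(idx)
    ea, eb, w = _pair_weights(seed_to_reads.values(), len(node_ids), params)
    if params.max_degree_mode == "node":
        mask = _cap_node_degree(ea, eb, w, params.max_degree)
        ea, eb, w = ea[mask], eb[mask], w[mask]
    return node_ids, ea, eb, w


def build_read_graph(reads: Iterable[Read], params: LocalParams) -> nx.Graph:
    """Weighted read-overlap graph (weight = distinct shared seeds ≥
    min_shared_kmers, density-bounded per ``max_degree_mode``). Every input
    read is a node, including isolated ones."""
    reads = list(reads)
    node_ids, ea, eb, w = _build_edge_arrays(reads, params)
    graph = nx.Graph()
    graph.add_nodes_from(node_ids)
    graph.add_weighted_edges_from(
        (node_ids[a], node_ids[b], int(c))
        for a, b, c in zip(ea.tolist(), eb.tolist(), w.tolist())
    )
    return graph


# ---------------------------------------------------------------------------
# Label propagation


@njit(cache=True)
def _lpa_sweeps(indptr, indices, weights, perms, labels, max_iters):  # pragma: no cover
    n = labels.size
    for it in range(max_iters):
        changed = 0
        perm = perms[it]
        for pi in range(n):
            node = perm[pi]
            lo, hi = indptr[node], indptr[node + 1]
            deg = hi - lo
            if deg == 0:
                continue
            # small-buffer tally: labels are few per neighborhood
            best_lab = -1
            best_sup = -1.0
            for j in range(lo, hi):
                lab = labels[indices[j]]
                # skip if this label already tallied (first occurrence wins)
                seen = False
                for j2 in range(lo, j):
                    if labels[indices[j2]] == lab:
                        seen = True
                        break
                if seen:
                    continue
                sup = 0.0
                for j2 in range(j, hi):
                    if labels[indices[j2]] == lab:
                        sup += weights[j2]
                if sup > best_sup or (sup == best_sup and lab < best_lab):
                    best_sup = sup
                    best_lab = lab
            if best_lab != labels[node]:
                labels[node] = best_lab
                changed += 1
        if changed == 0:
            break
    return labels


def _lpa_on_csr(
    indptr: np.ndarray,
    indices: np.ndarray,
    weights: np.ndarray,
    n_nodes: int,
    max_iters: int,
    rng_seed: int,
) -> np.ndarray:
    rng = np.random.default_rng(rng_seed)
    perms = np.empty((max_iters, n_nodes), dtype=np.int64)
    for i in range(max_iters):
        perms[i] = rng.permutation(n_nodes)
    labels = np.arange(n_nodes, dtype=np.int64)
    return _lpa_sweeps(indptr, indices, weights, perms, labels, max_iters)


def label_propagation(
    graph: nx.Graph,
    max_iters: int = 20,
    rng_seed: int = 0,
    weighted: bool = False,
) -> Dict[Hashable, Hashable]:
    """Deterministic asynchronous label propagation.

    Each node starts with its own label; per sweep, nodes are visited in a
    seeded shuffle and adopt the label with maximum total neighbor support
    (summed edge weight when ``weighted``, else neighbor count), ties
    broken toward the smallest label. Terminates when a sweep changes
    nothing or after ``max_iters`` sweeps. Labels never cross connected
    components.
    """
    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    indptr, indices, weights = _csr_from_graph(graph, nodes, index, weighted)
    labels = _lpa_on_csr(indptr, indices, weights, len(nodes), max_iters, rng_seed)
    return {n: nodes[labels[i]] for n, i in index.items()}


def _csr_from_graph(graph, nodes, index, weighted):
    n = len(nodes)
    deg = np.zeros(n, dtype=np.int64)
    for a, b in graph.edges:
        deg[index[a]] += 1
        deg[index[b]] += 1
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(deg, out=indptr[1:])
    indices = np.empty(indptr[-1], dtype=np.int64)
    weights = np.empty(indptr[-1], dtype=np.float64)
    cursor = indptr[:-1].copy()
    for a, b, data in graph.edges(data=True):
        ia, ib = index[a], index[b]
        w = float(data.get("weight", 1)) if weighted else 1.0
        indices[cursor[ia]] = ib
        weights[cursor[ia]] = w
        cursor[ia] += 1
        indices[cursor[ib]] = ia
        weights[cursor[ib]] = w
        cursor[ib] += 1
    return indptr, indices, weights


def _csr_from_arrays(n_nodes, ea, eb, w, weighted):
    deg = np.bincount(ea, minlength=n_nodes) + np.bincount(eb, minlength=n_nodes)
    indptr = np.zeros(n_nodes + 1, dtype=np.int64)
    np.cumsum(deg, out=indptr[1:])
    indices = np.empty(indptr[-1], dtype=np.int64)
    weights = np.empty(indptr[-1], dtype=np.float64)
    cursor = indptr[:-1].copy()
    wf = w.astype(np.float64) if weighted else np.ones(ea.size, dtype=np.float64)
    for a, b, ww in zip(ea.tolist(), eb.tolist(), wf.tolist()):
        indices[cursor[a]] = b
        weights[cursor[a]] = ww
        cursor[a] += 1
        indices[cursor[b]] = a
        weights[cursor[b]] = ww
        cursor[b] += 1
    return indptr, indices, weights


# ---------------------------------------------------------------------------
# Clustering


def partition_to_clusters(
    labels: Dict[Hashable, Hashable], min_size: int, prefix: str = "c"
) -> List[ReadCluster]:
    """Group nodes by label, drop groups below ``min_size``, and assign
    stable cluster ids (sorted by descending size, then smallest member)."""
    groups: Dict[Hashable, Set[str]] = defaultdict(set)
    for node, lab in labels.items():
        groups[lab].add(node)
    surviving = [g for g in groups.values() if len(g) >= min_size]
    surviving.sort(key=lambda g: (-len(g), min(g)))
    width = max(5, len(str(len(surviving))))
    return [
        ReadCluster(f"{prefix}{i:0{width}d}", members)
        for i, members in enumerate(surviving, start=1)
    ]


def local_cluster(reads: Sequence[Read], params: LocalParams) -> List[ReadCluster]:
    """Full local stage: overlap graph, LPA partition, size filter.

    Equivalent to build_read_graph + label_propagation but skips the
    networkx container for speed on large read sets.
    """
    reads = list(reads)
    node_ids, ea, eb, w = _build_edge_arrays(reads, params)
    # node ids must be visited in sorted order for parity with
    # label_propagation(build_read_graph(...)); relabel accordingly
    order = np.argsort(np.asarray(node_ids, dtype=object), kind="stable")
    rank = np.empty(len(node_ids), dtype=np.int64)
    rank[order] = np.arange(len(node_ids))
    sorted_ids = [node_ids[i] for i in order.tolist()]
    ea2, eb2 = rank[ea], rank[eb]
    indptr, indices, weights = _csr_from_arrays(len(node_ids), ea2, eb2, w, False)
    labels = _lpa_on_csr(
        indptr, indices, weights, len(node_ids), params.lpa_max_iters, params.rng_seed
    )
    label_map = {sorted_ids[i]: sorted_ids[labels[i]] for i in range(len(sorted_ids))}
    return partition_to_clusters(label_map, params.min_reads_per_cluster)
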