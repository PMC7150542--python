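"""Read-overlap graph construction and label propagation."""

from collections import Counter

import networkx as nx
import numpy as np
import pytest

from readclust.local_clustering import (
    LocalParams,
    build_read_graph,
    label_propagation,
    local_cluster,
    partition_to_clusters,
)
from readclust.seeds import SeedParams, seeds_of
from readclust.sequence_io import Read

from conftest import random_dna


def brute_force_graph(reads, params):
    """Independent all-pairs shared-seed counter with the same filtering
    semantics: per-seed occupancy filters first, node-degree cap last."""
    seed_sets = [seeds_of(r.sequence, params.seed_params) for r in reads]
    occupancy = Counter()
    for ss in seed_sets:
        occupancy.update(ss)

    def survives(seed):
        n = occupancy[seed]
        if params.max_degree_mode == "seed" and n > params.max_degree:
            return False
        if params.repeat_seed_limit is not None and n > params.repeat_seed_limit:
            return False
        return True

    edges = {}
    for i in range(len(reads)):
        for j in range(i + 1, len(reads)):
            w = sum(1 for s in seed_sets[i] & seed_sets[j] if survives(s))
            if w >= params.min_shared_kmers:
                a, b = sorted((reads[i].read_id, reads[j].read_id))
                edges[(a, b)] = w
    if params.max_degree_mode == "node":
        incident = {}
        for (a, b), w in edges.items():
            incident.setdefault(a, []).append((-w, b, (a, b)))
            incident.setdefault(b, []).append((-w, a, (a, b)))
        kept = set()
        for node, lst in incident.items():
            lst.sort()
            kept.update(key for _, _, key in lst[: params.max_degree])
        edges = {key: w for key, w in edges.items() if key in kept}
    return edges


def graph_edges(graph):
    return {
        tuple(sorted((a, b))): data["weight"] for a, b, data in graph.edges(data=True)
    }


class TestBuildReadGraph:
    def test_identical_reads_share_all_kmers(self, rng):
        seq = random_dna(rng, 100)
        reads = [Read("r1", "s1", seq), Read("r2", "s1", seq)]
        params = LocalParams(seed_params=SeedParams(41, 22, "kmer"))
        g = build_read_graph(reads, params)
        assert g["r1"]["r2"]["weight"] == 60  # 100 - 41 + 1 distinct k-mers

    def test_disjoint_reads_no_edge(self, rng):
        reads = [Read("r1", "s1", random_dna(rng, 80)), Read("r2", "s1", random_dna(rng, 80))]
        params = LocalParams(seed_params=SeedParams(41, 22, "kmer"))
        assert build_read_graph(reads, params).number_of_edges() == 0

    def test_seed_mode_drops_overfull_seed(self, rng):
        # 26 single-k-mer reads sharing exactly one seed; max_degree=25
        seq = random_dna(rng, 41)
        reads = [Read(f"r{i:02d}", "s1", seq) for i in range(26)]
        params = LocalParams(
            seed_params=SeedParams(41, 22, "kmer"),
            min_shared_kmers=1,
            max_degree_mode="seed",
        )
        assert build_read_graph(reads, params).number_of_edges() == 0
        # one read fewer and the seed survives: complete graph on 25
        g25 = build_read_graph(reads[:25], params)
        assert g25.number_of_edges() == 25 * 24 // 2

    def test_repeat_seed_limit_applies_in_node_mode(self, rng):
        seq = random_dna(rng, 41)
        reads = [Read(f"r{i:02d}", "s1", seq) for i in range(30)]
        params = LocalParams(
            seed_params=SeedParams(41, 22, "kmer"),
            min_shared_kmers=1,
            max_degree_mode="node",
            repeat_seed_limit=29,
        )
        assert build_read_graph(reads, params).number_of_edges() == 0

    @pytest.mark.parametrize("mode", ["seed", "node"])
    def test_matches_brute_force_oracle(self, rng, mode):
        # reads drawn from two templates so overlaps, repeats and the
        # degree cap are all exercised
        templates = [random_dna(rng, 300), random_dna(rng, 300)]
        reads = []
        for i in range(40):
            t = templates[i % 2]
            start = int(rng.integers(0, 200))
            reads.append(Read(f"r{i:02d}", "s1", t[start : start + 100]))
        params = LocalParams(
            seed_params=SeedParams(21, 11, "minimizer"),
            min_shared_kmers=1,
            max_degree=5,
            max_degree_mode=mode,
        )
        assert graph_edges(build_read_graph(reads, params)) == brute_force_graph(
            reads, params
        )

    def test_isolated_reads_are_nodes(self, rng):
        reads = [Read("r1", "s1", random_dna(rng, 60)), Read("r2", "s1", random_dna(rng, 60))]
        g = build_read_graph(reads, LocalParams())
        assert set(g.nodes) == {"r1", "r2"}


class TestLabelPropagation:
    def test_disjoint_triangles_two_labels(self):
        g = nx.Graph([(1, 2), (2, 3), (1, 3), (4, 5), (5, 6), (4, 6)])
        labels = label_propagation(g, rng_seed=7)
        assert len({labels[1], labels[4]}) == 2
        assert labels[1] == labels[2] == labels[3]
        assert labels[4] == labels[5] == labels[6]

    def test_isolated_node_keeps_own_label(self):
        g = nx.Graph()
        g.add_node("x")
        assert label_propagation(g) == {"x": "x"}

    def test_star_converges_to_one_label(self):
        labels = label_propagation(nx.star_graph(5), max_iters=50, rng_seed=3)
        assert len(set(labels.values())) == 1

    def test_no_label_spans_components(self, rng):
        g = nx.Graph()
        for offset in (0, 100):
            nodes = list(range(offset, offset + 20))
            for _ in range(40):
                a, b = rng.choice(nodes, 2, replace=False)
                g.add_edge(int(a), int(b))
        labels = label_propagation(g, rng_seed=5)
        left = {labels[n] for n in g.nodes if n < 100}
        right = {labels[n] for n in g.nodes if n >= 100}
        assert not (left & right)

    def test_weighted_support_dominates_tie_break(self):
        # weighted star: one heavy spoke (weight 5) outweighs three light
        # ones combined, so the light leaves' labels can never win the
        # center — consensus is the center's or the heavy leaf's label,
        # regardless of the asynchronous schedule
        g = nx.Graph()
        for leaf, w in (("l1", 1), ("l2", 1), ("l3", 1), ("l4", 5)):
            g.add_edge("z", leaf, weight=w)
        for seed in range(5):
            labels = label_propagation(g, max_iters=30, rng_seed=seed, weighted=True)
            assert len(set(labels.values())) == 1
            assert labels["z"] in {"z", "l4"}


class TestLocalCluster:
    def _template_reads(self, rng, template, n, prefix):
        return [
            Read(f"{prefix}{i:03d}", "s1", template[s : s + 100])
            for i, s in enumerate(rng.integers(0, len(template) - 100, n))
        ]

    def test_small_cluster_discarded(self, rng):
        big = self._template_reads(rng, random_dna(rng, 160), 60, "a")
        small = self._template_reads(rng, random_dna(rng, 160), 10, "b")
        params = LocalParams(
            seed_params=SeedParams(21, 11, "minimizer"),
            min_shared_kmers=1,
            max_degree=100,  # mutual overlap: let the clique stay complete
            rng_seed=1,
        )
        clusters = local_cluster(big + small, params)
        assert len(clusters) == 1 and len(clusters[0]) == 60

    def test_size_threshold_is_inclusive(self):
        labels = {f"n{i}": "x" for i in range(49)}
        assert partition_to_clusters(labels, 50) == []
        labels["n49"] = "x"
        assert len(partition_to_clusters(labels, 50)) == 1

    def test_all_singletons_no_clusters(self, rng):
        reads = [Read(f"r{i}", "s1", random_dna(rng, 60)) for i in range(20)]
        assert local_cluster(reads, LocalParams()) == []

    def test_partition_property_and_purity_on_separable_input(self, rng):
        t1, t2 = random_dna(rng, 400), random_dna(rng, 400)
        reads = self._template_reads(rng, t1, 30, "a") + self._template_reads(
            rng, t2, 30, "b"
        )
        params = LocalParams(
            seed_params=SeedParams(21, 11, "minimizer"),
            min_shared_kmers=1,
            min_reads_per_cluster=1,
            rng_seed=9,
        )
        clusters = local_cluster(reads, params)
        all_ids = [rid for c in clusters for rid in c.read_ids]
        assert len(all_ids) == len(set(all_ids))  # disjoint
        assert set(all_ids) <= {r.read_id for r in reads}
        for c in clusters:  # genomes share no seeds => pure clusters
            origins = {rid[0] for rid in c.read_ids}
            assert len(origins) == 1

    def test_deterministic_given_seed(self, rng):
        t = random_dna(rng, 300)
        reads = self._template_reads(rng, t, 40, "r")
        params = LocalParams(
            seed_params=SeedParams(21, 11, "minimizer"),
            min_shared_kmers=1,
            min_reads_per_cluster=1,
            rng_seed=4,
        )
        c1 = local_cluster(reads, params)
        c2 = local_cluster(reads, params)
        assert [sorted(c.read_ids) for c in c1] == [sorted(c.read_ids) for c in c2]

    def test_matches_graph_plus_lpa_composition(self, rng):
        t = random_dna(rng, 300)
        reads = self._template_reads(rng, t, 30, "r")
        params = LocalParams(
            seed_params=SeedParams(21, 11, "minimizer"),
            min_shared_kmers=1,
            min_reads_per_cluster=1,
            rng_seed=42,
        )
        via_fast_path = local_cluster(reads, params)
        labels = label_propagation(
            build_read_graph(reads, params), params.lpa_max_iters, params.rng_seed
        )
        via_composition = partition_to_clusters(labels, 1)
        assert [sorted(c.read_ids) for c in via_fast_path] == [
            sorted(c.read_ids) for c in via_composition
        ]
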