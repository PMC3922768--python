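"""Graph search: edge costs, cost hierarchy, Dijkstra, tree mapping."""

import math

import numpy as np
import pytest

from conftest import brute_force_search, random_graph
from retivessel.config import PipelineConfig
from retivessel.evaluation import structural_segment_accuracy
from retivessel.features import EndFeatures
from retivessel.treesearch import (
    EdgeCosts,
    SegmentGraph,
    dijkstra_tree,
    edge_costs,
    extract_primary_path,
    hierarchical_cost,
)

CFG = PipelineConfig()


def end(travel, w=1.0, i=1.0):
    return EndFeatures(
        theta=0.0, travel_dir=travel, width_raw=1, intensity_raw=1,
        width_norm=w, intensity_norm=i,
    )


class TestEdgeCosts:
    def test_straight_continuation_is_free(self):
        # u travels +x away from the junction, v continues +x beyond it
        c = edge_costs(end((1.0, 0.0)), end((-1.0, 0.0)))
        assert c.c_theta == pytest.approx(0.0, abs=1e-9)

    def test_right_angle(self):
        c = edge_costs(end((1.0, 0.0)), end((0.0, 1.0)))
        assert c.c_theta == pytest.approx(math.pi / 2)

    def test_width_cost_scaled_by_pi(self):
        c = edge_costs(end((1.0, 0.0), w=0.5), end((-1.0, 0.0), w=1.0))
        assert c.c_w == pytest.approx(0.5 * math.pi)

    def test_more_similar_orientation_costs_less(self):
        straight = edge_costs(end((1.0, 0.0)), end((-1.0, 0.0)))
        oblique = edge_costs(end((1.0, 0.0)), end((-0.5, math.sqrt(3) / 2)))
        assert straight.c_theta < oblique.c_theta

    def test_degenerate_end_max_cost(self):
        c = edge_costs(
            EndFeatures(theta=None, travel_dir=None, width_raw=1,
                        intensity_raw=1, width_norm=1, intensity_norm=1),
            end((1.0, 0.0)),
        )
        assert c.c_theta == pytest.approx(math.pi)


def star_graph(costs):
    """Node 0 joined to nodes 1..n with the given cost triples."""
    g = SegmentGraph()
    g.add_node(0)
    for k, c in enumerate(costs, start=1):
        g.add_node(k, endpoint=True)
        g.add_edge(0, k, k, c)
    return g


class TestHierarchicalCost:
    def test_distinct_orientations_use_theta(self):
        g = star_graph([EdgeCosts(0.2, 0.1, 0.05), EdgeCosts(0.9, 0.6, 0.3)])
        e1, e2 = g.edges_from(0)
        assert hierarchical_cost(g, e1) == 0.2
        assert hierarchical_cost(g, e2) == 0.9

    def test_orientation_tie_falls_back_to_width(self):
        g = star_graph([EdgeCosts(0.2, 0.1, 0.05), EdgeCosts(0.2, 0.6, 0.3)])
        e1, e2 = g.edges_from(0)
        assert hierarchical_cost(g, e1) == 0.1
        assert hierarchical_cost(g, e2) == 0.6

    def test_double_tie_falls_back_to_intensity(self):
        g = star_graph([EdgeCosts(0.2, 0.1, 0.05), EdgeCosts(0.2, 0.1, 0.3)])
        e1, e2 = g.edges_from(0)
        assert hierarchical_cost(g, e1) == 0.05
        assert hierarchical_cost(g, e2) == 0.3

    def test_tolerance_drives_tie(self):
        g = star_graph([EdgeCosts(0.20, 0.1, 0.05), EdgeCosts(0.24, 0.6, 0.3)])
        e1, _ = g.edges_from(0)
        assert hierarchical_cost(g, e1, eps_theta=0.05) == 0.1
        assert hierarchical_cost(g, e1, eps_theta=0.01) == 0.2


def chain_graph(costs):
    g = SegmentGraph()
    g.add_node(0)
    for k, c in enumerate(costs, start=1):
        g.add_node(k, endpoint=(k == len(costs)))
        g.add_edge(k - 1, k, k, c)
    return g


class TestDijkstra:
    def test_chain_distances_and_normalization(self):
        g = chain_graph([EdgeCosts(1.0, 1, 1), EdgeCosts(2.0, 2, 2)])
        pr = dijkstra_tree(g, 0)
        assert pr.dist[2] == pytest.approx(3.0)
        assert pr.davg[2] == pytest.approx(1.0)  # 3 nodes on the path

    def test_y_graph_prefers_lower_average(self):
        """Short cheap path (davg 0.10) beats longer path (davg 0.1333)."""
        g = SegmentGraph()
        for n, ep in [(0, False), (1, False), (2, True), (3, True)]:
            g.add_node(n, endpoint=ep)
        g.add_edge(0, 2, 0, EdgeCosts(0.2, 0.2, 0.2))   # S -> E2
        g.add_edge(0, 1, 1, EdgeCosts(0.1, 0.1, 0.1))   # S -> A
        g.add_edge(1, 3, 2, EdgeCosts(0.3, 0.3, 0.3))   # A -> E1
        pr = dijkstra_tree(g, 0)
        assert pr.davg[2] == pytest.approx(0.1)
        assert pr.davg[3] == pytest.approx(0.4 / 3)
        assert pr.best_endpoint == 2
        assert extract_primary_path(pr) == [0, 2]

    def test_seed_not_its_own_endpoint(self):
        g = chain_graph([EdgeCosts(1.0, 1, 1)])
        g.endpoint_nodes.add(0)
        pr = dijkstra_tree(g, 0)
        assert pr.best_endpoint == 1

    def test_no_reachable_endpoint_returns_seed(self):
        g = SegmentGraph()
        g.add_node(0)
        pr = dijkstra_tree(g, 0)
        assert extract_primary_path(pr) == [0]

    def test_allowed_restricts_search(self):
        g = chain_graph([EdgeCosts(1.0, 1, 1), EdgeCosts(1.0, 1, 1)])
        pr = dijkstra_tree(g, 0, allowed={0, 1})
        assert 2 not in pr.dist

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_enumeration(self, seed):
        """dist[] and path selection equal brute-force simple-path search."""
        rng = np.random.default_rng(1000 + seed)
        g = random_graph(rng)
        pr = dijkstra_tree(g, 0, CFG)
        dist_bf, best_bf = brute_force_search(g, 0, CFG)
        assert set(pr.dist) == set(dist_bf)
        for v, d in dist_bf.items():
            assert pr.dist[v] == pytest.approx(d, abs=1e-9)
        assert pr.best_endpoint == best_bf

    @pytest.mark.parametrize("seed", range(10))
    def test_cost_scaling_preserves_selection(self, seed):
        """Scaling all costs by k scales davg by k, same path selected."""
        rng = np.random.default_rng(2000 + seed)
        g = random_graph(rng)
        k = 3.7
        g2 = SegmentGraph()
        for n in g.nodes:
            g2.add_node(n, endpoint=n in g.endpoint_nodes)
        seen = set()
        for u in sorted(g.nodes):
            for e in g.edges_from(u):
                key = (min(e.u, e.v), max(e.u, e.v), e.junction)
                if key not in seen:
                    seen.add(key)
                    g2.add_edge(e.u, e.v, e.junction, e.costs.scaled(k))
        cfg1 = PipelineConfig()
        cfg2 = PipelineConfig(eps_theta=CFG.eps_theta * k, eps_wI=CFG.eps_wI * k)
        pr1 = dijkstra_tree(g, 0, cfg1)
        pr2 = dijkstra_tree(g2, 0, cfg2)
        assert pr1.best_endpoint == pr2.best_endpoint
        for v in pr1.davg:
            assert pr2.davg[v] == pytest.approx(k * pr1.davg[v], rel=1e-9)


class TestNetworkMapping:
    def test_single_tree_partition(self, scene_batch):
        """Labeling is a partition: each segment carries exactly one tree id."""
        for scene, res in scene_batch[:5]:
            labeled = set(res.labeling.assignment) | res.labeling.noise
            assert labeled == set(res.segment_map.segments)
            assert not set(res.labeling.assignment) & res.labeling.noise

    def test_crossing_claims_two_segments_per_tree(self, scene_batch):
        """At a degree-4 crossing each tree claims exactly 2 of 4 stubs."""
        checked = 0
        for scene, res in scene_batch:
            for jid, j in res.segment_map.junctions.items():
                if j.degree != 4:
                    continue
                sids = res.segment_map.incident_segments(jid)
                trees = [res.labeling.tree_of(s) for s in sids]
                counts = {t: trees.count(t) for t in set(trees) if t is not None}
                if len(counts) == 2:
                    assert sorted(counts.values()) == [2, 2]
                    checked += 1
        assert checked >= 10

    def test_structural_recovery_on_default_scene(self, default_scene, default_result):
        acc, _, _ = structural_segment_accuracy(
            default_result.segment_map,
            default_result.labeling,
            default_scene.gt.tree_id_image,
        )
        assert acc >= 0.9

    def test_tree_count_matches_ground_truth(self, default_scene, default_result):
        assert len(default_result.labeling.roots) == len(default_scene.gt.av_labels)

    def test_primary_paths_are_connected(self, default_result):
        from retivessel.topology import segment_adjacency

        adj = {}
        for a, b, _ in segment_adjacency(default_result.segment_map):
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        for tid, path in default_result.labeling.primary_paths.items():
            for u, v in zip(path[:-1], path[1:]):
                assert v in adj.get(u, set())
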