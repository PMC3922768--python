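"""Shared fixtures: constructed skeletons, synthetic scenes, graph oracles."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from retivessel.config import PipelineConfig
from retivessel.pipeline import run_pipeline
from retivessel.synthetic import SceneSpec, generate_scene
from retivessel.treesearch import EdgeCosts, SegmentGraph, hierarchical_cost


# ---------------------------------------------------------------------------
# constructed skeleton fixtures


def _pixels_to_mask(pixels, shape=(20, 24)):
    s = np.zeros(shape, dtype=bool)
    for p in pixels:
        s[p] = True
    return s


@pytest.fixture
def skeleton_line():
    """Straight 10-pixel line: 2 endpoints, no junctions."""
    return _pixels_to_mask([(5, c) for c in range(2, 12)])


@pytest.fixture
def skeleton_y():
    """Three rays meeting at one pixel: 3 endpoints, one degree-3 branch."""
    return _pixels_to_mask(
        [(5, 8), (6, 8), (7, 8), (8, 8),
         (4, 7), (3, 6), (2, 5),
         (4, 9), (3, 10), (2, 11)]
    )


@pytest.fixture
def skeleton_plus():
    """Two crossing lines: 4 endpoints, one degree-4 crossing."""
    return _pixels_to_mask(
        [(5, c) for c in range(1, 16)] + [(r, 8) for r in range(1, 10) if r != 5]
    )


@pytest.fixture
def skeleton_double_bifurcation():
    """A crossing rendered as two bifurcations joined by a short run.

    Thinning produces this pattern for transversal crossings of thick
    vessels; junction consolidation must recover a single degree-4
    crossing with 4 endpoints.
    """
    return _pixels_to_mask(
        [(5, c) for c in range(0, 9)] + [(4, 8), (3, 8), (2, 8)]
        + [(5, 9), (5, 10), (5, 11)]
        + [(5, 12)] + [(5, c) for c in range(13, 21)] + [(6, 12), (7, 12), (8, 12)]
    )


# ---------------------------------------------------------------------------
# synthetic scenes


SCENE_COMPOSITIONS = [
    (1, 1, 1),
    (2, 1, 1),
    (2, 2, 1),
    (2, 2, 2),
    (3, 2, 2),
    (3, 3, 3),
]


def make_scene(seed: int, **overrides):
    spec = SceneSpec(seed=seed, **overrides)
    return generate_scene(spec)


def run_on_scene(scene):
    cfg = PipelineConfig(
        od_center=scene.spec.od_center, od_radius=scene.spec.resolved_od_radius()
    )
    return run_pipeline(scene.rgb, scene.mask, cfg)


@pytest.fixture(scope="session")
def default_scene():
    return make_scene(seed=0)


@pytest.fixture(scope="session")
def default_result(default_scene):
    return run_on_scene(default_scene)


@pytest.fixture(scope="session")
def scene_batch():
    """20 seeded scenes cycling 2-6 trees, each with >= 1 AV crossing."""
    batch = []
    for seed in range(20):
        na, nv, npair = SCENE_COMPOSITIONS[seed % len(SCENE_COMPOSITIONS)]
        scene = make_scene(seed, n_arteries=na, n_veins=nv, n_crossing_pairs=npair)
        batch.append((scene, run_on_scene(scene)))
    return batch


# ---------------------------------------------------------------------------
# constant-width bars for feature fidelity checks


def draw_bar(width: float, angle_deg: float, length: int = 40, shape=(80, 80)):
    """Rasterized constant-width bar; returns (mask, centerline pixel list)."""
    from retivessel.synthetic import _stamp

    mask = np.zeros(shape, dtype=bool)
    ang = math.radians(angle_deg)
    d = np.array([-math.sin(ang), math.cos(ang)])  # row decreases upward
    c0 = np.array(shape, dtype=float) / 2.0 - 0.5 * length * d
    pts = np.array([c0 + t * d for t in np.arange(0, length, 1.0)])
    _stamp(mask, pts, np.full(len(pts), float(width)))
    centerline = []
    for p in pts:
        q = (int(round(p[0])), int(round(p[1])))
        if not centerline or q != centerline[-1]:
            centerline.append(q)
    return mask, centerline


# ---------------------------------------------------------------------------
# random segment graphs and the exhaustive path oracle


def random_graph(rng: np.random.Generator, max_nodes: int = 12) -> SegmentGraph:
    """Connected random segment graph with random cost triples."""
    n = int(rng.integers(3, max_nodes + 1))
    g = SegmentGraph()
    for i in range(n):
        g.add_node(i, endpoint=bool(rng.random() < 0.5) or i in (0, n - 1))
    jid = 0
    # random spanning tree keeps it connected
    order = rng.permutation(n)
    for a, b in zip(order[:-1], order[1:]):
        g.add_edge(int(a), int(b), jid, _random_costs(rng))
        jid += 1
    existing = {tuple(sorted((int(a), int(b)))) for a, b in zip(order[:-1], order[1:])}
    n_extra = int(rng.integers(0, n))
    for _ in range(n_extra):
        a, b = rng.integers(0, n, size=2)
        key = tuple(sorted((int(a), int(b))))
        if a == b or key in existing:
            continue
        existing.add(key)
        g.add_edge(int(a), int(b), jid, _random_costs(rng))
        jid += 1
    return g


def _random_costs(rng) -> EdgeCosts:
    return EdgeCosts(
        c_theta=float(rng.uniform(0, math.pi)),
        c_w=float(rng.uniform(0, math.pi)),
        c_I=float(rng.uniform(0, math.pi)),
    )


def brute_force_search(graph: SegmentGraph, seed: int, cfg: PipelineConfig):
    """Exhaustive enumeration of all simple paths from ``seed``.

    Returns (dist, best_endpoint) where dist[v] is the minimal summed
    hierarchical edge cost over simple paths and best_endpoint minimizes
    dist/n_nodes over endpoint nodes (ties: more nodes, then lower id).
    """
    dist = {seed: 0.0}
    best_count = {seed: 1}
    stack = [(seed, {seed}, 0.0)]
    while stack:
        u, visited, cost = stack.pop()
        for e in graph.edges_from(u):
            if e.v in visited:
                continue
            w = hierarchical_cost(graph, e, cfg.eps_theta, cfg.eps_wI)
            nc = cost + w
            if e.v not in dist or nc < dist[e.v] - 1e-12:
                dist[e.v] = nc
                best_count[e.v] = len(visited) + 1
            stack.append((e.v, visited | {e.v}, nc))
    candidates = [
        (dist[v] / best_count[v], -best_count[v], v)
        for v in sorted(graph.endpoint_nodes)
        if v != seed and v in dist
    ]
    best = min(candidates)[2] if candidates else None
    return dist, best
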