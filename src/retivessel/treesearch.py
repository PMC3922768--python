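"""Vessel-tree separation by hierarchical-cost graph search.

Vessel segments are nodes of a graph; an edge joins two segments meeting at
a junction and carries three costs measured between the two meeting end
regions: the direction-aware orientation difference ``c_theta``, and the
normalized width and intensity differences ``c_w`` and ``c_I`` (scaled by pi
so all three share the range [0, pi]).

A tree is recovered by Dijkstra's algorithm from a root segment (the one
whose free endpoint lies nearest the optic-disc rim). Edges are costed with
``c_theta`` unless two of a node's orientation differences tie (within a
tolerance), in which case the width difference decides, and if widths also
tie, the intensity difference. The minimal summed cost to each endpoint
segment is normalized by the number of segments on the path; the endpoint
with the lowest normalized cost defines the primary (true) vessel path.
Branches are mapped recursively by the same principle from the side
segments at branch junctions; at crossings (degree >= 4) a tree claims only
its own continuation pair, leaving the transversal pair for another tree.
"""

from __future__ import annotations

import dataclasses
import heapq
import math
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .config import PipelineConfig
from .features import EndFeatures, EndKey
from .topology import VesselSegmentMap

MAX_COST = math.pi


@dataclasses.dataclass(frozen=True)
class EdgeCosts:
    c_theta: float
    c_w: float
    c_I: float

    def scaled(self, k: float) -> "EdgeCosts":
        return EdgeCosts(self.c_theta * k, self.c_w * k, self.c_I * k)


@dataclasses.dataclass(frozen=True)
class Edge:
    u: int
    v: int
    junction: int
    costs: EdgeCosts


class SegmentGraph:
    """Undirected multigraph over vessel segments with triple edge costs."""

    def __init__(self) -> None:
        self.nodes: Set[int] = set()
        self.endpoint_nodes: Set[int] = set()
        self._adj: Dict[int, List[Edge]] = {}

    def add_node(self, node: int, endpoint: bool = False) -> None:
        self.nodes.add(node)
        self._adj.setdefault(node, [])
        if endpoint:
            self.endpoint_nodes.add(node)

    def add_edge(self, u: int, v: int, junction: int, costs: EdgeCosts) -> None:
        self.add_node(u)
        self.add_node(v)
        self._adj[u].append(Edge(u, v, junction, costs))
        self._adj[v].append(Edge(v, u, junction, costs))

    def edges_from(self, u: int, allowed: Optional[Set[int]] = None) -> List[Edge]:
        edges = self._adj.get(u, [])
        if allowed is None:
            return list(edges)
        return [e for e in edges if e.v in allowed]

    def __contains__(self, node: int) -> bool:
        return node in self.nodes


@dataclasses.dataclass
class PathResult:
    seed: int
    dist: Dict[int, float]
    previous: Dict[int, Optional[int]]
    davg: Dict[int, float]          # endpoint node -> dist / n_nodes_on_path
    node_count: Dict[int, int]      # endpoint node -> nodes on path incl. seed
    best_endpoint: Optional[int]


@dataclasses.dataclass
class TreeLabeling:
    # segment id -> (tree id, depth); depth 0 = primary vessel
    assignment: Dict[int, Tuple[int, int]]
    roots: Dict[int, int]
    primary_paths: Dict[int, List[int]]
    noise: Set[int]

    def tree_of(self, sid: int) -> Optional[int]:
        entry = self.assignment.get(sid)
        return None if entry is None else entry[0]

    def segments_of(self, tree_id: int) -> List[int]:
        return sorted(s for s, (t, _) in self.assignment.items() if t == tree_id)

    @property
    def tree_ids(self) -> List[int]:
        return sorted(self.roots)


# ---------------------------------------------------------------------------
# edge costs


def _angle_between(a: Sequence[float], b: Sequence[float]) -> float:
    dot = a[0] * b[0] + a[1] * b[1]
    return math.acos(max(-1.0, min(1.0, dot)))


def edge_costs(u_end: EndFeatures, v_end: EndFeatures) -> EdgeCosts:
    """Cost triple between two end regions meeting at a junction.

    ``c_theta`` is the angle between the continuation direction of the
    incoming segment (the reverse of its travel direction, which points
    away from the junction into its interior) and the travel direction of
    the outgoing segment, so a straight continuation costs 0 and a U-turn
    costs pi. Degenerate (single-pixel) ends get the maximal orientation
    cost. Width and intensity costs are the absolute normalized differences
    scaled by pi to match the orientation unit.
    """
    if u_end.travel_dir is None or v_end.travel_dir is None:
        c_theta = MAX_COST
    else:
        continuation = (-u_end.travel_dir[0], -u_end.travel_dir[1])
        c_theta = _angle_between(continuation, v_end.travel_dir)
    c_w = abs(u_end.width_norm - v_end.width_norm) * math.pi
    c_I = abs(u_end.intensity_norm - v_end.intensity_norm) * math.pi
    if math.isnan(c_w):
        c_w = MAX_COST
    if math.isnan(c_I):
        c_I = MAX_COST
    return EdgeCosts(c_theta=c_theta, c_w=c_w, c_I=c_I)


def build_graph(
    seg_map: VesselSegmentMap, feats: Dict[EndKey, EndFeatures]
) -> SegmentGraph:
    """Segment graph with one edge per pair of stubs meeting at a junction."""
    g = SegmentGraph()
    for sid, seg in seg_map.segments.items():
        g.add_node(sid, endpoint=seg.is_endpoint_segment)
    for jid in sorted(seg_map.incidence):
        stubs = sorted(seg_map.incidence[jid])
        for i in range(len(stubs)):
            for k in range(i + 1, len(stubs)):
                (su, eu), (sv, ev) = stubs[i], stubs[k]
                if su == sv:
                    continue  # a segment looping back to its own junction
                g.add_edge(su, sv, jid, edge_costs(feats[(su, eu)], feats[(sv, ev)]))
    return g


# ---------------------------------------------------------------------------
# hierarchical cost and Dijkstra search


def hierarchical_cost(
    graph: SegmentGraph,
    edge: Edge,
    eps_theta: float = 0.05,
    eps_wI: float = 0.05 * math.pi,
    allowed: Optional[Set[int]] = None,
) -> float:
    """Scalar relaxation cost of ``edge`` leaving node ``edge.u``.

    Defaults to the orientation difference. If another edge from the same
    node has an orientation difference within ``eps_theta``, orientation
    cannot discriminate and the width difference is used for the tied set;
    if a width difference within the tied set also ties (``eps_wI``), the
    intensity difference decides.
    """
    siblings = [e for e in graph.edges_from(edge.u, allowed) if e is not edge]
    theta_tied = [
        e for e in siblings if abs(e.costs.c_theta - edge.costs.c_theta) <= eps_theta
    ]
    if not theta_tied:
        return edge.costs.c_theta
    width_tied = [
        e for e in theta_tied if abs(e.costs.c_w - edge.costs.c_w) <= eps_wI
    ]
    if not width_tied:
        return edge.costs.c_w
    return edge.costs.c_I


def dijkstra_tree(
    graph: SegmentGraph,
    seed: int,
    config: Optional[PipelineConfig] = None,
    allowed: Optional[Set[int]] = None,
) -> PathResult:
    """Single-source minimal-sum search with the hierarchical edge cost.

    ``allowed`` restricts the search to a subset of nodes (the seed is
    always included). For every reachable endpoint node the summed cost is
    normalized by the number of nodes on the path (seed and endpoint
    included); the endpoint minimizing this normalized cost is selected,
    with ties broken toward more nodes, then the lower node id. The seed is
    not its own candidate endpoint.
    """
    cfg = config or PipelineConfig()
    if seed not in graph:
        raise KeyError(f"seed node {seed} not in graph")
    if allowed is not None:
        allowed = set(allowed) | {seed}

    dist: Dict[int, float] = {seed: 0.0}
    previous: Dict[int, Optional[int]] = {seed: None}
    done: Set[int] = set()
    heap: List[Tuple[float, int]] = [(0.0, seed)]
    while heap:
        d, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        for e in graph.edges_from(u, allowed):
            w = hierarchical_cost(graph, e, cfg.eps_theta, cfg.eps_wI, allowed)
            nd = d + w
            if e.v not in dist or nd < dist[e.v]:
                dist[e.v] = nd
                previous[e.v] = u
                heapq.heappush(heap, (nd, e.v))

    davg: Dict[int, float] = {}
    node_count: Dict[int, int] = {}
    for e_node in sorted(graph.endpoint_nodes):
        if e_node == seed or e_node not in dist:
            continue
        n = len(_backtrack(previous, e_node))
        node_count[e_node] = n
        davg[e_node] = dist[e_node] / n

    best = None
    if davg:
        best = min(davg, key=lambda e: (davg[e], -node_count[e], e))
    return PathResult(
        seed=seed,
        dist=dist,
        previous=previous,
        davg=davg,
        node_count=node_count,
        best_endpoint=best,
    )


def _backtrack(previous: Dict[int, Optional[int]], node: int) -> List[int]:
    path = [node]
    while previous[path[-1]] is not None:
        path.append(previous[path[-1]])
    return path[::-1]


def extract_primary_path(pr: PathResult) -> List[int]:
    """Node list of the selected lowest-normalized-cost root-to-endpoint path.

    Falls back to the seed alone when no endpoint is reachable.
    """
    if pr.best_endpoint is None:
        return [pr.seed]
    return _backtrack(pr.previous, pr.best_endpoint)


# ---------------------------------------------------------------------------
# root selection and network mapping


def select_root(
    seg_map: VesselSegmentMap,
    candidates: Iterable[int],
    od_center: Optional[Tuple[float, float]],
    od_radius: Optional[float],
) -> Optional[int]:
    """Unassigned endpoint-bearing segment rooting the next tree.

    The chosen segment has a free endpoint nearest the optic-disc rim
    (minimal ``|distance(endpoint, od_center) - od_radius|``); without an
    OD configuration the lowest-id candidate is taken. Ties break toward
    the lower segment id. Returns None when no candidate has a free
    endpoint.
    """
    best: Optional[Tuple[float, int]] = None
    for sid in sorted(candidates):
        seg = seg_map.segments[sid]
        free_ends = [
            end for end in (seg.end_a, seg.end_b) if end.junction_id is None
        ]
        if not free_ends:
            continue
        if od_center is None or od_radius is None:
            return sid
        key = min(
            abs(math.hypot(t[0] - od_center[0], t[1] - od_center[1]) - od_radius)
            for t in (e.terminal for e in free_ends)
        )
        if best is None or key < best[0]:
            best = (key, sid)
    return None if best is None else best[1]


def map_branches(
    graph: SegmentGraph,
    seg_map: VesselSegmentMap,
    primary: List[int],
    assigned: Set[int],
    labeling: TreeLabeling,
    tree_id: int,
    config: PipelineConfig,
) -> None:
    """Claim branches and sub-branches of one tree, in place.

    From every branch junction (degree 3) touching an already-claimed
    segment, each unclaimed incident segment seeds a sub-search over the
    remaining unclaimed nodes; its primary path joins the tree one depth
    deeper, recursively. Crossing junctions (degree >= 4) are skipped: the
    tree keeps only the continuation the main search chose, leaving the
    transversal pair to another tree.
    """
    queue: List[Tuple[List[int], int]] = [(primary, 0)]
    while queue:
        path, depth = queue.pop(0)
        for sid in path:
            seg = seg_map.segments[sid]
            for end in (seg.end_a, seg.end_b):
                jid = end.junction_id
                if jid is None:
                    continue
                if seg_map.junctions[jid].degree >= 4:
                    continue
                for other in sorted(seg_map.incident_segments(jid)):
                    if other in assigned:
                        continue
                    unassigned = set(seg_map.segments) - assigned
                    pr = dijkstra_tree(graph, other, config, allowed=unassigned)
                    sub = extract_primary_path(pr)
                    for s in sub:
                        assigned.add(s)
                        labeling.assignment[s] = (tree_id, depth + 1)
                    queue.append((sub, depth + 1))


def map_network(
    seg_map: VesselSegmentMap,
    feats: Dict[EndKey, EndFeatures],
    config: Optional[PipelineConfig] = None,
    od_center: Optional[Tuple[float, float]] = None,
    od_radius: Optional[float] = None,
) -> TreeLabeling:
    """Separate the whole segment map into vessel trees.

    Repeatedly selects a root among unassigned segments, searches its
    primary path over the unassigned subgraph, maps its branches, and
    marks the tree's segments assigned. Segments left without any
    endpoint-bearing root candidate are labeled noise.
    """
    cfg = config or PipelineConfig()
    graph = build_graph(seg_map, feats)
    labeling = TreeLabeling(assignment={}, roots={}, primary_paths={}, noise=set())
    assigned: Set[int] = set()
    tree_id = 0
    while True:
        unassigned = set(seg_map.segments) - assigned
        root = select_root(seg_map, unassigned, od_center, od_radius)
        if root is None:
            break
        pr = dijkstra_tree(graph, root, cfg, allowed=unassigned)
        primary = extract_primary_path(pr)
        for s in primary:
            assigned.add(s)
            labeling.assignment[s] = (tree_id, 0)
        labeling.roots[tree_id] = root
        labeling.primary_paths[tree_id] = primary
        map_branches(graph, seg_map, primary, assigned, labeling, tree_id, cfg)
        tree_id += 1
    labeling.noise = set(seg_map.segments) - assigned
    return labeling


# ---------------------------------------------------------------------------
# exports


def tree_id_image(seg_map: VesselSegmentMap, labeling: TreeLabeling) -> np.ndarray:
    """Per-pixel tree id raster (tree ids offset by +1; 0 = background)."""
    out = np.zeros(seg_map.shape, dtype=np.int32)
    for sid, (tid, _) in labeling.assignment.items():
        px = seg_map.segment_mask_pixels(sid)
        out[px[:, 0], px[:, 1]] = tid + 1
    return out


def labeling_table(labeling: TreeLabeling):
    """Per-segment labeling as a pandas DataFrame (CSV-exportable)."""
    import pandas as pd

    rows = [
        dict(segment_id=sid, tree_id=tid, depth=depth,
             role="primary" if depth == 0 else "branch")
        for sid, (tid, depth) in sorted(labeling.assignment.items())
    ]
    rows += [
        dict(segment_id=sid, tree_id=-1, depth=-1, role="noise")
        for sid in sorted(labeling.noise)
    ]
    return pd.DataFrame(rows)


def forest_graph(seg_map: VesselSegmentMap, labeling: TreeLabeling):
    """The mapped forest as a networkx graph (GraphML/JSON-exportable)."""
    import networkx as nx

    g = nx.Graph()
    for sid, (tid, depth) in labeling.assignment.items():
        g.add_node(sid, tree_id=tid, depth=depth)
    from .topology import segment_adjacency

    for a, b, jid in segment_adjacency(seg_map):
        if labeling.tree_of(a) is not None and labeling.tree_of(a) == labeling.tree_of(b):
            g.add_edge(a, b, junction=jid)
    return g
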