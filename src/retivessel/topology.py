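"""Skeleton topology: landmarks and the vessel segment map.

The single-pixel skeleton is analyzed in 3x3 neighborhoods: pixels with one
neighbor are vessel endpoints, pixels with more than two neighbors belong to
junctions (branch points, degree 3, or crossing points, degree >= 4).
Removing junction pixels cuts the skeleton into junction-free runs; each run
becomes a :class:`VesselSegment`, the node of the later graph search.

Thinning renders a transversal crossing of two thick vessels as two nearby
bifurcations joined by a short skeleton run. Two consolidation stages make
the degree-4 crossing recoverable: junction pixels within a small chessboard
distance are merged into one junction cluster, and short runs joining two
clusters are absorbed into a single merged junction.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

Pixel = Tuple[int, int]

_S8 = np.ones((3, 3), dtype=int)  # 8-connectivity structuring element


# ---------------------------------------------------------------------------
# data types


@dataclasses.dataclass
class Junction:
    id: int
    pixels: frozenset
    degree: int = 0

    @property
    def kind(self) -> str:
        """'branch' for degree 3, 'crossing' for degree >= 4."""
        return "crossing" if self.degree >= 4 else "branch"

    @property
    def centroid(self) -> Tuple[float, float]:
        arr = np.array(sorted(self.pixels), dtype=float)
        return tuple(arr.mean(axis=0))


@dataclasses.dataclass
class LandmarkSet:
    endpoints: List[Pixel]
    junctions: Dict[int, Junction]

    @property
    def branch_points(self) -> List[Junction]:
        return [j for j in self.junctions.values() if j.kind == "branch"]

    @property
    def crossing_points(self) -> List[Junction]:
        return [j for j in self.junctions.values() if j.kind == "crossing"]


@dataclasses.dataclass
class EndRegion:
    """Up to ``end_region_len`` skeleton pixels at one end of a segment.

    ``pixels[0]`` is the terminal pixel; the list runs inward along the
    segment path. ``junction_id`` is None for a network endpoint.
    """

    pixels: List[Pixel]
    junction_id: Optional[int]

    @property
    def terminal(self) -> Pixel:
        return self.pixels[0]


@dataclasses.dataclass
class VesselSegment:
    id: int
    path: List[Pixel]
    end_a: EndRegion
    end_b: EndRegion

    def __len__(self) -> int:
        return len(self.path)

    def end(self, label: str) -> EndRegion:
        return self.end_a if label == "a" else self.end_b

    @property
    def is_endpoint_segment(self) -> bool:
        """True if at least one end is a free network endpoint."""
        return self.end_a.junction_id is None or self.end_b.junction_id is None


@dataclasses.dataclass
class VesselSegmentMap:
    segments: Dict[int, VesselSegment]
    junctions: Dict[int, Junction]
    # per junction: incident (segment_id, end_label) stubs
    incidence: Dict[int, List[Tuple[int, str]]]
    segment_id_image: np.ndarray
    shape: Tuple[int, int]

    def incident_segments(self, junction_id: int) -> List[int]:
        return [sid for sid, _ in self.incidence.get(junction_id, [])]

    def segment_mask_pixels(self, segment_id: int) -> np.ndarray:
        return np.argwhere(self.segment_id_image == segment_id)


# ---------------------------------------------------------------------------
# low-level helpers


def neighbor_counts(skel: np.ndarray) -> np.ndarray:
    """Number of 8-neighbors of each skeleton pixel (0 off the skeleton)."""
    s = np.asarray(skel, dtype=bool)
    counts = ndimage.convolve(s.astype(np.uint8), _S8, mode="constant") - s
    return np.where(s, counts, 0)


def prune_spurs(skel: np.ndarray, min_len: int = 3) -> np.ndarray:
    """Remove skeleton spurs shorter than ``min_len`` that end in an endpoint.

    Only twigs hanging off a junction are removed (thinning artifacts);
    isolated short runs with two free ends are kept. A final pass drops
    redundant bump pixels (>=3 neighbors that stay mutually connected
    without the pixel), which is what a spur reduces to when its base
    touches the line diagonally. Iterates until stable.
    """
    s = np.asarray(skel, dtype=bool).copy()
    if min_len <= 0:
        return s
    changed = True
    while changed:
        changed = False
        counts = neighbor_counts(s)
        junction_px = counts > 2
        for r, c in np.argwhere(counts == 1):
            path = [(int(r), int(c))]
            prev = None
            cur = (int(r), int(c))
            hit_junction = False
            while len(path) < min_len:
                nbrs = _neighbors_of(s, cur)
                nbrs = [p for p in nbrs if p != prev]
                if not nbrs:
                    break
                nxt = nbrs[0]
                if junction_px[nxt]:
                    hit_junction = True
                    break
                if len(nbrs) > 1:
                    break
                prev, cur = cur, nxt
                path.append(cur)
            if hit_junction and len(path) < min_len:
                for p in path:
                    s[p] = False
                changed = True
        counts = neighbor_counts(s)
        for r, c in np.argwhere(counts >= 3):
            p = (int(r), int(c))
            if _is_redundant_bump(s, p):
                s[p] = False
                changed = True
    return s


def _is_redundant_bump(s: np.ndarray, p: Pixel) -> bool:
    """True if ``p``'s neighbors stay mutually 8-connected without ``p``."""
    nbrs = _neighbors_of(s, p)
    if len(nbrs) < 3:
        return False
    remaining = set(nbrs)
    stack = [nbrs[0]]
    seen = {nbrs[0]}
    while stack:
        q = stack.pop()
        for o in remaining:
            if o not in seen and max(abs(q[0] - o[0]), abs(q[1] - o[1])) == 1:
                seen.add(o)
                stack.append(o)
    return seen == remaining


def _neighbors_of(s: np.ndarray, p: Pixel) -> List[Pixel]:
    r, c = p
    out = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < s.shape[0] and 0 <= cc < s.shape[1] and s[rr, cc]:
                out.append((rr, cc))
    return out


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _order_run(pixels: Sequence[Pixel]) -> List[Pixel]:
    """Order the pixels of a junction-free run into a simple path.

    Runs have at most two terminal pixels (<=1 in-run neighbor); a cycle
    (no terminal) is opened at its lexicographically smallest pixel.
    """
    pixset = set(pixels)
    if len(pixset) == 1:
        return list(pixset)
    adj: Dict[Pixel, List[Pixel]] = {}
    for p in pixset:
        r, c = p
        adj[p] = [
            (r + dr, c + dc)
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if (dr or dc) and (r + dr, c + dc) in pixset
        ]
    terminals = sorted(p for p, ns in adj.items() if len(ns) <= 1)
    start = terminals[0] if terminals else min(pixset)
    path = [start]
    seen = {start}
    cur = start
    while True:
        nxt = [p for p in adj[cur] if p not in seen]
        if not nxt:
            break
        # prefer 4-connected steps so diagonal shortcuts don't skip pixels
        nxt.sort(key=lambda p: (abs(p[0] - cur[0]) + abs(p[1] - cur[1]), p))
        cur = nxt[0]
        path.append(cur)
        seen.add(cur)
    return path


def _trace_runs(skel: np.ndarray, junction_mask: np.ndarray) -> List[List[Pixel]]:
    """Ordered junction-free runs of ``skel`` minus ``junction_mask``."""
    rest = np.asarray(skel, dtype=bool) & ~junction_mask
    labels, n = ndimage.label(rest, structure=_S8)
    runs = []
    for sl, lab in zip(ndimage.find_objects(labels), range(1, n + 1)):
        pix = np.argwhere(labels[sl] == lab)
        pix[:, 0] += sl[0].start
        pix[:, 1] += sl[1].start
        runs.append(_order_run([tuple(p) for p in pix]))
    return runs


def _touching_junction(
    p: Pixel, junction_of_pixel: Dict[Pixel, int]
) -> Optional[int]:
    """Junction id whose pixel set is 8-adjacent to ``p`` (lowest id wins)."""
    r, c = p
    hits = [
        junction_of_pixel[(r + dr, c + dc)]
        for dr in (-1, 0, 1)
        for dc in (-1, 0, 1)
        if (dr or dc) and (r + dr, c + dc) in junction_of_pixel
    ]
    return min(hits) if hits else None


# ---------------------------------------------------------------------------
# landmark detection


def detect_landmarks(
    skel: np.ndarray,
    merge_dist: int = 2,
    connector_max_len: int = 5,
) -> LandmarkSet:
    """Endpoints and consolidated junctions of a single-pixel skeleton.

    Junction pixels (>2 neighbors) within chessboard distance
    ``merge_dist`` are merged into one cluster; runs of length at most
    ``connector_max_len`` joining two clusters are absorbed, merging the
    clusters into a single junction. The degree of a junction is the number
    of incident run ends.
    """
    s = np.asarray(skel, dtype=bool)
    counts = neighbor_counts(s)
    endpoints = [tuple(p) for p in np.argwhere(counts == 1)]

    jpix = [tuple(p) for p in np.argwhere(counts > 2)]
    if not jpix:
        return LandmarkSet(endpoints=endpoints, junctions={})

    # stage 1: merge junction pixels within chessboard distance merge_dist
    uf = _UnionFind(len(jpix))
    tree = cKDTree(np.array(jpix, dtype=float))
    for i, j in tree.query_pairs(r=merge_dist, p=np.inf):
        uf.union(i, j)
    cluster_pixels: Dict[int, set] = {}
    for i, p in enumerate(jpix):
        cluster_pixels.setdefault(uf.find(i), set()).add(p)
    clusters: List[set] = [cluster_pixels[r] for r in sorted(cluster_pixels)]

    # stage 2: absorb short connector runs between clusters
    cuf = _UnionFind(len(clusters))
    jmask = np.zeros_like(s)
    jof: Dict[Pixel, int] = {}
    for k, pix in enumerate(clusters):
        for p in pix:
            jmask[p] = True
            jof[p] = k
    runs = _trace_runs(s, jmask)
    changed = True
    absorbed: set = set()
    while changed:
        changed = False
        for ridx, run in enumerate(runs):
            if ridx in absorbed or len(run) > connector_max_len:
                continue
            ja = _touching_junction(run[0], jof)
            jb = _touching_junction(run[-1], jof)
            if ja is None or jb is None:
                continue
            # absorb the run; merge its two junction clusters
            cuf.union(cuf.find(ja), cuf.find(jb))
            target = cuf.find(ja)
            absorbed.add(ridx)
            for p in run:
                jof[p] = target
            changed = True

    # final junction pixel sets
    final_pixels: Dict[int, set] = {}
    for p, k in jof.items():
        final_pixels.setdefault(cuf.find(k), set()).add(p)

    # degrees: incident run-ends of surviving runs. Clusters with degree <= 2
    # are not real junctions (corner artifacts of thinning, or leftovers of
    # spur pruning); their pixels are returned to the runs and degrees are
    # recomputed until stable.
    while True:
        jmask2 = np.zeros_like(s)
        jof2: Dict[Pixel, int] = {}
        for k, pix in final_pixels.items():
            for p in pix:
                jmask2[p] = True
                jof2[p] = k
        degree: Dict[int, int] = {k: 0 for k in final_pixels}
        for run in _trace_runs(s, jmask2):
            ends = [run[0]] if len(run) == 1 else [run[0], run[-1]]
            for e in ends:
                k = _touching_junction(e, jof2)
                if k is not None:
                    degree[k] += 1
        weak = [k for k, d in degree.items() if d <= 2]
        if not weak:
            break
        for k in weak:
            del final_pixels[k]

    junctions = {}
    for new_id, k in enumerate(sorted(final_pixels)):
        junctions[new_id] = Junction(
            id=new_id, pixels=frozenset(final_pixels[k]), degree=degree[k]
        )
    return LandmarkSet(endpoints=endpoints, junctions=junctions)


# ---------------------------------------------------------------------------
# segment map


def build_segment_map(
    skel: np.ndarray,
    lm: LandmarkSet,
    mask: np.ndarray,
    end_region_len: int = 15,
) -> VesselSegmentMap:
    """Cut the skeleton at ``lm``'s junctions into ordered vessel segments.

    Each junction-free run becomes a segment with two end regions (up to
    ``end_region_len`` pixels each; short segments use the whole path for
    both). Binary-mask pixels are assigned to the nearest segment skeleton
    pixel, giving ``segment_id_image``.
    """
    s = np.asarray(skel, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    jmask = np.zeros_like(s)
    jof: Dict[Pixel, int] = {}
    for j in lm.junctions.values():
        for p in j.pixels:
            jmask[p] = True
            jof[p] = j.id

    segments: Dict[int, VesselSegment] = {}
    incidence: Dict[int, List[Tuple[int, str]]] = {j: [] for j in lm.junctions}
    for sid, run in enumerate(_trace_runs(s, jmask), start=1):
        ja = _touching_junction(run[0], jof)
        jb = _touching_junction(run[-1], jof) if len(run) > 1 else None
        end_a = EndRegion(pixels=run[:end_region_len], junction_id=ja)
        end_b = EndRegion(pixels=run[::-1][:end_region_len], junction_id=jb)
        seg = VesselSegment(id=sid, path=run, end_a=end_a, end_b=end_b)
        segments[sid] = seg
        if ja is not None:
            incidence.setdefault(ja, []).append((sid, "a"))
        if jb is not None:
            incidence.setdefault(jb, []).append((sid, "b"))

    # keep junction degrees consistent with the incidence actually built
    junctions = {
        j.id: Junction(id=j.id, pixels=j.pixels, degree=len(incidence.get(j.id, [])))
        for j in lm.junctions.values()
    }

    seg_image = np.zeros(s.shape, dtype=np.int32)
    if segments:
        all_px = []
        all_ids = []
        for sid, seg in segments.items():
            all_px.extend(seg.path)
            all_ids.extend([sid] * len(seg.path))
        tree = cKDTree(np.array(all_px, dtype=float))
        mask_px = np.argwhere(mask)
        if mask_px.size:
            _, idx = tree.query(mask_px.astype(float), k=1)
            ids = np.asarray(all_ids)[idx]
            seg_image[mask_px[:, 0], mask_px[:, 1]] = ids

    return VesselSegmentMap(
        segments=segments,
        junctions=junctions,
        incidence=incidence,
        segment_id_image=seg_image,
        shape=s.shape,
    )


def segment_adjacency(seg_map: VesselSegmentMap) -> List[Tuple[int, int, int]]:
    """Unordered distinct-segment pairs sharing a junction.

    Emitted once per shared junction as ``(segment_a, segment_b, junction)``
    with ``segment_a < segment_b``.
    """
    out = []
    for jid in sorted(seg_map.incidence):
        sids = sorted({sid for sid, _ in seg_map.incidence[jid]})
        for i in range(len(sids)):
            for k in range(i + 1, len(sids)):
                out.append((sids[i], sids[k], jid))
    return out


def adjacency_components(seg_map: VesselSegmentMap) -> List[set]:
    """Connected components of the segment adjacency graph (sets of ids)."""
    parent = {sid: sid for sid in seg_map.segments}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, _ in segment_adjacency(seg_map):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    comps: Dict[int, set] = {}
    for sid in seg_map.segments:
        comps.setdefault(find(sid), set()).add(sid)
    return [comps[k] for k in sorted(comps)]
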