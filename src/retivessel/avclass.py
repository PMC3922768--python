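"""Artery-vein classification of mapped vessel trees.

Trees sharing a crossing junction are anatomically of different kinds: at a
crossing one vessel is an artery and the other a vein. Tree pairs are
formed from the crossings found during structural mapping. For every
comparison, centerline pixels of the wide segments of the compared trees
(width above 60% of the tree maximum, excluding thin peripheral segments)
are described by 4 color features — mean and standard deviation of the
green channel and of the hue channel over each pixel's 3x3 neighborhood —
and clustered into two fuzzy classes with fuzzy C-means. Pixels with nearly
equal membership in both clusters (difference below a 0.2 margin) are
rejected as noise; the cluster with the higher mean green intensity is the
arterial one, since arteries appear brighter than veins. Within a pair the
tree with the higher arterial-pixel proportion becomes the artery. Unpaired
trees are grouped by spatial nearness, compared pairwise within each group,
and hard-labeled by the median of their per-pairing soft labels.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .config import PipelineConfig
from .features import EndKey, EndFeatures, segment_width
from .topology import LandmarkSet, VesselSegmentMap
from .treesearch import TreeLabeling

logger = logging.getLogger(__name__)

ARTERY = "artery"
VEIN = "vein"
UNKNOWN = "unknown"


@dataclasses.dataclass
class FuzzyClusterResult:
    centroids: np.ndarray        # (2, d) in the clustered (standardized) space
    raw_centroids: np.ndarray    # (2, d) membership-weighted means of raw features
    membership: np.ndarray       # (n, 2); rows sum to 1
    objective_history: List[float]
    n_iter: int


@dataclasses.dataclass
class TreePairing:
    pairs: List[Tuple[int, int, int]]      # (tree_a, tree_b, junction_id)
    unpaired: List[int]
    groups: List[List[int]]                # partition of unpaired trees

    @property
    def paired_trees(self) -> Set[int]:
        return {t for a, b, _ in self.pairs for t in (a, b)}


@dataclasses.dataclass
class AVLabelMap:
    tree_labels: Dict[int, str]            # tree id -> artery | vein | unknown
    label_image: np.ndarray                # 0 bg, 1 artery, 2 vein, 3 unknown
    noise_pixels: Set[Tuple[int, int]]     # centerline pixels rejected by the margin
    report: Dict


# ---------------------------------------------------------------------------
# pairing and centerline features


def pair_trees(
    labeling: TreeLabeling, seg_map: VesselSegmentMap
) -> Tuple[List[Tuple[int, int, int]], List[int]]:
    """Tree pairs sharing a crossing junction, plus the unpaired tree ids.

    A crossing whose incident segments belong to exactly two trees yields
    one pair; repeated crossings of the same two trees are deduplicated
    (multiplicity logged) and crossings touching more than two trees are
    skipped.
    """
    pairs: List[Tuple[int, int, int]] = []
    seen: Set[Tuple[int, int]] = set()
    for jid, junction in sorted(seg_map.junctions.items()):
        if junction.degree < 4:
            continue
        trees = sorted(
            {
                t
                for sid in seg_map.incident_segments(jid)
                if (t := labeling.tree_of(sid)) is not None
            }
        )
        if len(trees) != 2:
            if len(trees) > 2:
                logger.info("crossing %d touches %d trees; skipped", jid, len(trees))
            continue
        key = (trees[0], trees[1])
        if key in seen:
            logger.info("repeated crossing of trees %s deduplicated", key)
            continue
        seen.add(key)
        pairs.append((trees[0], trees[1], jid))
    paired = {t for a, b, _ in pairs for t in (a, b)}
    unpaired = sorted(set(labeling.roots) - paired)
    return pairs, unpaired


def extract_centerline_pixels(
    tree_id: int,
    labeling: TreeLabeling,
    seg_map: VesselSegmentMap,
    feats: Dict[EndKey, EndFeatures],
    width_fraction: float = 0.6,
) -> List[Tuple[int, int]]:
    """Skeleton pixels of the tree's significantly wide segments.

    Keeps segments strictly wider than ``width_fraction`` times the tree's
    maximum segment width, suppressing thin peripheral or single-pixel
    segments whose colors are unreliable.
    """
    sids = labeling.segments_of(tree_id)
    if not sids:
        return []
    widths = {sid: segment_width(seg_map, feats, sid) for sid in sids}
    w_max = max(widths.values())
    keep = [sid for sid in sids if widths[sid] > width_fraction * w_max]
    pixels: List[Tuple[int, int]] = []
    for sid in keep:
        pixels.extend(seg_map.segments[sid].path)
    return pixels


def compute_features(
    pixels: Sequence[Tuple[int, int]], green: np.ndarray, hue: np.ndarray
) -> np.ndarray:
    """(n, 4) feature matrix [mu_g, sigma_g, mu_h, sigma_h] per pixel.

    Statistics are taken over the 3x3 neighborhood, clipped at image
    borders; sigma is the population standard deviation.
    """
    g = np.asarray(green, dtype=float)
    h = np.asarray(hue, dtype=float)
    out = np.empty((len(pixels), 4), dtype=float)
    H, W = g.shape
    for i, (r, c) in enumerate(pixels):
        r0, r1 = max(r - 1, 0), min(r + 2, H)
        c0, c1 = max(c - 1, 0), min(c + 2, W)
        wg = g[r0:r1, c0:c1]
        wh = h[r0:r1, c0:c1]
        out[i] = (wg.mean(), wg.std(), wh.mean(), wh.std())
    return out


# ---------------------------------------------------------------------------
# fuzzy C-means


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def fuzzy_cmeans(
    X: np.ndarray,
    c: int = 2,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    standardize: bool = True,
) -> FuzzyClusterResult:
    """Fuzzy C-means clustering with deterministic farthest-pair init.

    Memberships follow the standard fixed point
    ``u_ik = 1 / sum_j (d_ik / d_jk)^(2/(m-1))`` with Euclidean distances,
    centroids are ``u^m``-weighted means, and iteration stops when the
    maximum membership change falls below ``tol``. The objective
    ``sum u^m d^2`` is non-increasing. Initial centroids are the two data
    points farthest apart in feature space, so the result needs no seed.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) < c:
        raise ValueError(f"need at least {c} feature vectors")
    if m <= 1:
        raise ValueError("fuzzifier m must exceed 1")
    Xw = _standardize(X) if standardize else X
    if not np.any(Xw.std(axis=0) > 0):
        raise ValueError("degenerate input: all feature vectors identical")

    # deterministic init: the two points farthest apart
    if len(Xw) > 2048:
        # subsample deterministically for the O(n^2) farthest-pair scan
        idx = np.linspace(0, len(Xw) - 1, 2048).astype(int)
        cand = Xw[idx]
    else:
        cand = Xw
    d2 = ((cand[:, None, :] - cand[None, :, :]) ** 2).sum(-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    centroids = np.stack([cand[i], cand[j]])
    if c != 2:
        raise ValueError("this implementation clusters into exactly 2 classes")

    exponent = 2.0 / (m - 1.0)
    U = None
    history: List[float] = []
    for it in range(1, max_iter + 1):
        d = np.linalg.norm(Xw[:, None, :] - centroids[None, :, :], axis=2)
        d = np.maximum(d, 1e-12)
        ratio = (d[:, :, None] / d[:, None, :]) ** exponent
        U_new = 1.0 / ratio.sum(axis=2)
        history.append(float((U_new**m * d**2).sum()))
        if U is not None and np.abs(U_new - U).max() < tol:
            U = U_new
            break
        U = U_new
        Um = U**m
        centroids = (Um.T @ Xw) / Um.sum(axis=0)[:, None]

    Um = U**m
    raw_centroids = (Um.T @ X) / Um.sum(axis=0)[:, None]
    return FuzzyClusterResult(
        centroids=centroids,
        raw_centroids=raw_centroids,
        membership=U,
        objective_history=history,
        n_iter=len(history),
    )


def assign_pixels(result: FuzzyClusterResult, margin: float = 0.2) -> np.ndarray:
    """Per-pixel hard class (0 or 1), or -1 for margin-rejected noise.

    A pixel whose two membership degrees differ by more than ``margin``
    joins the higher-degree cluster; pixels with nearly equal affinity to
    both clusters are treated as noise and removed from further analysis.
    """
    U = result.membership
    diff = np.abs(U[:, 0] - U[:, 1])
    cls = np.argmax(U, axis=1)
    return np.where(diff > margin, cls, -1)


def label_clusters(result: FuzzyClusterResult) -> Optional[int]:
    """Index of the arterial cluster: the one with higher mean green (mu_g).

    Returns None on an exact tie (undecidable).
    """
    mu_g = result.raw_centroids[:, 0]
    if mu_g[0] == mu_g[1]:
        return None
    return int(np.argmax(mu_g))


def classify_pair(
    classes_a: np.ndarray, classes_b: np.ndarray, arterial_cluster: int
) -> Tuple[str, str]:
    """Opposite labels for two crossing trees from their pixel classes.

    The tree with the higher proportion of arterial-class centerline pixels
    is the artery. Requires at least one classified pixel per tree;
    returns (unknown, unknown) on an exact proportion tie.
    """
    pa = _arterial_proportion(classes_a, arterial_cluster)
    pb = _arterial_proportion(classes_b, arterial_cluster)
    if pa is None or pb is None or pa == pb:
        return UNKNOWN, UNKNOWN
    return (ARTERY, VEIN) if pa > pb else (VEIN, ARTERY)


def _arterial_proportion(classes: np.ndarray, arterial_cluster: int) -> Optional[float]:
    valid = classes >= 0
    if not valid.any():
        return None
    return float((classes[valid] == arterial_cluster).mean())


# ---------------------------------------------------------------------------
# grouping of unpaired trees


def group_unpaired(
    centroids: Dict[int, Tuple[float, float]], threshold_px: float
) -> List[List[int]]:
    """Single-linkage grouping of unpaired-tree centroid pixels.

    Two trees share a group when their centers of mass are within
    ``threshold_px``; singleton groups are merged into the spatially
    nearest group.
    """
    if threshold_px <= 0:
        raise ValueError("grouping threshold must be positive")
    ids = sorted(centroids)
    parent = {t: t for t in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if np.hypot(
                centroids[a][0] - centroids[b][0], centroids[a][1] - centroids[b][1]
            ) < threshold_px:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    groups: Dict[int, List[int]] = {}
    for t in ids:
        groups.setdefault(find(t), []).append(t)
    glist = [sorted(g) for g in groups.values()]
    glist.sort()

    # merge singletons into the nearest non-singleton (or nearest other) group
    merged = True
    while merged and len(glist) > 1:
        merged = False
        for gi, g in enumerate(glist):
            if len(g) > 1:
                continue
            t = g[0]
            best = None
            for gj, other in enumerate(glist):
                if gi == gj:
                    continue
                dmin = min(
                    np.hypot(
                        centroids[t][0] - centroids[o][0],
                        centroids[t][1] - centroids[o][1],
                    )
                    for o in other
                )
                if best is None or dmin < best[0]:
                    best = (dmin, gj)
            glist[best[1]] = sorted(glist[best[1]] + [t])
            del glist[gi]
            merged = True
            break
    return glist


def _median_soft_label(soft: List[int], arterial_prop: Optional[float]) -> str:
    """Hard label from soft labels (artery=1, vein=0) by their median.

    A median of exactly 0.5 falls back to the tree's own arterial-pixel
    proportion.
    """
    med = float(np.median(soft))
    if med > 0.5:
        return ARTERY
    if med < 0.5:
        return VEIN
    if arterial_prop is None:
        return UNKNOWN
    return ARTERY if arterial_prop > 0.5 else VEIN


# ---------------------------------------------------------------------------
# full classification


def classify_trees(
    labeling: TreeLabeling,
    seg_map: VesselSegmentMap,
    feats: Dict[EndKey, EndFeatures],
    green: np.ndarray,
    hue: np.ndarray,
    config: Optional[PipelineConfig] = None,
) -> Tuple[AVLabelMap, TreePairing]:
    """Label every mapped tree artery or vein.

    Crossing pairs are 2-colored so paired trees always receive opposite
    labels (the coloring's orientation comes from the pooled per-pair
    arterial proportions); unpaired trees are grouped by nearness and
    labeled by median soft-label voting over all in-group pairings. A lone
    unpaired tree with no possible partner is classified against the pooled
    pixels of every tree.
    """
    cfg = config or PipelineConfig()
    pairs, unpaired = pair_trees(labeling, seg_map)

    tree_pixels: Dict[int, List[Tuple[int, int]]] = {}
    tree_features: Dict[int, np.ndarray] = {}
    for tid in labeling.tree_ids:
        px = extract_centerline_pixels(tid, labeling, seg_map, feats, cfg.width_fraction)
        tree_pixels[tid] = px
        tree_features[tid] = compute_features(px, green, hue) if px else np.empty((0, 4))

    labels: Dict[int, str] = {}
    noise_pixels: Set[Tuple[int, int]] = set()
    report: Dict = {"pairs": pairs, "groups": [], "votes": {}, "fallbacks": []}

    def run_pairing(ta: int, tb: int):
        """FCM over the pooled pixels of two trees -> per-tree arterial proportions."""
        na, nb = len(tree_features[ta]), len(tree_features[tb])
        if na + nb < 2 or na == 0 or nb == 0:
            return None
        X = np.vstack([tree_features[ta], tree_features[tb]])
        try:
            res = fuzzy_cmeans(X, m=cfg.fuzzifier, tol=cfg.fcm_tol, max_iter=cfg.fcm_max_iter)
        except ValueError:
            return None
        cls = assign_pixels(res, cfg.membership_margin)
        art = label_clusters(res)
        if art is None:
            return None
        pxs = tree_pixels[ta] + tree_pixels[tb]
        for p, k in zip(pxs, cls):
            if k < 0:
                noise_pixels.add(p)
        pa = _arterial_proportion(cls[:na], art)
        pb = _arterial_proportion(cls[na:], art)
        return pa, pb

    # --- paired trees: 2-color each connected component of the pairing graph
    adj: Dict[int, Set[int]] = {}
    for a, b, _ in pairs:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    prop_sum: Dict[int, float] = {t: 0.0 for t in adj}
    prop_n: Dict[int, int] = {t: 0 for t in adj}
    for a, b, _ in pairs:
        r = run_pairing(a, b)
        if r is None:
            continue
        pa, pb = r
        if pa is not None:
            prop_sum[a] += pa
            prop_n[a] += 1
        if pb is not None:
            prop_sum[b] += pb
            prop_n[b] += 1

    visited: Set[int] = set()
    for start in sorted(adj):
        if start in visited:
            continue
        color = {start: 0}
        order = [start]
        queue = [start]
        bipartite = True
        while queue:
            u = queue.pop(0)
            for v in sorted(adj[u]):
                if v not in color:
                    color[v] = 1 - color[u]
                    order.append(v)
                    queue.append(v)
                elif color[v] == color[u]:
                    bipartite = False
        visited |= set(color)
        if not bipartite:
            logger.warning("non-bipartite crossing component at tree %d; per-tree fallback", start)
            report["fallbacks"].append({"component": sorted(color), "reason": "odd cycle"})
            for t in order:
                p = prop_sum[t] / prop_n[t] if prop_n[t] else None
                labels[t] = UNKNOWN if p is None else (ARTERY if p > 0.5 else VEIN)
            continue
        side = {0: [t for t in order if color[t] == 0], 1: [t for t in order if color[t] == 1]}
        score = {
            k: (np.mean([prop_sum[t] / prop_n[t] for t in side[k] if prop_n[t]])
                if any(prop_n[t] for t in side[k]) else np.nan)
            for k in (0, 1)
        }
        if np.isnan(score[0]) or np.isnan(score[1]) or score[0] == score[1]:
            art_side = 0  # undecidable by color; arbitrary but deterministic
            logger.warning("pair component %s undecidable by color; defaulting", sorted(color))
        else:
            art_side = 0 if score[0] > score[1] else 1
        for t in side[art_side]:
            labels[t] = ARTERY
        for t in side[1 - art_side]:
            labels[t] = VEIN

    # --- unpaired trees: spatial groups, pairwise comparisons, median voting
    centroids = {
        t: tuple(np.mean(tree_pixels[t], axis=0)) for t in unpaired if tree_pixels[t]
    }
    threshold = cfg.grouping_threshold_frac * seg_map.shape[1]
    groups = group_unpaired(centroids, threshold) if centroids else []
    report["groups"] = groups
    for group in groups:
        if len(group) == 1:
            t = group[0]
            labels[t] = _classify_against_pool(
                t, tree_features, tree_pixels, noise_pixels, cfg
            )
            report["fallbacks"].append({"tree": t, "reason": "lone unpaired tree"})
            continue
        soft: Dict[int, List[int]] = {t: [] for t in group}
        props: Dict[int, List[float]] = {t: [] for t in group}
        for i, a in enumerate(group):
            for b in group[i + 1 :]:
                r = run_pairing(a, b)
                if r is None:
                    continue
                pa, pb = r
                if pa is None or pb is None or pa == pb:
                    continue
                soft[a].append(1 if pa > pb else 0)
                soft[b].append(1 if pb > pa else 0)
                props[a].append(pa)
                props[b].append(pb)
        for t in group:
            if soft[t]:
                mean_prop = float(np.mean(props[t])) if props[t] else None
                labels[t] = _median_soft_label(soft[t], mean_prop)
            else:
                labels[t] = UNKNOWN
        report["votes"].update({t: soft[t] for t in group})

    for tid in labeling.tree_ids:
        labels.setdefault(tid, UNKNOWN)

    label_image = np.zeros(seg_map.shape, dtype=np.uint8)
    code = {ARTERY: 1, VEIN: 2, UNKNOWN: 3}
    for sid, (tid, _) in labeling.assignment.items():
        px = seg_map.segment_mask_pixels(sid)
        label_image[px[:, 0], px[:, 1]] = code[labels[tid]]

    pairing = TreePairing(pairs=pairs, unpaired=unpaired, groups=groups)
    av = AVLabelMap(
        tree_labels=labels,
        label_image=label_image,
        noise_pixels=noise_pixels,
        report=report,
    )
    return av, pairing


def _classify_against_pool(
    tree_id: int,
    tree_features: Dict[int, np.ndarray],
    tree_pixels: Dict[int, List[Tuple[int, int]]],
    noise_pixels: Set[Tuple[int, int]],
    cfg: PipelineConfig,
) -> str:
    """Label a lone unpaired tree against the pooled pixels of all trees."""
    own = tree_features[tree_id]
    others = [f for t, f in tree_features.items() if t != tree_id and len(f)]
    if not len(own) or not others:
        return UNKNOWN
    X = np.vstack([own] + others)
    try:
        res = fuzzy_cmeans(X, m=cfg.fuzzifier, tol=cfg.fcm_tol, max_iter=cfg.fcm_max_iter)
    except ValueError:
        return UNKNOWN
    cls = assign_pixels(res, cfg.membership_margin)
    art = label_clusters(res)
    if art is None:
        return UNKNOWN
    p = _arterial_proportion(cls[: len(own)], art)
    if p is None:
        return UNKNOWN
    return ARTERY if p > 0.5 else VEIN
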