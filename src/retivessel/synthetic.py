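"""Seeded synthetic vascular scenes with ground truth.

Scenes emulate the structural assumptions the mapping relies on: vessel
trees radiate from the optic-disc rim as smooth polylines (bounded per-step
turn), widths taper gradually from root to tip, branches leave at moderate
angles, and each artery-vein pair crosses transversally (steep incidence so
thinning yields a recoverable degree-4 junction). Colors follow fundus
physiology: arteries carry a higher green-channel intensity than veins
(oxygenated blood absorbs less in the green band) over a brighter
background, with Gaussian pixel noise and an optional illumination
gradient. Every scene is a deterministic function of its seed and carries
per-pixel tree-id, artery/vein and role ground truth plus the true
landmark list.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import imageio.v3 as iio
import numpy as np
from scipy import ndimage


@dataclasses.dataclass
class SceneSpec:
    """Study conditions of one synthetic scene."""

    shape: Tuple[int, int] = (256, 256)
    od_center: Tuple[float, float] = (128.0, 128.0)
    od_radius: Optional[float] = None          # default: 0.12 x image height
    n_arteries: int = 2
    n_veins: int = 2
    n_crossing_pairs: int = 1
    branches_per_tree: int = 1
    branch_angle: Tuple[float, float] = (0.35, 0.65)   # radians off the parent
    branch_at: Tuple[float, float] = (0.30, 0.78)      # fraction along parent
    max_turn: float = 0.08                     # radians per 1.5-px step
    step: float = 1.5
    artery_root_width: float = 5.0
    vein_root_width: float = 6.0
    tip_width: float = 2.0
    crossing_angle: Tuple[float, float] = (0.96, 1.40)  # 55-80 deg incidence
    bg_rgb: Tuple[float, float, float] = (190.0, 110.0, 60.0)
    vein_rgb: Tuple[float, float, float] = (130.0, 55.0, 50.0)
    artery_green_offset: float = 15.0          # 3 x noise_sd by default
    noise_sd: float = 5.0
    blur_sigma: float = 0.7
    illumination_gradient: float = 0.0         # relative ramp across columns
    seed: int = 0
    max_retries: int = 10

    @property
    def artery_rgb(self) -> Tuple[float, float, float]:
        r, g, b = self.vein_rgb
        return (r + 35.0, g + self.artery_green_offset, b + 2.0)

    def resolved_od_radius(self) -> float:
        return self.od_radius if self.od_radius is not None else 0.12 * self.shape[0]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        kwargs = dict(d)
        for f in dataclasses.fields(cls):
            if f.name in kwargs and isinstance(kwargs[f.name], list):
                kwargs[f.name] = tuple(kwargs[f.name])
        return cls(**kwargs)


@dataclasses.dataclass
class TreeTruth:
    tree_id: int
    av: str                                    # 'artery' | 'vein'
    centerline: np.ndarray                     # (n, 2) float (row, col)
    widths: np.ndarray                         # per centerline sample
    branches: List[Tuple[np.ndarray, np.ndarray]]  # (centerline, widths)
    root: Tuple[float, float]


@dataclasses.dataclass
class GroundTruth:
    tree_id_image: np.ndarray                  # 0 = background, ids offset +1
    av_image: np.ndarray                       # 0 bg, 1 artery, 2 vein
    role_image: np.ndarray                     # 0 bg, 1 primary, 2 branch
    tree_masks: Dict[int, np.ndarray]
    av_labels: Dict[int, str]
    endpoints: List[Tuple[float, float]]
    branch_points: List[Tuple[float, float]]
    crossings: List[Tuple[Tuple[float, float], int, int]]  # (point, tree_a, tree_b)


@dataclasses.dataclass
class Scene:
    spec: SceneSpec
    rgb: np.ndarray
    mask: np.ndarray
    gt: GroundTruth


# ---------------------------------------------------------------------------
# path construction (row/col coordinates; headings in radians, row-major)


def _unit(theta: float) -> np.ndarray:
    return np.array([math.sin(theta), math.cos(theta)])  # (drow, dcol)


def _heading(vec: np.ndarray) -> float:
    return math.atan2(vec[0], vec[1])


def _wrap(a: float) -> float:
    return (a + math.pi) % (2 * math.pi) - math.pi


def _grow_random(
    start: np.ndarray,
    heading: float,
    n_steps: int,
    spec: SceneSpec,
    rng: np.random.Generator,
    shape: Tuple[int, int],
    margin: float = 8.0,
) -> np.ndarray:
    """Smooth random polyline: per-step turn ~ N(0, 0.3*max_turn), clipped."""
    pts = [start.copy()]
    h = heading
    pos = start.copy()
    for _ in range(n_steps):
        turn = float(np.clip(rng.normal(0.0, 0.3 * spec.max_turn), -spec.max_turn, spec.max_turn))
        h += turn
        pos = pos + spec.step * _unit(h)
        if not (margin <= pos[0] < shape[0] - margin and margin <= pos[1] < shape[1] - margin):
            break
        pts.append(pos.copy())
    return np.array(pts)


def _walk_to_rim(
    start: np.ndarray,
    heading: float,
    spec: SceneSpec,
    center: np.ndarray,
    od_radius: float,
) -> Optional[np.ndarray]:
    """Turn-limited walk from ``start`` until it reaches the OD rim.

    Steers gently toward the OD center (half the turn limit per step), so
    the path stays smooth; returns None if the rim is not reached inside
    the image.
    """
    pts = [start.copy()]
    pos = start.copy()
    h = heading
    H, W = spec.shape
    for _ in range(500):
        bearing = _heading(center - pos)
        h += float(np.clip(_wrap(bearing - h), -0.5 * spec.max_turn, 0.5 * spec.max_turn))
        pos = pos + spec.step * _unit(h)
        if not (2 <= pos[0] < H - 2 and 2 <= pos[1] < W - 2):
            return None
        pts.append(pos.copy())
        if np.linalg.norm(pos - center) <= od_radius + 1.5:
            return np.array(pts)
    return None


def _taper(n: int, w_root: float, w_tip: float) -> np.ndarray:
    return np.linspace(w_root, w_tip, max(n, 2))[:n]


def _clear_of(
    path: np.ndarray,
    others: List[np.ndarray],
    clearance: float,
    exclusions: Optional[List[Tuple[np.ndarray, float]]] = None,
) -> bool:
    """True when ``path`` keeps ``clearance`` pixels from every other polyline.

    Points inside an exclusion zone (center, radius) — e.g. around an
    intended crossing or a branch spawn point — are ignored on both sides.
    """
    exclusions = exclusions or []

    def keep(pts: np.ndarray) -> np.ndarray:
        ok = np.ones(len(pts), dtype=bool)
        for c, r in exclusions:
            ok &= np.linalg.norm(pts - c, axis=1) > r
        return pts[ok]

    mine = keep(path)
    if not len(mine):
        return True
    for other in others:
        theirs = keep(other)
        if not len(theirs):
            continue
        d2 = ((mine[:, None, :] - theirs[None, :, :]) ** 2).sum(-1)
        if d2.min() < clearance**2:
            return False
    return True


def _stamp(mask: np.ndarray, centerline: np.ndarray, widths: np.ndarray) -> None:
    """Stroke a polyline with per-sample widths into ``mask`` (in place)."""
    H, W = mask.shape
    # subdivide for a smooth stroke
    for i in range(len(centerline)):
        pts = [centerline[i]]
        ws = [widths[i]]
        if i + 1 < len(centerline):
            pts.append(0.5 * (centerline[i] + centerline[i + 1]))
            ws.append(0.5 * (widths[i] + widths[i + 1]))
        for p, w in zip(pts, ws):
            rad = max(w / 2.0, 0.3)
            # the nearest pixel is always marked so thin strokes stay connected
            pr, pc = int(round(p[0])), int(round(p[1]))
            if 0 <= pr < H and 0 <= pc < W:
                mask[pr, pc] = True
            r0 = max(int(math.floor(p[0] - rad)), 0)
            r1 = min(int(math.ceil(p[0] + rad)) + 1, H)
            c0 = max(int(math.floor(p[1] - rad)), 0)
            c1 = min(int(math.ceil(p[1] + rad)) + 1, W)
            if r0 >= r1 or c0 >= c1:
                continue
            rr, cc = np.mgrid[r0:r1, c0:c1]
            mask[r0:r1, c0:c1] |= (rr - p[0]) ** 2 + (cc - p[1]) ** 2 <= rad**2


def _local_tangent(path: np.ndarray, idx: int) -> np.ndarray:
    lo, hi = max(idx - 2, 0), min(idx + 3, len(path))
    vec = path[hi - 1] - path[lo]
    return vec / np.linalg.norm(vec)


# ---------------------------------------------------------------------------
# scene generation


def generate_scene(spec: SceneSpec) -> Scene:
    """Render one synthetic scene; deterministic in ``spec.seed``."""
    if spec.n_crossing_pairs > min(spec.n_arteries, spec.n_veins):
        raise ValueError("n_crossing_pairs exceeds available arteries/veins")
    rng = np.random.default_rng(spec.seed)
    H, W = spec.shape
    center = np.array(spec.od_center, dtype=float)
    od_r = spec.resolved_od_radius()

    n_pairs = spec.n_crossing_pairs
    n_ua = spec.n_arteries - n_pairs
    n_uv = spec.n_veins - n_pairs
    n_sectors = n_pairs + n_ua + n_uv
    if n_sectors == 0:
        raise ValueError("scene must contain at least one tree")
    sector_half = math.pi / n_sectors
    base = rng.uniform(0.0, 2 * math.pi)

    trees: List[TreeTruth] = []
    crossings: List[Tuple[Tuple[float, float], int, int]] = []
    tree_id = 0
    reach = min(H, W) / 2.0 - 10.0
    main_steps = int((reach - od_r) / spec.step) + 8

    def rim_point(angle: float) -> Tuple[np.ndarray, float]:
        p = center + (od_r + 1.0) * _unit(angle)
        return p, angle  # outward radial heading equals the rim angle

    placed: List[np.ndarray] = []
    clearance = 7.0

    sector = 0
    for _ in range(n_pairs):
        ac = base + 2 * math.pi * sector / n_sectors
        for attempt in range(spec.max_retries):
            a_start, a_head = rim_point(ac - 0.35 * sector_half)
            artery = _grow_random(a_start, a_head, main_steps, spec, rng, spec.shape)
            if len(artery) < 20 or not _clear_of(artery, placed, clearance):
                continue
            # crossing waypoint on the artery, clear of the OD
            lo, hi = int(0.45 * len(artery)), int(0.65 * len(artery))
            cand = [
                i for i in range(lo, hi)
                if np.linalg.norm(artery[i] - center) > od_r + 18.0
            ]
            if not cand:
                continue
            widx = cand[rng.integers(len(cand))]
            Wpt = artery[widx]
            tau = _local_tangent(artery, widx)
            psi = rng.uniform(*spec.crossing_angle) * (1 if rng.random() < 0.5 else -1)
            th = _heading(tau) + psi
            d = _unit(th)
            if np.dot(d, Wpt - center) < 0:
                d = -d  # vein continues outward after the crossing
            # grow the vein backward from the crossing to the OD rim (so the
            # crossing point and incidence angle hold exactly), then forward
            # past the crossing with a smooth random tail
            back = _walk_to_rim(Wpt, _heading(-d), spec, center, od_r)
            if back is None or len(back) < 12:
                continue
            root_angle = _heading(back[-1] - center)
            if abs(_wrap(root_angle - ac)) > 0.95 * sector_half:
                continue  # root escaped the pair's sector
            fwd = _grow_random(Wpt.copy(), _heading(d), int(main_steps * 0.5),
                               spec, rng, spec.shape)
            if len(fwd) < 10:
                continue
            vein = np.vstack([back[::-1], fwd[1:]])
            # the pair must touch only inside the crossing zone, and stay
            # clear of every previously placed tree
            if not _clear_of(vein, [artery], clearance, exclusions=[(Wpt, 14.0)]):
                continue
            if not _clear_of(vein, placed, clearance):
                continue
            a_tree = _finish_tree(tree_id, "artery", artery, spec.artery_root_width,
                                  spec, rng, avoid=[tuple(Wpt)], others=placed + [vein])
            v_tree = _finish_tree(
                tree_id + 1, "vein", vein, spec.vein_root_width, spec, rng,
                avoid=[tuple(Wpt)],
                others=placed + [artery] + [b for b, _ in a_tree.branches],
            )
            trees += [a_tree, v_tree]
            crossings.append(((float(Wpt[0]), float(Wpt[1])), tree_id, tree_id + 1))
            placed += [artery, vein]
            placed += [b for b, _ in a_tree.branches + v_tree.branches]
            tree_id += 2
            break
        else:
            raise RuntimeError("could not realize the crossing policy")
        sector += 1

    for av, count, w_root in (("artery", n_ua, spec.artery_root_width),
                              ("vein", n_uv, spec.vein_root_width)):
        for _ in range(count):
            ac = base + 2 * math.pi * sector / n_sectors
            for attempt in range(spec.max_retries):
                start, head = rim_point(ac + rng.uniform(-0.2, 0.2) * sector_half)
                path = _grow_random(start, head, main_steps, spec, rng, spec.shape)
                if len(path) < 20 or not _clear_of(path, placed, clearance):
                    continue
                tree = _finish_tree(tree_id, av, path, w_root, spec, rng,
                                    avoid=[], others=placed)
                trees.append(tree)
                placed += [path] + [b for b, _ in tree.branches]
                tree_id += 1
                break
            else:
                raise RuntimeError("could not grow an unpaired tree")
            sector += 1

    return _render(spec, trees, crossings)


def _finish_tree(
    tree_id: int,
    av: str,
    path: np.ndarray,
    w_root: float,
    spec: SceneSpec,
    rng: np.random.Generator,
    avoid: List[Tuple[float, float]],
    others: Optional[List[np.ndarray]] = None,
) -> TreeTruth:
    """Attach tapering widths and branches to a primary centerline.

    Branches spawn away from ``avoid`` points (intended crossings) and must
    keep clear of every polyline in ``others`` so no unintended contacts
    arise.
    """
    others = others or []
    widths = _taper(len(path), w_root, spec.tip_width)
    branches: List[Tuple[np.ndarray, np.ndarray]] = []
    for _ in range(spec.branches_per_tree):
        for attempt in range(spec.max_retries):
            t = rng.uniform(*spec.branch_at)
            idx = int(t * len(path))
            if idx < 5 or idx > len(path) - 8:
                continue
            p = path[idx]
            if any(np.hypot(p[0] - a[0], p[1] - a[1]) < 22.0 for a in avoid):
                continue
            tau = _local_tangent(path, idx)
            ang = rng.uniform(*spec.branch_angle) * (1 if rng.random() < 0.5 else -1)
            h = _heading(tau) + ang
            n_steps = max(int(0.5 * (len(path) - idx)), 10)
            br = _grow_random(p.copy(), h, n_steps, spec, rng, spec.shape, margin=6.0)
            if len(br) < 8:
                continue
            if not _clear_of(br, others + [b for b, _ in branches], 7.0):
                continue
            w0 = 0.7 * widths[idx]
            branches.append((br, _taper(len(br), w0, max(1.6, 0.6 * w0))))
            break
    return TreeTruth(
        tree_id=tree_id,
        av=av,
        centerline=path,
        widths=widths,
        branches=branches,
        root=(float(path[0][0]), float(path[0][1])),
    )


def _render(
    spec: SceneSpec,
    trees: List[TreeTruth],
    crossings: List[Tuple[Tuple[float, float], int, int]],
) -> Scene:
    H, W = spec.shape
    tree_masks: Dict[int, np.ndarray] = {}
    role_masks: Dict[int, np.ndarray] = {}
    for t in trees:
        m = np.zeros((H, W), dtype=bool)
        _stamp(m, t.centerline, t.widths)
        primary = m.copy()
        for br, bw in t.branches:
            _stamp(m, br, bw)
        tree_masks[t.tree_id] = m
        role_masks[t.tree_id] = primary

    # draw veins first so arteries lie on top at crossings
    order = sorted(trees, key=lambda t: (t.av != "vein", t.tree_id))
    tree_id_image = np.zeros((H, W), dtype=np.int32)
    av_image = np.zeros((H, W), dtype=np.uint8)
    role_image = np.zeros((H, W), dtype=np.uint8)
    rgb = np.empty((H, W, 3), dtype=float)
    rgb[:] = spec.bg_rgb
    for t in order:
        m = tree_masks[t.tree_id]
        tree_id_image[m] = t.tree_id + 1
        av_image[m] = 1 if t.av == "artery" else 2
        role_image[m] = 2
        role_image[role_masks[t.tree_id]] = 1
        color = spec.artery_rgb if t.av == "artery" else spec.vein_rgb
        rgb[m] = color

    if spec.blur_sigma > 0:
        for ch in range(3):
            rgb[:, :, ch] = ndimage.gaussian_filter(rgb[:, :, ch], spec.blur_sigma)
    if spec.illumination_gradient:
        ramp = 1.0 + spec.illumination_gradient * (
            np.linspace(-0.5, 0.5, W)[None, :]
        )
        rgb *= ramp[:, :, None]
    rng = np.random.default_rng(spec.seed + 1_000_003)
    rgb += rng.normal(0.0, spec.noise_sd, size=rgb.shape)
    rgb = np.clip(rgb, 0, 255).astype(np.uint8)

    mask = np.zeros((H, W), dtype=bool)
    for m in tree_masks.values():
        mask |= m

    endpoints: List[Tuple[float, float]] = []
    branch_points: List[Tuple[float, float]] = []
    for t in trees:
        endpoints.append(t.root)
        endpoints.append((float(t.centerline[-1][0]), float(t.centerline[-1][1])))
        for br, _ in t.branches:
            branch_points.append((float(br[0][0]), float(br[0][1])))
            endpoints.append((float(br[-1][0]), float(br[-1][1])))

    gt = GroundTruth(
        tree_id_image=tree_id_image,
        av_image=av_image,
        role_image=role_image,
        tree_masks=tree_masks,
        av_labels={t.tree_id: t.av for t in trees},
        endpoints=endpoints,
        branch_points=branch_points,
        crossings=crossings,
    )
    return Scene(spec=spec, rgb=rgb, mask=mask, gt=gt)


# ---------------------------------------------------------------------------
# degradation and fixtures


def degrade_mask(
    mask: np.ndarray,
    jitter_rate: float = 0.0,
    gap_rate: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Stress a clean mask: boundary jitter and random gap pixels, seeded.

    Boundary foreground pixels flip off with probability ``jitter_rate``;
    every foreground pixel drops with probability ``gap_rate`` (expected
    gap count = rate x foreground count). Zero rates return the mask
    unchanged.
    """
    out = np.asarray(mask, dtype=bool).copy()
    if jitter_rate <= 0 and gap_rate <= 0:
        return out
    rng = np.random.default_rng(seed)
    if jitter_rate > 0:
        boundary = out & ~ndimage.binary_erosion(out)
        flips = rng.random(out.shape) < jitter_rate
        out[boundary & flips] = False
    if gap_rate > 0:
        drops = rng.random(out.shape) < gap_rate
        out[out & drops] = False
    return out


def scene_to_fixtures(scene: Scene, outdir: str | Path) -> Dict[str, Path]:
    """Write the scene as PNG rasters plus a JSON spec; lossless round-trip."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": outdir / "image.png",
        "mask": outdir / "mask.png",
        "gt_tree_id": outdir / "gt_tree_id.png",
        "gt_av": outdir / "gt_av.png",
        "gt_role": outdir / "gt_role.png",
        "spec": outdir / "spec.json",
    }
    iio.imwrite(paths["image"], scene.rgb)
    iio.imwrite(paths["mask"], scene.mask.astype(np.uint8) * 255)
    iio.imwrite(paths["gt_tree_id"], scene.gt.tree_id_image.astype(np.uint16))
    iio.imwrite(paths["gt_av"], scene.gt.av_image)
    iio.imwrite(paths["gt_role"], scene.gt.role_image)
    paths["spec"].write_text(json.dumps(scene.spec.to_dict(), indent=2))
    return paths


def load_fixtures(outdir: str | Path) -> Tuple[np.ndarray, np.ndarray, np.ndarray, SceneSpec]:
    """Read back (rgb, mask, gt_tree_id, spec) written by scene_to_fixtures."""
    outdir = Path(outdir)
    rgb = iio.imread(outdir / "image.png")
    mask = iio.imread(outdir / "mask.png") > 0
    tid = iio.imread(outdir / "gt_tree_id.png").astype(np.int32)
    spec = SceneSpec.from_dict(json.loads((outdir / "spec.json").read_text()))
    return rgb, mask, tid, spec
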