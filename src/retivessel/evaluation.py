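"""Accuracy metrics against a reference labeling.

Two views of misclassification: a segment-level rate binned by vessel width
(small/medium/major vessels carry different diagnostic weight) and a
pixel-level rate over all vessel pixels, optionally split into paired
(crossing-constrained) and unpaired trees. Tree identities between a
predicted and a reference structural mapping are matched by maximal pixel
overlap (Hungarian assignment) before structural errors are counted; AV
labels are absolute and need no matching.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment

from .treesearch import TreeLabeling
from .topology import VesselSegmentMap

WIDTH_BINS = (
    ("1<=w<4", 1.0, 4.0, "left"),
    ("4<=w<=6", 4.0, 6.0, "both"),
    ("6<w<=9", 6.0, 9.0, "right"),
    ("w>9", 9.0, float("inf"), "open"),
)


@dataclasses.dataclass
class WidthBinRow:
    label: str
    n_segments: int
    n_misclassified: int

    @property
    def rate(self) -> Optional[float]:
        if self.n_segments == 0:
            return None
        return 100.0 * self.n_misclassified / self.n_segments


@dataclasses.dataclass
class WidthBinReport:
    bins: List[WidthBinRow]
    overall_above4: Optional[float]  # R_seg (%) for widths > 4 px


@dataclasses.dataclass
class PixelReport:
    rate: float                       # R_pix (%) for this image
    n_vessel_pixels: int
    n_misclassified: int
    paired_rate: Optional[float] = None
    unpaired_rate: Optional[float] = None


def _bin_index(w: float) -> Optional[int]:
    if 1.0 <= w < 4.0:
        return 0
    if 4.0 <= w <= 6.0:
        return 1
    if 6.0 < w <= 9.0:
        return 2
    if w > 9.0:
        return 3
    return None


def segment_metric(
    pred: Dict[int, str], ref: Dict[int, str], widths: Dict[int, float]
) -> WidthBinReport:
    """Width-binned segment misclassification rates (percent).

    ``pred`` and ``ref`` map the same segment ids to labels; a segment is
    misclassified when the labels differ. ``widths`` carries each segment's
    representative (median) width in pixels.
    """
    if set(pred) != set(ref):
        raise ValueError("prediction and reference cover different segments")
    rows = [WidthBinRow(label=lab, n_segments=0, n_misclassified=0)
            for lab, *_ in WIDTH_BINS]
    above4_n = above4_bad = 0
    for sid, plabel in pred.items():
        w = widths[sid]
        b = _bin_index(w)
        if b is None:
            continue
        bad = plabel != ref[sid]
        rows[b].n_segments += 1
        rows[b].n_misclassified += bad
        if w > 4.0:
            above4_n += 1
            above4_bad += bad
    overall = 100.0 * above4_bad / above4_n if above4_n else None
    return WidthBinReport(bins=rows, overall_above4=overall)


def pixel_metric(
    pred_image: np.ndarray,
    ref_image: np.ndarray,
    mask: np.ndarray,
    paired_mask: Optional[np.ndarray] = None,
) -> PixelReport:
    """Pixel misclassification rate R_pix (%) over the vessel mask.

    ``pred_image`` / ``ref_image`` hold integer labels per pixel; only
    pixels under ``mask`` count. ``paired_mask`` (pixels of trees with an
    AV crossing) splits the rate into paired/unpaired parts.
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty vessel mask")
    wrong = (np.asarray(pred_image) != np.asarray(ref_image)) & mask
    rep = PixelReport(
        rate=100.0 * int(wrong.sum()) / n,
        n_vessel_pixels=n,
        n_misclassified=int(wrong.sum()),
    )
    if paired_mask is not None:
        paired_mask = np.asarray(paired_mask, dtype=bool) & mask
        unpaired_mask = mask & ~paired_mask
        if paired_mask.any():
            rep.paired_rate = 100.0 * int((wrong & paired_mask).sum()) / int(paired_mask.sum())
        if unpaired_mask.any():
            rep.unpaired_rate = 100.0 * int((wrong & unpaired_mask).sum()) / int(unpaired_mask.sum())
    return rep


def match_trees(
    pred_image: np.ndarray, ref_image: np.ndarray
) -> Dict[int, int]:
    """Maximal-overlap assignment of predicted tree ids to reference ids.

    Both rasters use 0 for background. Returns predicted id -> reference id
    for the Hungarian matching maximizing total pixel overlap; predicted
    trees without a partner are absent from the mapping.
    """
    pred_ids = sorted(set(np.unique(pred_image)) - {0})
    ref_ids = sorted(set(np.unique(ref_image)) - {0})
    if not pred_ids or not ref_ids:
        return {}
    overlap = np.zeros((len(pred_ids), len(ref_ids)), dtype=float)
    for i, p in enumerate(pred_ids):
        pm = pred_image == p
        for j, r in enumerate(ref_ids):
            overlap[i, j] = np.count_nonzero(pm & (ref_image == r))
    rows, cols = linear_sum_assignment(-overlap)
    return {
        pred_ids[i]: ref_ids[j]
        for i, j in zip(rows, cols)
        if overlap[i, j] > 0
    }


def structural_segment_accuracy(
    seg_map: VesselSegmentMap,
    labeling: TreeLabeling,
    gt_tree_id_image: np.ndarray,
) -> Tuple[float, int, int]:
    """Fraction of segments assigned their ground-truth tree after matching.

    Each segment's ground-truth tree is the majority ground-truth id over
    its skeleton pixels; noise segments count as errors. Returns
    (accuracy, n_correct, n_segments).
    """
    from .treesearch import tree_id_image as _pred_image

    pred_img = _pred_image(seg_map, labeling)
    mapping = match_trees(pred_img, gt_tree_id_image)

    n_total = len(seg_map.segments)
    n_correct = 0
    for sid, seg in seg_map.segments.items():
        gts = [gt_tree_id_image[p] for p in seg.path if gt_tree_id_image[p] != 0]
        if not gts:
            n_total -= 1  # segment outside the ground-truth drawing; ignore
            continue
        gt_id = int(np.bincount(gts).argmax())
        tid = labeling.tree_of(sid)
        if tid is None:
            continue
        if mapping.get(tid + 1) == gt_id:
            n_correct += 1
    acc = n_correct / n_total if n_total else float("nan")
    return acc, n_correct, n_total


def av_tree_accuracy(
    labeling: TreeLabeling,
    tree_labels: Dict[int, str],
    seg_map: VesselSegmentMap,
    gt_av_image: np.ndarray,
) -> Tuple[float, Dict[int, bool]]:
    """Fraction of predicted trees whose AV label matches the ground truth.

    A predicted tree's true class is the majority ground-truth AV value
    over its skeleton pixels (1 = artery, 2 = vein). Returns
    (accuracy, per-tree correctness).
    """
    correct: Dict[int, bool] = {}
    for tid in labeling.tree_ids:
        vals = []
        for sid in labeling.segments_of(tid):
            vals.extend(
                gt_av_image[p] for p in seg_map.segments[sid].path if gt_av_image[p] != 0
            )
        if not vals:
            continue
        truth = "artery" if np.bincount(vals).argmax() == 1 else "vein"
        correct[tid] = tree_labels.get(tid) == truth
    acc = float(np.mean(list(correct.values()))) if correct else float("nan")
    return acc, correct
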