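"""End-to-end pipeline: segmentation image -> mapped, AV-labeled trees."""

from __future__ import annotations

import dataclasses
import logging
import time
from typing import Dict, Optional

import numpy as np

from . import avclass, features, preprocess, topology, treesearch
from .config import PipelineConfig

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineResult:
    config: PipelineConfig
    mask: np.ndarray
    skeleton: np.ndarray
    landmarks: topology.LandmarkSet
    segment_map: topology.VesselSegmentMap
    end_features: Dict
    labeling: treesearch.TreeLabeling
    tree_image: np.ndarray
    pairing: avclass.TreePairing
    av: avclass.AVLabelMap
    timings: Dict[str, float]

    @property
    def report(self) -> dict:
        return {
            "n_segments": len(self.segment_map.segments),
            "n_junctions": len(self.segment_map.junctions),
            "n_endpoints": len(self.landmarks.endpoints),
            "n_trees": len(self.labeling.roots),
            "n_noise_segments": len(self.labeling.noise),
            "pairs": [list(p) for p in self.pairing.pairs],
            "unpaired": list(self.pairing.unpaired),
            "groups": [list(g) for g in self.pairing.groups],
            "tree_labels": {int(k): v for k, v in self.av.tree_labels.items()},
            "n_noise_pixels": len(self.av.noise_pixels),
            "timings_s": {k: round(v, 3) for k, v in self.timings.items()},
            "config": self.config.to_dict(),
        }


def run_pipeline(
    rgb: np.ndarray,
    segmentation: np.ndarray,
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Run preprocessing, topology, feature measurement, tree search and
    AV classification on one image.

    ``segmentation`` is either a vessel probability image in [0, 1]
    (thresholded by Otsu's method) or an already binary mask (at most two
    distinct values; Otsu is skipped). The optic-disc circle from the
    config is removed from the mask and used for root selection.
    """
    cfg = config or PipelineConfig()
    timings: Dict[str, float] = {}

    t0 = time.perf_counter()
    green, hue = preprocess.extract_channels(rgb)
    seg = np.asarray(segmentation)
    if preprocess.is_binary(seg):
        logger.info("binary segmentation input; skipping Otsu thresholding")
        mask = seg > (seg.max() / 2.0 if seg.max() > 1 else 0)
    else:
        mask = preprocess.binarize_otsu(seg)
    od_radius = cfg.resolved_od_radius(rgb.shape[0])
    if cfg.od_center is not None:
        mask = preprocess.apply_od_mask(mask, cfg.od_center, od_radius)
    skel = preprocess.skeletonize(mask)
    skel = topology.prune_spurs(skel, cfg.spur_min_len)
    timings["preprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    lm = topology.detect_landmarks(skel, cfg.junction_merge_dist, cfg.connector_max_len)
    seg_map = topology.build_segment_map(skel, lm, mask, cfg.end_region_len)
    timings["topology"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    feats = features.compute_normalized_features(seg_map, mask, green)
    timings["features"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    labeling = treesearch.map_network(
        seg_map, feats, cfg, od_center=cfg.od_center, od_radius=od_radius
    )
    tree_image = treesearch.tree_id_image(seg_map, labeling)
    timings["treesearch"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    av, pairing = avclass.classify_trees(labeling, seg_map, feats, green, hue, cfg)
    timings["avclass"] = time.perf_counter() - t0

    return PipelineResult(
        config=cfg,
        mask=mask,
        skeleton=skel,
        landmarks=lm,
        segment_map=seg_map,
        end_features=feats,
        labeling=labeling,
        tree_image=tree_image,
        pairing=pairing,
        av=av,
        timings=timings,
    )
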