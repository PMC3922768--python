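"""Pipeline configuration.

Every threshold used anywhere in the pipeline lives here so that a run is
fully described by (inputs, config). Values can be loaded from a YAML or
JSON mapping; unknown keys raise.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Optional, Tuple

import yaml


@dataclasses.dataclass
class PipelineConfig:
    """All tunable parameters of the vessel mapping / AV classification pipeline.

    Attributes
    ----------
    od_center : (row, col) of the optic-disc mask center, in pixels.
        ``None`` disables OD masking and OD-based root selection.
    od_radius : optic-disc mask radius in pixels. If ``None``, derived as
        ``od_radius_frac`` times the image height.
    od_radius_frac : fallback fractional radius (of image height).
    spur_min_len : skeleton spurs shorter than this (pixels, ending in an
        endpoint) are pruned as thinning artifacts before landmark detection.
    junction_merge_dist : chessboard distance within which junction pixels
        are merged into one junction cluster.
    connector_max_len : skeleton runs no longer than this joining two
        junction clusters are absorbed into a single merged junction
        (recovers degree-4 crossings that thinning splits into two
        bifurcations).
    end_region_len : number of skeleton pixels in a segment end region.
    eps_theta : tolerance (radians) under which two orientation-difference
        costs count as equal in the hierarchical cost rule.
    eps_wI : tolerance under which two width-difference costs count as
        equal (same scale as the costs, i.e. radians after scale matching).
    width_fraction : centerline pixels are taken only from segments wider
        than this fraction of the tree's maximum width.
    membership_margin : minimum fuzzy-membership difference for a centerline
        pixel to be assigned to a cluster (smaller -> noise, removed).
    fuzzifier : fuzzy C-means exponent m.
    fcm_tol : convergence tolerance on the maximum membership change.
    fcm_max_iter : iteration cap for fuzzy C-means.
    grouping_threshold_frac : unpaired-tree grouping distance threshold as a
        fraction of image width.
    """

    od_center: Optional[Tuple[float, float]] = None
    od_radius: Optional[float] = None
    od_radius_frac: float = 0.12
    spur_min_len: int = 3
    junction_merge_dist: int = 2
    connector_max_len: int = 5
    end_region_len: int = 15
    eps_theta: float = 0.05
    eps_wI: float = 0.05 * math.pi
    width_fraction: float = 0.6
    membership_margin: float = 0.2
    fuzzifier: float = 2.0
    fcm_tol: float = 1e-5
    fcm_max_iter: int = 300
    grouping_threshold_frac: float = 0.25

    def resolved_od_radius(self, image_height: int) -> Optional[float]:
        if self.od_center is None:
            return None
        if self.od_radius is not None:
            return float(self.od_radius)
        return self.od_radius_frac * image_height

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - fields
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(mapping)
        if kwargs.get("od_center") is not None:
            kwargs["od_center"] = tuple(float(v) for v in kwargs["od_center"])
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_mapping(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["od_center"] is not None:
            d["od_center"] = list(d["od_center"])
        return d
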