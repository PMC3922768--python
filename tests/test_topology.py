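"""Skeleton topology: landmarks, segment map, adjacency, invariants."""

import numpy as np
import pytest

from retivessel import topology
from retivessel.topology import (
    build_segment_map,
    detect_landmarks,
    prune_spurs,
    segment_adjacency,
)


def _full_map(skel, end_region_len=15):
    lm = detect_landmarks(skel)
    return lm, build_segment_map(skel, lm, skel, end_region_len)


class TestLandmarks:
    def test_line(self, skeleton_line):
        lm = detect_landmarks(skeleton_line)
        assert len(lm.endpoints) == 2
        assert len(lm.junctions) == 0

    def test_y_branch(self, skeleton_y):
        lm = detect_landmarks(skeleton_y)
        assert len(lm.endpoints) == 3
        assert [(j.degree, j.kind) for j in lm.junctions.values()] == [(3, "branch")]

    def test_plus_crossing(self, skeleton_plus):
        lm = detect_landmarks(skeleton_plus)
        assert len(lm.endpoints) == 4
        assert [(j.degree, j.kind) for j in lm.junctions.values()] == [(4, "crossing")]

    def test_double_bifurcation_consolidates_to_crossing(
        self, skeleton_double_bifurcation
    ):
        """Two nearby bifurcations joined by a short run = one crossing."""
        lm = detect_landmarks(skeleton_double_bifurcation)
        assert len(lm.endpoints) == 4
        assert [(j.degree, j.kind) for j in lm.junctions.values()] == [(4, "crossing")]

    def test_empty_skeleton(self):
        lm = detect_landmarks(np.zeros((5, 5), bool))
        assert lm.endpoints == [] and lm.junctions == {}


class TestSpurPruning:
    def test_short_spur_removed(self, skeleton_line):
        skel = skeleton_line.copy()
        skel[4, 6] = True  # 1-pixel twig off the line
        out = prune_spurs(skel, min_len=3)
        assert (out == skeleton_line).all()

    def test_two_pixel_spur_removed(self, skeleton_line):
        skel = skeleton_line.copy()
        skel[4, 6] = True
        skel[3, 6] = True
        out = prune_spurs(skel, min_len=3)
        assert (out == skeleton_line).all()

    def test_long_branch_kept(self, skeleton_y):
        assert (prune_spurs(skeleton_y, min_len=3) == skeleton_y).all()

    def test_isolated_short_run_kept(self):
        s = np.zeros((5, 5), bool)
        s[2, 1:3] = True
        assert (prune_spurs(s, min_len=3) == s).all()


class TestSegmentMap:
    def test_plus_four_segments_one_junction(self, skeleton_plus):
        _, sm = _full_map(skeleton_plus)
        assert len(sm.segments) == 4
        jids = {
            e.junction_id
            for seg in sm.segments.values()
            for e in (seg.end_a, seg.end_b)
            if e.junction_id is not None
        }
        assert len(jids) == 1

    def test_y_three_segments(self, skeleton_y):
        _, sm = _full_map(skeleton_y)
        assert len(sm.segments) == 3

    def test_line_single_segment_free_ends(self, skeleton_line):
        _, sm = _full_map(skeleton_line)
        (seg,) = sm.segments.values()
        assert seg.end_a.junction_id is None and seg.end_b.junction_id is None
        assert len(seg.path) == int(skeleton_line.sum())

    def test_partition_invariant(self, skeleton_plus, skeleton_y,
                                 skeleton_double_bifurcation):
        """Every skeleton pixel is in exactly one segment or one junction."""
        for skel in (skeleton_plus, skeleton_y, skeleton_double_bifurcation):
            lm, sm = _full_map(skel)
            seg_px = [p for s in sm.segments.values() for p in s.path]
            jcn_px = [p for j in sm.junctions.values() for p in j.pixels]
            assert len(seg_px) == len(set(seg_px))
            assert not set(seg_px) & set(jcn_px)
            assert len(seg_px) + len(jcn_px) == int(skel.sum())

    def test_paths_are_simple(self, skeleton_plus, skeleton_double_bifurcation):
        """Internal path pixels have exactly 2 within-segment neighbors."""
        for skel in (skeleton_plus, skeleton_double_bifurcation):
            _, sm = _full_map(skel)
            for seg in sm.segments.values():
                for prev, cur in zip(seg.path[:-1], seg.path[1:]):
                    assert max(abs(prev[0] - cur[0]), abs(prev[1] - cur[1])) == 1

    def test_short_segment_end_regions_cover_whole_path(self, skeleton_y):
        _, sm = _full_map(skeleton_y)
        for seg in sm.segments.values():
            if len(seg.path) <= 15:
                assert set(seg.end_a.pixels) == set(seg.path)
                assert set(seg.end_b.pixels) == set(seg.path)

    def test_end_region_is_path_prefix(self):
        skel = np.zeros((5, 40), bool)
        skel[2, 2:38] = True
        _, sm = _full_map(skel)
        (seg,) = sm.segments.values()
        assert len(seg.end_a.pixels) == 15
        assert seg.end_a.pixels == seg.path[:15]
        assert seg.end_b.pixels == seg.path[::-1][:15]

    def test_mask_pixels_assigned_to_nearest_segment(self, skeleton_line):
        mask = np.zeros_like(skeleton_line)
        mask[4:7, 2:12] = True  # 3-wide bar around the line
        lm = detect_landmarks(skeleton_line)
        sm = build_segment_map(skeleton_line, lm, mask)
        assert (sm.segment_id_image[mask] == 1).all()
        assert (sm.segment_id_image[~mask] == 0).all()


class TestAdjacency:
    def test_degree3_yields_three_pairs(self, skeleton_y):
        _, sm = _full_map(skeleton_y)
        assert len(segment_adjacency(sm)) == 3

    def test_degree4_yields_six_pairs(self, skeleton_plus):
        _, sm = _full_map(skeleton_plus)
        assert len(segment_adjacency(sm)) == 6

    def test_two_junction_chain(self):
        # A--j1--B--j2--C plus stubs so both junctions have degree 3
        px = (
            [(8, c) for c in range(0, 20)]
            + [(r, 5) for r in range(3, 8)]
            + [(r, 14) for r in range(9, 14)]
        )
        skel = np.zeros((16, 22), bool)
        for p in px:
            skel[p] = True
        lm, sm = _full_map(skel)
        pairs = segment_adjacency(sm)
        assert len(lm.junctions) == 2
        assert len(pairs) == 6  # C(3,2) per junction
        per_junction = {}
        for a, b, j in pairs:
            per_junction.setdefault(j, []).append((a, b))
        assert sorted(len(v) for v in per_junction.values()) == [3, 3]

    def test_components(self, skeleton_plus):
        _, sm = _full_map(skeleton_plus)
        comps = topology.adjacency_components(sm)
        assert len(comps) == 1 and comps[0] == set(sm.segments)
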