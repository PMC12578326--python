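"""Branch extraction: junctions, path splitting, geometry measurements."""

import numpy as np
import pytest

from parallign import (
    BranchSegment,
    FixtureSpec,
    PlantedGroup,
    branch_length,
    branch_orientation,
    filter_by_length,
    find_junctions,
    map_length_slider,
    min_distance,
    render_fixture,
    run_single,
    segment_image,
    split_into_branches,
)
from parallign.branches import chord_orientation


def _brute_classify(sk):
    """Independent 8-neighbor counting oracle."""
    ends, juncs = set(), set()
    H, W = sk.shape
    for r, c in zip(*np.nonzero(sk)):
        n = sum(
            sk[r + dr, c + dc]
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if (dr, dc) != (0, 0) and 0 <= r + dr < H and 0 <= c + dc < W
        )
        if n == 1:
            ends.add((r, c))
        elif n >= 3:
            juncs.add((r, c))
    return ends, juncs


def _cross():
    sk = np.zeros((15, 15), bool)
    sk[7, 2:13] = True
    sk[2:13, 7] = True
    return sk


class TestJunctions:
    def test_straight_path(self):
        sk = np.zeros((5, 14), bool)
        sk[2, 2:12] = True
        jm = find_junctions(sk)
        assert len(jm.endpoint_pixels) == 2 and len(jm.junction_pixels) == 0

    def test_cross_matches_bruteforce(self):
        sk = _cross()
        jm = find_junctions(sk)
        ends, juncs = _brute_classify(sk)
        assert set(jm.endpoint_pixels) == ends and len(ends) == 4
        assert set(jm.junction_pixels) == juncs
        assert (7, 7) in juncs  # the crossing pixel is always a junction

    def test_empty_skeleton(self):
        jm = find_junctions(np.zeros((8, 8), bool))
        assert not jm.endpoint_pixels and not jm.junction_pixels


class TestSplit:
    def test_cross_splits_into_four_equal_arms(self):
        segs = split_into_branches(_cross())
        assert len(segs) == 4
        sizes = {len(s.path) for s in segs}
        assert len(sizes) == 1  # all arms identical by symmetry

    def test_single_path_is_one_segment(self):
        sk = np.zeros((5, 20), bool)
        sk[2, 3:17] = True
        segs = split_into_branches(sk)
        assert len(segs) == 1 and len(segs[0].path) == 14
        # ordered traversal: consecutive pixels are 8-neighbors
        arr = np.asarray(segs[0].path)
        assert np.all(np.abs(np.diff(arr, axis=0)).max(axis=1) == 1)

    def test_t_shape_gives_three_segments(self):
        sk = np.zeros((25, 25), bool)
        sk[10, 0:21] = True
        sk[11:21, 10] = True
        assert len(split_into_branches(sk)) == 3

    def test_partition_conservation(self, standard_fixture):
        img, _ = standard_fixture
        _, _, sk = segment_image(img)
        segs = split_into_branches(sk)
        jm = find_junctions(sk)
        assert sum(len(s.path) for s in segs) + len(jm.junction_pixels) == int(sk.sum())


class TestLengthSlider:
    @pytest.mark.parametrize("s,expected", [(None, 50), (1, 5), (4, 70), (10, 200)])
    def test_map(self, s, expected):
        assert map_length_slider(s) == expected

    @pytest.mark.parametrize("s", [0, 11])
    def test_bounds(self, s):
        with pytest.raises(ValueError):
            map_length_slider(s)


def _hline(n, row=0, start=0):
    return BranchSegment(0, [(row, start + i) for i in range(n)])


class TestFilterByLength:
    def test_boundary_inclusive(self):
        branches = [_hline(L + 1) for L in (5, 49, 50, 200)]
        kept = filter_by_length(branches, 50)
        assert [round(branch_length(b)) for b in kept] == [50, 200]

    def test_min_zero_keeps_all_and_idempotent(self):
        branches = [_hline(5), _hline(80)]
        assert filter_by_length(branches, 0) == branches
        once = filter_by_length(branches, 50)
        assert filter_by_length(once, 50) == once


class TestGeometry:
    def test_axial_and_diagonal_lengths(self):
        assert branch_length(_hline(11)) == pytest.approx(10.0)
        diag = BranchSegment(0, [(i, i) for i in range(11)])
        assert branch_length(diag) == pytest.approx(10 * np.sqrt(2))

    def test_arc_length_within_5pct(self):
        # one gently curved branch: arc sweep 40 deg, arc length 120 px
        spec = FixtureSpec(
            seed=11,
            planted_groups=(PlantedGroup(2, 30.0, spacing_px=40.0),),
            n_distractors=0,
            curvature_sweep_deg=40.0,
        )
        img, truth = render_fixture(spec)
        res = run_single(img)
        assert res.record.n_branches == 2
        for b in res.branches:
            assert branch_length(b) == pytest.approx(120.0, rel=0.05)

    def test_orientation_cardinal_cases(self):
        assert branch_orientation(_hline(20)) == pytest.approx(0.0)
        diag = BranchSegment(0, [(10 - i, i) for i in range(11)])  # up-right
        assert branch_orientation(diag) == pytest.approx(45.0)
        vert = BranchSegment(0, [(i, 4) for i in range(12)])
        assert branch_orientation(vert) == pytest.approx(90.0)

    def test_orientation_of_rendered_30deg_line(self):
        spec = FixtureSpec(
            seed=5,
            planted_groups=(PlantedGroup(2, 30.0, length_px=80.0, spacing_px=40.0),),
            n_distractors=0,
        )
        img, _ = render_fixture(spec)
        res = run_single(img)
        for b in res.branches:
            assert abs(branch_orientation(b) - 30.0) <= 2.0

    def test_chord_estimator_agrees_on_straight_line(self):
        diag = BranchSegment(0, [(10 - i, i) for i in range(11)])
        assert chord_orientation(diag) == pytest.approx(45.0)

    def test_single_pixel_orientation_error(self):
        with pytest.raises(ValueError):
            branch_orientation(BranchSegment(0, [(3, 3)]))

    def test_rotation_consistency_under_rot90(self, standard_fixture):
        from parallign import RawImage, circular_angle_distance

        img, _ = standard_fixture
        res = run_single(img)
        rot = run_single(RawImage(np.rot90(img.pixels).copy()))
        originals = [b.angle_deg for b in res.branches]
        shifted = [(b.angle_deg + 90.0) % 180.0 for b in rot.branches]
        assert len(originals) == len(shifted)
        for a in shifted:
            assert min(circular_angle_distance(a, o) for o in originals) <= 2.0


class TestMinDistance:
    def test_parallel_rows(self):
        a = _hline(20, row=0)
        b = BranchSegment(1, [(10, i) for i in range(20)])
        assert min_distance(a, b) == pytest.approx(10.0)

    def test_touching(self):
        a = _hline(5)
        b = BranchSegment(1, [(0, 4 + i) for i in range(5)])
        assert min_distance(a, b) == 0.0

    def test_matches_bruteforce_on_random_pair(self):
        rng = np.random.default_rng(7)
        pa = [tuple(map(int, p)) for p in rng.integers(0, 50, (30, 2))]
        pb = [tuple(map(int, p)) for p in rng.integers(60, 120, (25, 2))]
        a, b = BranchSegment(0, pa), BranchSegment(1, pb)
        brute = min(
            np.hypot(p[0] - q[0], p[1] - q[1]) for p in pa for q in pb
        )
        assert min_distance(a, b) == pytest.approx(brute)

    def test_identical_segments_error(self):
        a = _hline(5)
        with pytest.raises(ValueError):
            min_distance(a, a)
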