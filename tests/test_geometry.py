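"""Cobb-angle geometry: filtering, outliers, imputation, apex, end vertebrae."""

import math

import numpy as np
import pytest

from cobbmeter.geometry import (DegenerateBoxError, MeasurementInfeasibleError,
                                Point2D, SpineSequence, VertebraBox,
                                _box_from_pose, detect_outliers, edge_tilt,
                                filter_by_score, find_apex, gap_profile,
                                impute_boxes, measure_cobb,
                                select_end_vertebrae)
from cobbmeter.synthetic import PhantomConfig, generate_phantom

from conftest import (axis_box, make_phantom, mirror_sequence, shift_box,
                      straight_sequence, transform_sequence)


class TestFilterByScore:
    def test_all_above_threshold_retained(self):
        seq = straight_sequence(scores=[0.9] * 17)
        assert len(filter_by_score(seq, 0.5)) == 17

    def test_low_score_boxes_dropped_order_preserved(self):
        scores = [0.9] * 17
        scores[3] = scores[10] = 0.4
        seq = straight_sequence(scores=scores)
        kept = filter_by_score(seq, 0.5)
        assert len(kept) == 15
        ys = [b.center.y for b in kept.boxes]
        assert ys == sorted(ys)

    def test_matches_per_box_scan_on_random_scores(self):
        rng = np.random.default_rng(42)
        scores = rng.uniform(0, 1, 17)
        seq = straight_sequence(scores=scores)
        kept = filter_by_score(seq, 0.5)
        expected = [i for i, s in enumerate(scores) if s > 0.5]
        assert [b.center.y for b in kept.boxes] == \
               [seq[i].center.y for i in expected]

    def test_too_few_survivors_is_infeasible(self):
        seq = straight_sequence(n=8, scores=[0.4] * 4 + [0.9] * 4)
        with pytest.raises(MeasurementInfeasibleError, match="4"):
            filter_by_score(seq, 0.5)


class TestDetectOutliers:
    def test_straight_column_has_none(self):
        assert detect_outliers(straight_sequence()) == []

    def test_grossly_shifted_box_is_flagged(self):
        seq = straight_sequence()
        boxes = list(seq.boxes)
        boxes[7] = shift_box(boxes[7], 2 * boxes[7].width)
        assert detect_outliers(SpineSequence(tuple(boxes))) == [7]

    @pytest.mark.parametrize("factor,flagged", [(0.51, True), (0.49, False)])
    def test_half_width_boundary(self, factor, flagged):
        seq = straight_sequence()
        boxes = list(seq.boxes)
        boxes[8] = shift_box(boxes[8], factor * boxes[8].width)
        out = detect_outliers(SpineSequence(tuple(boxes)))
        assert (8 in out) is flagged

    def test_first_box_compared_to_single_neighbour(self):
        seq = straight_sequence()
        boxes = list(seq.boxes)
        boxes[0] = shift_box(boxes[0], 0.6 * boxes[0].width)
        assert 0 in detect_outliers(SpineSequence(tuple(boxes)))


class TestImputeBoxes:
    def test_no_bad_indices_is_identity(self, phantom_40):
        assert impute_boxes(phantom_40.seq, []) is phantom_40.seq

    def test_imputed_center_lands_on_analytic_centerline(self, phantom_40):
        from cobbmeter.synthetic import _centerline_x

        seq = phantom_40.seq
        boxes = list(seq.boxes)
        boxes[8] = shift_box(boxes[8], 200.0)  # corrupt vertebra 8 laterally
        corrupted = SpineSequence(tuple(boxes), seq.image_width, seq.image_height)
        fixed = impute_boxes(corrupted, [8])
        cy = fixed[8].center.y
        expected_x = float(_centerline_x(phantom_40.config, np.array([cy]))[0])
        assert fixed[8].imputed
        assert abs(fixed[8].center.x - expected_x) < 1.0

    def test_two_imputations_preserve_cobb_within_2deg(self, phantom_40):
        intact = measure_cobb(phantom_40.seq).angle_deg
        seq = phantom_40.seq
        boxes = list(seq.boxes)
        boxes[5] = shift_box(boxes[5], 180.0)
        boxes[12] = shift_box(boxes[12], -180.0)
        corrupted = SpineSequence(tuple(boxes), seq.image_width, seq.image_height)
        fixed = impute_boxes(corrupted, [5, 12])
        assert abs(measure_cobb(fixed).angle_deg - intact) <= 2.0

    def test_more_than_two_bad_boxes_is_infeasible(self, phantom_40):
        with pytest.raises(MeasurementInfeasibleError):
            impute_boxes(phantom_40.seq, [3, 7, 11])


class TestEdgeTilt:
    @pytest.mark.parametrize("tr,expected", [
        ((10.0, 0.0), 0.0),       # flat edge
        ((10.0, 10.0), 45.0),     # right corner lower on screen
        ((20.0, -5.0), -14.036243467926477),
    ])
    def test_known_inclinations(self, tr, expected):
        box = VertebraBox(Point2D(0, 0), Point2D(*tr),
                          Point2D(0, 30), Point2D(tr[0], 30 + tr[1]))
        assert edge_tilt(box, "top") == pytest.approx(expected, abs=1e-9)

    def test_coincident_corners_raise(self):
        box = VertebraBox(Point2D(0, 0), Point2D(10, 0),
                          Point2D(5, 30), Point2D(5, 30))
        with pytest.raises(DegenerateBoxError):
            edge_tilt(box, "bottom")


class TestGapProfile:
    def test_touching_boxes_have_zero_gaps(self):
        a = axis_box(100, 100, 40, 20)
        b = axis_box(100, 120, 40, 20)  # top edge coincides with a's bottom
        gp = gap_profile(SpineSequence((a, b)))
        assert gp.left_gaps == (0.0,) and gp.right_gaps == (0.0,)

    def test_pure_vertical_separation(self):
        a = axis_box(100, 100, 40, 20)
        b = axis_box(100, 127, 40, 20)  # 7 px clearance between the edges
        gp = gap_profile(SpineSequence((a, b)))
        assert gp.left_gaps[0] == pytest.approx(7.0)
        assert gp.right_gaps[0] == pytest.approx(7.0)

    def test_concave_side_has_smaller_gap_sum(self):
        ph = make_phantom(30.0)  # arch bulges rightward: left side is concave
        gp = gap_profile(ph.seq)
        assert sum(gp.left_gaps) < sum(gp.right_gaps)


class TestFindApex:
    def test_straight_spine_flags_zero_curve(self):
        apex, direction, zero = find_apex(straight_sequence())
        assert zero and apex == 8 and direction == "straight"

    def test_phantom_apex_at_constructed_vertebra(self, phantom_40):
        apex, direction, zero = find_apex(phantom_40.seq)
        assert not zero
        assert apex == phantom_40.true_apex_index == 8
        assert direction == "right-convex"

    def test_mirror_flips_direction_not_apex(self, phantom_40):
        apex, direction, _ = find_apex(phantom_40.seq)
        m_apex, m_direction, _ = find_apex(mirror_sequence(phantom_40.seq))
        assert m_apex == apex
        assert {direction, m_direction} == {"left-convex", "right-convex"}


class TestSelectEndVertebrae:
    def test_unique_maximum_above_apex(self):
        seq = straight_sequence()
        boxes = list(seq.boxes)
        b = boxes[2]
        boxes[2] = _box_from_pose(b.center.x, b.center.y, b.width, b.height,
                                  12.0, b.score)
        seq = SpineSequence(tuple(boxes))
        sup, _ = select_end_vertebrae(seq, 8)
        assert sup == 2

    def test_monotone_tilts_pick_the_extremes(self, phantom_40):
        seq = phantom_40.seq
        apex = 8
        # independent oracle: exhaustive argmax over endplate tilts
        sup_oracle = max(range(apex + 1),
                         key=lambda i: (abs(edge_tilt(seq[i], "top")), -i))
        inf_oracle = max(range(apex, len(seq)),
                         key=lambda i: (abs(edge_tilt(seq[i], "bottom")), i))
        assert select_end_vertebrae(seq, apex) == (sup_oracle, inf_oracle) == (0, 16)

    def test_tie_breaks_away_from_apex(self):
        seq = straight_sequence()
        boxes = list(seq.boxes)
        for i in (1, 3):
            b = boxes[i]
            boxes[i] = _box_from_pose(b.center.x, b.center.y, b.width,
                                      b.height, 9.0, b.score)
        seq = SpineSequence(tuple(boxes))
        sup, _ = select_end_vertebrae(seq, 8)
        assert sup == 1


class TestMeasureCobb:
    def test_straight_phantom_measures_zero(self):
        cfg = PhantomConfig(amplitude=0.0, seed=1)
        res = measure_cobb(generate_phantom(cfg).seq)
        assert res.zero_curve and res.angle_deg == 0.0

    def test_hand_constructed_tilts_give_their_difference(self):
        tilts = [10.0, 7.0, 3.0, 0.0, -5.0, -10.0, -15.0]
        bulge = [0.0, 5.0, 9.0, 11.0, 9.0, 5.0, 0.0]
        boxes = [_box_from_pose(150.0 + bulge[i], 100.0 + 50.0 * i,
                                40.0, 20.0, tilts[i], 1.0)
                 for i in range(7)]
        res = measure_cobb(SpineSequence(tuple(boxes)))
        assert res.angle_deg == pytest.approx(abs(10.0 - (-15.0)), abs=1e-9)
        assert (res.superior_index, res.inferior_index) == (0, 6)

    def test_noise_free_phantom_recovers_true_angle(self, phantom_40):
        res = measure_cobb(phantom_40.seq)
        assert abs(res.angle_deg - phantom_40.true_cobb_deg) < 1.0
        assert res.angle_deg == pytest.approx(40.0, abs=1.0)
        assert res.superior_index <= res.apex_index <= res.inferior_index

    def test_rounding_is_half_away_from_zero(self, phantom_40):
        res = measure_cobb(phantom_40.seq)
        assert res.angle_deg_rounded == int(math.floor(res.angle_deg + 0.5))


class TestInvariances:
    def test_rigid_motion_leaves_angle_unchanged(self, phantom_40):
        base = measure_cobb(phantom_40.seq).angle_deg
        theta = math.radians(4.0)
        c, s = math.cos(theta), math.sin(theta)

        def rot(p):
            x, y = p.x - 256.0, p.y - 512.0
            return Point2D(x * c - y * s + 300.0, x * s + y * c + 550.0)

        moved = transform_sequence(phantom_40.seq, rot)
        assert measure_cobb(moved).angle_deg == pytest.approx(base, abs=1e-6)

    def test_mirror_preserves_angle_flips_tilt_signs(self, phantom_40):
        res = measure_cobb(phantom_40.seq)
        mres = measure_cobb(mirror_sequence(phantom_40.seq))
        assert mres.angle_deg == pytest.approx(res.angle_deg, abs=1e-6)
        assert mres.apex_index == res.apex_index
        assert mres.direction != res.direction
        assert mres.tilt_sup_deg == pytest.approx(-res.tilt_sup_deg, abs=1e-6)
        assert mres.tilt_inf_deg == pytest.approx(-res.tilt_inf_deg, abs=1e-6)

    def test_uniform_scaling_leaves_angle_unchanged(self, phantom_40):
        base = measure_cobb(phantom_40.seq).angle_deg
        scaled = transform_sequence(phantom_40.seq,
                                    lambda p: Point2D(2.5 * p.x, 2.5 * p.y))
        assert measure_cobb(scaled).angle_deg == pytest.approx(base, abs=1e-6)

    def test_measured_angle_monotone_in_amplitude(self):
        cfg = PhantomConfig(seed=5)
        amps = np.linspace(12, 216, 9)
        angles = []
        for a in amps:
            ph = generate_phantom(PhantomConfig(amplitude=float(a), seed=5))
            angles.append(measure_cobb(ph.seq).angle_deg)
        assert all(a < b for a, b in zip(angles, angles[1:]))

    def test_apex_and_ends_match_brute_force_on_random_phantoms(self):
        rng = np.random.default_rng(99)
        for trial in range(100):
            ph = make_phantom(float(rng.uniform(8, 70)), noise=0.5,
                              seed=int(rng.integers(1 << 30)))
            seq = ph.seq
            apex, _, zero = find_apex(seq)
            assert not zero
            # oracle: explicit perpendicular point-to-chord distance
            p0 = np.array([seq[0].center.x, seq[0].center.y])
            p1 = np.array([seq[-1].center.x, seq[-1].center.y])
            u = (p1 - p0) / np.linalg.norm(p1 - p0)
            dists = []
            for b in seq.boxes:
                v = np.array([b.center.x, b.center.y]) - p0
                dists.append(np.linalg.norm(v - (v @ u) * u))
            assert apex == int(np.argmax(dists))
            sup, inf = select_end_vertebrae(seq, apex)
            assert sup == max(range(apex + 1),
                              key=lambda i: (abs(edge_tilt(seq[i], "top")), -i))
            assert inf == max(range(apex, len(seq)),
                              key=lambda i: (abs(edge_tilt(seq[i], "bottom")), i))
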