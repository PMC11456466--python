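import numpy as np
import pytest

from cabbagepose import (
    CabbageScene,
    PostureConfig,
    PostureLabel,
    SceneParams,
    StageError,
    bezier,
    generate_scene,
    geometry,
    posture,
    synthetic,
)


class TestFindBreakPoint:
    def test_symmetric_top_row_of_bar(self):
        m = np.zeros((20, 20), bool)
        m[10:18, 4:7] = True  # columns 4..6 from row 10
        assert posture.find_break_point(m) == (5.0, 10.0)

    def test_single_pixel_top_row(self):
        m = np.zeros((10, 10), bool)
        m[2, 7] = True
        m[3:7, 5:9] = True
        assert posture.find_break_point(m) == (7.0, 2.0)

    def test_random_stem_matches_row_scan(self, random_blob):
        x, y = posture.find_break_point(random_blob)
        ys, xs = np.nonzero(random_blob)
        assert y == ys.min()
        row_cols = xs[ys == ys.min()]
        assert row_cols.min() <= x <= row_cols.max()


class TestSnapToContour:
    def test_contour_pixel_is_fixed_point(self):
        m = np.zeros((10, 10), bool)
        m[3:8, 3:8] = True
        assert posture.snap_to_contour((3.0, 3.0), m) == (3.0, 3.0)

    def test_gap_center_tie_goes_lexicographically_smaller(self):
        m = np.zeros((5, 9), bool)
        m[2, 2] = True
        m[2, 6] = True
        assert posture.snap_to_contour((4.0, 2.0), m) == (2.0, 2.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_linear_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = np.zeros((30, 30), bool)
        m[rng.integers(2, 28, 80), rng.integers(2, 28, 80)] = True
        cand = tuple(rng.uniform(0, 30, 2))
        got = posture.snap_to_contour(cand, m)
        pts = geometry.contour_points(m)
        keys = [((x - cand[0]) ** 2 + (y - cand[1]) ** 2, x, y) for x, y in pts]
        expected = min(keys)[1:]
        assert got == expected


class TestCurveHeadIntersection:
    def test_straight_entry_into_solid_square(self):
        head = np.zeros((40, 40), bool)
        head[5:20, 10:30] = True  # lower boundary row y=19
        curve = bezier.sample_curve([(20.0, 35.0), (20.0, 25.0), (20.0, 10.0)], 300)
        (x, y), t = posture.curve_head_intersection(curve, head)
        assert abs(y - 19.0) <= 1.0 and x == pytest.approx(20.0, abs=0.5)
        assert 0 < t < 1

    def test_start_inside_head_degenerate(self):
        head = np.ones((10, 10), bool)
        curve = bezier.sample_curve([(5.0, 5.0), (5.0, 4.0), (5.0, 2.0)], 50)
        (_, _), t = posture.curve_head_intersection(curve, head)
        assert t == 0.0

    def test_single_transition_for_convex_head(self):
        head = np.zeros((40, 40), bool)
        head[5:20, 10:30] = True
        curve = bezier.sample_curve([(20.0, 35.0), (22.0, 25.0), (20.0, 12.0)], 300)
        cols = np.floor(curve.points[:, 0] + 0.5).astype(int)
        rows = np.floor(curve.points[:, 1] + 0.5).astype(int)
        hits = head[rows, cols]
        transitions = np.diff(hits.astype(int))
        assert (transitions == 1).sum() == 1  # one false->true entry

    def test_no_intersection_raises(self):
        head = np.zeros((10, 10), bool)
        head[0, 0] = True
        curve = bezier.sample_curve([(9.0, 9.0), (8.0, 9.0), (7.0, 9.0)], 10)
        with pytest.raises(posture.NoIntersectionError if hasattr(posture, "NoIntersectionError") else Exception):
            posture.curve_head_intersection(curve, head)


class TestAxisAngle:
    def test_plumb_axis_is_zero(self):
        assert posture.axis_angle((5, 0), (5, 10)) == 0.0

    def test_diagonal_is_45(self):
        assert posture.axis_angle((0, 0), (10, 10)) == pytest.approx(45.0)

    def test_horizontal_reference_matches_slope_form(self):
        # |arctan(dy/dx)| of a unit-slope line
        assert posture.axis_angle((0, 0), (10, 10), "horizontal") == pytest.approx(45.0)
        assert posture.axis_angle((0, 5), (10, 5), "horizontal") == 0.0
        assert posture.axis_angle((5, 0), (5, 10), "horizontal") == 90.0

    def test_vertical_and_horizontal_are_complementary(self):
        v = posture.axis_angle((0, 0), (3, 10), "vertical")
        h = posture.axis_angle((0, 0), (3, 10), "horizontal")
        assert v + h == pytest.approx(90.0)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            posture.axis_angle((1, 1), (1, 1))


class TestClassify:
    @pytest.mark.parametrize(
        "theta, beta, label",
        [
            (5.0, 10.0, PostureLabel.VERTICAL),
            (10.0, 10.0, PostureLabel.VERTICAL),  # boundary inclusive
            (10.01, 10.0, PostureLabel.TILTED),
        ],
    )
    def test_threshold_rule(self, theta, beta, label):
        assert posture.classify(theta, beta) == label

    def test_negative_angles_rejected(self):
        with pytest.raises(ValueError):
            posture.classify(-1.0, 10.0)


class TestPredictPosture:
    def test_vertical_scene_recovers_plumb_axis(self, vertical_scene):
        scene, _ = vertical_scene
        result = posture.predict_posture(scene, beta_deg=10.0)
        assert result.theta_deg < 1.0
        assert result.label is PostureLabel.VERTICAL

    def test_tilted_occluded_scene_recovers_angle(self):
        scene, truth = generate_scene(
            SceneParams(true_angle_deg=30.0, occlusion_frac=0.3, seed=4)
        )
        result = posture.predict_posture(scene, beta_deg=10.0)
        assert abs(result.theta_deg - 30.0) <= 3.0
        assert result.label is PostureLabel.TILTED

    def test_p3_inside_head_and_theta_range(self, vertical_scene):
        scene, _ = vertical_scene
        r = posture.predict_posture(scene)
        x3, y3 = r.p3
        combined = scene.head  # overlap pixels belong to the head
        assert combined[round(y3), round(x3)]
        assert 0.0 <= r.theta_deg <= 90.0

    def test_empty_root_fails_at_keypoints_stage(self):
        head = np.zeros((20, 20), bool)
        head[2:8, 5:15] = True
        scene = CabbageScene(head=head, root=np.zeros((20, 20), bool))
        with pytest.raises(StageError) as err:
            posture.predict_posture(scene)
        assert err.value.stage == "keypoints"
        assert "empty instance" in str(err.value)

    def test_label_always_consistent_with_rule(self, mixed_batch):
        for scene, _ in mixed_batch[:20]:
            r = posture.predict_posture(scene, beta_deg=10.0)
            expected = PostureLabel.VERTICAL if r.theta_deg <= 10.0 else PostureLabel.TILTED
            assert r.label is expected

    def test_inverted_scene_warns_in_diagnostics(self, vertical_scene):
        scene, _ = vertical_scene
        flipped = CabbageScene(
            head=np.flipud(scene.head), root=np.flipud(scene.root)
        )
        r = posture.predict_posture(flipped)
        assert any("inverted" in w for w in r.diagnostics["warnings"])


class TestPipelineSymmetries:
    def test_mirror_leaves_theta_unchanged(self):
        scene, truth = generate_scene(
            SceneParams(true_angle_deg=17.0, root_curvature=0.3,
                        occlusion_frac=0.2, seed=6)
        )
        t0 = posture.predict_posture(scene).theta_deg
        mirrored, mtruth = synthetic.augment(scene, [("mirror",)], truth=truth)
        t1 = posture.predict_posture(mirrored).theta_deg
        assert mtruth.true_angle_deg == -truth.true_angle_deg
        assert t1 == pytest.approx(t0, abs=0.5)

    @pytest.mark.parametrize("delta", [5.0, 12.0, 20.0])
    def test_rotation_shifts_theta_by_delta(self, delta):
        scene, truth = generate_scene(
            SceneParams(true_angle_deg=6.0, root_curvature=0.2,
                        occlusion_frac=0.25, seed=9)
        )
        t0 = posture.predict_posture(scene).theta_deg
        rotated, rtruth = synthetic.augment(scene, [("rotate", delta)], truth=truth)
        t1 = posture.predict_posture(rotated).theta_deg
        assert rtruth.true_angle_deg == pytest.approx(6.0 + delta)
        assert abs((t1 - t0) - delta) <= 2.0


class TestConfig:
    def test_invalid_config_values_rejected(self):
        with pytest.raises(ValueError):
            PostureConfig(beta_deg=-1)
        with pytest.raises(ValueError):
            PostureConfig(angle_reference="diagonal")
        with pytest.raises(ValueError):
            PostureConfig(n_samples=1)

    def test_result_json_shape(self, vertical_scene):
        scene, _ = vertical_scene
        d = posture.predict_posture(scene).to_dict()
        assert set(d) >= {"p0", "p1", "p2", "p3", "theta_deg", "label", "beta_deg"}
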