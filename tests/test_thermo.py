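"""Thermography pipeline: normalization, segmentation, body/tail split, CI."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

from phenopipe import synthgen, thermo


def _session(cfg):
    return synthgen.gen_thermal_session(cfg)


class TestNormalizeFrame:
    def test_affine_map_endpoints_and_midpoint(self):
        frame = np.array([[10.0, 20.0], [15.0, 10.0]])
        norm, degenerate = thermo.normalize_frame(frame)
        assert not degenerate
        assert norm[0, 0] == 0.0 and norm[0, 1] == 255.0
        assert norm[1, 0] == pytest.approx(127.5)

    def test_constant_frame_is_degenerate_zeros(self):
        norm, degenerate = thermo.normalize_frame(np.full((4, 4), 22.0))
        assert degenerate and (norm == 0).all()

    @given(
        hnp.arrays(
            np.float64,
            (6, 6),
            elements=st.floats(-50, 80, allow_nan=False, width=64),
        )
    )
    def test_pixel_ordering_preserved(self, frame):
        norm, _ = thermo.normalize_frame(frame)
        flat_in = frame.ravel()
        flat_out = norm.ravel()
        order = np.argsort(flat_in, kind="stable")
        assert (np.diff(flat_out[order]) >= 0).all()
        assert flat_out.min() >= 0.0 and flat_out.max() <= 255.0


class TestSegmentMouse:
    def test_noiseless_scene_recovered_exactly(self, small_scene):
        session, truth = _session(small_scene())
        masks = thermo.segment_mouse(session.frames[0], session.arena_mask)
        whole_true = truth.body_masks[0] | truth.tail_masks[0]
        assert masks.valid
        assert np.array_equal(masks.whole_mask, whole_true)

    def test_noisy_scene_iou_stays_high(self, small_scene):
        session, truth = _session(small_scene(noise_sd=0.3, duration=3.0))
        for i in range(session.n_frames):
            masks = thermo.segment_mouse(session.frames[i], session.arena_mask)
            whole_true = truth.body_masks[i] | truth.tail_masks[i]
            inter = (masks.whole_mask & whole_true).sum()
            union = (masks.whole_mask | whole_true).sum()
            assert inter / union >= 0.95

    def test_largest_of_two_warm_blobs_selected(self):
        frame = np.full((60, 60), 22.0)
        frame[10:20, 10:20] = 36.0     # 100 px mouse
        frame[40:47, 40:47] = 36.0     # 49 px artifact, about half the area
        arena = np.ones((60, 60), dtype=bool)
        masks = thermo.segment_mouse(frame, arena)
        assert masks.valid
        assert masks.whole_mask[15, 15] and not masks.whole_mask[43, 43]

    def test_blank_arena_flagged_invalid_not_raised(self):
        frame = np.full((40, 40), 22.0)
        masks = thermo.segment_mouse(frame, np.ones((40, 40), dtype=bool))
        assert not masks.valid

    def test_empty_arena_mask_rejected(self):
        with pytest.raises(ValueError):
            thermo.segment_mouse(np.zeros((5, 5)), np.zeros((5, 5), dtype=bool))


class TestSplitBodyTail:
    def test_body_and_tail_recall_against_truth(self, small_scene):
        # default animal geometry (30 x 15 px body, 3 px tail) on a compact frame
        session, truth = _session(
            small_scene(
                frame_size=(240, 320), arena_center=(160.0, 120.0),
                arena_radius=90.0, body_axes=(30.0, 15.0), tail_length=40.0,
            )
        )
        frame = session.frames[0]
        masks = thermo.split_body_tail(
            frame, thermo.segment_mouse(frame, session.arena_mask)
        )
        assert masks.tail_valid
        body_recall = (masks.body_mask & truth.body_masks[0]).sum() / truth.body_masks[0].sum()
        tail_recall = (masks.tail_mask & truth.tail_masks[0]).sum() / truth.tail_masks[0].sum()
        assert body_recall >= 0.98
        assert tail_recall >= 0.90
        # temperatures read off the split masks stay close to the truth
        assert frame[masks.body_mask].mean() == pytest.approx(36.0, abs=0.2)
        assert frame[masks.tail_mask].mean() == pytest.approx(30.0, abs=0.2)

    def test_partition_of_whole_mask(self, small_scene):
        session, _ = _session(small_scene(noise_sd=0.2))
        frame = session.frames[0]
        masks = thermo.split_body_tail(
            frame, thermo.segment_mouse(frame, session.arena_mask)
        )
        assert not (masks.body_mask & masks.tail_mask).any()
        assert np.array_equal(masks.body_mask | masks.tail_mask, masks.whole_mask)

    def test_tailless_animal_flagged_for_ci(self, small_scene):
        session, _ = _session(small_scene(render_tail=False))
        frame = session.frames[0]
        masks = thermo.split_body_tail(
            frame, thermo.segment_mouse(frame, session.arena_mask)
        )
        assert masks.valid and not masks.tail_valid
        assert masks.tail_mask.sum() == 0
        assert np.array_equal(masks.body_mask, masks.whole_mask)

    def test_invalid_input_propagates(self):
        invalid = thermo.BodyTailMasks(np.zeros((4, 4), dtype=bool), valid=False)
        assert not thermo.split_body_tail(np.zeros((4, 4)), invalid).valid


class TestCiSeries:
    def test_constant_temperatures_give_constant_ci(self, small_scene):
        session, _ = _session(small_scene(duration=3.0))
        series = thermo.extract_ci_series(session)
        valid = series.valid
        assert len(valid) == session.n_frames
        # measured CI carries the segmentation's junction-pixel error budget
        assert np.allclose(valid["ci"], 1.2, atol=0.02)

    def test_ci_identity_and_scale_covariance(self, small_scene):
        session, _ = _session(small_scene(noise_sd=0.2, duration=3.0))
        series = thermo.extract_ci_series(session)
        valid = series.valid
        assert np.max(np.abs(valid["ci"] - valid["body_temp"] / valid["tail_temp"])) <= 1e-12
        # adding a constant to every pixel shifts the temps by exactly that
        shifted = thermo.ThermalSession(
            session.frames + 5.0, session.frame_rate, session.arena_mask, session.phases
        )
        series2 = thermo.extract_ci_series(shifted)
        assert np.allclose(
            series2.frame["body_temp"], series.frame["body_temp"] + 5.0, atol=1e-9
        )
        assert np.allclose(
            series2.frame["tail_temp"], series.frame["tail_temp"] + 5.0, atol=1e-9
        )

    def test_cooling_tail_raises_ci_monotonically(self, small_scene):
        cfg = small_scene(
            duration=4.0,
            tail_temp=lambda t: 30.0 - 0.5 * t,  # 30 -> 28 over the session
        )
        session, truth = _session(cfg)
        series = thermo.extract_ci_series(session)
        ci = series.valid["ci"].to_numpy()
        assert len(ci) == session.n_frames
        assert (np.diff(ci) > 0).all()
        assert (np.diff(truth.ci) > 0).all()

    def test_all_background_session_has_no_valid_frames(self):
        frames = np.full((5, 40, 40), 22.0)
        session = thermo.ThermalSession(
            frames, 2.0, np.ones((40, 40), dtype=bool), [("trial", 0.0, 2.5)]
        )
        series = thermo.extract_ci_series(session)
        assert len(series.valid) == 0
        assert any("invalid" in w for w in series.meta["warnings"])


class TestWindowStats:
    @staticmethod
    def _constant_series(rate=2.0, duration=600.0, ci=1.2):
        import pandas as pd

        t = np.arange(int(rate * duration)) / rate
        df = pd.DataFrame(
            {"time": t, "body_temp": 36.0, "tail_temp": 30.0, "ci": ci, "valid": True}
        )
        return thermo.CISeries(df, {"frame_rate": rate})

    def test_constant_window(self):
        mean, sd, n = thermo.window_stats(self._constant_series(), 100.0, 200.0)
        assert mean == pytest.approx(1.2)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_frame_count_in_window(self):
        _, _, n = thermo.window_stats(self._constant_series(rate=2.0), 250.0, 350.0)
        assert n == 200

    def test_window_outside_session_is_empty(self):
        mean, sd, n = thermo.window_stats(self._constant_series(), 700.0, 800.0)
        assert n == 0 and np.isnan(mean)

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            thermo.window_stats(self._constant_series(), 200.0, 100.0)


class TestAreaFraction:
    def test_half_above_threshold(self):
        img = np.zeros((10, 10))
        img[:5] = 1.0
        assert thermo.area_fraction(img, np.ones_like(img, dtype=bool), 0.5) == 0.5

    def test_threshold_below_minimum_gives_one(self):
        img = np.random.default_rng(0).uniform(1, 2, (8, 8))
        assert thermo.area_fraction(img, np.ones_like(img, dtype=bool), 0.0) == 1.0

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            thermo.area_fraction(np.ones((4, 4)), np.zeros((4, 4), dtype=bool), 0.5)

    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 0.9))
    def test_matches_per_pixel_count_oracle(self, seed, threshold):
        rng = np.random.default_rng(seed)
        img = rng.uniform(0, 1, (12, 12))
        roi = rng.uniform(0, 1, (12, 12)) > 0.3
        if not roi.any():
            roi[0, 0] = True
        expected = sum(
            1 for y in range(12) for x in range(12) if roi[y, x] and img[y, x] >= threshold
        ) / roi.sum()
        assert thermo.area_fraction(img, roi, threshold) == pytest.approx(expected)
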