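"""Detection pipeline: paradigm arithmetic, SD projection, prominence
maxima, ROI placement, and event-start assignment."""

import numpy as np
import pytest

from dcvfusion.detect import (
    AcquisitionParadigm,
    DetectionParams,
    assign_event_start,
    detect_fusion_events,
    find_candidate_maxima,
    frames_for_duration,
    max_overlap_for_roi,
    place_rois,
    rolling_mean_sd,
    round_stim_window,
    sd_projection,
)
from dcvfusion.detect import _roi_overlap_px
from dcvfusion.movie_io import TimeLapse
from dcvfusion.normalize import NormalizationParams
from helpers import match_events, prominence_oracle, sd_projection_oracle

PARADIGM = AcquisitionParadigm(
    frame_rate_hz=2.0, baseline_frames=30, stim_start_frame=61,
    stim_len_frames=50, nh4_start_frame=160,
)


class TestParadigmArithmetic:
    @pytest.mark.parametrize(
        "seconds, rate, frames",
        [(24.0, 2.0, 48), (0.0, 5.0, 0), (80.0, 2.0, 160)],
    )
    def test_frames_for_duration(self, seconds, rate, frames):
        assert frames_for_duration(seconds, rate) == frames

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            frames_for_duration(-1.0, 2.0)

    @pytest.mark.parametrize("frames, rounded", [(48, 50), (50, 50), (1, 10), (41, 50)])
    def test_round_stim_window(self, frames, rounded):
        assert round_stim_window(frames) == rounded

    @pytest.mark.parametrize("size, overlap", [(3, 3), (1, 0), (5, 8)])
    def test_max_overlap_third_of_area(self, size, overlap):
        assert max_overlap_for_roi(size) == overlap

    def test_paradigm_ordering_enforced(self):
        with pytest.raises(ValueError):
            AcquisitionParadigm(2.0, 30, 20, 50, 160)

    def test_stim_blocks_partition_window(self):
        blocks = PARADIGM.stim_blocks(3)
        assert blocks[0][0] == 60 and blocks[-1][1] == 110
        assert all(b1 > b0 for b0, b1 in blocks)


class TestSdProjection:
    def test_constant_movie_gives_zero(self):
        assert np.all(sd_projection(np.full((10, 4, 4), 3.0), (0, 10)) == 0)

    def test_two_point_closed_form(self):
        frames = np.zeros((2, 1, 1))
        frames[1] = 2.0
        assert sd_projection(frames, (0, 2))[0, 0] == pytest.approx(np.sqrt(2.0))

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            frames = rng.uniform(0, 100, size=(20, 8, 8))
            np.testing.assert_allclose(
                sd_projection(frames, (3, 17)),
                sd_projection_oracle(frames, 3, 17),
                rtol=1e-9,
            )

    def test_blocks_combine_by_maximum(self):
        rng = np.random.default_rng(3)
        frames = rng.uniform(0, 10, size=(20, 5, 5))
        combined = sd_projection(frames, [(0, 10), (10, 20)])
        np.testing.assert_allclose(
            combined,
            np.maximum(sd_projection(frames, (0, 10)), sd_projection(frames, (10, 20))),
        )

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            sd_projection(np.zeros((5, 3, 3)), (2, 3))


class TestFindCandidateMaxima:
    def test_flat_image_empty(self):
        assert find_candidate_maxima(np.full((8, 8), 5.0), 10.0) == []

    def test_single_bump_found_at_center(self):
        y, x = np.mgrid[:15, :15]
        img = 100.0 * np.exp(-((y - 7) ** 2 + (x - 4) ** 2) / 6.0)
        peaks = find_candidate_maxima(img, 50.0)
        assert len(peaks) == 1
        assert peaks[0][:2] == (7, 4)

    def test_two_bumps_with_saddle_against_oracle(self):
        y, x = np.mgrid[:16, :16]
        img = np.exp(-((y - 4) ** 2 + (x - 4) ** 2) / 4.0)
        img += 0.7 * np.exp(-((y - 11) ** 2 + (x - 11) ** 2) / 4.0)
        oracle = prominence_oracle(img)
        for threshold in (10.0, 60.0, 120.0, 200.0):
            expected = sorted((r, c) for r, c, h, p in oracle if p >= threshold)
            got = sorted((r, c) for r, c, s in find_candidate_maxima(img, threshold))
            assert got == expected

    def test_random_images_against_flood_fill_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(40):
            img = rng.uniform(0, 1, size=(10, 10))
            oracle = {(r, c): p for r, c, h, p in prominence_oracle(img)}
            for threshold in (20.0, 80.0, 160.0):
                expected = sorted(k for k, p in oracle.items() if p >= threshold)
                got = sorted((r, c) for r, c, s in find_candidate_maxima(img, threshold))
                assert got == expected

    def test_plateau_collapses_to_centroid(self):
        img = np.zeros((9, 9))
        img[4, 3:6] = 10.0  # 3-pixel plateau centred on column 4
        peaks = find_candidate_maxima(img, 50.0)
        assert peaks == [(4, 4, 255.0)]

    def test_sorted_by_descending_score(self, clean_run):
        from dcvfusion.detect import sd_projection as sdp
        from dcvfusion.normalize import normalize_movie

        norm = normalize_movie(clean_run["movie"], clean_run["params"].normalization)
        sd = sdp(norm.frames, clean_run["paradigm"].stim_blocks(1))
        peaks = find_candidate_maxima(sd, 60.0)
        scores = [s for _, _, s in peaks]
        assert scores == sorted(scores, reverse=True)


class TestPlaceRois:
    def test_adjacent_maxima_suppressed(self):
        maxima = [(5, 5, 200.0), (5, 6, 150.0)]  # 1 px apart: overlap 6 > 3
        rois = place_rois(maxima, 3, 3, (16, 16))
        assert len(rois) == 1 and rois[0].center == (5, 5)

    def test_disjoint_maxima_both_kept(self):
        rois = place_rois([(5, 5, 200.0), (5, 9, 150.0)], 3, 3, (16, 16))
        assert [r.center for r in rois] == [(5, 5), (5, 9)]
        assert [r.roi_id for r in rois] == ["0000", "0001"]

    def test_empty_input(self):
        assert place_rois([], 3, 3, (16, 16)) == []

    def test_roi_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            place_rois([(1, 1, 1.0)], 5, 3, (4, 4))

    def test_overlap_arithmetic_matches_counting(self):
        rng = np.random.default_rng(4)
        shape = (20, 20)
        for _ in range(50):
            a = tuple(rng.integers(0, 20, size=2))
            b = tuple(rng.integers(0, 20, size=2))
            size = int(rng.choice([1, 3, 5]))
            grid_a = np.zeros(shape, dtype=bool)
            grid_b = np.zeros(shape, dtype=bool)
            half = size // 2
            grid_a[max(a[0]-half,0):a[0]+half+1, max(a[1]-half,0):a[1]+half+1] = True
            grid_b[max(b[0]-half,0):b[0]+half+1, max(b[1]-half,0):b[1]+half+1] = True
            assert _roi_overlap_px(a, b, size, shape) == int((grid_a & grid_b).sum())


class TestAssignEventStart:
    def test_step_detected_at_step_frame(self):
        trace = np.full(200, 100.0)
        trace[80:] = 110.0
        start = assign_event_start(trace, PARADIGM, 2.0)
        assert start == 81  # 1-based

    def test_never_crossing_returns_none(self):
        trace = np.full(200, 100.0)
        assert assign_event_start(trace, PARADIGM, 2.0) is None

    def test_step_before_stimulation_ignored(self):
        trace = np.full(200, 100.0)
        trace[40:55] = 200.0  # rises and settles before the window
        trace[55:] = 100.0
        assert assign_event_start(trace, PARADIGM, 2.0) is None

    def test_rolling_statistics_match_direct_computation(self):
        rng = np.random.default_rng(9)
        trace = rng.normal(100, 5, size=120)
        means, sds = rolling_mean_sd(trace, 20)
        for f in (19, 50, 119):
            window = trace[f - 19 : f + 1]
            assert means[f] == pytest.approx(window.mean())
            assert sds[f] == pytest.approx(window.std(ddof=1))
        assert np.isnan(means[18])

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            rolling_mean_sd(np.zeros(10), 11)


def _tiny_event_movie(offset=0.0):
    """Deterministic 80-frame movie with one planted step event."""
    frames = np.full((80, 32, 32), 100.0) + offset
    y, x = np.mgrid[:32, :32]
    bump = 80.0 * np.exp(-((y - 12) ** 2 + (x - 20) ** 2) / 2.0)
    for t in range(35, 45):
        frames[t] += bump * np.exp(-(t - 35) / 4.0)
    return TimeLapse(frames=frames, frame_rate_hz=2.0)


TINY_PARADIGM = AcquisitionParadigm(
    frame_rate_hz=2.0, baseline_frames=20, stim_start_frame=31,
    stim_len_frames=30, nh4_start_frame=70,
)


class TestDetectFusionEvents:
    def test_recovers_planted_events_on_clean_scene(self, clean_run):
        truth, rois = clean_run["truth"], clean_run["rois"]
        n_matched, errors, n_det = match_events(truth.events, rois)
        assert n_matched >= 0.9 * len(truth.events)
        assert n_matched >= 0.8 * n_det
        assert np.mean(errors <= 1) >= 0.9

    def test_null_scene_has_at_most_one_false_positive(self, null_run):
        assert len(null_run["rois"]) <= 1

    def test_no_roi_pair_exceeds_overlap_budget(self, clean_run):
        rois = clean_run["rois"]
        params = clean_run["params"]
        shape = clean_run["movie"].frame_shape
        budget = params.resolved_max_overlap()
        for i, a in enumerate(rois):
            for b in rois[i + 1 :]:
                assert _roi_overlap_px(a.center, b.center, params.roi_size_px, shape) <= budget

    def test_deterministic_rerun(self):
        movie = _tiny_event_movie()
        params = DetectionParams()
        first = detect_fusion_events(movie, TINY_PARADIGM, params)
        second = detect_fusion_events(movie, TINY_PARADIGM, params)
        assert [r.label for r in first[0]] == [r.label for r in second[0]]
        assert first[1].equals(second[1])

    def test_offset_invariance_in_baseline_subtraction_mode(self):
        params = DetectionParams(
            normalization=NormalizationParams(method="baseline_subtraction", baseline_frames=20)
        )
        base = detect_fusion_events(_tiny_event_movie(), TINY_PARADIGM, params)[0]
        shifted = detect_fusion_events(_tiny_event_movie(offset=500.0), TINY_PARADIGM, params)[0]
        assert [(r.center, r.event_start_frame) for r in base] == [
            (r.center, r.event_start_frame) for r in shifted
        ]
        assert len(base) == 1
        assert base[0].event_start_frame == 36
        assert base[0].center == (12, 20)

    def test_recall_and_precision_over_seeds(self, sweep_runs):
        recalls = [r["n_matched"] / r["n_events_gt"] for r in sweep_runs]
        precisions = [r["n_matched"] / r["n_detected"] for r in sweep_runs]
        assert np.mean(recalls) >= 0.9
        assert np.mean(precisions) >= 0.8
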