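"""Histograms, cumulative counts, QC flags, and batch collection."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcvfusion.aggregate import (
    analyze_cell,
    collect_folder,
    cumulative_counts,
    event_histogram,
    qc_evaluate,
)
from dcvfusion.config import dump_config, load_config
from dcvfusion.detect import DetectionParams
from dcvfusion.movie_io import write_stack
from dcvfusion.pool import PoolEstimate, estimate_pool
from dcvfusion.simulate import default_scenarios, simulate_movie
from helpers import small_scenario


class TestEventHistogram:
    def test_same_bin_counted_together(self):
        counts = event_histogram([30.0, 30.4], bin_s=0.5, recording_len_s=100.0)
        assert counts[60] == 2
        assert counts.sum() == 2

    def test_no_events_all_zero(self):
        counts = event_histogram([], bin_s=0.5, recording_len_s=100.0)
        assert counts.sum() == 0 and len(counts) == 200

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(times=st.lists(st.floats(min_value=0.0, max_value=99.74), max_size=40),
           bin_s=st.sampled_from([0.5, 1.5]))
    def test_counts_conserve_events(self, times, bin_s):
        counts = event_histogram(times, bin_s=bin_s, recording_len_s=100.0)
        assert counts.sum() == len(times)

    def test_bad_bin_rejected(self):
        with pytest.raises(ValueError):
            event_histogram([1.0], bin_s=0.0, recording_len_s=10.0)


class TestCumulativeCounts:
    def test_prefix_sums(self):
        np.testing.assert_array_equal(cumulative_counts([2, 0, 3]), [2, 2, 5])

    def test_normalized_ends_at_one(self):
        cum = cumulative_counts([2, 0, 3], normalize=True)
        assert cum[-1] == pytest.approx(1.0)
        assert np.all(np.diff(cum) >= 0)

    def test_differences_recover_histogram(self):
        hist = np.array([0, 4, 1, 0, 7])
        cum = cumulative_counts(hist)
        np.testing.assert_array_equal(np.diff(np.concatenate([[0], cum])), hist)


class TestQcFlags:
    def test_clean_cell_has_no_flags(self, clean_run):
        pool = estimate_pool(
            clean_run["movie"], clean_run["paradigm"], clean_run["params"],
            fusion_events=clean_run["events"],
        )
        assert qc_evaluate(clean_run["movie"], clean_run["paradigm"], pool) == set()

    def test_saturated_patch_outside_soma_flagged(self, scenarios):
        sc = scenarios["saturated"]
        movie, _, _ = simulate_movie(sc)
        pool = estimate_pool(movie, sc.paradigm, DetectionParams())
        flags = qc_evaluate(movie, sc.paradigm, pool)
        assert "nh4_saturation" in flags
        assert pool.n_saturated_px > 0

    def test_missing_nh4_response_flagged(self):
        sc = replace(
            default_scenarios(5)["null"], n_vesicles=0, n_events=0,
            shape=(96, 96), soma_radius_px=8, n_synapses=8,
        )
        movie, _, _ = simulate_movie(sc)
        pool = estimate_pool(movie, sc.paradigm, DetectionParams())
        assert "no_nh4_puncta" in qc_evaluate(movie, sc.paradigm, pool)

    def test_focus_drift_proxy(self, clean_run):
        movie = clean_run["movie"]
        drifting = movie.frames.astype(np.float64).copy()
        ramp = 1.0 + 2.0 * np.arange(movie.n_frames) / movie.n_frames
        drifting *= ramp[:, None, None]
        drifting_movie = movie.with_frames(drifting)
        pool = PoolEstimate(raw_pool=100, fused_corrected=100.0, puncta_corrected=100.0)
        flags = qc_evaluate(drifting_movie, clean_run["paradigm"], pool)
        assert "focus_drift" in flags

    def test_prestim_bright_vesicles_flagged(self):
        sc = small_scenario(6, nonacidic_fraction=0.5, n_vesicles=40, n_events=5)
        movie, _, _ = simulate_movie(sc)
        pool = estimate_pool(movie, sc.paradigm, DetectionParams())
        assert "bright_pre_stim" in qc_evaluate(movie, sc.paradigm, pool)


def _write_cells(folder, seeds, with_masks=()):
    """Simulate cells and write the folder layout expected by collect."""
    import tifffile

    from dcvfusion.synapse import make_synapse_mask

    paradigm = None
    for seed in seeds:
        sc = small_scenario(seed)
        movie, truth, marker = simulate_movie(sc)
        write_stack(movie, folder / f"cell{seed}.tif")
        if seed in with_masks:
            mask = make_synapse_mask(marker, radius_px=2)
            tifffile.imwrite(folder / f"cell{seed}_mask.tif",
                             mask.mask.astype(np.uint8) * 255)
        paradigm = sc.paradigm
    return paradigm


class TestCollectFolder:
    def test_batch_matches_single_runs(self, tmp_path):
        seeds = (3, 4)
        paradigm = _write_cells(tmp_path, seeds)
        params = DetectionParams()
        vesicles, pools = collect_folder(tmp_path, paradigm, params)
        assert sorted(pools["cell_id"]) == [f"cell{s}" for s in seeds]
        for seed in seeds:
            sc = small_scenario(seed)
            movie, _, _ = simulate_movie(sc)
            single = analyze_cell(movie, paradigm, params, cell_id=f"cell{seed}")
            batch_rows = vesicles[vesicles["cell_id"] == f"cell{seed}"].reset_index(drop=True)
            pd.testing.assert_frame_equal(
                batch_rows, single.vesicle_table, check_dtype=False
            )
            pool_row = pools[pools["cell_id"] == f"cell{seed}"].iloc[0]
            assert pool_row["n_events"] == single.n_events == len(batch_rows)
            assert pool_row["raw_pool"] == single.pool.raw_pool

    def test_missing_mask_skips_cell_with_warning(self, tmp_path, caplog):
        paradigm = _write_cells(tmp_path, (3, 4), with_masks=(3,))
        with caplog.at_level("WARNING", logger="dcvfusion"):
            vesicles, pools = collect_folder(
                tmp_path, paradigm, DetectionParams(), synaptic=True
            )
        assert list(pools["cell_id"]) == ["cell3"]
        assert any("cell4" in rec.message for rec in caplog.records)
        assert vesicles["synaptic"].notna().all()

    def test_empty_folder_gives_empty_tables(self, tmp_path):
        paradigm = small_scenario(0).paradigm
        vesicles, pools = collect_folder(tmp_path, paradigm, DetectionParams())
        assert len(vesicles) == 0 and len(pools) == 0


def test_config_roundtrip(tmp_path):
    sc = small_scenario(0)
    params = DetectionParams(snr=80.0, cleaning_threshold_sd=4.0)
    path = tmp_path / "config.yaml"
    dump_config(sc.paradigm, params, path)
    paradigm, loaded = load_config(path)
    assert paradigm == sc.paradigm
    assert loaded.snr == 80.0
    assert loaded.cleaning_threshold_sd == 4.0
    assert loaded.normalization.baseline_frames == paradigm.baseline_frames
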