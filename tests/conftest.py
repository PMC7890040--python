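"""Session fixtures: simulated recordings shared across the suite.

Everything heavy (256 x 256 x 200 renders and their detection runs) is
computed once per session and reused by unit, property, and acceptance
tests alike.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from dcvfusion import (
    DetectionParams,
    build_events,
    detect_fusion_events,
    estimate_pool,
)
from dcvfusion.simulate import default_scenarios, simulate_movie


@pytest.fixture(scope="session")
def scenarios():
    return default_scenarios(seed=1)


def _run_detection(scenario):
    movie, truth, marker = simulate_movie(scenario)
    paradigm = scenario.paradigm
    params = DetectionParams()
    rois, traces = detect_fusion_events(movie, paradigm, params)
    events = build_events(rois, traces, paradigm)
    return {
        "scenario": scenario,
        "movie": movie,
        "truth": truth,
        "marker": marker,
        "paradigm": paradigm,
        "params": params,
        "rois": rois,
        "traces": traces,
        "events": events,
    }


@pytest.fixture(scope="session")
def clean_run(scenarios):
    return _run_detection(scenarios["clean"])


@pytest.fixture(scope="session")
def null_run(scenarios):
    return _run_detection(scenarios["null"])


@pytest.fixture(scope="session")
def pool_run(scenarios):
    run = _run_detection(scenarios["pool"])
    run["pool"] = estimate_pool(
        run["movie"], run["paradigm"], run["params"], fusion_events=run["events"]
    )
    return run


@pytest.fixture(scope="session")
def cluster_run(scenarios):
    run = _run_detection(scenarios["clustered_pool"])
    run["pool"] = estimate_pool(
        run["movie"], run["paradigm"], run["params"], fusion_events=run["events"]
    )
    return run


@pytest.fixture(scope="session")
def sweep_runs():
    """Ten seeds of a desk-scale scene for recovery statistics."""
    from dcvfusion import classify_synaptic, make_synapse_mask, release_fraction

    from helpers import match_events

    results = []
    for seed in range(10):
        sc = replace(
            default_scenarios(seed)["clean"],
            shape=(192, 192), n_vesicles=100, n_events=30, n_synapses=30,
        )
        movie, truth, marker = simulate_movie(sc)
        paradigm = sc.paradigm
        params = DetectionParams()
        rois, traces = detect_fusion_events(movie, paradigm, params)
        events = build_events(rois, traces, paradigm)
        pool = estimate_pool(movie, paradigm, params, fusion_events=events)
        mask = make_synapse_mask(marker, radius_px=2)
        classify_synaptic(events, mask)
        n_matched, errors, n_det = match_events(truth.events, rois)
        results.append(
            {
                "seed": seed,
                "truth": truth,
                "n_events_gt": len(truth.events),
                "n_vesicles": len(truth.vesicle_positions),
                "n_matched": n_matched,
                "n_detected": n_det,
                "start_errors": errors,
                "release_measured": release_fraction(len(events), pool, "puncta"),
                "release_programmed": len(truth.events) / len(truth.vesicle_positions),
                "synaptic_measured": float(np.mean([e.synaptic for e in events])),
                "synaptic_programmed": float(np.mean([e.synaptic for e in truth.events])),
            }
        )
    return results
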