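"""Structured configuration: one YAML file per experiment.

The file carries everything the analysis must not guess from image
metadata: the acquisition paradigm (frame rate, baseline window,
stimulation window, NH4Cl onset) and the detection parameters.

Example::

    paradigm:
      frame_rate_hz: 2.0
      baseline_frames: 30
      stim_start_frame: 61
      stim_len_frames: 50
      nh4_start_frame: 160
    detection:
      snr: 60
      cleaning_threshold_sd: 5.0
      roi_size_px: 3
      n_stimulations: 1
    normalization:
      method: bw_opening
      smoothing_radius_px: 1
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .detect import AcquisitionParadigm, DetectionParams
from .normalize import NormalizationParams

__all__ = ["load_config", "dump_config"]


def _pick(cls, mapping: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return {k: v for k, v in mapping.items() if k in names}


def load_config(path: str | Path) -> tuple[AcquisitionParadigm, DetectionParams]:
    """Read paradigm + detection parameters from a YAML config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "paradigm" not in raw:
        raise ValueError(f"{path}: missing required 'paradigm' section")
    paradigm = AcquisitionParadigm(**_pick(AcquisitionParadigm, raw["paradigm"]))
    norm = NormalizationParams(
        baseline_frames=paradigm.baseline_frames,
        **_pick(NormalizationParams, {k: v for k, v in raw.get("normalization", {}).items() if k != "baseline_frames"}),
    )
    det_kwargs = _pick(DetectionParams, raw.get("detection", {}))
    det_kwargs.pop("normalization", None)
    params = DetectionParams(normalization=norm, **det_kwargs)
    return paradigm, params


def dump_config(
    paradigm: AcquisitionParadigm,
    params: DetectionParams,
    path: str | Path,
) -> None:
    """Write the configuration back out (round-trips with load_config)."""
    doc = {
        "paradigm": {
            "frame_rate_hz": paradigm.frame_rate_hz,
            "baseline_frames": paradigm.baseline_frames,
            "stim_start_frame": paradigm.stim_start_frame,
            "stim_len_frames": paradigm.stim_len_frames,
            "nh4_start_frame": paradigm.nh4_start_frame,
        },
        "detection": {
            "snr": params.snr,
            "detection_threshold_sd": params.detection_threshold_sd,
            "cleaning_threshold_sd": params.cleaning_threshold_sd,
            "roi_size_px": params.roi_size_px,
            "max_overlap_px": params.max_overlap_px,
            "n_stimulations": params.n_stimulations,
        },
        "normalization": {
            "method": params.normalization.method,
            "smoothing_radius_px": params.normalization.smoothing_radius_px,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
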