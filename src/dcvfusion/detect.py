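"""Fusion-event detection on the temporal-SD projection.

The detector follows the reference workflow: candidate fusion sites are
local maxima of the per-pixel standard deviation of the (normalized)
movie over the stimulation window; a greedy overlap rule turns maxima
into non-redundant square ROIs; each ROI's event start frame is the
first frame, searched from stimulation onset up to NH4Cl onset, where
the raw-movie ROI trace exceeds a causal rolling mean plus a multiple of
the causal rolling SD.  ROIs that never cross the threshold are
discarded.

Two deliberate conventions (the reference tool leaves them open):

* The prominence ("SNR") threshold acts on the SD image min-max rescaled
  to 0-255, matching the 8-bit semantics of the original interface.
* Rolling statistics use a trailing (causal) window of ``baseline_frames``
  frames, so an event cannot inflate its own detection threshold.

Event traces are measured on the *raw* movie so that dF/F0 amplitudes
stay physically interpretable; normalization is used only to build the
localization image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .movie_io import RoiRecord, TimeLapse, extract_trace, roi_slices
from .normalize import NormalizationParams, normalize_movie

__all__ = [
    "AcquisitionParadigm",
    "DetectionParams",
    "frames_for_duration",
    "round_stim_window",
    "max_overlap_for_roi",
    "sd_projection",
    "rescale_to_255",
    "find_candidate_maxima",
    "place_rois",
    "rolling_mean_sd",
    "assign_event_start",
    "detect_fusion_events",
]


@dataclass(frozen=True)
class AcquisitionParadigm:
    """Frame bookkeeping of one recording (all frame fields 1-based).

    baseline_frames is both the length of the quiet pre-stimulation
    window used for F0 and the window size of the rolling statistics.
    """

    frame_rate_hz: float
    baseline_frames: int
    stim_start_frame: int
    stim_len_frames: int
    nh4_start_frame: int

    def __post_init__(self) -> None:
        if not self.frame_rate_hz > 0:
            raise ValueError("frame_rate_hz must be > 0")
        if self.baseline_frames < 2:
            raise ValueError("baseline_frames must be >= 2")
        if not (self.baseline_frames < self.stim_start_frame < self.nh4_start_frame):
            raise ValueError(
                "expected baseline_frames < stim_start_frame < nh4_start_frame, got "
                f"{self.baseline_frames}, {self.stim_start_frame}, {self.nh4_start_frame}"
            )
        if self.stim_len_frames < 2:
            raise ValueError("stim_len_frames must be >= 2")

    def stim_window(self) -> tuple[int, int]:
        """0-based half-open [start, stop) of the stimulation window."""
        start = self.stim_start_frame - 1
        return start, start + self.stim_len_frames

    def stim_blocks(self, n_stimulations: int) -> list[tuple[int, int]]:
        """Split the stimulation window into n equal 0-based blocks.

        The remainder goes to the last block; every block keeps >= 2
        frames so a sample SD is defined.
        """
        if n_stimulations < 1:
            raise ValueError("n_stimulations must be >= 1")
        start, stop = self.stim_window()
        total = stop - start
        if total // n_stimulations < 2:
            raise ValueError(
                f"cannot split {total} stimulation frames into {n_stimulations} blocks of >= 2 frames"
            )
        size = total // n_stimulations
        blocks = []
        for k in range(n_stimulations):
            b0 = start + k * size
            b1 = stop if k == n_stimulations - 1 else b0 + size
            blocks.append((b0, b1))
        return blocks


@dataclass(frozen=True)
class DetectionParams:
    """User-tunable thresholds of the detection algorithm.

    snr
        Prominence threshold on the 0-255 rescaled SD image.
    detection_threshold_sd
        Extra per-pixel gate used in baseline-subtraction mode only:
        candidate sites must reach mean + k*SD of the normalized movie.
    cleaning_threshold_sd
        Multiples of the rolling SD a raw ROI trace must exceed for an
        event start to be assigned; ROIs that never cross are dropped.
    max_overlap_px
        Maximum pixels two retained ROIs may share; ``None`` means the
        1/3-of-ROI-area rule (:func:`max_overlap_for_roi`).
    """

    snr: float = 60.0
    detection_threshold_sd: float = 3.0
    cleaning_threshold_sd: float = 5.0
    roi_size_px: int = 3
    max_overlap_px: int | None = None
    n_stimulations: int = 1
    normalization: NormalizationParams = field(default_factory=NormalizationParams)

    def __post_init__(self) -> None:
        if not 0 <= self.snr <= 255:
            raise ValueError("snr must be on the 0-255 scale")
        if self.roi_size_px < 1 or self.roi_size_px % 2 == 0:
            raise ValueError("roi_size_px must be odd and >= 1")
        limit = max_overlap_for_roi(self.roi_size_px)
        if self.max_overlap_px is not None and self.max_overlap_px > limit:
            raise ValueError(
                f"max_overlap_px={self.max_overlap_px} exceeds 1/3 of the ROI area ({limit})"
            )
        if self.n_stimulations < 1:
            raise ValueError("n_stimulations must be >= 1")

    def resolved_max_overlap(self) -> int:
        if self.max_overlap_px is not None:
            return self.max_overlap_px
        return max_overlap_for_roi(self.roi_size_px)


def frames_for_duration(seconds: float, frame_rate_hz: float) -> int:
    """Number of frames spanned by a duration: round(seconds * F)."""
    if seconds < 0:
        raise ValueError("duration must be >= 0")
    return int(round(seconds * frame_rate_hz))


def round_stim_window(frames: int) -> int:
    """Round a stimulation duration up to the closest multiple of 10.

    The reference paradigm rounds its 48-frame stimulation to 50, so the
    smallest multiple of 10 that still covers the stimulation is used.
    """
    if frames < 1:
        raise ValueError("frames must be >= 1")
    return int(math.ceil(frames / 10) * 10)


def max_overlap_for_roi(roi_size_px: int) -> int:
    """Maximum shared pixels between retained ROIs: floor(area / 3)."""
    if roi_size_px < 1:
        raise ValueError("roi_size_px must be >= 1")
    return (roi_size_px * roi_size_px) // 3


def sd_projection(frames: np.ndarray | TimeLapse, windows) -> np.ndarray:
    """Per-pixel sample SD (ddof=1) over one or more frame windows.

    ``windows`` is a single 0-based half-open ``(start, stop)`` pair or a
    list of them (one per stimulation block); multiple blocks are
    combined by pixel-wise maximum.
    """
    arr = frames.frames if isinstance(frames, TimeLapse) else np.asarray(frames)
    if isinstance(windows, tuple) and len(windows) == 2 and np.isscalar(windows[0]):
        windows = [windows]
    out = None
    for start, stop in windows:
        if not (0 <= start < stop <= arr.shape[0]):
            raise ValueError(f"window ({start}, {stop}) outside movie of length {arr.shape[0]}")
        if stop - start < 2:
            raise ValueError("SD window must span at least 2 frames")
        sd = arr[start:stop].std(axis=0, ddof=1, dtype=np.float64)
        out = sd if out is None else np.maximum(out, sd)
    return out


def rescale_to_255(image: np.ndarray) -> np.ndarray:
    """Min-max rescale an image to [0, 255]; a flat image maps to 0."""
    image = np.asarray(image, dtype=np.float64)
    lo = image.min()
    hi = image.max()
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) * (255.0 / (hi - lo))


def find_candidate_maxima(
    image: np.ndarray, prominence: float
) -> list[tuple[int, int, float]]:
    """Local maxima of ``image`` with topographic prominence >= threshold.

    The image is first min-max rescaled to 0-255 (8-bit "SNR"
    semantics).  Prominence of a maximum is its height above the highest
    saddle connecting it to a higher maximum (the global maximum's
    prominence is its height above the image minimum).  Plateau maxima
    collapse to their (rounded) centroid.  Results are sorted by
    descending peak height, ties broken by (row, col).

    Implemented as a persistence sweep: pixels are activated in
    descending intensity order and merged with a union-find structure;
    a component dies - and its peak's prominence is fixed - when it
    meets a component born higher.
    """
    img = rescale_to_255(image)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    n_rows, n_cols = img.shape
    if img.max() == img.min():
        return []

    flat = img.ravel()
    size = flat.size
    # Stable descending order: by value desc, then linear index asc.
    order = np.lexsort((np.arange(size), -flat))

    parent = np.full(size, -1, dtype=np.int64)  # -1 = not yet active
    birth = np.zeros(size, dtype=np.float64)  # per-root peak height
    # Per-root plateau accumulator for the birth centroid.
    acc_r = np.zeros(size, dtype=np.float64)
    acc_c = np.zeros(size, dtype=np.float64)
    acc_n = np.zeros(size, dtype=np.int64)
    # Per-root representative pixel (lexicographic min) for tie-breaks.
    rep = np.zeros(size, dtype=np.int64)

    peaks: list[tuple[float, float, float, float]] = []  # (birth, prom, r, c)

    def find(a: int) -> int:
        root = a
        while parent[root] != root:
            root = parent[root]
        while parent[a] != root:
            parent[a], a = root, parent[a]
        return root

    def record_death(root: int, level: float) -> None:
        prom = birth[root] - level
        if prom > 0:
            peaks.append(
                (birth[root], prom, acc_r[root] / acc_n[root], acc_c[root] / acc_n[root])
            )

    def union(a: int, b: int, level: float) -> None:
        ra, rb = find(a), find(b)
        if ra == rb:
            return
        if birth[ra] == birth[rb] == level:
            # Two pieces of one plateau born this sweep: merge centroids.
            keep, drop = (ra, rb) if rep[ra] <= rep[rb] else (rb, ra)
            acc_r[keep] += acc_r[drop]
            acc_c[keep] += acc_c[drop]
            acc_n[keep] += acc_n[drop]
            parent[drop] = keep
            return
        if birth[ra] > birth[rb] or (birth[ra] == birth[rb] and rep[ra] <= rep[rb]):
            keep, drop = ra, rb
        else:
            keep, drop = rb, ra
        record_death(drop, level)
        parent[drop] = keep

    neighbor_steps = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]

    i = 0
    while i < size:
        v = flat[order[i]]
        j = i
        while j < size and flat[order[j]] == v:
            j += 1
        batch = order[i:j]
        for p in batch:
            parent[p] = p
            birth[p] = v
            r, c = divmod(int(p), n_cols)
            acc_r[p] = r
            acc_c[p] = c
            acc_n[p] = 1
            rep[p] = p
        for p in batch:
            r, c = divmod(int(p), n_cols)
            for dr, dc in neighbor_steps:
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols:
                    q = rr * n_cols + cc
                    if parent[q] != -1:
                        union(int(p), q, v)
        i = j

    # Surviving roots (one per connected image region) die at the floor.
    roots = {int(r) for r in np.flatnonzero(parent == np.arange(size))}
    for root in roots:
        record_death(int(root), img.min())

    selected = [
        (int(round(r)), int(round(c)), float(b))
        for (b, prom, r, c) in peaks
        if prom >= prominence
    ]
    selected.sort(key=lambda t: (-t[2], t[0], t[1]))
    return selected


def _roi_overlap_px(
    a: tuple[int, int], b: tuple[int, int], size_px: int, image_shape: tuple[int, int]
) -> int:
    """Shared pixels between two clipped square ROIs."""
    half = size_px // 2

    def interval(center: int, limit: int) -> tuple[int, int]:
        return max(center - half, 0), min(center + half + 1, limit)

    ar = interval(a[0], image_shape[0])
    br = interval(b[0], image_shape[0])
    ac = interval(a[1], image_shape[1])
    bc = interval(b[1], image_shape[1])
    dr = min(ar[1], br[1]) - max(ar[0], br[0])
    dc = min(ac[1], bc[1]) - max(ac[0], bc[0])
    return max(dr, 0) * max(dc, 0)


def place_rois(
    maxima: list[tuple[int, int, float]],
    roi_size_px: int,
    max_overlap_px: int,
    image_shape: tuple[int, int],
) -> list[RoiRecord]:
    """Greedy non-redundant ROI placement in descending score order.

    A candidate is rejected if its square ROI shares more than
    ``max_overlap_px`` pixels with any already-accepted ROI.  Accepted
    ROIs are numbered "0000", "0001", ... in acceptance order; the event
    start frame is a placeholder (1) until trace analysis assigns it.
    """
    if roi_size_px > min(image_shape):
        raise ValueError(f"ROI size {roi_size_px} larger than image {image_shape}")
    accepted: list[tuple[int, int]] = []
    rois: list[RoiRecord] = []
    for row, col, _score in maxima:
        center = (int(row), int(col))
        if any(
            _roi_overlap_px(center, prev, roi_size_px, image_shape) > max_overlap_px
            for prev in accepted
        ):
            continue
        accepted.append(center)
        rois.append(
            RoiRecord(
                roi_id=f"{len(rois):04d}",
                center_row=center[0],
                center_col=center[1],
                size_px=roi_size_px,
                event_start_frame=1,
            )
        )
    return rois


def rolling_mean_sd(trace: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Trailing rolling mean and sample SD (ddof=1) of a 1-D trace.

    Entry ``f`` summarizes ``trace[f - window + 1 : f + 1]``; entries
    with an incomplete window are NaN.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if window < 2:
        raise ValueError("window must be >= 2")
    if window > trace.size:
        raise ValueError("window longer than trace")
    s = pd.Series(trace)
    means = s.rolling(window).mean().to_numpy()
    sds = s.rolling(window).std(ddof=1).to_numpy()
    return means, sds


def assign_event_start(
    trace: np.ndarray,
    paradigm: AcquisitionParadigm,
    cleaning_threshold_sd: float,
    baseline_frames: int | None = None,
) -> int | None:
    """First threshold-crossing frame of a raw ROI trace (1-based).

    The event start is the first frame ``f`` in
    ``[stim_start, nh4_start)`` with
    ``trace[f] > rolling_mean[f-1] + k * rolling_SD[f-1]``, where the
    rolling statistics use a trailing window of ``baseline_frames``.
    Returns ``None`` when the trace never crosses (the ROI is then
    discarded by the caller).
    """
    trace = np.asarray(trace, dtype=np.float64)
    window = paradigm.baseline_frames if baseline_frames is None else baseline_frames
    means, sds = rolling_mean_sd(trace, window)
    start0 = paradigm.stim_start_frame - 1
    stop0 = min(paradigm.nh4_start_frame - 1, trace.size)
    if start0 < window:
        raise ValueError(
            "rolling window does not fit before the stimulation window "
            f"(window={window}, stim_start_frame={paradigm.stim_start_frame})"
        )
    for f in range(start0, stop0):
        threshold = means[f - 1] + cleaning_threshold_sd * sds[f - 1]
        if np.isfinite(threshold) and trace[f] > threshold:
            return f + 1  # back to 1-based
    return None


def detect_fusion_events(
    movie: TimeLapse,
    paradigm: AcquisitionParadigm,
    params: DetectionParams,
) -> tuple[list[RoiRecord], pd.DataFrame]:
    """Run the full detection pipeline on one movie.

    normalize -> SD projection over the stimulation block(s) ->
    prominence maxima -> greedy ROI placement -> raw-movie traces ->
    rolling-threshold event starts.  ROIs without a start frame are
    dropped; the survivors are renumbered "0000", "0001", ... in
    acceptance order.  Deterministic for a fixed input.

    Returns the retained ROIs and the trace table (one column per
    retained ROI, labelled ``ROIID-EventStart``; one row per frame).
    """
    normalized = normalize_movie(movie, params.normalization)
    blocks = paradigm.stim_blocks(params.n_stimulations)
    sd_image = sd_projection(normalized.frames, blocks)
    maxima = find_candidate_maxima(sd_image, params.snr)

    if params.normalization.method == "baseline_subtraction":
        # Conjunctive per-pixel gate: the normalized movie must reach
        # mean + k*SD (global statistics) somewhere in time at the site.
        norm = normalized.frames
        gate = norm.mean() + params.detection_threshold_sd * norm.std()
        peak_img = norm.max(axis=0)
        maxima = [m for m in maxima if peak_img[m[0], m[1]] > gate]

    candidates = place_rois(
        maxima, params.roi_size_px, params.resolved_max_overlap(), movie.frame_shape
    )

    raw = movie.frames
    kept: list[RoiRecord] = []
    traces: dict[str, np.ndarray] = {}
    for roi in candidates:
        trace = extract_trace(raw, roi)
        start = assign_event_start(
            trace, paradigm, params.cleaning_threshold_sd, paradigm.baseline_frames
        )
        if start is None:
            continue
        final = RoiRecord(
            roi_id=f"{len(kept):04d}",
            center_row=roi.center_row,
            center_col=roi.center_col,
            size_px=roi.size_px,
            event_start_frame=start,
        )
        kept.append(final)
        traces[final.label] = trace

    trace_table = pd.DataFrame(traces)
    return kept, trace_table
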