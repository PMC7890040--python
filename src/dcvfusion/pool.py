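"""Total labeled-DCV pool estimation from the NH4Cl dequenching window.

NH4Cl neutralizes the vesicle lumen and dequenches every pHluorin
molecule, so the maximum-intensity projection of the NH4 window (after
subtracting the pre-NH4 baseline) shows the entire labeled pool.  Three
estimates are reported per cell:

``raw_pool``
    Number of prominence maxima counted on the projection.  Undercounts
    when several vesicles share one punctum.
``fused_corrected``
    Total above-background projection intensity divided by the mean
    integrated intensity of the detected fusion events - appropriate
    when single fusion events are as bright as single resting vesicles.
``puncta_corrected``
    Total above-background projection intensity divided by the median
    integrated intensity of isolated single puncta (puncta within +/-50%
    of the modal punctum intensity) - appropriate when fusion events
    are dimmer than resting puncta.

The workflow names the three corrections without formulas; the
intensity-unit normalizations above are this package's reconstruction
and each lives in its own function so alternates can be swapped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .detect import (
    AcquisitionParadigm,
    DetectionParams,
    find_candidate_maxima,
    rescale_to_255,
)
from .events import FusionEvent
from .movie_io import TimeLapse, _square_slices
from .synapse import triangle_threshold_255

__all__ = [
    "PoolEstimate",
    "nh4_max_projection",
    "auto_snr_from_nh4",
    "estimate_pool",
    "release_fraction",
    "soma_mask_from_projection",
    "count_saturated_pixels",
]


@dataclass(frozen=True)
class PoolEstimate:
    """The three total-pool estimates for one cell."""

    raw_pool: int
    fused_corrected: float
    puncta_corrected: float
    n_saturated_px: int = 0
    punctum_unit_intensity: float = math.nan  # median isolated-punctum integral
    punctum_peak_height: float = math.nan  # median punctum peak, raw counts
    total_intensity: float = math.nan
    soma_mask: np.ndarray | None = field(default=None, repr=False)

    def get(self, which: str) -> float:
        key = {"raw": "raw_pool", "fused": "fused_corrected", "puncta": "puncta_corrected"}
        if which not in key:
            raise ValueError(f"unknown pool estimate {which!r}; expected raw/fused/puncta")
        return float(getattr(self, key[which]))


def nh4_max_projection(
    movie: TimeLapse, paradigm: AcquisitionParadigm, rescale: bool = True
) -> np.ndarray:
    """Baseline-subtracted maximum projection of the NH4 window.

    Per-pixel maximum over frames >= ``nh4_start_frame`` minus the
    per-pixel mean of the pre-NH4 baseline window; min-max rescaled to
    0-255 unless ``rescale=False`` (raw counts are needed for the
    intensity-unit corrections).
    """
    nh4_0 = paradigm.nh4_start_frame - 1
    if nh4_0 >= movie.n_frames:
        raise ValueError(
            f"empty NH4 window: nh4_start_frame={paradigm.nh4_start_frame}, "
            f"movie has {movie.n_frames} frames"
        )
    frames = movie.frames.astype(np.float64, copy=False)
    baseline = frames[: paradigm.baseline_frames].mean(axis=0)
    projection = frames[nh4_0:].max(axis=0) - baseline
    return rescale_to_255(projection) if rescale else projection


def auto_snr_from_nh4(projection: np.ndarray) -> float:
    """Automatic prominence from the NH4 projection (used when SNR=0).

    Background pixels are those below the projection's Triangle
    threshold; the prominence is their mean + 3*SD, on the projection's
    own (0-255) scale.  When the Triangle split does not isolate a
    clear background (fewer than half the pixels below it, as happens
    on a projection without real puncta) the statistics fall back to
    the whole image.  This mean+k*SD rule is a documented heuristic,
    floored at 1 so the returned prominence is always usable.
    """
    projection = np.asarray(projection, dtype=np.float64)
    if projection.max() == projection.min():
        raise ValueError("cannot derive an SNR from a flat projection")
    thr = triangle_threshold_255(projection)
    scaled = rescale_to_255(projection)
    background = scaled[scaled <= thr]
    if background.size < 0.5 * scaled.size:
        background = scaled.ravel()
    return float(max(background.mean() + 3.0 * background.std(ddof=1), 1.0))


def soma_mask_from_projection(projection_255: np.ndarray, dilation_px: int = 3) -> np.ndarray:
    """Soma proxy: largest connected component above the Triangle
    threshold of the NH4 projection, dilated.  Used only for the
    saturation QC."""
    thr = triangle_threshold_255(projection_255)
    fg = projection_255 > thr
    labels, n = ndimage.label(fg)
    if n == 0:
        return np.zeros(projection_255.shape, dtype=bool)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = labels == (int(np.argmax(sizes)) + 1)
    return ndimage.binary_dilation(largest, iterations=dilation_px)


def soma_mask_from_baseline(movie: TimeLapse, paradigm: AcquisitionParadigm,
                            dilation_px: int = 3) -> np.ndarray:
    """Soma proxy from the pre-stimulation image, for the saturation QC.

    The NH4 projection cannot serve here: a saturated patch would
    dominate its intensity scale and corrupt the mask.  The soma is the
    brightest baseline structure, so the proxy is the largest connected
    component above the midpoint between the median and the maximum of
    the smoothed baseline mean image.
    """
    base = movie.frames[: paradigm.baseline_frames].mean(axis=0, dtype=np.float64)
    smooth = ndimage.gaussian_filter(base, 2.0)
    thr = 0.5 * (np.median(smooth) + smooth.max())
    fg = smooth > thr
    labels, n = ndimage.label(fg)
    if n == 0:
        return np.zeros(base.shape, dtype=bool)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = labels == (int(np.argmax(sizes)) + 1)
    return ndimage.binary_dilation(largest, iterations=dilation_px)


def count_saturated_pixels(
    movie: TimeLapse, paradigm: AcquisitionParadigm, soma_mask: np.ndarray | None
) -> int:
    """Pixels at the bit-depth maximum during the NH4 window, outside
    the soma.  Any such pixel triggers the saturation QC exclusion.

    Float movies carry no bit depth; they report 0 saturated pixels.
    """
    dtype = movie.frames.dtype
    if not np.issubdtype(dtype, np.integer):
        return 0
    level = np.iinfo(dtype).max
    nh4 = movie.frames[paradigm.nh4_start_frame - 1 :]
    saturated = (nh4 == level).any(axis=0)
    if soma_mask is not None:
        saturated = saturated & ~np.asarray(soma_mask, dtype=bool)
    return int(saturated.sum())


def _integrated_intensity(
    image: np.ndarray,
    center: tuple[int, int],
    window_px: int,
    include: np.ndarray | None = None,
) -> float:
    rs, cs = _square_slices(center[0], center[1], window_px, image.shape)
    patch = image[rs, cs]
    if include is not None:
        patch = patch[include[rs, cs]]
    return float(patch.sum())


def _modal_intensity(units: np.ndarray) -> float:
    """Mode of the punctum-intensity distribution (peak histogram bin)."""
    units = np.asarray(units, dtype=np.float64)
    if units.size == 1:
        return float(units[0])
    n_bins = max(10, int(math.sqrt(units.size)))
    counts, edges = np.histogram(units, bins=n_bins)
    k = int(np.argmax(counts))
    return float(0.5 * (edges[k] + edges[k + 1]))


def _event_integrated_intensities(
    movie: TimeLapse,
    paradigm: AcquisitionParadigm,
    events: list[FusionEvent],
    window_px: int,
) -> np.ndarray:
    """Integrated dF of each fusion event at its peak frame, in raw
    counts over the same window size used for NH4 puncta."""
    frames = movie.frames.astype(np.float64, copy=False)
    baseline = frames[: paradigm.baseline_frames].mean(axis=0)
    units = []
    for e in events:
        if not e.valid:
            continue
        start0 = e.start_frame - 1
        stop0 = min(start0 + e.duration_frames, movie.n_frames)
        rs, cs = _square_slices(e.roi.center_row, e.roi.center_col, e.roi.size_px, movie.frame_shape)
        roi_trace = frames[start0:stop0, rs, cs].mean(axis=(1, 2))
        peak0 = start0 + int(np.argmax(roi_trace))
        diff = frames[peak0] - baseline
        # re-center on the local dF maximum: the detection ROI may sit a
        # pixel off the true punctum center, which would bias the integral
        nrs, ncs = _square_slices(e.roi.center_row, e.roi.center_col, 5, diff.shape)
        local = diff[nrs, ncs]
        dr, dc = np.unravel_index(int(np.argmax(local)), local.shape)
        center = (nrs.start + int(dr), ncs.start + int(dc))
        units.append(_integrated_intensity(diff, center, window_px))
    return np.asarray(units, dtype=np.float64)


def estimate_pool(
    movie: TimeLapse,
    paradigm: AcquisitionParadigm,
    params: DetectionParams,
    fusion_events: list[FusionEvent] | None = None,
    punctum_window_px: int = 7,
) -> PoolEstimate:
    """Estimate the labeled-DCV pool of one cell (three estimates).

    ``params.snr`` > 0 is used as the counting prominence; 0 switches to
    the automatic NH4-based prominence.  ``fusion_events`` (from
    :func:`dcvfusion.events.build_events`) are needed for the
    fused-corrected estimate; without events it is NaN.

    The soma region (largest dequenching component) is excluded from
    punctum counting and from the integrated intensity: its diffuse
    somatic response contains no resolvable single vesicles and would
    otherwise inflate every estimate.
    """
    proj_raw = nh4_max_projection(movie, paradigm, rescale=False)
    if proj_raw.max() == proj_raw.min():
        return PoolEstimate(
            raw_pool=0, fused_corrected=math.nan, puncta_corrected=math.nan,
            n_saturated_px=count_saturated_pixels(
                movie, paradigm, soma_mask_from_baseline(movie, paradigm)
            ),
        )
    proj255 = rescale_to_255(proj_raw)
    prominence = params.snr if params.snr > 0 else auto_snr_from_nh4(proj255)
    soma = soma_mask_from_projection(proj255)
    n_saturated = count_saturated_pixels(
        movie, paradigm, soma_mask_from_baseline(movie, paradigm)
    )

    maxima = [m for m in find_candidate_maxima(proj255, prominence) if not soma[m[0], m[1]]]
    raw_pool = len(maxima)

    if raw_pool == 0:
        return PoolEstimate(
            raw_pool=0, fused_corrected=math.nan, puncta_corrected=math.nan,
            n_saturated_px=n_saturated, soma_mask=soma,
        )

    thr = triangle_threshold_255(proj_raw)
    above = (proj255 > thr) & ~soma
    # "above background": remove the background level of the projection
    # (it carries the positive bias of a maximum over noisy frames)
    background = proj_raw[~(proj255 > thr) & ~soma]
    work = proj_raw - (float(background.mean()) if background.size else 0.0)
    total = float(work[above].sum())

    units = np.asarray(
        [_integrated_intensity(work, (r, c), punctum_window_px, include=above) for r, c, _ in maxima]
    )
    peaks = np.asarray([proj_raw[r, c] for r, c, _ in maxima])
    mode = _modal_intensity(units)
    singles = units[(units >= 0.5 * mode) & (units <= 1.5 * mode)]
    puncta_corrected = total / float(np.median(singles)) if singles.size else math.nan

    fused_corrected = math.nan
    if fusion_events:
        event_units = _event_integrated_intensities(movie, paradigm, fusion_events, punctum_window_px)
        if event_units.size and event_units.mean() > 0:
            fused_corrected = total / float(event_units.mean())

    return PoolEstimate(
        raw_pool=raw_pool,
        fused_corrected=fused_corrected,
        puncta_corrected=puncta_corrected,
        n_saturated_px=n_saturated,
        punctum_unit_intensity=float(np.median(singles)) if singles.size else math.nan,
        punctum_peak_height=float(np.median(peaks)),
        total_intensity=total,
        soma_mask=soma,
    )


def release_fraction(n_events: int, pool_estimate: PoolEstimate, which: str = "raw") -> float:
    """Fraction of the labeled pool released: n_events / pool."""
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    pool = pool_estimate.get(which)
    if not pool > 0:
        raise ValueError(f"pool estimate {which!r} is not positive ({pool})")
    return n_events / pool
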