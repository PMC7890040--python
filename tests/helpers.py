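"""Shared test utilities: brute-force oracles and ground-truth matching.

Every oracle here is deliberately independent of the package
implementation path it checks: direct neighborhood loops, explicit
kernels, exhaustive scans, and flood-fill region growth.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import ndimage

from dcvfusion.simulate import SimulationScenario, default_scenarios


# ---------------------------------------------------------------------------
# simulator helpers

def small_scenario(seed: int = 0, **overrides) -> SimulationScenario:
    """A quick desk-size scene for folder/batch tests."""
    base = default_scenarios(seed)["clean"]
    defaults = dict(
        shape=(96, 96), n_vesicles=25, n_events=8, n_synapses=12,
        soma_radius_px=8,
    )
    defaults.update(overrides)
    return replace(base, **defaults)


def match_events(truth_events, rois, tol_px: float = 2.0):
    """Greedy nearest matching of ground-truth events to detected ROIs.

    Returns (n_matched, start_frame_errors, n_detected).
    """
    used: set[int] = set()
    errors = []
    det = [(r.center_row, r.center_col, r.event_start_frame) for r in rois]
    for ev in truth_events:
        best = None
        for i, (dr, dc, ds) in enumerate(det):
            if i in used:
                continue
            d = np.hypot(ev.row - dr, ev.col - dc)
            if d <= tol_px and (best is None or d < best[0]):
                best = (d, i, ds)
        if best is not None:
            used.add(best[1])
            errors.append(abs(best[2] - ev.start_frame))
    return len(used), np.asarray(errors), len(det)


# ---------------------------------------------------------------------------
# brute-force oracles

def bw_open_oracle(frame: np.ndarray, radius: int) -> np.ndarray:
    """Direct evaluation of max -> min -> unit-sum Gaussian with reflect
    borders (np.pad 'symmetric' == scipy 'reflect')."""
    frame = np.asarray(frame, dtype=np.float64)

    def rank_filter(img, func):
        padded = np.pad(img, radius, mode="symmetric")
        out = np.empty_like(img)
        for r in range(img.shape[0]):
            for c in range(img.shape[1]):
                out[r, c] = func(padded[r : r + 2 * radius + 1, c : c + 2 * radius + 1])
        return out

    out = rank_filter(frame, np.max)
    out = rank_filter(out, np.min)

    sigma = float(radius)
    kr = int(4.0 * sigma + 0.5)  # scipy's default truncation
    x = np.arange(-kr, kr + 1, dtype=np.float64)
    k1 = np.exp(-0.5 * x**2 / sigma**2)
    k1 /= k1.sum()
    kernel = np.outer(k1, k1)
    padded = np.pad(out, kr, mode="symmetric")
    blurred = np.empty_like(out)
    for r in range(out.shape[0]):
        for c in range(out.shape[1]):
            blurred[r, c] = (padded[r : r + 2 * kr + 1, c : c + 2 * kr + 1] * kernel).sum()
    return blurred


def sd_projection_oracle(frames: np.ndarray, start: int, stop: int) -> np.ndarray:
    """Two-pass per-pixel sample SD, explicit loops."""
    frames = np.asarray(frames, dtype=np.float64)
    n = stop - start
    out = np.empty(frames.shape[1:])
    for r in range(frames.shape[1]):
        for c in range(frames.shape[2]):
            x = frames[start:stop, r, c]
            m = x.sum() / n
            out[r, c] = np.sqrt(((x - m) ** 2).sum() / (n - 1))
    return out


def prominence_oracle(image: np.ndarray) -> list[tuple[int, int, float, float]]:
    """Exhaustive flood-fill prominence of every local maximum.

    Works on images with pairwise-distinct values (no plateaus) after
    the same 0-255 min-max rescale the implementation uses.  Returns
    (row, col, height, prominence).
    """
    img = np.asarray(image, dtype=np.float64)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return []
    img = (img - lo) * (255.0 / (hi - lo))
    n_rows, n_cols = img.shape

    def neighbors(r, c):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols:
                    yield rr, cc

    maxima = [
        (r, c)
        for r in range(n_rows)
        for c in range(n_cols)
        if all(img[r, c] > img[rr, cc] for rr, cc in neighbors(r, c))
    ]
    levels = np.unique(img)[::-1]
    results = []
    for r, c in maxima:
        h = img[r, c]
        prom = h - img.min()  # default: no higher maximum reachable
        for v in levels:
            if v >= h:
                continue
            # connected component of img >= v containing (r, c)
            mask = img >= v
            labels, _ = ndimage.label(mask, structure=np.ones((3, 3)))
            comp = labels == labels[r, c]
            if img[comp].max() > h:
                prom = h - v
                break
        results.append((r, c, float(h), float(prom)))
    return results


def triangle_oracle(image: np.ndarray, nbins: int = 256) -> float:
    """Geometric triangle rule on the 0-255 rescaled histogram.

    A line is drawn from the histogram peak to the far end of the longer
    tail; the threshold is the bin maximizing the perpendicular distance
    to that line.
    """
    img = np.asarray(image, dtype=np.float64)
    lo, hi = img.min(), img.max()
    scaled = (img - lo) * (255.0 / (hi - lo))
    hist, edges = np.histogram(scaled.ravel(), bins=nbins, range=(0.0, 255.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak = int(np.argmax(hist))
    nz = np.flatnonzero(hist)
    low, high = int(nz[0]), int(nz[-1])
    if peak - low >= high - peak:  # longer tail on the left
        xs = np.arange(low, peak + 1)
    else:
        xs = np.arange(peak, high + 1)
    x0, y0 = xs[0], hist[xs[0]]
    x1, y1 = xs[-1], hist[xs[-1]]
    # ensure the line runs peak -> tail end
    if hist[xs[0]] < hist[xs[-1]]:
        (x0, y0), (x1, y1) = (x1, y1), (x0, y0)
    norm = np.hypot(x1 - x0, float(y1 - y0))
    dists = np.abs((x1 - x0) * (y0 - hist[xs]) - (x0 - xs) * (y1 - y0)) / norm
    best = xs[int(np.argmax(dists))]
    return float(centers[best])


def distance_oracle(point: tuple[float, float], mask: np.ndarray) -> float:
    """Minimum distance to foreground by scanning every pixel."""
    best = np.inf
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c]:
                best = min(best, np.hypot(r - point[0], c - point[1]))
    return float(best)
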