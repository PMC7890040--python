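"""Image-stack and tabular I/O for the fusion-detection workflow.

All user-facing frame indices (event start frames, trace tables) are
1-based, matching the ``(FusionStart - 1) / F`` timing convention of the
analysis; in-memory arrays are 0-based.  The conversion happens only at
this I/O boundary.

Pixel coordinates are ``(row, col)``, 0-based, origin top-left.  A square
ROI of side ``s`` centered at ``(r, c)`` spans the half-open square
``[r - s//2, r + s//2 + 1) x [c - s//2, c + s//2 + 1)``, clipped at the
image borders.

The movie frame rate always comes from the experiment configuration,
never from TIFF metadata (metadata dialects are unreliable across
acquisition software).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "TimeLapse",
    "RoiRecord",
    "ROI_LABEL_RE",
    "read_stack",
    "write_stack",
    "roi_slices",
    "roi_pixels",
    "extract_trace",
    "write_trace_table",
    "read_trace_table",
    "write_roi_set",
    "read_roi_set",
]

#: ROI labels follow ``ROIID-EventStart``: a 4-digit zero-padded
#: identifier starting at "0000", a dash, and the 1-based start frame.
ROI_LABEL_RE = re.compile(r"^(\d{4})-(\d+)$")


@dataclass(frozen=True, eq=False)
class TimeLapse:
    """An ordered stack of 2-D intensity frames.

    Parameters
    ----------
    frames
        Array of shape ``(time, row, col)`` with non-negative real or
        integer intensities (normalized movies may go negative; raw
        acquisitions do not).
    frame_rate_hz
        Acquisitions per second (the imaging frequency ``F``).
    pixel_size_um
        Optional microns per pixel.
    """

    frames: np.ndarray
    frame_rate_hz: float
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (time, row, col), got ndim={frames.ndim}")
        if frames.shape[0] < 2:
            raise ValueError("not a time series: need at least 2 frames")
        if not self.frame_rate_hz > 0:
            raise ValueError("frame_rate_hz must be > 0")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def with_frames(self, frames: np.ndarray) -> "TimeLapse":
        """A copy of this movie with ``frames`` replaced (rate kept)."""
        return replace(self, frames=frames)


@dataclass(frozen=True)
class RoiRecord:
    """One detection ROI: a square region plus its event start frame."""

    roi_id: str
    center_row: int
    center_col: int
    size_px: int
    event_start_frame: int  # 1-based (FusionStart)

    def __post_init__(self) -> None:
        if not re.fullmatch(r"\d{4}", self.roi_id):
            raise ValueError(f"roi_id must be exactly 4 digits, got {self.roi_id!r}")
        if self.size_px < 1 or self.size_px % 2 == 0:
            raise ValueError(f"size_px must be odd and >= 1, got {self.size_px}")
        if self.event_start_frame < 1:
            raise ValueError("event_start_frame is 1-based and must be >= 1")

    @property
    def label(self) -> str:
        """The ``ROIID-EventStart`` label, e.g. ``"0000-35"``."""
        return f"{self.roi_id}-{self.event_start_frame}"

    @property
    def center(self) -> tuple[int, int]:
        return (self.center_row, self.center_col)

    @classmethod
    def parse_label(cls, label: str) -> tuple[str, int]:
        m = ROI_LABEL_RE.match(label)
        if m is None:
            raise ValueError(f"malformed ROI label {label!r}; expected ROIID-EventStart")
        return m.group(1), int(m.group(2))


def read_stack(path: str | Path, frame_rate_hz: float, pixel_size_um: float | None = None) -> TimeLapse:
    """Read a multi-page grayscale TIFF as a :class:`TimeLapse`.

    ``frame_rate_hz`` must come from the acquisition configuration; it is
    deliberately never read from TIFF metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frames = tifffile.imread(path)
    frames = np.asarray(frames)
    if frames.ndim == 2:
        raise ValueError(f"{path} is not a time series (single page)")
    if frames.ndim != 3:
        raise ValueError(f"{path}: expected a single-channel T x H x W stack, got shape {frames.shape}")
    return TimeLapse(frames=frames, frame_rate_hz=frame_rate_hz, pixel_size_um=pixel_size_um)


def write_stack(movie: TimeLapse | np.ndarray, path: str | Path) -> None:
    """Write a movie (or bare 3-D array) as a multi-page TIFF."""
    frames = movie.frames if isinstance(movie, TimeLapse) else np.asarray(movie)
    tifffile.imwrite(Path(path), frames, photometric="minisblack")


def roi_slices(roi: RoiRecord, image_shape: tuple[int, int]) -> tuple[slice, slice]:
    """Row/col slices of the ROI square, clipped at the image borders."""
    return _square_slices(roi.center_row, roi.center_col, roi.size_px, image_shape)


def _square_slices(row: int, col: int, size_px: int, image_shape: tuple[int, int]) -> tuple[slice, slice]:
    half = size_px // 2
    r0 = max(row - half, 0)
    r1 = min(row + half + 1, image_shape[0])
    c0 = max(col - half, 0)
    c1 = min(col + half + 1, image_shape[1])
    return slice(r0, r1), slice(c0, c1)


def roi_pixels(roi: RoiRecord, image_shape: tuple[int, int]) -> int:
    """Number of in-image pixels covered by the (clipped) ROI."""
    rs, cs = roi_slices(roi, image_shape)
    return max(rs.stop - rs.start, 0) * max(cs.stop - cs.start, 0)


def extract_trace(frames: np.ndarray, roi: RoiRecord) -> np.ndarray:
    """Mean intensity of the ROI per frame (float64, length T)."""
    rs, cs = roi_slices(roi, frames.shape[1:])
    if (rs.stop - rs.start) <= 0 or (cs.stop - cs.start) <= 0:
        raise ValueError(f"ROI {roi.label} lies outside the image")
    return frames[:, rs, cs].mean(axis=(1, 2), dtype=np.float64)


def write_trace_table(traces: "pd.DataFrame | dict[str, np.ndarray]", path: str | Path) -> None:
    """Write ROI traces as CSV: one column per ROI, one row per frame.

    The first column ``frame`` holds the 1-based frame index; the
    remaining column headers are the ROI labels.
    """
    if not isinstance(traces, pd.DataFrame):
        lengths = {k: len(np.asarray(v)) for k, v in traces.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"unequal trace lengths: {lengths}")
        traces = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in traces.items()})
    df = traces.copy()
    df.insert(0, "frame", np.arange(1, len(df) + 1))
    df.to_csv(Path(path), index=False, float_format="%.6f")


def read_trace_table(path: str | Path) -> pd.DataFrame:
    """Read a trace CSV back; columns are ROI labels, index is dropped."""
    df = pd.read_csv(Path(path))
    if "frame" in df.columns:
        df = df.drop(columns=["frame"])
    return df


def write_roi_set(rois: list[RoiRecord], path: str | Path) -> None:
    """Write ROI records as CSV (label, centers, size, start frame)."""
    rows = [
        {
            "label": r.label,
            "roi_id": r.roi_id,
            "event_start_frame": r.event_start_frame,
            "center_row": r.center_row,
            "center_col": r.center_col,
            "size_px": r.size_px,
        }
        for r in rois
    ]
    pd.DataFrame(
        rows,
        columns=["label", "roi_id", "event_start_frame", "center_row", "center_col", "size_px"],
    ).to_csv(Path(path), index=False)


def read_roi_set(path: str | Path) -> list[RoiRecord]:
    """Read an ROI CSV written by :func:`write_roi_set` (lossless)."""
    df = pd.read_csv(Path(path), dtype={"roi_id": str})
    rois = []
    for row in df.itertuples(index=False):
        roi_id, start = RoiRecord.parse_label(str(row.label))
        rec = RoiRecord(
            roi_id=roi_id,
            center_row=int(row.center_row),
            center_col=int(row.center_col),
            size_px=int(row.size_px),
            event_start_frame=start,
        )
        if "roi_id" in df.columns and str(row.roi_id) != rec.roi_id:
            raise ValueError(f"inconsistent roi_id {row.roi_id!r} for label {row.label!r}")
        rois.append(rec)
    return rois
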