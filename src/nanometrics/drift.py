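"""Blind lateral drift estimation and removal for localization tables.

Long dSTORM acquisitions (tens of thousands of frames) accumulate nm-scale
mechanical and thermal stage drift.  With no fiducial markers, drift can be
estimated blindly from the data itself: the frame stack is split into
temporal bins, each bin is rendered as a superresolution image, and the
lateral shift of every bin relative to the first is read off the peak of
the image cross-correlation, refined to sub-pixel accuracy by a parabolic
fit.  Piecewise-linear interpolation between bin centers gives a per-frame
shift that is subtracted from every event.

Bins hold equal event counts (not equal frame spans), which keeps the
correlation signal stable when blinking density varies over the
acquisition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from nanometrics.loc_io import DEFAULT_PIXEL_SIZE_NM, LocalizationTable, render_image

__all__ = ["DriftTrace", "estimate_drift", "correct_drift"]


@dataclass
class DriftTrace:
    """Per-bin drift shifts and the interpolated per-frame trajectory.

    Shifts are relative to the first (reference) bin, whose shift is
    (0, 0) by construction.  Between bin centers the per-frame shift is
    piecewise linear; beyond the first/last bin center it is constant.
    """

    bin_frame_ranges: list[tuple[int, int]]
    bin_center_frames: np.ndarray
    shifts_nm: np.ndarray  # (n_bins, 2) as (dx, dy)
    peak_correlations: np.ndarray
    frame_range: tuple[int, int]

    def __post_init__(self) -> None:
        self.bin_center_frames = np.asarray(self.bin_center_frames, dtype=float)
        self.shifts_nm = np.asarray(self.shifts_nm, dtype=float)
        if not np.allclose(self.shifts_nm[0], 0.0):
            raise ValueError("reference-bin shift must be (0, 0)")

    def shift_at(self, frames: np.ndarray) -> np.ndarray:
        """Interpolated (dx, dy) in nm for each frame index."""
        frames = np.asarray(frames, dtype=float)
        dx = np.interp(frames, self.bin_center_frames, self.shifts_nm[:, 0])
        dy = np.interp(frames, self.bin_center_frames, self.shifts_nm[:, 1])
        return np.column_stack([dx, dy])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "bin_frame_ranges": [list(r) for r in self.bin_frame_ranges],
                    "bin_center_frames": self.bin_center_frames.tolist(),
                    "shifts_nm": self.shifts_nm.tolist(),
                    "peak_correlations": np.asarray(
                        self.peak_correlations
                    ).tolist(),
                    "frame_range": list(self.frame_range),
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "DriftTrace":
        d = json.loads(Path(path).read_text())
        return cls(
            bin_frame_ranges=[tuple(r) for r in d["bin_frame_ranges"]],
            bin_center_frames=np.asarray(d["bin_center_frames"]),
            shifts_nm=np.asarray(d["shifts_nm"]),
            peak_correlations=np.asarray(d["peak_correlations"]),
            frame_range=tuple(d["frame_range"]),
        )


def _subpixel_peak(corr: np.ndarray) -> tuple[float, float]:
    """Peak location with 3x3 parabolic refinement; ties break toward the
    smaller lag magnitude (the correlation map is centered on zero lag)."""
    n_rows, n_cols = corr.shape
    center = np.array([(n_rows - 1) / 2.0, (n_cols - 1) / 2.0])
    peak_val = corr.max()
    candidates = np.argwhere(corr >= peak_val * (1.0 - 1e-12))
    dist = np.hypot(candidates[:, 0] - center[0], candidates[:, 1] - center[1])
    r, c = candidates[int(np.argmin(dist))]

    def refine(vm: float, v0: float, vp: float) -> float:
        denom = vm - 2.0 * v0 + vp
        return 0.0 if denom == 0 else 0.5 * (vm - vp) / denom

    dr = dc = 0.0
    if 0 < r < n_rows - 1:
        dr = refine(corr[r - 1, c], corr[r, c], corr[r + 1, c])
    if 0 < c < n_cols - 1:
        dc = refine(corr[r, c - 1], corr[r, c], corr[r, c + 1])
    return float(r + dr - center[0]), float(c + dc - center[1])


def estimate_drift(
    table: LocalizationTable,
    n_bins: int = 10,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    min_events_per_bin: int = 100,
    smooth_sigma_px: float = 1.0,
) -> DriftTrace:
    """Estimate the lateral drift trajectory of an acquisition.

    Frames are split into ``n_bins`` contiguous equal-count ranges, each
    rendered at ``pixel_size_nm`` over the common bounding box, lightly
    smoothed, and cross-correlated against the first bin; the correlation
    peak (parabolic sub-pixel refinement) gives the bin shift.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 temporal bins")
    order = np.argsort(table.frame, kind="stable")
    splits = np.array_split(order, n_bins)
    if min(len(s) for s in splits) < min_events_per_bin:
        raise ValueError(
            f"under-populated temporal bins (< {min_events_per_bin} events); "
            "use fewer bins"
        )
    pad = 2.0 * pixel_size_nm
    bounds = (
        table.x_nm.min() - pad,
        table.x_nm.max() + pad,
        table.y_nm.min() - pad,
        table.y_nm.max() + pad,
    )
    renders = []
    centers = []
    ranges = []
    for idx in splits:
        sub = table.take(idx)
        img = render_image(sub, pixel_size_nm=pixel_size_nm, bounds=bounds).pixels
        if smooth_sigma_px > 0:
            img = ndimage.gaussian_filter(img, smooth_sigma_px)
        renders.append(img)
        centers.append(float(sub.frame.mean()))
        ranges.append((int(sub.frame.min()), int(sub.frame.max())))

    ref = renders[0]
    shifts = [(0.0, 0.0)]
    peaks = [float((ref * ref).sum())]
    for img in renders[1:]:
        corr = fftconvolve(img, ref[::-1, ::-1], mode="full")
        drow, dcol = _subpixel_peak(corr)
        shifts.append((dcol * pixel_size_nm, drow * pixel_size_nm))
        peaks.append(float(corr.max()))
    return DriftTrace(
        bin_frame_ranges=ranges,
        bin_center_frames=np.asarray(centers),
        shifts_nm=np.asarray(shifts),
        peak_correlations=np.asarray(peaks),
        frame_range=(int(table.frame.min()), int(table.frame.max())),
    )


def correct_drift(table: LocalizationTable, trace: DriftTrace) -> LocalizationTable:
    """Subtract the interpolated per-frame drift from every event.

    Record count is unchanged; frames must lie within the trace's frame
    range (the trace is constant beyond its first/last bin center, but
    frames outside the estimated range indicate a mismatched trace).
    """
    f_min, f_max = trace.frame_range
    if len(table) and (table.frame.min() < f_min or table.frame.max() > f_max):
        raise ValueError("trace does not cover the table's frame range")
    shift = trace.shift_at(table.frame)
    return LocalizationTable(
        frame=table.frame.copy(),
        x_nm=table.x_nm - shift[:, 0],
        y_nm=table.y_nm - shift[:, 1],
        precision_nm=table.precision_nm.copy(),
        photons=None if table.photons is None else table.photons.copy(),
        extras=None if table.extras is None else table.extras.copy(),
    )
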