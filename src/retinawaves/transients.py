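"""Per-ROI calcium-transient detection and inter-transient intervals.

A transient is a local maximum of a ROI's ΔF/F trace exceeding an
amplitude threshold of ``k_sigma`` times a robust estimate of the
baseline noise SD (median absolute deviation scaled to the normal), but
never less than an absolute floor (default 10 % ΔF/F).  Peaks closer than
``min_separation_s`` are de-duplicated, keeping the larger peak.  The
inter-transient interval (ITI) of a ROI is the time between its
successive detected peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core import TraceMatrix

__all__ = [
    "TransientRaster",
    "ItiSet",
    "detect_transients",
    "compute_iti",
    "iti_histogram",
]

MAD_TO_SD = 1.4826  # normal-consistency factor for the median absolute deviation


@dataclass
class TransientRaster:
    """Boolean peak raster plus peak amplitudes and effective thresholds.

    ``raster[i, t]`` marks a detected transient peak of ROI ``i`` at frame
    ``t``; ``amplitudes`` holds the peak ΔF/F at those positions (zero
    elsewhere); ``threshold_used[i]`` is the effective per-ROI threshold.
    """

    raster: np.ndarray
    amplitudes: np.ndarray
    threshold_used: np.ndarray
    fps: float
    roi_ids: np.ndarray
    roi_centroids_um: np.ndarray

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster, dtype=bool)
        if self.raster.shape != self.amplitudes.shape:
            raise ValueError("raster and amplitudes must share a shape")

    @property
    def n_roi(self) -> int:
        return self.raster.shape[0]

    @property
    def n_frames(self) -> int:
        return self.raster.shape[1]

    @property
    def duration_s(self) -> float:
        return self.raster.shape[1] / self.fps

    def to_table(self) -> pd.DataFrame:
        """Long-format table: one row per detected transient."""
        r, f = np.nonzero(self.raster)
        return pd.DataFrame(
            {
                "roi_id": self.roi_ids[r],
                "frame": f,
                "time_s": f / self.fps,
                "amplitude": self.amplitudes[r, f],
            }
        )


@dataclass
class ItiSet:
    """Per-ROI inter-transient intervals in seconds."""

    intervals: list[np.ndarray]
    roi_ids: np.ndarray

    def pooled(self) -> np.ndarray:
        if not self.intervals:
            return np.empty(0)
        return np.concatenate(self.intervals) if any(
            len(v) for v in self.intervals
        ) else np.empty(0)


def detect_transients(
    traces: TraceMatrix,
    k_sigma: float = 10.0,
    floor_dff: float = 0.10,
    min_separation_s: float = 1.0,
) -> TransientRaster:
    """Detect transient peaks in every ROI trace.

    The per-ROI threshold is ``max(k_sigma * SD_baseline, floor_dff)``
    where the baseline SD is the MAD of the whole trace scaled by 1.4826
    (robust to the transients themselves).  Local maxima above threshold
    and separated by at least ``min_separation_s`` are kept
    (:func:`scipy.signal.find_peaks` with height and distance).  Peaks
    must also be prominent by at least the threshold: noise ripples riding
    on the decay shoulder of a genuine transient sit above the absolute
    threshold but rise only by the noise scale, and would otherwise be
    double-counted as separate events.
    """
    x = np.asarray(traces.traces)
    if x.shape[1] < 3:
        raise ValueError("traces must have at least 3 frames")
    if not np.isfinite(x).all():
        raise ValueError("traces must be finite")
    med = np.median(x, axis=1, keepdims=True)
    sd = MAD_TO_SD * np.median(np.abs(x - med), axis=1)
    thr = np.maximum(k_sigma * sd, floor_dff)
    distance = max(1, int(round(min_separation_s * traces.fps)))
    raster = np.zeros(x.shape, dtype=bool)
    amps = np.zeros(x.shape, dtype=np.float32)
    # only traces that ever cross threshold can contain a peak
    for i in np.flatnonzero(x.max(axis=1) >= thr):
        peaks, props = find_peaks(
            x[i], height=thr[i], distance=distance, prominence=thr[i]
        )
        raster[i, peaks] = True
        amps[i, peaks] = props["peak_heights"]
    return TransientRaster(
        raster=raster,
        amplitudes=amps,
        threshold_used=thr,
        fps=traces.fps,
        roi_ids=traces.roi_ids,
        roi_centroids_um=traces.roi_centroids_um,
    )


def compute_iti(raster: TransientRaster) -> ItiSet:
    """Successive peak-frame differences per ROI, in seconds (frames / fps).

    ROIs with fewer than two transients contribute no intervals.
    """
    intervals = []
    for row in raster.raster:
        frames = np.flatnonzero(row)
        intervals.append(np.diff(frames) / raster.fps)
    return ItiSet(intervals=intervals, roi_ids=raster.roi_ids)


def iti_histogram(
    itis: ItiSet | np.ndarray, bin_edges: np.ndarray | None = None
) -> pd.DataFrame:
    """Pooled ITI histogram with counts and percentages per bin.

    Default bins span 0-200 s in 20-s steps; intervals beyond the last
    edge are collected in a separate overflow row (``bin_hi_s`` = inf).
    Percentages are relative to all intervals including overflow.
    """
    if bin_edges is None:
        bin_edges = np.arange(0.0, 201.0, 20.0)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if (np.diff(bin_edges) <= 0).any():
        raise ValueError("bin edges must be strictly increasing")
    pooled = itis.pooled() if isinstance(itis, ItiSet) else np.asarray(itis, float)
    counts, _ = np.histogram(pooled, bins=bin_edges)
    # keep all bins half-open [lo, hi): np.histogram closes the last bin
    counts[-1] -= int((pooled == bin_edges[-1]).sum())
    overflow = int((pooled >= bin_edges[-1]).sum())
    total = max(len(pooled), 1)
    table = pd.DataFrame(
        {
            "bin_lo_s": np.append(bin_edges[:-1], bin_edges[-1]),
            "bin_hi_s": np.append(bin_edges[1:], np.inf),
            "count": np.append(counts, overflow),
        }
    )
    table["percent"] = 100.0 * table["count"] / total
    return table
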