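"""Population-level wave segmentation and kinematics.

Waves are found as peaks of the z-scored "percent of ROIs active per
frame" trace (z >= 1, peaks at least 12 s apart), discarding peaks within
6 s of either end of the recording.  Each wave's participating ROIs are
those with at least one detected transient inside a symmetric 12-s window
around the peak; the wave's area is the participating fraction of all
ROIs.  Events whose participating-ROI bounding box stays within
160 x 160 µm on both axes are classed as non-propagating ("local") and
excluded from area/frequency summaries (their transients still count in
ITI statistics).  For propagating waves the initiation site is the
spatial median of the earliest-activating ROIs, and the propagation speed
is a robust (Theil-Sen, through-origin) slope of distance-from-initiation
against activation latency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core import CellRois, RoiGrid
from .transients import TransientRaster

__all__ = [
    "ActivityTrace",
    "WaveEvent",
    "WaveCatalog",
    "percent_active_trace",
    "detect_waves",
    "build_wave_events",
    "initiation_site",
    "estimate_speed",
    "annotate_kinematics",
    "wave_frequency",
    "summarize_speeds",
    "REFERENCE_WAVE_SPEEDS",
    "catalog_table",
]

LOCAL_EXTENT_UM = 160.0  # bounding-box criterion for non-propagating events

# Reference per-wave propagation speeds (µm/s) from whole-retina calcium
# imaging: embryonic (stage 1) waves in wild-type and β2-nAChR-KO retinas,
# and early postnatal (stage 2) waves.  Each entry is one wave.  Used as a
# worked example for the summary statistics and as a regression surface.
REFERENCE_WAVE_SPEEDS: dict[str, tuple[float, ...]] = {
    "wt_stage1": (
        174.17, 183.94, 192.19, 162.26, 189.84,
        237.34, 179.24, 165.68, 144.52, 182.07,
    ),
    "b2ko_stage1": (
        77.91, 92.40, 98.19, 117.34, 128.52,
        87.97, 92.40, 92.06, 103.25, 103.90,
    ),
    "stage2": (
        205.68, 124.44, 153.25, 120.47, 158.59,
        176.49, 263.86, 156.09, 108.62, 299.29,
    ),
}


@dataclass
class ActivityTrace:
    """Percent of ROIs with a transient peak at each frame, and its z-score."""

    percent_active: np.ndarray
    zscores: np.ndarray | None
    fps: float

    @property
    def n_frames(self) -> int:
        return len(self.percent_active)


@dataclass
class WaveEvent:
    """One segmented event and its measurements.

    ``first_frames[j]`` is the first in-window transient frame of
    participating ROI ``roi_index[j]`` (an index into the trace/raster
    rows, not the original grid id).  ``flags`` collects quality notes
    such as ``excluded`` (window clipped by the recording bounds),
    ``ambiguous_initiation`` or ``no_speed``.
    """

    event_id: int
    peak_frame: int
    window_s: tuple[float, float]
    roi_index: np.ndarray
    first_frames: np.ndarray
    area_pct: float
    extent_um: tuple[float, float]
    kind: str
    initiation_xy_um: tuple[float, float] | None = None
    speed_um_s: float | None = None
    flags: list[str] = dc_field(default_factory=list)

    @property
    def n_roi(self) -> int:
        return len(self.roi_index)


@dataclass
class WaveCatalog:
    """Ordered wave events plus the recording metadata they refer to."""

    events: list[WaveEvent]
    duration_s: float
    n_roi: int
    fps: float
    half_window_s: float = 6.0
    edge_exclusion_s: float = 6.0

    def retained(self) -> list[WaveEvent]:
        return [e for e in self.events if "excluded" not in e.flags]

    def propagating(self) -> list[WaveEvent]:
        return [e for e in self.retained() if e.kind == "propagating"]

    def local(self) -> list[WaveEvent]:
        return [e for e in self.retained() if e.kind == "local"]


def percent_active_trace(raster: TransientRaster) -> ActivityTrace:
    """Fraction (in %) of ROIs with a transient peak at each frame, z-scored.

    The z-score is taken against the whole-recording mean and SD.  A
    recording with no activity has zero SD; the z-trace is then undefined
    and wave detection is skipped downstream (with a warning here).
    """
    if raster.n_roi == 0:
        raise ValueError("raster has no ROIs")
    pct = 100.0 * raster.raster.sum(axis=0) / raster.n_roi
    sd = pct.std()
    if sd == 0:
        warnings.warn("activity trace has zero variance; z-scores undefined")
        return ActivityTrace(percent_active=pct, zscores=None, fps=raster.fps)
    return ActivityTrace(
        percent_active=pct, zscores=(pct - pct.mean()) / sd, fps=raster.fps
    )


def detect_waves(
    activity: ActivityTrace,
    z_threshold: float = 1.0,
    edge_exclusion_s: float = 6.0,
    min_peak_separation_s: float = 12.0,
) -> np.ndarray:
    """Frames of wave peaks in the z-scored activity trace.

    Local maxima with z >= ``z_threshold`` at least
    ``min_peak_separation_s`` apart; peaks within ``edge_exclusion_s`` of
    either end of the recording are removed as edge cases.
    """
    if activity.zscores is None:
        return np.empty(0, dtype=np.int64)
    distance = max(1, int(round(min_peak_separation_s * activity.fps)))
    peaks, _ = find_peaks(activity.zscores, height=z_threshold, distance=distance)
    t = peaks / activity.fps
    duration = activity.n_frames / activity.fps
    keep = (t >= edge_exclusion_s) & (t <= duration - edge_exclusion_s)
    return peaks[keep].astype(np.int64)


def build_wave_events(
    peaks: np.ndarray,
    raster: TransientRaster,
    rois: RoiGrid | CellRois | None = None,
    half_window_s: float = 6.0,
    edge_exclusion_s: float = 6.0,
) -> WaveCatalog:
    """Assemble a :class:`WaveCatalog` from wave peak frames.

    A ROI participates in a wave when it has at least one transient within
    ``half_window_s`` of the peak; where windows overlap, each transient
    counts only toward its nearest peak (ties to the earlier one).  The
    area is the participating percentage of all ROIs, and the event kind
    is assigned by the 160 x 160 µm bounding-extent rule on participating
    ROI centroids.  Events whose window is clipped by the recording bounds
    are flagged ``excluded``.
    """
    peaks = np.sort(np.asarray(peaks, dtype=np.int64))
    centroids = raster.roi_centroids_um
    n_roi, n_frames = raster.raster.shape
    w_frames = int(round(half_window_s * raster.fps))
    events: list[WaveEvent] = []

    rr, ff = np.nonzero(raster.raster)
    if len(peaks):
        # nearest-peak assignment (ties -> earlier peak)
        pos = np.searchsorted(peaks, ff)
        left = np.clip(pos - 1, 0, len(peaks) - 1)
        right = np.clip(pos, 0, len(peaks) - 1)
        d_left = np.abs(ff - peaks[left])
        d_right = np.abs(ff - peaks[right])
        assign = np.where(d_left <= d_right, left, right)
    else:
        assign = np.empty(0, dtype=np.int64)

    for k, p in enumerate(peaks):
        member = (assign == k) & (np.abs(ff - p) <= w_frames)
        first = np.full(n_roi, np.iinfo(np.int64).max, dtype=np.int64)
        np.minimum.at(first, rr[member], ff[member])
        roi_index = np.flatnonzero(first < np.iinfo(np.int64).max)
        first_frames = first[roi_index]
        area_pct = 100.0 * len(roi_index) / n_roi
        if len(roi_index):
            c = centroids[roi_index]
            extent = (
                float(c[:, 0].max() - c[:, 0].min()),
                float(c[:, 1].max() - c[:, 1].min()),
            )
        else:
            extent = (0.0, 0.0)
        kind = (
            "local"
            if extent[0] <= LOCAL_EXTENT_UM and extent[1] <= LOCAL_EXTENT_UM
            else "propagating"
        )
        window = (p / raster.fps - half_window_s, p / raster.fps + half_window_s)
        flags = []
        if window[0] < 0 or window[1] > n_frames / raster.fps:
            flags.append("excluded")
        events.append(
            WaveEvent(
                event_id=k,
                peak_frame=int(p),
                window_s=window,
                roi_index=roi_index,
                first_frames=first_frames,
                area_pct=area_pct,
                extent_um=extent,
                kind=kind,
                flags=flags,
            )
        )
    return WaveCatalog(
        events=events,
        duration_s=n_frames / raster.fps,
        n_roi=n_roi,
        fps=raster.fps,
        half_window_s=half_window_s,
        edge_exclusion_s=edge_exclusion_s,
    )


def initiation_site(
    event: WaveEvent, raster: TransientRaster, ambiguity_um: float = 200.0
) -> tuple[float, float]:
    """Spatial median of the centroids of earliest-activating ROIs.

    All ROIs whose first in-window transient falls in the earliest
    activation frame are included; if any two of them lie more than
    ``ambiguity_um`` apart the event is flagged ``ambiguous_initiation``
    (the site is still reported).
    """
    if event.kind != "propagating" or event.n_roi < 3:
        raise ValueError("initiation site needs a propagating event with >=3 ROIs")
    earliest = event.first_frames.min()
    sel = event.roi_index[event.first_frames == earliest]
    pts = raster.roi_centroids_um[sel]
    site = (float(np.median(pts[:, 0])), float(np.median(pts[:, 1])))
    if len(pts) > 1:
        span = np.hypot(
            pts[:, 0].max() - pts[:, 0].min(), pts[:, 1].max() - pts[:, 1].min()
        )
        if span > ambiguity_um and "ambiguous_initiation" not in event.flags:
            event.flags.append("ambiguous_initiation")
    event.initiation_xy_um = site
    return site


def estimate_speed(
    event: WaveEvent,
    raster: TransientRaster,
    min_latency_span_s: float = 0.3,
) -> float | None:
    """Propagation speed as a through-origin Theil-Sen slope (µm/s).

    Each participating ROI contributes one point: its distance from the
    initiation site versus its activation latency (first in-window
    transient relative to the earliest one).  The slope is the median of
    per-ROI distance/latency ratios, a through-origin Theil-Sen estimate
    robust to stragglers.  Returns None (and flags the event) when the
    event is too small, too synchronous (latency span below
    ``min_latency_span_s``), or geometrically degenerate.
    """
    if event.kind != "propagating" or event.n_roi < 10:
        event.flags.append("no_speed")
        return None
    if len(np.unique(event.first_frames)) < 3:
        event.flags.append("no_speed")
        return None
    if event.initiation_xy_um is None:
        initiation_site(event, raster)
    latency = (event.first_frames - event.first_frames.min()) / raster.fps
    if latency.max() < min_latency_span_s:
        event.flags.append("no_speed")
        return None
    pts = raster.roi_centroids_um[event.roi_index]
    x0, y0 = event.initiation_xy_um
    dist = np.hypot(pts[:, 0] - x0, pts[:, 1] - y0)
    pos = latency > 0
    if pos.sum() < 3 or np.all(dist[pos] == dist[pos][0]):
        event.flags.append("no_speed")
        return None
    speed = float(np.median(dist[pos] / latency[pos]))
    event.speed_um_s = speed
    return speed


def annotate_kinematics(catalog: WaveCatalog, raster: TransientRaster) -> WaveCatalog:
    """Fill initiation sites and speeds for all retained propagating events."""
    for event in catalog.propagating():
        try:
            initiation_site(event, raster)
        except ValueError:
            event.flags.append("no_initiation")
            continue
        estimate_speed(event, raster)
    return catalog


def wave_frequency(catalog: WaveCatalog) -> float:
    """Propagating-event rate in events/min over the analyzable duration.

    The analyzable duration excludes the edge-exclusion margins at both
    ends of the recording.
    """
    analyzable = catalog.duration_s - 2 * catalog.edge_exclusion_s
    if analyzable <= 0:
        raise ValueError("recording shorter than the edge exclusions")
    return len(catalog.propagating()) / (analyzable / 60.0)


def summarize_speeds(speeds) -> tuple[float, float | None]:
    """Arithmetic mean and (n-1) sample SD of per-wave speeds."""
    speeds = np.asarray(list(speeds), dtype=float)
    if len(speeds) == 0:
        raise ValueError("no speeds to summarize")
    mean = float(speeds.mean())
    sd = float(speeds.std(ddof=1)) if len(speeds) >= 2 else None
    return mean, sd


def catalog_table(catalog: WaveCatalog) -> pd.DataFrame:
    """Flat per-event table (one row per event, local and propagating)."""
    rows = []
    for e in catalog.events:
        rows.append(
            {
                "event_id": e.event_id,
                "peak_time_s": e.peak_frame / catalog.fps,
                "area_pct": e.area_pct,
                "kind": e.kind,
                "extent_x_um": e.extent_um[0],
                "extent_y_um": e.extent_um[1],
                "init_x_um": e.initiation_xy_um[0] if e.initiation_xy_um else np.nan,
                "init_y_um": e.initiation_xy_um[1] if e.initiation_xy_um else np.nan,
                "speed_um_s": e.speed_um_s if e.speed_um_s is not None else np.nan,
                "flags": ";".join(e.flags),
            }
        )
    return pd.DataFrame(rows)
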