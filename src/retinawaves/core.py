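"""Core in-memory containers shared across the pipeline.

All geometry is expressed in micrometres (µm) with a pixel-centred
convention: the image origin is the top-left corner, x increases with
column index, y with row index, and pixel (r, c) occupies the half-open
square [c*px_um, (c+1)*px_um) x [r*px_um, (r+1)*px_um), so its centre is
((c+0.5)*px_um, (r+0.5)*px_um).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RawMovie",
    "DffMovie",
    "RoiGrid",
    "CellRois",
    "TraceMatrix",
    "Mosaic",
]


@dataclass
class RawMovie:
    """A T x H x W fluorescence stack with its acquisition metadata.

    Parameters
    ----------
    data
        Non-negative intensities, arbitrary units, shape (T, H, W).
    fps
        Frame rate in frames per second.
    px_um
        Pixel pitch in µm per pixel.
    """

    data: np.ndarray
    fps: float
    px_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"movie must be T x H x W, got shape {self.data.shape}")
        if self.data.shape[0] < 2:
            raise ValueError("movie must have at least 2 frames")
        if not (self.fps > 0):
            raise ValueError("fps must be positive")
        if not (self.px_um > 0):
            raise ValueError("px_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape_hw(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def duration_s(self) -> float:
        return self.data.shape[0] / self.fps


@dataclass
class DffMovie:
    """A ΔF/F0 movie (unitless) plus the mask of pixels with a valid baseline."""

    data: np.ndarray
    fps: float
    px_um: float
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("dff movie must be T x H x W")
        if self.valid_mask.shape != self.data.shape[1:]:
            raise ValueError("valid_mask must match the frame shape")
        if not np.isfinite(self.data[:, self.valid_mask]).all():
            raise ValueError("ΔF/F values must be finite on the valid mask")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape_hw(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]


def _pixel_span(lo_um: float, hi_um: float, px_um: float) -> tuple[int, int]:
    """Indices of pixels whose centres fall in [lo_um, hi_um)."""
    lo = int(np.ceil(lo_um / px_um - 0.5))
    hi = int(np.ceil(hi_um / px_um - 0.5))
    return lo, hi


@dataclass
class RoiGrid:
    """A set of square grid ROIs over a movie frame.

    ROIs are stored structure-of-arrays style: ``x0_um[i], y0_um[i]`` is the
    top-left corner of ROI ``i`` (size ``size_um``), and ``r0/r1/c0/c1`` are
    its half-open pixel-row/column spans (pixel-centre membership rule).
    Ordering is row-major (y outer, x inner) and deterministic.
    """

    x0_um: np.ndarray
    y0_um: np.ndarray
    size_um: float
    pitch_um: float
    shape_hw: tuple[int, int]
    px_um: float
    mask: np.ndarray
    r0: np.ndarray = field(repr=False, default=None)
    r1: np.ndarray = field(repr=False, default=None)
    c0: np.ndarray = field(repr=False, default=None)
    c1: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.x0_um = np.asarray(self.x0_um, dtype=float)
        self.y0_um = np.asarray(self.y0_um, dtype=float)
        if self.r0 is None:
            spans_c = [_pixel_span(x, x + self.size_um, self.px_um) for x in self.x0_um]
            spans_r = [_pixel_span(y, y + self.size_um, self.px_um) for y in self.y0_um]
            self.c0 = np.array([s[0] for s in spans_c], dtype=np.int64)
            self.c1 = np.array([s[1] for s in spans_c], dtype=np.int64)
            self.r0 = np.array([s[0] for s in spans_r], dtype=np.int64)
            self.r1 = np.array([s[1] for s in spans_r], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.x0_um)

    @property
    def roi_ids(self) -> np.ndarray:
        return np.arange(len(self), dtype=np.int64)

    @property
    def centroids_um(self) -> np.ndarray:
        """(n, 2) array of ROI centre coordinates (x, y) in µm."""
        return np.column_stack(
            [self.x0_um + self.size_um / 2.0, self.y0_um + self.size_um / 2.0]
        )

    def label_image(self) -> np.ndarray:
        """(H, W) int32 image mapping each pixel to its ROI index, -1 outside.

        Grid ROIs are non-overlapping by construction so assignment order
        is immaterial.
        """
        lab = np.full(self.shape_hw, -1, dtype=np.int32)
        h, w = self.shape_hw
        for i in range(len(self)):
            r0, r1 = max(self.r0[i], 0), min(self.r1[i], h)
            c0, c1 = max(self.c0[i], 0), min(self.c1[i], w)
            lab[r0:r1, c0:c1] = i
        return lab


@dataclass
class CellRois:
    """Circular cell ROIs (e.g. somata from a two-photon field of view).

    ``group`` carries an optional label per cell (e.g. a genetic marker
    class) used by the group-comparison reporting layer.
    """

    centers_um: np.ndarray
    r_um: np.ndarray
    shape_hw: tuple[int, int]
    px_um: float
    group: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.centers_um = np.asarray(self.centers_um, dtype=float).reshape(-1, 2)
        self.r_um = np.broadcast_to(
            np.asarray(self.r_um, dtype=float), (len(self.centers_um),)
        ).copy()
        if self.group is not None:
            self.group = np.asarray(self.group)

    def __len__(self) -> int:
        return len(self.centers_um)

    @property
    def roi_ids(self) -> np.ndarray:
        return np.arange(len(self), dtype=np.int64)

    @property
    def centroids_um(self) -> np.ndarray:
        return self.centers_um

    def label_image(self) -> np.ndarray:
        h, w = self.shape_hw
        cx = (np.arange(w) + 0.5) * self.px_um
        cy = (np.arange(h) + 0.5) * self.px_um
        lab = np.full((h, w), -1, dtype=np.int32)
        for i, ((x, y), r) in enumerate(zip(self.centers_um, self.r_um)):
            c0, c1 = _pixel_span(x - r, x + r, self.px_um)
            r0, r1 = _pixel_span(y - r, y + r, self.px_um)
            c0, c1 = max(c0, 0), min(c1, w)
            r0, r1 = max(r0, 0), min(r1, h)
            if c1 <= c0 or r1 <= r0:
                continue
            dx = cx[c0:c1] - x
            dy = cy[r0:r1] - y
            inside = dx[None, :] ** 2 + dy[:, None] ** 2 <= r**2
            block = lab[r0:r1, c0:c1]
            block[inside] = i
        return lab


@dataclass
class TraceMatrix:
    """Per-ROI mean ΔF/F time series: rows align 1:1 with ``roi_ids``."""

    traces: np.ndarray
    roi_ids: np.ndarray
    fps: float
    roi_centroids_um: np.ndarray

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces)
        self.roi_ids = np.asarray(self.roi_ids)
        self.roi_centroids_um = np.asarray(self.roi_centroids_um, dtype=float)
        if self.traces.ndim != 2:
            raise ValueError("traces must be n_roi x T")
        if len(self.roi_ids) != self.traces.shape[0]:
            raise ValueError("roi_ids must match trace rows")
        if self.roi_centroids_um.shape != (self.traces.shape[0], 2):
            raise ValueError("roi_centroids_um must be (n_roi, 2)")

    @property
    def n_roi(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    @property
    def duration_s(self) -> float:
        return self.traces.shape[1] / self.fps


@dataclass
class Mosaic:
    """Soma centroids within a rectangular field, optionally with exclusions.

    ``points`` is an (n, 2) array of (x_um, y_um); ``width_um``/``height_um``
    define the rectangular boundary with origin (0, 0).
    """

    points: np.ndarray
    width_um: float
    height_um: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if len(self.points):
            x, y = self.points[:, 0], self.points[:, 1]
            if (x < 0).any() or (x > self.width_um).any() or (y < 0).any() or (
                y > self.height_um
            ).any():
                raise ValueError("all points must lie inside the boundary")
            if len(self.points) > 1:
                # duplicate check at 0.01 µm tolerance
                order = np.lexsort((y, x))
                p = self.points[order]
                d = np.abs(np.diff(p, axis=0)).max(axis=1)
                if (d < 0.01).any():
                    warnings.warn("mosaic contains near-duplicate points (<0.01 µm)")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def area_mm2(self) -> float:
        return self.width_um * self.height_um / 1e6

    @property
    def density_per_mm2(self) -> float:
        return len(self.points) / self.area_mm2
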