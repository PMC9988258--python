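"""Raw movie -> ΔF/F -> grid ROIs -> per-ROI traces.

The normalization follows the standard population-imaging recipe: the
baseline image F0 is the per-pixel temporal median of the stack, and each
frame F is mapped to (F - F0) / F0.  Pixels whose baseline falls at or
below a guard value are flagged invalid (rather than propagating NaN/inf)
and excluded from trace extraction.  The field is then tiled with small
square ROIs (nominally 10 µm, spaced ~7 µm apart) and each ROI's trace is
the mean ΔF/F over its valid pixels in every frame.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import CellRois, DffMovie, RawMovie, RoiGrid, TraceMatrix

__all__ = ["compute_dff", "bin_movie", "make_grid_rois", "extract_traces"]


def compute_dff(movie: RawMovie, eps: float = 1e-6) -> DffMovie:
    """Normalize a movie to ΔF/F0 with F0 the per-pixel temporal median.

    Pixels with F0 <= ``eps`` (e.g. dead sensor columns or regions outside
    the tissue) are marked invalid in the returned movie's ``valid_mask``
    and their ΔF/F is set to zero.
    """
    data = np.asarray(movie.data, dtype=np.float32)
    f0 = np.median(data, axis=0)
    valid = f0 > eps
    dff = np.zeros_like(data)
    np.divide(data - f0, f0, out=dff, where=valid[None, :, :])
    return DffMovie(dff, fps=movie.fps, px_um=movie.px_um, valid_mask=valid)


def bin_movie(movie: RawMovie, factor: int) -> RawMovie:
    """Spatially bin by ``factor`` x ``factor`` block averaging.

    Trailing rows/columns not filling a complete block are dropped (with a
    warning); the pixel pitch scales by ``factor``.  Block averaging
    conserves the global mean exactly up to those dropped edges.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("bin factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return RawMovie(movie.data.copy(), fps=movie.fps, px_um=movie.px_um)
    t, h, w = movie.data.shape
    h2, w2 = h // factor, w // factor
    if h2 * factor != h or w2 * factor != w:
        warnings.warn(
            f"dropping {h - h2 * factor} trailing rows and "
            f"{w - w2 * factor} columns not filling a {factor}x{factor} block"
        )
    cropped = movie.data[:, : h2 * factor, : w2 * factor]
    binned = cropped.reshape(t, h2, factor, w2, factor).mean(axis=(2, 4))
    return RawMovie(binned, fps=movie.fps, px_um=movie.px_um * factor)


def make_grid_rois(
    shape_hw: tuple[int, int],
    px_um: float,
    roi_size_um: float = 10.0,
    gap_um: float = 7.0,
    mask: np.ndarray | None = None,
) -> RoiGrid:
    """Tile the field with square ROIs at pitch ``roi_size_um + gap_um``.

    ROIs whose pixel footprint lies wholly outside ``mask`` (a boolean
    valid-region image, e.g. the retina outline) are dropped.  Ordering is
    row-major and deterministic.  The number of complete ROIs along a side
    of length L is ``floor((L - roi_size_um) / pitch) + 1``.
    """
    if roi_size_um < px_um:
        raise ValueError("roi_size_um must be at least one pixel")
    h, w = shape_hw
    if mask is None:
        mask = np.ones((h, w), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (h, w):
        raise ValueError("mask shape must match the frame shape")
    pitch = roi_size_um + gap_um
    lx, ly = w * px_um, h * px_um
    nx = int(np.floor((lx - roi_size_um) / pitch + 1e-9)) + 1 if lx >= roi_size_um else 0
    ny = int(np.floor((ly - roi_size_um) / pitch + 1e-9)) + 1 if ly >= roi_size_um else 0
    xs = np.arange(nx) * pitch
    ys = np.arange(ny) * pitch
    gx, gy = np.meshgrid(xs, ys)  # row-major: y outer, x inner
    grid = RoiGrid(
        x0_um=gx.ravel(),
        y0_um=gy.ravel(),
        size_um=roi_size_um,
        pitch_um=pitch,
        shape_hw=(h, w),
        px_um=px_um,
        mask=mask,
    )
    # drop ROIs whose footprint misses the mask entirely
    keep = np.zeros(len(grid), dtype=bool)
    for i in range(len(grid)):
        r0, r1 = max(grid.r0[i], 0), min(grid.r1[i], h)
        c0, c1 = max(grid.c0[i], 0), min(grid.c1[i], w)
        keep[i] = r1 > r0 and c1 > c0 and mask[r0:r1, c0:c1].any()
    if not keep.any():
        warnings.warn("mask excludes every ROI; returning an empty grid")
    return RoiGrid(
        x0_um=grid.x0_um[keep],
        y0_um=grid.y0_um[keep],
        size_um=roi_size_um,
        pitch_um=pitch,
        shape_hw=(h, w),
        px_um=px_um,
        mask=mask,
        r0=grid.r0[keep],
        r1=grid.r1[keep],
        c0=grid.c0[keep],
        c1=grid.c1[keep],
    )


def extract_traces(dff: DffMovie, rois: RoiGrid | CellRois) -> TraceMatrix:
    """Mean ΔF/F over each ROI's valid pixels, per frame.

    ROIs with no valid pixel (entirely outside the ΔF/F valid mask or the
    grid mask) are dropped with a warning; the returned ``roi_ids`` index
    into the original ROI set.
    """
    if rois.shape_hw != dff.shape_hw:
        raise ValueError(
            f"ROI set built for frame shape {rois.shape_hw}, movie is {dff.shape_hw}"
        )
    labels = rois.label_image()
    valid = dff.valid_mask.copy()
    if isinstance(rois, RoiGrid):
        valid &= rois.mask
    valid &= labels >= 0
    idx = np.flatnonzero(valid.ravel())
    lab = labels.ravel()[idx]
    n = len(rois)
    counts = np.bincount(lab, minlength=n)
    kept = counts > 0
    if not kept.all():
        warnings.warn(f"dropping {int((~kept).sum())} ROI(s) with no valid pixels")
    # sort pixels by ROI for a reduceat-based grouped mean
    order = np.argsort(lab, kind="stable")
    idx = idx[order]
    lab = lab[order]
    boundaries = np.searchsorted(lab, np.flatnonzero(kept))
    flat = dff.data.reshape(dff.n_frames, -1)[:, idx]
    sums = np.add.reduceat(flat, boundaries, axis=1)
    traces = (sums / counts[kept]).T.astype(np.float32)
    return TraceMatrix(
        traces=traces,
        roi_ids=rois.roi_ids[kept],
        fps=dff.fps,
        roi_centroids_um=rois.centroids_um[kept],
    )
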