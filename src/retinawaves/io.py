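"""File I/O: multi-page TIFF movies, CSV tables, JSON sidecars."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import Mosaic, RawMovie, RoiGrid
from .transients import TransientRaster
from .wavesim import GroundTruthEvent, WaveSimConfig

__all__ = [
    "read_movie",
    "write_movie",
    "write_ground_truth",
    "read_ground_truth",
    "write_mosaic_csv",
    "read_mosaic_csv",
    "write_traces_csv",
    "read_traces_csv",
    "write_roi_csv",
    "write_raster_csv",
]


def read_movie(path, fps: float, px_um: float) -> RawMovie:
    """Load a multi-page grayscale TIFF stack (8/16-bit or float)."""
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return RawMovie(data, fps=fps, px_um=px_um)


def write_movie(path, movie: RawMovie, dtype=np.uint16) -> None:
    """Write a movie as multi-page TIFF (unsigned 16-bit by default)."""
    data = movie.data
    if np.issubdtype(np.dtype(dtype), np.integer):
        info = np.iinfo(dtype)
        data = np.clip(np.rint(data), info.min, info.max).astype(dtype)
    else:
        data = data.astype(dtype)
    tifffile.imwrite(path, data)


def write_ground_truth(path, config: WaveSimConfig, events: list[GroundTruthEvent]) -> None:
    payload = {
        "config": dataclasses.asdict(config),
        "events": [dataclasses.asdict(e) for e in events],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_ground_truth(path) -> tuple[WaveSimConfig, list[GroundTruthEvent]]:
    payload = json.loads(Path(path).read_text())
    cfg = payload["config"]
    for key in ("speed_um_s", "footprint_fraction", "site_xy_um"):
        if isinstance(cfg.get(key), list):
            cfg[key] = tuple(cfg[key])
    config = WaveSimConfig(**cfg)
    events = []
    for e in payload["events"]:
        e = dict(e)
        e["site_xy_um"] = tuple(e["site_xy_um"])
        events.append(GroundTruthEvent(**e))
    return config, events


def write_mosaic_csv(path, mosaic: Mosaic) -> None:
    pd.DataFrame(mosaic.points, columns=["x_um", "y_um"]).to_csv(path, index=False)


def read_mosaic_csv(path, width_um: float, height_um: float) -> Mosaic:
    table = pd.read_csv(path)
    return Mosaic(
        table[["x_um", "y_um"]].to_numpy(), width_um=width_um, height_um=height_um
    )


def write_roi_csv(path, rois: RoiGrid) -> None:
    pd.DataFrame(
        {
            "roi_id": rois.roi_ids,
            "x0_um": rois.x0_um,
            "y0_um": rois.y0_um,
            "size_um": rois.size_um,
        }
    ).to_csv(path, index=False)


def write_traces_csv(path, traces, long_format: bool = False) -> None:
    """Trace matrix as CSV: wide (one column per frame) or long format."""
    if long_format:
        n, t = traces.traces.shape
        table = pd.DataFrame(
            {
                "roi_id": np.repeat(traces.roi_ids, t),
                "frame": np.tile(np.arange(t), n),
                "dff": traces.traces.ravel(),
            }
        )
    else:
        table = pd.DataFrame(
            traces.traces, columns=[f"f{t}" for t in range(traces.traces.shape[1])]
        )
        table.insert(0, "roi_id", traces.roi_ids)
        table.insert(1, "cx_um", traces.roi_centroids_um[:, 0])
        table.insert(2, "cy_um", traces.roi_centroids_um[:, 1])
    table.to_csv(path, index=False)


def read_traces_csv(path, fps: float):
    """Read a wide-format trace CSV back into a TraceMatrix."""
    from .core import TraceMatrix

    table = pd.read_csv(path)
    frame_cols = [c for c in table.columns if c.startswith("f") and c[1:].isdigit()]
    return TraceMatrix(
        traces=table[frame_cols].to_numpy(dtype=np.float32),
        roi_ids=table["roi_id"].to_numpy(),
        fps=fps,
        roi_centroids_um=table[["cx_um", "cy_um"]].to_numpy(),
    )


def write_raster_csv(path, raster: TransientRaster) -> None:
    raster.to_table().to_csv(path, index=False)
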