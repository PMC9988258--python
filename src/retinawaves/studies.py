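"""End-to-end validation studies on synthetic ground truth.

Each study generates data with :mod:`retinawaves.wavesim`, runs the full
analysis pipeline on it, and compares the measurements against the
programmed truth.  They exist because the pipeline's headline quantities
(wave area, speed, ITI structure, participation rates, mosaic regularity)
can only be validated against recordings whose true parameters are known;
the studies double as the reproducibility surface exercised by the test
suite and the acceptance script.

Problem sizes are deliberately desk-scale: single-wave movies on a
1.5 x 1.5 mm grid for speed, 1 x 1 mm for area, a small 400-µm field for
the hour-long ITI recording, and trace-level synthesis for the bootstrap
calibration.  See docs/methods.md for the rationale behind each choice.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import TraceMatrix
from .mosaics import compute_nnd, estimate_density, random_mosaic_reference
from .participation import build_null, test_participation
from .preprocessing import compute_dff, extract_traces, make_grid_rois
from .transients import compute_iti, detect_transients, iti_histogram
from .waves import (
    WaveCatalog,
    WaveEvent,
    annotate_kinematics,
    build_wave_events,
    detect_waves,
    percent_active_trace,
)
from .wavesim import (
    GroundTruthEvent,
    MosaicSimConfig,
    WaveSimConfig,
    simulate_mosaic,
    simulate_movie,
    transient_kernel,
)

__all__ = [
    "analyze_movie",
    "measure_single_wave",
    "speed_recovery_study",
    "area_recovery_study",
    "iti_study",
    "classification_study",
    "participation_calibration_study",
    "poisson_ri_study",
    "density_recovery_study",
]


def analyze_movie(movie, roi_size_um: float = 10.0, gap_um: float = 7.0):
    """Run the standard pipeline on a raw movie.

    Returns ``(traces, raster, catalog)`` with initiation sites and
    speeds annotated for all retained propagating events.
    """
    dff = compute_dff(movie)
    rois = make_grid_rois(movie.shape_hw, movie.px_um, roi_size_um, gap_um)
    traces = extract_traces(dff, rois)
    raster = detect_transients(traces)
    activity = percent_active_trace(raster)
    peaks = detect_waves(activity)
    catalog = build_wave_events(peaks, raster)
    annotate_kinematics(catalog, raster)
    return traces, raster, catalog


def measure_single_wave(
    speed_um_s: float,
    seed: int,
    footprint_fraction: float = 0.17,
    fov_um: float = 1500.0,
    px_um: float = 10.0,
    site_xy_um: tuple[float, float] | None = None,
) -> WaveEvent | None:
    """Simulate one centred wave and return the measured event (or None).

    The footprint is kept moderate so the wave's full activation spread
    fits inside the ±6 s participation window at the slowest speeds of
    interest.
    """
    cfg = WaveSimConfig(
        fov_um=fov_um,
        px_um=px_um,
        fps=10.0,
        duration_s=25.0,
        local_event_rate_per_min=0.0,
        noise_sd=1.0,
        seed=seed,
    )
    site = site_xy_um or (fov_um / 2.0, fov_um / 2.0)
    event = GroundTruthEvent(
        kind="propagating",
        t0_s=8.0,
        site_xy_um=site,
        speed_um_s=speed_um_s,
        footprint_fraction=footprint_fraction,
    )
    movie, _ = simulate_movie(cfg, events=[event])
    _, _, catalog = analyze_movie(movie)
    waves = catalog.propagating()
    return waves[0] if waves else None


def speed_recovery_study(speeds_um_s, seed: int) -> pd.DataFrame:
    """Measure each programmed speed on its own single-wave movie."""
    rng = np.random.default_rng(seed)
    rows = []
    for true_speed in speeds_um_s:
        event = measure_single_wave(float(true_speed), seed=int(rng.integers(2**31)))
        est = event.speed_um_s if event is not None else np.nan
        rows.append({"true_um_s": float(true_speed), "estimated_um_s": est})
    table = pd.DataFrame(rows)
    table["rel_error"] = (
        table["estimated_um_s"] - table["true_um_s"]
    ).abs() / table["true_um_s"]
    return table


def area_recovery_study(
    footprint_pcts=(10, 25, 50, 75, 90), n_seeds: int = 20, seed: int = 0
) -> pd.DataFrame:
    """Recover programmed wave footprints (percent of field) per seed.

    One wave per movie on a 1 x 1 mm grid; initiation sites are drawn
    from the central half of the field and speeds from the fast end of
    the regime so that even 90 % footprints finish propagating within the
    participation window.
    """
    rng = np.random.default_rng(seed)
    fov = 1000.0
    rows = []
    for pct in footprint_pcts:
        for _ in range(n_seeds):
            cfg = WaveSimConfig(
                fov_um=fov,
                px_um=10.0,
                fps=10.0,
                duration_s=25.0,
                local_event_rate_per_min=0.0,
                noise_sd=1.0,
                seed=int(rng.integers(2**31)),
            )
            site = (
                float(rng.uniform(0.25 * fov, 0.75 * fov)),
                float(rng.uniform(0.25 * fov, 0.75 * fov)),
            )
            event = GroundTruthEvent(
                kind="propagating",
                t0_s=8.0,
                site_xy_um=site,
                speed_um_s=float(rng.uniform(200.0, 250.0)),
                footprint_fraction=pct / 100.0,
            )
            movie, _ = simulate_movie(cfg, events=[event])
            _, _, catalog = analyze_movie(movie)
            waves = catalog.propagating()
            rows.append(
                {
                    "programmed_pct": float(pct),
                    "measured_pct": waves[0].area_pct if waves else np.nan,
                }
            )
    return pd.DataFrame(rows)


def iti_study(
    seed: int,
    duration_s: float = 3600.0,
    mean_wave_interval_s: float = 80.0,
    bin_width_s: float = 20.0,
) -> pd.DataFrame:
    """Hour-long small-field recording; returns the pooled ITI histogram.

    Wave intervals follow a gamma schedule (shape 8) around the mean:
    the refractory-like regularity implied by a peaked ITI distribution,
    as opposed to the mode-at-zero ITIs of a memoryless schedule.
    """
    cfg = WaveSimConfig(
        fov_um=400.0,
        px_um=10.0,
        fps=10.0,
        duration_s=duration_s,
        mean_wave_interval_s=mean_wave_interval_s,
        interval_model="gamma",
        interval_shape=8.0,
        footprint_fraction=0.95,
        local_event_rate_per_min=0.5,
        noise_sd=1.0,
        seed=seed,
    )
    movie, _ = simulate_movie(cfg)
    dff = compute_dff(movie)
    rois = make_grid_rois(movie.shape_hw, movie.px_um)
    traces = extract_traces(dff, rois)
    raster = detect_transients(traces)
    return iti_histogram(
        compute_iti(raster), bin_edges=np.arange(0.0, 201.0, bin_width_s)
    )


def classification_study(seed: int, n_events: int = 18) -> pd.DataFrame:
    """Alternate waves and local events; match detections to ground truth.

    Events are spaced 25 s apart so each is individually resolvable by
    the 12-s peak-separation rule.  Returns one row per programmed event
    with the kind the pipeline assigned (NaN if undetected).
    """
    rng = np.random.default_rng(seed)
    fov = 400.0
    cfg = WaveSimConfig(
        fov_um=fov,
        px_um=10.0,
        fps=10.0,
        duration_s=15.0 + 25.0 * n_events + 15.0,
        local_event_rate_per_min=0.0,
        noise_sd=1.0,
        seed=seed,
    )
    events = []
    t = 15.0
    for i in range(n_events):
        site = (float(rng.uniform(100, fov - 100)), float(rng.uniform(100, fov - 100)))
        speed = float(rng.uniform(100.0, 200.0))
        if i % 3 == 0:  # every third event a propagating wave (>=5 % footprint)
            events.append(
                GroundTruthEvent(
                    kind="propagating",
                    t0_s=t,
                    site_xy_um=site,
                    speed_um_s=speed,
                    footprint_fraction=0.25,
                )
            )
        else:
            events.append(
                GroundTruthEvent(
                    kind="local",
                    t0_s=t,
                    site_xy_um=site,
                    speed_um_s=speed,
                    footprint_radius_um=float(rng.uniform(40.0, 60.0)),
                )
            )
        t += 25.0
    movie, truth = simulate_movie(cfg, events=events)
    _, _, catalog = analyze_movie(movie)
    detected = catalog.retained()
    rows = []
    for g in truth:
        match = None
        for e in detected:
            if abs(e.peak_frame / catalog.fps - g.t0_s) < 12.0:
                match = e
                break
        rows.append(
            {
                "true_kind": g.kind,
                "true_t0_s": g.t0_s,
                "true_footprint_pct": 100.0 * g.footprint_fraction,
                "detected_kind": match.kind if match else np.nan,
            }
        )
    return pd.DataFrame(rows)


def synthetic_wave_catalog(
    n_waves: int, n_frames: int, fps: float, n_cells: int, spacing_frames: int = 800
) -> WaveCatalog:
    """A catalog of evenly spaced wave windows for trace-level studies."""
    events = []
    for i in range(n_waves):
        p = 500 + i * spacing_frames
        events.append(
            WaveEvent(
                event_id=i,
                peak_frame=p,
                window_s=(p / fps - 6.0, p / fps + 6.0),
                roi_index=np.empty(0, dtype=np.int64),
                first_frames=np.empty(0, dtype=np.int64),
                area_pct=50.0,
                extent_um=(500.0, 500.0),
                kind="propagating",
            )
        )
    return WaveCatalog(
        events=events, duration_s=n_frames / fps, n_roi=n_cells, fps=fps
    )


def participation_calibration_study(
    seed: int,
    n_cells: int = 100,
    n_waves: int = 20,
    n_boot: int = 1000,
    responsive: bool = False,
    noise_sd: float = 0.01,
    amplitude: float = 0.5,
) -> float:
    """Participation call rate (%) on synthetic traces.

    With ``responsive=False`` the traces are pure noise and the rate
    measures the size of the 95th-percentile test (nominally 5 %); with
    ``responsive=True`` every cell carries a programmed transient in each
    wave window and the rate measures power.
    """
    rng = np.random.default_rng(seed)
    fps = 10.0
    n_frames = 500 + n_waves * 800 + 500
    data = rng.normal(0.0, noise_sd, (n_cells, n_frames)).astype(np.float32)
    catalog = synthetic_wave_catalog(n_waves, n_frames, fps, n_cells)
    if responsive:
        kernel = amplitude * transient_kernel(0.2, 1.5, fps)
        for e in catalog.events:
            start = e.peak_frame - 5
            seg = min(len(kernel), n_frames - start)
            data[:, start : start + seg] += kernel[None, :seg]
    traces = TraceMatrix(
        data, np.arange(n_cells), fps, np.zeros((n_cells, 2))
    )
    null = build_null(traces, catalog, n_boot=n_boot, seed=int(rng.integers(2**31)))
    matrix = test_participation(traces, catalog, null)
    return float(100.0 * matrix.matrix.mean())


def poisson_ri_study(seed: int, n_mosaics: int = 100, n_points: int = 1000) -> float:
    """Mean regularity index over homogeneous Poisson mosaics."""
    rng = np.random.default_rng(seed)
    ris = []
    for _ in range(n_mosaics):
        mosaic = simulate_mosaic(
            MosaicSimConfig(
                width_um=1000.0,
                height_um=1000.0,
                intensity_per_mm2=float(n_points),
                min_separation_um=0.0,
                seed=int(rng.integers(2**31)),
            )
        )
        ris.append(compute_nnd(mosaic).regularity_index)
    return float(np.mean(ris))


def density_recovery_study(
    seed: int, intensity_per_mm2: float = 600.0, n_sample: int = 50
) -> tuple[float, float]:
    """Quadrat-sampled density vs the realized density of one mosaic."""
    rng = np.random.default_rng(seed)
    mosaic = simulate_mosaic(
        MosaicSimConfig(
            width_um=3000.0,
            height_um=3000.0,
            intensity_per_mm2=intensity_per_mm2,
            min_separation_um=8.0,
            seed=int(rng.integers(2**31)),
        )
    )
    est = estimate_density(
        mosaic, square_um=200.0, n_sample=n_sample, seed=int(rng.integers(2**31))
    )
    return est.density_per_mm2, mosaic.density_per_mm2
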