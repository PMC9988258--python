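"""Synthetic calcium-movie and soma-mosaic generators with ground truth.

The movie generator emulates low-magnification ("macroscope") recordings of
the embryonic retina: a dark field at a constant baseline intensity on which
propagating waves and small non-propagating events ride as fluorescence
transients with indicator-like rise/decay kinetics, plus additive Gaussian
sensor noise.  Each propagating wave is a circular front expanding at a
constant speed from a random initiation site until its footprint covers a
target fraction of the field; non-propagating ("local") events are identical
but confined to a small maximum extent.  Every generated event is returned
as a :class:`GroundTruthEvent`, so downstream detectors can be validated
against known initiation times, sites, speeds and footprints.

The mosaic generator produces soma centre patterns: a homogeneous Poisson
process when ``min_separation_um == 0``, otherwise a sequential-inhibition
(dart-throwing) hard-core process, with independent random thinning
available to emulate developmental cell loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import Mosaic, RawMovie

__all__ = [
    "WaveSimConfig",
    "MosaicSimConfig",
    "GroundTruthEvent",
    "PackingError",
    "simulate_movie",
    "simulate_mosaic",
    "thin_mosaic",
    "transient_kernel",
    "kinetic_peak_delay",
]


class PackingError(RuntimeError):
    """Raised when a hard-core mosaic cannot be packed to the target density."""


@dataclass
class WaveSimConfig:
    """Study conditions for a synthetic wave movie.

    Defaults describe the instrument and activity regime the pipeline is
    designed for: a 4.7 x 4.7 mm field of view imaged at 10 Hz with
    ~5.9 µm pixels (after 4x4 binning), waves recurring with a mean
    interval of 80 s at speeds between ~80 and 250 µm/s, covering 6-90 %
    of the field, alongside occasional non-propagating events confined to
    a <=160 µm extent, with GCaMP6s-like kinetics.
    """

    fov_um: float = 4700.0
    px_um: float = 5.875  # 4700/800; nominal 5.9 µm after 4x4 binning
    fps: float = 10.0
    duration_s: float = 60.0
    mean_wave_interval_s: float = 80.0
    speed_um_s: float | tuple[float, float] = (80.0, 250.0)
    footprint_fraction: float | tuple[float, float] = (0.06, 0.90)
    local_event_rate_per_min: float = 1.0
    local_event_extent_um: float = 120.0
    tau_rise_s: float = 0.2
    tau_decay_s: float = 1.5
    amplitude_dff: float = 0.5
    baseline_level: float = 100.0
    noise_sd: float = 1.0  # 1 % of default baseline
    interval_model: str = "exponential"  # exponential | gamma | fixed
    interval_shape: float = 8.0  # gamma shape when interval_model == "gamma"
    site_xy_um: tuple[float, float] | None = None  # pin all initiation sites
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.fov_um / self.px_um
        if abs(n - round(n)) > 1e-6:
            raise ValueError(
                f"fov_um/px_um = {n:.6f} must be an integer number of pixels"
            )
        if not (self.fps > 0):
            raise ValueError("fps must be positive")
        if not (0 <= self.tau_rise_s < self.tau_decay_s):
            raise ValueError("require tau_decay_s > tau_rise_s >= 0")
        lo, hi = self._range(self.footprint_fraction)
        if not (0 < lo <= hi <= 1):
            raise ValueError("footprint_fraction must lie in (0, 1]")
        if self.local_event_extent_um > 160.0:
            raise ValueError("local_event_extent_um must be <= 160 µm")
        if self.interval_model not in ("exponential", "gamma", "fixed"):
            raise ValueError(f"unknown interval_model {self.interval_model!r}")
        if round(self.duration_s * self.fps) < 1:
            raise ValueError("requested movie has zero frames")

    @staticmethod
    def _range(v) -> tuple[float, float]:
        if np.isscalar(v):
            return float(v), float(v)
        lo, hi = v
        return float(lo), float(hi)

    @property
    def n_px(self) -> int:
        return int(round(self.fov_um / self.px_um))

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


@dataclass
class GroundTruthEvent:
    """One simulated event: the truth the detectors are judged against.

    ``footprint_radius_um`` is the realized front radius (after any clipping
    at the field boundary); ``footprint_fraction`` is the realized fraction
    of field pixels covered.  ``clipped`` marks fronts that ran past the
    nearest field edge before reaching their target footprint.
    """

    kind: str  # "propagating" | "local"
    t0_s: float
    site_xy_um: tuple[float, float]
    speed_um_s: float
    footprint_fraction: float | None = None
    footprint_radius_um: float | None = None
    amplitude_dff: float | None = None
    clipped: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("propagating", "local"):
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class MosaicSimConfig:
    """Conditions for a synthetic soma mosaic.

    ``min_separation_um`` is the hard-core distance (a soma diameter,
    7-10 µm for the cells this emulates); zero gives a homogeneous
    Poisson process.  ``survival_p`` thins the pattern independently,
    emulating developmental cell death.
    """

    width_um: float = 1000.0
    height_um: float = 1000.0
    intensity_per_mm2: float = 1500.0
    min_separation_um: float = 8.0
    survival_p: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.survival_p <= 1):
            raise ValueError("survival_p must be in [0, 1]")
        if self.min_separation_um < 0:
            raise ValueError("min_separation_um must be >= 0")
        # crude feasibility guard: hard disks cannot exceed ~90.7 % packing
        if self.min_separation_um > 0:
            occupied = (
                self.intensity_per_mm2
                / 1e6
                * math.pi
                * (self.min_separation_um / 2) ** 2
            )
            if occupied > 0.9069:
                raise ValueError(
                    "requested intensity is incompatible with min_separation_um"
                )


def kinetic_peak_delay(tau_rise_s: float, tau_decay_s: float) -> float:
    """Time from transient onset to the peak of the fluorescence kernel."""
    if tau_rise_s == 0:
        return 0.0
    return (
        tau_rise_s
        * tau_decay_s
        / (tau_decay_s - tau_rise_s)
        * math.log(tau_decay_s / tau_rise_s)
    )


def transient_kernel(
    tau_rise_s: float, tau_decay_s: float, fps: float, tol: float = 1e-3
) -> np.ndarray:
    """Difference-of-exponentials kernel sampled at the frame grid.

    Normalized to unit peak; truncated once the decay term falls below
    ``tol`` of the peak.
    """
    t_peak = kinetic_peak_delay(tau_rise_s, tau_decay_s)
    t_end = t_peak + tau_decay_s * math.log(1.0 / tol)
    t = np.arange(0.0, t_end, 1.0 / fps)
    if tau_rise_s == 0:
        k = np.exp(-t / tau_decay_s)
    else:
        k = np.exp(-t / tau_decay_s) - np.exp(-t / tau_rise_s)
        k /= math.exp(-t_peak / tau_decay_s) - math.exp(-t_peak / tau_rise_s)
    return k.astype(np.float32)


def _draw_times(rng, model: str, mean: float, shape: float, duration: float):
    times = []
    t = 0.0
    while True:
        if model == "exponential":
            t += rng.exponential(mean)
        elif model == "fixed":
            t += mean
        else:  # gamma
            t += rng.gamma(shape, mean / shape)
        if t >= duration:
            break
        times.append(t)
    return times


def _sample(rng, v) -> float:
    lo, hi = WaveSimConfig._range(v)
    return float(lo) if lo == hi else float(rng.uniform(lo, hi))


def simulate_movie(
    config: WaveSimConfig, events: list[GroundTruthEvent] | None = None
) -> tuple[RawMovie, list[GroundTruthEvent]]:
    """Render a synthetic movie; returns the stack and its ground truth.

    If ``events`` is given, exactly those events are rendered (footprint
    radii are derived from ``footprint_fraction`` where unset); otherwise
    wave times are drawn from the configured interval model and local
    events from a Poisson process.  Identical config and seed yield a
    bit-identical movie.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_px
    n_frames = config.n_frames
    # pixel-centre coordinate axes
    ax = (np.arange(n, dtype=np.float64) + 0.5) * config.px_um

    if events is None:
        events = []
        for t0 in _draw_times(
            rng,
            config.interval_model,
            config.mean_wave_interval_s,
            config.interval_shape,
            config.duration_s,
        ):
            site = config.site_xy_um or (
                float(rng.uniform(0, config.fov_um)),
                float(rng.uniform(0, config.fov_um)),
            )
            events.append(
                GroundTruthEvent(
                    kind="propagating",
                    t0_s=t0,
                    site_xy_um=site,
                    speed_um_s=_sample(rng, config.speed_um_s),
                    footprint_fraction=_sample(rng, config.footprint_fraction),
                )
            )
        n_local = rng.poisson(
            config.local_event_rate_per_min * config.duration_s / 60.0
        )
        for t0 in sorted(rng.uniform(0, config.duration_s, size=n_local)):
            r_max = config.local_event_extent_um / 2.0
            events.append(
                GroundTruthEvent(
                    kind="local",
                    t0_s=float(t0),
                    site_xy_um=(
                        float(rng.uniform(0, config.fov_um)),
                        float(rng.uniform(0, config.fov_um)),
                    ),
                    speed_um_s=_sample(rng, config.speed_um_s),
                    footprint_radius_um=float(rng.uniform(0.5, 1.0) * r_max),
                )
            )
        events.sort(key=lambda e: e.t0_s)
    else:
        events = [replace(e) for e in events]  # do not mutate caller's list

    movie = np.full((n_frames, n, n), config.baseline_level, dtype=np.float32)
    flat = movie.reshape(n_frames, -1)
    kernel = transient_kernel(config.tau_rise_s, config.tau_decay_s, config.fps)
    n_total_px = n * n

    for ev in events:
        x0, y0 = ev.site_xy_um
        dist = np.hypot(ax[None, :] - x0, ax[:, None] - y0).ravel()
        if ev.kind == "propagating":
            if ev.footprint_radius_um is not None:
                radius = ev.footprint_radius_um
            else:
                target = max(1, int(round(ev.footprint_fraction * n_total_px)))
                target = min(target, n_total_px)
                radius = float(np.partition(dist, target - 1)[target - 1])
        else:
            radius = ev.footprint_radius_um
        fp = np.flatnonzero(dist <= radius)
        ev.footprint_radius_um = radius
        ev.footprint_fraction = len(fp) / n_total_px
        # clipped if the front disc is not fully contained in the field
        ev.clipped = (
            x0 - radius < 0
            or y0 - radius < 0
            or x0 + radius > config.fov_um
            or y0 + radius > config.fov_um
        )
        if ev.amplitude_dff is None:
            ev.amplitude_dff = config.amplitude_dff
        amp = np.float32(config.baseline_level * ev.amplitude_dff)
        act_frame = np.rint((ev.t0_s + dist[fp] / ev.speed_um_s) * config.fps).astype(
            np.int64
        )
        for f in np.unique(act_frame):
            if f >= n_frames:
                continue
            sel = fp[act_frame == f]
            f0 = max(int(f), 0)
            length = min(len(kernel), n_frames - f0)
            k0 = f0 - int(f)
            if k0 >= len(kernel) or length <= k0:
                continue
            flat[f0 : f0 + length - k0, sel] += amp * kernel[k0:length, None]

    if config.noise_sd > 0:
        movie += config.noise_sd * rng.standard_normal(movie.shape, dtype=np.float32)
        np.clip(movie, 0.0, None, out=movie)

    return RawMovie(movie, fps=config.fps, px_um=config.px_um), events


def simulate_mosaic(config: MosaicSimConfig) -> Mosaic:
    """Place soma centres by sequential-inhibition dart throwing.

    The point count is Poisson with mean ``intensity * area``; darts landing
    within ``min_separation_um`` of an accepted point are rejected.  A
    bounded total attempt budget guards against infeasible packings; on
    exhaustion a :class:`PackingError` names the density achieved.
    ``survival_p < 1`` additionally thins the result.
    """
    rng = np.random.default_rng(config.seed)
    w, h = config.width_um, config.height_um
    n_target = int(rng.poisson(config.intensity_per_mm2 * w * h / 1e6))
    sep = config.min_separation_um

    if sep == 0:
        pts = np.column_stack([rng.uniform(0, w, n_target), rng.uniform(0, h, n_target)])
    else:
        # cell grid for O(1) neighbour queries
        cell = sep
        nx, ny = int(w // cell) + 1, int(h // cell) + 1
        grid: dict[tuple[int, int], list[int]] = {}
        pts_list: list[tuple[float, float]] = []
        sep2 = sep * sep
        attempts = 0
        max_attempts = max(1000, 200 * n_target)
        while len(pts_list) < n_target and attempts < max_attempts:
            attempts += 1
            x, y = rng.uniform(0, w), rng.uniform(0, h)
            ix, iy = int(x // cell), int(y // cell)
            ok = True
            for jx in range(max(ix - 1, 0), min(ix + 2, nx)):
                for jy in range(max(iy - 1, 0), min(iy + 2, ny)):
                    for k in grid.get((jx, jy), ()):
                        px, py = pts_list[k]
                        if (x - px) ** 2 + (y - py) ** 2 < sep2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                grid.setdefault((ix, iy), []).append(len(pts_list))
                pts_list.append((x, y))
        if len(pts_list) < n_target:
            achieved = len(pts_list) / (w * h / 1e6)
            raise PackingError(
                f"packing failed: placed {len(pts_list)}/{n_target} points "
                f"({achieved:.0f}/mm² achieved vs "
                f"{config.intensity_per_mm2:.0f}/mm² requested)"
            )
        pts = np.asarray(pts_list, dtype=float).reshape(-1, 2)

    mosaic = Mosaic(pts, width_um=w, height_um=h)
    if config.survival_p < 1:
        mosaic = thin_mosaic(mosaic, config.survival_p, seed=int(rng.integers(2**31)))
    return mosaic


def thin_mosaic(mosaic: Mosaic, survival_p: float, seed: int | None = None) -> Mosaic:
    """Keep each point independently with probability ``survival_p``.

    Thinning cannot violate a hard-core constraint, and thinning a Poisson
    pattern yields a Poisson pattern of intensity ``survival_p * λ``.
    """
    if not (0 <= survival_p <= 1):
        raise ValueError("survival_p must be in [0, 1]")
    if survival_p == 1:
        return Mosaic(mosaic.points.copy(), mosaic.width_um, mosaic.height_um)
    rng = np.random.default_rng(seed)
    keep = rng.random(len(mosaic)) < survival_p
    return Mosaic(mosaic.points[keep], mosaic.width_um, mosaic.height_um)
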