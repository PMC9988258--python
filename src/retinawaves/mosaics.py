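"""Soma-mosaic statistics: density, nearest-neighbour distance, regularity.

Density is estimated by quadrat sampling: the field is tiled with square
quadrats (default 200 µm), quadrats overlapping the boundary or an
exclusion mask are dropped, a random subset is drawn, and the density is
the mean count per sampled quadrat divided by the quadrat area.

The nearest-neighbour distance (NND) of each soma is its shortest
Euclidean distance to any other soma; the regularity index (RI) is the
mean NND divided by its SD.  For a homogeneous Poisson pattern the RI
tends to sqrt(pi / (4 - pi)) ≈ 1.913 regardless of density; spatial
inhibition (e.g. a hard-core exclusion at the soma diameter) raises it.
A Monte-Carlo reference for hard-core mosaics at a given density provides
the "random mosaic" comparison band.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import Mosaic
from .wavesim import MosaicSimConfig, simulate_mosaic

__all__ = [
    "DensityEstimate",
    "NndResult",
    "RiReference",
    "POISSON_RI",
    "estimate_density",
    "compute_nnd",
    "regularity_index",
    "nnd_cdf",
    "random_mosaic_reference",
]

# Exact RI of an unbounded homogeneous Poisson process: the NND is Rayleigh
# distributed, whose mean/SD ratio is sqrt(pi / (4 - pi)).
POISSON_RI = math.sqrt(math.pi / (4.0 - math.pi))


@dataclass
class DensityEstimate:
    """Quadrat-sampled density with the per-quadrat counts that produced it."""

    density_per_mm2: float
    n_squares_sampled: int
    n_squares_eligible: int
    square_size_um: float
    per_square_counts: np.ndarray
    seed: int | None


@dataclass
class NndResult:
    """Per-point NNDs and their summary (mean, SD, median, RI, CDF)."""

    distances: np.ndarray
    mean_um: float
    sd_um: float | None
    median_um: float
    regularity_index: float | None
    degenerate: bool = False  # SD == 0 (e.g. a perfect lattice); RI undefined


@dataclass
class RiReference:
    """Monte-Carlo regularity-index distribution for random hard-core mosaics."""

    ris: np.ndarray
    mean: float
    sd: float
    ci95: tuple[float, float]
    soma_diameter_um: float
    density_per_mm2: float


def estimate_density(
    mosaic: Mosaic,
    square_um: float = 200.0,
    n_sample: int = 50,
    seed: int | None = None,
    exclusion_mask: np.ndarray | None = None,
    mask_px_um: float | None = None,
) -> DensityEstimate:
    """Estimate cell density (per mm²) by random quadrat sampling.

    Quadrats are tiled from the field origin; only quadrats lying fully
    inside the boundary and not touching the exclusion mask (True =
    excluded, at ``mask_px_um`` per pixel) are eligible.  ``n_sample``
    quadrats are drawn without replacement (all of them, with a warning,
    if fewer are eligible).
    """
    nx = int(mosaic.width_um // square_um)
    ny = int(mosaic.height_um // square_um)
    if nx < 1 or ny < 1:
        raise ValueError("field smaller than a single quadrat")
    eligible = np.ones((ny, nx), dtype=bool)
    if exclusion_mask is not None:
        if mask_px_um is None:
            raise ValueError("mask_px_um required with exclusion_mask")
        mask = np.asarray(exclusion_mask, dtype=bool)
        for iy in range(ny):
            for ix in range(nx):
                r0 = int(iy * square_um / mask_px_um)
                r1 = int(np.ceil((iy + 1) * square_um / mask_px_um))
                c0 = int(ix * square_um / mask_px_um)
                c1 = int(np.ceil((ix + 1) * square_um / mask_px_um))
                if mask[r0:r1, c0:c1].any():
                    eligible[iy, ix] = False
    elig_idx = np.flatnonzero(eligible.ravel())
    if len(elig_idx) == 0:
        raise ValueError("no eligible quadrats")
    if len(elig_idx) < n_sample:
        warnings.warn(
            f"only {len(elig_idx)} eligible quadrats (< n_sample={n_sample}); using all"
        )
        chosen = elig_idx
    else:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(elig_idx, size=n_sample, replace=False)

    counts_all = np.zeros(ny * nx, dtype=np.int64)
    if len(mosaic):
        ix = (mosaic.points[:, 0] // square_um).astype(np.int64)
        iy = (mosaic.points[:, 1] // square_um).astype(np.int64)
        inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        np.add.at(counts_all, iy[inside] * nx + ix[inside], 1)
    counts = counts_all[chosen]
    density = counts.mean() / (square_um**2) * 1e6
    return DensityEstimate(
        density_per_mm2=float(density),
        n_squares_sampled=len(chosen),
        n_squares_eligible=len(elig_idx),
        square_size_um=square_um,
        per_square_counts=counts,
        seed=seed,
    )


def compute_nnd(mosaic: Mosaic) -> NndResult:
    """Nearest-neighbour distance of every point (no edge correction)."""
    if len(mosaic) < 2:
        raise ValueError("NND requires at least 2 points")
    tree = cKDTree(mosaic.points)
    d, _ = tree.query(mosaic.points, k=2)
    distances = d[:, 1]
    sd = float(distances.std(ddof=1))
    degenerate = sd == 0.0
    return NndResult(
        distances=distances,
        mean_um=float(distances.mean()),
        sd_um=None if degenerate else sd,
        median_um=float(np.median(distances)),
        regularity_index=None if degenerate else float(distances.mean() / sd),
        degenerate=degenerate,
    )


def regularity_index(nnd: NndResult) -> float:
    """Mean NND / SD of NND; undefined (raises) when the SD is zero."""
    if nnd.degenerate or nnd.regularity_index is None:
        raise ValueError("regularity index undefined: NND standard deviation is zero")
    return nnd.regularity_index


def nnd_cdf(nnd: NndResult) -> pd.DataFrame:
    """Empirical CDF table of NNDs: sorted distances with fraction i/n."""
    d = np.sort(nnd.distances)
    return pd.DataFrame(
        {"distance_um": d, "cum_fraction": np.arange(1, len(d) + 1) / len(d)}
    )


def random_mosaic_reference(
    density_per_mm2: float,
    soma_diameter_um: float,
    field_um: float = 1000.0,
    n_reps: int = 100,
    seed: int | None = None,
) -> RiReference:
    """Monte-Carlo RI distribution for random mosaics of hard somata.

    Simulates ``n_reps`` sequential-inhibition mosaics with hard-core
    distance equal to the soma diameter at the stated density, and
    reports the mean, SD and central 95 % interval of their regularity
    indices.  With ``soma_diameter_um -> 0`` this converges to the
    Poisson value ``POISSON_RI``.
    """
    rng = np.random.default_rng(seed)
    ris = np.empty(n_reps)
    for i in range(n_reps):
        mosaic = simulate_mosaic(
            MosaicSimConfig(
                width_um=field_um,
                height_um=field_um,
                intensity_per_mm2=density_per_mm2,
                min_separation_um=soma_diameter_um,
                seed=int(rng.integers(2**31)),
            )
        )
        ris[i] = compute_nnd(mosaic).regularity_index
    lo, hi = np.percentile(ris, [2.5, 97.5])
    return RiReference(
        ris=ris,
        mean=float(ris.mean()),
        sd=float(ris.std(ddof=1)),
        ci95=(float(lo), float(hi)),
        soma_diameter_um=soma_diameter_um,
        density_per_mm2=density_per_mm2,
    )
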