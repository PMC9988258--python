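"""Bootstrap test for per-cell wave participation, plus amplitude summaries.

For each cell, the null distribution of "resting" activity is built by
sampling (with replacement) many windows of wave-window length from the
portions of the recording that contain no wave, recording the mean ΔF/F
of each.  A cell is said to participate in a wave when its mean ΔF/F over
that wave's window exceeds the 95th percentile of its own null — i.e. a
one-sided 5 % test against the cell's resting activity.  Response
amplitudes (window maxima) are then summarized per cell and per field of
view, with a thin two-sample-t reporting layer for labeled cell groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import TraceMatrix
from .waves import WaveCatalog

__all__ = [
    "NullDistribution",
    "ParticipationMatrix",
    "build_null",
    "test_participation",
    "response_amplitude",
    "compare_groups",
]


@dataclass
class NullDistribution:
    """Per-cell bootstrap baseline statistics and their 95th percentiles."""

    stats: np.ndarray  # (n_cells, n_boot) window-mean ΔF/F
    q95: np.ndarray  # (n_cells,)
    window_frames: int
    seed: int | None

    @property
    def n_boot(self) -> int:
        return self.stats.shape[1]


@dataclass
class ParticipationMatrix:
    """Cell x wave participation calls and per-cell percentages."""

    matrix: np.ndarray  # (n_cells, n_waves) bool
    cell_ids: np.ndarray
    wave_ids: np.ndarray
    percent_participation: np.ndarray  # (n_cells,)

    @property
    def n_waves(self) -> int:
        return self.matrix.shape[1]

    @property
    def fov_percent(self) -> float:
        """Field-of-view mean of per-cell participation percentages."""
        return float(self.percent_participation.mean())


def _wave_windows(traces: TraceMatrix, catalog: WaveCatalog):
    """Frame spans [a, b) of retained wave windows, dropping truncated ones."""
    w = int(round(catalog.half_window_s * traces.fps))
    spans, wave_ids = [], []
    for e in catalog.retained():
        a, b = e.peak_frame - w, e.peak_frame + w + 1
        if a < 0 or b > traces.n_frames:
            continue
        spans.append((a, b))
        wave_ids.append(e.event_id)
    return spans, np.asarray(wave_ids, dtype=np.int64), 2 * w + 1


def build_null(
    traces: TraceMatrix,
    catalog: WaveCatalog,
    n_boot: int = 1000,
    seed: int | None = None,
) -> NullDistribution:
    """Bootstrap null of window-mean ΔF/F from non-wave time, per cell.

    Windows are drawn uniformly with replacement among all start frames
    whose full window contains no wave-window frame, so every sampled
    window is disjoint from every wave.  Raises if the recording has no
    such window (insufficient non-wave coverage).
    """
    spans, _, window = _wave_windows(traces, catalog)
    in_wave = np.zeros(traces.n_frames, dtype=bool)
    for a, b in spans:
        in_wave[a:b] = True
    # a start s is valid when frames [s, s+window) are all outside waves
    free = ~in_wave
    ok = np.ones(traces.n_frames - window + 1, dtype=bool)
    csum = np.concatenate([[0], np.cumsum(free)])
    ok = (csum[window:] - csum[:-window]) == window
    valid_starts = np.flatnonzero(ok)
    if len(valid_starts) == 0:
        raise ValueError(
            f"insufficient non-wave time: {free.sum()}/{traces.n_frames} free "
            f"frames, none spanning a full {window}-frame window"
        )
    rng = np.random.default_rng(seed)
    starts = rng.choice(valid_starts, size=(traces.n_roi, n_boot), replace=True)
    c = np.concatenate(
        [np.zeros((traces.n_roi, 1)), np.cumsum(traces.traces, axis=1)], axis=1
    )
    rows = np.arange(traces.n_roi)[:, None]
    boot = (c[rows, starts + window] - c[rows, starts]) / window
    q95 = np.percentile(boot, 95, axis=1)
    return NullDistribution(stats=boot, q95=q95, window_frames=window, seed=seed)


def test_participation(
    traces: TraceMatrix, catalog: WaveCatalog, null: NullDistribution
) -> ParticipationMatrix:
    """Call cell-wave participation against each cell's null 95th percentile.

    Wave windows truncated by the recording edge are excluded from the
    denominator.  With zero analyzable waves the matrix is empty and the
    per-cell percentages are reported as NaN.
    """
    spans, wave_ids, window = _wave_windows(traces, catalog)
    if window != null.window_frames:
        raise ValueError("null distribution was built for a different window length")
    n_cells = traces.n_roi
    if not spans:
        return ParticipationMatrix(
            matrix=np.zeros((n_cells, 0), dtype=bool),
            cell_ids=traces.roi_ids,
            wave_ids=wave_ids,
            percent_participation=np.full(n_cells, np.nan),
        )
    means = np.stack(
        [traces.traces[:, a:b].mean(axis=1) for a, b in spans], axis=1
    )
    matrix = means > null.q95[:, None]
    pct = 100.0 * matrix.sum(axis=1) / matrix.shape[1]
    return ParticipationMatrix(
        matrix=matrix,
        cell_ids=traces.roi_ids,
        wave_ids=wave_ids,
        percent_participation=pct,
    )


def response_amplitude(
    traces: TraceMatrix,
    catalog: WaveCatalog,
    matrix: ParticipationMatrix,
    group: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-cell mean response amplitude over participated waves.

    The (cell, wave) amplitude is the maximum ΔF/F in the wave window;
    the per-cell amplitude averages over the waves that cell participated
    in (NaN for cells participating in none).  Returns a per-cell table
    with percent participation, mean amplitude and optional group label.
    """
    spans, _, _ = _wave_windows(traces, catalog)
    if len(spans) != matrix.n_waves:
        raise ValueError("participation matrix does not match the catalog")
    if spans:
        maxima = np.stack(
            [traces.traces[:, a:b].max(axis=1) for a, b in spans], axis=1
        )
        masked = np.where(matrix.matrix, maxima, np.nan)
        with warnings.catch_warnings():
            # cells participating in no wave deliberately yield NaN
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_amp = np.nanmean(masked, axis=1)
    else:
        mean_amp = np.full(traces.n_roi, np.nan)
    table = pd.DataFrame(
        {
            "cell_id": matrix.cell_ids,
            "percent_participation": matrix.percent_participation,
            "mean_amplitude": mean_amp,
        }
    )
    if group is not None:
        table["group"] = np.asarray(group)
    return table


def compare_groups(
    cell_table: pd.DataFrame, metric: str = "percent_participation"
) -> dict:
    """Two-sample t comparison of a per-cell metric between two groups.

    A thin reporting layer (Welch off, plain two-sample t as is standard
    for this comparison); requires a ``group`` column with exactly two
    levels.  Returns group means/SDs, t statistic and p value.
    """
    levels = pd.unique(cell_table["group"])
    if len(levels) != 2:
        raise ValueError("compare_groups needs exactly two group levels")
    a = cell_table.loc[cell_table["group"] == levels[0], metric].dropna()
    b = cell_table.loc[cell_table["group"] == levels[1], metric].dropna()
    t, p = stats.ttest_ind(a, b)
    return {
        "metric": metric,
        "groups": (str(levels[0]), str(levels[1])),
        "means": (float(a.mean()), float(b.mean())),
        "sds": (float(a.std(ddof=1)), float(b.std(ddof=1))),
        "t": float(t),
        "p": float(p),
    }
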