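"""Wave segmentation, classification, kinematics and summaries."""

import numpy as np
import pytest

import retinawaves as rw
from retinawaves import studies
from retinawaves.waves import REFERENCE_WAVE_SPEEDS


def raster_from_events(events, n_roi, n_frames, centroids=None, fps=10.0):
    """Build a raster where each event is a list of (roi, frame) transients."""
    raster = np.zeros((n_roi, n_frames), dtype=bool)
    for ev in events:
        for roi, frame in ev:
            raster[roi, frame] = True
    if centroids is None:
        centroids = np.zeros((n_roi, 2))
    return rw.TransientRaster(
        raster=raster,
        amplitudes=raster.astype(np.float32),
        threshold_used=np.full(n_roi, 0.1),
        fps=fps,
        roi_ids=np.arange(n_roi),
        roi_centroids_um=np.asarray(centroids, dtype=float),
    )


def synchronized_event(n_roi, frame):
    return [(i, frame) for i in range(n_roi)]


class TestPercentActive:
    def test_fraction_of_rois(self):
        raster = raster_from_events([[(i, 5) for i in range(50)]], 100, 20)
        act = rw.percent_active_trace(raster)
        assert act.percent_active[5] == 50.0
        assert act.percent_active[4] == 0.0

    def test_empty_raster_warns_and_disables_z(self):
        raster = raster_from_events([], 10, 20)
        with pytest.warns(UserWarning, match="zero variance"):
            act = rw.percent_active_trace(raster)
        assert act.zscores is None
        assert len(rw.detect_waves(act)) == 0

    def test_synchronized_event_has_large_z(self):
        raster = raster_from_events([synchronized_event(100, 500)], 100, 1000)
        act = rw.percent_active_trace(raster)
        assert act.zscores[500] > 5


class TestDetectWaves:
    def test_flat_trace_no_waves(self):
        act = rw.ActivityTrace(np.zeros(100), None, fps=10.0)
        assert len(rw.detect_waves(act)) == 0

    def test_two_separated_peaks_recovered(self):
        events = [synchronized_event(50, 200), synchronized_event(50, 800)]
        raster = raster_from_events(events, 50, 1200)
        peaks = rw.detect_waves(rw.percent_active_trace(raster))
        assert list(peaks) == [200, 800]

    def test_edge_events_excluded(self):
        # a wave at t = 3 s is an edge case and must be dropped
        events = [synchronized_event(50, 30), synchronized_event(50, 600)]
        raster = raster_from_events(events, 50, 1200)
        peaks = rw.detect_waves(rw.percent_active_trace(raster))
        assert list(peaks) == [600]

    def test_edge_rule_removes_exactly_the_shifted_wave(self):
        # shifting the recording so one wave enters the first 6 s removes
        # that wave only; the other peak keeps its (shifted) position
        events = [synchronized_event(50, 100), synchronized_event(50, 700)]
        full = raster_from_events(events, 50, 1200)
        peaks_full = rw.detect_waves(rw.percent_active_trace(full))
        shifted = raster_from_events(
            [synchronized_event(50, 50), synchronized_event(50, 650)], 50, 1150
        )
        peaks_shift = rw.detect_waves(rw.percent_active_trace(shifted))
        assert list(peaks_full) == [100, 700]
        assert list(peaks_shift) == [650]


class TestBuildWaveEvents:
    def grid_centroids(self, n_side, pitch=17.0):
        g = (np.arange(n_side) + 0.5) * pitch
        gx, gy = np.meshgrid(g, g)
        return np.column_stack([gx.ravel(), gy.ravel()])

    def test_full_participation_area_100(self):
        raster = raster_from_events(
            [synchronized_event(25, 100)], 25, 300, self.grid_centroids(5, 100.0)
        )
        catalog = rw.build_wave_events([100], raster)
        assert catalog.events[0].area_pct == 100.0
        assert catalog.events[0].kind == "propagating"

    def test_small_extent_classified_local(self):
        # participating centroids spanning 120 x 90 µm -> local
        centroids = np.zeros((30, 2))
        centroids[:10, 0] = np.linspace(0, 120, 10)
        centroids[:10, 1] = np.linspace(0, 90, 10)
        centroids[10:] = 500.0
        raster = raster_from_events([[(i, 100) for i in range(10)]], 30, 300, centroids)
        catalog = rw.build_wave_events([100], raster)
        event = catalog.events[0]
        assert event.kind == "local"
        assert event.extent_um == (120.0, 90.0)
        assert event.area_pct == pytest.approx(100 * 10 / 30)

    def test_overlap_ties_resolve_to_earlier_peak(self):
        # a transient equidistant from two peaks belongs to the earlier one
        raster = raster_from_events([[(0, 150)]], 1, 400)
        catalog = rw.build_wave_events([100, 200], raster)
        assert catalog.events[0].n_roi == 1
        assert catalog.events[1].n_roi == 0

    def test_clipped_window_flagged_excluded(self):
        raster = raster_from_events([synchronized_event(10, 30)], 10, 300)
        catalog = rw.build_wave_events([30], raster)  # window would start at -3 s
        assert "excluded" in catalog.events[0].flags
        assert catalog.retained() == []


class TestInitiationAndSpeed:
    def test_three_roi_median(self):
        centroids = np.array([[0.0, 0.0], [10.0, 0.0], [20.0, 30.0], [900.0, 900.0]])
        raster = raster_from_events(
            [[(0, 100), (1, 100), (2, 100), (3, 105)]], 4, 300, centroids
        )
        catalog = rw.build_wave_events([100], raster)
        site = rw.initiation_site(catalog.events[0], raster)
        assert site == (10.0, 0.0)

    def test_distant_simultaneous_seeds_flagged_ambiguous(self):
        centroids = np.array([[0.0, 0.0], [500.0, 0.0], [250.0, 10.0], [250.0, 20.0]])
        raster = raster_from_events(
            [[(0, 100), (1, 100), (2, 103), (3, 104)]], 4, 300, centroids
        )
        catalog = rw.build_wave_events([100], raster)
        rw.initiation_site(catalog.events[0], raster)
        assert "ambiguous_initiation" in catalog.events[0].flags

    def test_single_frame_event_has_no_speed(self):
        centroids = np.column_stack([np.linspace(0, 400, 12), np.zeros(12)])
        raster = raster_from_events(
            [[(i, 100) for i in range(12)]], 12, 300, centroids
        )
        catalog = rw.build_wave_events([100], raster)
        assert rw.estimate_speed(catalog.events[0], raster) is None
        assert "no_speed" in catalog.events[0].flags

    @pytest.mark.parametrize("true_speed", [181.0, 99.0])
    def test_simulated_wave_speed_within_ten_percent(self, true_speed):
        event = studies.measure_single_wave(true_speed, seed=21)
        assert event is not None
        assert event.speed_um_s == pytest.approx(true_speed, rel=0.10)

    def test_initiation_site_recovered_within_roi_pitch(self):
        event = studies.measure_single_wave(150.0, seed=22)
        x, y = event.initiation_xy_um
        assert abs(x - 750.0) <= 17.0 and abs(y - 750.0) <= 17.0


class TestFrequencyAndSummaries:
    def make_catalog(self, n_prop, duration_s, edge=0.0):
        events = [
            rw.WaveEvent(
                event_id=i,
                peak_frame=100 + 120 * i,
                window_s=(0, 12),
                roi_index=np.empty(0, dtype=np.int64),
                first_frames=np.empty(0, dtype=np.int64),
                area_pct=50.0,
                extent_um=(500.0, 500.0),
                kind="propagating",
            )
            for i in range(n_prop)
        ]
        return rw.WaveCatalog(
            events=events,
            duration_s=duration_s,
            n_roi=100,
            fps=10.0,
            edge_exclusion_s=edge,
        )

    def test_eight_waves_in_eight_minutes(self):
        assert rw.wave_frequency(self.make_catalog(8, 480.0)) == pytest.approx(1.0)

    def test_empty_catalog_zero_frequency(self):
        assert rw.wave_frequency(self.make_catalog(0, 480.0)) == 0.0

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            rw.wave_frequency(self.make_catalog(1, 10.0, edge=6.0))

    def test_identical_speeds_have_zero_sd(self):
        mean, sd = rw.summarize_speeds([100.0, 100.0, 100.0])
        assert mean == 100.0 and sd == 0.0

    def test_single_speed_has_no_sd(self):
        mean, sd = rw.summarize_speeds([123.0])
        assert mean == 123.0 and sd is None

    def test_reference_speed_summaries(self):
        # worked example on the packaged per-wave speed table
        mean, sd = rw.summarize_speeds(REFERENCE_WAVE_SPEEDS["wt_stage1"])
        assert (round(mean, 2), round(sd, 2)) == (181.12, 24.39)
        mean, sd = rw.summarize_speeds(REFERENCE_WAVE_SPEEDS["b2ko_stage1"])
        assert (round(mean, 2), round(sd, 2)) == (99.39, 14.72)


def test_programmed_wave_rate_recovered():
    """A 10-min recording at mean interval 80 s yields ~0.75 waves/min."""
    cfg = rw.WaveSimConfig(
        fov_um=400.0,
        px_um=10.0,
        duration_s=600.0,
        mean_wave_interval_s=80.0,
        interval_model="gamma",
        footprint_fraction=0.95,
        local_event_rate_per_min=0.0,
        noise_sd=1.0,
        seed=17,
    )
    movie, truth = rw.simulate_movie(cfg)
    _, _, catalog = studies.analyze_movie(movie)
    freq = rw.wave_frequency(catalog)
    # Poisson-scale tolerance around 0.75/min for a 10-min recording
    assert 0.3 <= freq <= 1.2
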