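"""Spot detection, tracking, MSD and motility classification."""

import numpy as np
import pytest

from piezoquant import tirf
from piezoquant.exceptions import InvalidParameterError, WindowError
from piezoquant.synthgen import (
    MotionModel,
    TirfMovieConfig,
    simulate_tirf_movie,
    simulate_trajectories,
)

PX = 0.11


def render_single_spot(x_px, y_px, shape=(64, 64), sigma_px=1.5, amp=800.0,
                       bg=200.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = bg + amp * np.exp(
        -((xx - x_px) ** 2 + (yy - y_px) ** 2) / (2 * sigma_px**2)
    )
    if noise:
        img = img + rng.normal(0, noise, shape)
    return img


class TestDetectSpots:
    def test_blank_frames_rarely_trigger(self):
        """At a threshold calibrated to 5x the blank-frame response, >= 95%
        of seeded blank frames yield no detection."""
        rng = np.random.default_rng(0)
        blanks = rng.normal(200.0, 20.0, size=(10, 64, 64))
        thr = tirf.calibrate_quality_threshold(blanks, PX)
        empty = 0
        for seed in range(40):
            frame = np.random.default_rng(100 + seed).normal(200.0, 20.0, (64, 64))
            empty += len(tirf.detect_spots(frame, PX, quality_min=thr)) == 0
        assert empty >= 38

    def test_single_spot_localized_to_half_pixel(self):
        img = render_single_spot(30.3, 17.7, noise=5.0)
        spots = tirf.detect_spots(img, PX, quality_min=10)
        assert len(spots) == 1
        assert abs(spots[0].x / PX - 30.3) <= 0.5
        assert abs(spots[0].y / PX - 17.7) <= 0.5

    def test_well_separated_pair_resolved(self):
        img = render_single_spot(20, 20) + render_single_spot(40, 40) - 200.0
        spots = tirf.detect_spots(img, PX, quality_min=10)
        assert len(spots) == 2

    def test_blob_smaller_than_2px_rejected(self):
        with pytest.raises(InvalidParameterError):
            tirf.detect_spots(np.zeros((32, 32)), pixel_size_um=0.5,
                              blob_diameter_um=0.7)


class TestLinkTracks:
    @staticmethod
    def _spots(positions_by_frame):
        return [
            [tirf.Spot(frame=f, x=x, y=y, quality=20.0, intensity=1.0)
             for x, y in pts]
            for f, pts in enumerate(positions_by_frame)
        ]

    def test_stationary_spot_yields_single_full_track(self):
        spots = self._spots([[(1.0, 1.0)]] * 50)
        tracks = tirf.link_tracks(spots, min_duration=40)
        assert len(tracks) == 1
        assert tracks[0].duration == 50

    def test_gap_longer_than_max_gap_splits_track(self):
        frames = [[(1.0, 1.0)]] * 20 + [[]] * 3 + [[(1.0, 1.0)]] * 20
        tracks = tirf.link_tracks(self._spots(frames), max_gap=2, min_duration=5)
        assert len(tracks) == 2

    def test_short_gap_closed_and_counted(self):
        frames = [[(1.0, 1.0)]] * 20 + [[]] * 2 + [[(1.0, 1.0)]] * 20
        tracks = tirf.link_tracks(self._spots(frames), max_gap=2, min_duration=5)
        assert len(tracks) == 1
        assert tracks[0].gaps == 2

    def test_empty_input_gives_empty_output(self):
        assert tirf.link_tracks([]) == []

    def test_no_track_shorter_than_min_duration(self):
        rng = np.random.default_rng(3)
        frames = []
        for f in range(60):
            pts = [(1.0 + 0.01 * rng.normal(), 1.0 + 0.01 * rng.normal())]
            if f % 13 == 0:
                pts = []  # periodic dropouts fragment the track
            frames.append(pts)
        tracks = tirf.link_tracks(self._spots(frames), max_gap=0, min_duration=10)
        assert all(t.duration >= 10 for t in tracks)

    def test_low_density_links_match_ground_truth(self):
        """>= 95% of frame-to-frame links agree with truth when steps are
        far smaller than the linking distance."""
        motions = [
            (MotionModel("diffusion", D=0.005), (1.0 + 1.2 * k, 1.0 + 0.9 * (k % 4)))
            for k in range(10)
        ]
        truth = simulate_trajectories(motions, 50, 10.0, seed=4)
        spots_per_frame = [
            [
                tirf.Spot(frame=f, x=row.x_um, y=row.y_um, quality=20.0, intensity=1.0)
                for row in sub.itertuples()
            ]
            for f, sub in truth.groupby("frame")
        ]
        tracks = tirf.link_tracks(spots_per_frame, min_duration=40)
        assert len(tracks) == 10
        good = total = 0
        for t in tracks:
            # truth track identified by the starting position
            start = np.array([t.x[0], t.y[0]])
            t0 = truth[truth.frame == 0]
            tid = t0.iloc[
                np.argmin(np.hypot(t0.x_um - start[0], t0.y_um - start[1]))
            ].track_id
            ref = truth[truth.track_id == tid].set_index("frame")
            for f, x, y in zip(t.frames, t.x, t.y):
                total += 1
                good += np.hypot(ref.loc[f, "x_um"] - x, ref.loc[f, "y_um"] - y) < 1e-9
        assert good / total >= 0.95


class TestComputeMsd:
    @staticmethod
    def _track(xy, frames=None):
        frames = frames if frames is not None else list(range(len(xy)))
        return tirf.Track(id=0, frames=frames, x=[p[0] for p in xy], y=[p[1] for p in xy])

    def test_stationary_track_msd_zero(self):
        msd = tirf.compute_msd(self._track([(1.0, 2.0)] * 40), 10.0)
        np.testing.assert_allclose(msd.msd, 0.0)

    def test_drift_track_msd_is_v2_tau2_exactly(self):
        v, rate = 0.8, 10.0
        xy = [(v * f / rate, 0.0) for f in range(60)]
        msd = tirf.compute_msd(self._track(xy), rate)
        np.testing.assert_allclose(msd.msd, v**2 * msd.lags**2, rtol=1e-12)

    def test_time_reversal_symmetry(self):
        rng = np.random.default_rng(5)
        xy = np.cumsum(rng.normal(0, 0.1, (80, 2)), axis=0)
        fwd = tirf.compute_msd(self._track(list(map(tuple, xy))), 10.0)
        rev = tirf.compute_msd(self._track(list(map(tuple, xy[::-1]))), 10.0)
        np.testing.assert_allclose(fwd.msd, rev.msd, rtol=1e-12)

    def test_short_track_rejected(self):
        with pytest.raises(WindowError):
            tirf.compute_msd(self._track([(0.0, 0.0)] * 3), 10.0)

    def test_brownian_ensemble_matches_4dt(self):
        from piezoquant.experiments import msd_diffusion_recovery

        res = msd_diffusion_recovery(n_tracks=100, seed=6)
        assert res["max_rel_deviation"] < 0.15


class TestClassifyTrack:
    def test_pure_drift_classified_directed(self):
        v, rate = 1.0, 10.0
        xy = [(v * f / rate, 0.0) for f in range(60)]
        track = tirf.Track(id=0, frames=list(range(60)), x=[p[0] for p in xy],
                           y=[p[1] for p in xy])
        cls = tirf.classify_track(tirf.compute_msd(track, rate), track)
        assert cls.category == "directed"
        assert cls.alpha == pytest.approx(2.0, abs=1e-6)

    def test_degenerate_all_zero_msd_flagged_confined(self):
        track = tirf.Track(id=0, frames=list(range(40)), x=[0.0] * 40, y=[0.0] * 40)
        cls = tirf.classify_track(tirf.compute_msd(track, 10.0), track)
        assert cls.category == "confined"
        assert cls.degenerate
        assert cls.D_fit == 0.0

    @pytest.mark.parametrize(
        "category", ["diffusion", "subdiffusion", "confined", "directed"]
    )
    def test_panel_accuracy_at_least_85_percent(self, category):
        from piezoquant.experiments import (
            EXPECTED_CATEGORY,
            motility_classification_panel,
        )

        res = motility_classification_panel(n_per_class=40, seed=7)
        assert res["per_class_accuracy"][category] >= 0.85


class TestClusterMeasures:
    def test_sigma_2px_gives_0p44_um_diameter(self):
        img = render_single_spot(20, 20, shape=(41, 41), sigma_px=2.0)
        fit = tirf.cluster_diameter(img, PX)
        assert fit.converged
        assert fit.diameter == pytest.approx(2 * 2.0 * PX, rel=0.02)

    def test_noiseless_spot_recovers_psf_sigma_exactly(self):
        sigma_um = 0.165  # 1.5 px
        img = render_single_spot(16, 16, shape=(33, 33), sigma_px=sigma_um / PX)
        fit = tirf.cluster_diameter(img, PX)
        assert fit.sigma_x == pytest.approx(sigma_um, abs=1e-4)
        assert fit.sigma_y == pytest.approx(sigma_um, abs=1e-4)

    def test_noisy_spot_diameter_within_10_percent_median(self):
        sigma_px = 1.5
        diams = []
        for seed in range(60):
            img = render_single_spot(
                16.4, 15.7, shape=(33, 33), sigma_px=sigma_px, noise=80.0, seed=seed
            )  # SNR ~ 10
            fit = tirf.cluster_diameter(img, PX)
            if fit.converged:
                diams.append(fit.diameter)
        median = np.median(diams)
        assert median == pytest.approx(2 * sigma_px * PX, rel=0.10)

    @pytest.mark.parametrize("n_spots,area,expected", [(50, 100.0, 0.5), (0, 10.0, 0.0)])
    def test_density_is_count_over_area(self, n_spots, area, expected):
        spots = [tirf.Spot(0, 0.0, 0.0, 20.0, 1.0)] * n_spots
        assert tirf.cluster_density(spots, area) == expected

    def test_nonpositive_area_rejected(self):
        with pytest.raises(InvalidParameterError):
            tirf.cluster_density([], 0.0)

    def test_planted_spots_recovered_exactly_when_recall_perfect(self):
        cfg = TirfMovieConfig(n_frames=2, frame_shape=(96, 96), seed=1)
        positions = [(2.0 + 2.0 * i, 2.0 + 1.5 * j) for i in range(4) for j in range(4)]
        motions = [(MotionModel("diffusion", D=0.0), p) for p in positions]
        stack, _ = simulate_tirf_movie(cfg, motions)
        spots = tirf.detect_spots(stack[0], cfg.pixel_size, quality_min=10)
        area = 50.0
        assert tirf.cluster_density(spots, area) == len(positions) / area


class TestTranslationInvariance:
    def test_integer_pixel_shift_shifts_tracks_exactly(self):
        """Rolling the whole movie by an integer pixel offset shifts every
        detected track coordinate by exactly that offset."""
        cfg = TirfMovieConfig(n_frames=45, frame_shape=(64, 64), seed=2)
        motions = [
            (MotionModel("diffusion", D=0.01), (2.0, 2.0)),
            (MotionModel("diffusion", D=0.01), (4.5, 3.5)),
        ]
        stack, _ = simulate_tirf_movie(cfg, motions)
        dy, dx = 7, 5
        shifted = np.roll(stack, (dy, dx), axis=(1, 2))

        def tracked(movie):
            spots = tirf.detect_movie(movie, cfg.pixel_size, quality_min=10)
            tracks = tirf.link_tracks(spots, min_duration=40)
            return sorted(tracks, key=lambda t: (t.x[0], t.y[0]))

        t0 = tracked(stack)
        t1 = tracked(shifted)
        assert len(t0) == len(t1) == 2
        for a, b in zip(t0, t1):
            np.testing.assert_allclose(
                np.array(b.x), np.array(a.x) + dx * cfg.pixel_size, atol=1e-9
            )
            np.testing.assert_allclose(
                np.array(b.y), np.array(a.y) + dy * cfg.pixel_size, atol=1e-9
            )
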