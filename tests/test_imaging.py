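import numpy as np
import pytest

import polarcomp as pc
from polarcomp.imaging import Spot


def frame_with_gaussians(size, centers, amps, sigma=1.5, background=100.0):
    img = np.full((size, size), background)
    yy, xx = np.mgrid[:size, :size]
    for (cy, cx), a in zip(centers, amps):
        img += a * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma ** 2))
    return img


class TestSegmentSpots:
    def test_blank_frame(self):
        img = np.full((32, 32), 50.0)
        assert pc.segment_spots(img, 10.0, 60.0) == []

    def test_two_spots_one_speckle(self):
        img = frame_with_gaussians(64, [(16, 16), (48, 48)], [100, 80])
        img[30, 5] = 400.0          # single-pixel speckle
        spots = pc.segment_spots(img, 50.0, 140.0, filter_size_px2=4)
        assert len(spots) == 2

    def test_centroid_accuracy(self):
        img = frame_with_gaussians(64, [(20.0, 31.0)], [120])
        spots = pc.segment_spots(img, 50.0, 140.0)
        assert len(spots) == 1
        cy, cx = spots[0].centroid
        assert abs(cy - 20.0) < 0.5 and abs(cx - 31.0) < 0.5

    def test_threshold_order_enforced(self):
        with pytest.raises(ValueError):
            pc.segment_spots(np.zeros((8, 8)), 100.0, 50.0)


def scripted_frames(positions_per_frame):
    """Build per-frame Spot lists from scripted (y, x, intensity) tuples."""
    out = []
    for t, frame in enumerate(positions_per_frame):
        out.append([Spot(frame=t, centroid=(y, x), area=5.0, intensity=i)
                    for (y, x, i) in frame])
    return out


class TestTrackSpots:
    def test_single_stationary_spot(self):
        frames = scripted_frames([[(10.0, 10.0, 50.0)]] * 20)
        tracks = pc.track_spots(frames, target_radius_px=3.0)
        assert len(tracks) == 1
        assert len(tracks[0]) == 20

    def test_blink_bridging(self):
        script = [[(10.0, 10.0, 50.0)]] * 5 + [[]] * 2 \
            + [[(10.5, 10.0, 50.0)]] * 5
        frames = scripted_frames(script)
        bridged = pc.track_spots(frames, 3.0, remove_blinking=True, max_gap=2)
        assert len(bridged) == 1 and len(bridged[0]) == 10
        split = pc.track_spots(frames, 3.0, remove_blinking=False)
        assert len(split) == 2

    def test_gap_longer_than_max_not_bridged(self):
        script = [[(10.0, 10.0, 50.0)]] * 3 + [[]] * 3 \
            + [[(10.0, 10.0, 50.0)]] * 3
        tracks = pc.track_spots(scripted_frames(script), 3.0,
                                remove_blinking=True, max_gap=2)
        assert len(tracks) == 2

    def test_no_identity_swaps(self):
        script = [[(10.0, 10.0, 50.0), (40.0, 40.0, 60.0)]] * 15
        tracks = pc.track_spots(scripted_frames(script), 3.0)
        assert len(tracks) == 2
        for tr in tracks:
            cents = {tr.spots[f].centroid for f in tr.frames}
            assert len(cents) == 1


class TestVicinityTrace:
    def test_uniform_image_minus_background(self):
        data = np.zeros((5, 1, 32, 32))
        data[0] = 10.0              # pre-detection reference frame
        data[1:] = 40.0
        stack = pc.ImageStack(data, frame_interval=1.0,
                              channel_names=("ch1",))
        track = pc.SpotTrack(0, {t: Spot(t, (16.0, 16.0), 5.0, 40.0)
                                 for t in range(1, 5)})
        trace = pc.vicinity_trace(stack, track, radius_px=4)
        assert trace.background[0] == pytest.approx(10.0)
        assert np.allclose(trace.values[1:, 0], 30.0)

    def test_ramp_normalizes_to_100(self):
        sp = pc.SpotScript(birth=1, death=16, path=(32.0, 32.0),
                           amplitude=np.linspace(0, 150, 16))
        ms = pc.MovieScript(n_frames=16, spots=[sp], noise_sd=0.0,
                            n_channels=1)
        stack, _ = pc.make_spot_movie(ms, seed=0)
        frames = [pc.segment_spots(stack.data[f, 0], 20.0, 130.0, 2, f)
                  for f in range(16)]
        tracks = pc.track_spots(frames, 4.0)
        trace = pc.vicinity_trace(stack, tracks[0], radius_px=5,
                                  statistic="sum", normalize=True)
        vals = trace.values[:, 0]
        assert np.nanmax(vals) == pytest.approx(100.0)
        assert np.nanargmax(vals) == 15
        live = vals[tracks[0].birth: 16]
        assert np.all(np.diff(live) > -1e-6)

    def test_channel_delay_shifts_crossing(self):
        """With channel 2 delayed k frames, its half-maximal crossing comes
        k frames later (amplitude ramp with a plateau in both channels)."""
        k = 3
        amp = np.concatenate([np.linspace(0, 200, 10), np.full(10, 200.0)])
        sp = pc.SpotScript(birth=0, death=20, path=(32.0, 32.0), amplitude=amp)
        ms = pc.MovieScript(n_frames=20, spots=[sp], noise_sd=0.0,
                            channel_delay_frames=k)
        stack, _ = pc.make_spot_movie(ms, seed=0)
        frames = [pc.segment_spots(stack.data[f, 0], 20.0, 130.0, 2, f)
                  for f in range(20)]
        tracks = pc.track_spots(frames, 4.0)
        trace = pc.vicinity_trace(stack, tracks[0], radius_px=6,
                                  statistic="sum", normalize=True)
        c1 = int(np.argmax(trace.values[:, 0] >= 50.0))
        c2 = int(np.argmax(trace.values[:, 1] >= 50.0))
        assert c2 - c1 == k

    def test_empty_track_rejected(self):
        stack = pc.ImageStack(np.zeros((3, 1, 8, 8)), 1.0)
        with pytest.raises(ValueError):
            pc.vicinity_trace(stack, pc.SpotTrack(0, {}), 3.0)


class TestCoexistenceTime:
    def test_definition_on_scripted_counts(self):
        """First frame with >1 spot is index 1, first frame back at exactly
        one is index 4: three 45-s intervals of coexistence."""
        out = pc.coexistence_time([1, 2, 2, 2, 1, 1], 45.0)
        assert out.seconds == 135.0 and out.defined and not out.censored

    def test_never_multi(self):
        out = pc.coexistence_time([1, 1, 1], 45.0)
        assert out.seconds is None and not out.defined

    def test_censored(self):
        out = pc.coexistence_time([1, 2, 2, 2], 45.0)
        assert out.censored and out.defined and out.seconds is None

    def test_multi_at_first_frame(self):
        assert pc.coexistence_time([2, 2, 1], 30.0).seconds == 60.0


class TestFlipNormalize:
    def test_printed_example(self):
        assert pc.flip_normalize([100.0], [90.0], [10.0])[0] == \
            pytest.approx(1.125)

    def test_focus_equals_neighbor(self):
        out = pc.flip_normalize([80.0, 70.0], [80.0, 70.0], [10.0, 10.0])
        assert np.allclose(out, 1.0)

    def test_bad_denominator_flagged(self):
        out = pc.flip_normalize([50.0], [10.0], [10.0])
        assert np.isnan(out[0])

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        f, n, b = rng.uniform(50, 100, 10), rng.uniform(100, 120, 10), \
            np.full(10, 20.0)
        base = pc.flip_normalize(f, n, b)
        scaled = pc.flip_normalize(3.0 * f + 7.0, 3.0 * n + 7.0, 3.0 * b + 7.0)
        assert np.allclose(base, scaled)

    def test_recovers_loss_rate(self):
        script = pc.TraceScript(loss_rate=0.08, n_frames=80,
                                frame_interval=1.0, noise_sd_fraction=0.01)
        traces, truth = pc.make_flip_traces(script, seed=4)
        norm = pc.flip_normalize(traces["focus"], traces["neighbor"],
                                 traces["background"])
        t = traces["times"]
        sel = (t >= truth["bleach_start"]) & (norm > 0.15 * np.nanmax(norm))
        rate = -np.polyfit(t[sel] - truth["bleach_start"],
                           np.log(norm[sel] / norm[sel][0]), 1)[0]
        assert rate == pytest.approx(0.08, rel=0.10)


class TestFrapHalftime:
    def test_recovers_scripted_rates(self):
        script = pc.TraceScript(k_slow=0.2, k_fast=2.0,
                                noise_sd_fraction=0.01)
        trace, truth = pc.make_frap_trace(script, seed=1)
        half, diag = pc.frap_halftime(trace, script.frame_interval,
                                      script.pre_bleach_frames,
                                      background=script.background)
        assert diag["converged"]
        assert half == pytest.approx(truth["half_time"], rel=0.05)

    def test_single_exponential_degenerate(self):
        """A pure single-exponential recovery still yields ln2/k from the
        slow component."""
        k = 0.3
        t = np.arange(120) * 0.5
        recovery = 0.2 + 0.6 * (1 - np.exp(-k * t))
        trace = np.concatenate([np.ones(3), recovery]) * 800.0 + 30.0
        half, diag = pc.frap_halftime(trace, 0.5, 3, background=30.0)
        assert half == pytest.approx(np.log(2) / k, rel=0.05)

    def test_zero_noise_exact(self):
        script = pc.TraceScript(k_slow=0.15, k_fast=1.5,
                                noise_sd_fraction=0.0)
        trace, truth = pc.make_frap_trace(script, seed=0)
        half, _ = pc.frap_halftime(trace, script.frame_interval,
                                   script.pre_bleach_frames,
                                   background=script.background)
        assert half == pytest.approx(truth["half_time"], rel=1e-3)

    def test_too_few_pre_bleach_frames(self):
        with pytest.raises(ValueError):
            pc.frap_halftime(np.ones(50), 0.5, 2)


class TestMultiClusterFraction:
    def test_quarter(self):
        pct, (lo, hi) = pc.multi_cluster_fraction([True, False, False, False])
        assert pct == 25.0 and lo < 25.0 < hi

    def test_all_false(self):
        pct, _ = pc.multi_cluster_fraction([False] * 10)
        assert pct == 0.0

    def test_scripted_cohort_within_ci(self):
        rng = np.random.default_rng(7)
        cohort = rng.uniform(size=200) < 0.5
        pct, (lo, hi) = pc.multi_cluster_fraction(cohort)
        assert lo <= 50.0 <= hi

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pc.multi_cluster_fraction([])


class TestImageStackIO:
    def test_tiff_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        data = rng.uniform(0, 100, (4, 2, 16, 16))
        stack = pc.ImageStack(data, frame_interval=45.0, pixel_size=0.1)
        path = tmp_path / "movie.tif"
        stack.to_tiff(path)
        loaded = pc.ImageStack.from_tiff(path)
        assert loaded.frame_interval == 45.0
        assert np.allclose(loaded.data, data, atol=1e-4)


class TestCorticalRatio:
    def test_rim_enrichment_detected(self):
        img = np.full((40, 40), 5.0)
        img[10:30, 10:30] = 100.0          # cell interior
        # bright rim
        img[10:30, 10:12] = 300.0
        img[10:30, 28:30] = 300.0
        img[10:12, 10:30] = 300.0
        img[28:30, 10:30] = 300.0
        from polarcomp.imaging import cortical_to_internal_ratio
        ratio = cortical_to_internal_ratio(img, cell_threshold=50.0, rim_px=2)
        assert ratio == pytest.approx(3.0, rel=0.05)

    def test_no_cell_rejected(self):
        from polarcomp.imaging import cortical_to_internal_ratio
        with pytest.raises(ValueError):
            cortical_to_internal_ratio(np.zeros((10, 10)), 1.0)
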