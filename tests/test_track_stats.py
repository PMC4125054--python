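"""Motility estimation, weighted-median gating and retention windows."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tcellsim import track_stats as tsx
from tcellsim.synthetic import SyntheticExperimentSpec, generate_track_set


def brownian_track(rng, m=60.0, n_samples=61, dt_min=20 / 60, track_id="t"):
    t = np.arange(n_samples) * dt_min
    steps = rng.normal(0, np.sqrt(2 * m * dt_min), size=(n_samples - 1, 3))
    xyz = np.vstack([[0.0, 0.0, 0.0], np.cumsum(steps, axis=0)])
    return tsx.Track(track_id, "control", "v0", "e0", t, xyz)


def persistent_track(rng, speed=9.49, tau=2.0, n_samples=10, dt_min=20 / 60):
    t = np.arange(n_samples) * dt_min
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    pos = [np.zeros(3)]
    for _ in range(n_samples - 1):
        if rng.random() < 1 - np.exp(-dt_min / tau):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
        pos.append(pos[-1] + speed * dt_min * d)
    return tsx.Track("p", "control", "v0", "e0", t, np.array(pos))


class TestTrackInvariants:
    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            tsx.Track("a", "control", "v", "e", [0.0], [[0, 0, 0]])

    def test_requires_increasing_time(self):
        with pytest.raises(ValueError):
            tsx.Track("a", "control", "v", "e", [0.0, 0.0], [[0, 0, 0], [1, 1, 1]])

    def test_short_track_filter(self, rng):
        long_tr = brownian_track(rng, n_samples=10)  # 3 min
        short_tr = brownian_track(rng, n_samples=4, track_id="s")  # 1 min
        ts = tsx.TrackSet([long_tr, short_tr]).filtered()
        assert [tr.track_id for tr in ts] == ["t"]


class TestMotilityCoefficient:
    def test_stationary_track_is_zero(self):
        t = np.arange(10) * 0.5
        xyz = np.tile([5.0, 5.0, 5.0], (10, 1))
        tr = tsx.Track("s", "control", "v", "e", t, xyz)
        assert tsx.motility_coefficient(tr) == 0.0

    def test_brownian_recovery(self):
        """Ensemble mean within 5% and median within 10% of the true M."""
        rng = np.random.default_rng(4)
        vals = np.array([tsx.motility_coefficient(brownian_track(rng)) for _ in range(1000)])
        assert np.mean(vals) == pytest.approx(60.0, rel=0.05)
        assert np.median(vals) == pytest.approx(60.0, rel=0.10)

    def test_quadratic_scaling(self, rng):
        tr = brownian_track(rng)
        scaled = tsx.Track("b", "control", "v", "e", tr.t, tr.xyz * 3.0)
        assert tsx.motility_coefficient(scaled) == pytest.approx(
            9.0 * tsx.motility_coefficient(tr)
        )

    def test_even_length_track_uses_central_average(self, rng):
        tr = brownian_track(rng, n_samples=60)
        assert tsx.motility_coefficient(tr) > 0  # exercised without error

    def test_short_persistent_tracks_underestimate(self):
        """The documented negative bias for short persistent-walk tracks."""
        rng = np.random.default_rng(5)
        target = 9.49**2 * 2.0 / 3.0  # ~60 µm²/min long-time motility
        vals = [tsx.motility_coefficient(persistent_track(rng)) for _ in range(800)]
        assert np.mean(vals) < 0.8 * target


class TestWeightedMedian:
    def test_brute_force_example(self):
        """{1 (w1), 3 (w1), 10 (w2)} expands to [1,3,10,10] -> median 6.5."""
        assert tsx.weighted_median(np.array([1.0, 3.0, 10.0]), np.array([1, 1, 2])) == 6.5

    def test_identical_controls(self):
        assert tsx.weighted_median(np.array([4.0, 4.0]), np.array([3, 5])) == 4.0

    @given(
        st.lists(
            st.tuples(st.floats(0.1, 100), st.integers(1, 6)), min_size=1, max_size=12
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_explicit_expansion(self, pairs):
        values = np.array([p[0] for p in pairs])
        weights = np.array([p[1] for p in pairs])
        expanded = np.repeat(values, weights)
        assert tsx.weighted_median(values, weights) == pytest.approx(
            float(np.median(expanded))
        )


class TestRetainedFraction:
    def test_duration_weighting(self, rng):
        slow = brownian_track(rng, m=0.5, n_samples=121, track_id="slow")  # 40 min
        fast = brownian_track(rng, m=80.0, n_samples=61, track_id="fast")  # 20 min
        frac = tsx.retained_fraction([slow, fast], threshold=10.0)
        assert frac == pytest.approx(40.0 / 60.0)

    def test_extreme_thresholds(self, rng):
        tracks = [brownian_track(rng, track_id=str(i)) for i in range(5)]
        assert tsx.retained_fraction(tracks, threshold=0.0) == 0.0
        assert tsx.retained_fraction(tracks, threshold=np.inf) == 1.0

    def test_invariant_to_order_and_duplication(self, rng):
        tracks = [brownian_track(rng, m=m, track_id=str(m)) for m in (1.0, 30.0, 90.0)]
        f1 = tsx.retained_fraction(tracks, 20.0)
        assert tsx.retained_fraction(tracks[::-1], 20.0) == pytest.approx(f1)
        assert tsx.retained_fraction(tracks * 2, 20.0) == pytest.approx(f1)

    def test_monotone_in_threshold(self, rng):
        tracks = [brownian_track(rng, m=m, track_id=str(i)) for i, m in enumerate(np.linspace(1, 100, 12))]
        fracs = [tsx.retained_fraction(tracks, thr) for thr in (1.0, 10.0, 50.0, 200.0)]
        assert fracs == sorted(fracs)


class TestBackgroundCorrect:
    def test_fixed_points(self):
        assert tsx.background_correct(0.2, 0.2) == 0.0
        assert tsx.background_correct(1.0, 0.2) == 1.0

    def test_affine_example(self):
        assert tsx.background_correct(0.5, 0.2) == pytest.approx(0.375)

    def test_full_background_rejected(self):
        with pytest.raises(ValueError):
            tsx.background_correct(0.5, 1.0)

    def test_subtractive_variant(self):
        assert tsx.background_correct_subtractive(0.5, 0.2) == pytest.approx(0.3)
        assert tsx.background_correct_subtractive(0.1, 0.2) == 0.0


class TestWindowing:
    def test_split_conserves_duration(self, rng):
        tr = brownian_track(rng, n_samples=181, dt_min=20 / 60)  # 60 min
        pieces = tsx.split_track_at(tr, [20.0, 40.0])
        assert len(pieces) == 3
        assert sum(p.duration for p in pieces) == pytest.approx(tr.duration)

    def test_sixty_minute_video_gives_three_windows(self):
        spec = SyntheticExperimentSpec(
            n_experiments=1, video_times_post_transfer=(5.0,),
            cognate_per_video=30, control_per_video=30,
        )
        tracks, _ = generate_track_set(spec, np.random.default_rng(6))
        pts = tsx.window_retention_series(tracks)
        assert len(pts) == 3
        mids = sorted(p.time_post_entry for p in pts)
        assert mids == pytest.approx([4 + 1 / 6, 4.5, 4 + 5 / 6])

    def test_window_longer_than_video_rejected(self):
        spec = SyntheticExperimentSpec(
            n_experiments=1, cognate_per_video=5, control_per_video=5
        )
        tracks, _ = generate_track_set(spec, np.random.default_rng(7))
        with pytest.raises(ValueError):
            tsx.window_retention_series(tracks, window_min=90.0)

    def test_switch_like_series_recovered(self):
        """A sharp retention switch near 5 h is seen between the 3 h and 6 h bins."""
        from tcellsim.priming import PrimingParams

        spec = SyntheticExperimentSpec(
            n_experiments=2,
            doses=(("switch", PrimingParams.signal_integration(24.0, 24.0 / 5.0)),),
            video_times_post_transfer=(4.0, 7.0),
            cognate_per_video=100,
            control_per_video=100,
        )
        tracks, _ = generate_track_set(spec, np.random.default_rng(8))
        pts = tsx.binned_retention_series(tracks, n_boot=100, rng=np.random.default_rng(9))
        by_bin = {round(p.time_post_entry - 0.5): p for p in pts}
        assert by_bin[3].corrected_fraction < 0.2
        assert by_bin[6].corrected_fraction > 0.8
        assert by_bin[6].ci_low is not None and by_bin[6].ci_high > by_bin[6].ci_low
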