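import math
import warnings

import numpy as np
import pytest

from endopatch import (IntensityTrace, Movie, PairedEvent, SimParams, Track,
                       annotate_T1, arrival_delay_stats,
                       average_aligned_profiles, colocalization_fraction,
                       compute_T1, detect_onset, extract_trace,
                       measure_lifetime, onset_fraction_stats, pair_channels,
                       simulate_event_trace, t1_t2_regression)
from endopatch.errors import (NoEventError, NoOnsetError, NoT1Error,
                              UndefinedFractionError)
from endopatch.event_quant import green_value_at, moving_average3
from endopatch.patch_tracking import Spot
from endopatch.synth_movie import _render_gaussian


def make_trace(values, birth=None, death=None, dt=1.0, channel="green"):
    v = np.asarray(values, dtype=float)
    if birth is None or death is None:
        on = np.flatnonzero(v > 0)
        birth = int(on[0]) if len(on) else 0
        death = int(on[-1]) if len(on) else len(v) - 1
    return IntensityTrace(track_id=0, channel=channel,
                          times_s=np.arange(len(v)) * dt, values=v,
                          smoothed=moving_average3(v), birth_frame=birth,
                          death_frame=death, frame_interval_s=dt)


def make_track(track_id, frames, positions, channel="green"):
    spots = [Spot(frame=f, channel=channel, position=tuple(p),
                  raw_intensity=1.0, local_background=0.0)
             for f, p in zip(frames, positions)]
    return Track(track_id=track_id, channel=channel, spots=spots)


def noisy_baseline(rng, n, level=0.0, sd=5.0):
    return level + rng.normal(0, sd, n)


class TestExtractTrace:
    def test_zero_movie_gives_zero_trace(self):
        movie = Movie(np.zeros((6, 2, 40, 40)), 65.0, 1.0)
        track = make_track(0, range(6), [(20.0, 20.0)] * 6)
        trace = extract_trace(movie, track)
        assert np.allclose(trace.values, 0.0)

    def test_noiseless_spot_recovers_aperture_psf_mass(self):
        amp, bg, sigma, rad = 1200.0, 30.0, 1.5, 3.0
        frame = np.full((50, 50), bg)
        _render_gaussian(frame, 25.0, 25.0, amp, sigma)
        movie = Movie(np.stack([np.stack([frame, frame])] * 5), 65.0, 1.0)
        track = make_track(0, range(5), [(25.0, 25.0)] * 5)
        trace = extract_trace(movie, track, aperture_radius_px=rad)
        yy, xx = np.mgrid[0:50, 0:50]
        d = np.hypot(yy - 25.0, xx - 25.0)
        mass = (np.exp(-d[d <= rad] ** 2 / (2 * sigma ** 2)).sum()
                / (2 * math.pi * sigma ** 2))
        assert trace.values[2] == pytest.approx(amp * mass, rel=1e-3)

    def test_max_intensity_cv_tracks_amplitude_cv(self, wt_movie, wt_analysis):
        movie, truth = wt_movie
        amps = np.array([t.amplitude for t in truth])
        maxima = []
        for tr in wt_analysis.green_tracks:
            if not tr.excluded_crowded:
                maxima.append(extract_trace(movie, tr, channel=0).max_value)
        cv_true = amps.std() / amps.mean()
        cv_meas = np.std(maxima) / np.mean(maxima)
        assert cv_meas == pytest.approx(cv_true, abs=0.2 * max(cv_true, 0.1))

    def test_aperture_must_clear_annulus(self):
        movie = Movie(np.zeros((4, 2, 30, 30)), 65.0, 1.0)
        track = make_track(0, range(4), [(15.0, 15.0)] * 4)
        with pytest.raises(ValueError):
            extract_trace(movie, track, aperture_radius_px=6.0,
                          bg_annulus=(5.0, 8.0))


class TestMeasureLifetime:
    def test_rectangular_pulse_gives_inclusive_duration(self):
        rng = np.random.default_rng(0)
        v = noisy_baseline(rng, 40, sd=3.0)
        v[5:25] += 500.0  # frames 5..24 inclusive
        life = measure_lifetime(make_trace(v, birth=5, death=24))
        assert life.lifetime_s == pytest.approx(20.0)
        assert (life.start_frame, life.end_frame) == (5, 24)

    def test_all_zero_trace_is_no_event(self):
        with pytest.raises(NoEventError):
            measure_lifetime(make_trace(np.zeros(30), birth=10, death=15))

    def test_single_frame_dip_bridged(self):
        rng = np.random.default_rng(1)
        v = noisy_baseline(rng, 40, sd=3.0)
        v[5:25] += 500.0
        v[14] -= 500.0  # one-frame dropout
        life = measure_lifetime(make_trace(v, birth=5, death=24))
        assert (life.start_frame, life.end_frame) == (5, 24)

    def test_run_must_overlap_track_span(self):
        rng = np.random.default_rng(2)
        v = noisy_baseline(rng, 60, sd=3.0)
        v[40:55] += 500.0
        # track claims frames 5..10 where nothing happens
        with pytest.raises(NoEventError):
            measure_lifetime(make_trace(v, birth=5, death=10))

    def test_increasing_k_on_never_lengthens_lifetime(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            v = noisy_baseline(rng, 60, sd=4.0)
            ramp = np.concatenate([np.linspace(20, 400, 15),
                                   np.full(10, 400.0),
                                   np.linspace(400, 10, 12)])
            v[10:10 + len(ramp)] += ramp
            trace = make_trace(v, birth=10, death=10 + len(ramp) - 1)
            lifetimes = []
            for k_on in (2.0, 3.0, 4.0, 6.0):
                try:
                    lifetimes.append(measure_lifetime(trace, k_on).lifetime_s)
                except NoEventError:
                    lifetimes.append(0.0)
            assert all(a >= b for a, b in zip(lifetimes, lifetimes[1:]))


class TestDetectOnset:
    def test_step_onset_at_frame_twelve(self):
        rng = np.random.default_rng(5)
        v = np.concatenate([rng.normal(10, 2, 12), np.full(20, 30.0)])
        assert detect_onset(v, frame_interval_s=1.0) == 12.0

    def test_all_baseline_is_no_onset(self):
        rng = np.random.default_rng(6)
        with pytest.raises(NoOnsetError):
            detect_onset(rng.normal(10, 2, 40), frame_interval_s=1.0)

    def test_brief_spike_not_an_onset(self):
        rng = np.random.default_rng(7)
        v = rng.normal(10, 2, 40)
        v[20] += 50.0  # single frame cannot satisfy m_consecutive = 3
        with pytest.raises(NoOnsetError):
            detect_onset(v, frame_interval_s=1.0)

    def test_frame_interval_scales_reported_time(self):
        rng = np.random.default_rng(5)
        v = np.concatenate([rng.normal(10, 2, 12), np.full(20, 30.0)])
        assert detect_onset(v, frame_interval_s=1.8) == pytest.approx(21.6)


class TestOnsetFraction:
    def ramp_trace(self):
        # linear ramp 0 -> 100 over 20 frames, then hold so the max is 100
        v = np.concatenate([np.arange(0, 101, 5.0), np.full(6, 100.0)])
        return make_trace(v, birth=1, death=len(v) - 1)

    def test_ramp_fraction_three_quarters(self):
        trace = self.ramp_trace()
        assert green_value_at(trace, 15.0) / trace.max_value == \
            pytest.approx(0.75, abs=0.01)

    def test_onset_at_max_gives_unit_fraction(self):
        pairs = [PairedEvent(onset_fraction=1.0) for _ in range(12)]
        mean, sd, per = onset_fraction_stats(pairs)
        assert mean == 1.0 and sd == 0.0 and len(per) == 12

    def test_few_pairs_warns_but_computes(self):
        pairs = [PairedEvent(onset_fraction=0.7) for _ in range(4)]
        with pytest.warns(UserWarning):
            mean, _sd, _ = onset_fraction_stats(pairs)
        assert mean == pytest.approx(0.7)

    def test_no_usable_pairs_raises(self):
        with pytest.raises(UndefinedFractionError), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            onset_fraction_stats([PairedEvent()])

    @pytest.mark.parametrize("f", [0.6, 0.7, 0.75, 0.8, 0.9])
    def test_noiseless_estimator_bias_small(self, f):
        """Trace-level onset-fraction recovery vs the realized ground truth
        (green value at the true onset frame over the true max)."""
        params = SimParams(threshold_fraction_f=f, amplitude_cv=0.0, seed=31)
        errs = []
        for k in range(12):
            green, red, truth = simulate_event_trace(params, k)
            pad = 12
            g = np.concatenate([np.zeros(pad), green, np.zeros(pad)])
            r = np.concatenate([np.zeros(pad), red, np.zeros(pad)])
            gt = make_trace(g, birth=pad, death=pad + len(green) - 1)
            rt = make_trace(r, birth=pad + truth.red_onset_frame,
                            death=pad + len(green) - 1)
            t2 = detect_onset(rt)
            est = green_value_at(gt, t2) / gt.max_value
            true_frac = green[truth.red_onset_frame] / green.max()
            errs.append(est - true_frac)
        assert abs(np.mean(errs)) < 0.03


class TestPairing:
    def test_no_red_tracks_gives_no_pairs(self):
        g = [make_track(0, range(8), [(20.0, 20.0)] * 8)]
        assert pair_channels(g, []) == []

    def test_coincident_tracks_pair_once(self):
        g = [make_track(0, range(8), [(20.0, 20.0)] * 8, "green")]
        r = [make_track(0, range(3, 8), [(20.5, 20.0)] * 5, "red")]
        pairs = pair_channels(g, r)
        assert len(pairs) == 1
        assert pairs[0].site_distance_px == pytest.approx(0.5)

    def test_distant_track_stays_unpaired(self):
        g = [make_track(0, range(8), [(20.0, 20.0)] * 8, "green")]
        r = [make_track(0, range(8), [(20.0, 30.0)] * 8, "red")]
        assert pair_channels(g, r, pairing_radius_px=3.0) == []

    def test_each_track_in_at_most_one_pair(self):
        g = [make_track(i, range(8), [(20.0, 20.0 + i)] * 8, "green")
             for i in range(2)]
        r = [make_track(0, range(8), [(20.0, 20.4)] * 8, "red")]
        pairs = pair_channels(g, r)
        assert len(pairs) == 1
        assert pairs[0].green_track.track_id == 0  # closer green wins


class TestT1:
    def test_ramp_reaches_level_at_frame_nine(self):
        v = np.concatenate([np.arange(0.0, 210.0, 10.0), np.full(5, 200.0)])
        trace = make_trace(v, birth=1, death=len(v) - 1)
        assert compute_T1(trace, level=90.0) == 9.0

    def test_single_spike_before_sustained_crossing_ignored(self):
        v = np.zeros(30)
        v[5] = 80.0            # brief flicker
        v[14:] = 200.0         # sustained accumulation
        trace = make_trace(v, birth=3, death=29)
        assert compute_T1(trace, level=60.0) == pytest.approx(14.0, abs=1.0)

    def test_level_above_max_is_no_t1(self):
        v = np.zeros(20)
        v[5:15] = 50.0
        with pytest.raises(NoT1Error):
            compute_T1(make_trace(v, birth=5, death=14), level=500.0)


class TestT1T2Regression:
    def make_pairs(self, t1, t2):
        return [PairedEvent(T1_s=a, T2_s=b, green_birth_s=0.0)
                for a, b in zip(t1, t2)]

    def test_identity_line(self):
        t = np.linspace(5, 40, 12)
        res = t1_t2_regression(self.make_pairs(t, t))
        assert res.slope == pytest.approx(1.0)
        assert res.intercept_s == pytest.approx(0.0, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0)

    def test_shuffled_control_has_low_r_squared(self):
        rng = np.random.default_rng(8)
        t1 = rng.uniform(5, 40, 50)
        t2 = rng.permutation(t1 + rng.normal(0, 0.5, 50))
        res = t1_t2_regression(self.make_pairs(t1, t2))
        assert res.r_squared < 0.2

    def test_too_few_events_raises(self):
        with pytest.raises(ValueError):
            t1_t2_regression(self.make_pairs([1.0, 2.0], [1.0, 2.0]))

    def test_annotate_T1_uses_cohort_mean_level(self):
        traces = []
        pairs = []
        for k, amp in enumerate([200.0, 300.0]):
            v = np.concatenate([np.zeros(5), np.linspace(0, amp, 20),
                                np.full(8, amp)])
            tr = make_trace(v, birth=5, death=len(v) - 1)
            pairs.append(PairedEvent(green_trace=tr, green_at_onset=150.0,
                                     green_birth_s=5.0))
        level = annotate_T1(pairs)
        assert level == pytest.approx(150.0)
        for p in pairs:
            assert p.T1_s is not None
            assert p.green_trace.smoothed[int(p.T1_s)] >= 140.0


class TestAlignedProfiles:
    def base_trace(self, shift=0, n=60):
        v = np.zeros(n)
        ramp = np.concatenate([np.linspace(0, 300, 15), np.full(10, 300.0),
                               np.linspace(300, 0, 10)])
        v[20 + shift:20 + shift + len(ramp)] = ramp
        return make_trace(v, birth=20 + shift, death=20 + shift + len(ramp) - 1)

    def test_identical_traces_have_zero_sd(self):
        traces = [self.base_trace() for _ in range(4)]
        _t, _mean, sd, n = average_aligned_profiles(traces, "green_max")
        assert np.nanmax(sd) == pytest.approx(0.0, abs=1e-9)
        assert n.max() == 4

    def test_shifted_copies_align_to_original(self):
        traces = [self.base_trace(-3), self.base_trace(0), self.base_trace(3)]
        t, mean, _sd, n = average_aligned_profiles(traces, "green_max")
        ref = self.base_trace(0)
        full = n == 3
        ref_at = np.interp(t[full] + ref.max_time_s, ref.times_s, ref.smoothed)
        assert np.max(np.abs(mean[full] - ref_at)) <= 1e-6

    def test_missing_alignment_event_drops_trace(self):
        traces = [self.base_trace(), self.base_trace()]
        with pytest.warns(UserWarning):
            _ = average_aligned_profiles(traces + [self.base_trace()],
                                         "red_onset",
                                         align_times_s=[30.0, 31.0, None])

    def test_normalization_caps_mean_at_one(self):
        traces = [self.base_trace(s) for s in (0, 2)]
        _t, mean, _sd, _n = average_aligned_profiles(traces, "green_max",
                                                     normalize=True)
        assert np.nanmax(mean) <= 1.0 + 1e-9


class TestArrivalDelay:
    def test_fixed_offset_recovered_exactly(self):
        pairs = [PairedEvent(T2_s=float(10 + k + 5), green_birth_s=float(10 + k))
                 for k in range(12)]
        mean, sd, n = arrival_delay_stats(pairs)
        assert (mean, sd, n) == (5.0, 0.0, 12)

    def test_simultaneous_arrival_gives_zero(self):
        pairs = [PairedEvent(T2_s=7.0, green_birth_s=7.0) for _ in range(12)]
        mean, _sd, _n = arrival_delay_stats(pairs)
        assert mean == 0.0


class TestColocalization:
    @staticmethod
    def static_greens(n):
        return [make_track(i, range(10), [(10.0 + 7 * (i % 18),
                                           10.0 + 7 * (i // 18))] * 10)
                for i in range(n)]

    def test_printed_counts_give_ten_point_five_percent(self):
        greens = self.static_greens(304)
        reds = [make_track(1000 + i, range(10),
                           [greens[i].spots[0].position] * 10, "red")
                for i in range(32)]
        frac, n_coloc, n_total = colocalization_fraction(greens, reds)
        assert (frac, n_coloc, n_total) == (10.5, 32, 304)

    def test_no_red_tracks_zero_percent(self):
        frac, n_coloc, _ = colocalization_fraction(self.static_greens(10), [])
        assert frac == 0.0 and n_coloc == 0

    def test_single_passing_comet_ten_percent(self):
        greens = self.static_greens(10)
        target = np.array(greens[3].spots[0].position)
        path = [tuple(target + (0.0, dc)) for dc in
                (-9.0, -6.0, -3.0, -0.5, 0.5, 3.0, 6.0, 9.0)]
        red = make_track(99, range(8), path, "red")
        frac, n_coloc, _ = colocalization_fraction(greens, [red],
                                                   radius_px=1.0, min_frames=2)
        assert (frac, n_coloc) == (10.0, 1)

    def test_no_static_tracks_is_undefined(self):
        with pytest.raises(UndefinedFractionError):
            colocalization_fraction([], [])


class TestScalingInvariance:
    def test_fractions_and_times_invariant_under_intensity_scaling(self):
        """Multiplying the movie by a global gain leaves lifetimes, T2 and
        onset fractions unchanged and scales intensities linearly."""
        from endopatch import analyze_movie
        params = SimParams(n_events=4, n_frames=100, seed=19)
        movie, _ = ep_simulate(params)
        scaled = Movie(movie.data * 4.0, movie.pixel_size_nm,
                       movie.frame_interval_s)
        a = analyze_movie(movie, classify=False)
        b = analyze_movie(scaled, classify=False)
        assert sorted(a.lifetimes_s) == sorted(b.lifetimes_s)
        fa = sorted(p.onset_fraction for p in a.pairs
                    if p.onset_fraction is not None)
        fb = sorted(p.onset_fraction for p in b.pairs
                    if p.onset_fraction is not None)
        assert np.allclose(fa, fb, atol=1e-6)
        ta = sorted(p.T2_s for p in a.pairs if p.T2_s is not None)
        tb = sorted(p.T2_s for p in b.pairs if p.T2_s is not None)
        assert ta == tb
        assert np.allclose(sorted(b.max_intensities),
                           4.0 * np.asarray(sorted(a.max_intensities)),
                           rtol=1e-6)


def ep_simulate(params):
    from endopatch import simulate_movie
    return simulate_movie(params)
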