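"""Event geometry, PETH/lag estimation, coupling and intervention effects."""

import numpy as np
import pytest
from scipy.signal import fftconvolve

from photosleep.core import Event, Hypnogram, Trace
from photosleep.simulate import (SimConfig, apply_intervention, event_kernel,
                                 simulate_session)
from photosleep.photometry import preprocess
from photosleep.transients import (PETH, aligned_average, auc_between,
                                   build_peth, c50, delineate_event,
                                   detect_events, estimate_lag,
                                   hemisphere_ratio, intervention_effect,
                                   paired_auc_correlation, shuffle_null,
                                   state_mean)
from conftest import coupling_config


def triangle_trace(h=5.0, w=20.0, center=500.0, n=1000, fs=1.0):
    t = np.arange(n) / fs
    vals = np.maximum(h * (1 - np.abs(t - center) / w), 0.0)
    return Trace(vals, fs=fs, unit="zscore")


class TestEventGeometry:
    def test_triangle_onset_offset_at_10pct_line(self):
        h, w = 5.0, 20.0
        tr = triangle_trace(h, w)
        ev = delineate_event(tr, Event(peak_time=500.0, peak_amp=h))
        assert ev.onset == pytest.approx(500.0 - 0.9 * w, abs=0.1)
        assert ev.offset == pytest.approx(500.0 + 0.9 * w, abs=0.1)
        assert ev.peak_amp == pytest.approx(h)

    def test_triangle_auc_matches_closed_form(self):
        # area of the triangle above the 10% line: 0.99*h*w
        h, w = 5.0, 20.0
        tr = triangle_trace(h, w)
        ev = delineate_event(tr, Event(peak_time=500.0, peak_amp=h))
        assert ev.auc == pytest.approx(0.99 * h * w, rel=0.02)

    def test_auc_additivity_over_subwindows(self):
        rng = np.random.default_rng(0)
        tr = Trace(rng.standard_normal(1000), fs=1.0, unit="zscore")
        full = auc_between(tr, 100.0, 300.0, 0.37)
        split = auc_between(tr, 100.0, 212.5, 0.37) + \
            auc_between(tr, 212.5, 300.0, 0.37)
        assert split == pytest.approx(full, abs=1e-9)

    def test_baseline_is_100s_pre_onset_mean(self):
        h, w = 5.0, 10.0
        tr = triangle_trace(h, w, center=500.0)
        tr.values[:491] += 0.75  # known pre-onset level
        ev = delineate_event(tr, Event(peak_time=500.0, peak_amp=h))
        expect = tr.values[int(ev.onset) - 100:int(ev.onset)].mean()
        assert ev.baseline == pytest.approx(expect, abs=0.02)

    def test_event_near_start_uses_available_history_and_flags(self):
        tr = triangle_trace(5.0, 10.0, center=50.0)
        ev = delineate_event(tr, Event(peak_time=50.0, peak_amp=5.0))
        assert ev.truncated


class TestDetection:
    def test_three_injected_bumps_found_at_injected_times(self):
        rng = np.random.default_rng(1)
        n = 3600
        noise = rng.standard_normal(n) * 0.1
        k = event_kernel(1.0, 2.0, 8.0)
        x = noise.copy()
        times = [600, 1500, 2800]
        for t0 in times:
            x[t0:t0 + k.size] += 5 * x.std() * k[:n - t0]
        tr = Trace((x - x.mean()) / x.std(), fs=1.0, unit="zscore")
        es = detect_events(tr, k=4.0)
        peaks = sorted(es.peak_times)
        assert len(peaks) == 3
        t_peak_offset = 1.0 * np.argmax(k)  # kernel peak delay
        for t0, p in zip(times, peaks):
            assert abs(p - (t0 + t_peak_offset)) <= 1.0

    def test_unreachable_threshold_gives_zero_events(self):
        rng = np.random.default_rng(2)
        tr = Trace(rng.standard_normal(1000), fs=1.0, unit="zscore")
        assert len(detect_events(tr, k=50.0)) == 0

    def test_false_positive_count_matches_bruteforce_scan(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(3600)
        tr = Trace(x, fs=1.0, unit="zscore")
        es = detect_events(tr, k=2.0, min_separation=10.0, delineate=False)
        # oracle: exhaustive local-maximum scan with the same constraints
        thr = x.mean() + 2.0 * x.std()
        cand = [i for i in range(1, 3599)
                if x[i] > thr and x[i] > x[i - 1] and x[i] > x[i + 1]]
        kept = []
        for i in sorted(cand, key=lambda i: -x[i]):
            if all(abs(i - j) >= 10 for j in kept):
                kept.append(i)
        assert len(es) == len(kept)

    def test_invariant_under_affine_rescaling(self):
        rng = np.random.default_rng(4)
        k = event_kernel(1.0, 2.0, 8.0)
        x = rng.standard_normal(2000) * 0.1
        for t0 in (300, 900, 1500):
            x[t0:t0 + k.size] += k
        tr = Trace(x, fs=1.0, unit="zscore")
        es1 = detect_events(tr)
        es2 = detect_events(tr.with_values(3.7 * x + 11.0))
        assert np.array_equal(es1.peak_times, es2.peak_times)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            detect_events(Trace(np.ones(100), fs=1.0, unit="zscore"))

    def test_wrong_unit_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            detect_events(Trace(np.random.default_rng(0).standard_normal(100),
                                fs=1.0, unit="raw_F"))


class TestPETHAndLag:
    def _template_trace(self, rng, refs, n=4000):
        k = event_kernel(1.0, 2.0, 8.0)
        x = np.zeros(n)
        for t0 in refs:
            x[t0:t0 + k.size] += k
        return Trace(x, fs=1.0, unit="zscore"), k

    def test_identical_templates_give_normalized_template(self):
        rng = np.random.default_rng(5)
        refs = [500, 1000, 1500, 2000]
        tr, k = self._template_trace(rng, refs)
        peth = build_peth(tr, [float(r) for r in refs], (-20.0, 60.0))
        seg = tr.values[480:561]
        expect = (seg - seg.min()) / (seg.max() - seg.min())
        assert np.allclose(peth.mean, expect)
        assert peth.n_events == 4

    def test_shifted_peth_recovers_10s_lag(self):
        rng = np.random.default_rng(6)
        refs = [500, 1100, 1900, 2600]
        tr, _ = self._template_trace(rng, refs)
        tr_b = Trace(np.roll(tr.values, 10), fs=1.0, unit="zscore")
        pa = build_peth(tr, [float(r) for r in refs], (-30.0, 80.0))
        pb = build_peth(tr_b, [float(r) for r in refs], (-30.0, 80.0))
        assert estimate_lag(pa, pb).lag == pytest.approx(10.0, abs=0.5)

    def test_identical_peths_give_zero_lag(self):
        rng = np.random.default_rng(7)
        refs = [400, 900, 1600]
        tr, _ = self._template_trace(rng, refs)
        p = build_peth(tr, [float(r) for r in refs], (-30.0, 80.0))
        assert estimate_lag(p, p).lag == 0.0

    def test_lag_antisymmetry(self, coupling_session):
        s, ta, tb = coupling_session
        es = detect_events(ta)
        onsets = [e.onset for e in es if np.isfinite(e.onset)]
        pa = build_peth(ta, onsets, (-60.0, 120.0))
        pb = build_peth(tb, onsets, (-60.0, 120.0))
        assert estimate_lag(pa, pb).lag == pytest.approx(
            -estimate_lag(pb, pa).lag)

    def test_simulator_lag_recovered_within_3s(self, coupling_session):
        s, ta, tb = coupling_session
        es = detect_events(ta)
        assert len(es) >= 60
        onsets = [e.onset for e in es if np.isfinite(e.onset)]
        pa = build_peth(ta, onsets, (-60.0, 120.0))
        pb = build_peth(tb, onsets, (-60.0, 120.0))
        assert estimate_lag(pa, pb).lag == pytest.approx(s.truth.lag, abs=3.0)

    def test_no_crossing_rejected(self):
        lags = np.arange(-10.0, 11.0)
        mean = np.linspace(1.0, 0.0, lags.size)  # falls, never rises to max
        peth = PETH(lags=lags, mean=mean, sem=np.zeros_like(mean), n_events=5)
        with pytest.raises(ValueError):
            c50(peth)

    def test_too_few_events_rejected(self):
        tr = Trace(np.random.default_rng(8).standard_normal(500), fs=1.0,
                   unit="zscore")
        with pytest.raises(ValueError, match=">= 3"):
            build_peth(tr, [100.0, 200.0], (-10.0, 10.0))


class TestCoupling:
    def test_self_coupling_gives_perfect_correlation(self):
        rng = np.random.default_rng(9)
        k = event_kernel(1.0, 2.0, 8.0)
        x = rng.standard_normal(6000) * 0.02
        amps = rng.lognormal(np.log(0.5), 0.4, 10)
        for i, t0 in enumerate(range(500, 5500, 500)):
            x[t0:t0 + k.size] += amps[i] * k
        tr_a = Trace((x - x.mean()) / x.std(), fs=1.0, unit="zscore")
        lag = 30.0
        tr_b = Trace(np.roll(tr_a.values, int(lag)), fs=1.0, unit="zscore")
        es = detect_events(tr_a)
        res, pairs = paired_auc_correlation(es, tr_b, lag)
        assert res.r == pytest.approx(1.0, abs=1e-6)
        assert res.slope == pytest.approx(1.0, abs=1e-6)

    def test_generative_correlation_recovered(self, coupling_session):
        s, ta, tb = coupling_session
        es = detect_events(ta)
        res, _ = paired_auc_correlation(es, tb, s.truth.lag)
        assert res.r == pytest.approx(0.7, abs=0.15)

    def test_shuffle_null_near_zero_for_independent_trace(self):
        cfg = coupling_config(seed=31)
        s = simulate_session(cfg, with_eeg=False)
        cfg2 = coupling_config(seed=77)
        s2 = simulate_session(cfg2, with_eeg=False)
        ta = preprocess(s.photo["a"], background=cfg.background)
        tb = preprocess(s2.photo["b"], background=cfg2.background)
        es = detect_events(ta)
        null = shuffle_null(es, tb, 23.0, n_perm=100, seed=0)
        assert null.mean_abs_r < 0.15

    def test_coupled_pair_beats_all_null_permutations(self, coupling_session):
        s, ta, tb = coupling_session
        es = detect_events(ta)
        null = shuffle_null(es, tb, s.truth.lag, n_perm=100, seed=1)
        assert null.p_empirical <= 1.0 / 101.0

    def test_null_shrinks_with_event_count(self):
        # mean |r| under independence scales like 1/sqrt(n)
        cfg = coupling_config(seed=32, duration=108000.0)
        s = simulate_session(cfg, with_eeg=False)
        ta = preprocess(s.photo["a"], background=cfg.background)
        cfg2 = coupling_config(seed=78, duration=108000.0)
        s2 = simulate_session(cfg2, with_eeg=False)
        tb = preprocess(s2.photo["b"], background=cfg2.background)
        es = detect_events(ta)
        for n in (30, 100, 300):
            sub = type(es)(events=es.events[:n], threshold=es.threshold,
                           sd=es.sd)
            if len(sub) < n:
                break
            null = shuffle_null(sub, tb, 23.0, n_perm=40, seed=2)
            assert null.mean_abs_r < 2.0 / np.sqrt(len(sub))


class TestIntervention:
    def test_proportional_channels_give_ratio_two(self):
        rng = np.random.default_rng(10)
        k = event_kernel(1.0, 2.0, 8.0)
        x = rng.standard_normal(6000) * 0.01
        for t0 in range(400, 5600, 400):
            x[t0:t0 + k.size] += 0.5 * k
        ref = Trace(x, fs=1.0, unit="detrended")
        test = Trace(2.0 * x, fs=1.0, unit="detrended")
        hr = hemisphere_ratio(ref, test, t_inject=3000.0)
        assert np.allclose(hr.ratios, 2.0, atol=0.05)

    @pytest.mark.parametrize("effect", [0.3, 2.86])
    def test_multiplier_recovered_by_hemisphere_ratio(self, effect):
        cfg = SimConfig(duration=14400, seed=40, photo_fs=5.0,
                        coupling_lag=0.0, coupling_slope=1.0,
                        coupling_noise_sd=0.002,
                        event_amp=(np.log(0.2), 0.1), white_noise_sd=0.01,
                        tonic_level={"W": 0, "N": 0, "R": 0},
                        event_rate={"W": 0.3, "N": 0.3, "R": 0.3})
        s = simulate_session(cfg, with_eeg=False)
        si = apply_intervention(s, 7200.0, effect, which_channel="b")
        ra = preprocess(si.photo["a"], background=cfg.background)
        rb = preprocess(si.photo["b"], background=cfg.background)
        hr = hemisphere_ratio(ra, rb, t_inject=7200.0)
        assert hr.post_mean / hr.pre_mean == pytest.approx(effect, rel=0.15)

    @pytest.mark.parametrize("effect", [0.3, 1.0])
    def test_multiplier_recovered_by_intervention_effect(self, effect):
        cfg = SimConfig(duration=14400, seed=41, photo_fs=5.0,
                        coupling_lag=0.0, coupling_slope=1.0,
                        coupling_noise_sd=0.002,
                        event_amp=(np.log(0.2), 0.1), white_noise_sd=0.01,
                        tonic_level={"W": 0, "N": 0, "R": 0},
                        event_rate={"W": 0.15, "N": 0.15, "R": 0.15})
        s = simulate_session(cfg, with_eeg=False)
        si = apply_intervention(s, 7200.0, effect, which_channel="a")
        ta = preprocess(si.photo["a"], background=cfg.background)
        ie = intervention_effect(ta, 7200.0)
        assert ie.ratio == pytest.approx(effect, rel=0.15)

    def test_post_window_respects_10min_delay(self):
        cfg = SimConfig(duration=14400, seed=42, photo_fs=5.0,
                        tonic_level={"W": 0, "N": 0, "R": 0},
                        event_rate={"W": 0.3, "N": 0.3, "R": 0.3})
        s = simulate_session(cfg, with_eeg=False)
        ta = preprocess(s.photo["a"], background=cfg.background)
        ie = intervention_effect(ta, 7200.0, post_delay=600.0)
        es = detect_events(ta)
        in_gap = [e for e in es
                  if 7200.0 <= e.peak_time < 7800.0]
        assert ie.n_pre + ie.n_post + len(in_gap) == len(es)


class TestStateMeansAndAverages:
    def test_constant_trace_all_states_equal(self):
        tr = Trace(np.ones(3600), fs=1.0, unit="zscore")
        hyp = Hypnogram(np.array(["W", "N", "R"] * 240))
        means = state_mean(tr, hyp)
        assert means == {"W": 1.0, "N": 1.0, "R": 1.0}

    def test_matches_masked_mean_oracle(self, small_session):
        s = small_session
        tr = preprocess(s.photo["a"], background=s.cfg.background)
        means = state_mean(tr, s.hypnogram)
        for state, val in means.items():
            m = s.hypnogram.mask_for_samples(tr.times, state)
            assert val == pytest.approx(tr.values[m].mean())

    def test_single_reference_returns_raw_segment(self):
        rng = np.random.default_rng(11)
        tr = Trace(rng.standard_normal(1000), fs=1.0, unit="zscore")
        avg = aligned_average(tr, [500.0], (-10.0, 10.0))
        assert np.array_equal(avg.mean, tr.values[490:511])
        assert avg.n_events == 1

    def test_step_at_transitions_recovered(self):
        # tonic level steps at state transitions; transition-aligned average
        # shows the step at lag 0
        cfg = SimConfig(duration=14400, seed=43, photo_fs=5.0,
                        event_rate={"W": 0, "N": 0, "R": 0},
                        tonic_level={"W": 0.3, "N": 0.0, "R": 0.3},
                        white_noise_sd=0.01)
        s = simulate_session(cfg, with_eeg=False)
        tr = preprocess(s.photo["a"], background=cfg.background)
        from photosleep.sleep import list_transitions
        refs = [t for t, _, _, kind in list_transitions(s.hypnogram)
                if kind == "N→W" and tr.t0 + 30 < t < tr.t0 + tr.duration - 30]
        avg = aligned_average(tr, refs, (-20.0, 20.0))
        pre = avg.mean[avg.lags < -5]
        post = avg.mean[avg.lags > 5]
        assert post.mean() > pre.mean() + 0.5 * (avg.sem.max() + 1e-12)
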