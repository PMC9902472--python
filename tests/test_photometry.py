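"""Photometry preprocessing: binning, ΔF/F₀, normalisation, drift, unmixing."""

import numpy as np
import pytest
from scipy.signal import butter, sosfiltfilt

from photosleep.core import Trace
from photosleep.photometry import (BleachCorrector, bin_to_1hz, default_cutoff,
                                   fit_bleach_baseline, normalize_trace,
                                   preprocess, remove_drift, trim_initial,
                                   unmix_isosbestic)
from photosleep.simulate import (SimConfig, bleach_trend, simulate_session)


class TestBinning:
    def test_constant_input_preserved(self):
        raw = Trace(np.full(10170, 7.0), fs=1017.0)
        out = bin_to_1hz(raw)
        assert out.n == 10 and np.allclose(out.values, 7.0)
        assert out.fs == 1.0

    def test_ramp_matches_explicit_block_means(self):
        raw = Trace(np.arange(5085, dtype=float), fs=1017.0)
        out = bin_to_1hz(raw)
        # oracle: explicit loop over 1017-sample blocks
        expect = [np.mean(np.arange(5085)[i * 1017:(i + 1) * 1017])
                  for i in range(5)]
        assert np.allclose(out.values, expect)

    def test_trailing_partial_block_dropped(self):
        raw = Trace(np.ones(2500), fs=1017.0)
        assert bin_to_1hz(raw).n == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bin_to_1hz(Trace(np.array([]), fs=1017.0))


class TestBleachBaseline:
    def test_pure_baseline_gives_zero_dff(self):
        t = np.arange(4000.0)
        f = 30 * np.exp(-t / 300) + 70 * np.exp(-t / 10000) + 5.0
        fit, dff = fit_bleach_baseline(Trace(f, fs=1.0))
        assert fit.converged
        assert fit.residual_rms < 1e-6
        assert np.abs(dff.values).max() < 1e-6

    def test_background_subtraction_precedes_fit(self):
        t = np.arange(4000.0)
        f = 30 * np.exp(-t / 300) + 70 * np.exp(-t / 10000) + 2.0
        bg = 11.0
        fit, dff = fit_bleach_baseline(Trace(f + bg, fs=1.0), background=bg)
        fit0, dff0 = fit_bleach_baseline(Trace(f, fs=1.0), background=0.0)
        assert np.allclose(dff.values, dff0.values, atol=1e-9)

    def test_time_constants_recovered_on_simulated_session(self):
        cfg = SimConfig(duration=14400, seed=20, photo_fs=5.0,
                        white_noise_sd=0.01,
                        tonic_level={"W": 0, "N": 0, "R": 0},
                        event_rate={"W": 0.2, "N": 0.2, "R": 0.2})
        s = simulate_session(cfg, with_eeg=False)
        fit, _ = fit_bleach_baseline(bin_to_1hz(s.photo["a"]),
                                     background=cfg.background)
        taus = sorted([fit.tau1, fit.tau2])
        a1, t1, a2, t2 = cfg.bleach
        assert abs(taus[0] - t1) / t1 < 0.2
        assert abs(taus[1] - t2) / t2 < 0.2

    def test_event_amplitudes_recovered_within_10pct(self):
        cfg = SimConfig(duration=14400, seed=21, photo_fs=5.0,
                        white_noise_sd=0.0, coupling_noise_sd=0.0,
                        tonic_level={"W": 0, "N": 0, "R": 0},
                        event_rate={"W": 0.2, "N": 0.2, "R": 0.2})
        s = simulate_session(cfg, with_eeg=False)
        _, dff = fit_bleach_baseline(bin_to_1hz(s.photo["a"]),
                                     background=cfg.background)
        from photosleep.transients import detect_events
        events = detect_events(dff, k=2.0)
        tt = np.array([t for t, _ in s.truth.events_a])
        aa = np.array([a for _, a in s.truth.events_a])
        errs = []
        for e in events:
            i = int(np.argmin(np.abs(tt - e.peak_time)))
            if abs(tt[i] - e.peak_time) < 5:
                errs.append(abs(e.peak_amp - aa[i]) / aa[i])
        assert len(errs) >= 20
        assert np.median(errs) < 0.10

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="60"):
            fit_bleach_baseline(Trace(np.ones(30), fs=1.0))

    def test_sklearn_params_roundtrip(self):
        est = BleachCorrector(background=3.0, dt=0.5)
        assert est.get_params() == {"background": 3.0, "dt": 0.5}
        est.set_params(background=1.0)
        assert est.background == 1.0


class TestNormalisation:
    def test_zscore_has_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        tr = Trace(rng.exponential(2.0, 5000) + 3, fs=1.0, unit="dFF")
        out = normalize_trace(tr)
        assert out.unit == "zscore"
        assert abs(out.values.mean()) < 1e-9
        assert abs(out.values.std() - 1.0) < 1e-9

    def test_zscore_is_idempotent(self):
        rng = np.random.default_rng(1)
        tr = Trace(rng.standard_normal(1000), fs=1.0, unit="dFF")
        once = normalize_trace(tr)
        twice = normalize_trace(once)
        assert np.allclose(once.values, twice.values, atol=1e-9)

    def test_nrem_restricted_sd_is_unity(self):
        cfg = SimConfig(duration=7200, seed=22, photo_fs=5.0,
                        white_noise_sd=0.5)
        s = simulate_session(cfg, with_eeg=False)
        tr = preprocess(s.photo["a"], background=cfg.background,
                        hyp=s.hypnogram, normalize="nrem_sd")
        assert tr.unit == "norm_zscore"
        m = s.hypnogram.mask_for_samples(tr.times, "N")
        assert abs(tr.values[m].std() - 1.0) < 0.05

    def test_nrem_sd_equals_zscore_when_nrem_already_unit(self):
        rng = np.random.default_rng(2)
        vals = rng.standard_normal(3600)
        tr = Trace(vals, fs=1.0, unit="dFF")
        from photosleep.core import Hypnogram
        hyp = Hypnogram(np.array(["N"] * 720))
        a = normalize_trace(tr, "zscore")
        b = normalize_trace(tr, "nrem_sd", hyp)
        # whole trace is NREM, so the extra scaling is exactly 1/SD(z)=1
        assert np.allclose(a.values, b.values, atol=1e-9)

    def test_requires_enough_nrem(self):
        tr = Trace(np.random.default_rng(3).standard_normal(100), fs=1.0,
                   unit="dFF")
        from photosleep.core import Hypnogram
        hyp = Hypnogram(np.array(["N"] * 5 + ["W"] * 15))
        with pytest.raises(ValueError, match="NREM"):
            normalize_trace(tr, "nrem_sd", hyp)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            normalize_trace(Trace(np.ones(100), fs=1.0, unit="dFF"))


class TestDriftRemoval:
    @pytest.mark.parametrize("method,tol", [("butter", 1e-6), ("asls", 1e-3)])
    def test_dc_rejected(self, method, tol):
        # the asls solve carries a large smoothing weight, so its DC
        # rejection is exact only to solver precision
        tr = Trace(np.full(4000, 3.0), fs=1.0, unit="zscore")
        out = remove_drift(tr, cutoff=0.001, method=method)
        assert np.abs(out.values).max() < tol

    @pytest.mark.parametrize("method", ["butter", "asls"])
    def test_fast_sinusoid_amplitude_preserved(self, method):
        t = np.arange(4000.0)
        tr = Trace(np.sin(2 * np.pi * 0.01 * t), fs=1.0, unit="zscore")
        out = remove_drift(tr, cutoff=0.001, method=method)
        core = slice(500, 3500)
        ratio = out.values[core].std() / tr.values[core].std()
        assert abs(ratio - 1.0) < 0.05

    def test_class_specific_default_cutoffs(self):
        assert default_cutoff("ado") == 0.00035
        assert default_cutoff("atp") == 0.00035
        assert default_cutoff("ca") == 0.001
        with pytest.raises(ValueError):
            default_cutoff("unknown")

    def test_event_auc_preserved_at_calcium_cutoff(self):
        # fast transient (decay 8 s <= 10 s) over a slow drift at 1 Hz
        from photosleep.simulate import event_kernel
        from photosleep.transients import auc_between
        k = event_kernel(1.0, 2.0, 8.0)
        x = np.zeros(4000)
        x[2000:2000 + k.size] += 0.5 * k
        tr = Trace(x, fs=1.0, unit="zscore")
        out = remove_drift(tr, cutoff=0.001)
        a0 = auc_between(tr, 1995.0, 2040.0, 0.0)
        a1 = auc_between(out, 1995.0, 2040.0,
                         float(out.values[1895:1995].mean()))
        assert abs(a1 - a0) / a0 < 0.10

    def test_invalid_cutoff_rejected(self):
        tr = Trace(np.zeros(100), fs=1.0, unit="zscore")
        with pytest.raises(ValueError, match="cutoff"):
            remove_drift(tr, cutoff=0.7)


class TestUnmixing:
    def _artifact(self, rng, n):
        a = sosfiltfilt(butter(2, 0.2, output="sos"), rng.standard_normal(n))
        return a / a.std()

    def test_uncorrelated_iso_leaves_signal_unchanged(self):
        rng = np.random.default_rng(4)
        n = 3000
        sig = Trace(rng.standard_normal(n), fs=1.0, unit="dFF")
        iso = Trace(self._artifact(rng, n), fs=1.0, unit="dFF")
        out = unmix_isosbestic(sig, iso)
        assert np.corrcoef(out.values, sig.values)[0, 1] > 0.99

    def test_shared_artifact_removed(self):
        rng = np.random.default_rng(5)
        n = 3000
        clean = rng.standard_normal(n)
        art = self._artifact(rng, n)
        sig = Trace(clean + 1.5 * art, fs=1.0, unit="dFF")
        iso = Trace(0.8 * art + 0.05 * rng.standard_normal(n), fs=1.0,
                    unit="dFF")
        out = unmix_isosbestic(sig, iso)
        c_raw = np.corrcoef(sig.values, clean)[0, 1]
        c_unmixed = np.corrcoef(out.values, clean)[0, 1]
        assert c_unmixed > c_raw

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        n = 2000
        art = self._artifact(rng, n)
        sig = Trace(rng.standard_normal(n) + art, fs=1.0, unit="dFF")
        iso = Trace(art, fs=1.0, unit="dFF")
        o1 = unmix_isosbestic(sig, iso, random_state=0)
        o2 = unmix_isosbestic(sig, iso, random_state=0)
        assert np.array_equal(o1.values, o2.values)

    def test_mismatched_traces_rejected(self):
        sig = Trace(np.zeros(100), fs=1.0, unit="dFF")
        iso = Trace(np.zeros(50), fs=1.0, unit="dFF")
        with pytest.raises(ValueError, match="length"):
            unmix_isosbestic(sig, iso)


class TestTrim:
    def test_arithmetic(self):
        tr = Trace(np.arange(3600.0), fs=1.0)
        out = trim_initial(tr, 600.0)
        assert out.n == 3000
        assert out.t0 == 600.0
        assert out.values[0] == 600.0

    def test_zero_trim_is_identity(self):
        tr = Trace(np.arange(100.0), fs=1.0)
        out = trim_initial(tr, 0.0)
        assert np.array_equal(out.values, tr.values) and out.t0 == tr.t0

    def test_default_is_600_seconds(self):
        tr = Trace(np.arange(3600.0), fs=1.0)
        assert trim_initial(tr).t0 == 600.0

    def test_overlong_trim_rejected(self):
        with pytest.raises(ValueError, match="longer"):
            trim_initial(Trace(np.arange(100.0), fs=1.0), 200.0)


class TestFullChain:
    def test_noise_free_bleach_only_dff_below_1e3(self):
        cfg = SimConfig(duration=3600, seed=23, photo_fs=5.0,
                        white_noise_sd=0.0,
                        event_rate={"W": 0, "N": 0, "R": 0},
                        tonic_level={"W": 0, "N": 0, "R": 0})
        s = simulate_session(cfg, with_eeg=False)
        _, dff = fit_bleach_baseline(bin_to_1hz(s.photo["a"]),
                                     background=cfg.background)
        assert np.abs(dff.values).max() < 1e-3

    def test_unmixing_in_chain_improves_artifact_rejection(self):
        cfg = SimConfig(duration=7200, seed=24, photo_fs=5.0,
                        artifact_sd=0.08, isosbestic=True,
                        white_noise_sd=0.005)
        s = simulate_session(cfg, with_eeg=False)
        plain = preprocess(s.photo["a"], background=cfg.background)
        unmixed = preprocess(s.photo["a"], background=cfg.background,
                             iso=s.photo["iso"])
        clean = s.truth.clean_a
        k = int(600 * cfg.photo_fs)
        clean_1hz = clean[k:].reshape(-1, int(cfg.photo_fs)).mean(axis=1)
        n = min(clean_1hz.size, plain.n)
        c_plain = np.corrcoef(plain.values[:n], clean_1hz[:n])[0, 1]
        c_unmix = np.corrcoef(unmixed.values[:n], clean_1hz[:n])[0, 1]
        assert c_unmix > c_plain
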