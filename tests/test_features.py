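"""Acoustic feature extractors: envelope, spectrum, pitch/saliency, formants,
the 22-feature vector, and the mixed-effects condition contrast."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sp_signal

from crysig import (
    FeatureError,
    PAF_NAMES,
    SPECTRAL_SUBSET,
    amplitude_envelope,
    estimate_formants,
    feature_condition_contrast,
    paf_vector,
    power_spectrum_summary,
    summarize_envelope,
    synthesize_cry,
    track_pitch,
)
from crysig.features import _normalized_entropy
from crysig.synth import CryRecording

from conftest import make_noise, make_tone


class TestEnvelope:
    def test_constant_sine_flat_envelope(self):
        rec = make_tone(400.0, 2.0)
        env, _ = amplitude_envelope(rec)
        core = env[len(env) // 5 : -len(env) // 5]
        assert core.std() / core.mean() < 0.05

    def test_am_tone_envelope_periodicity(self):
        """4 Hz, 100% depth AM: envelope spectrum peaks at 4 Hz, matching the
        Hilbert-magnitude oracle."""
        sr = 22050
        t = np.arange(4 * sr) / sr
        x = (1 + np.sin(2 * np.pi * 4 * t)) * np.sin(2 * np.pi * 500 * t) / 2
        rec = CryRecording(x / np.max(np.abs(x)), sr, "B", "M", "discomfort", "am")
        env, env_sr = amplitude_envelope(rec)
        spec = np.abs(np.fft.rfft(env - env.mean()))
        freqs = np.fft.rfftfreq(len(env), 1 / env_sr)
        assert freqs[np.argmax(spec)] == pytest.approx(4.0, abs=0.3)
        oracle = np.abs(sp_signal.hilbert(x))
        ospec = np.abs(np.fft.rfft(oracle - oracle.mean()))
        ofreqs = np.fft.rfftfreq(len(oracle), 1 / sr)
        mask = ofreqs > 0.5
        assert ofreqs[mask][np.argmax(ospec[mask])] == pytest.approx(4.0, abs=0.3)

    def test_silence_regions_near_zero(self):
        sr = 22050
        x = np.zeros(2 * sr)
        x[sr // 2 : sr] = np.sin(2 * np.pi * 400 * np.arange(sr // 2) / sr)
        rec = CryRecording(x, sr, "B", "M", "discomfort", "burst")
        env, env_sr = amplitude_envelope(rec)
        tail = env[int(1.5 * env_sr) :]
        assert tail.max() < 0.05 * env.max()


class TestEnvelopeSummary:
    def test_constant_envelope_statistics(self):
        stats = summarize_envelope(np.full(500, 0.7))
        assert stats["env_mean"] == pytest.approx(0.7)
        assert stats["env_sd"] == pytest.approx(0.0)
        assert stats["env_rms"] == pytest.approx(0.7)
        assert stats["env_max"] == pytest.approx(0.7)
        assert stats["env_entropy"] == pytest.approx(1.0)  # maximal

    def test_symmetric_envelope_zero_skew(self):
        env = np.concatenate([np.linspace(0, 1, 100), np.linspace(1, 0, 100)])
        assert summarize_envelope(env)["env_skew"] == pytest.approx(0.0, abs=1e-8)

    def test_concentrated_envelope_low_entropy(self):
        env = np.full(1000, 1e-12)
        env[500] = 1.0
        assert summarize_envelope(env)["env_entropy"] < 0.05

    def test_two_point_equal_mass_entropy_is_one(self):
        assert _normalized_entropy(np.array([0.5, 0.5])) == pytest.approx(1.0)

    def test_zero_envelope_rejected(self):
        with pytest.raises(FeatureError):
            summarize_envelope(np.zeros(100))


class TestSpectrum:
    def test_pure_tone_quartiles_collapse(self):
        rec = make_tone(400.0, 2.0)
        s = power_spectrum_summary(rec)
        bin_hz = rec.sample_rate / len(rec.waveform)
        for q in ("Q1", "Q2", "Q3"):
            assert abs(s[q] - 400.0) <= max(bin_hz, 2.0)

    def test_white_noise_median_near_half_nyquist(self):
        meds = [
            power_spectrum_summary(make_noise(2.0, seed=s))["Q2"] for s in range(3)
        ]
        assert np.mean(meds) == pytest.approx(22050 / 4, rel=0.05)

    def test_two_tone_mean_between(self):
        sr = 22050
        t = np.arange(2 * sr) / sr
        x = np.sin(2 * np.pi * 300 * t) + np.sin(2 * np.pi * 900 * t)
        rec = CryRecording(x / 2, sr, "B", "M", "discomfort", "two")
        s = power_spectrum_summary(rec)
        assert s["spec_mean"] == pytest.approx(600.0, abs=20.0)

    def test_silent_input_rejected(self):
        rec = CryRecording(np.zeros(22050), 22050, "B", "M", "discomfort", "z")
        with pytest.raises(FeatureError):
            power_spectrum_summary(rec)


class TestPitch:
    def test_sine_tracked_accurately(self):
        tr = track_pitch(make_tone(400.0))
        assert abs(np.nanmean(tr.f0) - 400.0) < 2.0
        assert np.nanmean(tr.saliency) > 0.95

    def test_white_noise_low_saliency(self):
        sals = [
            np.nanmean(track_pitch(make_noise(1.0, seed=s)).saliency)
            for s in range(10)
        ]
        assert np.mean(sals) < 0.3

    def test_chirp_monotonic_track(self):
        sr = 22050
        t = np.arange(2 * sr) / sr
        x = sp_signal.chirp(t, 300.0, 2.0, 500.0)
        rec = CryRecording(x, sr, "B", "M", "discomfort", "chirp")
        tr = track_pitch(rec)
        f0 = tr.f0[tr.voiced]
        # smoothed track strictly increases; instantaneous frequency oracle
        k = 5
        sm = np.convolve(f0, np.ones(k) / k, mode="valid")
        assert np.all(np.diff(sm) > -2.0)
        inst = 300.0 + (500.0 - 300.0) / 2.0 * tr.frame_times[tr.voiced]
        assert np.nanmedian(np.abs(f0 - inst) / inst) < 0.03

    def test_inverted_band_rejected(self):
        with pytest.raises(FeatureError):
            track_pitch(make_tone(400.0), f0_min=800, f0_max=300)

    def test_matches_cepstral_oracle_on_synthetic_cries(self, profiles):
        """Frame-matched independent cepstral pitch estimates agree within 5%
        with the autocorrelation tracker across 20 seeded cries."""
        errs = []
        for s in range(20):
            prof = profiles[s % len(profiles)]
            rec = synthesize_cry(prof, "discomfort", 1.5, seed=300 + s)
            tr = track_pitch(rec)
            sr = rec.sample_rate
            n = int(0.05 * sr)
            voiced_idx = np.flatnonzero(tr.voiced)
            per_frame = []
            for i in voiced_idx[:: max(1, len(voiced_idx) // 8)]:
                center = int(tr.frame_times[i] * sr)
                lo = max(0, center - n // 2)
                fr = rec.waveform[lo : lo + n]
                if len(fr) < n:
                    continue
                spec = np.log(np.abs(np.fft.rfft(fr * np.hanning(n))) + 1e-9)
                cep = np.abs(np.fft.irfft(spec))
                qmin, qmax = int(sr / 700), int(sr / 200)
                quef = qmin + np.argmax(cep[qmin:qmax])
                per_frame.append(abs(sr / quef - tr.f0[i]) / (sr / quef))
            errs.append(np.median(per_frame))
        assert np.median(errs) < 0.05

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_saliency_bounded_on_arbitrary_signals(self, seed):
        rng = np.random.default_rng(seed)
        kind = seed % 3
        n = 8000
        if kind == 0:
            x = rng.standard_normal(n)
        elif kind == 1:
            x = np.sin(2 * np.pi * rng.uniform(160, 900) * np.arange(n) / 8000)
        else:
            x = rng.standard_normal(n) * np.sin(2 * np.pi * 3 * np.arange(n) / 8000)
        rec = CryRecording(x / (np.max(np.abs(x)) or 1), 8000, "B", "M", "discomfort", "r")
        tr = track_pitch(rec, f0_max=1000)
        sal = tr.saliency[~np.isnan(tr.saliency)]
        assert np.all((sal >= 0) & (sal <= 1))


class TestFormants:
    def test_known_resonances_recovered(self, profiles):
        from dataclasses import replace

        prof = replace(profiles[0], F1=1100.0, F2=3300.0)
        rec = synthesize_cry(prof, "discomfort", 3.0, seed=42)
        est = estimate_formants(rec)
        assert abs(est.F1 - 1100) / 1100 < 0.15
        assert abs(est.F2 - 3300) / 3300 < 0.15

    def test_resonance_shift_tracked_in_rank_order(self, profiles):
        from dataclasses import replace

        a = estimate_formants(
            synthesize_cry(replace(profiles[0], F1=1100.0, F2=3300.0), "discomfort", 3.0, seed=42)
        )
        b = estimate_formants(
            synthesize_cry(replace(profiles[0], F1=1480.0, F2=3000.0), "discomfort", 3.0, seed=42)
        )
        assert b.F1 > a.F1
        assert b.F2 < a.F2

    def test_pure_tone_degenerate(self):
        rec = make_tone(400.0, 2.0)
        try:
            est = estimate_formants(rec)
            assert not est.confident
        except FeatureError:
            pass  # outright rejection is equally acceptable


class TestPAFVector:
    def test_twenty_two_finite_values(self, profiles):
        p = paf_vector(synthesize_cry(profiles[2], "pain", 2.0, seed=77))
        d = p.to_dict()
        assert len(d) == 22
        assert tuple(d) == PAF_NAMES
        assert np.all(np.isfinite(list(d.values())))
        assert p.Q1 <= p.Q2 <= p.Q3
        assert p.MinF0 <= p.meanF0 <= p.MaxF0

    def test_constant_f0_low_cv(self, profiles):
        from dataclasses import replace

        prof = replace(profiles[0], f0_mod_depth=0.0, jitter_sd=0.0)
        p = paf_vector(synthesize_cry(prof, "discomfort", 2.0, seed=5, noise_floor_db=-80))
        assert p.cvF0 < 0.01
        assert p.MaxF0 - p.MinF0 < 0.05 * p.meanF0

    def test_spectral_subset_fields(self, profiles):
        p = paf_vector(synthesize_cry(profiles[2], "discomfort", 2.0, seed=78))
        sub = p.spectral_subset()
        assert tuple(sub) == SPECTRAL_SUBSET
        assert len(sub) == 10

    def test_amplitude_scale_invariance(self, profiles):
        rec = synthesize_cry(profiles[4], "discomfort", 2.0, seed=9)
        scaled = CryRecording(
            rec.waveform * 0.2, rec.sample_rate, "B", "M", "discomfort", "s"
        )
        a, b = paf_vector(rec), paf_vector(scaled)
        # amplitude-invariant features
        for name in SPECTRAL_SUBSET + ("env_skew", "env_kurtosis", "env_entropy"):
            assert getattr(b, name) == pytest.approx(getattr(a, name), rel=1e-4, abs=1e-6)
        # linearly scaling features
        for name in ("env_mean", "env_sd", "env_rms", "env_max"):
            assert getattr(b, name) == pytest.approx(0.2 * getattr(a, name), rel=1e-4)


def _synthetic_feature_table(rng, n_babies=24, shift=0.0, per_cond=10):
    """Gaussian per-baby feature values with a condition shift in units of the
    within-baby SD -- cheap stand-in for audio when testing the contrast."""
    rows = []
    for i in range(n_babies):
        mu = rng.normal(0, 2)
        sex = "M" if i % 2 == 0 else "F"
        for cond in ("discomfort", "pain"):
            for _ in range(per_cond):
                val = mu + rng.normal(0, 1) + (shift if cond == "pain" else 0)
                rows.append(
                    {"baby_id": f"B{i:02d}", "sex": sex, "condition": cond, "val": val}
                )
    return pd.DataFrame(rows)


class TestConditionContrast:
    def test_null_calibration(self):
        """No true condition effect: Wald |z| < 1.96 in >= 90% of simulations."""
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(1000 + s)
            tab = _synthetic_feature_table(rng, shift=0.0)
            res = feature_condition_contrast(tab, "val")
            cond_term = next(k for k in res.wald_z if "condition" in k and ":" not in k)
            hits += abs(res.wald_z[cond_term]) < 1.96
        assert hits >= 18

    def test_power_for_two_sd_shift(self):
        """A 2-within-SD condition shift is detected in >= 80% of runs."""
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(2000 + s)
            tab = _synthetic_feature_table(rng, shift=2.0)
            res = feature_condition_contrast(tab, "val")
            cond_term = next(k for k in res.p_values if "condition" in k and ":" not in k)
            hits += res.p_values[cond_term] < 0.05
        assert hits >= 16

    def test_single_condition_rejected(self):
        rng = np.random.default_rng(0)
        tab = _synthetic_feature_table(rng)
        with pytest.raises(FeatureError):
            feature_condition_contrast(tab[tab.condition == "pain"], "val")
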