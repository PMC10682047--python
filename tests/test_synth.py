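"""Generator contracts: rates, spectra, amplitudes, determinism."""

import numpy as np
import pytest

import larynet as ln
from larynet import synth
from larynet.dsp import welch_psd

FS = 333.0


class TestCardiac:
    def test_wavelet_count_matches_rate(self, profile):
        x = ln.synthesize_cardiac(60, FS, 10, profile, seed=0)
        thr = 0.5 * x.max()
        crossings = np.sum((x[1:] >= thr) & (x[:-1] < thr))
        assert abs(crossings - 10) <= 1

    def test_welch_fundamental_at_beat_rate(self, profile):
        x = ln.synthesize_cardiac(72, FS, 60, profile, seed=1)
        spec = welch_psd(x, FS, segment_len=8192)
        assert abs(spec.peak_frequency() - 1.2) <= 0.05

    @pytest.mark.parametrize("hr", [0, 10, 250])
    def test_nonphysiological_rate_rejected(self, profile, hr):
        with pytest.raises(ValueError, match="heart rate"):
            ln.synthesize_cardiac(hr, FS, 10, profile, seed=0)

    def test_amplitude_scales_with_profile(self):
        lo = ln.SubjectProfile("a", cardiac_amp=0.01)
        hi = ln.SubjectProfile("b", cardiac_amp=0.02)
        xa = ln.synthesize_cardiac(60, FS, 10, lo, seed=0)
        xb = ln.synthesize_cardiac(60, FS, 10, hi, seed=0)
        assert np.isclose(xb.max(), 2 * xa.max(), rtol=1e-6)


class TestRespiration:
    def test_upcrossing_count_matches_rate(self, profile):
        x = ln.synthesize_respiration(12, FS, 60, profile, seed=0)
        m = x.mean()
        ups = np.sum((x[1:] >= m) & (x[:-1] < m))
        assert abs(ups - 12) <= 1

    def test_spectral_peak_at_breath_rate(self, profile):
        # 16 breaths/min -> 0.2667 Hz; full-length periodogram resolves it
        x = ln.synthesize_respiration(16, FS, 60, profile, seed=3)
        spec = welch_psd(x, FS, segment_len=x.size, overlap=0.0)
        assert abs(spec.peak_frequency() - 16 / 60) <= 0.01

    @pytest.mark.parametrize("rr", [2, 100])
    def test_rate_out_of_range_rejected(self, profile, rr):
        with pytest.raises(ValueError, match="respiration rate"):
            ln.synthesize_respiration(rr, FS, 30, profile, seed=0)


class TestEvents:
    @pytest.mark.parametrize("kind", synth.CLASSIFIER_KINDS)
    def test_laryngeal_amplitude_and_band(self, profile, kind):
        accel, _ = ln.synthesize_event(kind, FS, 3.0, 1.0, profile, seed=5)
        az = accel[2]
        assert np.abs(az).max() < 0.4
        spec = welch_psd(az, FS, segment_len=512)
        below = spec.band_power(0.0, min(200.0, FS / 2 - 1))
        total = spec.band_power(0.0, FS / 2 - 1e-9)
        assert below / total > 0.9

    @pytest.mark.parametrize("kind", synth.LOCOMOTION_KINDS)
    def test_locomotion_dominates_y_axis(self, profile, kind):
        accel, _ = ln.synthesize_event(kind, FS, 4.0, 1.0, profile, seed=5)
        rms = np.sqrt(np.mean(accel**2, axis=1))
        assert rms[2] < rms[1]  # az < ay
        spec = welch_psd(accel[1], FS, segment_len=512)
        assert spec.peak_frequency() < 5.0

    def test_locomotion_louder_than_laryngeal(self, profile):
        walk, _ = ln.synthesize_event("walk", FS, 4.0, 1.0, profile, seed=1)
        swallow, _ = ln.synthesize_event("swallow", FS, 4.0, 1.0, profile, seed=1)
        assert np.abs(walk).max() > np.abs(swallow).max()

    def test_acoustic_templates_have_distinct_centroids(self):
        c1 = synth.acoustic_spectral_centroid("pinyin1")
        c3 = synth.acoustic_spectral_centroid("pinyin3")
        assert abs(c1 - c3) > 10.0
        cents = [synth.acoustic_spectral_centroid(k) for k in synth.ACOUSTIC_KINDS]
        assert len(set(np.round(cents, 3))) == len(cents)

    def test_zero_jitter_event_centroid_matches_template(self):
        prof = ln.SubjectProfile("z", spectral_jitter=0.0, baseline_noise_sd=1e-6)
        for kind in ("pinyin1", "vowel5"):
            accel, _ = ln.synthesize_event(kind, FS, 3.0, 1.0, prof, seed=2)
            spec = welch_psd(accel[2], FS, segment_len=512)
            centroid = float(np.sum(spec.freqs * spec.power) / np.sum(spec.power))
            assert abs(centroid - synth.acoustic_spectral_centroid(kind)) < 12.0

    def test_behavior_events_coactivate_semg(self, profile):
        for kind in synth.BEHAVIOR_KINDS:
            _, env = ln.synthesize_event(kind, FS, 3.0, 1.0, profile, seed=0)
            assert env.max() > 0.1

    def test_unknown_kind_rejected(self, profile):
        with pytest.raises(ValueError, match="unknown event kind"):
            ln.synthesize_event("yodel", FS, 2.0, 1.0, profile, seed=0)


class TestSemg:
    def test_zero_envelope_gives_baseline_noise(self, profile):
        env = np.zeros(3330)
        x = ln.synthesize_semg(env, FS, profile, seed=0)
        rms = np.sqrt(np.mean(x**2))
        assert abs(rms - synth.SEMG_BASELINE_RMS) / synth.SEMG_BASELINE_RMS < 0.10

    def test_rectangular_burst_contrast(self, profile):
        env = np.zeros(6660)
        env[2000:4000] = 1.0
        x = ln.synthesize_semg(env, FS, profile, seed=0)
        inside = np.sqrt(np.mean(x[2100:3900] ** 2))
        outside = np.sqrt(np.mean(x[:1900] ** 2))
        assert inside > 5 * outside

    def test_invalid_inputs_rejected(self, profile):
        with pytest.raises(ValueError, match="non-negative"):
            ln.synthesize_semg(np.array([-1.0, 0.0]), FS, profile, seed=0)
        with pytest.raises(ValueError, match="sampling rate"):
            ln.synthesize_semg(np.zeros(10), 0.0, profile, seed=0)


class TestRecording:
    def test_axis_separation_of_vitals(self, profile):
        rec = ln.synthesize_recording([], (60, 12), FS, 30, profile, seed=2)
        az_spec = welch_psd(rec.az, FS, segment_len=4096)
        ay_spec = welch_psd(rec.ay, FS, segment_len=4096)
        assert abs(az_spec.peak_frequency() - 1.0) < 0.1   # cardiac on z
        assert abs(ay_spec.peak_frequency() - 0.2) < 0.05  # respiration on y

    def test_bit_identical_under_equal_seed(self, profile):
        sched = [ln.EventSpec("swallow", 5.0, 2.0)]
        a = ln.synthesize_recording(sched, (70, 15), FS, 20, profile, seed=9)
        b = ln.synthesize_recording(sched, (70, 15), FS, 20, profile, seed=9)
        for name in ln.Recording.CHANNEL_NAMES:
            assert np.array_equal(getattr(a, name), getattr(b, name))
        c = ln.synthesize_recording(sched, (70, 15), FS, 20, profile, seed=10)
        assert not np.array_equal(a.az, c.az)

    def test_annotations_pass_through(self, profile):
        sched = [ln.EventSpec("swallow", 5.0, 2.0, 0.9)]
        rec = ln.synthesize_recording(sched, (70, 15), FS, 20, profile, seed=0)
        assert rec.annotations == sched

    def test_identical_overlapping_events_warn(self, profile):
        sched = [ln.EventSpec("cough", 2.0, 1.0), ln.EventSpec("cough", 2.0, 1.0)]
        with pytest.warns(UserWarning, match="overlapping identical"):
            ln.synthesize_recording(sched, (70, 15), FS, 10, profile, seed=0)

    def test_event_past_end_rejected(self, profile):
        with pytest.raises(ValueError, match="past the recording end"):
            ln.synthesize_recording([ln.EventSpec("swallow", 9.5, 2.0)],
                                    (70, 15), FS, 10, profile, seed=0)


class TestCohort:
    def test_event_instance_counting(self):
        cohort = ln.synthesize_cohort(4, classes=("swallow", "drink", "cough"),
                                      reps_per_class=2, seed=0)
        n_events = sum(len(r.annotations) for recs in cohort.values() for r in recs)
        assert n_events == 4 * 3 * 2
        assert len(cohort) == 4
        assert len(set(cohort)) == 4

    def test_profiles_vary_between_subjects(self):
        cohort = ln.synthesize_cohort(3, classes=("swallow",), reps_per_class=1,
                                      seed=1)
        amps = {recs[0].subject.cardiac_amp for recs in cohort.values()}
        assert len(amps) == 3

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="at least 2 subjects"):
            ln.synthesize_cohort(1, classes=("swallow",), seed=0)


class TestValidation:
    def test_event_spec_invariants(self):
        with pytest.raises(ValueError):
            ln.EventSpec("swallow", -1.0, 2.0)
        with pytest.raises(ValueError):
            ln.EventSpec("swallow", 0.0, 0.0)

    def test_profile_invariants(self):
        with pytest.raises(ValueError):
            ln.SubjectProfile("x", cardiac_amp=0.0)
        with pytest.raises(ValueError):
            ln.SubjectProfile("x", spectral_jitter=0.7)
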