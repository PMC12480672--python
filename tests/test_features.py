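"""Voice feature extraction: perturbation suites, HNR, F0, formants,
syllable nuclei and daily aggregation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from copdmon import features as F
from copdmon.synth.voice import VoiceSpec, gen_voice

FS = 16000


def naive_jitter(T):
    """Direct-formula oracle for the jitter suite."""
    T = np.asarray(T, float)
    mean = T.mean()
    local = np.abs(np.diff(T)).mean() / mean
    rap = np.mean([abs(T[i] - (T[i - 1] + T[i] + T[i + 1]) / 3)
                   for i in range(1, len(T) - 1)]) / mean
    out = {"jitter": 100 * local,
           "absolute_jitter": np.abs(np.diff(T)).mean(),
           "rap_jitter": 100 * rap,
           "ddp_jitter": 300 * rap}
    if len(T) >= 5:
        ppq5 = np.mean([abs(T[i] - T[i - 2: i + 3].mean())
                        for i in range(2, len(T) - 2)]) / mean
        out["ppq5_jitter"] = 100 * ppq5
    return out


def naive_shimmer(A):
    A = np.asarray(A, float)
    mean = A.mean()
    out = {"shimmer": 100 * np.abs(np.diff(A)).mean() / mean}
    for k, name in ((3, "apq3_shimmer"), (5, "apq5_shimmer"),
                    (11, "apq11_shimmer")):
        if len(A) >= k:
            h = k // 2
            q = np.mean([abs(A[i] - A[i - h: i + h + 1].mean())
                         for i in range(h, len(A) - h)]) / mean
            out[name] = 100 * q
    if len(A) >= 3:
        out["dda_shimmer"] = 3 * out["apq3_shimmer"]
    return out


periods = st.lists(st.floats(min_value=4.0, max_value=14.0), min_size=5,
                   max_size=60).map(np.array)
amplitudes = st.lists(st.floats(min_value=0.05, max_value=2.0), min_size=11,
                      max_size=60).map(np.array)


class TestJitter:
    def test_constant_periods_all_zero(self):
        track = F.PeriodTrack(np.full(20, 6.0), np.ones(20))
        for v in F.jitter_features(track).values():
            assert v == pytest.approx(0.0, abs=1e-12)

    def test_alternating_periods_hand_values(self):
        T = np.tile([10.0, 10.1], 10)
        jf = F.jitter_features(F.PeriodTrack(T, np.ones(20)))
        assert jf["absolute_jitter"] == pytest.approx(0.1, rel=1e-9)
        assert jf["jitter"] == pytest.approx(100 * 0.1 / 10.05, rel=1e-9)
        assert jf["ddp_jitter"] == pytest.approx(100 * 0.2 / 10.05, rel=1e-9)
        assert jf["rap_jitter"] == pytest.approx(100 * 0.2 / 3 / 10.05,
                                                 rel=1e-9)

    def test_short_track_missing(self):
        jf = F.jitter_features(F.PeriodTrack(np.array([6.0, 6.1]),
                                             np.array([1.0, 1.0])))
        assert all(np.isnan(v) for v in jf.values())

    @given(periods)
    def test_ddp_is_three_times_rap(self, T):
        jf = F.jitter_features(F.PeriodTrack(T, np.ones_like(T)))
        assert jf["ddp_jitter"] == pytest.approx(3 * jf["rap_jitter"],
                                                 rel=1e-12)

    @given(periods)
    def test_oracle_equivalence(self, T):
        jf = F.jitter_features(F.PeriodTrack(T, np.ones_like(T)))
        for k, v in naive_jitter(T).items():
            assert jf[k] == pytest.approx(v, rel=1e-9, abs=1e-12)


class TestShimmer:
    def test_constant_amplitudes_all_zero(self):
        track = F.PeriodTrack(np.full(20, 6.0), np.ones(20))
        for v in F.shimmer_features(track).values():
            assert v == pytest.approx(0.0, abs=1e-12)

    def test_alternating_amplitudes(self):
        A = np.tile([1.0, 1.1], 10)
        sf = F.shimmer_features(F.PeriodTrack(np.full(20, 6.0), A))
        assert sf["shimmer"] == pytest.approx(100 * 0.1 / 1.05, rel=1e-9)

    @given(amplitudes)
    def test_dda_is_three_times_apq3(self, A):
        sf = F.shimmer_features(F.PeriodTrack(np.full_like(A, 6.0), A))
        assert sf["dda_shimmer"] == pytest.approx(3 * sf["apq3_shimmer"],
                                                  rel=1e-12)

    @given(amplitudes)
    def test_oracle_equivalence(self, A):
        sf = F.shimmer_features(F.PeriodTrack(np.full_like(A, 6.0), A))
        for k, v in naive_shimmer(A).items():
            assert sf[k] == pytest.approx(v, rel=1e-9, abs=1e-12)

    @given(amplitudes, st.floats(min_value=0.1, max_value=10))
    def test_scale_invariance(self, A, c):
        base = F.shimmer_features(F.PeriodTrack(np.full_like(A, 6.0), A))
        scaled = F.shimmer_features(F.PeriodTrack(np.full_like(A, 6.0), c * A))
        for k in base:
            assert scaled[k] == pytest.approx(base[k], rel=1e-9, abs=1e-12)


class TestTrackPeriods:
    def test_pulse_train_periods(self, clean_voice):
        track = F.track_periods(clean_voice.samples, FS)
        assert len(track) > 100
        assert track.periods_ms == pytest.approx(
            np.full(len(track), 1000 / 150), abs=0.05)

    def test_recovers_generator_period_list(self, perturbed_voice):
        track = F.track_periods(perturbed_voice.samples, FS)
        truth = perturbed_voice.true_periods_ms[0]
        est = track.periods_ms
        # align by best offset, compare the overlap
        best = None
        for off in range(-3, 4):
            lo = max(0, off)
            n = min(len(truth) - lo, len(est) - max(0, -off))
            if n < 50:
                continue
            d = np.abs(truth[lo: lo + n] - est[max(0, -off): max(0, -off) + n])
            if best is None or d.mean() < best.mean():
                best = d
        assert best is not None
        assert np.max(best) <= 0.2

    def test_white_noise_gives_empty_track(self):
        rng = np.random.default_rng(0)
        track = F.track_periods(0.3 * rng.standard_normal(FS), FS)
        assert len(track) == 0

    def test_amplitude_scaling_leaves_jitter_unchanged(self, perturbed_voice):
        x = perturbed_voice.samples
        j1 = F.jitter_features(F.track_periods(x, FS))
        j2 = F.jitter_features(F.track_periods(3.0 * x, FS))
        for k in j1:
            assert j2[k] == pytest.approx(j1[k], rel=1e-6, abs=1e-9)


class TestHnr:
    def test_pure_sine_reports_ceiling(self):
        t = np.arange(FS) / FS
        assert F.hnr(0.3 * np.sin(2 * np.pi * 150 * t), FS) == 60.0

    def test_snr_controls_hnr(self):
        spec = VoiceSpec(duration_s=2.0, f0_hz=140, jitter_pct=0.3,
                         shimmer_pct=1.0, noise_snr_db=10, seed=5)
        assert F.hnr(gen_voice(spec).samples, FS) == pytest.approx(10, abs=2)

    def test_white_noise_missing(self):
        rng = np.random.default_rng(0)
        assert np.isnan(F.hnr(0.3 * rng.standard_normal(FS), FS))


class TestF0:
    def test_constant_pitch(self, clean_voice):
        _, f0, _ = F.frame_f0(clean_voice.samples, FS)
        mean, std = F.f0_stats(f0)
        assert mean == pytest.approx(150, abs=0.5)
        assert std < 0.5

    def test_mean_of_two_pitches(self):
        mean, std = F.f0_stats(np.array([100.0] * 50 + [200.0] * 50))
        assert mean == 150.0

    def test_no_voiced_frames_missing(self):
        mean, std = F.f0_stats(np.array([]))
        assert np.isnan(mean) and np.isnan(std)


class TestFormants:
    def test_recovers_generator_resonators(self, perturbed_voice):
        fset, meta = F.estimate_formants(perturbed_voice.samples, FS)
        assert fset is not None
        assert fset.as_array() == pytest.approx([500, 1500, 2500, 3500],
                                                abs=50)

    def test_unvoiced_noise_missing(self):
        rng = np.random.default_rng(0)
        fset, _ = F.estimate_formants(0.3 * rng.standard_normal(FS), FS)
        assert fset is None

    def test_estimates_strictly_increasing(self, perturbed_voice):
        fset, _ = F.estimate_formants(perturbed_voice.samples, FS)
        assert np.all(np.diff(fset.as_array()) > 0)


class TestFormantDerived:
    def test_quarter_wave_pattern_closed_forms(self):
        out = F.formant_derived(F.FormantSet(500, 1500, 2500, 3500))
        assert out["fdisp"] == pytest.approx(1000)
        assert out["delta_f"] == pytest.approx(1000)
        assert out["fitch_vtl"] == pytest.approx(17.5)
        assert out["vtl_delta_f"] == pytest.approx(17.5)
        assert out["mff"] == pytest.approx((500 * 1500 * 2500 * 3500) ** 0.25,
                                           rel=1e-12)
        assert out["mean_formant"] == pytest.approx(2000)

    @given(st.floats(min_value=0.5, max_value=2.0))
    def test_homogeneity_under_frequency_scaling(self, k):
        base = F.formant_derived(F.FormantSet(550, 1450, 2600, 3400))
        scaled = F.formant_derived(F.FormantSet(550 * k, 1450 * k, 2600 * k,
                                                3400 * k))
        for name in ("delta_f", "fdisp", "mff", "mean_formant"):
            assert scaled[name] == pytest.approx(k * base[name], rel=1e-9)
        for name in ("fitch_vtl", "vtl_delta_f"):
            assert scaled[name] == pytest.approx(base[name] / k, rel=1e-9)

    def test_pF_zero_at_reference(self):
        f = np.array([500.0, 1500, 2500, 3500])
        out = F.formant_derived(F.FormantSet(*f), reference_means=f,
                                reference_sds=np.full(4, 100.0))
        assert out["pF"] == 0.0

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            F.FormantSet(1500, 500, 2500, 3500)


class TestSyllableNuclei:
    def test_burst_fixture_counts(self):
        pattern = ((0.4, 0.8),) * 3 + ((0.4, 0.0),)
        spec = VoiceSpec(duration_s=4.0, f0_hz=140, jitter_pct=1.0,
                         shimmer_pct=3.0, syllable_pattern=pattern, seed=11)
        out = F.syllable_nuclei_features(gen_voice(spec).samples, FS)
        assert out["speech_rate"] == pytest.approx(1.0, abs=0.01)
        assert out["pause_rate"] == pytest.approx(0.75, abs=0.01)

    def test_continuous_vowel_single_nucleus(self, clean_voice):
        out = F.syllable_nuclei_features(clean_voice.samples, FS)
        assert out["speech_rate"] == pytest.approx(
            1.0 / clean_voice.duration_s, abs=0.01)

    def test_silence_degenerate(self):
        rng = np.random.default_rng(0)
        out = F.syllable_nuclei_features(1e-4 * rng.standard_normal(2 * FS), FS)
        assert out["speech_rate"] == 0.0
        assert np.isnan(out["phonation_time"])

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            F.syllable_nuclei_features(np.array([]), FS)


class TestDailyAggregate:
    def test_single_segment_identity(self):
        row = F.daily_aggregate([{"jitter": 1.0}], "P01", "2024-01-01")
        assert row["jitter"] == 1.0

    def test_mean_of_two_segments(self):
        row = F.daily_aggregate([{"jitter": 1.0}, {"jitter": 3.0}], "P01",
                                "2024-01-01")
        assert row["jitter"] == 2.0

    def test_pairwise_deletion_of_missing(self):
        segs = [{"hnr": np.nan, "jitter": 1.0}, {"hnr": 12.0, "jitter": 3.0}]
        row = F.daily_aggregate(segs, "P01", "2024-01-01")
        assert row["hnr"] == 12.0
        assert row["jitter"] == 2.0

    def test_no_segments_rejected(self):
        with pytest.raises(ValueError):
            F.daily_aggregate([], "P01", "2024-01-01")

    def test_day_level_f0_pooling(self):
        segs = [{"mean_f0": 100.0}, {"mean_f0": 200.0}]
        f0s = [np.full(10, 100.0), np.full(30, 200.0)]
        row = F.daily_aggregate(segs, "P01", "2024-01-01", f0_frames=f0s)
        assert row["mean_f0"] == pytest.approx(175.0)  # pooled, not 150
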