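import numpy as np
import pytest

from ecgcluster.cohort import WaveParams, generate_clean_ecg
from ecgcluster.preprocess import Beat, denoise, detect_qrs, segment_beats
from ecgcluster.waveform import (
    WAVEFORM_FEATURE_NAMES,
    FiducialPoints,
    beat_waveform_features,
    extract_waveform_features,
    locate_fiducials,
    subject_waveform_feature,
)

from conftest import make_profile

FS = 1000.0


def _beats(waves=None, seed=1, duration=10.0):
    prof = make_profile(waves=waves)
    sig = denoise(generate_clean_ecg(prof, FS, duration, seed=seed))
    return sig, segment_beats(sig, detect_qrs(sig))


def _points(q=(0.0, 0.0), r=(40.0, 1.0), s=(80.0, 0.0)):
    """Fiducials at explicit (ms, mV) for Q, R, S; P and T at plausible spots."""
    fs = 1000.0
    r_idx = 400
    idx = {
        "P": r_idx + int(-160),
        "Q": r_idx + int(q[0] - 40),
        "R": r_idx + int(r[0] - 40),
        "S": r_idx + int(s[0] - 40),
        "T": r_idx + 260,
    }
    amps = {"P": 0.1, "Q": q[1], "R": r[1], "S": s[1], "T": 0.3}
    return FiducialPoints(indices=idx, amplitudes=amps, fs=fs)


class TestLocateFiducials:
    def test_points_recovered_within_one_sigma(self):
        waves = WaveParams.typical()
        sig, beats = _beats(waves)
        for beat in beats:
            pts = locate_fiducials(beat, FS)
            for name in ("P", "Q", "R", "S", "T"):
                wave = getattr(waves, name)
                assert abs(pts.time_ms(name) - wave.center_ms) <= wave.width_ms

    def test_order_always_ascending(self):
        sig, beats = _beats(seed=5)
        for beat in beats:
            pts = locate_fiducials(beat, FS)
            order = [pts.indices[p] for p in ("P", "Q", "R", "S", "T")]
            assert order == sorted(order) and len(set(order)) == 5

    def test_zero_p_wave_gives_small_p_features(self):
        waves = WaveParams.typical()
        waves.P.amplitude = 0.0
        prof = make_profile(waves=waves)
        raw = generate_clean_ecg(prof, FS, 10.0, seed=1)
        beats = segment_beats(raw, detect_qrs(denoise(raw)))
        pts = locate_fiducials(beats[0], FS)
        # with no P deflection the located P sits on baseline
        assert abs(pts.amplitudes["P"]) < 0.02
        feats = extract_waveform_features(pts)
        assert abs(feats[WAVEFORM_FEATURE_NAMES.index("amp_PQ")] - (0.0 - pts.amplitudes["Q"])) < 0.02


class TestExtractFeatures:
    def test_qrs_triangle_area_half_base_height(self):
        pts = _points(q=(0.0, 0.0), r=(40.0, 1.0), s=(80.0, 0.0))
        feats = extract_waveform_features(pts)
        area = feats[WAVEFORM_FEATURE_NAMES.index("area_QRS")]
        assert area == pytest.approx(40.0)  # 0.5 * 80 ms * 1 mV

    def test_collinear_qrs_area_zero(self):
        pts = _points(q=(0.0, 0.0), r=(40.0, 0.5), s=(80.0, 1.0))
        feats = extract_waveform_features(pts)
        assert feats[WAVEFORM_FEATURE_NAMES.index("area_QRS")] == pytest.approx(0.0)

    def test_vector_has_24_entries(self):
        sig, beats = _beats()
        feats = beat_waveform_features(beats[0], FS)
        assert feats.shape == (24,)
        assert len(WAVEFORM_FEATURE_NAMES) == 24

    def test_time_shift_invariance(self):
        sig, beats = _beats()
        beat = beats[0]
        pad = 150
        shifted = Beat(
            samples=np.concatenate([np.zeros(pad), beat.samples]),
            r_index=beat.r_index + pad,
            rr_prev=beat.rr_prev + pad,
            rr_next=beat.rr_next,
        )
        a = beat_waveform_features(beat, FS)
        b = beat_waveform_features(shifted, FS)
        assert np.allclose(a, b, atol=1e-9)

    def test_amplitude_scaling_covariance(self):
        sig, beats = _beats()
        beat = beats[0]
        scaled = Beat(
            samples=2.5 * beat.samples,
            r_index=beat.r_index,
            rr_prev=beat.rr_prev,
            rr_next=beat.rr_next,
        )
        a = beat_waveform_features(beat, FS)
        b = beat_waveform_features(scaled, FS)
        names = WAVEFORM_FEATURE_NAMES
        for i, name in enumerate(names):
            if name.startswith(("amp_", "slope_", "area_")):
                assert b[i] == pytest.approx(2.5 * a[i], abs=1e-9)
            else:  # positions and durations untouched
                assert b[i] == pytest.approx(a[i], abs=1e-9)


class TestSubjectAggregation:
    def test_identical_beats_median_equals_any_beat(self):
        sig, beats = _beats()
        peaks = detect_qrs(sig)
        subject = subject_waveform_feature(sig, peaks)
        per_beat = np.stack([beat_waveform_features(b, FS) for b in beats])
        assert np.allclose(subject, np.median(per_beat, axis=0))

    def test_median_robust_to_one_corrupted_beat(self):
        sig, beats = _beats(duration=22.0)
        assert len(beats) >= 15
        rows = [beat_waveform_features(b, FS) for b in beats]
        clean_median = np.median(np.stack(rows), axis=0)
        rows[3] = rows[3] + 100.0  # one grossly mis-delineated beat
        robust = np.median(np.stack(rows), axis=0)
        assert np.allclose(robust, clean_median, rtol=0.05, atol=1.0)

    def test_qs_duration_tracks_generating_qrs_width(self):
        from scipy.stats import spearmanr

        from ecgcluster.cohort import NoiseSpec, add_noise

        rng = np.random.default_rng(99)
        factors = rng.uniform(1.0, 1.6, size=100)
        measured = []
        for i, f in enumerate(factors):
            w = WaveParams.typical()
            for comp in ("Q", "R", "S"):
                getattr(w, comp).width_ms *= f
            w.Q.center_ms *= f
            w.S.center_ms *= f
            for comp in ("P", "Q", "R", "S", "T"):  # mild unrelated variability
                getattr(w, comp).amplitude *= 1.0 + 0.05 * rng.standard_normal()
            prof = make_profile(waves=w, subject_id=f"s{i}")
            sig = generate_clean_ecg(prof, FS, 6.0, seed=300 + i)
            sig = add_noise(sig, NoiseSpec(white_sigma=0.01), seed=600 + i)
            sig = denoise(sig)
            vec = subject_waveform_feature(sig, detect_qrs(sig))
            measured.append(vec[WAVEFORM_FEATURE_NAMES.index("dur_QS")])
        rho = spearmanr(factors, measured).statistic
        assert rho >= 0.9
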