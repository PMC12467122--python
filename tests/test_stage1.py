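import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cabinpulse import stage1
from cabinpulse.stage1 import (
    DecisionConfig,
    Peak,
    ar_psd,
    burg_ar,
    detect_peaks,
    dwt_decompose,
    peak_decision,
    plausibility_check,
    reconstruct,
    reconstruct_hr_band,
    subband_edges,
)


class TestDWT:
    def test_level3_band_edges_at_20hz(self):
        bands = subband_edges(20.0, 3)
        assert bands["A3"] == (0.0, 1.25)
        assert bands["D3"] == (1.25, 2.5)

    def test_zero_input_gives_zero_coefficients(self):
        d = dwt_decompose(np.zeros(100))
        assert all(np.all(a == 0) for a in d.approx)
        assert all(np.all(c == 0) for c in d.detail)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="short"):
            dwt_decompose(np.zeros(6), levels=3)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.integers(64, 300))
    def test_perfect_reconstruction(self, seed, n):
        x = np.random.default_rng(seed).standard_normal(n)
        d = dwt_decompose(x, levels=3)
        assert np.max(np.abs(reconstruct(d) - x)) < 1e-8

    def test_hr_band_keeps_tone_energy(self):
        # a 1.0 Hz tone at 20 Hz lives in A3; >=90% of its energy survives
        t = np.arange(100) / 20.0
        x = np.sin(2 * np.pi * 1.0 * t)
        rec = reconstruct_hr_band(dwt_decompose(x))
        assert np.sum(rec**2) / np.sum(x**2) >= 0.9

    @pytest.mark.parametrize("f,band", [(0.8, "A3"), (1.8, "D3")])
    def test_tone_energy_in_owning_subband(self, f, band):
        t = np.arange(256) / 20.0
        x = np.sin(2 * np.pi * f * t)
        d = dwt_decompose(x)
        keep_d3 = [False, False, True]
        only_a3 = reconstruct(d, keep_approx=True, keep_details=[False] * 3)
        only_d3 = reconstruct(d, keep_approx=False, keep_details=keep_d3)
        e_a3, e_d3 = np.sum(only_a3**2), np.sum(only_d3**2)
        hr_total = e_a3 + e_d3
        share = (e_a3 if band == "A3" else e_d3) / hr_total
        assert share >= 0.8

    def test_band_limited_input_passes_through(self):
        # content well inside A3 survives nearly unchanged; the octave
        # filter bank attenuates progressively toward the 2.5 Hz band edge
        rng = np.random.default_rng(3)
        t = np.arange(200) / 20.0
        x = sum(np.sin(2 * np.pi * f * t + rng.uniform(0, 6)) for f in (0.5, 0.7, 0.9))
        rec = reconstruct_hr_band(dwt_decompose(x))
        assert np.linalg.norm(rec - x) / np.linalg.norm(x) < 0.05

    def test_leakage_grows_toward_band_edge(self):
        t = np.arange(200) / 20.0
        errs = []
        for f in (0.7, 1.5, 2.3):
            x = np.sin(2 * np.pi * f * t)
            rec = reconstruct_hr_band(dwt_decompose(x))
            errs.append(np.linalg.norm(rec - x) / np.linalg.norm(x))
        assert errs[0] < errs[1] < errs[2]

    def test_dropping_everything_gives_zero(self):
        d = dwt_decompose(np.random.default_rng(0).standard_normal(100))
        out = reconstruct(d, keep_approx=False, keep_details=[False] * 3)
        assert np.allclose(out, 0.0)

    def test_filters_exposed(self):
        d = dwt_decompose(np.zeros(64), wavelet_name="db4")
        h, g = d.filters
        assert h.size == 8 and g.size == 8


class TestBurg:
    def test_order_zero_matches_sample_variance(self):
        x = np.random.default_rng(1).standard_normal(1000)
        model = burg_ar(x, 0, 20.0)
        assert model.noise_var == pytest.approx(np.var(x), rel=0.10)

    def test_recovers_ar2_coefficients(self):
        # x[n] = 1.0 x[n-1] - 0.5 x[n-2] + e[n]  (alpha = [-1.0, 0.5])
        rng = np.random.default_rng(42)
        n = 2000
        x = np.zeros(n)
        e = rng.standard_normal(n)
        for i in range(2, n):
            x[i] = 1.0 * x[i - 1] - 0.5 * x[i - 2] + e[i]
        model = burg_ar(x, 2, 20.0)
        assert np.all(np.abs(model.coeffs - np.array([-1.0, 0.5])) < 0.05)

    def test_consistency_error_decreases_with_n(self):
        rng = np.random.default_rng(9)
        errs = []
        for n in (500, 2000):
            x = np.zeros(n)
            e = rng.standard_normal(n)
            for i in range(2, n):
                x[i] = 1.0 * x[i - 1] - 0.5 * x[i - 2] + e[i]
            model = burg_ar(x, 2, 20.0)
            errs.append(np.max(np.abs(model.coeffs - np.array([-1.0, 0.5]))))
        assert errs[1] < errs[0]

    def test_short_tone_frequency_resolved(self):
        # 1.2 Hz tone + 5% noise in only 100 samples
        rng = np.random.default_rng(4)
        t = np.arange(100) / 20.0
        x = np.sin(2 * np.pi * 1.2 * t) + 0.05 * rng.standard_normal(100)
        model = burg_ar(x, 12, 20.0)
        spec = ar_psd(model, np.linspace(0.5, 2.5, 2001))
        assert spec.freqs[np.argmax(spec.psd)] == pytest.approx(1.2, abs=0.05)

    def test_model_stability(self):
        x = np.random.default_rng(5).standard_normal(300)
        assert burg_ar(x, 12, 20.0).is_stable()

    def test_invalid_order_rejected(self):
        x = np.zeros(50)
        with pytest.raises(ValueError):
            burg_ar(x, -1, 20.0)
        with pytest.raises(ValueError):
            burg_ar(x, 30, 20.0)


class TestARPSD:
    def test_order_zero_gives_flat_spectrum(self):
        model = stage1.ARModel(0, np.empty(0), 2.5, 20.0)
        spec = ar_psd(model)
        assert spec.freqs.size == 512
        assert np.allclose(spec.psd, 2.5)

    def test_positivity(self):
        x = np.random.default_rng(6).standard_normal(400)
        spec = ar_psd(burg_ar(x, 8, 20.0), np.linspace(0.0, 10.0, 256))
        assert np.all(spec.psd > 0)

    def test_spectrum_integrates_to_process_variance(self):
        rng = np.random.default_rng(7)
        n = 20000
        x = np.zeros(n)
        e = rng.standard_normal(n)
        for i in range(2, n):
            x[i] = 1.0 * x[i - 1] - 0.5 * x[i - 2] + e[i]
        model = burg_ar(x, 2, 20.0)
        f = np.linspace(0.0, 10.0, 4001)
        spec = ar_psd(model, f)
        var = 2.0 * np.trapezoid(spec.psd, f) / 20.0  # two-sided symmetry
        assert var == pytest.approx(np.var(x), rel=0.10)

    def test_grid_validation(self):
        model = stage1.ARModel(0, np.empty(0), 1.0, 20.0)
        with pytest.raises(ValueError):
            ar_psd(model, np.array([]))
        with pytest.raises(ValueError):
            ar_psd(model, np.array([15.0]))


class TestPeakDetection:
    def test_monotone_spectrum_has_no_peaks(self):
        spec = stage1.SpectrumEstimate(np.linspace(0.5, 2.5, 100), np.linspace(1, 2, 100))
        assert detect_peaks(spec) == []

    def test_two_gaussian_bumps_found_at_centres(self):
        f = np.linspace(0.5, 2.5, 512)
        psd = np.exp(-((f - 1.0) ** 2) / 0.005) + 0.7 * np.exp(-((f - 2.0) ** 2) / 0.005)
        spec = stage1.SpectrumEstimate(f, psd)
        peaks = detect_peaks(spec)
        assert len(peaks) == 2
        step = f[1] - f[0]
        assert abs(peaks[0].freq - 1.0) <= step
        assert abs(peaks[1].freq - 2.0) <= step


class TestPeakDecision:
    cfg = DecisionConfig()

    def test_no_peaks_invalid(self):
        est = peak_decision([])
        assert not est.valid and est.f0 is None

    def test_single_peak_taken(self):
        est = peak_decision([Peak(1.3, 1.0, 1.0)])
        assert est.f0 == 1.3 and est.rule_applied == "single"

    def test_harmonic_pair_selects_fundamental(self):
        est = peak_decision([Peak(0.9, 0.5, 0.5), Peak(1.8, 1.0, 1.0)])
        assert est.f0 == 0.9 and est.rule_applied == "H1"

    def test_near_equal_pair_averaged(self):
        est = peak_decision([Peak(1.10, 1.0, 1.0), Peak(1.20, 0.9, 0.9)])
        assert est.f0 == pytest.approx(1.15) and est.rule_applied == "M1"

    def test_unequal_inharmonic_pair_takes_stronger(self):
        est = peak_decision([Peak(1.0, 2.0, 2.0), Peak(1.6, 0.5, 0.5)])
        assert est.f0 == 1.0 and est.rule_applied == "A1"

    def test_three_peaks_prune_harmonic_then_decide(self):
        peaks = [Peak(0.9, 1.0, 1.0), Peak(1.78, 0.8, 0.8), Peak(2.3, 0.2, 0.2)]
        est = peak_decision(peaks)  # 1.78 ~ 2*0.9 pruned
        assert est.rule_applied.startswith("prune")
        assert est.f0 == pytest.approx(0.9)

    def test_many_peaks_follow_history_median(self):
        peaks = [Peak(f, 1.0 + 0.01 * i, 1.0) for i, f in enumerate((0.6, 0.9, 1.2, 1.5, 1.8))]
        est = peak_decision(peaks, history=[1.19, 1.21, 1.2])
        assert est.f0 == 1.2 and est.rule_applied == "history"

    def test_many_peaks_without_history_take_strongest(self):
        peaks = [Peak(f, a, a) for f, a in
                 ((0.6, 0.2), (0.9, 0.9), (1.2, 0.5), (1.5, 0.4), (1.8, 0.3))]
        est = peak_decision(peaks)
        assert est.f0 == 0.9 and est.rule_applied == "max-amp"

    def test_decision_is_deterministic(self):
        peaks = [Peak(1.0, 1.0, 1.0), Peak(1.9, 0.9, 0.9)]
        a = peak_decision(peaks, history=[1.0, 1.1])
        b = peak_decision(peaks, history=[1.0, 1.1])
        assert a == b


class TestPlausibility:
    def test_empty_history_accepts_in_band(self):
        est = plausibility_check(stage1.CoarseEstimate(1.4, 1, "single", True))
        assert est.valid

    def test_out_of_band_rejected(self):
        est = plausibility_check(stage1.CoarseEstimate(3.1, 1, "single", True))
        assert not est.valid

    def test_large_jump_suppressed(self):
        # history 72/73/72 bpm; 120 bpm is a 47 bpm jump > 15 bpm limit
        hist = [72 / 60, 73 / 60, 72 / 60]
        est = plausibility_check(stage1.CoarseEstimate(2.0, 1, "single", True), hist)
        assert not est.valid

    def test_moderate_change_accepted(self):
        hist = [72 / 60, 73 / 60, 72 / 60]
        est = plausibility_check(stage1.CoarseEstimate(78 / 60, 1, "single", True), hist)
        assert est.valid

    def test_gate_waits_for_three_accepted(self):
        est = plausibility_check(stage1.CoarseEstimate(2.0, 1, "single", True), [1.0])
        assert est.valid
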