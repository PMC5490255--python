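"""dF/F computation, bleach fitting/correction, ROI traces, normalization."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import odortrace as ot
from odortrace.processing import (
    ResponseWindow,
    auto_mask,
    bleach_corrected_dff,
    fit_bleach_auto,
)
from odortrace.trace import Trace, time_grid


def make_trace(values, rate=1.0, channel="fluorescence"):
    values = np.asarray(values, dtype=float)
    return Trace(np.arange(values.size) / rate, values, rate, channel)


class TestDeltaFOverF:
    def test_constant_trace_gives_all_zero(self):
        tr = make_trace(np.full(100, 100.0))
        dff = ot.delta_f_over_f(tr, ResponseWindow(0, 20))
        assert np.all(dff.values == 0.0)
        assert dff.channel == "dff"

    def test_formula_ten_percent_step(self):
        v = np.full(50, 100.0)
        v[30] = 110.0
        dff = ot.delta_f_over_f(make_trace(v), ResponseWindow(0, 20))
        assert dff.values[30] == pytest.approx(0.10)

    def test_baseline_mean_is_zero(self, rng):
        v = 100.0 + rng.normal(0, 1, 200)
        dff = ot.delta_f_over_f(make_trace(v), ResponseWindow(0, 50))
        idx = dff.window_indices(0, 50)
        assert abs(dff.values[idx].mean()) < 1e-12

    def test_recovers_injected_amplitude_flat_bleach(self, library,
                                                     flat_bleach_gc):
        trace, truth = ot.simulate_gc_imaging_trace(
            ot.SampleSpec(library["ethyl_acetate"], 1e-4), flat_bleach_gc)
        dff = ot.delta_f_over_f(trace, ResponseWindow(0, 60))
        assert dff.values.max() == pytest.approx(
            truth.response_amplitudes["ethyl_acetate"], rel=1e-9)

    def test_zero_f0_refused(self):
        tr = make_trace(np.zeros(50) + np.arange(50))
        with pytest.raises(ot.TraceValidationError):
            ot.delta_f_over_f(tr, ResponseWindow(0, 0.5))

    def test_empty_baseline_window_refused(self):
        tr = make_trace(np.full(50, 10.0))
        with pytest.raises(ot.TraceValidationError):
            ot.delta_f_over_f(tr, ResponseWindow(100, 200))

    @given(gain=st.floats(1e-3, 1e3))
    def test_gain_invariance(self, gain):
        """dF/F of g*F equals dF/F of F for any gain g > 0."""
        base = np.full(80, 50.0)
        base[40:50] += 10.0
        tr1 = make_trace(base)
        tr2 = make_trace(gain * base)
        w = ResponseWindow(0, 20)
        np.testing.assert_allclose(ot.delta_f_over_f(tr1, w).values,
                                   ot.delta_f_over_f(tr2, w).values,
                                   rtol=1e-9, atol=1e-12)


class TestFitBleach:
    def test_noiseless_exponential_recovered_exactly(self):
        t = time_grid(540, 1.0)
        tr = Trace(t, 2.0 * np.exp(-t / 50.0) + 1.0, 1.0)
        fit = ot.fit_bleach(tr)
        assert fit.a == pytest.approx(2.0, rel=1e-6)
        assert fit.b == pytest.approx(50.0, rel=1e-6)
        assert fit.c == pytest.approx(1.0, rel=1e-6)
        assert fit.rss < 1e-12

    def test_constant_trace_degenerates_to_offset(self):
        tr = make_trace(np.full(100, 7.5))
        fit = ot.fit_bleach(tr)
        assert fit.c == 7.5
        assert fit.a == 0.0
        assert not fit.b_identifiable
        assert math.isnan(fit.b)

    def test_masked_fit_ignores_response_transient(self, library):
        """A large transient inside the mask does not disturb the fit;
        the time constant is recovered to within its statistical
        information limit at the default noise (the per-trial CRB is
        ~7% relative here), checked as a median over seeds."""
        errs = []
        for seed in range(15):
            trial = ot.simulate_trial(
                ot.SampleSpec(library["ethyl_acetate"], 1e-3),
                ot.AcquisitionSpec.gc_coupled(),
                rng=np.random.default_rng(200 + seed))
            fit = ot.fit_bleach(trial.fluorescence,
                                (ResponseWindow(85.0, 250.0),))
            errs.append(abs(fit.b - trial.truth.bleach[1])
                        / trial.truth.bleach[1])
        assert np.median(errs) < 0.10

    def test_noiseless_masked_fit_exact_despite_transient(self, library,
                                                          noiseless_gc):
        # sub-saturation amplitude so the masked window fully contains
        # the transient's decay tail
        trace, truth = ot.simulate_gc_imaging_trace(
            ot.SampleSpec(library["ethyl_acetate"], 1e-6), noiseless_gc)
        fit = ot.fit_bleach(trace, (ResponseWindow(85.0, 250.0),))
        assert fit.a == pytest.approx(truth.bleach[0], rel=1e-6)
        assert fit.b == pytest.approx(truth.bleach[1], rel=1e-6)
        assert fit.c == pytest.approx(truth.bleach[2], rel=1e-6)

    def test_matches_grid_search_oracle(self):
        """The optimizer's objective is no worse than a dense grid search
        over (A, B, C) on a small instance."""
        t = time_grid(60, 1.0)
        y = 3.0 * np.exp(-t / 20.0) + 2.0 + 0.05 * np.sin(t)
        tr = Trace(t, y, 1.0)
        fit = ot.fit_bleach(tr)

        def rss(a, b, c):
            return float(np.sum((a * np.exp(-t / b) + c - y) ** 2))

        grid_best = min(
            rss(a, b, c)
            for a in np.linspace(2.0, 4.0, 30)
            for b in np.linspace(10.0, 40.0, 30)
            for c in np.linspace(1.0, 3.0, 30))
        assert fit.rss <= grid_best + 1e-9

    def test_too_few_samples_refused(self):
        tr = make_trace(np.arange(12.0))
        with pytest.raises(ot.TraceValidationError):
            ot.fit_bleach(tr, (ResponseWindow(1.0, 20.0),))

    def test_overlapping_mask_windows_refused(self):
        tr = make_trace(np.arange(50.0))
        with pytest.raises(ot.TraceValidationError):
            ot.fit_bleach(tr, (ResponseWindow(0, 10), ResponseWindow(5, 15)))


class TestCorrectBleach:
    def test_pure_decay_flattens_to_offset(self):
        t = time_grid(540, 1.0)
        tr = Trace(t, 250.0 * np.exp(-t / 300.0) + 750.0, 1.0)
        fit = ot.fit_bleach(tr)
        corr = ot.correct_bleach(tr, fit)
        assert np.ptp(corr.values) <= 1e-9 * abs(fit.c)

    def test_zero_a_fit_is_identity(self):
        tr = make_trace(np.full(100, 5.0) + np.arange(100) * 0.0)
        fit = ot.BleachFit(a=0.0, b=math.nan, c=5.0, b_identifiable=False)
        corr = ot.correct_bleach(tr, fit)
        np.testing.assert_array_equal(corr.values, tr.values)

    def test_transient_amplitude_preserved(self, library, noiseless_gc):
        """Correction removes the decay but leaves the response transient's
        height above the local baseline unchanged (within 1%)."""
        trace, truth = ot.simulate_gc_imaging_trace(
            ot.SampleSpec(library["ethyl_acetate"], 1e-3), noiseless_gc)
        a, b, c = truth.bleach
        bleach_curve = a * np.exp(-trace.times / b) + c
        before = np.max(trace.values - bleach_curve)
        fit = ot.fit_bleach(trace, (ResponseWindow(85.0, 300.0),))
        corr = ot.correct_bleach(trace, fit)
        after = np.max(corr.values - fit.c)
        assert after == pytest.approx(before, rel=0.01)

    def test_baseline_drift_reduced(self, library, noiseless_gc):
        trace, _ = ot.simulate_gc_imaging_trace(
            ot.SampleSpec(library["ethyl_acetate"], 1e-3), noiseless_gc)
        fit = ot.fit_bleach(trace, (ResponseWindow(85.0, 300.0),))
        corr = ot.correct_bleach(trace, fit)
        outside = (trace.times < 85.0) | (trace.times > 300.0)
        drift_before = np.ptp(trace.values[outside])
        drift_after = np.ptp(corr.values[outside])
        assert drift_after <= 0.01 * drift_before


class TestAutoMask:
    def test_flags_response_windows(self, library):
        trial = ot.simulate_trial(
            ot.SampleSpec(library["ethyl_acetate"], 1e-3),
            ot.AcquisitionSpec.gc_coupled(),
            rng=np.random.default_rng(5))
        windows = auto_mask(trial.fluorescence)
        assert any(w.start <= 100.0 <= w.end for w in windows)

    def test_pure_noise_trace_yields_few_or_no_windows(self, rng):
        t = time_grid(540, 1.0)
        tr = Trace(t, 1000.0 + rng.normal(0, 5, t.size), 1.0)
        windows = auto_mask(tr)
        masked = sum(w.end - w.start for w in windows)
        assert masked < 0.2 * 540


class TestRoiExtraction:
    def test_single_pixel_roi_returns_that_pixel(self, rng):
        stack = rng.normal(size=(30, 5, 5))
        roi = np.zeros((5, 5), dtype=bool)
        roi[2, 3] = True
        tr = ot.extract_roi_trace(stack, roi, rate=4.0)
        np.testing.assert_array_equal(tr.values, stack[:, 2, 3])

    def test_empty_roi_refused(self, rng):
        with pytest.raises(ot.TraceValidationError):
            ot.extract_roi_trace(rng.normal(size=(10, 4, 4)),
                                 np.zeros((4, 4), dtype=bool), rate=4.0)


class TestNormalizeToReference:
    def test_scales_by_reference(self):
        tr = make_trace(np.array([0.0, 0.25, 0.1, 0.0]), channel="dff")
        out = ot.normalize_to_reference(tr, 0.5)
        assert out.values.max() == pytest.approx(0.5)

    def test_own_peak_reference_maps_to_one(self):
        tr = make_trace(np.array([0.0, 0.4, 0.1, 0.0]), channel="dff")
        out = ot.normalize_to_reference(tr, 0.4)
        assert out.values.max() == pytest.approx(1.0)

    def test_identity_with_unit_reference(self):
        tr = make_trace(np.array([0.0, 0.4, 0.1, 0.0]), channel="dff")
        out = ot.normalize_to_reference(tr, 1.0)
        np.testing.assert_array_equal(out.values, tr.values)

    def test_nonpositive_reference_refused(self):
        tr = make_trace(np.zeros(5), channel="dff")
        with pytest.raises(ot.TraceValidationError):
            ot.normalize_to_reference(tr, 0.0)

    def test_two_gains_normalize_to_matching_peaks(self, library):
        """Animals with 1x and 2x gain yield matching normalized responses
        once each is scaled by its own reference peak."""
        from odortrace.peaks import measure_response
        from odortrace.substances import ethyl_butyrate_sample

        peaks = {}
        for gain in (1.0, 2.0):
            acq = ot.AcquisitionSpec.gc_coupled(animal_gain=gain)
            rng = np.random.default_rng(11)
            ref = ot.simulate_trial(ethyl_butyrate_sample(), acq, rng=rng)
            tst = ot.simulate_trial(
                ot.SampleSpec(library["ethyl_acetate"], 1e-4), acq, rng=rng)
            ref_dff = bleach_corrected_dff(
                ref.fluorescence, fit_bleach_auto(ref.fluorescence))
            tst_dff = bleach_corrected_dff(
                tst.fluorescence, fit_bleach_auto(tst.fluorescence))
            ref_amp = measure_response(ref_dff, library["ethyl_acetate"],
                                       mode="apex")
            norm = ot.normalize_to_reference(tst_dff, ref_amp)
            peaks[gain] = measure_response(norm, library["ethyl_acetate"],
                                           mode="apex")
        assert peaks[1.0] == pytest.approx(peaks[2.0], rel=0.15)
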