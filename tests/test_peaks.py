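"""Peak detection, channel alignment, and response measurement."""

import numpy as np
import pytest

import odortrace as ot
from odortrace.peaks import (
    AlignmentModel,
    assign_peaks,
    calibrate_alignment,
    default_prominence,
    detect_peaks,
    measure_response,
)
from odortrace.processing import bleach_corrected_dff, fit_bleach_auto
from odortrace.substances import ethyl_butyrate_sample
from odortrace.trace import Trace, time_grid


def flat_trace(n=500, value=0.0, rate=1.0, channel="dff"):
    t = np.arange(n) / rate
    return Trace(t, np.full(n, float(value)), rate, channel)


class TestDetectPeaks:
    def test_flat_trace_yields_empty_list(self):
        assert detect_peaks(flat_trace(), 0.1) == []

    def test_noiseless_gaussian_apex_and_amplitude(self, library,
                                                   noiseless_gc):
        trace, truth = ot.simulate_fid_trace(
            ot.SampleSpec(library["ethyl_acetate"], 1e-2), noiseless_gc)
        peaks = detect_peaks(trace, 1e-6, polarity="positive")
        assert len(peaks) == 1
        assert abs(peaks[0].apex_time - 100.0) <= trace.dt
        assert peaks[0].amplitude == pytest.approx(
            truth.fid_apex_heights["ethyl_acetate"], rel=0.01)
        assert peaks[0].width > 0

    @pytest.mark.parametrize("seed", range(6))
    def test_reference_sample_shows_four_response_peaks(self, seed):
        """The ethyl butyrate standard carries three trace impurities, so
        its GC-coupled dF/F trace shows exactly four response peaks at the
        default prominence."""
        trial = ot.simulate_trial(ethyl_butyrate_sample(),
                                  ot.AcquisitionSpec.gc_coupled(),
                                  rng=np.random.default_rng(seed))
        dff = bleach_corrected_dff(trial.fluorescence,
                                   fit_bleach_auto(trial.fluorescence))
        peaks = detect_peaks(dff, polarity="positive")
        assert len(peaks) == 4
        apexes = sorted(p.apex_time for p in peaks)
        for apex, rt in zip(apexes, (100.0, 130.0, 170.0, 200.0)):
            assert abs(apex - rt) <= 3.0

    def test_constant_offset_invariance(self, library, rng):
        trial = ot.simulate_trial(ethyl_butyrate_sample(),
                                  ot.AcquisitionSpec.gc_coupled(),
                                  rng=np.random.default_rng(1))
        dff = bleach_corrected_dff(trial.fluorescence,
                                   fit_bleach_auto(trial.fluorescence))
        prom = default_prominence(dff)
        p1 = detect_peaks(dff, prom)
        p2 = detect_peaks(dff.with_values(dff.values + 3.7), prom)
        assert [p.apex_time for p in p1] == [p.apex_time for p in p2]
        for a, b in zip(p1, p2):
            assert a.width == pytest.approx(b.width, rel=1e-9)
            assert a.amplitude == pytest.approx(b.amplitude, rel=1e-9)

    def test_negative_polarity_finds_dips(self):
        t = time_grid(200, 1.0)
        v = -0.4 * np.exp(-0.5 * ((t - 80) / 4.0) ** 2)
        tr = Trace(t, v, 1.0, "dff")
        peaks = detect_peaks(tr, 0.1, polarity="negative")
        assert len(peaks) == 1
        assert peaks[0].amplitude == pytest.approx(-0.4, rel=0.02)

    def test_invalid_prominence_rejected(self):
        with pytest.raises(ot.TraceValidationError):
            detect_peaks(flat_trace(), -1.0)


class TestCalibrateAlignment:
    def _peak(self, t, amp=1.0, channel="fid"):
        from odortrace.peaks import Peak
        return Peak(apex_time=t, amplitude=amp, width=3.0, baseline=0.0,
                    channel=channel)

    def test_offset_is_dff_minus_fid_apex(self, library):
        model = calibrate_alignment([self._peak(100.0)],
                                    [self._peak(101.5, channel="dff")],
                                    library["ethyl_acetate"])
        assert model.offset == pytest.approx(1.5)

    def test_identical_channels_give_zero_offset(self, library):
        model = calibrate_alignment([self._peak(100.0)],
                                    [self._peak(100.0, channel="dff")],
                                    library["ethyl_acetate"])
        assert model.offset == 0.0

    def test_missing_reference_raises(self, library):
        with pytest.raises(ot.AlignmentError):
            calibrate_alignment([self._peak(100.0)], [],
                                library["ethyl_acetate"])
        with pytest.raises(ot.AlignmentError):
            calibrate_alignment([self._peak(200.0)],
                                [self._peak(100.0, channel="dff")],
                                library["ethyl_acetate"])

    def test_tie_broken_by_amplitude(self, library):
        dff = [self._peak(98.0, amp=0.1, channel="dff"),
               self._peak(102.0, amp=0.5, channel="dff")]
        model = calibrate_alignment([self._peak(100.0)], dff,
                                    library["ethyl_acetate"])
        assert model.offset == pytest.approx(2.0)

    @pytest.mark.parametrize("offset", [0.0, 1.0, 2.0, 5.0, -3.0])
    def test_noiseless_recovery_exact_for_any_offset(self, library, offset):
        acq = ot.AcquisitionSpec.gc_coupled(noise_sd=0.0, fid_noise_sd=0.0,
                                            channel_offset=offset)
        trial = ot.simulate_trial(ot.SampleSpec(library["ethyl_acetate"], 1e-2),
                                  acq, rng=np.random.default_rng(0))
        dff = bleach_corrected_dff(trial.fluorescence,
                                   fit_bleach_auto(trial.fluorescence))
        model = calibrate_alignment(detect_peaks(trial.fid, 1e-6),
                                    detect_peaks(dff, 0.05),
                                    library["ethyl_acetate"])
        assert abs(model.offset - offset) <= 1.0 / acq.rate

    def test_noisy_recovery_within_one_sample(self, library):
        recovered = []
        for seed in range(10):
            acq = ot.AcquisitionSpec.gc_coupled(channel_offset=2.0)
            trial = ot.simulate_trial(
                ot.SampleSpec(library["ethyl_acetate"], 1e-2), acq,
                rng=np.random.default_rng(seed))
            dff = bleach_corrected_dff(trial.fluorescence,
                                       fit_bleach_auto(trial.fluorescence))
            model = calibrate_alignment(detect_peaks(trial.fid),
                                        detect_peaks(dff),
                                        library["ethyl_acetate"])
            recovered.append(model.offset)
        assert all(abs(off - 2.0) <= 1.0 for off in recovered)


class TestMeasureResponse:
    def test_noiseless_excitatory_amplitude_exact(self, library,
                                                  flat_bleach_gc, make_dff):
        trace, truth = ot.simulate_gc_imaging_trace(
            ot.SampleSpec(library["ethyl_acetate"], 1e-4), flat_bleach_gc)
        dff = make_dff(trace)
        amp = measure_response(dff, library["ethyl_acetate"])
        assert amp == pytest.approx(
            truth.response_amplitudes["ethyl_acetate"], rel=1e-9)

    def test_noiseless_inhibitory_dip_exact(self, library, flat_bleach_gc,
                                            make_dff):
        trace, _ = ot.simulate_gc_imaging_trace(
            ot.SampleSpec(library["benzaldehyde"], 1e-2), flat_bleach_gc)
        amp = measure_response(make_dff(trace), library["benzaldehyde"])
        assert amp == pytest.approx(-0.3, rel=1e-9)

    def test_monotone_in_injected_amplitude(self, library, flat_bleach_gc,
                                            make_dff):
        amps = []
        for dilution_exp in (-8, -6, -5, -4, -3):
            trace, _ = ot.simulate_gc_imaging_trace(
                ot.SampleSpec(library["ethyl_acetate"], 10.0 ** dilution_exp),
                flat_bleach_gc)
            amps.append(measure_response(make_dff(trace),
                                         library["ethyl_acetate"]))
        assert all(b > a for a, b in zip(amps, amps[1:]))

    def test_window_outside_span_refused(self, library, flat_bleach_gc,
                                         make_dff):
        trace, _ = ot.simulate_gc_imaging_trace(
            ot.SampleSpec(library["ethyl_acetate"], 1e-4), flat_bleach_gc)
        far = ot.SubstanceSpec("far", retention_time=5000.0, elution_width=3.0)
        with pytest.raises(ot.TraceValidationError):
            measure_response(make_dff(trace), far)

    def test_apex_mode_agrees_with_extremum_on_noiseless_trace(
            self, library, flat_bleach_gc, make_dff):
        trace, _ = ot.simulate_gc_imaging_trace(
            ot.SampleSpec(library["ethyl_acetate"], 1e-4), flat_bleach_gc)
        dff = make_dff(trace)
        a1 = measure_response(dff, library["ethyl_acetate"], mode="extremum")
        a2 = measure_response(dff, library["ethyl_acetate"], mode="apex")
        assert a1 == pytest.approx(a2, rel=1e-9)

    def test_contaminated_sample_sign_pattern(self, library):
        """Contaminated benzaldehyde-d5: positive response in the ethyl
        acetate window, negative in the benzaldehyde window — in every
        one of 50 seeded trials at default noise."""
        from odortrace.substances import benzaldehyde_d5_sample

        hits = 0
        for seed in range(50):
            trial = ot.simulate_trial(benzaldehyde_d5_sample(),
                                      ot.AcquisitionSpec.gc_coupled(),
                                      rng=np.random.default_rng(seed))
            dff = bleach_corrected_dff(trial.fluorescence,
                                       fit_bleach_auto(trial.fluorescence))
            ea = measure_response(dff, library["ethyl_acetate"])
            bz = measure_response(dff, library["benzaldehyde_d5"])
            hits += (ea > 0) and (bz < 0)
        assert hits == 50


class TestAssignPeaks:
    def test_nearest_peak_wins_and_rest_unassigned(self, library):
        from odortrace.peaks import Peak

        peaks = [Peak(99.0, 0.3, 3.0, 0.0, "dff"),
                 Peak(106.0, 0.8, 3.0, 0.0, "dff"),
                 Peak(300.0, 0.2, 3.0, 0.0, "dff")]
        result = assign_peaks(peaks, {"ethyl_acetate": library["ethyl_acetate"]},
                              AlignmentModel(0.0))
        assert result["ethyl_acetate"].apex_time == 99.0
        assert {p.apex_time for p in result["unassigned"]} == {106.0, 300.0}
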