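"""Synthetic GC-FID chromatograms and receptor fluorescence traces.

The generator emulates the statistical structure of GC-coupled antennal
calcium imaging with known ground truth:

* Gaussian elution peaks at substance-specific retention times on the FID
  channel (mass-proportional signal);
* receptor response transients — instantaneous rise, exponential decay
  whose time constant grows above a saturation threshold (responses "tail"
  at high concentration); inhibitory responses are negated transients;
* multiplicative dye bleaching ``A*exp(-t/B) + C`` on the fluorescence
  channel with additive Gaussian noise on the dF/F scale;
* per-animal multiplicative gain variability;
* the double-pulse direct-stimulation protocol (two 1-s pulses, 1.5-s gap,
  onsets at 6.75 and 9.25 s after the transit delay).

Every simulated trial carries a :class:`GroundTruth` record sufficient to
score every downstream estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Any, Mapping

import numpy as np

from .errors import TraceValidationError
from .substances import (
    DIRECT_KINETICS,
    GC_KINETICS,
    InertModel,
    Kinetics,
    ReceptorModel,
    SampleSpec,
    SubstanceSpec,
    stimulus_onsets,
)
from .trace import Trace, time_grid

logger = logging.getLogger(__name__)

# Default noise SD on the dF/F scale.  Chosen so that the ethyl butyrate
# reference peak (~0.35 dF/F with the default tuning) has a single-trial
# signal-to-noise ratio of about 20.
DEFAULT_NOISE_SD = 0.018


@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition parameters of one simulated trial.

    ``bleach`` holds the normalized multiplicative bleaching curve
    ``(A, B, C)``: the raw fluorescence baseline is
    ``baseline_f0 * (A*exp(-t/B) + C)``.  ``noise_sd`` is additive Gaussian
    noise on the dF/F scale, applied after bleach multiplication.
    ``channel_offset`` shifts imaging responses relative to FID elution
    (transit time from column split to antenna) in GC-coupled mode;
    ``transit_delay`` delays stimulus onsets in direct mode.
    """

    mode: str = "gc_coupled"  # "gc_coupled" | "direct_stim"
    duration: float = 540.0
    rate: float = 1.0
    bleach: tuple[float, float, float] = (0.25, 300.0, 0.75)
    baseline_f0: float = 1000.0
    noise_sd: float = DEFAULT_NOISE_SD
    fid_noise_sd: float = 1e-5
    animal_gain: float = 1.0
    channel_offset: float = 0.0
    transit_delay: float = 0.75
    seed: int | None = None

    def __post_init__(self):
        if self.mode not in ("gc_coupled", "direct_stim"):
            raise TraceValidationError(f"unknown acquisition mode {self.mode!r}")
        if self.duration <= 0 or self.rate <= 0:
            raise TraceValidationError("duration and rate must be > 0")
        if self.noise_sd < 0 or self.fid_noise_sd < 0:
            raise TraceValidationError("noise SD must be >= 0")
        if self.bleach[1] <= 0:
            raise TraceValidationError("bleach time constant B must be > 0")

    @classmethod
    def gc_coupled(cls, **overrides: Any) -> "AcquisitionSpec":
        """GC-coupled defaults: 1 Hz for 9 min."""
        return cls(**{"mode": "gc_coupled", "duration": 540.0, "rate": 1.0,
                      **overrides})

    @classmethod
    def direct_stim(cls, **overrides: Any) -> "AcquisitionSpec":
        """Direct-stimulation defaults: 4 Hz for 20 s, mild bleaching."""
        return cls(**{"mode": "direct_stim", "duration": 20.0, "rate": 4.0,
                      "bleach": (0.1, 60.0, 0.9), **overrides})

    def grid(self) -> np.ndarray:
        return time_grid(self.duration, self.rate)

    def rng(self, rng: np.random.Generator | None = None) -> np.random.Generator:
        if rng is not None:
            return rng
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """Per-trial ground truth emitted alongside every simulated trace."""

    elution_times: dict[str, float] = field(default_factory=dict)
    fid_apex_heights: dict[str, float] = field(default_factory=dict)
    response_amplitudes: dict[str, float] = field(default_factory=dict)
    response_onsets: dict[str, float] = field(default_factory=dict)
    bleach: tuple[float, float, float] | None = None  # raw units (A, B, C)
    contaminant_fractions: dict[str, float] = field(default_factory=dict)
    animal_gain: float = 1.0
    channel_offset: float = 0.0
    net_amplitude: float | None = None  # direct-stim: sum of signed amplitudes
    stimulus_onsets: tuple[float, ...] | None = None


def _resolve_model(sub: SubstanceSpec,
                   tuning: Mapping[str, ReceptorModel] | None) -> ReceptorModel:
    if tuning is None:
        return sub.receptor_model
    model = tuning.get(sub.name)
    if model is None:
        logger.warning("substance %s missing from tuning map; treated as inert",
                       sub.name)
        return InertModel()
    return model


def simulate_fid_trace(
    sample: SampleSpec,
    acq: AcquisitionSpec,
    rng: np.random.Generator | None = None,
) -> tuple[Trace, GroundTruth]:
    """Simulate the FID chromatogram of a headspace sample.

    The signal is a sum of unit-peak Gaussians at each substance's
    retention time, scaled by ``fid_response_factor * delivered amount``,
    plus additive Gaussian noise.
    """
    if acq.mode != "gc_coupled":
        raise TraceValidationError("FID traces require gc_coupled mode")
    rng = acq.rng(rng)
    t = acq.grid()
    signal = np.zeros_like(t)
    truth = GroundTruth(bleach=None,
                        contaminant_fractions={s.name: f for s, f in sample.contaminants})
    amounts = sample.delivered_amounts()
    for name, sub in sample.substances().items():
        amount = amounts[name]
        if amount < 0:
            raise TraceValidationError("negative delivered amount")
        apex = sub.fid_response_factor * amount
        if apex > 0:
            signal += apex * np.exp(-0.5 * ((t - sub.retention_time) / sub.elution_width) ** 2)
        truth.elution_times[name] = sub.retention_time
        truth.fid_apex_heights[name] = apex
    if acq.fid_noise_sd > 0:
        signal = signal + rng.normal(0.0, acq.fid_noise_sd, size=t.shape)
    trace = Trace(t, signal, acq.rate, channel="fid", meta={"mode": acq.mode})
    return trace, truth


def simulate_response_kernel(
    kinetics: Kinetics,
    amplitude: float,
    acq: AcquisitionSpec,
    onset: float,
) -> Trace:
    """A single response transient on the acquisition grid.

    Zero before ``onset``; from the first sample at or after onset the
    kernel jumps to ``amplitude`` (sign preserved) and decays with the
    kinetics' effective time constant, which grows with ``|amplitude|``
    above the saturation threshold.
    """
    t = acq.grid()
    if not (t[0] <= onset <= t[-1]):
        raise TraceValidationError(f"onset {onset} outside trace span")
    values = np.zeros_like(t)
    if amplitude != 0.0:
        i0 = int(np.searchsorted(t, onset - 1e-12))
        tau = kinetics.effective_tau(amplitude)
        values[i0:] = amplitude * np.exp(-(t[i0:] - t[i0]) / tau)
    return Trace(t, values, acq.rate, channel="dff", meta={"kind": "kernel"})


def _response_sum(
    sample: SampleSpec,
    tuning: Mapping[str, ReceptorModel] | None,
    acq: AcquisitionSpec,
    onsets_for: "callable",
    truth: GroundTruth,
    default_kinetics: Kinetics,
) -> np.ndarray:
    """Sum per-substance response kernels onto the acquisition grid."""
    t = acq.grid()
    resp = np.zeros_like(t)
    amounts = sample.delivered_amounts()
    for name, sub in sample.substances().items():
        model = _resolve_model(sub, tuning)
        amp = model.amplitude(amounts[name])
        kin = getattr(model, "kinetics", default_kinetics)
        truth.response_amplitudes[name] = amp
        for onset in onsets_for(sub):
            if amp != 0.0 and t[0] <= onset <= t[-1]:
                resp += simulate_response_kernel(kin, amp, acq, onset).values
            truth.response_onsets[name] = onset
    return resp


def _assemble_fluorescence(
    resp: np.ndarray,
    acq: AcquisitionSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Raw fluorescence = F0 * bleach(t) * (1 + gain*resp + noise)."""
    t = acq.grid()
    a, b, c = acq.bleach
    bleach = a * np.exp(-t / b) + c
    noise = rng.normal(0.0, acq.noise_sd, size=t.shape) if acq.noise_sd > 0 else 0.0
    raw = acq.baseline_f0 * bleach * (1.0 + acq.animal_gain * resp + noise)
    bleach_raw = (acq.baseline_f0 * a, b, acq.baseline_f0 * c)
    return raw, bleach_raw


def simulate_gc_imaging_trace(
    sample: SampleSpec,
    acq: AcquisitionSpec,
    tuning: Mapping[str, ReceptorModel] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Trace, GroundTruth]:
    """Simulate the receptor fluorescence trace of a GC-coupled trial.

    GC separation means each substance's response kernel sits at its own
    retention time (plus the imaging channel offset).  Kernel amplitudes
    come from each substance's tuning evaluated at the log10 delivered
    amount; the summed response is multiplied onto the bleaching baseline.
    """
    if acq.mode != "gc_coupled":
        raise TraceValidationError("gc imaging traces require gc_coupled mode")
    rng = acq.rng(rng)
    truth = GroundTruth(
        contaminant_fractions={s.name: f for s, f in sample.contaminants},
        animal_gain=acq.animal_gain,
        channel_offset=acq.channel_offset,
    )
    for name, sub in sample.substances().items():
        truth.elution_times[name] = sub.retention_time
    resp = _response_sum(
        sample, tuning, acq,
        onsets_for=lambda sub: (sub.retention_time + acq.channel_offset,),
        truth=truth, default_kinetics=GC_KINETICS,
    )
    raw, bleach_raw = _assemble_fluorescence(resp, acq, rng)
    truth.bleach = bleach_raw
    trace = Trace(acq.grid(), raw, acq.rate, channel="fluorescence",
                  meta={"mode": acq.mode})
    return trace, truth


def simulate_direct_stim_trace(
    sample: SampleSpec,
    acq: AcquisitionSpec,
    tuning: Mapping[str, ReceptorModel] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Trace, GroundTruth]:
    """Simulate a direct-stimulation (GC-bypass) trial.

    All substances co-arrive at both pulse onsets; the net response
    amplitude is the signed sum of each substance's tuned amplitude
    (excitatory positive, inhibitory negative).
    """
    if acq.mode != "direct_stim":
        raise TraceValidationError("direct-stim traces require direct_stim mode")
    rng = acq.rng(rng)
    onsets = stimulus_onsets(transit_delay=acq.transit_delay)
    truth = GroundTruth(
        contaminant_fractions={s.name: f for s, f in sample.contaminants},
        animal_gain=acq.animal_gain,
        stimulus_onsets=onsets,
    )
    resp = _response_sum(
        sample, tuning, acq,
        onsets_for=lambda sub: onsets,
        truth=truth, default_kinetics=DIRECT_KINETICS,
    )
    truth.net_amplitude = float(sum(truth.response_amplitudes.values()))
    raw, bleach_raw = _assemble_fluorescence(resp, acq, rng)
    truth.bleach = bleach_raw
    trace = Trace(acq.grid(), raw, acq.rate, channel="fluorescence",
                  meta={"mode": acq.mode})
    return trace, truth


def simulate_movie(
    trace: Trace,
    roi: np.ndarray,
    frame_shape: tuple[int, int],
    noise_sd: float = 0.0,
    background: np.ndarray | float | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Expand a trace into a small grayscale image stack.

    Pixels inside the ROI follow the trace (plus independent per-pixel
    noise); pixels outside follow ``background`` (a scalar, or a per-frame
    baseline/bleach trace).  The mean over the ROI recovers the input
    trace (exactly when ``noise_sd == 0``).
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != tuple(frame_shape):
        raise TraceValidationError("roi must match frame_shape")
    if not roi.any():
        raise TraceValidationError("ROI is empty")
    rng = rng or np.random.default_rng()
    n = trace.values.size
    if background is None:
        bg = np.zeros(n)
    elif np.isscalar(background):
        bg = np.full(n, float(background))
    else:
        bg = np.asarray(background, dtype=float)
        if bg.shape != (n,):
            raise TraceValidationError("background must match trace length")
    stack = np.empty((n, *frame_shape), dtype=float)
    stack[:] = bg[:, None, None]
    n_px = int(roi.sum())
    inside = trace.values[:, None] + (
        rng.normal(0.0, noise_sd, size=(n, n_px)) if noise_sd > 0 else 0.0
    )
    stack[:, roi] = inside
    return stack


# ---------------------------------------------------------------------------
# Trials and whole experiments
# ---------------------------------------------------------------------------

@dataclass
class Trial:
    """One simulated recording: fluorescence (+ FID in GC mode) + truth."""

    fluorescence: Trace
    sample: SampleSpec
    acquisition: AcquisitionSpec
    truth: GroundTruth
    fid: Trace | None = None
    meta: dict[str, Any] = field(default_factory=dict)


def simulate_trial(
    sample: SampleSpec,
    acq: AcquisitionSpec,
    tuning: Mapping[str, ReceptorModel] | None = None,
    rng: np.random.Generator | None = None,
    **meta: Any,
) -> Trial:
    """Simulate one trial (imaging + FID in GC-coupled mode)."""
    rng = acq.rng(rng)
    if acq.mode == "gc_coupled":
        fid, fid_truth = simulate_fid_trace(sample, acq, rng)
        fluo, truth = simulate_gc_imaging_trace(sample, acq, tuning, rng)
        truth.fid_apex_heights = fid_truth.fid_apex_heights
    else:
        fid = None
        fluo, truth = simulate_direct_stim_trace(sample, acq, tuning, rng)
    return Trial(fluorescence=fluo, fid=fid, sample=sample, acquisition=acq,
                 truth=truth, meta=dict(meta))


@dataclass
class Experiment:
    """A full impurity-quantification data set with ground truth."""

    calibration: list[Trial]   # pure contaminant dilution series (+ reference trials)
    samples: list[Trial]       # contaminated main-substance trials
    true_fraction_log10: float
    n_animals: int


def simulate_impurity_experiment(
    true_fraction_log10: float = -5.2,
    sample_dilutions_log10: tuple[float, ...] = (-2.0, -1.0),
    calibration_dilutions_log10: tuple[float, ...] = tuple(range(-10, -1)),
    n_animals: int = 3,
    seed: int | None = None,
    library: Mapping[str, SubstanceSpec] | None = None,
    main: str = "benzaldehyde_d5",
    contaminant: str = "ethyl_acetate",
    reference: str = "ethyl_butyrate",
    gain_spread: float = 0.2,
    acq_overrides: Mapping[str, Any] | None = None,
) -> Experiment:
    """Simulate the full study design of a trace-impurity quantification.

    Per animal: a contaminant dilution series (calibration), one reference
    trial (ethyl butyrate, whose first response peak is the across-animal
    normalization standard), and the contaminated sample at each sample
    dilution.  Per-animal gains are lognormal with ``gain_spread`` sigma
    on the log scale.  A global seed drives a per-trial seed sequence so
    trials are individually reproducible.
    """
    from .substances import default_library, ethyl_butyrate_sample

    lib = dict(library or default_library())
    overrides = dict(acq_overrides or {})
    ss = np.random.SeedSequence(seed)
    master = np.random.default_rng(ss.spawn(1)[0])
    gains = np.exp(master.normal(0.0, gain_spread, size=n_animals))
    frac = 10.0 ** true_fraction_log10

    calibration: list[Trial] = []
    samples: list[Trial] = []
    for animal in range(n_animals):
        gain = float(gains[animal])

        def make_acq():
            return AcquisitionSpec.gc_coupled(animal_gain=gain, **overrides)

        for c in calibration_dilutions_log10:
            trial = simulate_trial(
                SampleSpec(lib[contaminant], 10.0 ** c),
                make_acq(),
                rng=np.random.default_rng(ss.spawn(1)[0]),
                animal=animal, role="calibration", dilution_log10=float(c),
            )
            calibration.append(trial)

        ref_trial = simulate_trial(
            ethyl_butyrate_sample(library=lib),
            make_acq(),
            rng=np.random.default_rng(ss.spawn(1)[0]),
            animal=animal, role="reference", dilution_log10=-2.0,
        )
        calibration.append(ref_trial)

        for d in sample_dilutions_log10:
            sample = SampleSpec(
                lib[main], 10.0 ** d,
                contaminants=((lib[contaminant], frac),),
            )
            trial = simulate_trial(
                sample, make_acq(),
                rng=np.random.default_rng(ss.spawn(1)[0]),
                animal=animal, role="sample", dilution_log10=float(d),
            )
            samples.append(trial)

    return Experiment(calibration=calibration, samples=samples,
                      true_fraction_log10=true_fraction_log10,
                      n_animals=n_animals)
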