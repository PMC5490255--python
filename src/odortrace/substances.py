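"""Substance, sample and receptor-tuning definitions.

A :class:`SubstanceSpec` couples a GC elution profile (retention time,
Gaussian elution width, FID response factor) with a receptor model that
maps delivered headspace amount to a calcium-response amplitude.  Receptor
models come in three flavours:

* :class:`ExcitatoryModel` — a logistic dose-response on a log10 amount
  axis, ``R(c) = Rmax / (1 + exp(-h (c - ec50)))``, plus response kinetics.
* :class:`InhibitoryModel` — a fixed negative amplitude (a calcium dip)
  whenever the substance is delivered at a nonzero amount.
* :class:`InertModel` — no receptor response at all.

A :class:`SampleSpec` is a diluted main substance plus trace contaminants.
Contaminants co-dilute with the sample: the delivered amount of a
contaminant is ``relative_fraction * dilution``, so the ratio of
contaminant to main amount is fixed at every dilution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

from .errors import TraceValidationError

# Direct-stimulation double-pulse protocol: two 1-s headspace injections
# into the carrier flow, with a transit delay before the stimulus reaches
# the antenna.  Stimulus onsets are injection time + transit delay.
INJECTION_TIMES_S: tuple[float, float] = (6.0, 8.5)
TRANSIT_DELAY_S: float = 0.75
PULSE_DURATION_S: float = 1.0


def stimulus_onsets(
    injection_times: tuple[float, ...] = INJECTION_TIMES_S,
    transit_delay: float = TRANSIT_DELAY_S,
) -> tuple[float, ...]:
    """Stimulus-onset times at the antenna for a direct-stimulation trial.

    With the default protocol (injections at 6 and 8.5 s, 750 ms transit
    delay) the onsets are 6.75 and 9.25 s.
    """
    if transit_delay < 0:
        raise TraceValidationError("transit_delay must be >= 0")
    return tuple(t + transit_delay for t in injection_times)


@dataclass(frozen=True)
class Kinetics:
    """Response-transient kinetics of a receptor channel.

    The response kernel rises instantaneously at stimulus/elution onset and
    decays exponentially.  Above a saturation threshold the decay slows
    (responses "tail" at high concentration): the effective time constant is

        tau_eff = tau * (1 + tau_gain * max(0, |amplitude| - saturation))

    Parameters
    ----------
    tau : float
        Baseline decay time constant, seconds.
    saturation : float
        dF/F amplitude above which the decay slows.
    tau_gain : float
        Fractional increase of tau per dF/F unit above saturation.
    """

    tau: float = 8.0
    saturation: float = 0.5
    tau_gain: float = 4.0

    def effective_tau(self, amplitude: float) -> float:
        excess = max(0.0, abs(amplitude) - self.saturation)
        return self.tau * (1.0 + self.tau_gain * excess)


#: Default kinetics for slow GC-coupled recordings (1 Hz) and for fast
#: direct-stimulation recordings (4 Hz).
GC_KINETICS = Kinetics(tau=8.0, saturation=0.5, tau_gain=4.0)
DIRECT_KINETICS = Kinetics(tau=1.5, saturation=0.5, tau_gain=4.0)


@dataclass(frozen=True)
class ExcitatoryModel:
    """Logistic (sigmoidal) excitatory tuning on a log10 amount axis."""

    rmax: float
    ec50: float
    h: float
    kinetics: Kinetics = GC_KINETICS

    def __post_init__(self):
        if self.rmax <= 0:
            raise TraceValidationError("excitatory rmax must be > 0")
        if self.h <= 0:
            raise TraceValidationError("excitatory steepness h must be > 0")

    def amplitude(self, amount: float) -> float:
        """Response amplitude (dF/F) for a delivered headspace ``amount``."""
        if amount <= 0:
            return 0.0
        c = math.log10(amount)
        return self.rmax / (1.0 + math.exp(-self.h * (c - self.ec50)))


@dataclass(frozen=True)
class InhibitoryModel:
    """Fixed-amplitude inhibitory tuning (a calcium decrease)."""

    amplitude_value: float
    kinetics: Kinetics = GC_KINETICS

    def __post_init__(self):
        if self.amplitude_value >= 0:
            raise TraceValidationError("inhibitory amplitude must be < 0")

    def amplitude(self, amount: float) -> float:
        return self.amplitude_value if amount > 0 else 0.0


@dataclass(frozen=True)
class InertModel:
    """No receptor response."""

    def amplitude(self, amount: float) -> float:  # noqa: ARG002
        return 0.0


ReceptorModel = Union[ExcitatoryModel, InhibitoryModel, InertModel]


@dataclass(frozen=True)
class SubstanceSpec:
    """A chemical substance as seen by the GC column, FID and receptor.

    Parameters
    ----------
    name : str
        Text label (``"ethyl_acetate"``).
    retention_time : float
        GC elution apex, seconds; must be > 0.
    elution_width : float
        Gaussian sigma of the elution peak, seconds; must be > 0.
    fid_response_factor : float
        FID signal units per unit of delivered headspace amount; >= 0.
    receptor_model : ReceptorModel
        Tuning of the imaged receptor channel to this substance.
    """

    name: str
    retention_time: float
    elution_width: float
    fid_response_factor: float = 1.0
    receptor_model: ReceptorModel = field(default_factory=InertModel)

    def __post_init__(self):
        if self.retention_time <= 0:
            raise TraceValidationError(f"{self.name}: retention_time must be > 0")
        if self.elution_width <= 0:
            raise TraceValidationError(f"{self.name}: elution_width must be > 0")
        if self.fid_response_factor < 0:
            raise TraceValidationError(f"{self.name}: fid_response_factor must be >= 0")


@dataclass(frozen=True)
class SampleSpec:
    """A diluted odorant sample with optional trace contaminants.

    ``contaminants`` is a tuple of ``(SubstanceSpec, relative_fraction)``
    pairs with relative fractions in ``[0, 1)``.  The delivered headspace
    amount of the main substance is ``dilution`` and that of a contaminant
    is ``relative_fraction * dilution`` (co-dilution).
    """

    main_substance: SubstanceSpec
    dilution: float
    contaminants: tuple[tuple[SubstanceSpec, float], ...] = ()

    def __post_init__(self):
        if not (0.0 < self.dilution <= 1.0):
            raise TraceValidationError("dilution must be in (0, 1]")
        for sub, frac in self.contaminants:
            if not (0.0 <= frac < 1.0):
                raise TraceValidationError(
                    f"contaminant fraction for {sub.name} must be in [0, 1)"
                )

    def delivered_amounts(self) -> dict[str, float]:
        """Map substance name -> delivered headspace amount."""
        amounts = {self.main_substance.name: self.dilution}
        for sub, frac in self.contaminants:
            amounts[sub.name] = frac * self.dilution
        return amounts

    def substances(self) -> dict[str, SubstanceSpec]:
        subs = {self.main_substance.name: self.main_substance}
        for sub, _ in self.contaminants:
            subs[sub.name] = sub
        return subs


def empty_sample(dilution: float = 1.0) -> SampleSpec:
    """A blank (mineral-oil-only) sample: an inert main substance."""
    blank = SubstanceSpec("mineral_oil", retention_time=1.0, elution_width=1.0,
                          fid_response_factor=0.0, receptor_model=InertModel())
    return SampleSpec(main_substance=blank, dilution=dilution)


# ---------------------------------------------------------------------------
# Default substance library
# ---------------------------------------------------------------------------
#
# Retention times for ethyl acetate (~100 s) and benzaldehyde (~240 s) are
# the landmarks of the 30-m apolar column protocol; the remaining retention
# times are nominal values chosen to keep peaks well separated.  The ethyl
# acetate tuning is an Or42b-like channel: EC50 at a 1e-5 dilution on the
# log10 axis.  Benzaldehyde (and its ring-deuterated isotopomer) inhibit
# the same channel.

def default_library() -> dict[str, SubstanceSpec]:
    """Substance library with Or42b-like tuning defaults."""
    ea_tuning = ExcitatoryModel(rmax=1.0, ec50=-5.0, h=1.0, kinetics=GC_KINETICS)
    lib = {}

    def add(spec: SubstanceSpec):
        lib[spec.name] = spec

    add(SubstanceSpec("ethyl_acetate", 100.0, 3.0, 1.0, ea_tuning))
    add(SubstanceSpec("ethyl_propionate", 130.0, 3.0, 1.0,
                      ExcitatoryModel(rmax=0.8, ec50=-4.0, h=1.0)))
    add(SubstanceSpec("propyl_acetate", 150.0, 3.0, 1.0,
                      ExcitatoryModel(rmax=0.8, ec50=-4.0, h=1.0)))
    add(SubstanceSpec("ethyl_butyrate", 170.0, 3.5, 1.0,
                      ExcitatoryModel(rmax=1.0, ec50=-4.5, h=1.0)))
    add(SubstanceSpec("unknown_impurity", 200.0, 3.0, 1.0,
                      ExcitatoryModel(rmax=0.6, ec50=-4.5, h=1.0)))
    add(SubstanceSpec("benzaldehyde", 240.0, 4.0, 1.0,
                      InhibitoryModel(amplitude_value=-0.3)))
    add(SubstanceSpec("benzaldehyde_d5", 240.0, 4.0, 1.0,
                      InhibitoryModel(amplitude_value=-0.3)))
    add(SubstanceSpec("methyl_acetate", 85.0, 2.5, 1.0, InertModel()))
    add(SubstanceSpec("hexanone_3", 190.0, 3.5, 1.0, InertModel()))
    return lib


#: Relative ethyl acetate contamination of the benzaldehyde-d5 sample used
#: as the generator's ground-truth default (a 10^-5.2 trace impurity).
DEFAULT_BZA_D5_EA_FRACTION = 10.0 ** -5.2

#: Ethyl acetate fraction in the ethyl butyrate reference sample, such that
#: a 1e-2 dilution delivers ethyl acetate at 10^-5.6 (the calibration
#: reference peak).
ETHYL_BUTYRATE_EA_FRACTION = 10.0 ** -3.6


def benzaldehyde_d5_sample(
    dilution: float = 1e-2,
    ea_fraction: float = DEFAULT_BZA_D5_EA_FRACTION,
    library: dict[str, SubstanceSpec] | None = None,
) -> SampleSpec:
    """The contaminated benzaldehyde-d5 sample (default ground truth)."""
    lib = library or default_library()
    return SampleSpec(
        main_substance=lib["benzaldehyde_d5"],
        dilution=dilution,
        contaminants=((lib["ethyl_acetate"], ea_fraction),),
    )


def ethyl_butyrate_sample(
    dilution: float = 1e-2,
    library: dict[str, SubstanceSpec] | None = None,
) -> SampleSpec:
    """The ethyl butyrate reference sample.

    Carries three trace impurities so that a GC-coupled recording shows
    four response peaks; the first (earliest) peak is the ethyl acetate
    contamination and serves as the across-animal calibration reference.
    """
    lib = library or default_library()
    return SampleSpec(
        main_substance=lib["ethyl_butyrate"],
        dilution=dilution,
        contaminants=(
            (lib["ethyl_acetate"], ETHYL_BUTYRATE_EA_FRACTION),
            (lib["ethyl_propionate"], 10.0 ** -2.5),
            (lib["unknown_impurity"], 10.0 ** -3.0),
        ),
    )


def pure_sample(
    name: str,
    dilution: float,
    library: dict[str, SubstanceSpec] | None = None,
) -> SampleSpec:
    """A contaminant-free sample of a library substance."""
    lib = library or default_library()
    return SampleSpec(main_substance=lib[name], dilution=dilution)
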