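# Methods

## The measurement problem

A gas chromatograph separates the headspace of an odorant dilution in
time; half the eluate goes to a flame ionization detector (FID), half to
the antenna of a fly expressing a calcium indicator in one receptor
channel. A substance produces an FID peak at its retention time and — if
the imaged receptor is tuned to it — a calcium transient at (nearly) the
same time on the imaging channel. A trace contaminant that is a strong
ligand produces a clear calcium response at its own elution time even
when its FID peak is invisible, and its concentration can be read off a
dose–response curve recorded with the purified contaminant itself. The
package's pipeline (`quantify_impurity`) chains these steps; each stage
is available separately.

## Trace model and processing

Raw fluorescence is modeled as multiplicative bleaching times response:

    F(t) = F0 · (A·e^(−t/B) + C) · (1 + g·r(t) + ε(t))

with `r(t)` the summed response transients in ΔF/F units, `g` a
per-animal gain, and `ε` white Gaussian noise on the ΔF/F scale.

**Bleach correction.** The decay `A·e^(−x/B) + C` is fitted by
least squares to the samples outside response windows and the decaying
component subtracted (the offset `C` is kept, so the corrected baseline
is flat at `C`). ΔF/F is then `(corrected − C)/C`. Correction before
ΔF/F keeps amplitudes comparable across trials; this ordering is a
design choice of the package. Initialization is `A₀ = first − last`,
`C₀ = last`, `B₀ = half span`, with restarts at `0.1·B₀` and `10·B₀`;
`A` and `C` are constrained nonnegative (fluorescence decays toward a
nonnegative plateau). If the fitted decaying component vanishes, `B` is
reported as unidentifiable (NaN) and correction reduces to subtracting
a constant.

**Response masks.** When ground-truth onsets are absent, masks are built
iteratively: fit on unmasked samples, flag |residual| > 3× robust SD
(MAD-based), dilate flagged runs 5 s leftward and 25 s rightward
(transients decay rightward, so sub-threshold tails extend well past the
flagged run), refit; up to four rounds or until stable. A single
flag–refit round proved insufficient for trials with large saturated
responses, whose tails otherwise drag the exponential into degenerate
solutions.

**Identifiability of B.** At the default noise (ΔF/F SD 0.018) and the
default bleach curve (A = 0.25, B = 300 s, C = 0.75 of F0, 540 samples
at 1 Hz), the Cramér–Rao bound for the time constant is ≈ 7 % relative.
Tests therefore check the median recovery error over seeds against 10 %,
not a tighter per-trial figure, which the data cannot support.

**Normalization.** Responses are calibrated across animals by dividing
each animal's ΔF/F by that animal's reference response amplitude (the
first response peak of the ethyl butyrate standard, which is its ethyl
acetate impurity eluting at ~100 s). Because calibration and sample
responses are normalized by the same per-animal constant, multiplicative
nuisance factors — animal gain, the local value of the bleach curve at
the elution time — cancel exactly in the inverse read-off.

## Peak detection, alignment, amplitude measurement

Peaks are local extrema with prominence ≥ 3× the robust noise SD of the
trace (noise estimated from first differences, insensitive to slow
structure). Candidates are searched on a 5-sample boxcar-smoothed copy —
smoothing shortens noise excursions so the threshold rejects them, while
real peaks (wider than the window) survive — and apexes are refined on
the raw trace, so noiseless apex positions are exact. Amplitude is apex
minus local baseline (median of flanking bands placed one full width
beyond the half-height edges); width is full width at half extremum.

Channel alignment uses the reference substance's peak on both channels:
`offset = dF/F apex − FID apex`, nearest-to-retention-time within a 30-s
search window, ties broken by amplitude, and a hard error if the
reference peak is missing on either channel.

Response amplitudes in a substance's window (aligned retention time
± 10 s; GC peaks here are well separated) are signed extrema of
value − baseline, which captures excitatory increases and inhibitory
dips alike. Two estimators are provided:

* `extremum` — the signed extremum over the whole window (the generic
  contract). For near-zero responses this reads the maximum of the
  noise, a positive bias that flattens dose–response curves built from
  it at the low-concentration end.
* `apex` — the amplitude at the aligned elution apex itself against a
  pre-elution flanking baseline. For pure noise this is symmetric about
  zero, so calibration curves remain unbiased; the quantification
  pipeline uses it. The baseline uses the leading flank only because
  response kernels decay rightward, putting the trailing flank on the
  tail.

## Dose–response model

    R(c) = Rmax / (1 + e^(−h·(c − EC50)))

on a log₁₀-dilution axis: `Rmax` the saturation asymptote in normalized
response units, `EC50` the half-effective log₁₀ dilution, `h` the
steepness per log₁₀ unit (Hill-like). The lower asymptote is zero —
inhibitory responses are handled upstream by sign, not by a fourth
parameter. The fit is unweighted least squares on the per-dilution
across-animal means (per-point SEM is carried for reporting only);
bounds are `Rmax ∈ (0, 10·max]`, `h ∈ (0, 50]`, with `h₀ = 1` and
restarts at other steepness starts. The inverse,
`c = EC50 − ln(Rmax/R − 1)/h`, is exact; out-of-range responses raise
errors distinguishing "below detection" from "saturated". Note that on
noisy 3-animal data `EC50` alone is only loosely pinned — it trades off
against `Rmax` and `h` — while the fitted curve, and hence the inverse
read-off in the data range, is stable.

## Impurity quantification

Contaminants co-dilute with their sample, so the delivered contaminant
amount is `fraction × dilution` and `log₁₀ fraction = apparent_c −
sample_dilution`. Per-dilution fractions are aggregated as the
arithmetic mean of the *linear* fractions (the mean of 10⁻⁵·⁴ and
10⁻⁵·¹ is 10⁻⁵·²², displayed as 10⁻⁵·²); averaging in log space would
give −5.25 and need a tie-breaking rounding rule. Display rounding is
log₁₀ to one decimal, ppm and percent to one significant figure;
full-precision values are always retained in the report. Responses below
2× the robust noise SD of the averaged trace are flagged "not detected"
and excluded (a clean sample yields a "not detected" verdict, never a
number); responses ≥ 0.95·Rmax are flagged saturated and excluded
rather than clipped. The spread of per-dilution log₁₀ fractions is an
explicit report field — the dilution-consistency check.

## Synthetic data

The generator emulates the study design with known ground truth:

* **FID**: sum of unit-peak Gaussians at substance retention times
  (ethyl acetate ~100 s, benzaldehyde ~240 s are the landmarks; other
  retention times are nominal, chosen well separated), apex =
  FID factor × delivered amount, plus white noise (SD 10⁻⁵ signal
  units — the main peak of a 10⁻² dilution has SNR 1000 and a ppm-level
  contaminant is far below the noise, as in a real FID).
* **Responses**: instantaneous rise to the tuned amplitude at the
  (offset) elution time, exponential decay with τ = 8 s (GC mode) or
  1.5 s (direct mode), slowed above 0.5 ΔF/F by a factor
  `1 + 4·(|a| − 0.5)` — the saturation "tail". Excitatory tuning is the
  logistic above (the Or42b-like ethyl acetate channel: Rmax = 1 ΔF/F,
  EC50 = −5, h = 1); inhibition is a fixed negative amplitude (−0.3 for
  benzaldehyde). Mixtures are additive in signed amplitude — sufficient
  for the inhibitory-to-excitatory crossover when a contaminant is mixed
  into an inhibitory main odor — with no syntopic-competition model.
* **Acquisition**: GC-coupled 1 Hz × 540 s; direct stimulation
  4 Hz × 20 s with two 1-s pulses injected at 6 and 8.5 s and a 750-ms
  transit delay (onsets 6.75 and 9.25 s). Bleaching defaults
  (A, B, C) = (0.25, 300 s, 0.75), noise SD 0.018 ΔF/F — set so the
  ethyl butyrate reference peak (~0.35 ΔF/F) has single-trial SNR ≈ 20 —
  and lognormal per-animal gain with σ = 0.2 on the log scale (the
  imaging noise level and gain spread are declared defaults, not
  literature values).
* **Default experiment**: per animal, a pure ethyl acetate dilution
  series 10⁻¹⁰…10⁻² (calibration), one ethyl butyrate reference trial,
  and the contaminated benzaldehyde-d5 sample (true fraction 10⁻⁵·²) at
  dilutions 10⁻² and 10⁻¹; three animals; one global seed drives a
  per-trial seed sequence.

What the generator does **not** emulate: optics and point-spread,
motion artifacts, non-exponential bleaching, GC column thermodynamics
(peak asymmetry, retention drift), spike-to-calcium dynamics, or
receptor mixture interactions beyond additive amplitudes. Passing tests
therefore demonstrate correctness of the *estimators* under the stated
statistical model, not robustness to those real-data effects.

## Problem sizes

The Monte-Carlo checks use 200 replicates for the logistic-calibration
noise study and 100 (tests) / 50 (acceptance script) full simulated
experiments for end-to-end recovery, each experiment comprising
36 GC-coupled trials of 540 samples — sizes at which the Monte-Carlo
error of the reported medians is well below the tolerances being
checked.

## Known limitations

* The inhibitory model is dose-independent; real inhibitory responses
  scale with concentration.
* Inverse calibration is only informative between the detection
  threshold and ~0.95·Rmax; fractions whose responses fall outside that
  band at every tested sample dilution yield "not detected" (or
  all-saturated errors) rather than estimates.
* Alignment assumes one global time offset between channels; no
  retention-index recalibration across runs.
* The `extremum` amplitude estimator is biased upward for responses near
  the noise floor; use `apex` (the default in quantification) when
  building calibration curves.
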