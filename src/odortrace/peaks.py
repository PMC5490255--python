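"""Peak detection, FID/imaging channel alignment, and response measurement.

The GC separates substances in time, so a substance's receptor response
appears in the imaging channel at (about) its FID elution time plus a
fixed transit offset.  Alignment is calibrated from the response peak of
a reference substance (ethyl acetate); signed response amplitudes are
then measured in elution windows on the aligned dF/F trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, peak_widths

from .errors import AlignmentError, TraceValidationError
from .substances import SubstanceSpec
from .trace import Trace, robust_noise_sd

#: Default attribution window half-width, seconds.  GC peaks are well
#: separated (landmarks at ~100 and ~240 s), so a 10-s half-width isolates
#: one substance per window.
DEFAULT_WINDOW_HALFWIDTH = 10.0

#: Flanking-band width used for local baselines, seconds.
BASELINE_BAND_S = 5.0


@dataclass(frozen=True)
class Peak:
    """A detected apex on the FID or dF/F channel.

    ``amplitude`` is apex minus local baseline and is signed (negative for
    calcium dips on the dF/F channel).  ``width`` is the full width at
    half extremum in seconds.
    """

    apex_time: float
    amplitude: float
    width: float
    baseline: float
    channel: str
    index: int = -1


@dataclass(frozen=True)
class AlignmentModel:
    """Channel alignment: ``imaging_time = fid_time + offset``."""

    offset: float


def default_prominence(trace: Trace, mult: float = 3.0) -> float:
    """Default detection prominence: ``mult`` x robust noise SD."""
    sd = robust_noise_sd(trace.values)
    return mult * sd if sd > 0 else np.finfo(float).tiny


def _local_baseline(values: np.ndarray, times: np.ndarray,
                    left_edge: float, right_edge: float,
                    band_s: float = BASELINE_BAND_S) -> float:
    """Median of flanking non-peak samples around [left_edge, right_edge]."""
    in_band = (
        ((times >= left_edge - band_s) & (times < left_edge))
        | ((times > right_edge) & (times <= right_edge + band_s))
    )
    if not in_band.any():
        # peak spans the whole trace; fall back to global median
        return float(np.median(values))
    return float(np.median(values[in_band]))


def _detect_one_sign(trace: Trace, prominence: float, sign: int,
                     smooth_samples: int) -> list[Peak]:
    from scipy.ndimage import uniform_filter1d

    v = sign * trace.values
    if smooth_samples > 1:
        # Candidate search on a lightly smoothed copy: smoothing shortens
        # noise excursions so the prominence threshold (set from the raw
        # trace's noise) rejects them, while response peaks — wider than
        # the smoothing window — survive.  The apex is then refined on the
        # raw trace so noiseless apex positions are exact.
        vs = uniform_filter1d(v, smooth_samples)
        cand, _ = find_peaks(vs, prominence=prominence)
        half = smooth_samples // 2 + 1
        idx = []
        for i in cand:
            lo = max(0, i - half)
            hi = min(v.size, i + half + 1)
            j = lo + int(np.argmax(v[lo:hi]))
            # hill-climb to the nearest raw local maximum
            while 0 < j and v[j - 1] > v[j]:
                j -= 1
            while j < v.size - 1 and v[j + 1] > v[j]:
                j += 1
            idx.append(j)
        idx = np.unique(idx)
    else:
        idx, _ = find_peaks(v, prominence=prominence)
    if idx.size == 0:
        return []
    widths, _, left_ips, right_ips = peak_widths(v, idx, rel_height=0.5)
    dt = trace.dt
    t0 = trace.times[0]
    out = []
    for k, i in enumerate(idx):
        left = t0 + left_ips[k] * dt
        right = t0 + right_ips[k] * dt
        # flanking bands start one full width beyond the half-height
        # edges, clear of the peak's own shoulders
        w = max(right - left, dt)
        base = _local_baseline(trace.values, trace.times, left - w, right + w)
        out.append(Peak(
            apex_time=float(trace.times[i]),
            amplitude=float(trace.values[i] - base),
            width=float(max(widths[k] * dt, dt)),
            baseline=base,
            channel=trace.channel,
            index=int(i),
        ))
    return out


def detect_peaks(
    trace: Trace,
    min_prominence: float | None = None,
    polarity: str = "both",
    smooth_samples: int = 5,
) -> list[Peak]:
    """Detect local extrema with at least ``min_prominence`` prominence.

    ``polarity`` selects ``"positive"`` apexes, ``"negative"`` dips, or
    ``"both"``.  The default prominence is 3x the robust noise SD of the
    (unsmoothed) trace; candidates are searched on a ``smooth_samples``
    boxcar-smoothed copy and apexes refined on the raw trace (pass
    ``smooth_samples=1`` to disable).  Each peak carries its apex time,
    signed amplitude (apex - local baseline), full width at half
    extremum, and the local baseline (median of flanking non-peak
    samples).  Peaks are sorted by apex time; an empty list is a valid
    result.  Detection is invariant to adding a constant to the trace.
    """
    if min_prominence is None:
        min_prominence = default_prominence(trace)
    if min_prominence <= 0:
        raise TraceValidationError("min_prominence must be > 0")
    if polarity not in ("positive", "negative", "both"):
        raise TraceValidationError(f"unknown polarity {polarity!r}")
    peaks: list[Peak] = []
    if polarity in ("positive", "both"):
        peaks += _detect_one_sign(trace, min_prominence, +1, smooth_samples)
    if polarity in ("negative", "both"):
        peaks += _detect_one_sign(trace, min_prominence, -1, smooth_samples)
    peaks.sort(key=lambda p: p.apex_time)
    return peaks


def _nearest_peak(peaks: list[Peak], target: float, window: float) -> Peak:
    cands = [p for p in peaks if abs(p.apex_time - target) <= window]
    if not cands:
        raise AlignmentError(
            f"no peak within {window} s of t={target} s")
    best_dist = min(abs(p.apex_time - target) for p in cands)
    nearest = [p for p in cands if abs(p.apex_time - target) == best_dist]
    # ties broken by largest |amplitude|
    return max(nearest, key=lambda p: abs(p.amplitude))


def calibrate_alignment(
    fid_peaks: list[Peak],
    dff_peaks: list[Peak],
    reference: SubstanceSpec,
    search_window: float = 30.0,
) -> AlignmentModel:
    """Channel offset from the reference substance's peak on both channels.

    The peak nearest the reference retention time (within the search
    window) is taken on each channel; ``offset = dff apex - fid apex``.

    Raises
    ------
    AlignmentError
        If the reference peak is absent on either channel — there is no
        silent default.
    """
    try:
        fid_peak = _nearest_peak(fid_peaks, reference.retention_time, search_window)
    except AlignmentError as exc:
        raise AlignmentError(f"FID channel: {exc}") from exc
    try:
        dff_peak = _nearest_peak(dff_peaks, reference.retention_time, search_window)
    except AlignmentError as exc:
        raise AlignmentError(f"dF/F channel: {exc}") from exc
    return AlignmentModel(offset=dff_peak.apex_time - fid_peak.apex_time)


def measure_response(
    trace: Trace,
    substance: SubstanceSpec,
    align: AlignmentModel = AlignmentModel(0.0),
    window_halfwidth: float = DEFAULT_WINDOW_HALFWIDTH,
    mode: str = "extremum",
) -> float:
    """Signed response amplitude in a substance's aligned elution window.

    In ``"extremum"`` mode, returns the signed extremum of
    (value - local baseline) over the whole window
    ``retention_time + offset +/- halfwidth``: the maximum if the largest
    excursion is positive, the minimum if negative.  This captures both
    excitatory calcium increases and inhibitory decreases, but searching
    a wide window makes near-zero responses read as the maximum of the
    noise — a positive bias.

    ``"apex"`` mode reads the amplitude at the aligned elution apex
    itself (the signed extremum over the apex sample and its two
    successors, against a pre-elution flanking baseline).  For pure noise
    this estimate is symmetric around zero, so dose-response curves built
    from it are unbiased at the low-concentration end; it is the
    estimator the quantification pipeline uses.
    """
    center = substance.retention_time + align.offset
    start, end = center - window_halfwidth, center + window_halfwidth
    if start < trace.times[0] or end > trace.times[-1]:
        raise TraceValidationError(
            f"window [{start:.1f}, {end:.1f}] s outside trace span")
    if mode == "extremum":
        idx = trace.window_indices(start, end)
        # baseline from the pre-elution flank: response kernels decay to
        # the right of the apex, so the trailing flank sits on the tail
        pre = trace.window_indices(start - BASELINE_BAND_S, start)
        base = (float(np.median(trace.values[pre])) if pre.size
                else _local_baseline(trace.values, trace.times, start, end))
        excursions = trace.values[idx] - base
    elif mode == "apex":
        # baseline from the clean pre-elution flank only (the response
        # kernel decays to the right of the apex)
        pre = trace.window_indices(start, center - 2.0 * trace.dt)
        base = (float(np.median(trace.values[pre])) if pre.size
                else _local_baseline(trace.values, trace.times, start, end))
        idx = trace.window_indices(center - 0.5 * trace.dt,
                                   center + 2.5 * trace.dt)
        if idx.size == 0:
            raise TraceValidationError("no samples at the aligned apex")
        excursions = trace.values[idx] - base
    else:
        raise TraceValidationError(f"unknown measurement mode {mode!r}")
    lo, hi = float(excursions.min()), float(excursions.max())
    return hi if hi >= -lo else lo


def assign_peaks(
    peaks: list[Peak],
    substances: dict[str, SubstanceSpec],
    align: AlignmentModel = AlignmentModel(0.0),
    window_halfwidth: float = DEFAULT_WINDOW_HALFWIDTH,
) -> dict[str, Peak | None]:
    """Attribute detected peaks to substances by aligned retention time.

    When several peaks fall in one substance window, the one nearest the
    aligned retention time wins; remaining peaks surface under the key
    ``"unassigned"`` (as a list) — this is how unexpected impurity peaks
    are reported.
    """
    result: dict[str, Peak | None] = {name: None for name in substances}
    used: set[int] = set()
    for name, sub in substances.items():
        center = sub.retention_time + align.offset
        cands = [(abs(p.apex_time - center), i, p) for i, p in enumerate(peaks)
                 if abs(p.apex_time - center) <= window_halfwidth and i not in used]
        if cands:
            _, i, peak = min(cands, key=lambda c: (c[0], -abs(c[2].amplitude)))
            result[name] = peak
            used.add(i)
    result["unassigned"] = [p for i, p in enumerate(peaks) if i not in used]
    return result
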