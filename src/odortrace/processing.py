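"""Raw fluorescence -> bleach-corrected, normalized dF/F traces.

The processing chain for a GC-coupled recording is:

1. fit the photobleaching model ``A*exp(-x/B) + C`` to the raw trace,
   leaving out the parts where activity was recorded (explicit response
   windows, or an automatic residual-based mask);
2. subtract the fitted decay component (keeping the offset ``C``);
3. convert to dF/F against the bleach-free baseline;
4. normalize across animals to a reference response amplitude (the first
   response peak of the ethyl butyrate standard).

``delta_f_over_f`` is also available stand-alone with an explicit
pre-stimulus baseline window, which is the natural form for short
direct-stimulation trials where bleaching is negligible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitConvergenceError, TraceValidationError
from .trace import Trace, robust_noise_sd


@dataclass(frozen=True)
class ResponseWindow:
    """A labelled [start, end] interval in seconds."""

    start: float
    end: float
    label: str = ""

    def __post_init__(self):
        if not self.start < self.end:
            raise TraceValidationError("window start must precede end")


def _check_no_overlap(windows: tuple[ResponseWindow, ...]) -> None:
    ordered = sorted(windows, key=lambda w: w.start)
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.start < prev.end:
            raise TraceValidationError(
                f"windows {prev.label or prev.start} and "
                f"{nxt.label or nxt.start} overlap")


@dataclass
class BleachFit:
    """Parameters of the exponential bleaching model ``A*exp(-x/B) + C``.

    ``b`` is NaN (with ``b_identifiable=False``) when the decaying
    component vanishes and the time constant is unidentifiable; correction
    then reduces to subtracting a constant.
    """

    a: float
    b: float
    c: float
    mask: tuple[ResponseWindow, ...] = ()
    rss: float = 0.0
    b_identifiable: bool = True
    converged: bool = True

    def decay(self, times: np.ndarray) -> np.ndarray:
        """The decaying component ``A*exp(-x/B)`` (zero if unidentifiable)."""
        if not self.b_identifiable or self.a == 0.0:
            return np.zeros_like(np.asarray(times, dtype=float))
        return self.a * np.exp(-np.asarray(times, dtype=float) / self.b)

    def baseline(self, times: np.ndarray) -> np.ndarray:
        return self.decay(times) + self.c


def unmasked_indices(trace: Trace, mask: tuple[ResponseWindow, ...]) -> np.ndarray:
    keep = np.ones(trace.times.size, dtype=bool)
    for w in mask:
        keep &= ~((trace.times >= w.start) & (trace.times <= w.end))
    return np.nonzero(keep)[0]


def delta_f_over_f(trace: Trace, baseline_window: ResponseWindow) -> Trace:
    """Relative fluorescence change (F_i - F0)/F0.

    ``F0`` is the mean fluorescence over the (pre-stimulus) baseline
    window.  The output is a dF/F-channel trace whose mean over the
    baseline window is ~0.

    Raises
    ------
    TraceValidationError
        If the baseline window contains no samples or F0 is zero.
    """
    idx = trace.window_indices(baseline_window.start, baseline_window.end)
    if idx.size == 0:
        raise TraceValidationError("baseline window contains no samples")
    f0 = float(np.mean(trace.values[idx]))
    if f0 == 0.0:
        raise TraceValidationError("baseline fluorescence F0 is zero")
    return trace.with_values((trace.values - f0) / f0, channel="dff", f0=f0)


def fit_bleach(trace: Trace, mask: tuple[ResponseWindow, ...] = ()) -> BleachFit:
    """Least-squares fit of ``A*exp(-x/B) + C`` on unmasked samples.

    Initialization: ``A0`` = first - last unmasked value, ``C0`` = last
    unmasked value, ``B0`` = half the unmasked time span; on failure the
    fit restarts with ``B0`` scaled by 0.1 and 10.  The result is
    deterministic given identical inputs.

    Raises
    ------
    FitConvergenceError
        If no restart converges; carries the best parameters so far.
    TraceValidationError
        If fewer than 10 unmasked samples (or < 3 distinct times) remain.
    """
    mask = tuple(mask)
    _check_no_overlap(mask)
    idx = unmasked_indices(trace, mask)
    x = trace.times[idx]
    y = trace.values[idx]
    if idx.size < 10 or np.unique(x).size < 3:
        raise TraceValidationError(
            "bleach fit needs >= 10 unmasked samples at >= 3 distinct times")

    # Degenerate (constant) trace: C is the constant, the decay vanishes
    # and B is unidentifiable.
    if np.ptp(y) == 0.0:
        return BleachFit(a=0.0, b=math.nan, c=float(y[0]), mask=mask,
                         rss=0.0, b_identifiable=False)

    def model(t, a, b, c):
        return a * np.exp(-t / b) + c

    span = float(x[-1] - x[0])
    a0 = max(float(y[0] - y[-1]), 0.0)
    c0 = float(y[-1])
    best = None
    best_rss = math.inf
    for b_scale in (1.0, 0.1, 10.0):
        b0 = max(span / 2.0 * b_scale, 1e-6)
        try:
            # fluorescence decays toward a nonnegative plateau: A, C >= 0
            popt, _ = curve_fit(
                model, x, y, p0=(a0, b0, max(c0, 0.0)),
                bounds=([0.0, 1e-9, 0.0], [np.inf, 1e9, np.inf]),
                maxfev=20000, xtol=1e-14, ftol=1e-14)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((model(x, *popt) - y) ** 2))
        if rss < best_rss:
            best, best_rss = popt, rss
        # accept the first restart that already explains the data well
        if rss <= 1e-12 * max(1.0, float(np.sum(y ** 2))):
            break
    if best is None:
        raise FitConvergenceError("bleach fit did not converge", best_params=None)
    a, b, c = (float(v) for v in best)
    # Near-zero decaying component: report the time constant as
    # unidentifiable rather than a meaningless number.
    scale = max(abs(a) + abs(c), 1e-300)
    if abs(a) <= 1e-9 * scale:
        return BleachFit(a=0.0, b=math.nan, c=c, mask=mask, rss=best_rss,
                         b_identifiable=False)
    return BleachFit(a=a, b=b, c=c, mask=mask, rss=best_rss)


def correct_bleach(trace: Trace, fit: BleachFit) -> Trace:
    """Subtract the fitted decay component, preserving the offset ``C``.

    ``corrected = raw - (A*exp(-x/B) + C) + C = raw - A*exp(-x/B)``:
    response transients are untouched, and the unmasked baseline becomes
    flat at ``C``.
    """
    corrected = trace.values - fit.decay(trace.times)
    return trace.with_values(corrected, bleach_corrected=True)


def bleach_corrected_dff(trace: Trace, fit: BleachFit) -> Trace:
    """Bleach-correct and convert to dF/F against the C-based baseline."""
    if fit.c == 0.0:
        raise TraceValidationError("bleach baseline C is zero; dF/F undefined")
    corrected = trace.values - fit.decay(trace.times)
    return trace.with_values((corrected - fit.c) / fit.c, channel="dff")


def _windows_from_flags(trace: Trace, flagged: np.ndarray,
                        pad_left_s: float,
                        pad_right_s: float) -> tuple[ResponseWindow, ...]:
    """Merge flagged samples into padded, non-overlapping windows."""
    if not flagged.any():
        return ()
    t = trace.times
    idx = np.nonzero(flagged)[0]
    gap = max(1, int(round((pad_left_s + pad_right_s) * trace.rate)))
    runs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev > gap:
            runs.append((start, prev))
            start = i
        prev = i
    runs.append((start, prev))
    out: list[ResponseWindow] = []
    eps = 0.5 / trace.rate
    for s, e in runs:
        w_start = max(t[0] - eps, t[s] - pad_left_s)
        w_end = min(t[-1] + eps, t[e] + pad_right_s)
        if out and w_start <= out[-1].end:
            out[-1] = ResponseWindow(out[-1].start, w_end, label="auto")
        else:
            out.append(ResponseWindow(w_start, w_end, label="auto"))
    return tuple(out)


def auto_mask(
    trace: Trace,
    z: float = 3.0,
    pad_s: float = 5.0,
    pad_right_s: float = 25.0,
    max_iter: int = 4,
) -> tuple[ResponseWindow, ...]:
    """Build response-window masks from bleach-fit residuals.

    Iterates fit -> flag -> refit: the bleach model is fitted on the
    currently unmasked samples, samples whose absolute residual exceeds
    ``z`` times the robust residual SD are flagged, and flagged runs are
    dilated (``pad_s`` to the left, ``pad_right_s`` to the right —
    response transients decay rightward, so sub-threshold tails extend
    beyond the flagged run).  Stops when the mask stabilizes or after
    ``max_iter`` rounds.
    """
    windows: tuple[ResponseWindow, ...] = ()
    for _ in range(max_iter):
        try:
            fit = fit_bleach(trace, windows)
        except TraceValidationError:
            break  # mask swallowed the trace; keep the previous mask
        resid = trace.values - fit.baseline(trace.times)
        keep = unmasked_indices(trace, windows)
        r_ref = resid[keep]
        sd = 1.4826 * float(np.median(np.abs(r_ref - np.median(r_ref))))
        if sd == 0.0:
            return windows
        new = _windows_from_flags(trace, np.abs(resid) > z * sd,
                                  pad_s, pad_right_s)
        if new == windows:
            break
        windows = new
    return windows


def fit_bleach_auto(trace: Trace, z: float = 3.0) -> BleachFit:
    """Bleach fit with the automatic residual-based response mask."""
    mask = auto_mask(trace, z=z)
    try:
        return fit_bleach(trace, mask)
    except TraceValidationError:
        # mask swallowed too much of the trace; fall back to unmasked fit
        return fit_bleach(trace)


def extract_roi_trace(
    stack: np.ndarray,
    roi: np.ndarray,
    rate: float,
    t0: float = 0.0,
    channel: str = "fluorescence",
) -> Trace:
    """Per-frame mean over the ROI pixels of an image stack."""
    stack = np.asarray(stack, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    if stack.ndim != 3:
        raise TraceValidationError("stack must be (frames, height, width)")
    if roi.shape != stack.shape[1:]:
        raise TraceValidationError("ROI shape must match frame shape")
    if not roi.any():
        raise TraceValidationError("ROI is empty")
    values = stack[:, roi].mean(axis=1)
    times = t0 + np.arange(stack.shape[0]) / rate
    return Trace(times, values, rate, channel=channel)


def normalize_to_reference(trace: Trace, reference_amplitude: float) -> Trace:
    """Divide a dF/F trace by a reference response amplitude.

    Used to calibrate responses across animals: a response equal to the
    reference (the first ethyl butyrate response peak) maps to 1.0.
    """
    if reference_amplitude <= 0:
        raise TraceValidationError("reference amplitude must be > 0")
    return trace.with_values(trace.values / reference_amplitude,
                             reference_amplitude=reference_amplitude)


__all__ = [
    "ResponseWindow", "BleachFit", "delta_f_over_f", "fit_bleach",
    "correct_bleach", "bleach_corrected_dff", "auto_mask", "fit_bleach_auto",
    "extract_roi_trace", "normalize_to_reference", "robust_noise_sd",
]
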