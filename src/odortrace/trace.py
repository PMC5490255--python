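"""The core time-series container.

A :class:`Trace` is a uniformly sampled signal — raw fluorescence, FID
signal, or a processed dF/F trace — with its sampling rate, channel role
and free-form metadata tags (animal, stimulus, dilution).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .errors import TraceValidationError

CHANNELS = ("fluorescence", "fid", "dff")


@dataclass
class Trace:
    """A uniformly sampled time series.

    Parameters
    ----------
    times : ndarray
        Sample times in seconds; strictly increasing, uniform to within
        1e-9 relative spacing, length >= 2.
    values : ndarray
        Signal values, same length as ``times``.
    rate : float
        Sampling rate, Hz.
    channel : str
        One of ``"fluorescence"``, ``"fid"``, ``"dff"``.
    meta : dict
        Free-form tags (animal id, stimulus, dilution, ...).
    """

    times: np.ndarray
    values: np.ndarray
    rate: float
    channel: str = "fluorescence"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise TraceValidationError("trace needs at least 2 samples")
        if self.values.shape != self.times.shape:
            raise TraceValidationError("times and values must have equal length")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise TraceValidationError("times must be strictly increasing")
        dt0 = dt[0]
        if np.max(np.abs(dt - dt0)) > 1e-9 * abs(dt0) + 1e-12:
            raise TraceValidationError("time grid must be uniform")
        if self.rate <= 0:
            raise TraceValidationError("rate must be > 0")
        if self.channel not in CHANNELS:
            raise TraceValidationError(f"unknown channel {self.channel!r}")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def with_values(self, values: np.ndarray, channel: str | None = None,
                    **meta: Any) -> "Trace":
        """Copy of this trace with new values (and optionally channel/meta)."""
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return replace(self, values=np.asarray(values, dtype=float),
                       channel=channel or self.channel, meta=new_meta)

    def window_indices(self, start: float, end: float) -> np.ndarray:
        """Indices of samples with start <= t <= end."""
        return np.nonzero((self.times >= start) & (self.times <= end))[0]

    def same_grid(self, other: "Trace", atol: float = 1e-9) -> bool:
        return (self.times.shape == other.times.shape
                and np.allclose(self.times, other.times, rtol=0, atol=atol))


def time_grid(duration: float, rate: float, t0: float = 0.0) -> np.ndarray:
    """Uniform sample grid covering ``[t0, t0 + duration)`` at ``rate`` Hz."""
    if duration <= 0 or rate <= 0:
        raise TraceValidationError("duration and rate must be > 0")
    n = int(round(duration * rate))
    if n < 2:
        raise TraceValidationError("grid would have fewer than 2 samples")
    return t0 + np.arange(n) / rate


def robust_noise_sd(values: np.ndarray) -> float:
    """Noise SD estimate from first differences, robust to slow structure.

    For white noise of SD sigma riding on a slowly varying signal, the
    first differences have SD sigma*sqrt(2); the estimator scales the MAD
    of the differences accordingly (1.4826 * MAD / sqrt(2)).
    """
    v = np.asarray(values, dtype=float)
    d = np.diff(v)
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))
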