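"""Comparison metrics for rate trajectories.

The shifted correlation coefficient scores how well a rate model tracks
a spiking population: the Pearson correlation between the two rate
series, maximized over a small temporal shift (slow-timescale agreement
should not be penalized for a few milliseconds of latency).  Power
spectra and cross-correlograms quantify network oscillations and the
relative phase of the excitatory and inhibitory populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["ShiftedCorrelation", "shifted_correlation", "power_spectrum",
           "cross_correlogram"]


@dataclass(frozen=True)
class ShiftedCorrelation:
    coefficient: float   # in [-1, 1]
    shift_ms: float      # shift of b relative to a at the maximum
    max_shift_ms: float

    def to_dict(self):
        return {"coefficient": self.coefficient, "shift_ms": self.shift_ms,
                "max_shift_ms": self.max_shift_ms}


def _pearson(a, b):
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.sqrt(a @ a), np.sqrt(b @ b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("zero-variance input: correlation undefined")
    return float(a @ b / (na * nb))


def shifted_correlation(a, b, dt_ms: float, max_shift_ms: float = 5.0
                        ) -> ShiftedCorrelation:
    """Pearson correlation of ``a`` and ``b`` maximized over integer-bin
    shifts within +-max_shift_ms.

    Both series must share the sampling step ``dt_ms``.  A positive
    shift means ``b`` lags ``a``.  The overlap after shifting must keep
    at least 90% of the series length.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length and sampling")
    n = len(a)
    kmax = int(round(max_shift_ms / dt_ms))
    if n - kmax < int(0.9 * n):
        raise ValueError("max_shift too large: overlap below 90% of length")
    best = (-2.0, 0)
    for k in range(-kmax, kmax + 1):
        if k >= 0:
            c = _pearson(a[: n - k], b[k:])
        else:
            c = _pearson(a[-k:], b[: n + k])
        if c > best[0]:
            best = (c, k)
    return ShiftedCorrelation(coefficient=best[0], shift_ms=best[1] * dt_ms,
                              max_shift_ms=max_shift_ms)


def power_spectrum(rate_hz, dt_ms: float, segment_ms: float = 256.0,
                   overlap: float = 0.5):
    """Welch-averaged power spectrum of a rate series.

    Returns ``(freqs_hz, power)``; normalized so the integral over
    frequency equals the series variance (one-sided density).  Requires
    the series to span at least four segments.
    """
    rate_hz = np.asarray(rate_hz, dtype=float)
    nper = int(round(segment_ms / dt_ms))
    if len(rate_hz) < 4 * nper * (1 - overlap):
        raise ValueError("series shorter than four Welch segments")
    fs = 1000.0 / dt_ms  # Hz
    freqs, power = signal.welch(rate_hz, fs=fs, nperseg=nper,
                                noverlap=int(nper * overlap),
                                detrend="constant")
    return freqs, power


def dominant_frequency(rate_hz, dt_ms: float, segment_ms: float = 256.0
                       ) -> float:
    """Argmax of the Welch spectrum over f > 0 (DC excluded), in Hz."""
    f, p = power_spectrum(rate_hz, dt_ms, segment_ms=segment_ms)
    return float(f[1:][np.argmax(p[1:])])


def cross_correlogram(a, b, dt_ms: float, max_lag_ms: float = 20.0):
    """Normalized cross-correlation of two rate series over +-max_lag.

    Returns ``(lags_ms, corr)``; a peak at positive lag means ``b``
    follows ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length and sampling")
    kmax = int(round(max_lag_ms / dt_ms))
    if kmax >= len(a) // 2:
        raise ValueError("max_lag too large for series length")
    lags = np.arange(-kmax, kmax + 1)
    corr = np.empty(len(lags))
    n = len(a)
    for i, k in enumerate(lags):
        if k >= 0:
            corr[i] = _pearson(a[: n - k], b[k:])
        else:
            corr[i] = _pearson(a[-k:], b[: n + k])
    return lags * dt_ms, corr
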