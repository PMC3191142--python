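"""Temporal preprocessing of ROI time courses.

Order is fixed: discard initial volumes -> linear detrend -> band-pass ->
global-signal removal.  The band-pass is an ideal rectangular filter in the
frequency domain (zero every FFT bin outside [f_lo, f_hi], inclusive), which
makes it a projection: applying it twice equals applying it once.
"""

from __future__ import annotations

import numpy as np
import scipy.signal

from .timeseries import TimeSeriesMatrix

DEFAULT_DISCARD = 5
DEFAULT_F_LO = 0.01
DEFAULT_F_HI = 0.1


def discard_initial(ts: TimeSeriesMatrix, k: int = DEFAULT_DISCARD) -> TimeSeriesMatrix:
    """Drop the first ``k`` time points (initial-signal instability)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if k >= ts.n_timepoints:
        raise ValueError(
            f"cannot discard {k} of {ts.n_timepoints} time points"
        )
    return ts.with_values(ts.values[k:])


def detrend_linear(ts: TimeSeriesMatrix) -> TimeSeriesMatrix:
    """Remove per-column least-squares line (intercept + slope)."""
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 time points to detrend")
    return ts.with_values(scipy.signal.detrend(ts.values, axis=0, type="linear"))


def bandpass(
    ts: TimeSeriesMatrix,
    f_lo: float = DEFAULT_F_LO,
    f_hi: float = DEFAULT_F_HI,
) -> TimeSeriesMatrix:
    """Ideal band-pass: keep FFT bins with f_lo <= f <= f_hi, zero the rest.

    Frequencies are in Hz; the admissible band must sit inside
    [0, Nyquist] with Nyquist = 1 / (2 * tr_seconds).
    """
    nyquist = 1.0 / (2.0 * ts.tr_seconds)
    if not 0.0 <= f_lo < f_hi:
        raise ValueError("need 0 <= f_lo < f_hi")
    if f_hi > nyquist:
        raise ValueError(f"f_hi = {f_hi} Hz exceeds Nyquist = {nyquist} Hz")
    t = ts.n_timepoints
    freqs = np.fft.rfftfreq(t, d=ts.tr_seconds)
    keep = (freqs >= f_lo) & (freqs <= f_hi)
    spec = np.fft.rfft(ts.values, axis=0)
    spec[~keep] = 0.0
    return ts.with_values(np.fft.irfft(spec, n=t, axis=0))


def remove_global_signal(
    ts: TimeSeriesMatrix, global_signal: np.ndarray | None = None
) -> TimeSeriesMatrix:
    """Regress [intercept, global signal] out of every column.

    When no separate whole-brain series is supplied, the global signal is
    the mean over all ROI columns.  Each column is replaced by its
    least-squares residual, which is uncorrelated with the global signal.
    """
    if global_signal is None:
        global_signal = ts.values.mean(axis=1)
    g = np.asarray(global_signal, dtype=float)
    if g.shape != (ts.n_timepoints,):
        raise ValueError(
            f"global signal length {g.shape} != T = {ts.n_timepoints}"
        )
    if np.ptp(g) == 0.0:
        raise ValueError("global signal is constant (zero variance)")
    design = np.column_stack([np.ones_like(g), g])
    beta, *_ = np.linalg.lstsq(design, ts.values, rcond=None)
    return ts.with_values(ts.values - design @ beta)


def preprocess_pipeline(
    ts: TimeSeriesMatrix,
    discard: int = DEFAULT_DISCARD,
    f_lo: float = DEFAULT_F_LO,
    f_hi: float = DEFAULT_F_HI,
    global_signal_removal: bool = True,
    global_signal: np.ndarray | None = None,
) -> TimeSeriesMatrix:
    """Full temporal pipeline in the fixed order.

    ``global_signal``, if given, must match the length after discarding.
    """
    out = discard_initial(ts, discard)
    out = detrend_linear(out)
    out = bandpass(out, f_lo, f_hi)
    if global_signal_removal:
        out = remove_global_signal(out, global_signal)
    return out
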