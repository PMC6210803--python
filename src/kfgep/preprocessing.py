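"""Signal and trace preprocessing.

Raw sEMG is reduced to one RMS feature per channel per 50 ms adjacent
(non-overlapping) window; pen traces sampled on the same 50 ms clock are
converted to increment (delta) sequences.  Trial onset is found on the
trigger channel by a 30 µV threshold crossing followed by a 20 ms
maximum-peak search, and that onset index is broadcast to all channels.

Amplitude is taken as the rectified (absolute) signal value: sEMG is a
bipolar signal, so a one-sided threshold would miss negative-going bursts.
"""

from __future__ import annotations

import numpy as np

DEFAULT_THRESHOLD_UV = 30.0
DEFAULT_PEAK_WINDOW_S = 0.020
WINDOW_S = 0.050


class OnsetNotFoundError(ValueError):
    """No sample crossed the onset threshold."""


def detect_onset(
    signal: np.ndarray,
    fs: float = 1000.0,
    threshold: float = DEFAULT_THRESHOLD_UV,
    peak_window: float = DEFAULT_PEAK_WINDOW_S,
) -> int:
    """Locate the epoch onset on a trigger channel.

    The onset is the index of the maximum rectified amplitude within
    ``peak_window`` seconds after (and including) the first sample whose
    rectified amplitude reaches ``threshold``.

    Raises
    ------
    OnsetNotFoundError
        If no sample reaches the threshold.
    """
    x = np.abs(np.asarray(signal, dtype=float).ravel())
    if x.size == 0:
        raise ValueError("empty signal")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    crossings = np.flatnonzero(x >= threshold)
    if crossings.size == 0:
        raise OnsetNotFoundError(
            f"no sample reached the {threshold} µV onset threshold"
        )
    first = int(crossings[0])
    span = int(round(peak_window * fs))
    window = x[first : first + span + 1]  # inclusive of the crossing sample
    return first + int(np.argmax(window))


def window_rms(signal: np.ndarray, fs: float, window: float = WINDOW_S) -> np.ndarray:
    """RMS over adjacent non-overlapping windows; a trailing partial window
    is dropped."""
    x = np.asarray(signal, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty signal")
    n = fs * window
    if abs(n - round(n)) > 1e-9 or round(n) < 1:
        raise ValueError(
            f"window of {window} s at fs={fs} Hz is not a positive integer "
            "sample count"
        )
    n = int(round(n))
    if x.size < n:
        raise ValueError(f"signal shorter ({x.size}) than one window ({n} samples)")
    k = x.size // n
    frames = x[: k * n].reshape(k, n)
    return np.sqrt(np.mean(frames**2, axis=1))


def to_deltas(trace: np.ndarray):
    """Increment sequence of a trace plus its one-step-ahead shifted targets.

    Parameters
    ----------
    trace : (n, 2) array
        Pen coordinates on the 50 ms clock.

    Returns
    -------
    deltas : (n-1, 2) array
        Δ_i = trace_i - trace_{i-1}.
    shifted : (n-2, 2) array
        Δ'_i = Δ_{i+1}, the targets for fitting the increment dynamics.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 2:
        raise ValueError(f"trace must be (n, 2), got {trace.shape}")
    if trace.shape[0] < 2:
        raise ValueError("trace must have at least 2 points")
    if not np.isfinite(trace).all():
        raise ValueError("trace contains non-finite coordinates")
    deltas = np.diff(trace, axis=0)
    return deltas, deltas[1:]


def from_deltas(deltas: np.ndarray, origin=(0.0, 0.0)) -> np.ndarray:
    """Cumulative summation of increments from an origin; exact inverse of
    :func:`to_deltas` up to floating-point roundoff."""
    deltas = np.asarray(deltas, dtype=float).reshape(-1, 2) if np.size(deltas) else \
        np.empty((0, 2))
    if not np.isfinite(deltas).all():
        raise ValueError("non-finite deltas")
    origin = np.asarray(origin, dtype=float).reshape(2)
    return np.vstack([origin, origin + np.cumsum(deltas, axis=0)])
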