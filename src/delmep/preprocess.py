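"""Four-stage epoch conditioning for the latency regressor.

The raw EMG epoch is (1) trimmed to the 10–50 ms post-stimulus window
(half-open, exactly 120 samples at 3 kHz), (2) smoothed with a 3-sample
centered moving average, (3) centered by subtracting the mean of the first
15 samples (5 ms), and (4) min-max normalized to [0, 1].  The composition
is invariant to a positive gain applied to the raw trace, which is what lets
a single network annotate MEPs whose amplitudes span an order of magnitude.

A pre-activation screen rejects epochs whose pre-stimulus EMG exceeds
±15 µV within 1 s before the pulse (muscle pre-activation / movement
artifacts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from delmep.mep_io import MepTrace

__all__ = [
    "PreprocessedVector",
    "DegenerateTraceError",
    "PreprocessingError",
    "screen_preactivation",
    "trim",
    "smooth",
    "center",
    "normalize",
    "preprocess",
]

TRIM_START_MS = 10.0
TRIM_END_MS = 50.0
SMOOTH_WINDOW = 3
N_BASELINE = 15
PREACTIVATION_THRESHOLD_UV = 15.0
PREACTIVATION_WINDOW_MS = 1000.0


class DegenerateTraceError(ValueError):
    """Trace is flat (zero amplitude range); normalization is undefined.

    Callers must treat such a trace as unannotatable — the acquisition
    pipeline this emulates discards no-response epochs upstream.
    """


class PreprocessingError(ValueError):
    """A preprocessing stage failed; the stage name is in the message."""


@dataclass(frozen=True)
class PreprocessedVector:
    """The network input: a [0, 1]-normalized trimmed epoch.

    At 3 kHz with the default 10–50 ms window this is exactly 120 values
    with min 0 and max 1.
    """

    values: np.ndarray
    fs_hz: float
    source_trace_id: str
    trim_start_ms: float = TRIM_START_MS
    trim_end_ms: float = TRIM_END_MS

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        v = self.values
        expected = round((self.trim_end_ms - self.trim_start_ms) / 1000.0 * self.fs_hz)
        if v.size != expected:
            raise ValueError(
                f"expected {expected} samples for [{self.trim_start_ms}, "
                f"{self.trim_end_ms}) ms at {self.fs_hz} Hz, got {v.size}"
            )
        if abs(v.min()) > 1e-9 or abs(v.max() - 1.0) > 1e-9:
            raise ValueError("values must span [0, 1] after normalization")

    def __len__(self) -> int:
        return int(self.values.size)


def screen_preactivation(
    trace: MepTrace,
    threshold_uv: float = PREACTIVATION_THRESHOLD_UV,
    window_ms: float = PREACTIVATION_WINDOW_MS,
) -> bool:
    """Return True if the epoch passes the pre-activation screen.

    Fails iff any pre-stimulus sample in [-window_ms, 0) has an absolute
    amplitude strictly greater than ``threshold_uv``.  A trace with no
    pre-stimulus samples passes with a warning (nothing to screen).
    """
    t = trace.times_ms
    pre = trace.samples[(t >= -window_ms) & (t < 0.0)]
    if pre.size == 0:
        warnings.warn(
            f"trace {trace.trace_id!r} has no pre-stimulus samples in "
            f"[-{window_ms}, 0) ms; pre-activation screen skipped",
            stacklevel=2,
        )
        return True
    return bool(np.max(np.abs(pre)) <= threshold_uv)


def trim(
    trace: MepTrace,
    start_ms: float = TRIM_START_MS,
    end_ms: float = TRIM_END_MS,
) -> np.ndarray:
    """Samples of the half-open window start_ms <= t < end_ms (µV).

    The half-open convention yields exactly round((end-start)·fs/1000)
    samples — 120 at 3 kHz for the default 10–50 ms window.
    """
    t = trace.times_ms
    if not (t[0] <= start_ms and t[-1] >= end_ms - 1000.0 / trace.fs_hz):
        raise PreprocessingError(
            f"trim: trace {trace.trace_id!r} spans [{t[0]:g}, {t[-1]:g}] ms "
            f"and does not cover [{start_ms:g}, {end_ms:g}) ms"
        )
    # half-open selection with a half-sample guard against float round-off
    tol = 500.0 / trace.fs_hz
    out = trace.samples[(t >= start_ms - tol) & (t < end_ms - tol)]
    return np.asarray(out, dtype=float)


def smooth(x: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    """Centered moving average; window shrinks at the edges.

    Length-preserving and phase-neutral: out[i] is the mean of
    x[max(0, i-h) : i+h+1] with h = window // 2.  A trailing window would
    bias detected onsets late by about one sample, hence centered.
    """
    x = np.asarray(x, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if window == 1:
        return x.copy()
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones(x.size), kernel, mode="same")
    return num / den


def center(x: np.ndarray, n_baseline: int = N_BASELINE) -> np.ndarray:
    """Subtract the mean of the first ``n_baseline`` samples (5 ms at 3 kHz).

    Counteracts the offset that low-frequency noise adds to the epoch mean.
    Idempotent; leaves pairwise sample differences unchanged.
    """
    x = np.asarray(x, dtype=float)
    if x.size < n_baseline:
        raise ValueError(
            f"center: need at least {n_baseline} samples, got {x.size}"
        )
    return x - x[:n_baseline].mean()


def normalize(x: np.ndarray, eps: float = 1e-9) -> np.ndarray:
    """Min-max normalize to [0, 1]; invariant to any affine map a·x+b, a>0."""
    x = np.asarray(x, dtype=float)
    rng = x.max() - x.min()
    if rng <= eps:
        raise DegenerateTraceError(
            f"flat trace (amplitude range {rng:g} <= {eps:g} µV); "
            "normalization undefined — treat as unannotatable"
        )
    return (x - x.min()) / rng


def preprocess(
    trace: MepTrace,
    start_ms: float = TRIM_START_MS,
    end_ms: float = TRIM_END_MS,
    window: int = SMOOTH_WINDOW,
    n_baseline: int = N_BASELINE,
) -> PreprocessedVector:
    """trim → smooth → center → normalize, in that order.

    Raises :class:`PreprocessingError` (stage name in the message) or
    :class:`DegenerateTraceError` for flat traces.
    """
    x = trim(trace, start_ms, end_ms)
    try:
        x = smooth(x, window)
    except ValueError as e:
        raise PreprocessingError(f"smooth: {e}") from e
    try:
        x = center(x, n_baseline)
    except ValueError as e:
        raise PreprocessingError(f"center: {e}") from e
    x = normalize(x)  # DegenerateTraceError propagates with its own message
    return PreprocessedVector(
        values=x,
        fs_hz=trace.fs_hz,
        source_trace_id=trace.trace_id,
        trim_start_ms=start_ms,
        trim_end_ms=end_ms,
    )
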