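"""Rule-based MEP onset estimators used as comparison methods.

Four estimators operating on the *trimmed raw* epoch (10–50 ms window in
µV, no smoothing/centering/normalization unless the algorithm itself calls
for it):

* **Signal Hunter** — moving-average smooth, first difference, find the
  index maximizing |diff| − SD(diff), subtract a magic number of samples.
* **AHTE** (absolute hard threshold estimator) — threshold at 10 % of the
  maximum of |x|, first crossing index, subtract the magic number.
* **SHTE** (squared hard threshold estimator) — same on x² with threshold
  10 % of max(x²).
* **Bigoni's method** — derivative-based: on |x|, up to the peak, find the
  longest run of consecutive strictly positive first differences; the run's
  first sample is the onset.  Runs shorter than 5 samples mean the epoch is
  discarded (no reliable rising edge).

A sample index i maps to latency_ms = trim_start_ms + 1000·i/fs_hz.
All four estimators are invariant to a positive gain on the input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from delmep.preprocess import TRIM_START_MS, smooth

__all__ = [
    "EstimatorParams",
    "LatencyEstimate",
    "signal_hunter_latency",
    "ahte_latency",
    "shte_latency",
    "bigoni_latency",
    "ESTIMATORS",
]


@dataclass(frozen=True)
class EstimatorParams:
    """Shared tuning constants of the rule-based estimators.

    magic_number
        Samples subtracted from a detected index before ms conversion
        (Signal Hunter, AHTE, SHTE).
    v_thr
        Threshold fraction of the maximum (AHTE: of max|x|; SHTE: of
        max x²).
    min_run
        Minimum length, in samples, of the positive-derivative run Bigoni's
        method requires; shorter runs discard the epoch.
    sh_smooth_window
        Moving-average window of Signal Hunter's smoothing stage.
    """

    magic_number: int = 5
    v_thr: float = 0.10
    min_run: int = 5
    sh_smooth_window: int = 3

    def __post_init__(self) -> None:
        if self.magic_number < 0:
            raise ValueError("magic_number must be >= 0")
        if not (0.0 < self.v_thr < 1.0):
            raise ValueError("v_thr must be in (0, 1)")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")


@dataclass(frozen=True)
class LatencyEstimate:
    """One estimator's output for one trace.

    Exactly one of ``latency_ms`` / ``discarded``-with-``reason`` is
    populated.
    """

    trace_id: str
    estimator: str
    latency_ms: Optional[float] = None
    discarded: bool = False
    reason: str = ""

    def __post_init__(self) -> None:
        if self.discarded:
            if self.latency_ms is not None or not self.reason:
                raise ValueError("a discarded estimate carries a reason and no latency")
        else:
            if self.latency_ms is None or not np.isfinite(self.latency_ms):
                raise ValueError("a kept estimate carries a finite latency_ms")


def _index_to_ms(i: int, fs_hz: float, trim_start_ms: float) -> float:
    return trim_start_ms + 1000.0 * i / fs_hz


def _discard(trace_id: str, name: str, reason: str) -> LatencyEstimate:
    return LatencyEstimate(trace_id=trace_id, estimator=name,
                           discarded=True, reason=reason)


def signal_hunter_latency(
    x: np.ndarray,
    fs_hz: float = 3000.0,
    params: EstimatorParams = EstimatorParams(),
    trace_id: str = "",
    trim_start_ms: float = TRIM_START_MS,
) -> LatencyEstimate:
    """Statistical-measure estimator of the Signal Hunter software.

    Smooth, differentiate, find argmax(|diff| − SD(diff)), subtract the
    magic number.  The SD term is a constant and cannot change the argmax;
    it is applied literally nonetheless.
    """
    name = "signal_hunter"
    x = np.asarray(x, dtype=float)
    if x.size < params.sh_smooth_window + 2:
        return _discard(trace_id, name, "trace too short")
    s = smooth(x, params.sh_smooth_window)
    d = np.diff(s)
    if np.allclose(d, 0.0):
        return _discard(trace_id, name, "no deflection")
    score = np.abs(d) - d.std()
    idx = int(np.argmax(score)) - params.magic_number
    if idx < 0:
        return _discard(trace_id, name, "onset index before trim window")
    return LatencyEstimate(trace_id=trace_id, estimator=name,
                           latency_ms=_index_to_ms(idx, fs_hz, trim_start_ms))


def _threshold_crossing(
    a: np.ndarray,
    params: EstimatorParams,
    trace_id: str,
    name: str,
    fs_hz: float,
    trim_start_ms: float,
) -> LatencyEstimate:
    """First index with a >= v_thr·max(a), minus the magic number."""
    peak = a.max()
    if peak <= 0.0:
        return _discard(trace_id, name, "no deflection")
    thr = params.v_thr * peak
    idx = int(np.argmax(a >= thr)) - params.magic_number
    if idx < 0:
        return _discard(trace_id, name, "onset index before trim window")
    return LatencyEstimate(trace_id=trace_id, estimator=name,
                           latency_ms=_index_to_ms(idx, fs_hz, trim_start_ms))


def ahte_latency(
    x: np.ndarray,
    fs_hz: float = 3000.0,
    params: EstimatorParams = EstimatorParams(),
    trace_id: str = "",
    trim_start_ms: float = TRIM_START_MS,
) -> LatencyEstimate:
    """Absolute hard threshold estimator: crossing of 10 % of max|x|."""
    x = np.asarray(x, dtype=float)
    return _threshold_crossing(np.abs(x), params, trace_id, "ahte",
                               fs_hz, trim_start_ms)


def shte_latency(
    x: np.ndarray,
    fs_hz: float = 3000.0,
    params: EstimatorParams = EstimatorParams(),
    trace_id: str = "",
    trim_start_ms: float = TRIM_START_MS,
) -> LatencyEstimate:
    """Squared hard threshold estimator: crossing of 10 % of max(x²).

    Squaring makes the relative threshold √0.10 ≈ 0.316 of the peak
    amplitude, so the SHTE crossing never precedes AHTE's on the same trace.
    """
    x = np.asarray(x, dtype=float)
    return _threshold_crossing(x ** 2, params, trace_id, "shte",
                               fs_hz, trim_start_ms)


def bigoni_latency(
    x: np.ndarray,
    fs_hz: float = 3000.0,
    params: EstimatorParams = EstimatorParams(),
    trace_id: str = "",
    trim_start_ms: float = TRIM_START_MS,
) -> LatencyEstimate:
    """Derivative-based estimator: longest rising run of |x| before the peak.

    First differences of |x| are scanned up to the peak of |x|; the onset is
    the first sample of the longest run of consecutive strictly positive
    differences (earliest run on ties).  If that run is shorter than
    ``min_run`` samples the epoch is discarded — no magic-number offset is
    involved.
    """
    name = "bigoni"
    x = np.asarray(x, dtype=float)
    a = np.abs(x)
    if np.allclose(a, a[0]):
        return _discard(trace_id, name, "no deflection")
    peak = int(np.argmax(a))
    d = np.diff(a[: peak + 1])
    if d.size == 0:
        return _discard(trace_id, name, "peak at first sample")
    best_len = 0
    best_start = -1
    run_len = 0
    run_start = 0
    for i, di in enumerate(d):
        if di > 0.0:
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len > best_len:  # strict > keeps the earliest maximal run
                best_len = run_len
                best_start = run_start
        else:
            run_len = 0
    if best_len < params.min_run:
        return _discard(
            trace_id, name,
            f"longest positive-derivative run {best_len} < {params.min_run}",
        )
    return LatencyEstimate(trace_id=trace_id, estimator=name,
                           latency_ms=_index_to_ms(best_start, fs_hz, trim_start_ms))


#: Name → estimator function, for CLI and harness dispatch.
ESTIMATORS = {
    "signal_hunter": signal_hunter_latency,
    "ahte": ahte_latency,
    "shte": shte_latency,
    "bigoni": bigoni_latency,
}
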