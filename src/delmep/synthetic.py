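"""Seeded generator of TMS-evoked EMG epochs with known onset latencies.

Emulates the *retained* epochs of a multi-subject single/paired-pulse
TMS-EMG study: 3 kHz sampling, epochs from 1 s before to 100 ms after the
pulse, onset latencies around 15–30 ms with a per-subject offset, peak-to-
peak amplitudes drawn from a low/medium/high class mix (13 / 18 / 69 % by
default), 10–500 Hz band-limited Gaussian noise, and a slow sinusoidal
baseline drift.

The MEP waveform is a gamma envelope times a sinusoid,

    w(t) = ((t-L)/τ) · exp(1 − (t-L)/τ) · sin(2π (t-L)/T)   for t ≥ L,
    w(t) = 0                                                 for t < L,

which is identically zero before the onset L — so the ground-truth latency
is exact by construction — continuous at L, and biphasic with one dominant
positive and one dominant negative lobe, like a real MEP.  The waveform is
scaled so the noise-free post-stimulus peak-to-peak amplitude equals the
drawn V_PP target exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import signal as sp_signal

from delmep.mep_io import AnnotatedDataset, Annotation, MepTrace, amplitude_class

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "mep_template",
    "generate_trace",
    "generate_dataset",
]

_MUSCLES = ("APB", "ADM", "FDI")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-level generator settings.

    Defaults reproduce the emulated acquisition chain: 3 kHz sampling,
    epochs spanning [-1000, 100] ms around the pulse, onsets uniform in
    15–30 ms with a 1.5 ms SD subject effect, amplitude classes mixed
    13/18/69 % (low ≤100 µV, medium 100–200 µV, high >200 µV), 5 µV
    band-limited (10–500 Hz) noise and a 10 µV, 1 Hz baseline drift.
    """

    n_subjects: int = 9
    traces_per_subject: int = 100
    fs_hz: float = 3000.0
    epoch_ms: Tuple[float, float] = (-1000.0, 100.0)
    latency_range_ms: Tuple[float, float] = (15.0, 30.0)
    subject_latency_sd_ms: float = 1.5
    vpp_class_mix: Tuple[float, float, float] = (0.13, 0.18, 0.69)
    vpp_ranges_uv: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "low": (20.0, 100.0),
            "medium": (100.0, 200.0),
            "high": (200.0, 1000.0),
        }
    )
    noise_sd_uv: float = 5.0
    noise_band_hz: Tuple[float, float] = (10.0, 500.0)
    drift_amp_uv: float = 10.0
    drift_freq_hz: float = 1.0
    period_range_ms: Tuple[float, float] = (8.0, 16.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0 or self.traces_per_subject < 0 or self.fs_hz <= 0:
            raise ValueError("counts must be >= 0 and fs_hz > 0")
        if abs(sum(self.vpp_class_mix) - 1.0) > 1e-9:
            raise ValueError(f"vpp_class_mix must sum to 1, got {self.vpp_class_mix}")
        lo, hi = self.latency_range_ms
        if not (10.0 < lo <= hi < 50.0):
            raise ValueError("latency_range_ms must lie within the 10-50 ms window")
        if self.epoch_ms[0] >= self.epoch_ms[1]:
            raise ValueError("epoch_ms must be an increasing interval")
        nyq = self.fs_hz / 2.0
        if not (0.0 < self.noise_band_hz[0] < self.noise_band_hz[1] < nyq):
            raise ValueError("noise_band_hz must be within (0, Nyquist)")


@dataclass(frozen=True)
class GroundTruth:
    """Exact simulation parameters of one trace (stands in for an expert)."""

    trace_id: str
    subject_id: str
    true_latency_ms: float
    true_vpp_uv: float
    amplitude_class: str


def mep_template(
    t_ms: np.ndarray, onset_ms: float, period_ms: float, tau_ms: float
) -> np.ndarray:
    """Unit-scale biphasic MEP waveform; zero before ``onset_ms``."""
    if period_ms <= 0 or tau_ms <= 0:
        raise ValueError("period_ms and tau_ms must be positive")
    t_ms = np.asarray(t_ms, dtype=float)
    u = (t_ms - onset_ms) / tau_ms
    w = np.where(
        u >= 0.0,
        u * np.exp(1.0 - u) * np.sin(2.0 * np.pi * (t_ms - onset_ms) / period_ms),
        0.0,
    )
    return w if w.ndim else float(w)


def _band_limited_noise(
    rng: np.random.Generator, n: int, fs_hz: float,
    band_hz: Tuple[float, float], sd_uv: float,
) -> np.ndarray:
    """Gaussian noise filtered to ``band_hz`` and rescaled to sd ``sd_uv``."""
    white = rng.standard_normal(n)
    sos = sp_signal.butter(4, band_hz, btype="bandpass", fs=fs_hz, output="sos")
    filt = sp_signal.sosfiltfilt(sos, white)
    s = filt.std()
    return filt * (sd_uv / s) if s > 0 else filt


def generate_trace(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    latency_ms: float,
    vpp_uv: float,
    trace_id: str = "t0000",
    subject_id: str = "s00",
    muscle: str = "APB",
    period_ms: Optional[float] = None,
) -> Tuple[MepTrace, GroundTruth]:
    """One epoch: scaled template + band-limited noise + sinusoidal drift.

    The template scale is set so that at zero noise and drift the
    post-stimulus peak-to-peak amplitude equals ``vpp_uv`` exactly; the
    pre-stimulus segment contains noise and drift only.
    """
    if vpp_uv <= 0:
        raise ValueError(f"V_PP target must be positive, got {vpp_uv}")
    t0, t1 = cfg.epoch_ms
    n = int(round((t1 - t0) / 1000.0 * cfg.fs_hz))
    t = t0 + 1000.0 * np.arange(n) / cfg.fs_hz
    if period_ms is None:
        period_ms = float(rng.uniform(*cfg.period_range_ms))
    tau_ms = period_ms / 4.0
    w = mep_template(t, latency_ms, period_ms, tau_ms)
    post = w[t >= 0.0]
    pp = post.max() - post.min()
    if pp <= 0:
        raise ValueError("template peak-to-peak is zero; onset outside epoch?")
    x = (vpp_uv / pp) * w
    if cfg.noise_sd_uv > 0:
        x = x + _band_limited_noise(rng, n, cfg.fs_hz, cfg.noise_band_hz,
                                    cfg.noise_sd_uv)
    if cfg.drift_amp_uv > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        x = x + cfg.drift_amp_uv * np.sin(
            2.0 * np.pi * cfg.drift_freq_hz * t / 1000.0 + phase
        )
    trace = MepTrace(
        trace_id=trace_id, subject_id=subject_id, muscle=muscle,
        fs_hz=cfg.fs_hz, t_start_ms=t0, samples=x,
    )
    gt = GroundTruth(
        trace_id=trace_id, subject_id=subject_id,
        true_latency_ms=float(latency_ms), true_vpp_uv=float(vpp_uv),
        amplitude_class=amplitude_class(vpp_uv),
    )
    return trace, gt


def generate_dataset(cfg: SyntheticConfig = SyntheticConfig()) -> AnnotatedDataset:
    """A multi-subject dataset with ground truth attached as annotations.

    Each subject gets a mean onset latency drawn once uniformly from
    ``latency_range_ms`` (the subject effect that makes leave-one-subject-
    out non-trivial); per-trace latencies are Gaussian around it with SD
    ``subject_latency_sd_ms``, truncated at ±3 SD and kept inside the
    10–50 ms analysis window.  Amplitude classes are drawn from
    ``vpp_class_mix`` and V_PP uniformly within the class range.
    Annotations carry the exact simulated latency and V_PP
    (annotator = "ground_truth").
    """
    rng = np.random.default_rng(cfg.seed)
    classes = ("low", "medium", "high")
    lo, hi = cfg.latency_range_ms
    sd = cfg.subject_latency_sd_ms
    lat_floor = max(10.5, lo - 3.0 * sd)
    lat_ceil = min(49.5, hi + 3.0 * sd)

    traces: Dict[str, MepTrace] = {}
    annotations: Dict[str, Annotation] = {}
    for si in range(cfg.n_subjects):
        subject_id = f"s{si:02d}"
        mu = rng.uniform(lo, hi)
        for ti in range(cfg.traces_per_subject):
            trace_id = f"{subject_id}_t{ti:04d}"
            latency = float(np.clip(rng.normal(mu, sd), lat_floor, lat_ceil))
            cls = classes[rng.choice(3, p=cfg.vpp_class_mix)]
            vlo, vhi = cfg.vpp_ranges_uv[cls]
            vpp_target = float(rng.uniform(vlo, vhi))
            muscle = _MUSCLES[ti % len(_MUSCLES)]
            trace, gt = generate_trace(
                cfg, rng, latency, vpp_target,
                trace_id=trace_id, subject_id=subject_id, muscle=muscle,
            )
            traces[trace_id] = trace
            annotations[trace_id] = Annotation(
                trace_id=trace_id, latency_ms=gt.true_latency_ms,
                vpp_uv=gt.true_vpp_uv, annotator="ground_truth",
            )
    return AnnotatedDataset(
        traces=traces, annotations=annotations,
        provenance=f"synthetic seed={cfg.seed} n_subjects={cfg.n_subjects} "
                   f"traces_per_subject={cfg.traces_per_subject}",
    )
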