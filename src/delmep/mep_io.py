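"""Data model and delimited-text I/O for TMS-evoked EMG epochs.

An epoch (:class:`MepTrace`) is one EMG trace time-referenced to the TMS
pulse (pulse at t = 0 ms; samples may start before the pulse).  Expert or
estimator latencies live in :class:`Annotation`; a set of traces plus their
annotations forms an :class:`AnnotatedDataset`.

On-disk layout is two RFC-4180 CSV files:

* ``meta``    — one row per trace: trace_id, subject_id, muscle, fs_hz,
  t_start_ms, latency_ms, vpp_uv, annotator.
* ``samples`` — long format, one row per sample: trace_id, sample_index,
  amplitude_uv (0-based sample_index; variable-length epochs allowed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List

import numpy as np
import pandas as pd

__all__ = [
    "MepTrace",
    "Annotation",
    "AnnotatedDataset",
    "DatasetFormatError",
    "amplitude_class",
    "vpp",
    "read_dataset",
    "write_dataset",
]

#: V_PP boundaries (µV) between the low/medium and medium/high amplitude
#: classes used throughout the evaluation.
LOW_MEDIUM_UV = 100.0
MEDIUM_HIGH_UV = 200.0


class DatasetFormatError(ValueError):
    """A dataset file violates the documented CSV layout or referential rules."""


@dataclass
class MepTrace:
    """One EMG epoch referenced to the TMS pulse.

    Parameters
    ----------
    trace_id, subject_id, muscle
        Identifiers; muscle is e.g. ``APB``/``ADM``/``FDI``.
    fs_hz
        Sampling rate in Hz (3000 for the eXimia chain emulated here).
    t_start_ms
        Time of the first sample relative to the TMS pulse, in ms
        (negative when the epoch includes pre-stimulus baseline).
    samples
        Amplitudes in µV, ordered in time.
    """

    trace_id: str
    subject_id: str
    muscle: str
    fs_hz: float
    t_start_ms: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError(f"fs_hz must be positive, got {self.fs_hz}")
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"trace {self.trace_id!r} contains non-finite samples")

    @property
    def times_ms(self) -> np.ndarray:
        """Time of each sample in ms relative to the TMS pulse."""
        return self.t_start_ms + 1000.0 * np.arange(self.samples.size) / self.fs_hz

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)


@dataclass
class Annotation:
    """A latency annotation (expert or estimator) for one trace."""

    trace_id: str
    latency_ms: float
    vpp_uv: float
    annotator: str = "expert"

    def __post_init__(self) -> None:
        if not np.isfinite(self.latency_ms) or self.latency_ms <= 0:
            raise ValueError(
                f"latency_ms must be finite and > 0, got {self.latency_ms} "
                f"for trace {self.trace_id!r}"
            )
        if self.vpp_uv < 0:
            raise ValueError(f"vpp_uv must be >= 0, got {self.vpp_uv}")

    @property
    def amplitude_class(self) -> str:
        return amplitude_class(self.vpp_uv)


def amplitude_class(vpp_uv: float) -> str:
    """Classify a peak-to-peak amplitude as ``low``/``medium``/``high``.

    Low: V_PP <= 100 µV; medium: 100 < V_PP <= 200 µV; high: V_PP > 200 µV.
    The partition is exhaustive and mutually exclusive for any V_PP >= 0.
    """
    if vpp_uv < 0:
        raise ValueError(f"vpp_uv must be >= 0, got {vpp_uv}")
    if vpp_uv <= LOW_MEDIUM_UV:
        return "low"
    if vpp_uv <= MEDIUM_HIGH_UV:
        return "medium"
    return "high"


@dataclass
class AnnotatedDataset:
    """Traces plus annotations keyed by trace_id.

    Every annotation must reference an existing trace; traces without an
    annotation are allowed (e.g. fresh recordings awaiting annotation).
    """

    traces: Dict[str, MepTrace] = field(default_factory=dict)
    annotations: Dict[str, Annotation] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        orphans = sorted(set(self.annotations) - set(self.traces))
        if orphans:
            raise DatasetFormatError(
                f"annotations reference unknown trace ids: {orphans[:5]}"
            )

    @property
    def n_traces(self) -> int:
        return len(self.traces)

    @property
    def subject_ids(self) -> List[str]:
        return sorted({t.subject_id for t in self.traces.values()})

    def subset(self, trace_ids: Iterable[str], provenance: str = "") -> "AnnotatedDataset":
        ids = list(trace_ids)
        missing = [i for i in ids if i not in self.traces]
        if missing:
            raise KeyError(f"unknown trace ids: {missing[:5]}")
        return AnnotatedDataset(
            traces={i: self.traces[i] for i in ids},
            annotations={i: self.annotations[i] for i in ids if i in self.annotations},
            provenance=provenance or self.provenance,
        )

    def class_counts(self) -> Dict[str, int]:
        """Counts of annotated traces per amplitude class."""
        counts = {"low": 0, "medium": 0, "high": 0}
        for ann in self.annotations.values():
            counts[ann.amplitude_class] += 1
        return counts


def vpp(trace: MepTrace) -> float:
    """Peak-to-peak amplitude V_PP in µV over the post-stimulus window.

    Computed as max - min of the samples with t >= 0 ms; the pre-stimulus
    baseline is excluded because the onset-bearing signal is post-stimulus.

    Raises
    ------
    ValueError
        If the trace lies entirely before the stimulus.
    """
    post = trace.samples[trace.times_ms >= 0.0]
    if post.size == 0:
        raise ValueError(
            f"trace {trace.trace_id!r} has no post-stimulus samples; V_PP undefined"
        )
    return float(post.max() - post.min())


def write_dataset(ds: AnnotatedDataset, meta_path, samples_path) -> None:
    """Write a dataset to the meta/samples CSV pair (>= 6 significant digits)."""
    meta_rows = []
    sample_frames = []
    for tid in ds.traces:
        tr = ds.traces[tid]
        ann = ds.annotations.get(tid)
        meta_rows.append(
            {
                "trace_id": tr.trace_id,
                "subject_id": tr.subject_id,
                "muscle": tr.muscle,
                "fs_hz": tr.fs_hz,
                "t_start_ms": tr.t_start_ms,
                "latency_ms": ann.latency_ms if ann is not None else np.nan,
                "vpp_uv": ann.vpp_uv if ann is not None else np.nan,
                "annotator": ann.annotator if ann is not None else "",
            }
        )
        sample_frames.append(
            pd.DataFrame(
                {
                    "trace_id": tr.trace_id,
                    "sample_index": np.arange(tr.n_samples),
                    "amplitude_uv": tr.samples,
                }
            )
        )
    meta_cols = [
        "trace_id", "subject_id", "muscle", "fs_hz", "t_start_ms",
        "latency_ms", "vpp_uv", "annotator",
    ]
    meta = pd.DataFrame(meta_rows, columns=meta_cols)
    meta.to_csv(meta_path, index=False, float_format="%.10g")
    if sample_frames:
        samples = pd.concat(sample_frames, ignore_index=True)
    else:
        samples = pd.DataFrame(columns=["trace_id", "sample_index", "amplitude_uv"])
    samples.to_csv(samples_path, index=False, float_format="%.10g")


def read_dataset(meta_path, samples_path) -> AnnotatedDataset:
    """Read the meta/samples CSV pair written by :func:`write_dataset`.

    Sample order is restored by ``sample_index`` regardless of row order.

    Raises
    ------
    DatasetFormatError
        On missing columns, non-numeric amplitudes (reported with row
        number), or samples referencing a trace_id absent from the meta file.
    """
    meta = pd.read_csv(meta_path, dtype={"trace_id": str, "subject_id": str})
    required = {"trace_id", "subject_id", "muscle", "fs_hz", "t_start_ms",
                "latency_ms", "vpp_uv", "annotator"}
    if not required.issubset(meta.columns):
        raise DatasetFormatError(
            f"meta file missing columns: {sorted(required - set(meta.columns))}"
        )
    samples = pd.read_csv(samples_path, dtype={"trace_id": str})
    if not {"trace_id", "sample_index", "amplitude_uv"}.issubset(samples.columns):
        raise DatasetFormatError("samples file missing required columns")
    amp = pd.to_numeric(samples["amplitude_uv"], errors="coerce")
    bad = np.flatnonzero(amp.isna() & samples["amplitude_uv"].notna())
    if bad.size:
        # +2: header row plus 1-based numbering, matching what an editor shows
        raise DatasetFormatError(
            f"non-numeric amplitude_uv at samples file row {int(bad[0]) + 2}"
        )
    known = set(meta["trace_id"])
    orphan = set(samples["trace_id"]) - known
    if orphan:
        raise DatasetFormatError(
            f"samples reference trace ids absent from meta: {sorted(orphan)[:5]}"
        )

    traces: Dict[str, MepTrace] = {}
    annotations: Dict[str, Annotation] = {}
    grouped = dict(tuple(samples.groupby("trace_id", sort=False)))
    for row in meta.itertuples(index=False):
        tid = row.trace_id
        if tid not in grouped:
            raise DatasetFormatError(f"meta trace {tid!r} has no samples")
        g = grouped[tid].sort_values("sample_index")
        traces[tid] = MepTrace(
            trace_id=tid,
            subject_id=row.subject_id,
            muscle=str(row.muscle),
            fs_hz=float(row.fs_hz),
            t_start_ms=float(row.t_start_ms),
            samples=g["amplitude_uv"].to_numpy(dtype=float),
        )
        if pd.notna(row.latency_ms):
            annotations[tid] = Annotation(
                trace_id=tid,
                latency_ms=float(row.latency_ms),
                vpp_uv=float(row.vpp_uv),
                annotator=str(row.annotator) if pd.notna(row.annotator) else "",
            )
    return AnnotatedDataset(traces=traces, annotations=annotations)
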