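"""Metrics and validation harnesses for latency estimators.

Mean absolute error (MAE) against reference annotations, amplitude-
stratified MAE (low ≤100 µV, medium 100–200 µV, high >200 µV),
error-fraction summaries (|error| < 0.5 and < 1.0 ms), seeded 80/20
train/test splits, within-subject 5-fold cross-validation, and
leave-one-subject-out (LOSO) cross-validation.

Harnesses are estimator-agnostic: they take a fit function
``fit(train_ds) -> predict`` where ``predict(ds) -> {trace_id: latency_ms}``.

Discarded estimates (e.g. epochs Bigoni's method cannot annotate) are
excluded pairwise in single-estimator reports; multi-estimator comparison
tables instead restrict every method to the traces kept by *all* methods,
so the MAEs are computed on a common n.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from delmep.baselines import LatencyEstimate
from delmep.mep_io import AnnotatedDataset, amplitude_class

__all__ = [
    "EvalReport",
    "mae",
    "split_train_test",
    "kfold_within_subject",
    "leave_one_subject_out",
    "stratify_errors",
    "comparison_table",
    "FitFunction",
    "PredictFunction",
]

PredictFunction = Callable[[AnnotatedDataset], Dict[str, float]]
FitFunction = Callable[[AnnotatedDataset], PredictFunction]

#: |error| thresholds (ms) of the error-fraction summaries.
ERROR_THRESHOLDS_MS = (0.5, 1.0)


@dataclass
class EvalReport:
    """Evaluation summary for one estimator (or one CV harness run).

    ``summary`` holds the across-fold/subject mean and SD of MAE; the SD is
    the population SD (divisor n), recorded in ``metadata['sd_kind']``.
    ``error_table`` has one row per scored trace: trace_id, vpp_uv,
    true_latency_ms, pred_latency_ms, abs_error_ms — the input of an
    error-vs-amplitude/latency map.
    """

    n_total: int = 0
    n_discarded: int = 0
    mae_ms: float = float("nan")
    mae_by_class: Dict[str, float] = field(default_factory=dict)
    n_by_class: Dict[str, int] = field(default_factory=dict)
    frac_err_below: Dict[float, float] = field(default_factory=dict)
    per_fold: List[Tuple[str, float]] = field(default_factory=list)
    summary: Dict[str, float] = field(default_factory=dict)
    error_table: Optional[pd.DataFrame] = None
    metadata: Dict[str, object] = field(default_factory=dict)


def mae(pred: Sequence[float], truth: Sequence[float]) -> float:
    """Mean absolute error in ms between paired latency sequences."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    if p.size == 0:
        raise ValueError("MAE of an empty set is undefined")
    return float(np.mean(np.abs(p - t)))


def _kept_latency(est: Union[float, LatencyEstimate]) -> Optional[float]:
    if isinstance(est, LatencyEstimate):
        return None if est.discarded else est.latency_ms
    return float(est)


def split_train_test(
    ds: AnnotatedDataset, ratio: float = 0.8, seed: int = 0
) -> Tuple[AnnotatedDataset, AnnotatedDataset]:
    """Seeded disjoint/exhaustive split; train gets floor(ratio·n) traces."""
    if ds.n_traces < 5:
        raise ValueError(f"need at least 5 traces to split, got {ds.n_traces}")
    ids = sorted(ds.traces)
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    n_train = int(np.floor(ratio * len(ids)))
    return (
        ds.subset(ids[:n_train], provenance=f"{ds.provenance} [train]"),
        ds.subset(ids[n_train:], provenance=f"{ds.provenance} [test]"),
    )


def _fold_blocks(ids: List[str], k: int, rng: np.random.Generator) -> List[List[str]]:
    """Seeded shuffle then contiguous blocks; remainder spread one per leading fold."""
    ids = list(ids)
    rng.shuffle(ids)
    base, rem = divmod(len(ids), k)
    folds = []
    start = 0
    for f in range(k):
        size = base + (1 if f < rem else 0)
        folds.append(ids[start:start + size])
        start += size
    return folds


def _population_sd(values: Sequence[float]) -> float:
    return float(np.std(np.asarray(values, dtype=float)))  # ddof=0


def kfold_within_subject(
    ds: AnnotatedDataset,
    fit: FitFunction,
    k: int = 5,
    seed: int = 0,
) -> Dict[str, EvalReport]:
    """Per-subject k-fold CV: train on k-1 folds of a subject, score the rest.

    Every trace of a subject appears in exactly one validation fold.
    Returns one report per subject with per-fold MAEs plus their mean and
    population SD.
    """
    reports: Dict[str, EvalReport] = {}
    by_subject: Dict[str, List[str]] = {}
    for tid, tr in ds.traces.items():
        if tid in ds.annotations:
            by_subject.setdefault(tr.subject_id, []).append(tid)
    for subject in sorted(by_subject):
        ids = sorted(by_subject[subject])
        if len(ids) < k:
            raise ValueError(
                f"subject {subject!r} has {len(ids)} annotated traces; "
                f"needs >= k={k} for {k}-fold CV"
            )
        rng = np.random.default_rng(seed)
        folds = _fold_blocks(ids, k, rng)
        per_fold: List[Tuple[str, float]] = []
        for f, val_ids in enumerate(folds):
            train_ids = [i for i in ids if i not in set(val_ids)]
            predict = fit(ds.subset(train_ids))
            preds = predict(ds.subset(val_ids))
            fold_mae = mae(
                [preds[i] for i in val_ids],
                [ds.annotations[i].latency_ms for i in val_ids],
            )
            per_fold.append((f"fold{f + 1}", fold_mae))
        maes = [m for _, m in per_fold]
        reports[subject] = EvalReport(
            n_total=len(ids),
            mae_ms=float(np.mean(maes)),
            per_fold=per_fold,
            summary={"mean_mae_ms": float(np.mean(maes)),
                     "sd_mae_ms": _population_sd(maes)},
            metadata={"harness": "kfold_within_subject", "k": k,
                      "seed": seed, "sd_kind": "population"},
        )
    return reports


def leave_one_subject_out(ds: AnnotatedDataset, fit: FitFunction) -> EvalReport:
    """LOSO CV: for each subject, train on all others and score that subject."""
    subjects = ds.subject_ids
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs >= 2 subjects")
    per_subject: List[Tuple[str, float]] = []
    for subject in subjects:
        test_ids = sorted(
            tid for tid, tr in ds.traces.items()
            if tr.subject_id == subject and tid in ds.annotations
        )
        train_ids = sorted(
            tid for tid, tr in ds.traces.items()
            if tr.subject_id != subject and tid in ds.annotations
        )
        predict = fit(ds.subset(train_ids))
        preds = predict(ds.subset(test_ids))
        s_mae = mae(
            [preds[i] for i in test_ids],
            [ds.annotations[i].latency_ms for i in test_ids],
        )
        per_subject.append((subject, s_mae))
    maes = [m for _, m in per_subject]
    return EvalReport(
        n_total=sum(1 for tid in ds.annotations),
        mae_ms=float(np.mean(maes)),
        per_fold=per_subject,
        summary={"mean_mae_ms": float(np.mean(maes)),
                 "sd_mae_ms": _population_sd(maes)},
        metadata={"harness": "leave_one_subject_out",
                  "n_subjects": len(subjects), "sd_kind": "population"},
    )


def stratify_errors(
    estimates: Mapping[str, Union[float, LatencyEstimate]],
    ds: AnnotatedDataset,
    thresholds_ms: Sequence[float] = ERROR_THRESHOLDS_MS,
) -> EvalReport:
    """Single-estimator report: overall and amplitude-stratified MAE,
    error fractions, and the per-trace error table.

    Discarded estimates and traces without a reference annotation are
    excluded pairwise and counted in ``n_discarded`` / ``metadata``.
    """
    rows = []
    n_discarded = 0
    for tid, est in estimates.items():
        if tid not in ds.annotations:
            continue
        lat = _kept_latency(est)
        if lat is None:
            n_discarded += 1
            continue
        ann = ds.annotations[tid]
        rows.append(
            {
                "trace_id": tid,
                "vpp_uv": ann.vpp_uv,
                "true_latency_ms": ann.latency_ms,
                "pred_latency_ms": lat,
                "abs_error_ms": abs(lat - ann.latency_ms),
                "amplitude_class": amplitude_class(ann.vpp_uv),
            }
        )
    if not rows:
        raise ValueError("no scorable (kept and annotated) estimates")
    table = pd.DataFrame(rows)
    err = table["abs_error_ms"].to_numpy()
    mae_by_class: Dict[str, float] = {}
    n_by_class: Dict[str, int] = {}
    for cls in ("low", "medium", "high"):
        sel = table["amplitude_class"] == cls
        n_by_class[cls] = int(sel.sum())
        mae_by_class[cls] = float(err[sel].mean()) if sel.any() else float("nan")
    return EvalReport(
        n_total=len(rows) + n_discarded,
        n_discarded=n_discarded,
        mae_ms=float(err.mean()),
        mae_by_class=mae_by_class,
        n_by_class=n_by_class,
        frac_err_below={thr: float(np.mean(err < thr)) for thr in thresholds_ms},
        error_table=table,
        metadata={"sd_kind": "population"},
    )


def comparison_table(
    estimates_by_method: Mapping[str, Mapping[str, Union[float, LatencyEstimate]]],
    ds: AnnotatedDataset,
) -> pd.DataFrame:
    """Multi-estimator comparison on the common kept-trace set.

    Traces discarded by *any* method (or missing a reference annotation)
    are removed from all methods, so every row reports an MAE over the same
    n.  Columns: mae_low_ms, mae_medium_ms, mae_high_ms, mae_all_ms, n,
    n_discarded_own (how many the method itself discarded before
    intersection).
    """
    kept_ids = None
    own_discards: Dict[str, int] = {}
    for method, ests in estimates_by_method.items():
        kept = {tid for tid, e in ests.items()
                if tid in ds.annotations and _kept_latency(e) is not None}
        own_discards[method] = sum(
            1 for tid, e in ests.items()
            if tid in ds.annotations and _kept_latency(e) is None
        )
        kept_ids = kept if kept_ids is None else (kept_ids & kept)
    if not kept_ids:
        raise ValueError("no trace kept by every method")
    rows = []
    for method, ests in estimates_by_method.items():
        sub = {tid: ests[tid] for tid in kept_ids}
        rep = stratify_errors(sub, ds)
        rows.append(
            {
                "method": method,
                "mae_low_ms": rep.mae_by_class["low"],
                "mae_medium_ms": rep.mae_by_class["medium"],
                "mae_high_ms": rep.mae_by_class["high"],
                "mae_all_ms": rep.mae_ms,
                "n": rep.n_total,
                "n_discarded_own": own_discards[method],
            }
        )
    return pd.DataFrame(rows).set_index("method")
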