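import numpy as np
import pytest

from delmep.baselines import LatencyEstimate
from delmep.evaluation import (
    comparison_table,
    kfold_within_subject,
    leave_one_subject_out,
    mae,
    split_train_test,
    stratify_errors,
)
from delmep.mep_io import AnnotatedDataset, Annotation, MepTrace
from delmep.synthetic import SyntheticConfig, generate_dataset


def oracle_fit(train_ds):
    """Perfect predictor: answers with the reference annotation."""

    def predict(test_ds):
        return {tid: ann.latency_ms for tid, ann in test_ds.annotations.items()}

    return predict


def _dataset(n_subjects=3, traces_per_subject=20, seed=0):
    cfg = SyntheticConfig(n_subjects=n_subjects,
                          traces_per_subject=traces_per_subject,
                          epoch_ms=(-50.0, 100.0), seed=seed)
    return generate_dataset(cfg)


def _toy_dataset(errors_and_vpps):
    """Dataset plus predictions with prescribed absolute errors and V_PP."""
    traces, annotations, preds = {}, {}, {}
    for i, (err, v) in enumerate(errors_and_vpps):
        tid = f"t{i}"
        traces[tid] = MepTrace(tid, f"s{i % 2}", "APB", 3000.0, 0.0,
                               np.linspace(0, 10, 30))
        annotations[tid] = Annotation(tid, 20.0, v)
        preds[tid] = 20.0 + err
    return AnnotatedDataset(traces=traces, annotations=annotations), preds


class TestMae:
    def test_perfect_zero(self):
        assert mae([20.0, 25.0], [20.0, 25.0]) == 0.0

    def test_constant_offset(self):
        assert mae([21.0, 26.0], [20.0, 25.0]) == pytest.approx(1.0)

    def test_hand_example(self):
        assert mae([20.0, 25.0], [21.0, 23.0]) == pytest.approx(1.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mae([], [])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mae([1.0], [1.0, 2.0])


class TestSplit:
    def test_sizes_floor_rule(self):
        ds = _dataset(1, 10)
        tr, te = split_train_test(ds, 0.8, seed=0)
        assert (tr.n_traces, te.n_traces) == (8, 2)

    def test_disjoint_and_exhaustive(self):
        ds = _dataset(2, 15)
        tr, te = split_train_test(ds, 0.8, seed=1)
        assert set(tr.traces) | set(te.traces) == set(ds.traces)
        assert set(tr.traces) & set(te.traces) == set()

    def test_seeded_repeatability(self):
        ds = _dataset(2, 15)
        a = split_train_test(ds, 0.8, seed=7)
        b = split_train_test(ds, 0.8, seed=7)
        assert set(a[0].traces) == set(b[0].traces)
        c = split_train_test(ds, 0.8, seed=8)
        assert set(a[0].traces) != set(c[0].traces)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(_dataset(1, 4), 0.8, seed=0)


class TestKFold:
    def test_fold_sizes_and_coverage(self):
        ds = _dataset(1, 100)
        seen = []

        def spy_fit(train_ds):
            predict = oracle_fit(train_ds)

            def spy_predict(test_ds):
                seen.append(set(test_ds.traces))
                return predict(test_ds)

            return spy_predict

        reports = kfold_within_subject(ds, spy_fit, k=5, seed=0)
        assert len(seen) == 5
        assert all(len(fold) == 20 for fold in seen)
        # pairwise disjoint, union covers the subject
        union = set()
        for fold in seen:
            assert not (union & fold)
            union |= fold
        assert union == set(ds.traces)
        (rep,) = reports.values()
        assert rep.summary["mean_mae_ms"] == 0.0
        assert rep.summary["sd_mae_ms"] == 0.0

    def test_remainder_spread_over_leading_folds(self):
        ds = _dataset(1, 23)
        sizes = []

        def spy_fit(train_ds):
            def spy_predict(test_ds):
                sizes.append(test_ds.n_traces)
                return oracle_fit(train_ds)(test_ds)

            return spy_predict

        kfold_within_subject(ds, spy_fit, k=5, seed=0)
        assert sorted(sizes, reverse=True) == [5, 5, 5, 4, 4]

    def test_small_subject_named_in_error(self):
        ds = _dataset(2, 3)
        with pytest.raises(ValueError, match="s00"):
            kfold_within_subject(ds, oracle_fit, k=5)


class TestLoso:
    def test_one_evaluation_per_subject(self):
        ds = _dataset(9, 6)
        rep = leave_one_subject_out(ds, oracle_fit)
        assert len(rep.per_fold) == 9
        assert rep.mae_ms == 0.0
        assert rep.summary["sd_mae_ms"] == 0.0

    def test_test_subject_never_in_training(self):
        ds = _dataset(4, 8)
        pairs = []

        def spy_fit(train_ds):
            train_subjects = set(train_ds.subject_ids)

            def spy_predict(test_ds):
                pairs.append((train_subjects, set(test_ds.subject_ids)))
                return oracle_fit(train_ds)(test_ds)

            return spy_predict

        leave_one_subject_out(ds, spy_fit)
        assert len(pairs) == 4
        for train_subjects, test_subjects in pairs:
            assert len(test_subjects) == 1
            assert not (train_subjects & test_subjects)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            leave_one_subject_out(_dataset(1, 10), oracle_fit)


class TestStratifyErrors:
    def test_error_fractions_hand_count(self):
        ds, preds = _toy_dataset([(0.2, 50), (0.4, 150), (-0.7, 300), (1.5, 500)])
        rep = stratify_errors(preds, ds)
        assert rep.frac_err_below[0.5] == pytest.approx(0.5)
        assert rep.frac_err_below[1.0] == pytest.approx(0.75)
        assert rep.frac_err_below[0.5] <= rep.frac_err_below[1.0]

    def test_all_high_amplitude(self):
        ds, preds = _toy_dataset([(0.1, 300), (0.3, 400), (0.5, 500)])
        rep = stratify_errors(preds, ds)
        assert rep.n_by_class == {"low": 0, "medium": 0, "high": 3}
        assert np.isnan(rep.mae_by_class["low"])
        assert rep.mae_ms == pytest.approx(rep.mae_by_class["high"])

    def test_overall_is_count_weighted_stratum_mean(self):
        ds, preds = _toy_dataset(
            [(0.2, 50), (0.6, 80), (0.4, 150), (1.0, 300), (2.0, 400)]
        )
        rep = stratify_errors(preds, ds)
        weighted = sum(
            rep.mae_by_class[c] * rep.n_by_class[c]
            for c in ("low", "medium", "high")
        ) / sum(rep.n_by_class.values())
        assert rep.mae_ms == pytest.approx(weighted)

    def test_discarded_excluded_pairwise(self):
        ds, preds = _toy_dataset([(0.2, 50), (0.4, 150), (0.6, 300)])
        ests = {
            "t0": LatencyEstimate("t0", "bigoni", discarded=True, reason="run"),
            "t1": LatencyEstimate("t1", "bigoni", latency_ms=preds["t1"]),
            "t2": LatencyEstimate("t2", "bigoni", latency_ms=preds["t2"]),
        }
        rep = stratify_errors(ests, ds)
        assert rep.n_discarded == 1
        assert rep.n_total == 3
        assert rep.mae_ms == pytest.approx(0.5)

    def test_comparison_restricts_to_common_kept_set(self):
        ds, preds = _toy_dataset([(0.2, 50), (0.4, 150), (0.6, 300), (0.8, 400)])
        a = {tid: LatencyEstimate(tid, "a", latency_ms=v)
             for tid, v in preds.items()}
        b = dict(a)
        b["t0"] = LatencyEstimate("t0", "b", discarded=True, reason="run")
        b = {tid: LatencyEstimate(tid, "b", discarded=e.discarded,
                                  latency_ms=e.latency_ms, reason=e.reason)
             for tid, e in b.items()}
        table = comparison_table({"a": a, "b": b}, ds)
        assert (table["n"] == 3).all()
        assert table.loc["b", "n_discarded_own"] == 1


def test_mean_predictor_mae_matches_distribution_mad():
    """The trivial mean-latency predictor's MAE equals the mean absolute
    deviation of the latency distribution (~(b-a)/4 for uniform onsets)."""
    cfg = SyntheticConfig(n_subjects=300, traces_per_subject=3,
                          subject_latency_sd_ms=0.1,
                          epoch_ms=(-50.0, 100.0), seed=6)
    ds = generate_dataset(cfg)
    y = np.array([a.latency_ms for a in ds.annotations.values()])
    pred = np.full(y.size, y.mean())
    got = mae(pred, y)
    assert got == pytest.approx(np.abs(y - y.mean()).mean(), abs=1e-12)
    lo, hi = cfg.latency_range_ms
    assert got == pytest.approx((hi - lo) / 4.0, rel=0.15)
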