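"""Grid enumeration, metric formulas, CV behavior, and model selection."""

import numpy as np
import pytest

from epiqsar.datasets import RegulatorModule
from epiqsar.featurization import DescriptorSet
from epiqsar.models import (
    Algorithm,
    ConfusionCounts,
    CVReport,
    GridEntry,
    GridResult,
    MetricsReport,
    ModelConfig,
    auc_score,
    compute_confusion,
    compute_metrics,
    cross_validate,
    enumerate_grid,
    evaluate_grid,
    evaluate_on,
    select_best,
    train_classifier,
)


def test_full_grid_is_180_configs():
    configs = enumerate_grid()
    assert len(configs) == 180
    assert len(set(configs)) == 180


@pytest.mark.parametrize(
    "n_mod,n_alg,n_set,expected", [(1, 1, 1, 1), (2, 3, 2, 12)]
)
def test_grid_product_arithmetic(n_mod, n_alg, n_set, expected):
    configs = enumerate_grid(
        list(RegulatorModule)[:n_mod], list(Algorithm)[:n_alg], list(DescriptorSet)[:n_set]
    )
    assert len(configs) == expected


def test_grid_empty_list_errors():
    with pytest.raises(ValueError, match="algorithms"):
        enumerate_grid(list(RegulatorModule), [], list(DescriptorSet))


def test_confusion_hand_cases():
    c = compute_confusion([1, 1, 0, 0], [1, 1, 0, 0])
    assert (c.TP, c.TN, c.FP, c.FN) == (2, 2, 0, 0)
    c = compute_confusion([1, 0], [0, 1])
    assert (c.TP, c.TN, c.FP, c.FN) == (0, 0, 1, 1)


def test_confusion_matches_bruteforce_oracle():
    rng = np.random.default_rng(0)
    y_true = rng.integers(0, 2, 100)
    y_pred = rng.integers(0, 2, 100)
    c = compute_confusion(y_true, y_pred)
    pairs = list(zip(y_true, y_pred))
    assert c.TP == sum(1 for t, p in pairs if t == 1 and p == 1)
    assert c.TN == sum(1 for t, p in pairs if t == 0 and p == 0)
    assert c.FP == sum(1 for t, p in pairs if t == 0 and p == 1)
    assert c.FN == sum(1 for t, p in pairs if t == 1 and p == 0)


def test_confusion_length_mismatch():
    with pytest.raises(ValueError):
        compute_confusion([1, 0], [1])


def test_metrics_hand_checked_case():
    rep = compute_metrics(ConfusionCounts(TP=6, TN=5, FP=3, FN=2))
    assert rep.ACC == pytest.approx(0.6875)
    assert rep.PPV == pytest.approx(0.6667, abs=1e-4)
    assert rep.Recall == pytest.approx(0.75)
    assert rep.F1 == pytest.approx(0.7059, abs=1e-4)
    assert rep.MCC == pytest.approx(0.3780, abs=1e-4)


def test_metrics_perfect_classifier():
    rep = compute_metrics(ConfusionCounts(TP=10, TN=10, FP=0, FN=0))
    assert rep.ACC == rep.F1 == rep.MCC == 1.0


def test_metrics_match_direct_formulas_on_random_tables():
    rng = np.random.default_rng(42)
    for _ in range(200):
        tp, tn, fp, fn = (int(v) for v in rng.integers(0, 30, 4))
        if tp + tn + fp + fn == 0:
            continue
        rep = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
        n = tp + tn + fp + fn
        assert rep.ACC == pytest.approx((tp + tn) / n, abs=1e-12)
        if tp + fp:
            assert rep.PPV == pytest.approx(tp / (tp + fp), abs=1e-12)
        if tp + fn:
            assert rep.Recall == pytest.approx(tp / (tp + fn), abs=1e-12)
        den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        if den:
            assert rep.MCC == pytest.approx((tp * tn - fp * fn) / den**0.5, abs=1e-12)


def test_degenerate_metrics_flagged_not_nan():
    rep = compute_metrics(ConfusionCounts(TP=0, TN=5, FP=0, FN=5))
    assert rep.PPV == 0.0 and "PPV" in rep.degenerate_flags
    assert rep.AUC == 0.0 and "AUC" in rep.degenerate_flags
    assert np.isfinite(list(rep.as_dict().values())).all()


def test_mcc_symmetric_under_class_swap():
    rng = np.random.default_rng(1)
    for _ in range(50):
        tp, tn, fp, fn = (int(v) + 1 for v in rng.integers(0, 20, 4))
        a = compute_metrics(ConfusionCounts(tp, tn, fp, fn)).MCC
        b = compute_metrics(ConfusionCounts(tn, tp, fn, fp)).MCC
        assert a == pytest.approx(b, abs=1e-12)


def test_auc_perfect_ranking():
    assert auc_score([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0


def test_auc_equals_trapezoidal_roc_integration():
    """Rank-statistic AUC vs an independent ROC-curve integration."""
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(7)
    for _ in range(100):
        n = int(rng.integers(10, 60))
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            continue
        scores = np.round(rng.normal(size=n), 1)  # ties on purpose
        assert auc_score(y, scores) == pytest.approx(roc_auc_score(y, scores), abs=1e-12)


def _config(algorithm, dset=DescriptorSet.MACCS_FP, seed=0):
    return ModelConfig(
        module=RegulatorModule.MIR34A, algorithm=algorithm, descriptor_set=dset, seed=seed
    )


@pytest.mark.parametrize("algorithm", list(Algorithm), ids=lambda a: a.value)
def test_separable_toy_perfect_training_accuracy(algorithm):
    rng = np.random.default_rng(2)
    X = rng.integers(0, 2, size=(40, 6)).astype(float)
    y = X[:, 0].astype(int)  # label = one feature
    if len(np.unique(y)) < 2:
        pytest.skip("degenerate draw")
    clf = train_classifier(_config(algorithm), X, y)
    assert (clf.predict_label(X) == y).mean() == 1.0


def test_constant_features_predict_majority():
    X = np.ones((30, 4))
    X[:, 0] = np.arange(30) % 2  # keep one informative-free but varying column
    y = np.array([1] * 20 + [0] * 10)
    clf = train_classifier(_config(Algorithm.GNB), X, y)
    acc = (clf.predict_label(X) == y).mean()
    assert acc == pytest.approx(max((y == 1).mean(), (y == 0).mean()), abs=0.2)


def test_training_deterministic_given_seed():
    rng = np.random.default_rng(3)
    X = rng.integers(0, 2, size=(60, 12)).astype(float)
    y = rng.integers(0, 2, 60)
    for algorithm in (Algorithm.ANN, Algorithm.RF, Algorithm.XGB):
        a = train_classifier(_config(algorithm, seed=9), X, y).predict_score(X)
        b = train_classifier(_config(algorithm, seed=9), X, y).predict_score(X)
        assert np.array_equal(a, b)


def test_single_class_training_errors():
    X = np.random.default_rng(0).normal(size=(10, 3))
    with pytest.raises(ValueError):
        train_classifier(_config(Algorithm.GNB), X, np.ones(10, dtype=int))


def test_cross_validate_ten_folds_and_determinism():
    rng = np.random.default_rng(4)
    X = rng.integers(0, 2, size=(200, 20)).astype(float)
    y = np.array([0, 1] * 100)
    cfg = _config(Algorithm.GNB, seed=5)
    report = cross_validate(cfg, X, y, folds=10)
    assert report.n_folds == 10
    report2 = cross_validate(cfg, X, y, folds=10)
    assert [r.as_dict() for r in report.fold_reports] == [
        r.as_dict() for r in report2.fold_reports
    ]


def test_cross_validate_small_class_errors():
    X = np.random.default_rng(0).normal(size=(20, 3))
    y = np.array([1] * 5 + [0] * 15)
    with pytest.raises(ValueError, match="folds"):
        cross_validate(_config(Algorithm.GNB), X, y, folds=10)


def _entry(config, values):
    rep = MetricsReport(**values)
    cv = CVReport(fold_reports=[rep], mean=rep.as_dict(), std={m: 0.0 for m in rep.as_dict()})
    return GridEntry(config=config, cv=cv, test=rep)


def _values(acc, auc=0.5, ppv=0.5, rec=0.5, f1=0.5, mcc=0.0):
    return {"ACC": acc, "AUC": auc, "PPV": ppv, "Recall": rec, "F1": f1, "MCC": mcc}


def test_select_best_single_and_dominant():
    c1 = _config(Algorithm.GNB)
    c2 = _config(Algorithm.RF)
    single = GridResult(entries=[_entry(c1, _values(0.6))])
    assert select_best(single, RegulatorModule.MIR34A) == c1
    grid = GridResult(
        entries=[
            _entry(c1, _values(0.6, auc=0.6, f1=0.6, mcc=0.2)),
            _entry(c2, _values(0.9, auc=0.9, f1=0.9, mcc=0.8)),
        ]
    )
    assert select_best(grid, RegulatorModule.MIR34A) == c2


def test_select_best_matches_bruteforce_ranking():
    rng = np.random.default_rng(8)
    entries = []
    for algorithm in Algorithm:
        vals = _values(*np.round(rng.uniform(0.3, 1.0, 6), 3))
        entries.append(_entry(_config(algorithm), vals))
    grid = GridResult(entries=entries)
    chosen = select_best(grid, RegulatorModule.MIR34A)

    def composite(e):
        sel = ["ACC", "AUC", "F1", "MCC"]
        avg = {m: 0.5 * (e.cv.mean[m] + getattr(e.test, m)) for m in sel}
        return (np.mean([avg[m] for m in sel]), avg["MCC"], avg["AUC"])

    best = max(range(len(entries)), key=lambda i: composite(entries[i]) + (-i,))
    assert chosen == entries[best].config


def test_select_best_no_successful_entries():
    grid = GridResult(entries=[GridEntry(config=_config(Algorithm.GNB), error="boom")])
    with pytest.raises(ValueError):
        select_best(grid, RegulatorModule.MIR34A)


def test_one_config_grid_consistent_with_direct_calls():
    rng = np.random.default_rng(10)
    X = rng.integers(0, 2, size=(100, 15)).astype(float)
    y = np.array([0, 1] * 50)
    module = RegulatorModule.HDAC
    cfg = ModelConfig(module=module, algorithm=Algorithm.GNB,
                      descriptor_set=DescriptorSet.MACCS_FP, seed=4)
    result = evaluate_grid({(module, DescriptorSet.MACCS_FP): X}, {module: y},
                           configs=[cfg], folds=5, seed=4)
    assert len(result.entries) == 1 and result.entries[0].error is None
    from epiqsar.datasets import split_train_test

    split = split_train_test(y, seed=4)
    cv = cross_validate(cfg, X[split.train_indices], y[split.train_indices], folds=5)
    clf = train_classifier(cfg, X[split.train_indices], y[split.train_indices])
    test = evaluate_on(clf, X[split.test_indices], y[split.test_indices])
    entry = result.entries[0]
    assert entry.cv.mean == cv.mean
    assert entry.test.as_dict() == test.as_dict()


def test_grid_failure_recorded_not_raised():
    module = RegulatorModule.HDAC
    X = np.zeros((20, 3))
    y = np.ones(20, dtype=int)  # single class: every config must fail
    cfg = ModelConfig(module=module, algorithm=Algorithm.GNB,
                      descriptor_set=DescriptorSet.MACCS_FP, seed=0)
    result = evaluate_grid({(module, DescriptorSet.MACCS_FP): X}, {module: y},
                           configs=[cfg], folds=5, seed=0)
    assert result.entries[0].error is not None
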