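"""Evaluation protocol: balancing, metrics, leakage-free LOOCV."""

import numpy as np
import pytest

from namts.evaluate import (
    EvalConfig,
    average_roc,
    build_dataset,
    horizon_curve,
    loocv,
    metrics_at_fpr,
    modality_importance,
    single_modality_suite,
    undersample,
    auroc,
)
from namts.synthgen import cohort_summary
from namts.sigio import EventAnnotation
from namts.windowing import WindowingConfig


def brute_force_auroc(scores, labels):
    """O(n^2) pairwise oracle: P(pos > neg) + 0.5 P(tie)."""
    scores, labels = np.asarray(scores), np.asarray(labels)
    pos, neg = scores[labels == 1], scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            wins += p > q
            ties += p == q
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def test_auroc_examples_and_errors():
    assert auroc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]) == 1.0
    assert auroc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5
    assert auroc([0.9, 0.4, 0.6, 0.2], [1, 0, 0, 1]) == 0.5
    with pytest.raises(ValueError):
        auroc([0.1, 0.2], [1, 1])


def test_auroc_matches_pairwise_oracle_sample():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = int(rng.integers(4, 30))
        labels = np.zeros(n, dtype=int)
        labels[: int(rng.integers(1, n))] = 1
        rng.shuffle(labels)
        if labels.min() == labels.max():
            continue
        scores = np.round(rng.uniform(size=n), 1)  # coarse -> ties occur
        assert auroc(scores, labels) == pytest.approx(
            brute_force_auroc(scores, labels), abs=1e-12
        )


def test_undersample_balances_each_patient():
    y = np.array([1] * 10 + [0] * 40 + [1] * 9 + [0] * 5)
    g = np.array(["a"] * 50 + ["b"] * 14)
    idx = undersample(y, g, seed=0)
    ya, yb = y[idx][g[idx] == "a"], y[idx][g[idx] == "b"]
    assert (ya == 1).sum() == 10 and (ya == 0).sum() == 10
    assert (yb == 1).sum() == 5 and (yb == 0).sum() == 5  # majority = targets
    np.testing.assert_array_equal(idx, undersample(y, g, seed=0))
    assert not np.array_equal(idx, undersample(y, g, seed=1))


def test_undersample_excludes_single_class_patient(caplog):
    y = np.array([1, 1, 1, 0, 1])
    g = np.array(["a", "a", "a", "b", "b"])
    idx = undersample(y, g, seed=0)
    assert set(g[idx]) == {"b"}
    with pytest.raises(ValueError):
        undersample(np.ones(4), np.array(["a"] * 4), seed=0)


def test_metrics_at_fpr_enumeration():
    tpr, prec, conf = metrics_at_fpr([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0], 0.0)
    assert (tpr, prec) == (0.5, 1.0)
    np.testing.assert_array_equal(conf, [[2, 0], [1, 1]])
    tpr, prec, _ = metrics_at_fpr([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0], 0.2)
    assert (tpr, prec) == (1.0, 1.0)


def test_metrics_at_fpr_null_behavior():
    rng = np.random.default_rng(1)
    n = 4000
    scores, labels = rng.uniform(size=n), rng.integers(0, 2, n)
    for target in (0.1, 0.2, 0.3):
        tpr, _, _ = metrics_at_fpr(scores, labels, target)
        assert tpr == pytest.approx(target, abs=0.04)


@pytest.fixture(scope="module")
def fast_eval_dataset(tiny_cohort):
    _, recordings, ann_lists, _ = tiny_cohort
    return build_dataset(recordings, ann_lists, WindowingConfig())


FAST = {"epochs": 3}


def test_loocv_protocol_and_leakage_audit(fast_eval_dataset):
    ds = fast_eval_dataset
    cfg = EvalConfig(seed=3, collect_explanations=True, permutation_test=True,
                     n_perm=99, model_params=FAST)
    report = loocv(ds, "nam", [{"kernel_size": 9, "hidden_channels": 8}], cfg)
    patients = set(np.unique(ds.groups))
    assert {p.patient for p in report.patients} == patients
    for p in report.patients:
        # held-out windows never in the training pool
        assert p.patient not in p.train_patients
        assert set(p.train_patients) == patients - {p.patient}
        assert p.n_test == (ds.groups == p.patient).sum()
        assert 0.0 <= p.auroc <= 1.0
        assert p.chosen_params["kernel_size"] == 9
        assert p.permutation is not None and 0 < p.permutation.p_value <= 1
        assert p.patient in report.explanations
    # aggregate statistics are pure functions of the per-patient entries
    agg = report.aggregate()
    assert agg["mean_auroc"] == pytest.approx(np.mean([p.auroc for p in report.patients]))
    assert agg["sd_auroc"] == pytest.approx(np.std([p.auroc for p in report.patients]))
    tprs = [p.metrics[0.2][0] for p in report.patients]
    assert agg["tpr_at_fpr_0.2"]["median"] == pytest.approx(np.median(tprs))
    grid, mean_tpr, sd_tpr = average_roc(report)
    assert grid.shape == mean_tpr.shape == sd_tpr.shape == (101,)
    assert mean_tpr[0] <= mean_tpr[-1]


def test_loocv_nested_selection_tie_break(fast_eval_dataset):
    cfg = EvalConfig(seed=1, inner_folds=2, model_params={"epochs": 1})
    grid = [{"kernel_size": 9, "hidden_channels": 8},
            {"kernel_size": 5, "hidden_channels": 8}]
    report = loocv(fast_eval_dataset, "nam", grid, cfg)
    for p in report.patients:
        assert p.chosen_params["kernel_size"] in (5, 9)


def test_loocv_baselines_and_errors(fast_eval_dataset):
    report = loocv(fast_eval_dataset, "logreg", None, EvalConfig(seed=0))
    assert 0.0 <= report.mean_auroc <= 1.0
    with pytest.raises(ValueError, match="at least 3"):
        ds = fast_eval_dataset
        mask = np.isin(ds.groups, np.unique(ds.groups)[:2])
        from namts.evaluate import WindowDataset
        small = WindowDataset(ds.X[mask], ds.y[mask], ds.groups[mask],
                              ds.start_s[mask])
        loocv(small, "logreg", None, EvalConfig())
    with pytest.raises(ValueError, match="grid"):
        loocv(fast_eval_dataset, "nam", [], EvalConfig())


def test_horizon_curve_singleton_matches_plain_loocv(tiny_cohort):
    _, recordings, ann_lists, _ = tiny_cohort
    cfg = EvalConfig(seed=2, model_params=FAST)
    curve = horizon_curve(recordings, ann_lists, [15.0], WindowingConfig(),
                          "logreg", None, cfg)
    assert set(curve) == {15.0}
    ds = build_dataset(recordings, ann_lists, WindowingConfig(horizon_s=15.0))
    plain = loocv(ds, "logreg", None, cfg)
    np.testing.assert_allclose(curve[15.0].patient_aurocs, plain.patient_aurocs)


def test_modality_importance_report(fast_eval_dataset):
    cfg = EvalConfig(seed=5, collect_explanations=True, model_params=FAST)
    report = loocv(fast_eval_dataset, "nam",
                   [{"kernel_size": 9, "hidden_channels": 8}], cfg)
    imp = modality_importance(report.explanations)
    assert set(imp.pooled_sd) == set(imp.ranking)
    assert list(imp.per_patient_sd.columns) == list(
        next(iter(report.explanations.values())).modalities
    )
    # pooled sd recomputable from the stored contributions
    pooled = np.concatenate([e.contributions for e in report.explanations.values()])
    for j, m in enumerate(next(iter(report.explanations.values())).modalities):
        assert imp.pooled_sd[m] == pytest.approx(pooled[:, j].std())
    # an untrained zeroed model has no contribution spread
    from namts.models import build_nam
    zero = build_nam(seed=0).zero_parameters()
    z = zero.explain(fast_eval_dataset.X[:10])
    assert all(v == 0.0 for v in
               modality_importance({"p": z}).pooled_sd.values())


def test_single_modality_suite_subsets(fast_eval_dataset):
    cfg = EvalConfig(seed=6, model_params={"epochs": 1})
    out = single_modality_suite(fast_eval_dataset, ["NP", ("NP", "TA")],
                                [{"kernel_size": 5, "hidden_channels": 4}], cfg)
    assert set(out) == {"NP", ("NP", "TA")}
    for rep in out.values():
        assert len(rep.patients) == 3


def test_cohort_summary_edge_cases():
    assert cohort_summary([[]], 3600.0).iloc[0]["events_per_h"] == 0.0
    df = cohort_summary([[EventAnnotation("central_apnea", 100.0, 105.0)]], 3600.0)
    assert df.iloc[0]["events_per_h"] == 1.0
    assert df.iloc[0]["median_event_duration_s"] == 5.0
    with pytest.raises(ValueError):
        cohort_summary([[]], 0.0)
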