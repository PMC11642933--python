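"""Additive-model identities, training behavior, baselines."""

import numpy as np
import pytest
from sklearn.model_selection import cross_val_score

from namts.models import (
    BlackboxFCNClassifier,
    HyperParams,
    NAMClassifier,
    build_blackbox,
    build_nam,
    fit_baseline,
    nam_forward,
    train_model,
)
from namts.preprocess import MODALITIES, modality_slices
from namts.evaluate import auroc


def random_X(n=12, seed=0):
    return np.random.default_rng(seed).normal(size=(n, 540))


def separable_X(n=100, seed=0):
    """Targets carry an oscillation in NP; controls are white noise."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 540))
    y = (np.arange(n) % 2).astype(int)
    t = np.arange(150) / 5.0
    sl = modality_slices(30.0)["NP"]
    for i in np.flatnonzero(y):
        s = np.sin(2 * np.pi * 0.9 * t + rng.uniform(0, 2 * np.pi))
        X[i, sl] = (s - s.mean()) / s.std()
    return X, y


def test_exact_additivity_and_map_identity():
    model = build_nam(seed=3)
    exp = model.explain(random_X())
    np.testing.assert_array_equal(
        exp.logits, exp.contributions.sum(axis=1) + exp.bias
    )
    for j, m in enumerate(exp.modalities):
        np.testing.assert_allclose(
            exp.activation_maps[m].mean(axis=1), exp.contributions[:, j],
            rtol=0, atol=1e-12,
        )
    np.testing.assert_allclose(exp.probabilities, 1 / (1 + np.exp(-exp.logits)))
    # single-prediction view carries the same decomposition
    p0 = exp[0]
    assert p0.logit == pytest.approx(sum(p0.contributions.values()) + p0.bias)


def test_perturbing_one_modality_changes_only_its_contribution():
    Xtr, ytr = separable_X(40, seed=4)
    model = NAMClassifier(random_state=4, epochs=2).fit(Xtr, ytr)
    X = random_X(6, seed=1)
    base = model.explain(X)
    X2 = X.copy()
    X2[:, modality_slices(30.0)["SPO2"]] += 0.5
    pert = model.explain(X2)
    j = MODALITIES.index("SPO2")
    for k, m in enumerate(MODALITIES):
        if k == j:
            assert np.all(pert.contributions[:, k] != base.contributions[:, k])
        else:
            np.testing.assert_array_equal(pert.contributions[:, k],
                                          base.contributions[:, k])
    np.testing.assert_allclose(
        pert.logits - base.logits,
        pert.contributions[:, j] - base.contributions[:, j],
        atol=1e-12,
    )


def test_zeroed_model_predicts_half():
    model = build_nam(seed=0).zero_parameters()
    exp = model.explain(random_X())
    np.testing.assert_array_equal(exp.contributions, 0.0)
    np.testing.assert_array_equal(exp.probabilities, 0.5)


def test_build_nam_variants_and_seed_determinism():
    assert len(build_nam(HyperParams(), seed=0).subnets_) == 6
    reduced = build_nam(HyperParams(modalities=("NP", "TA", "SPO2")), seed=0)
    assert set(reduced.subnets_) == {"NP", "TA", "SPO2"}
    with pytest.raises(ValueError):
        build_nam(HyperParams(modalities=()), seed=0)
    with pytest.raises(ValueError):
        HyperParams(kernel_size=8)
    a, b = build_nam(seed=9), build_nam(seed=9)
    for pa, pb in zip(a._params(), b._params()):
        np.testing.assert_array_equal(pa.value, pb.value)


def test_training_determinism_and_lr_zero():
    X, y = separable_X(60, seed=2)
    m1 = NAMClassifier(random_state=5, epochs=2).fit(X, y)
    m2 = NAMClassifier(random_state=5, epochs=2).fit(X, y)
    assert m1.loss_curve_ == m2.loss_curve_
    np.testing.assert_array_equal(m1.decision_function(X), m2.decision_function(X))

    # full-batch training keeps batch statistics identical across epochs,
    # so with lr=0 the parameters stay at init and the loss is constant
    frozen = NAMClassifier(random_state=5, epochs=3, lr=0.0,
                           batch_size=len(X)).fit(X, y)
    init = build_nam(seed=5)
    for pa, pb in zip(frozen._params(), init._params()):
        np.testing.assert_array_equal(pa.value, pb.value)
    # constant up to float32 summation order (batches are reshuffled)
    assert frozen.loss_curve_[0] == pytest.approx(frozen.loss_curve_[-1], rel=1e-5)


def test_training_separates_synthetic_classes():
    X, y = separable_X(120, seed=3)
    model = NAMClassifier(random_state=0).fit(X, y)
    assert auroc(model.predict_proba(X)[:, 1], y) > 0.95


def test_single_class_fit_rejected():
    X = random_X(10)
    with pytest.raises(ValueError, match="both classes"):
        NAMClassifier(random_state=0).fit(X, np.zeros(10, dtype=int))
    with pytest.raises(ValueError, match="both classes"):
        train_model(BlackboxFCNClassifier(random_state=0), X, np.ones(10, dtype=int))


def test_blackbox_forward_shapes_and_determinism():
    model = build_blackbox(seed=1)
    X = random_X(8)
    z1 = model.decision_function(X)
    z2 = model.decision_function(X)
    np.testing.assert_array_equal(z1, z2)
    model._forward_batch(X.astype(np.float32), training=False)
    assert model._feat.shape == (8, 120)  # 6 modalities x 20 channels
    p = model.predict_proba(X)
    assert p.shape == (8, 2)
    np.testing.assert_allclose(p.sum(axis=1), 1.0)


def test_nam_forward_wrapper_and_shape_validation():
    model = build_nam(seed=2)
    exp = nam_forward(model, random_X(3))
    assert len(exp) == 3
    with pytest.raises(ValueError):
        model.decision_function(np.zeros((2, 10)))
    with pytest.raises(ValueError):
        model.fit(np.zeros((4, 10)), np.array([0, 1, 0, 1]))


def test_fit_baseline_contracts():
    rng = np.random.default_rng(0)
    F = rng.normal(size=(80, 24))
    margin = F[:, 0] + F[:, 1]
    F, margin = F[np.abs(margin) > 0.5], margin[np.abs(margin) > 0.5]
    y = (margin > 0).astype(int)
    clf = fit_baseline("logreg", F, y)
    assert (clf.predict(F) == y).mean() == 1.0

    y_perm = rng.permutation(y)
    scores = cross_val_score(
        fit_baseline("logreg", F, y_perm), F, y_perm, cv=5, scoring="roc_auc"
    )
    assert 0.3 < scores.mean() < 0.7

    m1 = fit_baseline("mlp", F, y, seed=7)
    m2 = fit_baseline("mlp", F, y, seed=7)
    np.testing.assert_array_equal(m1.predict_proba(F), m2.predict_proba(F))
    with pytest.raises(ValueError):
        fit_baseline("logreg", F, np.zeros(80))
    with pytest.raises(ValueError):
        fit_baseline("tree", F, y)
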