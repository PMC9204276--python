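"""Feature vectors, mean imputation and the second-stage backends."""

import numpy as np
import pytest
from scipy import stats

from tnbk.nbk import train
from tnbk.two_phase import (
    ALGORITHMS,
    Phase2Classifier,
    SlotMeanImputer,
    TissueFeatureVector,
    build_feature_vectors,
    impute,
    predict_phase2,
    train_phase2,
)

TISSUES = [f"t{i}" for i in range(23)]


def _models(tissues):
    # distinct but arbitrary Phase I models; AAAA-ish vs CCCC-ish classes
    m = train(["AAAAAAA", "CCCCCCC"], ["c1", "c0"], k=2)
    return {t: m for t in tissues}


def test_feature_vector_has_25_elements_in_23_tissue_design():
    vectors = build_feature_vectors(
        _models(TISSUES), {"g1": "AAACAAA"}, ["g1"], "t0", TISSUES
    )
    (v,) = vectors
    assert len(v.predictions) == 23
    assert v.n_elements == 25
    assert not v.missing_slots


def test_missing_measurements_propagate_to_slots():
    measured = {t: {"g1"} for t in TISSUES}
    for t in ("t3", "t7", "t9"):
        measured[t] = set()
    (v,) = build_feature_vectors(
        _models(TISSUES), {"g1": "AAACAAA"}, ["g1"], "t0", TISSUES, measured
    )
    assert v.missing_slots == [3, 7, 9]


def test_two_assigned_tissues_share_slots():
    models = _models(TISSUES)
    seqs = {"g1": "AAACAAA"}
    (a,) = build_feature_vectors(models, seqs, ["g1"], "t0", TISSUES)
    (b,) = build_feature_vectors(models, seqs, ["g1"], "t5", TISSUES)
    assert a.predictions == b.predictions
    assert (a.assigned_tissue, b.assigned_tissue) == ("t0", "t5")


def test_missing_model_errors():
    models = _models(TISSUES[:-1])
    with pytest.raises(ValueError, match="no Phase I model"):
        build_feature_vectors(models, {"g1": "AAA"}, ["g1"], "t0", TISSUES)


# ------------------------------------------------------------- imputation

def test_impute_uses_slot_mean():
    vs = [TissueFeatureVector("g1", (1.0, np.nan), "t0")]
    (out,) = impute(vs, np.array([0.2, 0.7]))
    assert out.predictions == (1.0, 0.7)


def test_impute_identity_when_complete():
    vs = [TissueFeatureVector("g1", (1.0, 0.0), "t0")]
    (out,) = impute(vs, np.array([0.5, 0.5]))
    assert out.predictions == (1.0, 0.0)


def test_imputer_all_missing_slot_falls_back_half():
    X = np.array([[1.0, np.nan], [0.0, np.nan]])
    with pytest.warns(UserWarning, match="no training observations"):
        imp = SlotMeanImputer().fit(X)
    assert imp.means_[1] == 0.5
    assert imp.means_[0] == 0.5  # mean of 1 and 0


def test_imputer_layout_mismatch_errors():
    imp = SlotMeanImputer().fit(np.zeros((3, 4)))
    with pytest.raises(ValueError, match="expected 4 slots"):
        imp.transform(np.zeros((2, 5)))


# ---------------------------------------------------------------- backends

def _vectors(X, tissue="t0"):
    return [TissueFeatureVector(f"g{i}", tuple(row), tissue) for i, row in enumerate(X)]


def test_single_class_labels_error():
    vs = _vectors(np.zeros((4, 3)))
    with pytest.raises(ValueError, match="single-class"):
        train_phase2(vs, ["c1"] * 4)


def test_decision_tree_fits_separable_data():
    rng = np.random.default_rng(0)
    y = np.array(["c0", "c1"] * 40)
    X = np.where((y == "c1")[:, None], 1.0, 0.0) * np.ones((80, 5))
    model = train_phase2(_vectors(X), y, algorithm="DT", random_state=0)
    assert (predict_phase2(model, _vectors(X)) == y).all()


def test_constant_slot_tolerated():
    rng = np.random.default_rng(1)
    X = rng.integers(0, 2, size=(60, 4)).astype(float)
    X[:, 2] = 1.0
    y = np.where(X[:, 0] > 0.5, "c1", "c0")
    for alg in ALGORITHMS:
        model = train_phase2(_vectors(X), y, algorithm=alg, random_state=0)
        assert len(predict_phase2(model, _vectors(X))) == 60


def test_knn_symmetry_under_label_and_feature_flip():
    rng = np.random.default_rng(2)
    X = rng.integers(0, 2, size=(50, 6)).astype(float)
    y = np.where(rng.random(50) < 0.5, "c1", "c0")
    m1 = train_phase2(_vectors(X), y, algorithm="KNN")
    m2 = train_phase2(_vectors(1.0 - X), np.where(y == "c1", "c0", "c1"), algorithm="KNN")
    q = rng.integers(0, 2, size=(20, 6)).astype(float)
    p1 = predict_phase2(m1, _vectors(q))
    p2 = predict_phase2(m2, _vectors(1.0 - q))
    assert (p1 != p2).all()


def test_predict_layout_mismatch_errors():
    model = train_phase2(_vectors(np.eye(4)), ["c0", "c1", "c0", "c1"])
    with pytest.raises(ValueError, match="layout"):
        model.predict(_vectors(np.zeros((2, 5))))
    with pytest.raises(ValueError, match="unknown assigned tissue"):
        model.predict(_vectors(np.zeros((1, 4)), tissue="nowhere"))


def test_mean_vector_input_tolerated():
    model = train_phase2(_vectors(np.eye(4)), ["c0", "c1", "c0", "c1"])
    out = model.predict(_vectors(np.full((1, 4), 0.5)))
    assert out[0] in ("c0", "c1")


def test_imputation_means_fitted_attribute():
    X = np.array([[1.0, np.nan], [0.0, 1.0], [1.0, 0.0]])
    model = train_phase2(_vectors(X), ["c1", "c0", "c1"], algorithm="BN")
    assert model.imputation_means_[1] == pytest.approx(0.5)


def test_random_labels_cross_validated_near_chance():
    """Features independent of labels give ~0.5 accuracy out of fold."""
    rng = np.random.default_rng(3)
    n = 500
    X = rng.integers(0, 2, size=(n, 23)).astype(float)
    y = np.array(["c0", "c1"] * (n // 2))
    vs = _vectors(X)
    from sklearn.model_selection import StratifiedKFold
    hits = 0
    for tr, te in StratifiedKFold(5, shuffle=True, random_state=0).split(X, y):
        m = train_phase2([vs[i] for i in tr], y[tr], algorithm="DT", random_state=0)
        hits += (predict_phase2(m, [vs[i] for i in te]) == y[te]).sum()
    assert abs(hits / n - 0.5) <= 0.05


def test_planted_majority_structure_gain():
    """Stacking beats the single-tissue readout when the assigned label is
    a noisy majority of five correlated tissue labels and slot errors are
    independent."""
    rng = np.random.default_rng(7)
    n, T, rho = 1500, 23, 0.8
    zq = stats.norm.ppf(0.5)
    U = rng.standard_normal(n)
    Z = np.sqrt(rho) * U[:, None] + np.sqrt(1 - rho) * rng.standard_normal((n, T))
    labels = (Z > zq).astype(int)
    # assigned label: noisy majority of tissues 1..5
    maj = (labels[:, 1:6].sum(axis=1) >= 3).astype(int)
    flip = rng.random(n) < 0.1
    y_num = np.where(flip, 1 - maj, maj)
    y = np.where(y_num == 1, "c1", "c0")
    # slots: noisy readouts of each tissue's label (independent errors)
    slot_acc = 0.75
    slots = np.where(rng.random((n, T)) < slot_acc, labels, 1 - labels).astype(float)
    # slot 0 reads the assigned label itself, equally noisily: Phase I analogue
    slots[:, 0] = np.where(rng.random(n) < slot_acc, y_num, 1 - y_num)
    vs = _vectors(slots)

    def f_measure(pred, truth):
        tp = ((pred == "c1") & (truth == "c1")).sum()
        fp = ((pred == "c1") & (truth == "c0")).sum()
        fn = ((pred == "c0") & (truth == "c1")).sum()
        return 2 * tp / (2 * tp + fp + fn)

    from sklearn.model_selection import StratifiedKFold
    phase1_preds = np.where(slots[:, 0] > 0.5, "c1", "c0")
    f1 = f_measure(phase1_preds, y)
    preds = np.empty(n, dtype=object)
    for tr, te in StratifiedKFold(5, shuffle=True, random_state=0).split(slots, y):
        m = train_phase2([vs[i] for i in tr], y[tr], algorithm="BN")
        preds[te] = predict_phase2(m, [vs[i] for i in te])
    f2 = f_measure(preds.astype(str), y)
    assert f2 - f1 >= 0.05
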