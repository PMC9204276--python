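"""Phase II: cross-tissue feature vectors and the second-stage classifier.

Each gene's Phase I predictions across all tissues form a feature vector:
one 0/1 slot per tissue (NaN where the gene has no measured value in that
tissue's labeled data), plus the gene id and the name of the tissue whose
label is being predicted.  In the 23-tissue study design that is 25
elements per vector.  The gene id is provenance only and is never a
learned feature; the assigned tissue enters the feature matrix one-hot.

Missing slots are mean-imputed with per-slot means computed on training
vectors only; a slot never observed in training falls back to 0.5.  The
second-stage backend is one of four classical learners (naive-structure
Bayes network, decision tree, 1-nearest-neighbour, linear-kernel SVM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.naive_bayes import BernoulliNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .nbk import KmerNaiveBayes

ALGORITHMS = ("BN", "DT", "KNN", "SVM")

MISSING = float("nan")


@dataclass(frozen=True)
class TissueFeatureVector:
    """Per-(gene, assigned tissue) record of cross-tissue predictions.

    ``predictions`` is ordered like the study's tissue list; entries are
    0.0, 1.0 or NaN (missing).  ``n_elements`` counts gene id + slots +
    assigned tissue, i.e. 25 in the 23-tissue design.
    """

    gene_id: str
    predictions: tuple[float, ...]
    assigned_tissue: str

    @property
    def n_elements(self) -> int:
        return len(self.predictions) + 2

    @property
    def missing_slots(self) -> list[int]:
        return [i for i, v in enumerate(self.predictions) if np.isnan(v)]


def build_feature_vectors(
    phase1_models: Mapping[str, KmerNaiveBayes],
    sequences: Mapping[str, str],
    genes: Sequence[str],
    assigned_tissue: str,
    tissues: Sequence[str],
    measured: Mapping[str, frozenset[str] | set[str]] | None = None,
) -> list[TissueFeatureVector]:
    """Featurize ``genes`` with one Phase I model per tissue.

    ``measured`` maps each tissue to the genes with a measured value
    there; a gene's slot for a tissue it is not measured in is NaN.  When
    ``measured`` is None every slot is filled.  The caller is responsible
    for the out-of-fold contract: models must have been trained without
    the genes being featurized (see ``experiments.cross_validate``).
    """
    missing_models = [t for t in tissues if t not in phase1_models]
    if missing_models:
        raise ValueError(f"no Phase I model for tissues: {missing_models}")
    seqs = [sequences[g] for g in genes]
    slots = np.full((len(genes), len(tissues)), np.nan)
    for col, tissue in enumerate(tissues):
        model = phase1_models[tissue]
        preds = model.predict(seqs)
        numeric = (preds == model.classes_[1]).astype(float)
        if measured is not None:
            ok = np.array([g in measured[tissue] for g in genes])
            numeric[~ok] = np.nan
        slots[:, col] = numeric
    return [
        TissueFeatureVector(g, tuple(slots[i]), assigned_tissue)
        for i, g in enumerate(genes)
    ]


def slot_matrix(vectors: Sequence[TissueFeatureVector]) -> np.ndarray:
    return np.array([v.predictions for v in vectors], dtype=float)


class SlotMeanImputer(TransformerMixin, BaseEstimator):
    """Replace NaN slots with the per-slot training mean.

    Means are computed only from the vectors passed to :meth:`fit`; a
    slot with no observed training value falls back to 0.5 (maximal
    uncertainty between the two prediction states) with a warning.
    """

    def fit(self, X: np.ndarray, y=None) -> "SlotMeanImputer":
        X = np.asarray(X, dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            means = np.nanmean(X, axis=0)
        empty = np.isnan(means)
        if empty.any():
            warnings.warn(
                f"slots {np.flatnonzero(empty).tolist()} have no training "
                "observations; imputing 0.5"
            )
            means = np.where(empty, 0.5, means)
        self.means_ = means
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "means_")
        X = np.asarray(X, dtype=float).copy()
        if X.shape[1] != self.means_.size:
            raise ValueError(f"expected {self.means_.size} slots, got {X.shape[1]}")
        nan = np.isnan(X)
        X[nan] = np.broadcast_to(self.means_, X.shape)[nan]
        return X


def impute(vectors: Sequence[TissueFeatureVector], means: np.ndarray
           ) -> list[TissueFeatureVector]:
    """Fill missing slots with the supplied per-slot training means."""
    imp = SlotMeanImputer()
    imp.means_ = np.asarray(means, dtype=float)
    filled = imp.transform(slot_matrix(vectors))
    return [
        TissueFeatureVector(v.gene_id, tuple(row), v.assigned_tissue)
        for v, row in zip(vectors, filled)
    ]


def _make_backend(algorithm: str, random_state: int | None):
    if algorithm == "BN":
        return BernoulliNB(binarize=0.5)
    if algorithm == "DT":
        return DecisionTreeClassifier(random_state=random_state, ccp_alpha=0.002)
    if algorithm == "KNN":
        return KNeighborsClassifier(n_neighbors=1)
    if algorithm == "SVM":
        return SVC(kernel="linear", C=1.0, random_state=random_state)
    raise ValueError(f"algorithm must be one of {ALGORITHMS}, got {algorithm!r}")


class Phase2Classifier(ClassifierMixin, BaseEstimator):
    """Second-stage classifier over tissue feature vectors.

    Parameters
    ----------
    algorithm : {"BN", "DT", "KNN", "SVM"}, default "BN"
        Backend family: Bernoulli naive-structure Bayes network, pruned
        decision tree, 1-nearest-neighbour, or linear-kernel SVM.
    tissues : sequence of str, optional
        Slot layout; inferred from the training vectors' slot count when
        omitted (slots then named positionally).
    random_state : int, optional

    The learned features are the imputed tissue slots plus a one-hot
    encoding of the assigned tissue; the gene id is deliberately not a
    feature.
    """

    def __init__(self, algorithm: str = "BN", tissues: Sequence[str] | None = None,
                 random_state: int | None = None):
        self.algorithm = algorithm
        self.tissues = tissues
        self.random_state = random_state

    def _feature_matrix(self, vectors: Sequence[TissueFeatureVector],
                        slots: np.ndarray) -> np.ndarray:
        onehot = np.zeros((len(vectors), len(self.tissue_index_)))
        for i, v in enumerate(vectors):
            try:
                onehot[i, self.tissue_index_[v.assigned_tissue]] = 1.0
            except KeyError:
                raise ValueError(f"unknown assigned tissue {v.assigned_tissue!r}") from None
        return np.hstack([slots, onehot])

    def fit(self, vectors: Sequence[TissueFeatureVector], y: Sequence) -> "Phase2Classifier":
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}")
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError(f"training labels are single-class: {classes.tolist()}")
        self.classes_ = classes
        n_slots = len(vectors[0].predictions)
        if any(len(v.predictions) != n_slots for v in vectors):
            raise ValueError("inconsistent slot counts across vectors")
        self.n_slots_ = n_slots
        names = list(self.tissues) if self.tissues is not None else [
            f"slot{i}" for i in range(n_slots)
        ]
        if len(names) != n_slots:
            raise ValueError(f"{len(names)} tissue names for {n_slots} slots")
        seen = sorted({v.assigned_tissue for v in vectors})
        self.tissue_index_ = {t: i for i, t in enumerate(
            names if self.tissues is not None else seen
        )}
        self.imputer_ = SlotMeanImputer().fit(slot_matrix(vectors))
        X = self._feature_matrix(vectors, self.imputer_.transform(slot_matrix(vectors)))
        self.backend_ = _make_backend(self.algorithm, self.random_state).fit(X, y)
        return self

    def predict(self, vectors: Sequence[TissueFeatureVector]) -> np.ndarray:
        check_is_fitted(self, "backend_")
        if any(len(v.predictions) != self.n_slots_ for v in vectors):
            raise ValueError(f"vectors do not match the trained layout of {self.n_slots_} slots")
        X = self._feature_matrix(vectors, self.imputer_.transform(slot_matrix(vectors)))
        return self.backend_.predict(X)

    @property
    def imputation_means_(self) -> np.ndarray:
        return self.imputer_.means_


def train_phase2(vectors: Sequence[TissueFeatureVector], labels: Sequence,
                 algorithm: str = "BN", tissues: Sequence[str] | None = None,
                 random_state: int | None = None) -> Phase2Classifier:
    """Fit a :class:`Phase2Classifier` (imputation means from these vectors)."""
    return Phase2Classifier(algorithm=algorithm, tissues=tissues,
                            random_state=random_state).fit(list(vectors), labels)


def predict_phase2(model: Phase2Classifier, vectors: Iterable[TissueFeatureVector]) -> np.ndarray:
    return model.predict(list(vectors))
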