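"""Experiment grid, cross-validation and evaluation reports.

A configuration names one classifier: phase (I or II), input sequence
type, label type, tissue, k, cutoff (direction + percent) and, for Phase
II, the backend algorithm.  The full grid over 23 tissues is
23 x 5 (k) x 12 (cutoffs) x 2 (inputs) x 2 (label types) = 5,520 Phase I
configurations and four times that, 22,080, for Phase II.

Evaluation is stratified 10-fold cross-validation on a balanced labeled
set, with confusion counts pooled over folds before metrics are computed
(micro-averaging; stabler than per-fold means at small n).  Phase II
folds are nested: the held-out genes are featurized by Phase I models
trained with those genes excluded, and the training-fold vectors are
themselves produced out-of-fold via an inner split, so no gene's slots
ever come from a model that saw its label.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .kmer import KmerCorpus
from .labeling import BOTTOM, PERCENTS, POSITIVE, TOP, LabeledSet, balanced_labeled_set
from .nbk import KmerNaiveBayes
from .two_phase import ALGORITHMS, Phase2Classifier, TissueFeatureVector, build_feature_vectors

PHASES = ("I", "II")
INPUTS = ("PROMOTER", "PROTEIN")
LABEL_TYPES = ("RA", "PA")
K_RANGE = (3, 4, 5, 6, 7)


def config_seed(*parts) -> int:
    """Deterministic per-configuration RNG seed (CRC32 of the key, < 2**31)."""
    return zlib.crc32("|".join(str(p) for p in parts).encode()) & 0x7FFFFFFF


@dataclass(frozen=True)
class ExperimentConfig:
    phase: str
    input: str
    label_type: str
    tissue: str
    k: int
    direction: str
    percent: int
    algorithm: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if self.phase == "II":
            if self.algorithm not in ALGORITHMS:
                raise ValueError("Phase II configs need an algorithm in " + str(ALGORITHMS))
        elif self.algorithm is not None:
            raise ValueError("Phase I configs carry no algorithm")
        if self.k not in K_RANGE:
            raise ValueError(f"k must be in {K_RANGE}, got {self.k}")
        if self.percent not in PERCENTS:
            raise ValueError(f"percent must be in {PERCENTS}, got {self.percent}")


def enumerate_grid(tissues: Sequence[str], phase: str,
                   ks: Sequence[int] = K_RANGE,
                   inputs: Sequence[str] = INPUTS,
                   label_types: Sequence[str] = LABEL_TYPES,
                   percents: Sequence[int] = PERCENTS,
                   algorithms: Sequence[str] = ALGORITHMS) -> list[ExperimentConfig]:
    """Cartesian experiment grid in deterministic order.

    Phase I: inputs x label types x tissues x k x (top/bottom x percents);
    Phase II: the same times the backend algorithms.
    """
    if not tissues:
        raise ValueError("tissue list must be non-empty")
    algs: Sequence[str | None] = algorithms if phase == "II" else (None,)
    out = []
    for inp in inputs:
        for lab in label_types:
            for tissue in tissues:
                for k in ks:
                    for direction in (TOP, BOTTOM):
                        for percent in percents:
                            for alg in algs:
                                seed = config_seed(phase, inp, lab, tissue, k,
                                                   direction, percent, alg)
                                out.append(ExperimentConfig(
                                    phase, inp, lab, tissue, int(k), direction,
                                    int(percent), alg, seed))
    return out


# ------------------------------------------------------------------- metrics

def metrics(tp: int, fp: int, fn: int, tn: int) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, F1) from confusion counts.

    Precision, recall and F default to 0 when their denominator is 0;
    an empty confusion table is an error.
    """
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + fp + fn + tn
    if total == 0:
        raise ValueError("empty confusion table")
    accuracy = (tp + tn) / total
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return accuracy, precision, recall, f


@dataclass(frozen=True)
class EvalReport:
    """Pooled cross-validation outcome of one configuration."""

    config: ExperimentConfig
    tp: int
    fp: int
    fn: int
    tn: int
    folds: int

    @property
    def accuracy(self) -> float:
        return metrics(self.tp, self.fp, self.fn, self.tn)[0]

    @property
    def precision(self) -> float:
        return metrics(self.tp, self.fp, self.fn, self.tn)[1]

    @property
    def recall(self) -> float:
        return metrics(self.tp, self.fp, self.fn, self.tn)[2]

    @property
    def f_measure(self) -> float:
        return metrics(self.tp, self.fp, self.fn, self.tn)[3]

    @property
    def n_evaluated(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


# --------------------------------------------------------------- data bundle

@dataclass
class DataBundle:
    """Everything one cross-validation run needs.

    ``sequences`` maps gene id to residues (one input type); ``measured``
    maps tissue to the genes with a present measurement there (slots for
    other genes are missing in Phase II vectors).  When ``measured`` is
    None, labeled-set membership is used.
    """

    sequences: Mapping[str, str]
    alphabet: str
    labeled_sets: Mapping[str, LabeledSet]
    measured: Mapping[str, frozenset[str]] | None = None

    @property
    def tissues(self) -> list[str]:
        return list(self.labeled_sets)

    def measured_genes(self, tissue: str) -> frozenset[str]:
        if self.measured is not None:
            return frozenset(self.measured[tissue])
        return frozenset(self.labeled_sets[tissue].genes)


def bundle_from_study(study, direction: str = TOP, percent: int = 5,
                      seed: int = 0) -> DataBundle:
    """Label and balance a :class:`~tnbk.synthetic.SyntheticStudy`."""
    matrix = study.expression
    labeled = {
        t: balanced_labeled_set(matrix, t, direction, percent,
                                seed=config_seed(seed, t, direction, percent))
        for t in matrix.tissues
    }
    measured = {t: matrix.measured_genes(t) for t in matrix.tissues}
    return DataBundle(study.sequences, study.design.alphabet, labeled, measured)


# ------------------------------------------------------------ cross-validate

def _effective_folds(y: np.ndarray, folds: int) -> int:
    smallest = min(int((y == c).sum()) for c in np.unique(y))
    if smallest < folds:
        warnings.warn(f"only {smallest} members in the smallest class; "
                      f"reducing folds from {folds} to {smallest}")
        return smallest
    return folds


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    pos_t, pos_p = y_true == POSITIVE, y_pred == POSITIVE
    tp = int((pos_t & pos_p).sum())
    fp = int((~pos_t & pos_p).sum())
    fn = int((pos_t & ~pos_p).sum())
    tn = int((~pos_t & ~pos_p).sum())
    return tp, fp, fn, tn


def cross_validate(config: ExperimentConfig, bundle: DataBundle, folds: int = 10,
                   alpha: float = 1.0, inner_folds: int = 3) -> EvalReport:
    """Stratified k-fold evaluation of one configuration.

    Phase I trains one NB(k) per fold and scores the held-out genes.
    Phase II additionally trains, per fold, one NB(k) per tissue on the
    in-fold genes only, featurizes the held-out genes with them, builds
    the training vectors through an inner ``inner_folds`` split (so
    training slots are also out-of-fold), and fits the backend on those.
    Confusion counts are pooled over folds.  Identical seeds give
    identical fold assignments and reports.
    """
    ls = bundle.labeled_sets[config.tissue]
    if len(ls) == 0:
        raise ValueError(f"empty labeled set for tissue {config.tissue!r}")
    genes = ls.genes
    y = ls.labels
    folds = _effective_folds(y, folds)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.seed)

    if config.phase == "I":
        corpus = KmerCorpus.build([bundle.sequences[g] for g in genes],
                                  config.k, bundle.alphabet)
        tp = fp = fn = tn = 0
        for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
            model = KmerNaiveBayes(k=config.k, alpha=alpha, alphabet=bundle.alphabet)
            model.fit(corpus.select(train_idx), y[train_idx])
            preds = model.predict(corpus.select(test_idx))
            d = _confusion(y[test_idx], preds)
            tp, fp, fn, tn = tp + d[0], fp + d[1], fn + d[2], tn + d[3]
        return EvalReport(config, tp, fp, fn, tn, folds)

    return _cross_validate_phase2(config, bundle, skf, y, genes, alpha, inner_folds)


def _fit_tissue_models(bundle: DataBundle, config: ExperimentConfig, alpha: float,
                       corpus: KmerCorpus, row_of: Mapping[str, int],
                       excluded: frozenset[str]) -> dict[str, KmerNaiveBayes]:
    """One NB(k) per tissue, trained on that tissue's labeled set minus
    ``excluded`` (the out-of-fold leak guard)."""
    models: dict[str, KmerNaiveBayes] = {}
    for tissue, ls in bundle.labeled_sets.items():
        keep = [(g, c) for g, c in ls.members if g not in excluded]
        labels = np.array([c for _, c in keep])
        if np.unique(labels).size < 2:
            raise ValueError(
                f"tissue {tissue!r}: excluding the featurized genes leaves a "
                "single-class training set; labeled set too small for nesting"
            )
        rows = np.array([row_of[g] for g, _ in keep])
        model = KmerNaiveBayes(k=config.k, alpha=alpha, alphabet=bundle.alphabet)
        model.fit(corpus.select(rows), labels)
        model.training_genes_ = frozenset(g for g, _ in keep)
        models[tissue] = model
    return models


def _cross_validate_phase2(config: ExperimentConfig, bundle: DataBundle,
                           skf: StratifiedKFold, y: np.ndarray, genes: list[str],
                           alpha: float, inner_folds: int) -> EvalReport:
    tissues = bundle.tissues
    all_genes = sorted({g for ls in bundle.labeled_sets.values() for g in ls.genes}
                       | set(genes))
    row_of = {g: i for i, g in enumerate(all_genes)}
    corpus = KmerCorpus.build([bundle.sequences[g] for g in all_genes],
                              config.k, bundle.alphabet)
    measured = {t: bundle.measured_genes(t) for t in tissues}

    def featurize(target_genes: list[str], excluded: frozenset[str]
                  ) -> list[TissueFeatureVector]:
        models = _fit_tissue_models(bundle, config, alpha, corpus, row_of, excluded)
        # leak guard: no featurized gene may appear in any model's training set
        assert all(g not in models[t].training_genes_
                   for t in tissues for g in target_genes)
        seq_rows = {g: bundle.sequences[g] for g in target_genes}
        return build_feature_vectors(models, seq_rows, target_genes,
                                     config.tissue, tissues, measured)

    tp = fp = fn = tn = 0
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        test_genes = [genes[i] for i in test_idx]
        train_genes = [genes[i] for i in train_idx]
        y_train = y[train_idx]

        test_vectors = featurize(test_genes, frozenset(test_genes))

        inner = StratifiedKFold(n_splits=inner_folds, shuffle=True,
                                random_state=config.seed + 1)
        train_vectors: list[TissueFeatureVector] = []
        train_labels: list[str] = []
        for _, part_idx in inner.split(np.zeros(len(y_train)), y_train):
            part_genes = [train_genes[i] for i in part_idx]
            train_vectors.extend(
                featurize(part_genes, frozenset(test_genes) | frozenset(part_genes)))
            train_labels.extend(y_train[part_idx])

        clf = Phase2Classifier(algorithm=config.algorithm, tissues=tissues,
                               random_state=config.seed)
        clf.fit(train_vectors, np.array(train_labels))
        preds = clf.predict(test_vectors)
        d = _confusion(np.array([y[i] for i in test_idx]), preds)
        tp, fp, fn, tn = tp + d[0], fp + d[1], fn + d[2], tn + d[3]
    return EvalReport(config, tp, fp, fn, tn, skf.get_n_splits())


# -------------------------------------------------------------------- report

_LONG_COLUMNS = ["phase", "input", "label_type", "tissue", "k", "direction",
                 "percent", "algorithm", "folds", "tp", "fp", "fn", "tn",
                 "accuracy", "precision", "recall", "f_measure"]


def report(reports: Sequence[EvalReport]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format results plus a wide per-tissue FM/AC summary.

    Duplicate configurations keep the last occurrence (with a warning).
    Returns ``(long, wide)``; both are empty for empty input.
    """
    rows = []
    for r in reports:
        c = r.config
        rows.append((c.phase, c.input, c.label_type, c.tissue, c.k, c.direction,
                     c.percent, c.algorithm or "", r.folds, r.tp, r.fp, r.fn, r.tn,
                     r.accuracy, r.precision, r.recall, r.f_measure))
    long = pd.DataFrame(rows, columns=_LONG_COLUMNS)
    if long.empty:
        return long, pd.DataFrame()
    key = ["phase", "input", "label_type", "tissue", "k", "direction", "percent",
           "algorithm"]
    if long.duplicated(subset=key).any():
        warnings.warn("duplicate configurations in report; keeping the last of each")
        long = long.drop_duplicates(subset=key, keep="last").reset_index(drop=True)
    wide = long.pivot_table(index="tissue",
                            columns=["phase", "input", "label_type"],
                            values=["f_measure", "accuracy"], aggfunc="last")
    wide = wide.rename(columns={"f_measure": "FM", "accuracy": "AC"})
    return long, wide
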