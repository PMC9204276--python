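"""The NB(k) classifier: a naive-Bayes view of an order-(k-1) Markov chain.

For a sequence S = s_1..s_n over alphabet A and class c, the class score
is

    log P(c) + sum_{i=1..n-k+1} log P_a(s_i..s_{i+k-1} | c, k)
             - sum_{i=2..n-k+1} log P_a(s_i..s_{i+k-2} | c, k-1)

where P_a is the additively smoothed (pseudocount ``alpha``) class
frequency of the k-mer, respectively (k-1)-mer.  Dividing out the shared
(k-1)-letter overlaps of consecutive k-mers removes the double counting a
plain product of k-mer probabilities would commit; at k = 1 the second
sum is empty and the score is the ordinary single-letter naive Bayes.

The default denominator range stops at offset n-k+1 ("shared"); the
variant running through n-k+2 ("full"), which additionally divides by the
trailing (k-1)-mer, is available via the ``denominator`` parameter.  The
two differ by one boundary term and correspond to conditioning the Markov
likelihood on the leading, respectively trailing, k-1 letters.

Windows containing non-canonical symbols are skipped from the numerator
and denominator sums symmetrically.  A sequence with zero valid windows
is "unscorable": both class scores degenerate to the priors and the
prediction falls back to the first class with a flag raised.

All probabilities live in log space; the product form underflows long
before the 5 kb promoter windows this model is meant for.
"""

from __future__ import annotations

import json
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .kmer import (
    ALPHABETS,
    MAX_K,
    KmerCorpus,
    _DENSE_LIMIT,
    alphabet_size,
    encode,
    kmer_index_to_string,
    kmer_string_to_index,
    window_indices,
)

_MODEL_FORMAT = "tnbk-nbk/1"


def _smoothed_log_probs(counts: np.ndarray, total: float, alpha: float, n_cells: int) -> np.ndarray:
    return np.log(counts + alpha) - np.log(total + alpha * n_cells)


class KmerNaiveBayes(ClassifierMixin, BaseEstimator):
    """Binary k-mer naive Bayes / order-(k-1) Markov sequence classifier.

    Parameters
    ----------
    k : int, default 3
        Window length, 1..7.  Larger k is refused: the number of
        parameters grows as ``|A|**k`` and cannot be estimated reliably.
    alpha : float, default 1.0
        Additive smoothing pseudocount shared by the k-mer and (k-1)-mer
        tables; must be > 0 so unseen k-mers keep non-zero probability.
    alphabet : {"DNA", "PROTEIN"}, default "DNA"
    denominator : {"shared", "full"}, default "shared"
        Offset range of the (k-1)-mer correction sum (see module notes).

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Sorted class labels; ties and unscorable sequences resolve to
        ``classes_[0]`` (the conservative "unexpressed" class under the
        c0 < c1 convention).
    class_log_prior_ : ndarray of shape (2,)
    kmer_log_prob_ : ndarray of shape (2, |A|**k) or dict per class
    km1_log_prob_ : ndarray of shape (2, |A|**(k-1)), absent for k = 1
    """

    def __init__(self, k: int = 3, alpha: float = 1.0, alphabet: str = "DNA",
                 denominator: str = "shared"):
        self.k = k
        self.alpha = alpha
        self.alphabet = alphabet
        self.denominator = denominator

    # ------------------------------------------------------------------ fit

    def _validate_params_(self) -> None:
        if not 1 <= int(self.k) <= MAX_K:
            raise ValueError(f"k must be in [1, {MAX_K}], got {self.k}")
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.alphabet not in ALPHABETS:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        if self.denominator not in ("shared", "full"):
            raise ValueError(f"denominator must be 'shared' or 'full', got {self.denominator!r}")

    @property
    def _dense(self) -> bool:
        return alphabet_size(self.alphabet) ** int(self.k) <= _DENSE_LIMIT

    def fit(self, X: Sequence[str] | KmerCorpus, y: Sequence) -> "KmerNaiveBayes":
        """Fit class-conditional k-mer and (k-1)-mer tables.

        ``X`` is either a list of residue strings or a prebuilt
        :class:`~tnbk.kmer.KmerCorpus` (the fast path used by the
        cross-validation machinery, which reuses one corpus across folds).
        """
        self._validate_params_()
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"exactly two classes required, got {classes.tolist()}")
        self.classes_ = classes
        n = len(X)
        if y.shape[0] != n:
            raise ValueError("X and y length mismatch")
        counts_per_class = np.array([(y == c).sum() for c in classes], dtype=float)
        self.class_log_prior_ = np.log(counts_per_class / n)

        if isinstance(X, KmerCorpus):
            if X.k != int(self.k) or X.alphabet != self.alphabet:
                raise ValueError("corpus k/alphabet does not match estimator")
            corpus = X
        elif self._dense:
            corpus = KmerCorpus.build(X, int(self.k), self.alphabet)
        else:
            corpus = None

        k = int(self.k)
        n_letters = alphabet_size(self.alphabet)
        if corpus is not None:
            kc = np.stack([corpus.numer[y == c].sum(axis=0) for c in classes])
            totals = kc.sum(axis=1)
            if np.any(totals == 0):
                bad = classes[totals == 0]
                raise ValueError(f"class {bad.tolist()} has zero countable windows")
            self.kmer_counts_ = kc
            self.window_totals_ = totals
            self.kmer_log_prob_ = np.stack([
                _smoothed_log_probs(kc[j], totals[j], self.alpha, n_letters**k)
                for j in range(2)
            ])
            if k >= 2:
                mc = np.stack([corpus.train_km1[y == c].sum(axis=0) for c in classes])
                mt = mc.sum(axis=1)
                self.km1_counts_ = mc
                self.km1_totals_ = mt
                self.km1_log_prob_ = np.stack([
                    _smoothed_log_probs(mc[j], max(mt[j], 0.0), self.alpha, n_letters ** (k - 1))
                    for j in range(2)
                ])
        else:
            self._fit_sparse(X, y, classes)
        return self

    def _fit_sparse(self, X: Sequence[str], y: np.ndarray, classes: np.ndarray) -> None:
        # dict-backed tables for alphabets where |A|**k is too large to
        # materialise (protein k >= 6); scoring walks windows per sequence
        k = int(self.k)
        kc: list[dict[int, int]] = [{}, {}]
        mc: list[dict[int, int]] = [{}, {}]
        totals = np.zeros(2)
        mtotals = np.zeros(2)
        n_letters = alphabet_size(self.alphabet)
        for residues, label in zip(X, y):
            j = int(np.searchsorted(classes, label))
            codes = encode(residues.upper(), self.alphabet)
            idx, valid = window_indices(codes, k, n_letters)
            for i in idx[valid].tolist():
                kc[j][i] = kc[j].get(i, 0) + 1
            totals[j] += int(valid.sum())
            if k >= 2 and codes.size >= k:
                idx1, valid1 = window_indices(codes, k - 1, n_letters)
                sl = slice(1, codes.size - k + 2)
                for i in idx1[sl][valid1[sl]].tolist():
                    mc[j][i] = mc[j].get(i, 0) + 1
                    mtotals[j] += 1
        if np.any(totals == 0):
            raise ValueError(f"class {classes[totals == 0].tolist()} has zero countable windows")
        self.kmer_counts_ = kc
        self.window_totals_ = totals
        self.km1_counts_ = mc
        self.km1_totals_ = mtotals

    # ---------------------------------------------------------------- score

    def joint_log_scores(self, X: Sequence[str] | KmerCorpus) -> tuple[np.ndarray, np.ndarray]:
        """Per-class log scores and an "unscorable" mask.

        Returns ``(scores, unscorable)`` with ``scores`` of shape
        ``(n_sequences, 2)`` ordered like ``classes_``.  Sequences with
        zero valid windows contribute nothing beyond the priors and are
        flagged in ``unscorable``.
        """
        check_is_fitted(self, "classes_")
        k = int(self.k)
        if isinstance(X, KmerCorpus):
            corpus = X
        elif self._dense:
            corpus = KmerCorpus.build(X, k, self.alphabet)
        else:
            return self._score_sparse(X)
        scores = corpus.numer @ self.kmer_log_prob_.T
        if k >= 2:
            den = corpus.denom_shared if self.denominator == "shared" else corpus.denom_full
            scores = scores - den @ self.km1_log_prob_.T
        scores = scores + self.class_log_prior_
        return scores, corpus.n_valid_windows == 0

    def _sparse_log_prob(self, table: dict[int, int], total: float, order: int, idx: int) -> float:
        n_cells = alphabet_size(self.alphabet) ** order
        return float(np.log(table.get(idx, 0) + self.alpha) - np.log(total + self.alpha * n_cells))

    def _score_sparse(self, X: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        k = int(self.k)
        n_letters = alphabet_size(self.alphabet)
        out = np.zeros((len(X), 2))
        unscorable = np.zeros(len(X), dtype=bool)
        for r, residues in enumerate(X):
            codes = encode(residues.upper(), self.alphabet)
            idx, valid = window_indices(codes, k, n_letters)
            if valid.sum() == 0:
                out[r] = self.class_log_prior_
                unscorable[r] = True
                continue
            if k >= 2:
                idx1, _ = window_indices(codes, k - 1, n_letters)
            for j in range(2):
                s = self.class_log_prior_[j]
                for p in np.flatnonzero(valid).tolist():
                    s += self._sparse_log_prob(self.kmer_counts_[j], self.window_totals_[j], k, int(idx[p]))
                    if k >= 2 and 1 <= p <= codes.size - k:
                        s -= self._sparse_log_prob(self.km1_counts_[j], self.km1_totals_[j], k - 1, int(idx1[p]))
                if k >= 2 and self.denominator == "full" and valid[-1]:
                    s -= self._sparse_log_prob(self.km1_counts_[j], self.km1_totals_[j], k - 1, int(idx1[codes.size - k + 1]))
                out[r, j] = s
        return out, unscorable

    # -------------------------------------------------------------- predict

    def predict(self, X: Sequence[str] | KmerCorpus) -> np.ndarray:
        labels, _ = self.predict_with_flags(X)
        return labels

    def predict_with_flags(self, X: Sequence[str] | KmerCorpus) -> tuple[np.ndarray, np.ndarray]:
        """Predict classes; exact ties and unscorable inputs fall back to
        ``classes_[0]`` (flagged in the second return value for the
        unscorable case)."""
        scores, unscorable = self.joint_log_scores(X)
        # strict ">" keeps ties on classes_[0]
        which = (scores[:, 1] > scores[:, 0]).astype(int)
        which[unscorable] = 0
        return self.classes_[which], unscorable

    def conditional_probs(self, class_label) -> np.ndarray:
        """Smoothed next-letter conditionals P(a | context, class).

        Returns an array of shape ``(|A|**(k-1), |A|)`` whose rows are the
        model-implied transition distributions of the order-(k-1) Markov
        chain, computed by renormalising the smoothed k-mer table within
        each (k-1)-letter context.  Requires k >= 2 and a dense table.
        """
        check_is_fitted(self, "classes_")
        k = int(self.k)
        if k < 2:
            raise ValueError("conditionals need k >= 2")
        j = int(np.searchsorted(self.classes_, class_label))
        n_letters = alphabet_size(self.alphabet)
        probs = np.exp(self.kmer_log_prob_[j]).reshape(n_letters ** (k - 1), n_letters)
        return probs / probs.sum(axis=1, keepdims=True)

    # ------------------------------------------------------------ serialise

    def to_json(self) -> str:
        check_is_fitted(self, "classes_")
        k = int(self.k)

        def table(counts, order):
            if isinstance(counts, list):  # sparse per-class dicts
                return [
                    {kmer_index_to_string(i, order, self.alphabet): c for i, c in d.items()}
                    for d in counts
                ]
            return [
                {
                    kmer_index_to_string(i, order, self.alphabet): int(c)
                    for i, c in enumerate(row)
                    if c
                }
                for row in counts
            ]

        doc = {
            "format": _MODEL_FORMAT,
            "alphabet": self.alphabet,
            "k": k,
            "alpha": self.alpha,
            "denominator": self.denominator,
            "classes": [str(c) for c in self.classes_.tolist()],
            "priors": np.exp(self.class_log_prior_).tolist(),
            "window_totals": np.asarray(self.window_totals_).tolist(),
            "kmer_counts": table(self.kmer_counts_, k),
        }
        if k >= 2:
            doc["km1_totals"] = np.asarray(self.km1_totals_).tolist()
            doc["km1_counts"] = table(self.km1_counts_, k - 1)
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "KmerNaiveBayes":
        doc = json.loads(text)
        if doc.get("format") != _MODEL_FORMAT:
            raise ValueError(f"unrecognised model format {doc.get('format')!r}")
        est = cls(k=doc["k"], alpha=doc["alpha"], alphabet=doc["alphabet"],
                  denominator=doc["denominator"])
        k, alphabet = doc["k"], doc["alphabet"]
        n_letters = alphabet_size(alphabet)
        est.classes_ = np.array(doc["classes"])
        est.class_log_prior_ = np.log(np.asarray(doc["priors"], dtype=float))
        est.window_totals_ = np.asarray(doc["window_totals"], dtype=float)

        def untable(rows, order):
            if n_letters**order <= _DENSE_LIMIT:
                out = np.zeros((2, n_letters**order))
                for j, d in enumerate(rows):
                    for w, c in d.items():
                        out[j, kmer_string_to_index(w, alphabet)] = c
                return out
            return [
                {kmer_string_to_index(w, alphabet): c for w, c in d.items()} for d in rows
            ]

        est.kmer_counts_ = untable(doc["kmer_counts"], k)
        if isinstance(est.kmer_counts_, np.ndarray):
            est.kmer_log_prob_ = np.stack([
                _smoothed_log_probs(est.kmer_counts_[j], est.window_totals_[j],
                                    est.alpha, n_letters**k)
                for j in range(2)
            ])
        if k >= 2:
            est.km1_totals_ = np.asarray(doc["km1_totals"], dtype=float)
            est.km1_counts_ = untable(doc["km1_counts"], k - 1)
            if isinstance(est.km1_counts_, np.ndarray):
                est.km1_log_prob_ = np.stack([
                    _smoothed_log_probs(est.km1_counts_[j], est.km1_totals_[j],
                                        est.alpha, n_letters ** (k - 1))
                    for j in range(2)
                ])
        return est


# thin functional wrappers ---------------------------------------------------

def train(sequences: Iterable[str], labels: Iterable, k: int, alpha: float = 1.0,
          alphabet: str = "DNA", denominator: str = "shared") -> KmerNaiveBayes:
    """Fit a :class:`KmerNaiveBayes` on labelled residue strings."""
    return KmerNaiveBayes(k=k, alpha=alpha, alphabet=alphabet,
                          denominator=denominator).fit(list(sequences), list(labels))


def score(model: KmerNaiveBayes, residues: str) -> np.ndarray:
    """Per-class log scores for one sequence (ordered like ``classes_``)."""
    return model.joint_log_scores([residues])[0][0]


def classify(model: KmerNaiveBayes, residues: str):
    """Predicted class for one sequence (ties and unscorable -> classes_[0])."""
    return model.predict([residues])[0]
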