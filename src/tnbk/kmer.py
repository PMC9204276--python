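"""k-mer window enumeration and counting.

Sequences are scanned with a sliding window of length ``k`` over every
offset.  Windows containing a symbol outside the canonical alphabet
(``N`` and other IUPAC ambiguity codes in DNA; ``X``, ``B``, ``Z``, ``U``
etc. in protein) are skipped, and the number of skipped windows is
reported so callers can distinguish "no signal" from "all ambiguous".

The heavy path used by model fitting and scoring is vectorised: a corpus
of sequences is turned once into dense per-sequence count matrices over
the ``|A|**k`` index space, after which training is a row sum and scoring
a matrix product.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

ALPHABETS: Mapping[str, str] = {
    "DNA": "ACGT",
    "PROTEIN": "ACDEFGHIKLMNPQRSTVWY",
}

MAX_K = 7

#: largest |A|**k for which dense count vectors are used (4**7 and 20**5 fit)
_DENSE_LIMIT = 4_500_000

_ENCODE_TABLES: dict[str, np.ndarray] = {}


def _encode_table(alphabet: str) -> np.ndarray:
    table = _ENCODE_TABLES.get(alphabet)
    if table is None:
        letters = ALPHABETS[alphabet]
        table = np.full(256, -1, dtype=np.int64)
        for i, ch in enumerate(letters):
            table[ord(ch)] = i
            table[ord(ch.lower())] = i
        _ENCODE_TABLES[alphabet] = table
    return table


def alphabet_size(alphabet: str) -> int:
    try:
        return len(ALPHABETS[alphabet])
    except KeyError:  # pragma: no cover - guarded by callers
        raise ValueError(f"unknown alphabet {alphabet!r}") from None


def encode(residues: str, alphabet: str) -> np.ndarray:
    """Map residues to integer codes; non-canonical symbols become -1."""
    raw = np.frombuffer(residues.encode("ascii", errors="replace"), dtype=np.uint8)
    return _encode_table(alphabet)[raw]


def window_indices(codes: np.ndarray, k: int, n_letters: int) -> tuple[np.ndarray, np.ndarray]:
    """Indices of every length-``k`` window plus a validity mask.

    Returns ``(idx, valid)`` where ``idx[p]`` is the base-``n_letters``
    integer index of the window starting at position ``p`` (0-based) and
    ``valid[p]`` is False when the window touches a non-canonical symbol
    (``idx`` is meaningless there).
    """
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    m = n - k + 1
    idx = np.zeros(m, dtype=np.int64)
    valid = np.ones(m, dtype=bool)
    for j in range(k):
        col = codes[j : j + m]
        valid &= col >= 0
        idx = idx * n_letters + np.where(col >= 0, col, 0)
    return idx, valid


def kmer_index_to_string(index: int, k: int, alphabet: str) -> str:
    letters = ALPHABETS[alphabet]
    n = len(letters)
    out = []
    for _ in range(k):
        out.append(letters[index % n])
        index //= n
    return "".join(reversed(out))


def kmer_string_to_index(kmer: str, alphabet: str) -> int:
    letters = ALPHABETS[alphabet]
    idx = 0
    for ch in kmer:
        idx = idx * len(letters) + letters.index(ch)
    return idx


def count_kmers(residues: str, k: int, alphabet: str = "DNA") -> tuple[dict[str, int], int]:
    """Count every valid length-``k`` window of ``residues``.

    Returns ``(counts, n_skipped)`` where ``counts`` maps k-mer strings to
    occurrence counts over all overlapping offsets and ``n_skipped`` is
    the number of windows discarded because they contained a symbol
    outside the canonical alphabet.  Sequences shorter than ``k`` yield
    empty counts.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    codes = encode(residues.upper(), alphabet)
    idx, valid = window_indices(codes, k, alphabet_size(alphabet))
    counts: dict[str, int] = {}
    uniq, cnt = np.unique(idx[valid], return_counts=True)
    for u, c in zip(uniq.tolist(), cnt.tolist()):
        counts[kmer_index_to_string(u, k, alphabet)] = int(c)
    return counts, int((~valid).sum())


@dataclass
class KmerCorpus:
    """Dense per-sequence count matrices for one corpus at one ``k``.

    Three matrices are kept because training and scoring enumerate
    (k-1)-mers over different offset ranges:

    - ``numer``: k-mer counts over all valid windows (offsets 1..n-k+1,
      1-based) — used both for the class k-mer tables and as the scoring
      numerator.
    - ``train_km1``: (k-1)-mer counts over offsets 2..n-k+2 (each window's
      shared-overlap positions), skipping windows with ambiguous symbols —
      the class (k-1)-mer tables are fit from these.
    - ``denom_shared`` / ``denom_full``: (k-1)-mer counts over the scoring
      denominator offsets 2..n-k+1 (respectively 2..n-k+2), where a
      (k-1)-mer is included iff the k-mer window at the same offset
      (respectively the preceding window for the final boundary term) is
      valid, so ambiguous windows drop out of numerator and denominator
      symmetrically.

    All matrices are ``float64`` of shape ``(n_sequences, |A|**k)`` or
    ``(n_sequences, |A|**(k-1))``; for k == 1 the (k-1)-mer matrices are
    ``None``.
    """

    k: int
    alphabet: str
    numer: np.ndarray
    train_km1: np.ndarray | None
    denom_shared: np.ndarray | None
    denom_full: np.ndarray | None
    n_valid_windows: np.ndarray = field(default=None)  # per sequence

    @classmethod
    def build(cls, sequences: Iterable[str], k: int, alphabet: str = "DNA") -> "KmerCorpus":
        if not 1 <= k <= MAX_K:
            raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
        n_letters = alphabet_size(alphabet)
        if n_letters**k > _DENSE_LIMIT:
            raise ValueError(
                f"|A|**k = {n_letters}**{k} exceeds the dense-table limit; "
                "use the per-sequence scoring path instead"
            )
        seqs = list(sequences)
        n = len(seqs)
        numer = np.zeros((n, n_letters**k), dtype=np.float64)
        if k >= 2:
            train_km1 = np.zeros((n, n_letters ** (k - 1)), dtype=np.float64)
            denom_shared = np.zeros_like(train_km1)
            denom_full = np.zeros_like(train_km1)
        else:
            train_km1 = denom_shared = denom_full = None
        n_valid = np.zeros(n, dtype=np.int64)
        for r, residues in enumerate(seqs):
            codes = encode(residues.upper(), alphabet)
            idx, valid = window_indices(codes, k, n_letters)
            if idx.size:
                np.add.at(numer[r], idx[valid], 1.0)
            n_valid[r] = int(valid.sum())
            if k >= 2:
                idx1, valid1 = window_indices(codes, k - 1, n_letters)
                # training table: (k-1)-mers at 0-based starts 1..n-k+1
                sl = slice(1, codes.size - k + 2)
                v = valid1[sl]
                np.add.at(train_km1[r], idx1[sl][v], 1.0)
                # scoring denominator, shared range: starts 1..n-k, gated
                # on the validity of the k-window at the same start
                if idx.size >= 2:
                    starts = np.arange(1, codes.size - k + 1)
                    gate = valid[starts]
                    np.add.at(denom_shared[r], idx1[starts][gate], 1.0)
                    denom_full[r] += denom_shared[r]
                    # boundary term of the full range: the trailing
                    # (k-1)-mer, gated on the last k-window's validity
                    if valid[-1]:
                        np.add.at(denom_full[r], [idx1[codes.size - k + 1]], 1.0)
                elif idx.size == 1:
                    # single window: shared range empty, full range has
                    # only the trailing boundary term
                    if valid[0]:
                        np.add.at(denom_full[r], [idx1[1]], 1.0)
        return cls(k, alphabet, numer, train_km1, denom_shared, denom_full, n_valid)

    def __len__(self) -> int:
        return self.numer.shape[0]

    def select(self, rows: Sequence[int] | np.ndarray) -> "KmerCorpus":
        rows = np.asarray(rows)
        pick = lambda m: None if m is None else m[rows]
        return KmerCorpus(
            self.k,
            self.alphabet,
            self.numer[rows],
            pick(self.train_km1),
            pick(self.denom_shared),
            pick(self.denom_full),
            self.n_valid_windows[rows],
        )
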