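"""Independent scoring oracle for the NB(k) classifier.

Evaluates class scores directly in non-log arithmetic, term by term:
product of smoothed k-mer probabilities over offsets 1..n-k+1 divided by
the product of smoothed (k-1)-mer probabilities over offsets 2..n-k+1,
times the class prior.  Shares no code with the log-space implementation
it checks.
"""

import math

from tnbk.kmer import ALPHABETS


def oracle_scores(train_seqs, train_labels, k, alpha, query, alphabet="DNA"):
    """Direct product-form evaluation of the class scores."""
    letters = set(ALPHABETS[alphabet])
    A = len(letters)

    def windows(s, kk, offsets):
        out = []
        for i in offsets:  # 1-based
            w = s[i - 1 : i - 1 + kk]
            if len(w) == kk and set(w) <= letters:
                out.append(w)
        return out

    classes = sorted(set(train_labels))
    result = {}
    for c in classes:
        seqs = [s for s, y in zip(train_seqs, train_labels) if y == c]
        kmers = [w for s in seqs for w in windows(s, k, range(1, len(s) - k + 2))]
        km1 = (
            [w for s in seqs for w in windows(s, k - 1, range(2, len(s) - k + 3))]
            if k >= 2 else []
        )

        def p_k(w):
            return (kmers.count(w) + alpha) / (len(kmers) + alpha * A**k)

        def p_km1(w):
            return (km1.count(w) + alpha) / (len(km1) + alpha * A ** (k - 1))

        prior = sum(1 for y in train_labels if y == c) / len(train_labels)
        n = len(query)
        log_s = math.log(prior)
        for i in range(1, n - k + 2):
            if set(query[i - 1 : i - 1 + k]) <= letters:
                log_s += math.log(p_k(query[i - 1 : i - 1 + k]))
        if k >= 2:
            for i in range(2, n - k + 2):
                if set(query[i - 1 : i - 1 + k]) <= letters:
                    log_s -= math.log(p_km1(query[i - 1 : i - 1 + k - 1]))
        result[c] = log_s
    return result
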