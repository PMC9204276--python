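"""Synthetic study generator: planted Markov sequences and a correlated
multi-tissue expression matrix.

The generator mirrors the statistical structure the two-phase method
assumes rather than any particular organism:

- Each gene carries a latent binary class ("high"/"low") driven by a
  standard-normal gene factor U thresholded at the top ``high_fraction``
  quantile.
- Per-tissue binary labels come from a Gaussian copula
  ``Z_t = sqrt(rho) * U + sqrt(1 - rho) * eps_t`` thresholded at the same
  quantile, so labels of any two tissues have latent correlation ``rho``
  and each label is a noisy readout of the gene class.
- Abundance is log-normal with a class-dependent median (high genes
  ~10x low genes by default), and a per-tissue missingness mask is
  applied (every gene keeps at least one present value).
- Each gene's sequence is sampled from the order-(k-1) Markov chain of
  its latent class; the separation between the two planted chains is
  controlled through their per-step KL divergence.

In the full study design each gene's sequence carries all tissue labels
at once through additive loadings: every tissue has a class-conditional
chain pair ``(base - d_t, base + d_t)`` and a gene's sequence is sampled
from ``base + sum_t s_t d_t`` with ``s_t = +1/-1`` for a high/low label
in tissue t — a caricature of promoters whose overall composition
reflects many tissues' regulatory propensities simultaneously.  Each
single-tissue classifier then sees its own tissue's (weak) loading mixed
with the correlated loadings of the other 22, while Phase II sees the 23
per-tissue predictions; because the per-tissue loadings point in
near-orthogonal directions of k-mer space, the per-tissue classifiers
make partially independent errors that the second stage can pool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix
from .kmer import ALPHABETS, alphabet_size


# --------------------------------------------------------------- Markov chain

@dataclass(frozen=True)
class MarkovChain:
    """Order-``m`` Markov chain over a residue alphabet.

    ``transition`` has shape ``(|A|**m, |A|)``: row ``c`` is the
    next-letter distribution given the length-``m`` context with
    base-``|A|`` index ``c``.  ``initial`` is a distribution over
    contexts (defaults to the stationary distribution).
    """

    alphabet: str
    order: int
    transition: np.ndarray
    initial: np.ndarray | None = None

    def __post_init__(self):
        n = alphabet_size(self.alphabet)
        t = np.asarray(self.transition, dtype=float)
        if t.shape != (n**self.order, n):
            raise ValueError(f"transition must have shape {(n**self.order, n)}, got {t.shape}")
        if np.any(t.sum(axis=1) == 0):
            raise ValueError("transition has an all-zero row")
        if not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if self.initial is not None and not np.isclose(np.sum(self.initial), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")

    @property
    def n_letters(self) -> int:
        return alphabet_size(self.alphabet)

    def stationary(self) -> np.ndarray:
        """Stationary distribution over contexts (power iteration)."""
        C = self.transition.shape[0]
        n = self.n_letters
        pi = np.full(C, 1.0 / C)
        for _ in range(500):
            nxt = np.zeros(C)
            # context c -> (c * n + a) mod C with prob transition[c, a]
            for a in range(n):
                np.add.at(nxt, (np.arange(C) * n + a) % C, pi * self.transition[:, a])
            if np.abs(nxt - pi).sum() < 1e-12:
                return nxt
            pi = nxt
        return pi


def chain_kl(p: MarkovChain, q: MarkovChain) -> float:
    """Per-step KL divergence D(p || q) under p's stationary context law."""
    if p.transition.shape != q.transition.shape:
        raise ValueError("chains must share alphabet and order")
    pi = p.stationary()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(p.transition > 0, np.log(p.transition / q.transition), 0.0)
    return float((pi[:, None] * p.transition * ratio).sum())


def make_chain_pair(alphabet: str, order: int, per_step_kl: float,
                    seed: int, concentration: float = 5.0) -> tuple[MarkovChain, MarkovChain]:
    """Two chains whose symmetrised per-step KL is tuned to a target.

    The class-0 chain has Dirichlet(``concentration``) rows; the class-1
    chain mixes those rows with an independent Dirichlet draw, the mixing
    weight solved by bisection so that ``chain_kl(c0, c1)`` hits
    ``per_step_kl``.
    """
    n = alphabet_size(alphabet)
    rng = np.random.default_rng(seed)
    base = rng.dirichlet(np.full(n, concentration), size=n**order)
    alt = rng.dirichlet(np.full(n, concentration), size=n**order)
    c0 = MarkovChain(alphabet, order, base)

    def kl_at(delta: float) -> float:
        mixed = (1 - delta) * base + delta * alt
        return chain_kl(c0, MarkovChain(alphabet, order, mixed / mixed.sum(axis=1, keepdims=True)))

    if kl_at(1.0) < per_step_kl:
        raise ValueError(f"target per-step KL {per_step_kl} unreachable (max {kl_at(1.0):.4f})")
    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if kl_at(mid) < per_step_kl:
            lo = mid
        else:
            hi = mid
    mixed = (1 - hi) * base + hi * alt
    c1 = MarkovChain(alphabet, order, mixed / mixed.sum(axis=1, keepdims=True))
    return c0, c1


# ---------------------------------------------------------------- the design

#: default sequence length ranges by alphabet (promoter-like / peptide-like)
DEFAULT_LENGTH_RANGE = {"DNA": (300, 5000), "PROTEIN": (100, 1000)}


@dataclass(frozen=True)
class PlantedDesign:
    """Ground-truth parameters of one synthetic study.

    Defaults describe the reference study: 23 tissues, 2,000 genes,
    order-2 (k = 3) DNA chains with weak additive per-tissue loadings,
    tissue-label correlation 0.8, a top-20% high class (large enough for
    stable balanced sets at this gene count), 10x separated log-normal
    abundance and 10% per-tissue missingness.
    """

    chains: tuple[MarkovChain, MarkovChain]
    n_tissues: int = 23
    n_genes: int = 2000
    rho: float = 0.8
    high_fraction: float = 0.2
    missing_rate: float = 0.1
    mean_low: float = 10.0
    mean_high: float = 100.0
    sdlog: float = 0.5
    seq_length: tuple[int, int] = (1000, 3000)
    tissue_chains: tuple[tuple[MarkovChain, MarkovChain], ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [0, 1], got {self.rho}")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError(f"missing_rate must be in [0, 1], got {self.missing_rate}")
        if not 0.0 < self.high_fraction < 0.5:
            raise ValueError(f"high_fraction must be in (0, 0.5), got {self.high_fraction}")

    @property
    def alphabet(self) -> str:
        return self.chains[0].alphabet

    @property
    def k(self) -> int:
        return self.chains[0].order + 1

    @property
    def tissues(self) -> list[str]:
        return [f"tissue{i + 1:02d}" for i in range(self.n_tissues)]


def make_tissue_chain_pairs(alphabet: str, order: int, n_tissues: int,
                            per_step_kl: float, seed: int,
                            concentration: float = 20.0
                            ) -> tuple[tuple[MarkovChain, MarkovChain], ...]:
    """Per-tissue class-conditional chain pairs around one shared base.

    The base chain has Dirichlet(``concentration``) rows.  Tissue t's
    pair is ``(base - e_t * d_t, base + e_t * d_t)`` where ``d_t`` is an
    independent random zero-row-sum direction and ``e_t`` is solved by
    bisection so that the pair's per-step KL divergence equals
    ``per_step_kl``.  The directions are i.i.d., hence nearly orthogonal
    in k-mer space: each tissue perturbs its own axes of composition.
    """
    n = alphabet_size(alphabet)
    rng = np.random.default_rng(seed)
    C = n**order
    base = rng.dirichlet(np.full(n, concentration), size=C)
    pairs = []
    for _ in range(n_tissues):
        d = rng.standard_normal((C, n))
        d -= d.mean(axis=1, keepdims=True)
        d /= np.sqrt(np.sum(d * d / base))
        eps_max = 0.95 * float(np.min(base / np.maximum(np.abs(d), 1e-12)))

        def build(eps: float) -> tuple[MarkovChain, MarkovChain]:
            lo_m = np.clip(base - eps * d, 1e-6, None)
            hi_m = np.clip(base + eps * d, 1e-6, None)
            return (
                MarkovChain(alphabet, order, lo_m / lo_m.sum(axis=1, keepdims=True)),
                MarkovChain(alphabet, order, hi_m / hi_m.sum(axis=1, keepdims=True)),
            )

        if chain_kl(*build(eps_max)) < per_step_kl:
            raise ValueError(
                f"per-step KL {per_step_kl} unreachable for this base chain "
                f"(max {chain_kl(*build(eps_max)):.4f})"
            )
        lo, hi = 0.0, eps_max
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if chain_kl(*build(mid)) < per_step_kl:
                lo = mid
            else:
                hi = mid
        pairs.append(build(hi))
    return tuple(pairs)


def make_design(seed: int = 0, per_step_kl: float = 0.002, k: int = 3,
                alphabet: str = "DNA", n_tissues: int = 23,
                base_pair_kl: float = 0.1, **overrides) -> PlantedDesign:
    """Reference design: per-tissue additive loadings plus a base pair.

    ``per_step_kl`` sets the separation of every tissue's class pair (a
    deliberately weak 0.002 by default, so single-tissue classifiers
    operate in the noisy regime the method targets); ``base_pair_kl``
    sets the well-separated generic pair used by the single-chain
    sampler.
    """
    chains = make_chain_pair(alphabet, k - 1, base_pair_kl, seed)
    tissue_chains = make_tissue_chain_pairs(alphabet, k - 1, n_tissues,
                                            per_step_kl, seed=(seed * 1009 + 17) & 0x7FFFFFFF)
    return PlantedDesign(chains=chains, tissue_chains=tissue_chains,
                         n_tissues=n_tissues, seed=seed, **overrides)


# ------------------------------------------------------------------ sampling

def _decode(codes: np.ndarray, alphabet: str) -> str:
    letters = np.frombuffer(ALPHABETS[alphabet].encode(), dtype=np.uint8)
    return letters[codes].tobytes().decode()


def sample_chain_sequences(chain: MarkovChain, lengths: Sequence[int],
                           rng: np.random.Generator) -> list[str]:
    """Sample one sequence per requested length (vectorised over sequences)."""
    lengths = np.asarray(lengths, dtype=int)
    if lengths.size == 0:
        return []
    if np.any(lengths < chain.order + 1):
        raise ValueError(f"lengths must be >= order + 1 = {chain.order + 1}")
    n = chain.n_letters
    C = chain.transition.shape[0]
    init = chain.initial if chain.initial is not None else chain.stationary()
    ctx = rng.choice(C, size=lengths.size, p=init)
    maxlen = int(lengths.max())
    out = np.zeros((lengths.size, maxlen), dtype=np.int64)
    # leading `order` letters decode the initial context
    for j in range(chain.order):
        shift = n ** (chain.order - 1 - j)
        out[:, j] = (ctx // shift) % n
    cum = np.cumsum(chain.transition, axis=1)
    for pos in range(chain.order, maxlen):
        u = rng.random(lengths.size)
        nxt = (u[:, None] < cum[ctx]).argmax(axis=1)
        out[:, pos] = nxt
        ctx = (ctx * n + nxt) % C
    return [_decode(out[i, : lengths[i]], chain.alphabet) for i in range(lengths.size)]


def sample_sequences(design: PlantedDesign, class_assignments: Sequence[int],
                     seed: int | None = None,
                     length_range: tuple[int, int] | None = None) -> list[str]:
    """One sequence per gene, drawn from its class's planted chain.

    ``class_assignments`` holds 0/1 per gene; lengths are uniform over
    ``length_range`` (default: promoter-like 300-5000 nt for DNA,
    peptide-like 100-1000 aa for protein).  Output order matches the
    input order and is reproducible given the seed.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    classes = np.asarray(class_assignments, dtype=int)
    lo, hi = length_range or DEFAULT_LENGTH_RANGE[design.alphabet]
    lengths = rng.integers(lo, hi + 1, size=classes.size)
    out: list[str | None] = [None] * classes.size
    for cls in (0, 1):
        rows = np.flatnonzero(classes == cls)
        for row, seq in zip(rows, sample_chain_sequences(design.chains[cls], lengths[rows], rng)):
            out[row] = seq
    return out  # type: ignore[return-value]


def sample_expression(design: PlantedDesign, seed: int | None = None
                      ) -> tuple[ExpressionMatrix, pd.DataFrame, pd.Series]:
    """Correlated tissue labels, abundance matrix and gene-level truth.

    Returns ``(matrix, tissue_labels, gene_class)``: the abundance matrix
    with its missing mask applied, the planted per-tissue binary labels
    (genes x tissues, bool), and the latent per-gene class (bool, True =
    "high"), all indexed by gene id.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    N, T = design.n_genes, design.n_tissues
    genes = [f"g{i + 1:05d}" for i in range(N)]
    zq = stats.norm.ppf(1 - design.high_fraction)
    U = rng.standard_normal(N)
    Z = np.sqrt(design.rho) * U[:, None] + np.sqrt(1 - design.rho) * rng.standard_normal((N, T))
    labels = Z > zq
    gene_class = U > zq

    mu = np.where(labels, np.log(design.mean_high), np.log(design.mean_low))
    values = np.exp(mu + design.sdlog * rng.standard_normal((N, T)))
    mask = rng.random((N, T)) < design.missing_rate
    all_missing = mask.all(axis=1)
    if all_missing.any():
        keep = rng.integers(0, T, size=int(all_missing.sum()))
        mask[np.flatnonzero(all_missing), keep] = False
    values = np.where(mask, np.nan, values)

    tissues = design.tissues
    matrix = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=tissues))
    label_df = pd.DataFrame(labels, index=genes, columns=tissues)
    return matrix, label_df, pd.Series(gene_class, index=genes, name="gene_class")


def sample_tissue_sequences(design: PlantedDesign, tissue_labels: pd.DataFrame,
                            seed: int | None = None) -> dict[str, str]:
    """One sequence per gene from the gene's additive mixture chain.

    Gene g's transition matrix is ``base + sum_t s_gt * d_t`` where
    ``(base - d_t, base + d_t)`` is tissue t's class-conditional chain
    pair and ``s_gt`` is +1 when g's planted label in tissue t is high,
    -1 otherwise; rows are clipped to stay positive and renormalised.
    Every window of the sequence therefore carries all 23 labels as weak
    additive tilts along near-orthogonal k-mer directions.  Lengths are
    uniform over ``design.seq_length``.
    """
    if design.tissue_chains is None:
        raise ValueError("design has no per-tissue chain pairs")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    genes = list(tissue_labels.index)
    N = len(genes)
    s = 2.0 * tissue_labels.to_numpy(dtype=float) - 1.0  # (N, T) in {-1, +1}
    lows = np.stack([p[0].transition for p in design.tissue_chains])   # (T, C, A)
    highs = np.stack([p[1].transition for p in design.tissue_chains])
    base = 0.5 * (lows.mean(axis=0) + highs.mean(axis=0))
    deltas = 0.5 * (highs - lows)
    trans = base[None] + np.einsum("gt,tca->gca", s, deltas)
    trans = np.clip(trans, 1e-6, None)
    trans /= trans.sum(axis=2, keepdims=True)

    alphabet = design.tissue_chains[0][0].alphabet
    n_let = design.tissue_chains[0][0].n_letters
    C = trans.shape[1]
    order = design.tissue_chains[0][0].order
    lo, hi = design.seq_length
    lengths = rng.integers(lo, hi + 1, size=N)
    maxlen = int(lengths.max())
    cum = np.cumsum(trans, axis=2)
    init = MarkovChain(alphabet, order, base).stationary()
    ctx = rng.choice(C, size=N, p=init)
    out = np.zeros((N, maxlen), dtype=np.int64)
    for j in range(order):
        shift = n_let ** (order - 1 - j)
        out[:, j] = (ctx // shift) % n_let
    rows = np.arange(N)
    for pos in range(order, maxlen):
        u = rng.random(N)
        nxt = (u[:, None] < cum[rows, ctx]).argmax(axis=1)
        out[:, pos] = nxt
        ctx = (ctx * n_let + nxt) % (n_let**order)
    return {g: _decode(out[i, : lengths[i]], alphabet) for i, g in enumerate(genes)}


@dataclass(frozen=True)
class SyntheticStudy:
    """One fully sampled study: sequences, abundance, and ground truth."""

    design: PlantedDesign
    sequences: dict[str, str]
    expression: ExpressionMatrix
    tissue_labels: pd.DataFrame
    gene_class: pd.Series


def simulate_study(design: PlantedDesign, seed: int | None = None) -> SyntheticStudy:
    """Sample expression + labels, then per-tissue segmented sequences."""
    base = design.seed if seed is None else seed
    matrix, label_df, gene_class = sample_expression(design, seed=base)
    sequences = sample_tissue_sequences(design, label_df, seed=base + 1)
    return SyntheticStudy(design, sequences, matrix, label_df, gene_class)
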