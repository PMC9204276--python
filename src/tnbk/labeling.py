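"""Percentile-based class labeling and balanced set construction.

Per tissue, genes at or beyond a nearest-rank percentile cutoff of the
present abundance values form the positive ("expressed", c1) class: for a
TOP p% cutoff a gene is positive iff its value is >= the cutoff value;
for a BOTTOM p% cutoff iff it is <= the cutoff.  Genes without a present
measurement in the tissue are excluded.  Because the positive class is
(at most) p% of the genes, a balanced dataset keeps all positives and
draws an equal number of negatives uniformly without replacement, with
the RNG seed recorded for provenance.

Nearest-rank percentiles (value at rank ceil(p/100 * N), no
interpolation) guarantee the cutoff is a value some gene actually attains,
so the >=-rule selects exactly ceil(p/100 * N) positives absent ties.
Ties at the cutoff are all labeled positive, which can push the positive
class past p%.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from os import PathLike
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

TOP = "TOP"
BOTTOM = "BOTTOM"
#: the study's cutoff grid: top/bottom six percentiles at 5% increments
PERCENTS = (5, 10, 15, 20, 25, 30)
NEGATIVE, POSITIVE = "c0", "c1"


@dataclass(frozen=True)
class CutoffSpec:
    """A derived abundance threshold for one tissue.

    ``value`` is the nearest-rank percentile of the tissue's present
    values: the r-th largest (TOP) or r-th smallest (BOTTOM) with
    r = ceil(percent/100 * N); by construction it is attained by some
    gene.
    """

    tissue: str
    direction: str
    percent: int
    value: float

    def __post_init__(self):
        if self.direction not in (TOP, BOTTOM):
            raise ValueError(f"direction must be TOP or BOTTOM, got {self.direction!r}")
        if self.percent not in PERCENTS:
            raise ValueError(f"percent must be one of {PERCENTS}, got {self.percent}")


@dataclass(frozen=True)
class LabeledSet:
    """Balanced per-tissue binary labels with sampling provenance."""

    tissue: str
    cutoff: CutoffSpec
    members: tuple[tuple[str, str], ...]  # (gene id, class) pairs
    seed: int

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.members]

    @property
    def labels(self) -> np.ndarray:
        return np.array([c for _, c in self.members])

    def __len__(self) -> int:
        return len(self.members)


def compute_cutoff(matrix: ExpressionMatrix, tissue: str, direction: str,
                   percent: int) -> CutoffSpec:
    """Nearest-rank percentile cutoff of one tissue's present values."""
    values = matrix.present(tissue).to_numpy()
    if values.size == 0:
        raise ValueError(f"tissue {tissue!r} has no present values")
    r = math.ceil(percent / 100 * values.size)
    ordered = np.sort(values)
    value = float(ordered[-r] if direction == TOP else ordered[r - 1])
    return CutoffSpec(tissue, direction, percent, value)


def label_genes(matrix: ExpressionMatrix, cutoff: CutoffSpec) -> list[tuple[str, str]]:
    """Binary labels against a cutoff; genes missing in the tissue are
    excluded.  TOP: positive iff value >= cutoff; BOTTOM: iff <=."""
    present = matrix.present(cutoff.tissue)
    if cutoff.direction == TOP:
        positive = present >= cutoff.value
    else:
        positive = present <= cutoff.value
    return [
        (gene, POSITIVE if pos else NEGATIVE)
        for gene, pos in zip(present.index, positive.to_numpy())
    ]


def balance(labels: Sequence[tuple[str, str]], cutoff: CutoffSpec, seed: int) -> LabeledSet:
    """Keep all positives, subsample an equal number of negatives.

    Sampling is uniform without replacement and fully determined by
    ``seed``.  More positives than negatives violates the <=50% cutoff
    regime and is an error; zero positives yields an empty set with a
    warning.
    """
    genes = [g for g, _ in labels]
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene ids in label list")
    positives = [(g, c) for g, c in labels if c == POSITIVE]
    negatives = [(g, c) for g, c in labels if c == NEGATIVE]
    if len(positives) > len(negatives):
        raise ValueError(
            f"{len(positives)} positives > {len(negatives)} negatives; "
            "balancing expects the positive class to be the minority"
        )
    if not positives:
        warnings.warn(f"no positive genes for {cutoff}; empty labeled set")
        return LabeledSet(cutoff.tissue, cutoff, (), seed)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(negatives), size=len(positives), replace=False)
    members = tuple(positives) + tuple(negatives[i] for i in sorted(chosen.tolist()))
    return LabeledSet(cutoff.tissue, cutoff, members, seed)


def balanced_labeled_set(matrix: ExpressionMatrix, tissue: str, direction: str,
                         percent: int, seed: int) -> LabeledSet:
    """Cutoff -> labels -> balance in one step."""
    cutoff = compute_cutoff(matrix, tissue, direction, percent)
    return balance(label_genes(matrix, cutoff), cutoff, seed)


def write_labels(labeled_sets: Iterable[LabeledSet], path: str | PathLike) -> None:
    rows = [
        (gene, ls.tissue, ls.cutoff.direction, ls.cutoff.percent, cls)
        for ls in labeled_sets
        for gene, cls in ls.members
    ]
    pd.DataFrame(rows, columns=["gene", "tissue", "direction", "percent", "class"]).to_csv(
        path, sep="\t", index=False
    )


def write_cutoffs(cutoffs: Iterable[CutoffSpec], path: str | PathLike) -> None:
    rows = [(c.tissue, c.direction, c.percent, c.value) for c in cutoffs]
    pd.DataFrame(rows, columns=["tissue", "direction", "percent", "value"]).to_csv(
        path, sep="\t", index=False
    )
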