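"""Sequence and expression-table I/O.

Sequences travel as :class:`SequenceRecord` (id, alphabet tag, upper-cased
residues); expression data as :class:`ExpressionMatrix`, a thin wrapper
around a genes x tissues :class:`pandas.DataFrame` with NaN marking
missing measurements.  Promoter windows are the ``window`` bases of
genomic sequence immediately upstream (strand-aware) of each annotated
gene's 5' end, clipped at chromosome boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from os import PathLike
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

from .kmer import ALPHABETS

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN"
)


@dataclass(frozen=True)
class SequenceRecord:
    """One named sequence over a declared alphabet.

    ``residues`` are upper-case and may contain ambiguity symbols (N and
    IUPAC codes for DNA; X/B/Z/U for protein); those are preserved here
    and excluded only at k-mer counting time.
    """

    id: str
    alphabet: str
    residues: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if self.alphabet not in ALPHABETS:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)


def reverse_complement(residues: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware, case-insensitive)."""
    return residues.upper().translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | PathLike, alphabet: str = "DNA") -> list[SequenceRecord]:
    """Read a FASTA file into records.

    Ids are the header token before the first whitespace; residues are
    upper-cased.  An empty file is an error.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: line {lineno}: expected FASTA header '>', got {line.strip()[:20]!r}"
                    )
                break
        else:
            raise ValueError(f"no FASTA records in {path}")
    records = [
        SequenceRecord(rec.id, alphabet, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | PathLike) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), 80):
                fh.write(rec.residues[i : i + 80] + "\n")


def extract_promoters(genome_path: str | PathLike, annotation_path: str | PathLike,
                      window: int = 5000) -> list[SequenceRecord]:
    """Extract the ``window`` bp upstream of each annotated gene's 5' end.

    Coordinates in the GFF3 are 1-based, fully closed.  For a + strand
    gene starting at ``start`` the window is ``[start - window, start - 1]``;
    for a - strand gene ending at ``end`` it is the reverse complement of
    ``[end + 1, end + window]``.  Windows are clipped at chromosome
    boundaries and may come back shorter than ``window``; genes whose
    window clips to zero length, or whose seqid is absent from the
    genome, are skipped with a warning.
    """
    import gffutils
    from pyfaidx import Fasta

    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    genome = Fasta(str(genome_path), as_raw=True, sequence_always_upper=True)
    db = gffutils.create_db(str(annotation_path), ":memory:",
                            merge_strategy="create_unique", keep_order=True)
    out: list[SequenceRecord] = []
    for gene in db.features_of_type("gene"):
        if gene.seqid not in genome:
            warnings.warn(f"gene {gene.id}: seqid {gene.seqid!r} not in genome; skipped")
            continue
        chrom_len = len(genome[gene.seqid])
        if gene.strand == "-":
            lo = gene.end + 1
            hi = min(gene.end + window, chrom_len)
        else:
            lo = max(gene.start - window, 1)
            hi = gene.start - 1
        if hi < lo:
            warnings.warn(f"gene {gene.id}: upstream window is empty after clipping; skipped")
            continue
        seq = str(genome[gene.seqid][lo - 1 : hi])
        if gene.strand == "-":
            seq = reverse_complement(seq)
        out.append(SequenceRecord(gene.id, "DNA", seq))
    return out


class ExpressionMatrix:
    """Genes x tissues abundance matrix with a missing-value mask.

    Values are non-negative (FPKM-like or dNSAF-like); NaN marks a
    missing measurement.  Every gene must carry at least one present
    value and tissue names must be unique.
    """

    def __init__(self, values: pd.DataFrame):
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if values.columns.duplicated().any():
            raise ValueError("tissue names must be unique")
        arr = values.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValueError("expression values must be non-negative")
        all_missing = np.isnan(arr).all(axis=1)
        if all_missing.any():
            bad = values.index[all_missing].tolist()
            raise ValueError(f"genes with no present value: {bad}")
        self.values = values.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)

    def present(self, tissue: str) -> pd.Series:
        """Present (non-missing) values of one tissue, indexed by gene."""
        col = self.values[tissue]
        return col[col.notna()]

    def measured_genes(self, tissue: str) -> frozenset[str]:
        return frozenset(self.present(tissue).index)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        a, b = self.values, other.values
        return (
            a.shape == b.shape
            and list(a.index) == list(b.index)
            and list(a.columns) == list(b.columns)
            and bool(((a == b) | (a.isna() & b.isna())).all().all())
        )


def read_expression(path: str | PathLike) -> ExpressionMatrix:
    """Read a tab-delimited expression table.

    The header row names the tissues, the first column holds gene ids,
    and empty cells or ``NA`` denote missing measurements.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    df.index = df.index.astype(str)
    return ExpressionMatrix(df)


def write_expression(matrix: ExpressionMatrix, path: str | PathLike) -> None:
    df = matrix.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", na_rep="NA")


def records_as_dict(records: Iterable[SequenceRecord]) -> dict[str, str]:
    """Map record ids to residue strings (convenience for the pipeline)."""
    return {rec.id: rec.residues for rec in records}
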