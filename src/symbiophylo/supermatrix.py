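"""Marker selection, alignment trimming and partitioned concatenation.

Builds multi-gene supermatrices for phylogenomic inference:

* markers are selected from a per-taxon status matrix (complete / fragmented /
  duplicated / missing, plus copy numbers) by two strict thresholds —
  presence in complete-or-fragmented form in more than 60% of taxa, and mean
  copy number per taxon below 1.5;
* per-marker alignments are trimmed two ways: terminal trimming to the range
  between the first and last column whose residue identity exceeds 70%, and
  gap trimming that keeps only columns with at least a minimum fraction of
  non-gap residues (the trimAl ``-gt`` rule, default 0.5);
* trimmed alignments are concatenated over the taxon union, padding absent
  taxa with gaps and recording 1-based inclusive partition bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "MarkerMatrix",
    "Alignment",
    "Supermatrix",
    "select_markers",
    "trim_termini_identity",
    "trim_gap_fraction",
    "concatenate",
]

GAP = "-"
PRESENT_STATUSES = frozenset({"complete", "fragmented"})
VALID_STATUSES = frozenset({"complete", "fragmented", "duplicated", "missing"})


@dataclass
class MarkerMatrix:
    """Marker status and copy number per taxon.

    ``status`` and ``copy_number`` are taxon x marker DataFrames; statuses are
    one of complete/fragmented/duplicated/missing, with missing <=> copy 0 and
    duplicated => copy >= 2.
    """

    status: pd.DataFrame
    copy_number: pd.DataFrame

    def __post_init__(self):
        if not self.status.index.equals(self.copy_number.index) or not (
            self.status.columns.equals(self.copy_number.columns)
        ):
            raise ValueError("status and copy_number must share taxa and markers")
        bad = set(np.unique(self.status.values)) - VALID_STATUSES
        if bad:
            raise ValueError(f"invalid statuses: {sorted(bad)}")
        missing = self.status.values == "missing"
        if np.any((self.copy_number.values == 0) != missing):
            raise ValueError("status missing must coincide with copy_number 0")
        if np.any((self.status.values == "duplicated") & (self.copy_number.values < 2)):
            raise ValueError("duplicated status requires copy_number >= 2")

    @property
    def taxa(self) -> list[str]:
        return list(self.status.index)

    @property
    def markers(self) -> list[str]:
        return list(self.status.columns)

    @classmethod
    def from_tsv(cls, status_path, copy_path) -> "MarkerMatrix":
        status = pd.read_csv(status_path, sep="\t", index_col=0)
        copies = pd.read_csv(copy_path, sep="\t", index_col=0)
        return cls(status, copies)


@dataclass
class Alignment:
    """Rectangular alignment: ordered taxa with equal-length rows."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = {t for t in self.taxa if self.taxa.count(t) > 1}
            raise ValueError(f"duplicate taxa: {sorted(dupes)}")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("rows differ in length")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def to_array(self) -> np.ndarray:
        return np.array([list(r) for r in self.rows], dtype="U1")

    def take_columns(self, cols) -> "Alignment":
        arr = self.to_array()[:, list(cols)]
        return Alignment(list(self.taxa), ["".join(r) for r in arr])

    @classmethod
    def from_fasta(cls, source) -> "Alignment":
        records = list(SeqIO.parse(source, "fasta"))
        if not records:
            raise ValueError("empty alignment FASTA")
        return cls([r.id for r in records], [str(r.seq).upper() for r in records])

    def to_fasta(self, handle) -> None:
        SeqIO.write(
            (SeqRecord(Seq(row), id=taxon, description="")
             for taxon, row in zip(self.taxa, self.rows)),
            handle,
            "fasta",
        )


@dataclass
class Supermatrix:
    alignment: Alignment
    partitions: list[tuple[str, int, int]] = field(default_factory=list)  # 1-based incl.

    def __post_init__(self):
        expected_start = 1
        for name, start, end in self.partitions:
            if start != expected_start or end < start:
                raise ValueError(f"partition {name!r} not contiguous")
            expected_start = end + 1
        if self.partitions and expected_start - 1 != self.alignment.length:
            raise ValueError("partitions do not cover the alignment")

    def partition_text(self) -> str:
        return "".join(f"{n} = {s}-{e}\n" for n, s, e in self.partitions)


def select_markers(
    matrix: MarkerMatrix,
    min_presence: float = 0.60,
    max_mean_copy: float = 1.5,
) -> list[str]:
    """Markers present (complete or fragmented) in a strict majority of taxa.

    Selected iff presence fraction > ``min_presence`` and mean copy number
    over *all* taxa (missing counted as 0) < ``max_mean_copy``; both
    comparisons strict.
    """
    if not matrix.taxa:
        raise ValueError("empty marker matrix")
    present = matrix.status.isin(PRESENT_STATUSES).mean(axis=0)
    mean_copy = matrix.copy_number.mean(axis=0)
    keep = (present > min_presence) & (mean_copy < max_mean_copy)
    return [m for m in matrix.markers if keep[m]]


def _column_identity(arr: np.ndarray) -> np.ndarray:
    """Per-column identity: modal non-gap residue count / non-gap count.

    Columns with fewer than 2 non-gap residues score 0 (identity of a single
    residue is vacuous).
    """
    n_cols = arr.shape[1]
    identity = np.zeros(n_cols)
    for j in range(n_cols):
        col = arr[:, j]
        residues = col[col != GAP]
        if residues.size < 2:
            continue
        _, counts = np.unique(residues, return_counts=True)
        identity[j] = counts.max() / residues.size
    return identity


def trim_termini_identity(
    alignment: Alignment, identity_threshold: float = 0.70
) -> tuple[Alignment, tuple[int, int] | None]:
    """Trim terminal columns outside the first/last high-identity column.

    Keeps the contiguous range from the first through the last column whose
    identity strictly exceeds ``identity_threshold`` (1-based inclusive kept
    range returned).  If no column qualifies the result is empty, with a
    warning.
    """
    if alignment.n_taxa == 0:
        raise ValueError("empty alignment")
    identity = _column_identity(alignment.to_array())
    qualifying = np.flatnonzero(identity > identity_threshold)
    if qualifying.size == 0:
        warnings.warn("no column exceeds the identity threshold; empty trim")
        return Alignment(list(alignment.taxa), [""] * alignment.n_taxa), None
    first, last = int(qualifying[0]), int(qualifying[-1])
    return alignment.take_columns(range(first, last + 1)), (first + 1, last + 1)


def trim_gap_fraction(
    alignment: Alignment, gt: float = 0.5
) -> tuple[Alignment, list[int]]:
    """Keep columns whose non-gap fraction is at least ``gt`` (order preserved).

    Returns the trimmed alignment and the kept column indices (0-based).
    """
    if alignment.n_taxa == 0:
        raise ValueError("empty alignment")
    arr = alignment.to_array()
    nongap = (arr != GAP).mean(axis=0)
    kept = [int(j) for j in np.flatnonzero(nongap >= gt)]
    return alignment.take_columns(kept), kept


def concatenate(named_alignments: list[tuple[str, Alignment]]) -> Supermatrix:
    """Concatenate per-marker alignments over the union of their taxa.

    Taxa absent from a marker are padded with gaps across that partition;
    partition bounds are 1-based inclusive and contiguous.
    """
    if not named_alignments:
        raise ValueError("no alignments to concatenate")
    taxa: list[str] = []
    for _, aln in named_alignments:
        for t in aln.taxa:
            if t not in taxa:
                taxa.append(t)
    rows = {t: [] for t in taxa}
    partitions: list[tuple[str, int, int]] = []
    pos = 1
    for name, aln in named_alignments:
        by_taxon = dict(zip(aln.taxa, aln.rows))
        for t in taxa:
            rows[t].append(by_taxon.get(t, GAP * aln.length))
        partitions.append((name, pos, pos + aln.length - 1))
        pos += aln.length
    merged = Alignment(taxa, ["".join(rows[t]) for t in taxa])
    return Supermatrix(merged, partitions)
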