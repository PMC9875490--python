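"""Core genomic data types and plain-text readers/writers.

All coordinates are 0-based half-open (BED convention) everywhere in the
package; conversion to other conventions happens only at I/O boundaries.
Contact matrices are per-chromosome and cis-only.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

Strand = Literal["+", "-", "."]
_STRANDS = {"+", "-", "."}


class FormatError(ValueError):
    """Raised when an input file violates the declared format."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    ``length == end - start`` holds for every stored interval.
    """

    chrom: str
    start: int
    end: int
    strand: Strand = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start, got [{self.start}, {self.end})")
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Gene:
    """A gene model with a strand-aware transcription start site.

    For minus-strand genes the TSS is ``end - 1`` (the last base of the
    half-open interval).
    """

    interval: GenomicInterval
    gene_id: str

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.tss < self.interval.end):
            raise ValueError(f"TSS outside gene body for {self.gene_id}")

    @property
    def tss(self) -> int:
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start


@dataclass(frozen=True)
class Peak:
    """A peak call with summit offset, score and per-sample read counts."""

    interval: GenomicInterval
    peak_id: str
    summit: int | None = None
    score: float = 0.0
    counts: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.summit is not None and not (0 <= self.summit < self.interval.length):
            raise ValueError(
                f"summit offset {self.summit} outside peak {self.peak_id} "
                f"of length {self.interval.length}"
            )
        if self.score < 0:
            raise ValueError(f"negative score for peak {self.peak_id}")

    @property
    def summit_pos(self) -> int:
        """Absolute summit coordinate (midpoint when no summit was called)."""
        if self.summit is None:
            return self.interval.midpoint
        return self.interval.start + self.summit


class ContactMatrix:
    """Symmetric binned cis contact counts for one chromosome.

    Entries are stored sparsely; ``matrix`` returns a symmetric CSR matrix.
    """

    def __init__(self, chrom: str, resolution: int, n_bins: int, matrix: sp.spmatrix):
        if resolution <= 0:
            raise ValueError("resolution must be positive")
        if n_bins <= 0:
            raise ValueError("n_bins must be positive")
        m = sp.csr_matrix(matrix, shape=(n_bins, n_bins), dtype=float)
        if (m != m.T).nnz != 0:
            raise ValueError("contact matrix must be symmetric")
        if m.nnz and m.data.min() < 0:
            raise ValueError("contact counts must be nonnegative")
        self.chrom = chrom
        self.resolution = int(resolution)
        self.n_bins = int(n_bins)
        self.matrix = m
        self._total: float | None = None

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ContactMatrix({self.chrom}, res={self.resolution}, "
            f"n_bins={self.n_bins}, total={self.total:.0f})"
        )

    @property
    def total(self) -> float:
        """Total contacts, counting each off-diagonal pair once."""
        if self._total is None:
            full = self.matrix.sum()
            diag = self.matrix.diagonal().sum()
            self._total = float(full + diag) / 2.0
        return self._total

    def entry(self, i: int, j: int) -> float:
        if not (0 <= i < self.n_bins and 0 <= j < self.n_bins):
            raise IndexError(f"bin ({i},{j}) outside matrix of {self.n_bins} bins")
        return float(self.matrix[i, j])

    def bin_of(self, pos: int) -> int:
        b = pos // self.resolution
        if not 0 <= b < self.n_bins:
            raise IndexError(f"position {pos} outside binned region")
        return b

    def bin_interval(self, i: int) -> GenomicInterval:
        return GenomicInterval(self.chrom, i * self.resolution, (i + 1) * self.resolution)

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()

    def bin_totals(self) -> np.ndarray:
        """Per-bin marginal contact counts (row sums of the symmetric matrix)."""
        return np.asarray(self.matrix.sum(axis=1)).ravel()


def contact_matrix_from_triplets(
    chrom: str,
    resolution: int,
    rows: np.ndarray,
    cols: np.ndarray,
    counts: np.ndarray,
    n_bins: int | None = None,
) -> ContactMatrix:
    """Build a symmetric ContactMatrix from (i, j, count) triplets.

    Duplicate (i, j) entries are summed; each pair given once is mirrored.
    """
    rows = np.asarray(rows, dtype=np.int64)
    cols = np.asarray(cols, dtype=np.int64)
    counts = np.asarray(counts, dtype=float)
    if n_bins is None:
        n_bins = int(max(rows.max(initial=-1), cols.max(initial=-1)) + 1)
    lo = np.minimum(rows, cols)
    hi = np.maximum(rows, cols)
    upper = sp.coo_matrix((counts, (lo, hi)), shape=(n_bins, n_bins)).tocsr()
    upper.sum_duplicates()
    sym = upper + sp.triu(upper, k=1).T
    return ContactMatrix(chrom, resolution, n_bins, sym)


def read_contact_matrix(
    path, resolution: int, chrom: str = "chr1", n_bins: int | None = None
) -> ContactMatrix:
    """Read a whitespace-delimited sparse triplet contact file.

    Each line is ``i j count`` where ``i``/``j`` are either bin indices or bp
    positions that are exact multiples of ``resolution``. Duplicate pairs are
    summed and the matrix is mirrored to be symmetric.
    """
    ii: list[int] = []
    jj: list[int] = []
    cc: list[float] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) < 3:
                raise FormatError(f"line {ln}: expected 3 columns, got {len(parts)}")
            try:
                a, b = float(parts[0]), float(parts[1])
                c = float(parts[2])
            except ValueError as exc:
                raise FormatError(f"line {ln}: non-numeric field") from exc
            if c < 0:
                raise FormatError(f"line {ln}: negative count {c}")
            coords = []
            for v in (a, b):
                if v != int(v):
                    raise FormatError(f"line {ln}: non-integer coordinate {v}")
                v = int(v)
                if v >= resolution:
                    # bp position: must align to the bin grid
                    if v % resolution != 0:
                        raise FormatError(
                            f"line {ln}: position {v} not a multiple of "
                            f"resolution {resolution}"
                        )
                    v //= resolution
                coords.append(v)
            ii.append(coords[0])
            jj.append(coords[1])
            cc.append(c)
    if not ii:
        raise FormatError(f"{path}: no contact records")
    return contact_matrix_from_triplets(
        chrom, resolution, np.array(ii), np.array(jj), np.array(cc), n_bins=n_bins
    )


def write_contact_matrix(cm: ContactMatrix, path) -> None:
    """Write the upper triangle (incl. diagonal) as bin-index triplets."""
    upper = sp.triu(sp.coo_matrix(cm.matrix))
    with open(path, "w") as fh:
        for i, j, v in zip(upper.row, upper.col, upper.data):
            fh.write(f"{i}\t{j}\t{v:.6g}\n")


def _parse_strand(tok: str, ln: int) -> Strand:
    if tok not in _STRANDS:
        raise FormatError(f"line {ln}: unknown strand symbol {tok!r}")
    return tok  # type: ignore[return-value]


def read_bed_like(path, kind: str) -> list[Peak] | list[Gene]:
    """Read peaks or genes from a BED-derived TSV.

    ``kind='peak'``: chrom start end name score [summit_offset] [sample=count ...]
    ``kind='gene'``: chrom start end gene_id score strand

    Intervals are 0-based half-open; input ordering is preserved.
    """
    if kind not in {"peak", "gene"}:
        raise ValueError(f"kind must be 'peak' or 'gene', got {kind!r}")
    records: list = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith(("#", "track", "browser")):
                continue
            if len(parts) < 3:
                raise FormatError(f"line {ln}: expected at least 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise FormatError(f"line {ln}: end {end} <= start {start}")
            if kind == "gene":
                if len(parts) < 6:
                    raise FormatError(f"line {ln}: gene records need 6 columns")
                strand = _parse_strand(parts[5], ln)
                iv = GenomicInterval(chrom, start, end, strand)
                records.append(Gene(iv, parts[3]))
            else:
                name = parts[3] if len(parts) > 3 else f"peak_{ln}"
                score = float(parts[4]) if len(parts) > 4 else 0.0
                summit = None
                counts: dict[str, float] = {}
                for tok in parts[5:]:
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        counts[k] = float(v)
                    elif summit is None:
                        summit = int(tok)
                iv = GenomicInterval(chrom, start, end)
                records.append(Peak(iv, name, summit=summit, score=score, counts=counts))
    return records


def write_bed_like(records: Sequence[Peak | Gene], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            iv = r.interval
            if isinstance(r, Gene):
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.gene_id}\t0\t{iv.strand}\n"
                )
            else:
                fields = [iv.chrom, iv.start, iv.end, r.peak_id, f"{r.score:.6g}"]
                if r.summit is not None:
                    fields.append(r.summit)
                for k in sorted(r.counts):
                    fields.append(f"{k}={r.counts[k]:.6g}")
                fh.write("\t".join(str(f) for f in fields) + "\n")


def write_table(records: pd.DataFrame | Iterable[Mapping], path) -> None:
    """Write records as a TSV with a header row and stable column order.

    Floats are written at 6 significant digits.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(list(records))
    records.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def sort_key(chrom: str, start: int, end: int, name: str):
    """Deterministic (chrom, start, end, id) lexicographic sort key."""
    return (chrom, start, end, name)


def write_bedgraph(intervals: Sequence[GenomicInterval], values: Sequence[float], path) -> None:
    """Write per-interval values (e.g. a PC1 track) as bedGraph."""
    with open(path, "w") as fh:
        for iv, v in zip(intervals, values):
            val = "NA" if v is None or (isinstance(v, float) and np.isnan(v)) else f"{v:.6g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{val}\n")
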