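"""Readers and writers for every on-disk format the pipeline touches.

Conventions fixed here and relied on everywhere else:

* all coordinates are 0-based half-open (BED convention); bin ``i`` spans
  ``[i * bin_size, (i + 1) * bin_size)``;
* contact matrices are stored as whitespace-delimited COO text
  (``chrom  i  j  count``) holding only the upper triangle ``i <= j``;
* missing track values are written as ``nan`` tokens (or skipped on request)
  so that scores undefined near chromosome ends survive round-trips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import BoundsError, ParseError, ValidationError

__all__ = [
    "GenomicBin",
    "ContactMatrix",
    "IntervalRecord",
    "IntervalPairRecord",
    "make_bins",
    "parse_contacts",
    "serialize_contacts",
    "parse_intervals",
    "serialize_intervals",
    "serialize_track",
    "parse_track",
    "serialize_pairs",
    "parse_pairs",
    "parse_counts",
    "serialize_counts",
    "parse_metadata",
]


@dataclass(frozen=True)
class GenomicBin:
    """One fixed-width bin on a chromosome."""

    chrom: str
    start: int
    end: int
    index: int


@dataclass(frozen=True)
class IntervalRecord:
    """BED3/BED6 interval; 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float | None = None
    strand: str | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )
        if self.score is not None and not math.isfinite(self.score):
            raise ValidationError("interval score must be finite when present")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class IntervalPairRecord:
    """BEDPE pair of anchors plus score columns (loop calls)."""

    anchor1: IntervalRecord
    anchor2: IntervalRecord
    name: str = "."
    scores: tuple[float, ...] = ()

    def __post_init__(self):
        key1 = (self.anchor1.chrom, self.anchor1.start)
        key2 = (self.anchor2.chrom, self.anchor2.start)
        if key1 > key2:
            raise ValidationError("pair anchors must be ordered by (chrom, start)")


class ContactMatrix:
    """Symmetric per-chromosome binned raw-count matrix, stored upper-triangular.

    Parameters
    ----------
    chrom : chromosome name.
    bin_size : bp per bin.
    n_bins : number of bins on the chromosome.
    counts : mapping ``(i, j) -> count`` with ``i <= j``; values >= 0.
    """

    def __init__(self, chrom: str, bin_size: int, n_bins: int,
                 counts: dict[tuple[int, int], float] | None = None):
        if bin_size <= 0 or n_bins <= 0:
            raise ValidationError("bin_size and n_bins must be positive")
        self.chrom = chrom
        self.bin_size = int(bin_size)
        self.n_bins = int(n_bins)
        self.counts: dict[tuple[int, int], float] = {}
        if counts:
            for (i, j), v in counts.items():
                self.add(i, j, v)

    def add(self, i: int, j: int, value: float) -> None:
        if value < 0:
            raise ValidationError(f"negative contact count at ({i}, {j})")
        if not (0 <= i < self.n_bins and 0 <= j < self.n_bins):
            raise BoundsError(
                f"bin index ({i}, {j}) outside [0, {self.n_bins}) on {self.chrom}"
            )
        if i > j:
            i, j = j, i
        if value:
            self.counts[(i, j)] = self.counts.get((i, j), 0.0) + value

    def to_dense(self) -> np.ndarray:
        """Full symmetric dense matrix (float64)."""
        m = np.zeros((self.n_bins, self.n_bins))
        for (i, j), v in self.counts.items():
            m[i, j] = v
            m[j, i] = v
        return m

    @classmethod
    def from_dense(cls, dense: np.ndarray, chrom: str, bin_size: int) -> "ContactMatrix":
        dense = np.asarray(dense)
        n = dense.shape[0]
        out = cls(chrom, bin_size, n)
        iu, ju = np.nonzero(np.triu(dense))
        for i, j in zip(iu.tolist(), ju.tolist()):
            out.counts[(i, j)] = float(dense[i, j])
        return out

    def total(self) -> float:
        return float(sum(self.counts.values()))

    def bins(self) -> list[GenomicBin]:
        return make_bins(self.chrom, self.bin_size, self.n_bins)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ContactMatrix)
            and self.chrom == other.chrom
            and self.bin_size == other.bin_size
            and self.n_bins == other.n_bins
            and self.counts == other.counts
        )

    def __repr__(self) -> str:
        return (f"ContactMatrix({self.chrom}, bin_size={self.bin_size}, "
                f"n_bins={self.n_bins}, nnz={len(self.counts)})")


def make_bins(chrom: str, bin_size: int, n_bins: int,
              chrom_length: int | None = None) -> list[GenomicBin]:
    """Tile a chromosome with fixed-width bins; the terminal bin may be short."""
    length = chrom_length if chrom_length is not None else n_bins * bin_size
    return [
        GenomicBin(chrom, i * bin_size, min((i + 1) * bin_size, length), i)
        for i in range(n_bins)
    ]


# ---------------------------------------------------------------------------
# contact COO text

def parse_contacts(path: str | Path, bin_size: int, chrom_length: int) -> ContactMatrix:
    """Read ``chrom i j count`` COO text; entries are folded to the upper triangle."""
    n_bins = math.ceil(chrom_length / bin_size)
    chrom = None
    matrix = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if line.startswith("# chrom="):
                chrom = line.split("=", 1)[1]
                matrix = ContactMatrix(chrom, bin_size, n_bins)
                continue
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(f"expected 4 fields, got {len(parts)}", line=lineno)
            c, i_s, j_s, v_s = parts
            try:
                i, j = int(i_s), int(j_s)
                v = float(v_s)
            except ValueError as exc:
                raise ParseError(str(exc), line=lineno) from exc
            if chrom is None:
                chrom = c
                matrix = ContactMatrix(chrom, bin_size, n_bins)
            elif c != chrom:
                raise ParseError(
                    f"multiple chromosomes in one file ({chrom!r} vs {c!r})",
                    line=lineno,
                )
            try:
                matrix.add(i, j, v)
            except (BoundsError, ValidationError) as exc:
                raise type(exc)(f"line {lineno}: {exc}") from exc
    if matrix is None:
        matrix = ContactMatrix("chrU", bin_size, n_bins)
    return matrix


def serialize_contacts(matrix: ContactMatrix, path: str | Path) -> None:
    """Write COO text; round-trips entry-for-entry through :func:`parse_contacts`."""
    with open(path, "w") as fh:
        fh.write(f"# chrom={matrix.chrom}\n")
        for (i, j) in sorted(matrix.counts):
            v = matrix.counts[(i, j)]
            v_s = repr(int(v)) if float(v).is_integer() else repr(v)
            fh.write(f"{matrix.chrom}\t{i}\t{j}\t{v_s}\n")


# ---------------------------------------------------------------------------
# BED intervals

def parse_intervals(path: str | Path) -> list[IntervalRecord]:
    """Read BED3–BED6; records returned in file order."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError("BED line needs >= 3 columns", line=lineno)
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"non-integer coordinate: {exc}", line=lineno) from exc
            name = parts[3] if len(parts) > 3 else "."
            score = None
            if len(parts) > 4 and parts[4] not in (".", ""):
                try:
                    score = float(parts[4])
                except ValueError as exc:
                    raise ParseError(f"bad score: {parts[4]}", line=lineno) from exc
            strand = parts[5] if len(parts) > 5 else None
            try:
                records.append(IntervalRecord(parts[0], start, end, name, score, strand))
            except ValidationError as exc:
                raise ValidationError(f"line {lineno}: {exc}") from exc
    return records


def serialize_intervals(records: Sequence[IntervalRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fields = [r.chrom, str(r.start), str(r.end)]
            if r.name != "." or r.score is not None or r.strand is not None:
                fields.append(r.name)
            if r.score is not None or r.strand is not None:
                fields.append("." if r.score is None else repr(r.score))
            if r.strand is not None:
                fields.append(r.strand)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# bedGraph tracks

def serialize_track(bins: Sequence[GenomicBin], values: Sequence[float],
                    path: str | Path, skip_missing: bool = False) -> None:
    """Write one value per bin as bedGraph; NaN written as ``nan`` or skipped."""
    if len(bins) != len(values):
        raise ValidationError(
            f"{len(bins)} bins but {len(values)} values"
        )
    with open(path, "w") as fh:
        for b, v in zip(bins, values):
            missing = v is None or (isinstance(v, float) and math.isnan(v))
            if missing:
                if skip_missing:
                    continue
                token = "nan"
            else:
                token = format(float(v), ".6g")
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{token}\n")


def parse_track(path: str | Path) -> tuple[list[IntervalRecord], np.ndarray]:
    """Read bedGraph back as (intervals, values); ``nan`` tokens become NaN."""
    intervals, values = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError("bedGraph line needs 4 columns", line=lineno)
            intervals.append(IntervalRecord(parts[0], int(parts[1]), int(parts[2])))
            values.append(float(parts[3]))
    return intervals, np.asarray(values, dtype=float)


# ---------------------------------------------------------------------------
# BEDPE pairs

def serialize_pairs(pairs: Sequence[IntervalPairRecord], path: str | Path) -> None:
    """Write BEDPE: 6 coordinate fields, name, then score columns."""
    with open(path, "w") as fh:
        for p in pairs:
            fields = [
                p.anchor1.chrom, str(p.anchor1.start), str(p.anchor1.end),
                p.anchor2.chrom, str(p.anchor2.start), str(p.anchor2.end),
                p.name,
            ]
            fields.extend(format(float(s), ".10g") for s in p.scores)
            fh.write("\t".join(fields) + "\n")


def parse_pairs(path: str | Path) -> list[IntervalPairRecord]:
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError("BEDPE line needs >= 6 columns", line=lineno)
            a1 = IntervalRecord(parts[0], int(parts[1]), int(parts[2]))
            a2 = IntervalRecord(parts[3], int(parts[4]), int(parts[5]))
            name = parts[6] if len(parts) > 6 else "."
            scores = tuple(float(x) for x in parts[7:])
            pairs.append(IntervalPairRecord(a1, a2, name, scores))
    return pairs


# ---------------------------------------------------------------------------
# counts table + metadata

COUNT_POSITION_COLS = ["gene", "chrom", "start", "end"]


def parse_counts(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the counts TSV.

    Returns ``(counts, positions)`` where ``counts`` is a gene x sample integer
    frame indexed by gene id and ``positions`` holds gene coordinates.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COUNT_POSITION_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"counts table missing columns {missing}")
    if df["gene"].duplicated().any():
        dupes = df.loc[df["gene"].duplicated(), "gene"].tolist()
        raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
    df = df.set_index("gene")
    positions = df[["chrom", "start", "end"]].copy()
    counts = df.drop(columns=["chrom", "start", "end"])
    if (counts.to_numpy() < 0).any():
        raise ValidationError("negative counts in counts table")
    return counts.astype(np.int64), positions


def serialize_counts(counts: pd.DataFrame, positions: pd.DataFrame,
                     path: str | Path) -> None:
    out = positions.join(counts)
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def parse_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata TSV (columns sample_id, subgroup, ...)."""
    meta = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "subgroup"):
        if col not in meta.columns:
            raise ParseError(f"metadata missing required column {col!r}")
    if meta["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample ids in metadata")
    return meta


def align_counts_to_metadata(counts: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Reorder counts columns to metadata sample order; error on missing samples."""
    wanted = meta["sample_id"].tolist()
    missing = [s for s in wanted if s not in counts.columns]
    if missing:
        raise ValidationError(f"samples in metadata but not in counts: {missing}")
    return counts[wanted]
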