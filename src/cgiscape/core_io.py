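"""Genomic interval algebra and readers/writers for annotation formats.

All coordinates are 0-based half-open (UCSC table convention) throughout the
package; 1-based formats are converted at the I/O boundary.  Interval sets are
strand-blind: strand is carried on :class:`GenomicInterval` but overlap lengths
never condition on it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "IntervalSet",
    "ParseError",
    "read_gene_table",
    "filter_genes",
    "read_bed",
    "write_bed",
    "read_fasta",
    "read_cage_table",
    "read_chrom_sizes",
    "is_random_chrom",
]

STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """Raised on malformed input rows; message names the offending line."""


def is_random_chrom(chrom: str) -> bool:
    """True for unplaced/random contigs that are excluded at read time."""
    low = chrom.lower()
    return "random" in low or low.startswith("chrun") or "_hap" in low


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A transcript model in knownGene coordinates.

    ``exons`` are sorted, non-overlapping and contained in [tx_start, tx_end).
    The TSS is ``tx_start`` on "+" and ``tx_end - 1`` on "-"; helper properties
    expose the strand-aware ends.
    """

    name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: tuple[GenomicInterval, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.name}: strand must be + or -")
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValueError(f"gene {self.name}: tx/cds coordinate order violated")
        prev_end = -1
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValueError(f"gene {self.name}: exon on wrong chrom")
            if ex.start < prev_end:
                raise ValueError(f"gene {self.name}: exons overlap or unsorted")
            if ex.start < self.tx_start or ex.end > self.tx_end:
                raise ValueError(f"gene {self.name}: exon outside transcript")
            prev_end = ex.end

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start < self.cds_end

    @property
    def tss(self) -> int:
        """Transcription start coordinate (strand-aware, 0-based)."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        """Introns in genomic order (gaps between consecutive exons)."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return tuple(out)

    def key(self) -> tuple:
        """Identity key used for duplicate removal (name + location)."""
        return (self.name, self.chrom, self.strand, self.tx_start, self.tx_end)


def _merge_array(arr: np.ndarray) -> np.ndarray:
    """Merge a (n, 2) start/end array into sorted disjoint intervals.

    Touching intervals ([0,5) and [5,9)) are coalesced.
    """
    if arr.size == 0:
        return arr.reshape(0, 2)
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    starts, ends = arr[:, 0], arr[:, 1]
    # an interval starts a new block when it begins after the running max end
    run_max = np.maximum.accumulate(ends)
    new_block = np.empty(len(arr), dtype=bool)
    new_block[0] = True
    new_block[1:] = starts[1:] > run_max[:-1]
    block_id = np.cumsum(new_block) - 1
    n_blocks = block_id[-1] + 1
    out = np.empty((n_blocks, 2), dtype=np.int64)
    out[:, 0] = starts[new_block]
    block_ends = np.full(n_blocks, -1, dtype=np.int64)
    np.maximum.at(block_ends, block_id, ends)
    out[:, 1] = block_ends
    return out


class IntervalSet:
    """Chromosome-keyed collection of sorted, merged, disjoint intervals.

    The substrate of every overlap/classification computation.  Construction
    always merges, so invariants (sortedness, disjointness) hold by
    construction.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._ivals: dict[str, np.ndarray] = {
            c: _merge_array(np.asarray(v, dtype=np.int64))
            for c, v in sorted(per_chrom.items())
        }

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_arrays(cls, arrays: Mapping[str, np.ndarray]) -> "IntervalSet":
        """Build from {chrom: (n,2) array}; input is merged defensively."""
        obj = cls.__new__(cls)
        obj._ivals = {
            c: _merge_array(np.asarray(a, dtype=np.int64).reshape(-1, 2))
            for c, a in sorted(arrays.items())
            if np.asarray(a).size
        }
        obj._ivals = {c: a for c, a in obj._ivals.items() if len(a)}
        return obj

    # -- inspection -----------------------------------------------------------

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self._ivals)

    def array(self, chrom: str) -> np.ndarray:
        """(n, 2) start/end array for ``chrom`` (empty if absent)."""
        return self._ivals.get(chrom, np.empty((0, 2), dtype=np.int64))

    @property
    def total_length(self) -> int:
        return int(
            sum((a[:, 1] - a[:, 0]).sum() for a in self._ivals.values())
        )

    def __len__(self) -> int:
        return sum(len(a) for a in self._ivals.values())

    def __bool__(self) -> bool:
        return len(self) > 0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if set(self._ivals) != set(other._ivals):
            return False
        return all(np.array_equal(self._ivals[c], other._ivals[c]) for c in self._ivals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom, arr in self._ivals.items():
            for s, e in arr:
                yield GenomicInterval(chrom, int(s), int(e))

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals, {self.total_length} bp)"

    # -- set algebra ----------------------------------------------------------

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out: dict[str, np.ndarray] = {}
        for chrom in self._ivals:
            a, b = self.array(chrom), other.array(chrom)
            if not len(a) or not len(b):
                continue
            pieces = _intersect_arrays(a, b)
            if len(pieces):
                out[chrom] = pieces
        return IntervalSet.from_arrays(out)

    def intersect_length(self, other: "IntervalSet") -> int:
        """Total overlapping base pairs with ``other`` (symmetric)."""
        total = 0
        for chrom in self._ivals:
            a, b = self.array(chrom), other.array(chrom)
            if len(a) and len(b):
                total += intersect_length_arrays(a, b)
        return int(total)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        out: dict[str, np.ndarray] = {}
        for chrom, a in self._ivals.items():
            b = other.array(chrom)
            res = _subtract_arrays(a, b) if len(b) else a
            if len(res):
                out[chrom] = res
        return IntervalSet.from_arrays(out)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        out: dict[str, np.ndarray] = {}
        for chrom in set(self._ivals) | set(other._ivals):
            stack = np.vstack([self.array(chrom), other.array(chrom)])
            if len(stack):
                out[chrom] = stack
        return IntervalSet.from_arrays(out)

    def merge(self) -> "IntervalSet":
        """Return self (sets are merged by construction); kept for API parity."""
        return IntervalSet.from_arrays(self._ivals)

    def contains_points(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean mask: does each position fall inside an interval?"""
        arr = self.array(chrom)
        positions = np.asarray(positions, dtype=np.int64)
        if not len(arr):
            return np.zeros(len(positions), dtype=bool)
        idx = np.searchsorted(arr[:, 0], positions, side="right") - 1
        ok = idx >= 0
        inside = np.zeros(len(positions), dtype=bool)
        inside[ok] = positions[ok] < arr[idx[ok], 1]
        return inside


def intersect_length_arrays(a: np.ndarray, b: np.ndarray) -> int:
    """Overlap bp between two merged (n,2) arrays via a two-pointer sweep."""
    pieces = _intersect_arrays(a, b)
    if not len(pieces):
        return 0
    return int((pieces[:, 1] - pieces[:, 0]).sum())


def _intersect_arrays(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def _subtract_arrays(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j, 1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k, 0] < e:
            if b[k, 0] > cur:
                out.append((cur, b[k, 0]))
            cur = max(cur, b[k, 1])
            k += 1
        if cur < e:
            out.append((cur, e))
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


# -- gene table ---------------------------------------------------------------

_GENE_COLUMNS = 10


def _parse_csv_ints(text: str) -> tuple[int, ...]:
    return tuple(int(x) for x in text.rstrip(",").split(",") if x)


def read_gene_table(
    path: str | Path | io.TextIOBase,
    *,
    dedupe: bool = True,
    exclude_random: bool = True,
) -> list[GeneModel]:
    """Parse a knownGene-style tab table into :class:`GeneModel` records.

    Columns: name, chrom, strand, txStart, txEnd, cdsStart, cdsEnd, exonCount,
    exonStarts, exonEnds (starts/ends comma-separated).  With ``dedupe`` (the
    default) exact duplicate records are collapsed and gene names that still
    map to more than one location are dropped entirely.  Unplaced/"random"
    contigs are excluded at read time.

    This returns the *unfiltered* gene view used for CGI classification;
    apply :func:`filter_genes` for the >=3-exon element-building set.
    """
    close = False
    if isinstance(path, (str, Path)):
        handle = open(path)
        close = True
    else:
        handle = path
    genes: list[GeneModel] = []
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < _GENE_COLUMNS:
                raise ParseError(
                    f"line {lineno}: expected {_GENE_COLUMNS} tab-separated "
                    f"fields, got {len(fields)}"
                )
            try:
                name, chrom, strand = fields[0], fields[1], fields[2]
                tx_start, tx_end = int(fields[3]), int(fields[4])
                cds_start, cds_end = int(fields[5]), int(fields[6])
                exon_count = int(fields[7])
                starts = _parse_csv_ints(fields[8])
                ends = _parse_csv_ints(fields[9])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            if len(starts) != exon_count or len(ends) != exon_count:
                raise ParseError(
                    f"line {lineno}: exonCount={exon_count} but "
                    f"{len(starts)} starts / {len(ends)} ends"
                )
            if exclude_random and is_random_chrom(chrom):
                continue
            exons = tuple(
                GenomicInterval(chrom, s, e, strand) for s, e in zip(starts, ends)
            )
            try:
                genes.append(
                    GeneModel(
                        name, chrom, strand, tx_start, tx_end,
                        cds_start, cds_end, exons,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    finally:
        if close:
            handle.close()

    if dedupe:
        seen: dict[tuple, GeneModel] = {}
        for g in genes:
            seen.setdefault(g.key(), g)
        by_name: dict[str, list[GeneModel]] = {}
        for g in seen.values():
            by_name.setdefault(g.name, []).append(g)
        genes = [gs[0] for gs in by_name.values() if len(gs) == 1]
        genes.sort(key=lambda g: (g.chrom, g.tx_start, g.name))
    return genes


def filter_genes(genes: Sequence[GeneModel], *, min_exons: int = 3) -> list[GeneModel]:
    """Element-building filter: keep genes with at least ``min_exons`` exons."""
    return [g for g in genes if g.exon_count >= min_exons]


def write_gene_table(
    genes: Sequence[GeneModel], path: str | Path | io.TextIOBase
) -> None:
    """Write genes in the knownGene-style tab dialect read by read_gene_table."""
    close = False
    if isinstance(path, (str, Path)):
        handle = open(path, "w")
        close = True
    else:
        handle = path
    try:
        for g in genes:
            starts = ",".join(str(e.start) for e in g.exons) + ","
            ends = ",".join(str(e.end) for e in g.exons) + ","
            handle.write(
                f"{g.name}\t{g.chrom}\t{g.strand}\t{g.tx_start}\t{g.tx_end}\t"
                f"{g.cds_start}\t{g.cds_end}\t{g.exon_count}\t{starts}\t{ends}\n"
            )
    finally:
        if close:
            handle.close()


# -- BED ----------------------------------------------------------------------

def read_bed(
    path: str | Path | io.TextIOBase, *, exclude_random: bool = True
) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals (0-based half-open, as on disk)."""
    close = False
    if isinstance(path, (str, Path)):
        handle = open(path)
        close = True
    else:
        handle = path
    out: list[GenomicInterval] = []
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: BED needs >=3 fields")
            chrom = fields[0]
            if exclude_random and is_random_chrom(chrom):
                continue
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in STRANDS else "."
            try:
                out.append(GenomicInterval(chrom, start, end, strand))
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    finally:
        if close:
            handle.close()
    return out


def write_bed(
    intervals: Iterable[GenomicInterval] | IntervalSet,
    path: str | Path | io.TextIOBase,
    *,
    names: Sequence[str] | None = None,
) -> None:
    """Write intervals as BED (BED3, or BED6 when names are given)."""
    close = False
    if isinstance(path, (str, Path)):
        handle = open(path, "w")
        close = True
    else:
        handle = path
    try:
        for i, iv in enumerate(intervals):
            if names is not None:
                handle.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{names[i]}\t0\t{iv.strand}\n"
                )
            else:
                handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    finally:
        if close:
            handle.close()


# -- FASTA --------------------------------------------------------------------

def read_fasta(
    path: str | Path | io.TextIOBase, *, exclude_random: bool = True
) -> dict[str, str]:
    """Read FASTA into {name: uppercase sequence}; soft-masking is lifted."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if exclude_random and is_random_chrom(rec.id):
            continue
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def fetch_sequence(seqs: Mapping[str, str], iv: GenomicInterval) -> str:
    """Sequence of an interval; unknown chromosome is an error."""
    if iv.chrom not in seqs:
        raise KeyError(f"unknown chromosome {iv.chrom!r}")
    return seqs[iv.chrom][iv.start : iv.end]


# -- CAGE tag table -----------------------------------------------------------

def read_cage_table(
    path: str | Path | io.TextIOBase,
    *,
    min_identity: float = 0.88,
    exclude_random: bool = True,
) -> list[tuple[str, int, str]]:
    """Read a CAGE tag table (chrom, pos, strand[, identity]) -> records.

    Tags whose mapping identity falls below ``min_identity`` are discarded;
    rows without an identity column are kept.
    """
    close = False
    if isinstance(path, (str, Path)):
        handle = open(path)
        close = True
    else:
        handle = path
    out: list[tuple[str, int, str]] = []
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: CAGE row needs >=3 fields")
            chrom, pos_s, strand = fields[0], fields[1], fields[2]
            if exclude_random and is_random_chrom(chrom):
                continue
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            if len(fields) >= 4 and fields[3] not in ("", "."):
                try:
                    ident = float(fields[3])
                except ValueError as exc:
                    raise ParseError(f"line {lineno}: {exc}") from exc
                if ident < min_identity:
                    continue
            out.append((chrom, pos, strand if strand in STRANDS else "."))
    finally:
        if close:
            handle.close()
    return out


def read_chrom_sizes(path: str | Path | io.TextIOBase) -> dict[str, int]:
    """Read a two-column chrom/size table."""
    close = False
    if isinstance(path, (str, Path)):
        handle = open(path)
        close = True
    else:
        handle = path
    sizes: dict[str, int] = {}
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"line {lineno}: chrom sizes need 2 fields")
            sizes[fields[0]] = int(fields[1])
    finally:
        if close:
            handle.close()
    return sizes
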