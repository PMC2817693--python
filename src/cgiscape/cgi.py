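"""CpG island detection and gene-relative classification.

A CpG island (CGI) is a segment longer than 200 bp with G+C content above 50%
and an observed/expected CpG ratio of at least 0.6, where the expectation
assumes independent letters with the segment's own composition.  Detected or
imported islands are classified into four mutually exclusive classes by their
overlap with gene elements, with 5' precedence: a single bp of overlap with
any gene's 5' region makes a CGI 5' regardless of what else it touches.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from cgiscape._util import round_half_away
from cgiscape.core_io import GeneModel, GenomicInterval, IntervalSet
from cgiscape.gene_elements import (
    ElementAnnotation,
    FIVE_PRIME_GROUPS,
    INTERNAL_GROUPS,
    THREE_PRIME_GROUPS,
    build_elements,
)

__all__ = [
    "CgiClass",
    "CpGIsland",
    "gc_fraction",
    "obs_exp_cpg",
    "detect_cgis",
    "cgis_from_intervals",
    "classify_cgis",
    "class_census",
    "cgi_interval_set",
]


class CgiClass(str, enum.Enum):
    FIVE_PRIME = "five_prime"
    INTRAGENIC = "intragenic"
    THREE_PRIME = "three_prime"
    INTERGENIC = "intergenic"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


CLASS_ORDER = (
    CgiClass.FIVE_PRIME,
    CgiClass.INTRAGENIC,
    CgiClass.THREE_PRIME,
    CgiClass.INTERGENIC,
)


@dataclass
class CpGIsland:
    """A CpG island with composition statistics and (optional) class label."""

    interval: GenomicInterval
    gc_fraction: float
    obs_exp_cpg: float
    cgi_class: CgiClass | None = None
    cage_count: int = 0

    @property
    def length(self) -> int:
        return self.interval.length


_BASES = {"A", "C", "G", "T"}


def gc_fraction(seq: str) -> float:
    """G+C fraction of a sequence; N (or other ambiguity) positions excluded."""
    seq = seq.upper()
    n_eff = sum(seq.count(b) for b in _BASES)
    if n_eff == 0:
        raise ValueError("sequence has no unambiguous bases")
    return (seq.count("C") + seq.count("G")) / n_eff


def obs_exp_cpg(seq: str) -> float:
    """Observed/expected CpG ratio: (#CpG * N) / (#C * #G).

    N is the number of unambiguous bases; CpG pairs broken by an ambiguous
    base are not counted.  Returns 0 when the sequence has no C or no G.
    """
    seq = seq.upper()
    n_eff = sum(seq.count(b) for b in _BASES)
    if n_eff == 0:
        raise ValueError("sequence has no unambiguous bases")
    c, g = seq.count("C"), seq.count("G")
    cpg = seq.count("CG")
    if c == 0 or g == 0:
        return 0.0
    return cpg * n_eff / (c * g)


def _encode(seq: str) -> np.ndarray:
    lookup = np.zeros(256, dtype=np.int8)
    lookup[:] = -1
    for i, b in enumerate("ACGT"):
        lookup[ord(b)] = i
    return lookup[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def detect_cgis(
    seq: str,
    chrom: str = "chr1",
    *,
    min_len: int = 201,
    window: int = 200,
    min_gc: float = 0.5,
    min_oe: float = 0.6,
) -> list[CpGIsland]:
    """Detect CpG islands by a sliding-window seed/extend/merge scheme.

    Every ``window``-bp window meeting the G+C and observed/expected
    thresholds is a seed; the union of overlapping or adjacent qualifying
    windows forms candidate segments, which are then re-checked against all
    three criteria (length >= ``min_len``, G+C > ``min_gc``,
    obs/exp >= ``min_oe``) on their full extent.  Segments failing the
    re-check are discarded.
    """
    n = len(seq)
    if n < window:
        return []
    code = _encode(seq)
    is_c = (code == 1).astype(np.int64)
    is_g = (code == 2).astype(np.int64)
    is_acgt = (code >= 0).astype(np.int64)
    is_cpg = np.zeros(n, dtype=np.int64)
    is_cpg[:-1] = (code[:-1] == 1) & (code[1:] == 2)

    def windowed(x: np.ndarray, w: int) -> np.ndarray:
        c = np.concatenate([[0], np.cumsum(x)])
        return c[w:] - c[:-w]

    c_w = windowed(is_c, window)
    g_w = windowed(is_g, window)
    eff_w = windowed(is_acgt, window)
    # CpG whose C sits in the window's last position pairs with the next base;
    # count pairs fully inside the window.
    cpg_w = windowed(is_cpg, window).copy()
    last = np.arange(window - 1, n)
    cpg_w -= is_cpg[last]  # drop the pair spanning the window's right edge

    with np.errstate(divide="ignore", invalid="ignore"):
        gc_ok = (c_w + g_w) > min_gc * np.maximum(eff_w, 1)
        oe = np.where(c_w * g_w > 0, cpg_w * eff_w / np.maximum(c_w * g_w, 1), 0.0)
    qualifying = gc_ok & (oe >= min_oe) & (eff_w == window)

    islands: list[CpGIsland] = []
    starts = np.flatnonzero(qualifying)
    if not len(starts):
        return islands
    # merge overlapping/adjacent qualifying windows
    seg_start = int(starts[0])
    seg_end = seg_start + window
    segments: list[tuple[int, int]] = []
    for s in starts[1:]:
        s = int(s)
        if s <= seg_end:
            seg_end = s + window
        else:
            segments.append((seg_start, seg_end))
            seg_start, seg_end = s, s + window
    segments.append((seg_start, seg_end))

    for s, e in segments:
        sub = seq[s:e]
        if e - s < min_len:
            continue
        gc = gc_fraction(sub)
        oe_val = obs_exp_cpg(sub)
        if gc > min_gc and oe_val >= min_oe:
            islands.append(
                CpGIsland(GenomicInterval(chrom, s, e), gc, oe_val)
            )
    return islands


def cgis_from_intervals(
    intervals: Iterable[GenomicInterval],
    seqs: Mapping[str, str] | None = None,
    *,
    validate: bool = True,
) -> list[CpGIsland]:
    """Wrap imported (e.g. precomputed-track) intervals as CpG islands.

    Imported islands are trusted as-is; when genome sequence is supplied their
    composition is computed and criterion violations are *warned*, not
    enforced, since external annotation pipelines use differing algorithms.
    """
    out: list[CpGIsland] = []
    for iv in intervals:
        gc = oe = float("nan")
        if seqs is not None and iv.chrom in seqs:
            sub = seqs[iv.chrom][iv.start : iv.end]
            try:
                gc, oe = gc_fraction(sub), obs_exp_cpg(sub)
            except ValueError:
                pass
            if validate and not (iv.length > 200 and gc > 0.5 and oe >= 0.6):
                warnings.warn(
                    f"imported island {iv.chrom}:{iv.start}-{iv.end} does not "
                    f"meet detection criteria (len={iv.length}, gc={gc:.3f}, "
                    f"oe={oe:.3f})",
                    stacklevel=2,
                )
        out.append(CpGIsland(iv, gc, oe))
    return out


def _overlaps(iset: IntervalSet, iv: GenomicInterval) -> bool:
    arr = iset.array(iv.chrom)
    if not len(arr):
        return False
    i = np.searchsorted(arr[:, 0], iv.end, side="left")
    return i > 0 and arr[i - 1, 1] > iv.start


def classify_cgis(
    cgis: Sequence[CpGIsland],
    genes: Sequence[GeneModel],
    elements: ElementAnnotation | None = None,
    *,
    near_bp: int = 3000,
) -> list[CpGIsland]:
    """Assign each CGI to one of the four gene-relative classes (in place).

    All genes — including single- and double-exon models — participate.
    Precedence: one bp of overlap with any gene's 5' region (flank, 5' UTR
    exons/introns, initial coding exon, initial intron) makes the island 5';
    otherwise overlap with a 3' region (final exon/intron, 3' UTR, or the
    ``near_bp`` window downstream of the transcript end) makes it 3';
    otherwise overlap with any gene body makes it intragenic; islands at
    least ``near_bp`` away from every gene are intergenic.
    """
    if elements is None:
        elements = build_elements(genes, flank_bp=near_bp)
    five_set = elements.union(FIVE_PRIME_GROUPS)
    downstream = IntervalSet(
        GenomicInterval(
            g.chrom,
            g.tx_end if g.strand == "+" else max(0, g.tx_start - near_bp),
            g.tx_end + near_bp if g.strand == "+" else g.tx_start,
            g.strand,
        )
        for g in genes
        if (g.tx_end + near_bp if g.strand == "+" else g.tx_start) > 0
    )
    three_set = elements.union(THREE_PRIME_GROUPS).union(downstream)
    body_set = IntervalSet(
        GenomicInterval(g.chrom, g.tx_start, g.tx_end, g.strand) for g in genes
    ).union(elements.union(INTERNAL_GROUPS))

    for cgi in cgis:
        iv = cgi.interval
        if _overlaps(five_set, iv):
            cgi.cgi_class = CgiClass.FIVE_PRIME
        elif _overlaps(three_set, iv):
            cgi.cgi_class = CgiClass.THREE_PRIME
        elif _overlaps(body_set, iv):
            cgi.cgi_class = CgiClass.INTRAGENIC
        else:
            cgi.cgi_class = CgiClass.INTERGENIC
    return list(cgis)


def cgi_interval_set(
    cgis: Iterable[CpGIsland], cgi_class: CgiClass | None = None
) -> IntervalSet:
    """IntervalSet of (optionally one class of) CGIs."""
    return IntervalSet(
        c.interval
        for c in cgis
        if cgi_class is None or c.cgi_class == cgi_class
    )


def class_census(cgis: Sequence[CpGIsland]) -> pd.DataFrame:
    """Per-class counts, total lengths, mean GC and class fractions.

    Fractions are count/total * 100, rounded half away from zero to 2
    decimals.  An empty input yields an all-zero census.
    """
    rows = []
    total = len(cgis)
    for cls in CLASS_ORDER:
        members = [c for c in cgis if c.cgi_class == cls]
        n = len(members)
        rows.append(
            {
                "cgi_class": cls.value,
                "n_cgis": n,
                "total_length": sum(c.length for c in members),
                "mean_gc_pct": (
                    round_half_away(
                        100 * float(np.mean([c.gc_fraction for c in members])), 2
                    )
                    if n
                    else float("nan")
                ),
                "fraction_pct": (
                    round_half_away(100 * n / total, 2) if total else 0.0
                ),
            }
        )
    return pd.DataFrame(rows).set_index("cgi_class")
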