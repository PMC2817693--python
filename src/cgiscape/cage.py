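"""CAGE tag assignment, per-class density summaries and transcript association.

Each mapped CAGE tag marks one transcription start event.  Tags are assigned
to CpG islands strand-blind by position (half-open containment), per-class
density statistics are tabulated, CAGE-enriched islands are selected by tag
count bands, and non-5' islands are associated with the highest-priority
transcript catalogue (RefSeq > mRNA > EST) that has a start inside them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cgiscape._util import round_half_away
from cgiscape.cgi import CLASS_ORDER, CgiClass, CpGIsland

__all__ = [
    "TranscriptCategory",
    "assign_tags",
    "summarize",
    "select_enriched",
    "associate_transcripts",
    "association_matrix",
]


class TranscriptCategory(str, enum.Enum):
    REFSEQ = "refseq"
    MRNA = "mrna"
    EST = "est"
    NONE = "none"


def assign_tags(
    cgis: Sequence[CpGIsland], tags: Sequence[tuple[str, int, str]]
) -> list[CpGIsland]:
    """Count tags per CGI (in place): a tag at position p is counted for a
    CGI [start, end) when start <= p < end, regardless of strand."""
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos, _strand in tags:
        by_chrom.setdefault(chrom, []).append(pos)
    pos_sorted = {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in by_chrom.items()}
    for cgi in cgis:
        iv = cgi.interval
        arr = pos_sorted.get(iv.chrom)
        if arr is None:
            cgi.cage_count = 0
            continue
        lo = np.searchsorted(arr, iv.start, side="left")
        hi = np.searchsorted(arr, iv.end, side="left")
        cgi.cage_count = int(hi - lo)
    return list(cgis)


@dataclass(frozen=True)
class _ClassTotals:
    n_cgis: int
    total_length: int
    mean_gc_pct: float
    n_with_tags: int
    length_with_tags: int
    tags: int


def _totals(members: Sequence[CpGIsland]) -> _ClassTotals:
    tagged = [c for c in members if c.cage_count > 0]
    gcs = [c.gc_fraction for c in members if not np.isnan(c.gc_fraction)]
    return _ClassTotals(
        n_cgis=len(members),
        total_length=sum(c.length for c in members),
        mean_gc_pct=100 * float(np.mean(gcs)) if gcs else float("nan"),
        n_with_tags=len(tagged),
        length_with_tags=sum(c.length for c in tagged),
        tags=sum(c.cage_count for c in members),
    )


def summarize(
    cgis: Sequence[CpGIsland],
    total_tags_genomewide: int,
    *,
    from_totals: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Per-class CAGE summary table (classes as columns, plus a total column).

    Statistics and rounding conventions: densities (tags per bp) to 4
    decimals; percentages to 2 decimals; per-CGI tag means and bp-per-tag to
    the nearest integer — all rounding half away from zero.  The class
    partition's derived cells are pure arithmetic on the per-class counts,
    lengths and tag totals, so the function also accepts precomputed totals
    via ``from_totals`` ({class: {n_cgis, total_length, mean_gc_pct,
    n_with_tags, length_with_tags, tags}}) to tabulate an external census.
    """
    classes = [c.value for c in CLASS_ORDER]
    totals: dict[str, _ClassTotals] = {}
    if from_totals is not None:
        for cls in classes + ["total"]:
            t = from_totals[cls]
            totals[cls] = _ClassTotals(
                n_cgis=int(t["n_cgis"]),
                total_length=int(t["total_length"]),
                mean_gc_pct=float(t.get("mean_gc_pct", float("nan"))),
                n_with_tags=int(t["n_with_tags"]),
                length_with_tags=int(t["length_with_tags"]),
                tags=int(t["tags"]),
            )
    else:
        for cls in classes:
            totals[cls] = _totals(
                [c for c in cgis if c.cgi_class is not None and c.cgi_class.value == cls]
            )
        all_t = _totals(list(cgis))
        totals["total"] = all_t

    grand_n = totals["total"].n_cgis
    out: dict[str, dict[str, float]] = {}
    for cls in classes + ["total"]:
        t = totals[cls]
        col: dict[str, float] = {}
        col["n_cgis"] = t.n_cgis
        col["fraction_of_cgis_pct"] = (
            round_half_away(100 * t.n_cgis / grand_n, 2) if grand_n else 0.0
        )
        col["total_length"] = t.total_length
        col["mean_gc_pct"] = (
            round_half_away(t.mean_gc_pct, 2)
            if not np.isnan(t.mean_gc_pct)
            else float("nan")
        )
        col["n_cgis_with_tags"] = t.n_with_tags
        col["length_with_tags"] = t.length_with_tags
        col["pct_length_with_tags"] = (
            round_half_away(100 * t.length_with_tags / t.total_length, 2)
            if t.total_length
            else float("nan")
        )
        col["tags_in_class"] = t.tags
        col["fraction_of_all_tags_pct"] = (
            round_half_away(100 * t.tags / total_tags_genomewide, 2)
            if total_tags_genomewide
            else float("nan")
        )
        col["pct_cgis_with_tag"] = (
            round_half_away(100 * t.n_with_tags / t.n_cgis, 2)
            if t.n_cgis
            else float("nan")
        )
        col["mean_tags_per_cgi"] = (
            round_half_away(t.tags / t.n_cgis, 0) if t.n_cgis else float("nan")
        )
        col["mean_tags_per_tagged_cgi"] = (
            round_half_away(t.tags / t.n_with_tags, 0)
            if t.n_with_tags
            else float("nan")
        )
        col["density_per_bp"] = (
            round_half_away(t.tags / t.total_length, 4)
            if t.total_length
            else float("nan")
        )
        col["density_per_bp_tagged"] = (
            round_half_away(t.tags / t.length_with_tags, 4)
            if t.length_with_tags
            else float("nan")
        )
        col["bp_per_tag"] = (
            round_half_away(t.total_length / t.tags, 0) if t.tags else float("nan")
        )
        out[cls] = col
    return pd.DataFrame(out)


def select_enriched(
    cgis: Sequence[CpGIsland],
    min_tags: float,
    max_tags: float = float("inf"),
    *,
    classes: Sequence[CgiClass] | None = None,
    inclusive_min: bool = False,
) -> list[CpGIsland]:
    """Filter CGIs by tag-count band.

    The default band semantics match the "> min" convention (a CGI with
    exactly ``min_tags`` tags is excluded); with ``inclusive_min`` the band
    is [min_tags, max_tags] as in a "20-40 tags" selection.  ``classes``
    optionally restricts to given CGI classes.
    """
    if min_tags > max_tags:
        raise ValueError("min_tags > max_tags")
    out = []
    for c in cgis:
        if classes is not None and c.cgi_class not in classes:
            continue
        lo_ok = c.cage_count >= min_tags if inclusive_min else c.cage_count > min_tags
        if lo_ok and c.cage_count <= max_tags:
            out.append(c)
    return out


def associate_transcripts(
    cgis: Sequence[CpGIsland],
    refseq_starts: Sequence[tuple[str, int]],
    mrna_starts: Sequence[tuple[str, int]],
    est_starts: Sequence[tuple[str, int]],
) -> list[TranscriptCategory]:
    """Associate each CGI with the highest-priority transcript catalogue.

    Each catalogue is a list of (chrom, TSS) positions.  The category is the
    first of RefSeq, mRNA, EST with at least one start inside the CGI, else
    ``none`` — categories are mutually exclusive by priority.
    """
    def index(starts: Sequence[tuple[str, int]]) -> dict[str, np.ndarray]:
        by: dict[str, list[int]] = {}
        for chrom, pos in starts:
            by.setdefault(chrom, []).append(pos)
        return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in by.items()}

    catalogues = [
        (TranscriptCategory.REFSEQ, index(refseq_starts)),
        (TranscriptCategory.MRNA, index(mrna_starts)),
        (TranscriptCategory.EST, index(est_starts)),
    ]
    out = []
    for cgi in cgis:
        iv = cgi.interval
        cat = TranscriptCategory.NONE
        for name, idx in catalogues:
            arr = idx.get(iv.chrom)
            if arr is None:
                continue
            lo = np.searchsorted(arr, iv.start, side="left")
            hi = np.searchsorted(arr, iv.end, side="left")
            if hi > lo:
                cat = name
                break
        out.append(cat)
    return out


def association_matrix(
    cgis: Sequence[CpGIsland],
    categories: Sequence[TranscriptCategory],
    *,
    bands: Sequence[tuple[float, float, bool]] = ((40, float("inf"), False), (20, 40, True)),
    classes: Sequence[CgiClass] = (CgiClass.THREE_PRIME, CgiClass.INTRAGENIC),
) -> pd.DataFrame:
    """Count matrix of transcript association per CGI class and tag band.

    ``bands`` are (min, max, inclusive_min) tuples; the default reproduces
    the ">40 tags" and "20-40 tags" selections.
    """
    rows = []
    for lo, hi, inc in bands:
        band_label = (
            f">{lo:g}" if hi == float("inf") and not inc else f"{lo:g}-{hi:g}"
        )
        for cls in classes:
            counts = {c: 0 for c in TranscriptCategory}
            total = 0
            for cgi, cat in zip(cgis, categories):
                if cgi.cgi_class != cls:
                    continue
                lo_ok = cgi.cage_count >= lo if inc else cgi.cage_count > lo
                if not (lo_ok and cgi.cage_count <= hi):
                    continue
                counts[cat] += 1
                total += 1
            rows.append(
                {
                    "band": band_label,
                    "cgi_class": cls.value,
                    "refseq": counts[TranscriptCategory.REFSEQ],
                    "mrna": counts[TranscriptCategory.MRNA],
                    "est": counts[TranscriptCategory.EST],
                    "none": counts[TranscriptCategory.NONE],
                    "total": total,
                }
            )
    return pd.DataFrame(rows)
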