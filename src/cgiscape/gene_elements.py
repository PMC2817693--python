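"""Gene-element categories and intron-terminal segments.

A filtered gene set (deduplicated, >=3 exons) is decomposed into 11
categories of gene fragments: the 3 kb 5' flank, 5' UTR exons/introns, the
initial coding exon and intron, internal exons/introns, the final coding exon
and intron, and 3' UTR exons/introns.  Later categories subtract earlier ones
where the definitions require it (e.g. the 5' flank excludes all transcribed
sequence; UTR categories exclude translated sequence).  Because introns dwarf
exons in length, 200 bp intron segments flanking the donor and acceptor
splice sites are carried as additional element sets comparable to exons.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from cgiscape.core_io import GeneModel, GenomicInterval, IntervalSet

__all__ = [
    "ElementCategory",
    "ElementAnnotation",
    "build_elements",
    "intron_terminal_regions",
    "INTRON_CATEGORIES",
    "FIVE_PRIME_GROUPS",
    "THREE_PRIME_GROUPS",
    "INTERNAL_GROUPS",
]


class ElementCategory(str, enum.Enum):
    """The 11 gene-element categories, in definition (exclusion) order."""

    FIVE_FLANK = "five_flank"
    UTR5_EXON = "utr5_exon"
    UTR5_INTRON = "utr5_intron"
    INITIAL_CODING_EXON = "initial_coding_exon"
    INITIAL_INTRON = "initial_intron"
    INTERNAL_EXON = "internal_exon"
    INTERNAL_INTRON = "internal_intron"
    FINAL_EXON = "final_exon"
    FINAL_INTRON = "final_intron"
    UTR3_EXON = "utr3_exon"
    UTR3_INTRON = "utr3_intron"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


INTRON_CATEGORIES = (
    ElementCategory.UTR5_INTRON,
    ElementCategory.INITIAL_INTRON,
    ElementCategory.INTERNAL_INTRON,
    ElementCategory.FINAL_INTRON,
    ElementCategory.UTR3_INTRON,
)

#: groups 1-5: overlap defines a 5' CGI
FIVE_PRIME_GROUPS = (
    ElementCategory.FIVE_FLANK,
    ElementCategory.UTR5_EXON,
    ElementCategory.UTR5_INTRON,
    ElementCategory.INITIAL_CODING_EXON,
    ElementCategory.INITIAL_INTRON,
)

#: groups 8-11: overlap defines a 3' CGI
THREE_PRIME_GROUPS = (
    ElementCategory.FINAL_EXON,
    ElementCategory.FINAL_INTRON,
    ElementCategory.UTR3_EXON,
    ElementCategory.UTR3_INTRON,
)

#: groups 6-7: overlap defines an intragenic CGI
INTERNAL_GROUPS = (
    ElementCategory.INTERNAL_EXON,
    ElementCategory.INTERNAL_INTRON,
)


@dataclass
class ElementAnnotation:
    """Element sets plus the stranded raw introns they were derived from."""

    sets: dict[ElementCategory, IntervalSet]
    stranded_introns: dict[ElementCategory, list[GenomicInterval]]
    n_noncoding_excluded: int = 0
    flank_bp: int = 3000

    def union(self, categories: Iterable[ElementCategory]) -> IntervalSet:
        out = IntervalSet()
        for cat in categories:
            out = out.union(self.sets[cat])
        return out


def _clip(iv: GenomicInterval, start: int, end: int) -> GenomicInterval | None:
    s, e = max(iv.start, start), min(iv.end, end)
    if s >= e:
        return None
    return GenomicInterval(iv.chrom, s, e, iv.strand)


def _per_gene_elements(
    g: GeneModel, flank_bp: int
) -> dict[ElementCategory, list[GenomicInterval]]:
    """Raw per-gene category intervals, before merging and exclusions."""
    out: dict[ElementCategory, list[GenomicInterval]] = {
        c: [] for c in ElementCategory
    }
    exons = list(g.exons)
    introns = list(g.introns)  # genomic order; intron i sits after exon i

    # transcript orientation: index sequences run 5'->3'
    if g.strand == "+":
        ex_order = list(range(len(exons)))
        intr_order = list(range(len(introns)))
    else:
        ex_order = list(range(len(exons)))[::-1]
        intr_order = list(range(len(introns)))[::-1]

    # 5' flank: 3 kb upstream of the TSS, clamped at 0
    if g.strand == "+":
        fs, fe = max(0, g.tx_start - flank_bp), g.tx_start
    else:
        fs, fe = g.tx_end, g.tx_end + flank_bp
    if fs < fe:
        out[ElementCategory.FIVE_FLANK].append(
            GenomicInterval(g.chrom, fs, fe, g.strand)
        )

    cds_s, cds_e = g.cds_start, g.cds_end
    coding_tpos = [
        t for t, gi in enumerate(ex_order)
        if exons[gi].start < cds_e and exons[gi].end > cds_s
    ]
    if not coding_tpos:
        return out
    first_c, last_c = coding_tpos[0], coding_tpos[-1]

    # UTR regions in genomic coordinates
    if g.strand == "+":
        utr5_span, utr3_span = (g.tx_start, cds_s), (cds_e, g.tx_end)
    else:
        utr5_span, utr3_span = (cds_e, g.tx_end), (g.tx_start, cds_s)

    for t, gi in enumerate(ex_order):
        ex = exons[gi]
        u5 = _clip(ex, *utr5_span)
        if u5:
            out[ElementCategory.UTR5_EXON].append(u5)
        u3 = _clip(ex, *utr3_span)
        if u3:
            out[ElementCategory.UTR3_EXON].append(u3)
        if t in coding_tpos:
            cex = _clip(ex, cds_s, cds_e)
            if cex is None:
                continue
            if t == first_c:
                out[ElementCategory.INITIAL_CODING_EXON].append(cex)
            elif t == last_c:
                out[ElementCategory.FINAL_EXON].append(cex)
            else:
                out[ElementCategory.INTERNAL_EXON].append(cex)

    # introns: transcript position t separates exon t and exon t+1 (5'->3')
    for t, gi in enumerate(intr_order):
        intr = introns[gi]
        if t < first_c:
            out[ElementCategory.UTR5_INTRON].append(intr)
        elif t == first_c and last_c > first_c:
            out[ElementCategory.INITIAL_INTRON].append(intr)
        elif t == last_c - 1 and last_c - 1 > first_c:
            out[ElementCategory.FINAL_INTRON].append(intr)
        elif first_c < t < last_c - 1:
            out[ElementCategory.INTERNAL_INTRON].append(intr)
        elif t >= last_c:
            out[ElementCategory.UTR3_INTRON].append(intr)
    return out


def build_elements(
    genes: Sequence[GeneModel], flank_bp: int = 3000
) -> ElementAnnotation:
    """Build the 11 element categories from a gene set.

    Strand-aware: on "-" genes the TSS is ``tx_end`` and transcript order is
    reversed.  Non-coding genes (cdsStart == cdsEnd) are excluded and counted.
    Exclusions follow the category numbering: the 5' flank subtracts all
    transcribed sequence, UTR exon/intron sets subtract all translated
    sequence, the initial intron subtracts groups 1-4, internal exons subtract
    initial/final coding exons, and the remaining intron/UTR categories
    subtract translated sequence.
    """
    raw: dict[ElementCategory, list[GenomicInterval]] = {
        c: [] for c in ElementCategory
    }
    n_noncoding = 0
    coding_genes: list[GeneModel] = []
    for g in genes:
        if not g.is_coding:
            n_noncoding += 1
            continue
        coding_genes.append(g)
        per = _per_gene_elements(g, flank_bp)
        for cat, ivs in per.items():
            raw[cat].extend(ivs)

    transcribed = IntervalSet(
        GenomicInterval(g.chrom, g.tx_start, g.tx_end, g.strand)
        for g in coding_genes
    )
    translated = IntervalSet(
        iv
        for g in coding_genes
        for ex in g.exons
        if (iv := _clip(ex, g.cds_start, g.cds_end)) is not None
    )

    sets = {cat: IntervalSet(ivs) for cat, ivs in raw.items()}
    C = ElementCategory
    sets[C.FIVE_FLANK] = sets[C.FIVE_FLANK].subtract(transcribed)
    sets[C.UTR5_EXON] = sets[C.UTR5_EXON].subtract(translated)
    sets[C.UTR5_INTRON] = sets[C.UTR5_INTRON].subtract(translated)
    groups_1_4 = (
        sets[C.FIVE_FLANK]
        .union(sets[C.UTR5_EXON])
        .union(sets[C.UTR5_INTRON])
        .union(sets[C.INITIAL_CODING_EXON])
    )
    sets[C.INITIAL_INTRON] = sets[C.INITIAL_INTRON].subtract(groups_1_4)
    sets[C.INTERNAL_EXON] = sets[C.INTERNAL_EXON].subtract(
        sets[C.INITIAL_CODING_EXON].union(sets[C.FINAL_EXON])
    )
    sets[C.INTERNAL_INTRON] = sets[C.INTERNAL_INTRON].subtract(translated)
    sets[C.FINAL_INTRON] = sets[C.FINAL_INTRON].subtract(translated)
    sets[C.UTR3_EXON] = sets[C.UTR3_EXON].subtract(translated)
    sets[C.UTR3_INTRON] = sets[C.UTR3_INTRON].subtract(translated)

    stranded = {cat: raw[cat] for cat in INTRON_CATEGORIES}
    return ElementAnnotation(
        sets=sets,
        stranded_introns=stranded,
        n_noncoding_excluded=n_noncoding,
        flank_bp=flank_bp,
    )


def intron_terminal_regions(
    introns: Iterable[GenomicInterval], w: int = 200
) -> tuple[IntervalSet, IntervalSet]:
    """Donor- and acceptor-side terminal segments of introns.

    For each intron the first and last ``w`` bp in transcript orientation are
    returned (donor side abuts the upstream exon).  Introns shorter than
    ``2*w`` are split at their midpoint so the two segments stay disjoint and
    never jointly exceed the intron.
    """
    donor: list[GenomicInterval] = []
    acceptor: list[GenomicInterval] = []
    for iv in introns:
        strand = iv.strand if iv.strand in ("+", "-") else "+"
        if iv.length >= 2 * w:
            low = (iv.start, iv.start + w)
            high = (iv.end - w, iv.end)
        else:
            mid = iv.start + iv.length // 2
            low = (iv.start, mid)
            high = (mid, iv.end)
        lo_iv = GenomicInterval(iv.chrom, *low, strand) if low[0] < low[1] else None
        hi_iv = GenomicInterval(iv.chrom, *high, strand) if high[0] < high[1] else None
        if strand == "+":
            if lo_iv:
                donor.append(lo_iv)
            if hi_iv:
                acceptor.append(hi_iv)
        else:
            if hi_iv:
                donor.append(hi_iv)
            if lo_iv:
                acceptor.append(lo_iv)
    return IntervalSet(donor), IntervalSet(acceptor)
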