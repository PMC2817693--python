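"""Codon-class dS/dN estimation for alignments in and out of CpG islands.

The estimator follows the approximate codon-based scheme of Ina's method I:

1. the transition/transversion rate ratio is estimated from the corrected
   proportions of transitional and transversional differences over all codon
   sites (Kimura two-parameter formulas);
2. potential synonymous/nonsynonymous site counts weight each of the three
   possible mutations at a site by its relative rate — ``kappa`` for the
   transition, 1 for each transversion (``kappa`` is the transition rate per
   transversion-type rate, i.e. twice the corrected transition/transversion
   count ratio);
3. synonymous and nonsynonymous differences between codon pairs are counted
   by enumerating minimal mutational pathways, equally weighted, with
   pathways through stop codons excluded (unless all are blocked);
4. the transition and transversion proportions at synonymous and
   nonsynonymous sites receive the Kimura two-parameter multiple-hit
   correction, yielding dS and dN.

Saturated corrections (non-positive log arguments) are flagged as undefined,
never silently clipped.  All heavy computation is expressed over a 64x64
codon-pair count vector so that 2000-replicate bootstraps stay cheap.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from cgiscape._util import round_half_away
from cgiscape.core_io import IntervalSet

__all__ = [
    "CodonAlignment",
    "SubstitutionRates",
    "AlignmentRecord",
    "filter_alignments",
    "select_codon_class",
    "mark_in_cgi",
    "ina_estimate",
    "bootstrap_ci",
    "rates_report",
    "dn_ds_ratio",
    "ds_reduction_pct",
    "CODON_CLASSES",
    "EXON_POSITIONS",
]

BASES = "ACGT"
CODON_CLASSES = ("CG", "GC", "AG", "GA")
EXON_POSITIONS = ("initial", "internal", "final")

_CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
_CODON_INDEX = {c: i for i, c in enumerate(_CODONS)}

_STANDARD_CODE = {}
_STOPS = {"TAA", "TAG", "TGA"}


def _build_code() -> None:
    from Bio.Data.CodonTable import standard_dna_table

    for codon in _CODONS:
        if codon in standard_dna_table.stop_codons:
            _STANDARD_CODE[codon] = "*"
        else:
            _STANDARD_CODE[codon] = standard_dna_table.forward_table[codon]


_build_code()

_IS_STOP = np.array([_STANDARD_CODE[c] == "*" for c in _CODONS])
_AA = np.array([_STANDARD_CODE[c] for c in _CODONS])

#: public views used by the simulator and tests
CODONS = tuple(_CODONS)
IS_STOP = _IS_STOP
AMINO_ACIDS = _AA

_TRANSITION = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _is_transition(a: str, b: str) -> bool:
    return (a, b) in _TRANSITION


# -- per-codon potential-site tallies (numbers of synonymous mutations) -------

_SYN_TS = np.zeros(64)
_SYN_TV = np.zeros(64)
for _ci, _codon in enumerate(_CODONS):
    if _STANDARD_CODE[_codon] == "*":
        continue
    for _pos in range(3):
        for _alt in BASES:
            if _alt == _codon[_pos]:
                continue
            _mut = _codon[:_pos] + _alt + _codon[_pos + 1:]
            _syn = (
                _STANDARD_CODE[_mut] != "*"
                and _STANDARD_CODE[_mut] == _STANDARD_CODE[_codon]
            )
            if _syn:
                if _is_transition(_codon[_pos], _alt):
                    _SYN_TS[_ci] += 1
                else:
                    _SYN_TV[_ci] += 1


# -- per-pair difference tallies (pathway enumeration) ------------------------

def _pair_tables() -> dict[str, np.ndarray]:
    """Codon-pair statistics indexed by 64*i + j.

    ``ts_diff``/``tv_diff``: per-site difference classification;
    ``syn_ts/syn_tv/nonsyn_ts/nonsyn_tv``: pathway-averaged difference counts.
    """
    n = 64 * 64
    ts_diff = np.zeros(n)
    tv_diff = np.zeros(n)
    syn_ts = np.zeros(n)
    syn_tv = np.zeros(n)
    nonsyn_ts = np.zeros(n)
    nonsyn_tv = np.zeros(n)
    for i, c1 in enumerate(_CODONS):
        for j, c2 in enumerate(_CODONS):
            k = 64 * i + j
            diff_pos = [p for p in range(3) if c1[p] != c2[p]]
            for p in diff_pos:
                if _is_transition(c1[p], c2[p]):
                    ts_diff[k] += 1
                else:
                    tv_diff[k] += 1
            if not diff_pos:
                continue
            paths = []
            for order in itertools.permutations(diff_pos):
                cur = c1
                steps = []
                blocked = False
                for p in order:
                    nxt = cur[:p] + c2[p] + cur[p + 1:]
                    steps.append((cur, nxt))
                    if _STANDARD_CODE[nxt] == "*" and nxt != c2:
                        blocked = True
                    cur = nxt
                paths.append((blocked, steps))
            usable = [s for b, s in paths if not b] or [s for _, s in paths]
            w = 1.0 / len(usable)
            for steps in usable:
                for cur, nxt in steps:
                    p = next(q for q in range(3) if cur[q] != nxt[q])
                    ts = _is_transition(cur[p], nxt[p])
                    syn = (
                        _STANDARD_CODE[cur] != "*"
                        and _STANDARD_CODE[nxt] != "*"
                        and _STANDARD_CODE[cur] == _STANDARD_CODE[nxt]
                    )
                    if syn and ts:
                        syn_ts[k] += w
                    elif syn:
                        syn_tv[k] += w
                    elif ts:
                        nonsyn_ts[k] += w
                    else:
                        nonsyn_tv[k] += w
    site_syn_ts = np.add.outer(_SYN_TS, _SYN_TS).ravel() / 2.0
    site_syn_tv = np.add.outer(_SYN_TV, _SYN_TV).ravel() / 2.0
    return {
        "ts_diff": ts_diff,
        "tv_diff": tv_diff,
        "syn_ts": syn_ts,
        "syn_tv": syn_tv,
        "nonsyn_ts": nonsyn_ts,
        "nonsyn_tv": nonsyn_tv,
        "site_syn_ts": site_syn_ts,
        "site_syn_tv": site_syn_tv,
    }


_PAIR: dict[str, np.ndarray] = _pair_tables()


# -- containers ---------------------------------------------------------------

def encode_codons(seq: str) -> np.ndarray:
    """Encode an in-frame nucleotide sequence as codon indices (0..63)."""
    seq = seq.upper()
    if len(seq) % 3:
        raise ValueError("sequence length is not a multiple of 3")
    base_idx = {b: i for i, b in enumerate(BASES)}
    out = np.empty(len(seq) // 3, dtype=np.int16)
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if any(b not in base_idx for b in codon):
            raise ValueError(f"ambiguous or gapped codon {codon!r} at {i}")
        out[i // 3] = (
            16 * base_idx[codon[0]] + 4 * base_idx[codon[1]] + base_idx[codon[2]]
        )
    return out


def decode_codons(idx: np.ndarray) -> str:
    return "".join(_CODONS[i] for i in idx)


@dataclass
class CodonAlignment:
    """Paired in-frame codon sequences with per-codon annotation.

    ``codons1``/``codons2`` are codon indices (0..63).  Optional per-codon
    genome coordinates (``chrom``, ``start``: first base of the codon,
    occupying [start, start+3)), exon position labels and in-CGI flags
    support the partitioned substitution-rate reports.
    """

    codons1: np.ndarray
    codons2: np.ndarray
    chrom: np.ndarray | None = None
    start: np.ndarray | None = None
    exon_position: np.ndarray | None = None
    in_cgi: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.codons1 = np.asarray(self.codons1, dtype=np.int16)
        self.codons2 = np.asarray(self.codons2, dtype=np.int16)
        if self.codons1.shape != self.codons2.shape:
            raise ValueError("codon sequences differ in length")
        for arr in (self.codons1, self.codons2):
            if arr.size and (_IS_STOP[arr]).any():
                raise ValueError("alignment contains stop codons")
        if self.in_cgi is not None:
            self.in_cgi = np.asarray(self.in_cgi, dtype=bool)

    @classmethod
    def from_sequences(
        cls,
        seq1: str,
        seq2: str,
        *,
        chrom: str | Sequence[str] | None = None,
        starts: Sequence[int] | None = None,
        exon_position: str | Sequence[str] | None = None,
    ) -> "CodonAlignment":
        c1, c2 = encode_codons(seq1), encode_codons(seq2)
        n = len(c1)
        chrom_arr = None
        if chrom is not None:
            chrom_arr = (
                np.full(n, chrom) if isinstance(chrom, str) else np.asarray(chrom)
            )
        pos_arr = None
        if exon_position is not None:
            pos_arr = (
                np.full(n, exon_position)
                if isinstance(exon_position, str)
                else np.asarray(exon_position)
            )
        return cls(
            c1,
            c2,
            chrom=chrom_arr,
            start=np.asarray(starts, dtype=np.int64) if starts is not None else None,
            exon_position=pos_arr,
        )

    def __len__(self) -> int:
        return len(self.codons1)

    def subset(self, mask: np.ndarray) -> "CodonAlignment":
        mask = np.asarray(mask)
        return CodonAlignment(
            self.codons1[mask],
            self.codons2[mask],
            chrom=self.chrom[mask] if self.chrom is not None else None,
            start=self.start[mask] if self.start is not None else None,
            exon_position=(
                self.exon_position[mask] if self.exon_position is not None else None
            ),
            in_cgi=self.in_cgi[mask] if self.in_cgi is not None else None,
        )

    def concatenated(self, other: "CodonAlignment") -> "CodonAlignment":
        def cat(a, b):
            if a is None or b is None:
                return None
            return np.concatenate([a, b])

        return CodonAlignment(
            np.concatenate([self.codons1, other.codons1]),
            np.concatenate([self.codons2, other.codons2]),
            chrom=cat(self.chrom, other.chrom),
            start=cat(self.start, other.start),
            exon_position=cat(self.exon_position, other.exon_position),
            in_cgi=cat(self.in_cgi, other.in_cgi),
        )

    def pair_counts(self) -> np.ndarray:
        """Codon-pair count vector of length 4096 (64*c1 + c2)."""
        return np.bincount(
            64 * self.codons1.astype(np.int64) + self.codons2, minlength=4096
        ).astype(np.float64)


@dataclass(frozen=True)
class SubstitutionRates:
    """dN, dS and the transition/transversion ratio with uncertainty."""

    dn: float
    ds: float
    r: float  #: corrected transition/transversion count ratio
    kappa: float  #: transition rate per transversion-type rate (2r)
    n_codons: int
    saturated: bool = False
    ci95_dn: tuple[float, float] | None = None
    ci95_ds: tuple[float, float] | None = None
    n_boot_failed: int = 0

    @property
    def dn_ds(self) -> float:
        return self.dn / self.ds if self.ds > 0 else float("nan")

    def summary(self) -> str:
        lines = [
            "Substitution rate estimates (Ina-style method I)",
            f"  codon pairs : {self.n_codons}",
            f"  dN          : {self.dn:.4f}"
            + (f"  95% CI [{self.ci95_dn[0]:.4f}, {self.ci95_dn[1]:.4f}]"
               if self.ci95_dn else ""),
            f"  dS          : {self.ds:.4f}"
            + (f"  95% CI [{self.ci95_ds[0]:.4f}, {self.ci95_ds[1]:.4f}]"
               if self.ci95_ds else ""),
            f"  dN/dS       : {self.dn_ds:.4f}",
            f"  ts/tv ratio : R = {self.r:.3f} (kappa = {self.kappa:.3f})",
        ]
        if self.saturated:
            lines.append("  WARNING: correction saturated; estimates undefined")
        return "\n".join(lines)


# -- record-level filtering ---------------------------------------------------

@dataclass
class AlignmentRecord:
    """One gene isoform's alignment with the metadata the filters need."""

    gene: str
    isoform: str
    alignment: CodonAlignment
    n_coding_exons: int
    exon_protein_identity: tuple[float, ...] = field(default_factory=tuple)

    @property
    def length(self) -> int:
        return len(self.alignment)


def filter_alignments(
    records: Iterable[AlignmentRecord],
    *,
    min_coding_exons: int = 3,
    min_exon_identity: float = 0.70,
) -> list[AlignmentRecord]:
    """Apply the gene-level inclusion rules.

    Keeps the longest isoform per gene, drops genes with fewer than
    ``min_coding_exons`` coding exons, and drops genes with any coding exon
    below ``min_exon_identity`` protein identity.
    """
    best: dict[str, AlignmentRecord] = {}
    for rec in records:
        cur = best.get(rec.gene)
        if cur is None or rec.length > cur.length:
            best[rec.gene] = rec
    out = []
    for rec in best.values():
        if rec.n_coding_exons < min_coding_exons:
            continue
        if any(x < min_exon_identity for x in rec.exon_protein_identity):
            continue
        out.append(rec)
    return out


# -- codon-class selection ----------------------------------------------------

def _codon_str(idx: int) -> str:
    return _CODONS[idx]


def codon_class_mask(
    codons: np.ndarray, dinuc: str, *, include_boundary: bool = True
) -> np.ndarray:
    """Mask of codons containing ``dinuc`` (within or spanning boundaries).

    A dinucleotide split between two adjacent codons selects both.  The
    concatenated coding sequence is used, so exon-terminal junctions count.
    """
    if dinuc not in CODON_CLASSES:
        raise ValueError(f"unknown codon class {dinuc!r}")
    n = len(codons)
    mask = np.zeros(n, dtype=bool)
    strs = [_codon_str(i) for i in codons]
    for i, s in enumerate(strs):
        if dinuc in s:
            mask[i] = True
    if include_boundary:
        for i in range(n - 1):
            if strs[i][2] + strs[i + 1][0] == dinuc:
                mask[i] = True
                mask[i + 1] = True
    return mask


def select_codon_class(
    aln: CodonAlignment, dinuc: str, *, on: str = "ref"
) -> CodonAlignment:
    """Select codons of one dinucleotide class (CG, GC, AG or GA).

    Membership is decided on the reference (first) sequence by default;
    ``on="either"`` selects codons flagged in either sequence.  Classes are
    not exclusive: a codon may belong to several selections.
    """
    mask = codon_class_mask(aln.codons1, dinuc)
    if on == "either":
        mask |= codon_class_mask(aln.codons2, dinuc)
    elif on != "ref":
        raise ValueError("on must be 'ref' or 'either'")
    return aln.subset(mask)


def mark_in_cgi(aln: CodonAlignment, cgis: IntervalSet) -> CodonAlignment:
    """Flag codons overlapping a CGI by at least one base pair (in place)."""
    if aln.chrom is None or aln.start is None:
        raise ValueError("alignment has no genome coordinates")
    flags = np.zeros(len(aln), dtype=bool)
    for chrom in np.unique(aln.chrom):
        sel = aln.chrom == chrom
        starts = aln.start[sel]
        arr = cgis.array(str(chrom))
        if not len(arr):
            continue
        # >=1 bp of [start, start+3) inside a CGI interval
        idx = np.searchsorted(arr[:, 0], starts + 3, side="left") - 1
        hit = (idx >= 0) & (arr[np.maximum(idx, 0), 1] > starts)
        flags[np.flatnonzero(sel)[hit]] = True
    aln.in_cgi = flags
    return aln


# -- the estimator ------------------------------------------------------------

def _k2p(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Kimura two-parameter distance from transition/transversion proportions."""
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    with np.errstate(divide="ignore", invalid="ignore"):
        d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
    return np.where((w1 > 0) & (w2 > 0), d, np.nan)


def _estimate_from_counts(counts: np.ndarray) -> tuple[float, float, float, float, bool]:
    """(dN, dS, R, kappa, saturated) from a 4096 codon-pair count vector."""
    res = _estimate_many(counts[None, :])
    dn, ds, r, kappa = (float(res[key][0]) for key in ("dn", "ds", "r", "kappa"))
    return dn, ds, r, kappa, bool(res["saturated"][0])


def _estimate_many(counts: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorised estimation over rows of codon-pair count matrices."""
    counts = np.atleast_2d(np.asarray(counts, dtype=np.float64))
    n = counts.sum(axis=1)
    sites = 3.0 * n
    ts = counts @ _PAIR["ts_diff"]
    tv = counts @ _PAIR["tv_diff"]
    p_all = ts / sites
    q_all = tv / sites
    w1 = 1.0 - 2.0 * p_all - q_all
    w2 = 1.0 - 2.0 * q_all
    ok = (w1 > 0) & (w2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        s_dist = -0.5 * np.log(w1) + 0.25 * np.log(w2)
        v_dist = -0.5 * np.log(w2)
        kappa = np.where(v_dist > 0, 2.0 * s_dist / v_dist, np.inf)
    no_diff = (ts + tv) == 0
    kappa = np.where(no_diff, np.nan, kappa)
    r = kappa / 2.0

    a_sites = counts @ _PAIR["site_syn_ts"]
    b_sites = counts @ _PAIR["site_syn_tv"]
    with np.errstate(invalid="ignore"):
        l_s = np.where(
            np.isinf(kappa),
            a_sites,
            (kappa * a_sites + b_sites) / (kappa + 2.0),
        )
    # with no differences kappa is undefined; site counts then use kappa = 1
    l_s = np.where(no_diff, (a_sites + b_sites) / 3.0, l_s)
    l_n = sites - l_s

    s_ts = counts @ _PAIR["syn_ts"]
    s_tv = counts @ _PAIR["syn_tv"]
    n_ts = counts @ _PAIR["nonsyn_ts"]
    n_tv = counts @ _PAIR["nonsyn_tv"]
    with np.errstate(divide="ignore", invalid="ignore"):
        ds = _k2p(s_ts / l_s, s_tv / l_s)
        dn = _k2p(n_ts / l_n, n_tv / l_n)
    ds = np.where(no_diff, 0.0, ds)
    dn = np.where(no_diff, 0.0, dn)
    saturated = ~ok & ~no_diff
    saturated |= np.isnan(ds) | np.isnan(dn)
    return {
        "dn": dn,
        "ds": ds,
        "r": r,
        "kappa": kappa,
        "saturated": saturated,
        "l_s": l_s,
        "l_n": l_n,
    }


def ina_estimate(aln: CodonAlignment) -> SubstitutionRates:
    """Estimate dS, dN and the ts/tv ratio for a codon alignment."""
    if len(aln) == 0:
        raise ValueError("empty alignment")
    counts = aln.pair_counts()
    dn, ds, r, kappa, saturated = _estimate_from_counts(counts)
    return SubstitutionRates(
        dn=dn, ds=ds, r=r, kappa=kappa, n_codons=len(aln), saturated=saturated
    )


def bootstrap_ci(
    aln: CodonAlignment, b: int = 2000, seed: int = 0
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Percentile bootstrap 95% CIs for (dN, dS).

    Codon pairs are resampled with replacement ``b`` times; replicates whose
    estimation fails (saturation) are dropped and counted, with a warning
    above 5% failures.
    """
    if len(aln) < 10:
        raise ValueError("need at least 10 codon pairs to bootstrap")
    counts = aln.pair_counts()
    n = int(counts.sum())
    rng = np.random.default_rng(seed)
    reps = rng.multinomial(n, counts / n, size=b).astype(np.float64)
    res = _estimate_many(reps)
    good = ~res["saturated"]
    n_failed = int(b - good.sum())
    if n_failed > 0.05 * b:
        warnings.warn(
            f"{n_failed}/{b} bootstrap replicates failed estimation",
            stacklevel=2,
        )
    if not good.any():
        raise ValueError("all bootstrap replicates failed")
    dn = res["dn"][good]
    ds = res["ds"][good]
    ci_dn = (float(np.percentile(dn, 2.5)), float(np.percentile(dn, 97.5)))
    ci_ds = (float(np.percentile(ds, 2.5)), float(np.percentile(ds, 97.5)))
    return ci_dn, ci_ds


def estimate_with_ci(
    aln: CodonAlignment, b: int = 2000, seed: int = 0
) -> SubstitutionRates:
    """Point estimates plus percentile-bootstrap CIs."""
    est = ina_estimate(aln)
    ci_dn, ci_ds = bootstrap_ci(aln, b=b, seed=seed)
    return replace(est, ci95_dn=ci_dn, ci95_ds=ci_ds)


# -- reports ------------------------------------------------------------------

def dn_ds_ratio(dn: float, ds: float, ndigits: int = 3) -> float:
    """dN/dS rounded for reporting (ratio computed before rounding)."""
    if ds == 0:
        return float("nan")
    return round_half_away(dn / ds, ndigits)


def ds_reduction_pct(ds_in: float, ds_out: float) -> float:
    """Percent dS reduction inside CGIs, to the nearest percent."""
    if ds_out == 0:
        return float("nan")
    return round_half_away(100.0 * (1.0 - ds_in / ds_out), 0)


def rates_report(
    aln: CodonAlignment,
    *,
    boot: int = 0,
    seed: int = 0,
    min_codons: int = 10,
) -> pd.DataFrame:
    """Partitioned dN/dS report over codon classes, CGI overlap and position.

    Rows: the four dinucleotide codon classes plus "all", crossed with
    in/out of CGI and the three exon positions.  dN/dS is computed from
    unrounded dN and dS and printed to 3 decimals; a companion
    ``ds_reduction_pct`` column carries 1 - dS_in/dS_out per
    (class, exon position) to the nearest percent.  Groups with no codons
    yield NA rows.
    """
    if aln.in_cgi is None:
        raise ValueError("alignment has no in_cgi flags; run mark_in_cgi first")
    if aln.exon_position is None:
        raise ValueError("alignment has no exon_position labels")
    rows = []
    class_masks: dict[str, np.ndarray] = {
        cls: codon_class_mask(aln.codons1, cls) for cls in CODON_CLASSES
    }
    class_masks["all"] = np.ones(len(aln), dtype=bool)
    ds_lookup: dict[tuple[str, str, bool], float] = {}
    for cls, cmask in class_masks.items():
        for pos in EXON_POSITIONS:
            pmask = aln.exon_position == pos
            for in_cgi in (True, False):
                mask = cmask & pmask & (aln.in_cgi == in_cgi)
                n = int(mask.sum())
                row = {
                    "codon_class": cls,
                    "exon_position": pos,
                    "in_cgi": in_cgi,
                    "n_codons": n,
                }
                if n >= max(1, min_codons):
                    sub = aln.subset(mask)
                    if boot:
                        est = estimate_with_ci(sub, b=boot, seed=seed)
                        row["ci95_dn_low"], row["ci95_dn_high"] = est.ci95_dn
                        row["ci95_ds_low"], row["ci95_ds_high"] = est.ci95_ds
                    else:
                        est = ina_estimate(sub)
                    row["dn"] = round_half_away(est.dn, 3)
                    row["ds"] = round_half_away(est.ds, 3)
                    row["dn_ds"] = dn_ds_ratio(est.dn, est.ds)
                    ds_lookup[(cls, pos, in_cgi)] = est.ds
                else:
                    row["dn"] = row["ds"] = row["dn_ds"] = float("nan")
                rows.append(row)
    df = pd.DataFrame(rows)
    reductions = []
    for _, row in df.iterrows():
        key_in = (row["codon_class"], row["exon_position"], True)
        key_out = (row["codon_class"], row["exon_position"], False)
        if key_in in ds_lookup and key_out in ds_lookup and ds_lookup[key_out] > 0:
            reductions.append(
                ds_reduction_pct(ds_lookup[key_in], ds_lookup[key_out])
            )
        else:
            reductions.append(float("nan"))
    df["ds_reduction_pct"] = reductions
    return df
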