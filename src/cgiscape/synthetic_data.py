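"""Synthetic inputs for the whole pipeline, with the structure the analyses assume.

Every generator is a pure function of (config, seed): one master seed spawns
named substreams (genome, cage, codon, motif, chip) so modules can be
regenerated independently.  The generators emulate:

* an AT-biased, CpG-depleted genome background (first-order chain) carrying
  multi-exon genes and planted GC-rich CGI-like islands (~66% G+C,
  CpG obs/exp ~0.75) at 5', intragenic, 3' and intergenic positions, with
  ground-truth class labels;
* CAGE tags placed by Poisson sampling at class-dependent densities inside
  islands (defaults 0.0504 / 0.0049 / 0.0058 / 0.0117 per bp) over a sparse
  genomic background (1 tag per 1891 bp);
* human-mouse-like codon alignments evolved under a
  transition/transversion-biased mutation process with a ten-fold CpG
  transition multiplier outside CGI-protected codons, purifying selection on
  amino-acid changes, and stop-codon rejection;
* CGI-like sequences with planted 9-bp Sp1-style motif occurrences plus
  dinucleotide-preserving shuffled controls;
* tiling-array probe tables with lognormal intensities and an elevated
  treated/input ratio inside CGIs (largest for 5' islands).

Ground truth is always returned (and written) beside the simulated data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cgiscape import core_io
from cgiscape.cgi import CgiClass, CpGIsland, gc_fraction, obs_exp_cpg
from cgiscape.core_io import GeneModel, GenomicInterval, IntervalSet
from cgiscape.sp1_motif import PWM, make_control
from cgiscape.subst_rates import IS_STOP, AMINO_ACIDS, CodonAlignment

__all__ = [
    "SimulationConfig",
    "SimulatedGenome",
    "simulate_genome",
    "simulate_cage",
    "simulate_codon_alignment",
    "simulate_sp1_training_sites",
    "simulate_sp1_sequences",
    "simulate_probes",
    "simulate_all",
]

_STREAMS = {"genome": 0, "cage": 1, "codon": 2, "motif": 3, "chip": 4}

BASES = "ACGT"

#: AT-biased, CpG-depleted background chain: P(next | current), order A,C,G,T
BACKGROUND_TRANSITION = np.array(
    [
        [0.33, 0.17, 0.20, 0.30],
        [0.30, 0.25, 0.04, 0.41],
        [0.28, 0.21, 0.25, 0.26],
        [0.25, 0.18, 0.22, 0.35],
    ]
)

#: CGI-like chain: ~66% G+C with CpG obs/exp well above the 0.6 criterion
CGI_TRANSITION = np.array(
    [
        [0.18, 0.33, 0.33, 0.16],
        [0.16, 0.35, 0.25, 0.24],
        [0.18, 0.33, 0.33, 0.16],
        [0.14, 0.34, 0.36, 0.16],
    ]
)


@dataclass
class SimulationConfig:
    """Study conditions for all generators.

    Defaults mirror the analysis conditions at desk scale: CAGE densities per
    CGI class and the genome background rate, a ten-fold CpG transition
    multiplier relieved inside CGIs, a neutral divergence of ~0.5
    substitutions per site, and a treated/input ChIP effect that is largest
    for 5' islands and absent outside CGIs.
    """

    seed: int
    n_chroms: int = 2
    chrom_len: int = 300_000
    genes_per_chrom: int = 10
    mean_exons: float = 6.0
    mean_exon_len: float = 160.0
    min_intron_len: int = 800
    mean_intron_len: float = 1600.0
    # CGI planting
    p_cgi_five: float = 0.75
    p_cgi_intragenic: float = 0.4
    p_cgi_three: float = 0.4
    intergenic_cgis_per_chrom: float = 6.0
    cgi_len_min: int = 400
    cgi_len_max: int = 1400
    # CAGE tag densities (per bp) inside islands, by class, plus background
    cage_density: dict[str, float] = field(
        default_factory=lambda: {
            "five_prime": 0.0504,
            "intragenic": 0.0049,
            "three_prime": 0.0058,
            "intergenic": 0.0117,
        }
    )
    cage_background_density: float = 1.0 / 1891.0
    # codon evolution
    kappa: float = 2.0  #: transition rate per transversion-type rate
    branch_length: float = 0.5  #: neutral substitutions per site
    cpg_multiplier: float = 10.0  #: CpG transition multiplier outside CGIs
    omega: float = 0.2  #: acceptance probability of amino-acid changes
    n_codons: int = 30_000
    in_cgi_fraction: float = 0.5
    cgi_block_codons: int = 25
    # motif planting
    motif_seq_len: int = 400
    motif_lambda: dict[str, float] = field(
        default_factory=lambda: {
            "five_prime": 4.0,
            "intragenic": 1.0,
            "three_prime": 2.5,
            "intergenic": 2.0,
        }
    )
    n_motif_seqs: int = 40
    # ChIP probes
    probe_spacing: int = 35
    chip_effect: dict[str, float] = field(
        default_factory=lambda: {
            "five_prime": 1.5,
            "intragenic": 1.3,
            "three_prime": 1.3,
            "intergenic": 1.2,
            "non_cgi": 1.0,
        }
    )
    chip_sigma: float = 0.5
    chip_rep_sigma: float = 0.15
    mm_fraction: float = 0.1

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])


def _markov_seq(n: int, transition: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample n bases (0..3) from a first-order chain."""
    cum = np.cumsum(transition, axis=1)
    out = np.empty(n, dtype=np.int8)
    u = rng.random(n)
    state = int(rng.integers(0, 4))
    for i in range(n):
        state = int(np.searchsorted(cum[state], u[i], side="right"))
        state = min(state, 3)
        out[i] = state
    return out


def _decode(arr: np.ndarray) -> str:
    return "".join(BASES[i] for i in arr)


@dataclass
class SimulatedGenome:
    """Genome FASTA-equivalent, gene models and ground-truth islands."""

    seqs: dict[str, str]
    genes: list[GeneModel]
    cgis: list[CpGIsland]  #: truth labels in ``cgi_class``

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.seqs.items()}


def _make_gene(
    chrom: str, start: int, cfg: SimulationConfig, rng: np.random.Generator, idx: int
) -> GeneModel:
    n_exons = 3 + int(rng.poisson(max(cfg.mean_exons - 3, 0)))
    exon_lens = np.maximum(
        60, rng.lognormal(np.log(cfg.mean_exon_len), 0.35, n_exons)
    ).astype(int)
    intron_lens = (
        cfg.min_intron_len
        + rng.exponential(
            max(cfg.mean_intron_len - cfg.min_intron_len, 1), n_exons - 1
        )
    ).astype(int)
    strand = "+" if rng.random() < 0.5 else "-"
    exons = []
    pos = start
    for i in range(n_exons):
        exons.append(GenomicInterval(chrom, pos, pos + int(exon_lens[i]), strand))
        pos += int(exon_lens[i])
        if i < n_exons - 1:
            pos += int(intron_lens[i])
    tx_start, tx_end = exons[0].start, exons[-1].end
    # CDS starts inside the first exon and ends inside the last (UTRs on both
    # ends); transcript orientation decides which end is 5'
    first, last = exons[0], exons[-1]
    if strand == "+":
        cds_start = first.start + max(20, first.length // 3)
        cds_end = last.end - max(20, last.length // 3)
    else:
        cds_start = first.start + max(20, first.length // 3)
        cds_end = last.end - max(20, last.length // 3)
    return GeneModel(
        name=f"gene{idx}",
        chrom=chrom,
        strand=strand,
        tx_start=tx_start,
        tx_end=tx_end,
        cds_start=cds_start,
        cds_end=cds_end,
        exons=tuple(exons),
    )


def simulate_genome(cfg: SimulationConfig) -> SimulatedGenome:
    """Genome background with genes and planted, labelled CGI-like islands.

    Gene spacings guarantee that planted islands of each class satisfy the
    class definitions (e.g. intergenic islands are placed over 3 kb away from
    every gene).  Raises if island packing repeatedly fails.
    """
    rng = cfg.rng("genome")
    seqs: dict[str, str] = {}
    genes: list[GeneModel] = []
    islands: list[tuple[GenomicInterval, CgiClass]] = []
    gene_idx = 0
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        margin = 9000
        pos = margin
        chrom_genes: list[GeneModel] = []
        while len(chrom_genes) < cfg.genes_per_chrom:
            g = _make_gene(chrom, pos, cfg, rng, gene_idx)
            if g.tx_end > cfg.chrom_len - margin:
                break
            chrom_genes.append(g)
            gene_idx += 1
            pos = g.tx_end + 13_000 + int(rng.exponential(6000))
        genes.extend(chrom_genes)

        chrom_islands: list[tuple[GenomicInterval, CgiClass]] = []

        def _try_add(s: int, e: int, cls: CgiClass) -> None:
            if s < 0 or e > cfg.chrom_len or s >= e:
                return
            for iv, _ in chrom_islands:
                if iv.start < e + 200 and s < iv.end + 200:
                    return
            chrom_islands.append((GenomicInterval(chrom, s, e), cls))

        for g in chrom_genes:
            if rng.random() < cfg.p_cgi_five:
                length = int(rng.integers(cfg.cgi_len_min, cfg.cgi_len_max + 1))
                if g.strand == "+":
                    s = g.tx_start - int(0.4 * length)
                else:
                    s = g.tx_end - length + int(0.4 * length)
                _try_add(s, s + length, CgiClass.FIVE_PRIME)
            if rng.random() < cfg.p_cgi_intragenic:
                introns = list(g.introns)
                if g.strand == "-":
                    introns = introns[::-1]
                internal = introns[1:-1]  # transcript order, drop initial/final
                fits = [iv for iv in internal if iv.length >= cfg.cgi_len_min + 100]
                if fits:
                    iv = fits[int(rng.integers(0, len(fits)))]
                    length = int(
                        min(cfg.cgi_len_max, iv.length - 100)
                    )
                    length = max(length, cfg.cgi_len_min)
                    off = int(rng.integers(0, iv.length - length + 1))
                    _try_add(iv.start + off, iv.start + off + length,
                             CgiClass.INTRAGENIC)
            if rng.random() < cfg.p_cgi_three:
                length = int(rng.integers(cfg.cgi_len_min, cfg.cgi_len_max + 1))
                if g.strand == "+":
                    s = g.tx_end - length // 2
                else:
                    s = g.tx_start - length + length // 2
                _try_add(s, s + length, CgiClass.THREE_PRIME)

        # intergenic islands: over 3 kb + flank away from every gene
        forbidden = IntervalSet(
            GenomicInterval(chrom, max(0, g.tx_start - 3500), g.tx_end + 3500)
            for g in chrom_genes
        )
        n_inter = int(rng.poisson(cfg.intergenic_cgis_per_chrom))
        placed = 0
        for _ in range(60 * max(n_inter, 1)):
            if placed >= n_inter:
                break
            length = int(rng.integers(cfg.cgi_len_min, cfg.cgi_len_max + 1))
            s = int(rng.integers(500, cfg.chrom_len - length - 500))
            iv = GenomicInterval(chrom, s, s + length)
            if forbidden.intersect_length(IntervalSet([iv])):
                continue
            before = len(chrom_islands)
            _try_add(s, s + length, CgiClass.INTERGENIC)
            if len(chrom_islands) > before:
                placed += 1
        if n_inter and placed < n_inter // 2:
            raise RuntimeError(f"island packing failed on {chrom}")

        # lay down sequence: background chain, islands overwritten
        bases = _markov_seq(cfg.chrom_len, BACKGROUND_TRANSITION, rng)
        for iv, _cls in chrom_islands:
            bases[iv.start : iv.end] = _markov_seq(iv.length, CGI_TRANSITION, rng)
        seqs[chrom] = _decode(bases)
        islands.extend(chrom_islands)

    cgis = []
    for iv, cls in islands:
        sub = seqs[iv.chrom][iv.start : iv.end]
        cgis.append(CpGIsland(iv, gc_fraction(sub), obs_exp_cpg(sub), cgi_class=cls))
    cgis.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    genes.sort(key=lambda g: (g.chrom, g.tx_start))
    return SimulatedGenome(seqs=seqs, genes=genes, cgis=cgis)


def simulate_cage(
    cgis: Sequence[CpGIsland],
    chrom_sizes: Mapping[str, int],
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, int, str, float]]:
    """Poisson CAGE tags: class-dependent densities in islands, sparse outside.

    Returns (chrom, pos, strand, identity) records; identities are >= 0.88 so
    the reader's mapping-identity filter keeps them all.
    """
    rng = cfg.rng("cage") if rng is None else rng
    tags: list[tuple[str, int, str, float]] = []
    island_set = IntervalSet(c.interval for c in cgis)
    for c in cgis:
        if c.cgi_class is None:
            raise ValueError("islands must carry class labels")
        dens = cfg.cage_density[c.cgi_class.value]
        n = int(rng.poisson(dens * c.length))
        if not n:
            continue
        pos = rng.integers(c.interval.start, c.interval.end, size=n)
        for p in pos:
            strand = "+" if rng.random() < 0.5 else "-"
            tags.append((c.interval.chrom, int(p), strand, 0.9 + 0.1 * rng.random()))
    for chrom, size in chrom_sizes.items():
        n = int(rng.poisson(cfg.cage_background_density * size))
        if not n:
            continue
        pos = rng.integers(0, size, size=n)
        keep = ~island_set.contains_points(chrom, pos)
        for p in pos[keep]:
            strand = "+" if rng.random() < 0.5 else "-"
            tags.append((chrom, int(p), strand, 0.9 + 0.1 * rng.random()))
    tags.sort()
    return tags


_TRANSVERSIONS = {0: (1, 3), 1: (0, 2), 2: (1, 3), 3: (0, 2)}  # A,C,G,T indices


def simulate_codon_alignment(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    *,
    n_codons: int | None = None,
    cpg_multiplier: float | None = None,
    omega: float | None = None,
    branch_length: float | None = None,
) -> tuple[CodonAlignment, dict]:
    """Evolve a coding alignment under CpG-hypermutation with CGI protection.

    Two lineages evolve independently from a random ancestor for
    ``branch_length / 2`` each, so the pair diverges by ``branch_length``
    expected neutral substitutions per (non-CpG) site in total: transitions
    run at ``kappa`` times each transversion-type rate, transitions at
    CpG-context sites (the C of CpG, or the G preceded by C) are multiplied
    by ``cpg_multiplier`` unless the codon is CGI-protected, amino-acid
    changes are accepted with probability ``omega`` and stop codons are
    rejected.  The realised mutation process (continuous-time, with multiple
    hits and context destruction) is simulated exactly via thinning.
    Selecting CpG-class codons on the first (extant) sequence therefore
    reproduces the survivorship structure of real alignments, where
    fast-mutating CpG sites that persist are the ones still observable.

    Returns the alignment (exon positions in equal thirds, in-CGI mask in
    blocks) and a truth dict with the generating parameters.
    """
    rng = cfg.rng("codon") if rng is None else rng
    n = cfg.n_codons if n_codons is None else n_codons
    m = cfg.cpg_multiplier if cpg_multiplier is None else cpg_multiplier
    om = cfg.omega if omega is None else omega
    t = cfg.branch_length if branch_length is None else branch_length
    kappa = cfg.kappa

    # ancestor: uniform random codons, stop codons resampled
    codons = rng.integers(0, 64, size=n)
    while IS_STOP[codons].any():
        bad = np.flatnonzero(IS_STOP[codons])
        codons[bad] = rng.integers(0, 64, size=len(bad))
    anc = np.empty(3 * n, dtype=np.int8)
    anc[0::3] = codons // 16
    anc[1::3] = (codons // 4) % 4
    anc[2::3] = codons % 4

    block = max(cfg.cgi_block_codons, 1)
    n_blocks = (n + block - 1) // block
    block_in = rng.random(n_blocks) < cfg.in_cgi_fraction
    in_cgi = np.repeat(block_in, block)[:n]

    thirds = np.array(["initial", "internal", "final"])
    exon_position = thirds[np.minimum(np.arange(n) * 3 // n, 2)]

    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    mu_max = max(m, 1.0) * alpha + 2.0 * beta
    n_sites = 3 * n
    aa = AMINO_ACIDS

    def evolve(branch_t: float) -> np.ndarray:
        seq = anc.copy()
        n_events = int(rng.poisson(mu_max * n_sites * branch_t))
        sites = rng.integers(0, n_sites, size=n_events)
        us = rng.random(n_events) * mu_max
        accept_u = rng.random(n_events)
        for ev in range(n_events):
            i = int(sites[ev])
            b = int(seq[i])
            # CpG context on the current state of the evolving sequence
            context = (
                b == 1 and i + 1 < n_sites and seq[i + 1] == 2
            ) or (b == 2 and i > 0 and seq[i - 1] == 1)
            protected = in_cgi[i // 3]
            ms = m if (context and not protected) else 1.0
            u = us[ev]
            if u < ms * alpha:
                new_b = b ^ 2  # transition partner
            elif u < ms * alpha + beta:
                new_b = _TRANSVERSIONS[b][0]
            elif u < ms * alpha + 2.0 * beta:
                new_b = _TRANSVERSIONS[b][1]
            else:
                continue  # thinned
            c0 = 3 * (i // 3)
            old_codon = 16 * seq[c0] + 4 * seq[c0 + 1] + seq[c0 + 2]
            offset = i - c0
            new_codon = old_codon + (new_b - b) * (16, 4, 1)[offset]
            if IS_STOP[new_codon]:
                continue
            if aa[new_codon] != aa[old_codon] and accept_u[ev] >= om:
                continue
            seq[i] = new_b
        return seq

    seq1 = evolve(t / 2.0)
    seq2 = evolve(t / 2.0)
    to_codons = lambda s: 16 * s[0::3].astype(np.int16) + 4 * s[1::3] + s[2::3]
    aln = CodonAlignment(
        to_codons(seq1),
        to_codons(seq2),
        exon_position=exon_position,
        in_cgi=in_cgi,
    )
    truth = {
        "branch_length": t,
        "kappa": kappa,
        "cpg_multiplier": m,
        "omega": om,
        "n_codons": n,
    }
    return aln, truth


def simulate_sp1_training_sites(
    rng: np.random.Generator,
    n: int = 221,
    consensus: str = "GGGGCGGGG",
    mutation_rate: float = 0.08,
) -> list[str]:
    """Aligned GC-box-like training sites: consensus with sparse mutations."""
    sites = []
    L = len(consensus)
    cons = np.array([BASES.index(b) for b in consensus])
    for _ in range(n):
        s = cons.copy()
        mut = rng.random(L) < mutation_rate
        s[mut] = rng.integers(0, 4, size=int(mut.sum()))
        sites.append(_decode(s.astype(np.int8)))
    return sites


def _sample_site(pwm: PWM, rng: np.random.Generator) -> str:
    if pwm.counts is not None:
        freq = pwm.counts + 0.5
    else:
        freq = np.exp(pwm.weights)
    freq = freq / freq.sum(axis=1, keepdims=True)
    return "".join(
        BASES[int(rng.choice(4, p=freq[i]))] for i in range(pwm.length)
    )


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def simulate_sp1_sequences(
    pwm: PWM,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, list[str]]:
    """CGI-like sequences with planted motif occurrences, plus shuffled controls.

    One set per CGI class at its configured planting intensity; for each set a
    matched ``<name>_control`` set holds dinucleotide-preserving shuffles of
    the same sequences.
    """
    rng = cfg.rng("motif") if rng is None else rng
    out: dict[str, list[str]] = {}
    for name, lam in cfg.motif_lambda.items():
        seqs = []
        for _ in range(cfg.n_motif_seqs):
            bases = _markov_seq(cfg.motif_seq_len, CGI_TRANSITION, rng)
            seq = list(_decode(bases))
            n_plant = int(rng.poisson(lam))
            used: list[tuple[int, int]] = []
            for _ in range(n_plant):
                site = _sample_site(pwm, rng)
                if rng.random() < 0.5:
                    site = _revcomp(site)
                for _try in range(20):
                    off = int(rng.integers(0, cfg.motif_seq_len - len(site) + 1))
                    if all(off >= e or off + len(site) <= s for s, e in used):
                        seq[off : off + len(site)] = list(site)
                        used.append((off, off + len(site)))
                        break
            seqs.append("".join(seq))
        out[name] = seqs
        out[f"{name}_control"] = [make_control(s, rng) for s in seqs]
    return out


def simulate_probes(
    cgis: Sequence[CpGIsland],
    chrom_sizes: Mapping[str, int],
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Tiling-array probe table: 2 samples x 3 technical replicates x 2 conditions.

    Input intensities are lognormal around 500; treated intensities multiply
    in the class-dependent CGI effect; per-chip scale factors exercise the
    median scaling; a fraction of rows are MM probes to exercise filtering.
    """
    rng = cfg.rng("chip") if rng is None else rng
    class_index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in chrom_sizes:
        rows = [
            (c.interval.start, c.interval.end, c.cgi_class.value)
            for c in cgis
            if c.interval.chrom == chrom and c.cgi_class is not None
        ]
        rows.sort()
        class_index[chrom] = (
            np.array([r[0] for r in rows], dtype=np.int64),
            np.array([r[1] for r in rows], dtype=np.int64),
            np.array([r[2] for r in rows], dtype=object),
        )

    records = []
    conditions = [
        f"{cond}.{s}.{r}" for cond in ("treated", "input")
        for s in (1, 2) for r in (1, 2, 3)
    ]
    chip_scale = {c: float(rng.uniform(0.8, 1.25)) for c in conditions}
    pid = 0
    for chrom, size in chrom_sizes.items():
        starts, ends, labels = class_index[chrom]
        for pos in range(500, size - 500, cfg.probe_spacing):
            i = int(np.searchsorted(starts, pos, side="right")) - 1
            if i >= 0 and pos < ends[i]:
                cls = str(labels[i])
            else:
                cls = "non_cgi"
            base = float(rng.lognormal(np.log(500.0), cfg.chip_sigma))
            effect = cfg.chip_effect[cls]
            kind = "MM" if rng.random() < cfg.mm_fraction else "PM"
            row = {"probe_id": f"p{pid}", "chrom": chrom, "pos": pos, "kind": kind}
            for col in conditions:
                cond = col.split(".")[0]
                mean = base * (effect if cond == "treated" else 1.0)
                noise = float(rng.lognormal(0.0, cfg.chip_rep_sigma))
                row[col] = mean * noise * chip_scale[col]
            records.append(row)
            pid += 1
    return pd.DataFrame(records)


def simulate_all(cfg: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write every pipeline input plus ground truth.

    Writes genome.fa, genes.tsv, cgi_truth.bed, cage.tsv, probes.tsv,
    sp1_sites.fa, sp1_sequences.fa and truth.json under ``out_dir``; returns
    the path of each artifact.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(cfg)

    fasta = out / "genome.fa"
    with open(fasta, "w") as fh:
        for chrom, seq in genome.seqs.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    genes_path = out / "genes.tsv"
    core_io.write_gene_table(genome.genes, genes_path)

    cgi_path = out / "cgi_truth.bed"
    core_io.write_bed(
        [c.interval for c in genome.cgis],
        cgi_path,
        names=[c.cgi_class.value for c in genome.cgis],
    )

    tags = simulate_cage(genome.cgis, genome.chrom_sizes, cfg)
    cage_path = out / "cage.tsv"
    with open(cage_path, "w") as fh:
        for chrom, pos, strand, ident in tags:
            fh.write(f"{chrom}\t{pos}\t{strand}\t{ident:.3f}\n")

    probes = simulate_probes(genome.cgis, genome.chrom_sizes, cfg)
    probes_path = out / "probes.tsv"
    probes.to_csv(probes_path, sep="\t", index=False)

    motif_rng = cfg.rng("motif")
    sites = simulate_sp1_training_sites(motif_rng)
    sites_path = out / "sp1_sites.fa"
    with open(sites_path, "w") as fh:
        for i, s in enumerate(sites):
            fh.write(f">site{i}\n{s}\n")

    from cgiscape.sp1_motif import build_pwm

    pwm = build_pwm(sites)
    seq_sets = simulate_sp1_sequences(pwm, cfg, motif_rng)
    seqs_path = out / "sp1_sequences.fa"
    with open(seqs_path, "w") as fh:
        for name, seqs in seq_sets.items():
            for i, s in enumerate(seqs):
                fh.write(f">{name}|{i}\n{s}\n")

    sizes_path = out / "chrom.sizes"
    with open(sizes_path, "w") as fh:
        for chrom, size in genome.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")

    truth_path = out / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "seed": cfg.seed,
                "n_cgis": len(genome.cgis),
                "class_counts": {
                    cls.value: sum(1 for c in genome.cgis if c.cgi_class == cls)
                    for cls in CgiClass
                },
                "n_genes": len(genome.genes),
            },
            fh,
            indent=2,
        )
    return {
        "fasta": fasta,
        "genes": genes_path,
        "cgi_truth": cgi_path,
        "cage": cage_path,
        "probes": probes_path,
        "sp1_sites": sites_path,
        "sp1_sequences": seqs_path,
        "chrom_sizes": sizes_path,
        "truth": truth_path,
    }
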