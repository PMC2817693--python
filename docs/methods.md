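# Methods

This note records the models, conventions and numerical choices behind each
module, what the synthetic data does and does not emulate, and the known
limitations.

## Coordinates and interval algebra

All coordinates are 0-based half-open (UCSC table convention); 1-based
formats would be converted at the I/O boundary. Interval sets are kept as
chromosome-keyed sorted arrays of merged, disjoint intervals, so sortedness
and disjointness hold by construction and every operation
(intersect/subtract/union, overlap lengths) is a linear sweep. Strand is
carried on intervals but never used for overlap lengths: the overlap
statistics of this package are strand-agnostic by design, while strand
decides which end of a gene is 5' wherever that matters. Chromosome names
containing "random" (and unplaced/haplotype contigs) are dropped at read
time. Duplicate gene records are collapsed and names mapping to several
locations are removed entirely, since such entries are ambiguous copies.

## Gene elements

Eleven element categories are built per gene in transcript orientation and
then merged across genes, with exclusions applied in definition order: the
3 kb 5' flank (clamped at position 0) subtracts *all* transcribed sequence;
5' UTR exons/introns subtract all translated sequence; the initial intron
(between the first and second coding exons) subtracts everything already in
the four 5' categories; internal exons subtract initial and final coding
exons; the remaining intron and 3' UTR categories subtract translated
sequence. Overlapping exons of different isoforms merge; when isoforms
disagree about which exon is final, each contributes its own final exon
before merging. Non-coding models (cdsStart = cdsEnd) are excluded and
counted. Exclusion against other genes is strand-blind — for overlapping
genes on opposite strands, "any transcribed sequence" is taken literally.

Intron-terminal segments are the first and last 200 bp of each intron in
transcript orientation (donor side abuts the upstream exon). Introns
shorter than 400 bp are split at the midpoint so the two segments stay
disjoint and the donor/acceptor totals never double-count; this keeps
ratio statistics on the segment sets well defined.

## CGI detection and classification

Islands are detected by the composition criteria — length > 200 bp,
G+C > 50%, observed/expected CpG ≥ 0.6 with
obs/exp = #CpG · N / (#C · #G) — using a 200 bp sliding window:
qualifying windows seed candidate segments, overlapping or adjacent
qualifying windows merge, and each merged segment is re-checked against all
three criteria on its full extent (failing segments are dropped, not
trimmed). Ambiguous bases are excluded from all counts and break CpG pairs.
Islands imported from an external annotation are accepted verbatim; when
sequence is available their composition is computed and criterion
violations produce warnings only, because external island callers use
different algorithms and their tracks should not be silently edited.

Classification uses *all* gene models, including single- and double-exon
ones, and is a strict precedence: one bp of overlap with any gene's 5'
region (flank, 5' UTR exons/introns, initial coding exon, initial intron)
makes an island 5', whatever else it touches; otherwise one bp of overlap
with a 3' region (final exon/intron, 3' UTR exons/introns, or the 3 kb
window downstream of the transcript end — measured from the transcript
terminus, not the CDS end) makes it 3'; otherwise overlap with any gene
body makes it intragenic; everything else is intergenic (equivalently, at
least 3 kb from every gene, since the flank and downstream windows cover
the near zone). The precedence makes classification total, deterministic
and monotone: adding genes can only move an island toward the 5' class.

## Monte-Carlo overlap significance

For two merged interval sets, the observed aggregated overlap (bp) is
compared with the distribution obtained by re-placing the *template* set:
per chromosome, inter-interval gaps (including the two terminal flanks) are
drawn with replacement from the template's empirical gap distribution,
interval lengths are a random permutation — a shuffle, not a resample — of
the genuine lengths, and intervals are laid down left to right without
overlapping until one would cross the chromosome end (that one is
discarded). The asymmetric treatment (gaps with replacement, lengths
shuffled) keeps the length multiset essentially fixed while randomising
positions. The headline statistic is observed / simulated mean; empirical
one-sided p-values (ties counted on both sides) are reported alongside.
Both fix/sample directions are run, and the element-category report emits
21 rows: the 11 categories plus donor- and acceptor-side 200 bp segments
for the five intron categories.

Randomness: one master seed; per-chromosome generators are derived from
(seed, chromosome index), so results are bit-reproducible and independent
of chromosome iteration order. Sampled placements ignore assembly gaps;
synthetic genomes have none, and on real assemblies this overstates the
placeable space (a documented limitation).

## Substitution rates

The estimator is an Ina-style approximate method ("method I" in spirit):

1. **Ts/tv ratio.** Transitional and transversional difference proportions
   P and Q over all codon sites receive the Kimura two-parameter
   correction; the transition distance s = −½ln(1−2P−Q) + ¼ln(1−2Q) and
   transversion distance v = −½ln(1−2Q) give the corrected count ratio
   R = s/v and the per-type rate ratio kappa = 2s/v (transition rate per
   single-transversion-type rate). Kappa is the weight used below; both are
   reported. With no transversions kappa is infinite and the site counts
   take their limiting values, so R grows without bound as transitions
   accumulate — expected, and tested for monotonicity.
2. **Potential sites.** At each codon position the three possible mutations
   are weighted kappa : 1 : 1; the synonymous fraction of the site is the
   weight share of synonymous changes. Changes producing stop codons count
   as nonsynonymous. Site counts are averaged over the two sequences.
3. **Differences.** For codon pairs differing at 1–3 positions, all
   orderings of the single-base steps are enumerated with equal weight;
   orderings passing through a stop codon are excluded unless every
   ordering is blocked (then all are used). Each step is classified
   synonymous/nonsynonymous and transition/transversion.
4. **Correction.** The transition and transversion proportions at
   synonymous and at nonsynonymous sites receive the same two-parameter
   correction, giving dS and dN. A non-positive logarithm argument
   (saturation) flags the estimate as undefined — it is never clipped.

Codon-class selection (CpG, GpC, ApG, GpA) is decided on the first
(reference) sequence by default — reproducible and matching how extant
sequences are classified — with an "either sequence" mode available. A
dinucleotide split across a codon boundary selects both codons, including
across exon junctions in the concatenated CDS. A codon overlaps a CGI when
at least one of its three bases does.

Everything is computed from a 64×64 codon-pair count vector with
precomputed per-pair tables, so a 2000-replicate percentile bootstrap
(multinomial resampling of codon pairs) is a vectorised batch of dot
products; replicates failing estimation are dropped and counted, with a
warning above 5%. Report tables print rates to 3 decimals, compute dN/dS
*before* rounding, and give percent dS reductions (1 − dS_in/dS_out) to the
nearest percent.

## CAGE statistics

Tags are counted per island by half-open position containment, strand-blind
(transcription initiation within an island is of interest whichever strand
fires), with multiple tags at one position each counting. The summary table
derives, per class and in total: counts, lengths, tagged subsets, tag
totals, fraction of genome-wide tags, per-CGI means, densities and
bp-per-tag. Rounding is half-away-from-zero: densities to 4 decimals,
percentages to 2, per-CGI means and bp-per-tag to integers. Enrichment
bands follow the "> 40 tags" and "20–40 tags" (inclusive) conventions.
Transcript association takes the highest-priority catalogue (RefSeq >
mRNA > EST) with a start inside the island, making categories mutually
exclusive.

## Sp1 motif statistics

The PWM weight is w(i,b) = ln((n(i,b) + a·p_b) / ((N + a)·p_b)) with
pseudocount a = 1 distributed by the background composition — a standard
regularised log-odds form. The scan threshold is the empirical
(1 − sensitivity) quantile of per-site best scores on the training set, so
at 90% sensitivity at least 90% of training sites score above it by
construction. Scanning slides both strands and counts every window at or
above threshold; overlapping hits all count.

The P-value of observing ≥ k such hits in a random sequence of the same
length and composition is computed exactly: all 4^L words are scored, the
above-threshold word set (plus, in the default double-strand mode, words
whose reverse complement is above threshold, contributing weight 2 when
both strands hit) is compiled into an Aho–Corasick automaton — since all
words share one length, occurrences fire exactly on the deepest states —
and a dynamic program over (state, hit count capped at k) propagates
probability position by position as sparse matrix products. The background
is i.i.d. by default; a first-order Markov mode conditions each emission on
the state's last character (the four depth-1 states are always
materialised, so the previous base is known everywhere except before the
first character). The cap at k is sufficient for P(≥ k) and keeps the state
space linear in k. Exactness is verified against exhaustive enumeration of
all 4^8 sequences for toy motifs; the automaton approach stays fast for
9-bp motifs at calibrated thresholds, where the hit-word set is small
(~10²), but would grow expensive for very permissive thresholds.

Composition-matched controls are dinucleotide-preserving shuffles (random
Eulerian path with fixed endpoints, preserving the dinucleotide count
vector exactly) or samples from a first-order chain fitted to the input.
Enrichment curves compute, per sequence, the exact P(≥ k observed) under
that sequence's own composition, and report cumulative fractions of
sequences at or beyond each significance level.

## ChIP-chip comparison

The pipeline order is fixed: per-chip median scaling to 500 (exact by
construction), quantile normalisation across chips (sorted values replaced
by across-chip means of order statistics; ties receive the mean of the
quantile values they would occupy; rank order within a chip is preserved),
replicate averaging to one value per probe and condition (missing
replicates are averaged over what is present, with a count warning),
partitioning of probes by the CGI class containing the probe midpoint, and
Wilcoxon–Mann–Whitney tests: treated vs input per class, and pairwise
between classes on per-probe treated/input ratios (raw-signal mode behind a
flag). Tests are two-sided, exact for group sizes under 30 and
tie-corrected asymptotic otherwise. Mismatch probes are dropped before any
normalisation.

A caveat worth knowing: quantile normalisation forces identical marginal
distributions across chips, so when a *large* fraction of probes carries a
genuine treated-only effect (as on a deliberately CGI-dense synthetic
genome), the non-CGI remainder absorbs a small opposite shift, which a rank
test on many probes can detect. At realistic CGI fractions (<1% of the
genome) the distortion is negligible; the planted-effect acceptance check
therefore evaluates the class tests on a directly constructed probe table,
where the non-CGI null is exact.

## Synthetic data

The generators are pure functions of (config, seed); a master seed spawns
named substreams (genome, cage, codon, motif, chip) so any module's input
can be regenerated independently. Defaults are the study conditions:

* CAGE densities inside islands 0.0504 / 0.0049 / 0.0058 / 0.0117 per bp
  for 5'/intragenic/3'/intergenic, background 1 tag per 1891 bp;
* CpG transition multiplier m = 10 outside islands, 1 inside (methylation
  protection), total divergence 0.5 neutral substitutions per site,
  kappa = 2, amino-acid acceptance ω = 0.2;
* island composition ~66% G+C with obs/exp CpG ≈ 0.75–0.8, on an AT-biased
  CpG-depleted first-order background;
* ChIP treated/input effects 1.5 / 1.3 / 1.3 / 1.2 by class and 1.0 outside
  islands, lognormal intensities around a median of 500, two samples ×
  three technical replicates, per-chip scale jitter;
* desk scale: two 300 kb chromosomes, ~10 genes each — about 1/1000 of a
  mammalian genome workload, chosen so the full pipeline and its
  Monte-Carlo stages run in seconds to a couple of minutes on one CPU.

Genes have ≥ 3 exons, UTRs on both terminal exons, and are spaced ≥ 13 kb
apart so that planted islands of each class satisfy their defining
geometry (intergenic islands are placed > 3.5 kb from every gene; island
packing failures raise rather than mislabel). Codon alignments evolve two
lineages independently from a random ancestor for half the divergence
each, with CpG context evaluated on the current state of the evolving
sequence — so a CpG destroyed by mutation stops being hypermutable, and
selecting CpG-containing codons on the extant first sequence reproduces
the survivorship structure of real alignments. (Selecting on the ancestor
instead would pick codons whose CpG sites have since been obliterated,
saturating the synonymous correction — a behaviour worth knowing when
configuring extreme multipliers.) The mutation process is a thinned
continuous-time chain: multiple hits, back mutations and context dynamics
are all realised, and at neutrality (m = 1, ω = 1) the expected divergence
per site equals the configured branch length, which is what the bootstrap
coverage calibration checks.

What the synthetic data does **not** emulate: repeats and low-complexity
sequence (real CAGE mapping excludes them; real islands often overlap Alu),
assembly gaps, isoform diversity, codon usage bias, GC-content
heterogeneity at the isochore scale, and probe-sequence hybridisation
effects. Passing tests therefore demonstrate the correctness and
calibration of the machinery under the stated model, not robustness to
those real-data complications.

## Numerical conventions

Report rounding is half-away-from-zero throughout (school rounding), since
banker's rounding would disagree with conventional table arithmetic in
half cases. Ratios are computed from unrounded inputs and rounded last.
Degenerate inputs have defined behaviour rather than silent fixes:
all-ambiguous sequences, empty alignments, infeasible interval placements
and zero-median chips raise; saturated distance corrections return flagged
NaN; empty censuses return zero tables.
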