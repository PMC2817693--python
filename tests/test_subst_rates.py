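"""Substitution-rate estimation: codon selection, pathway counting, bootstrap."""

import itertools

import numpy as np
import pytest

from cgiscape.core_io import GenomicInterval, IntervalSet
from cgiscape.subst_rates import (
    AMINO_ACIDS,
    AlignmentRecord,
    CODONS,
    CodonAlignment,
    IS_STOP,
    bootstrap_ci,
    codon_class_mask,
    dn_ds_ratio,
    ds_reduction_pct,
    encode_codons,
    filter_alignments,
    ina_estimate,
    mark_in_cgi,
    rates_report,
    select_codon_class,
)
from cgiscape.synthetic_data import SimulationConfig, simulate_codon_alignment

GI = GenomicInterval


def _aln(seq1, seq2, **kw):
    return CodonAlignment.from_sequences(seq1, seq2, **kw)


# -- independent pathway-counting oracle --------------------------------------

_TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}


def oracle_pair_differences(c1: str, c2: str):
    """Average (syn_ts, syn_tv, nonsyn_ts, nonsyn_tv) over mutational pathways.

    Independent brute force: enumerate every ordering of the differing
    positions, drop orderings that pass through a stop codon (falling back to
    all orderings when every one is blocked), classify each single-base step.
    """
    code = dict(zip(CODONS, AMINO_ACIDS))
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    all_paths, open_paths = [], []
    for order in itertools.permutations(diffs):
        path, cur, blocked = [], c1, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            path.append((cur, nxt, pos))
            if code[nxt] == "*" and nxt != c2:
                blocked = True
            cur = nxt
        all_paths.append(path)
        if not blocked:
            open_paths.append(path)
    paths = open_paths or all_paths
    tally = np.zeros(4)
    for path in paths:
        for cur, nxt, pos in path:
            ts = _TRANSITIONS[cur[pos]] == nxt[pos]
            syn = code[cur] != "*" and code[nxt] != "*" and code[cur] == code[nxt]
            tally[(0 if syn else 2) + (0 if ts else 1)] += 1
    return tally / len(paths)


def oracle_syn_sites(codon: str, kappa: float) -> float:
    """Potential synonymous sites of one codon with kappa:1:1 mutation weights."""
    code = dict(zip(CODONS, AMINO_ACIDS))
    if code[codon] == "*":
        return 0.0
    total = 0.0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1 :]
            w = kappa if _TRANSITIONS[codon[pos]] == alt else 1.0
            if code[mut] != "*" and code[mut] == code[codon]:
                total += w
    return total / (kappa + 2.0)


class TestCodonClassSelection:
    def test_within_codon_membership(self):
        codons = encode_codons("ACGGAT")  # [ACG][GAT]
        assert codon_class_mask(codons, "CG").tolist() == [True, False]
        assert codon_class_mask(codons, "GA").tolist() == [False, True]

    def test_boundary_spanning_selects_both(self):
        codons = encode_codons("AACGTT")  # [AAC][GTT]: CG spans the boundary
        assert codon_class_mask(codons, "CG").tolist() == [True, True]

    def test_matches_sliding_dinucleotide_oracle(self, rng):
        bases = "".join(rng.choice(list("ACGT"), 3 * 1000))
        codons = encode_codons(bases)
        for dinuc in ("CG", "GC", "AG", "GA"):
            mask = codon_class_mask(codons, dinuc)
            expected = np.zeros(1000, dtype=bool)
            for i in range(len(bases) - 1):
                if bases[i : i + 2] == dinuc:
                    c = i // 3
                    expected[c] = True
                    if (i + 1) // 3 != c:  # spans a codon boundary
                        expected[i // 3 + 1] = True
            assert mask.tolist() == expected.tolist(), dinuc

    def test_selection_subsets_alignment(self, rng):
        aln, _ = simulate_codon_alignment(
            SimulationConfig(seed=5), n_codons=500, branch_length=0.3
        )
        sub = select_codon_class(aln, "CG")
        assert len(sub) == int(codon_class_mask(aln.codons1, "CG").sum())


class TestMarkInCgi:
    def test_overlap_rules(self):
        aln = _aln("ATGGCTAAA", "ATGGCTAAA", chrom="chr1", starts=[100, 103, 106])
        cgis = IntervalSet([GI("chr1", 104, 120)])
        mark_in_cgi(aln, cgis)
        # codon at 100-103: outside; 103-106: one bp overlap; 106-109: inside
        assert aln.in_cgi.tolist() == [False, True, True]

    def test_adjacent_codon_excluded(self):
        aln = _aln("ATG", "ATG", chrom="chr1", starts=[101])
        mark_in_cgi(aln, IntervalSet([GI("chr1", 104, 120)]))
        assert aln.in_cgi.tolist() == [False]


class TestInaEstimate:
    def test_identical_sequences(self):
        est = ina_estimate(_aln("ATGGCTTTA" * 10, "ATGGCTTTA" * 10))
        assert est.ds == 0.0 and est.dn == 0.0 and not est.saturated

    def test_sequence_role_swap_invariance(self):
        aln, _ = simulate_codon_alignment(
            SimulationConfig(seed=6), n_codons=800, branch_length=0.4
        )
        e1 = ina_estimate(aln)
        e2 = ina_estimate(CodonAlignment(aln.codons2, aln.codons1))
        assert e1.ds == pytest.approx(e2.ds, abs=1e-12)
        assert e1.dn == pytest.approx(e2.dn, abs=1e-12)

    def test_codon_order_permutation_invariance(self, rng):
        aln, _ = simulate_codon_alignment(
            SimulationConfig(seed=7), n_codons=400, branch_length=0.4
        )
        perm = rng.permutation(len(aln))
        e1 = ina_estimate(aln)
        e2 = ina_estimate(CodonAlignment(aln.codons1[perm], aln.codons2[perm]))
        assert e1.ds == pytest.approx(e2.ds, abs=1e-12)

    def test_empty_alignment_raises(self):
        with pytest.raises(ValueError):
            ina_estimate(CodonAlignment(np.array([]), np.array([])))

    def test_single_fourfold_synonymous_transition(self):
        """dS for one synonymous transition among 100 codons reproduces the
        value computed independently from the method's defining formulas."""
        # GGC -> GGT at a fourfold-degenerate third position (C->T transition)
        seq1 = "GGC" * 100
        seq2 = "GGT" + "GGC" * 99
        est = ina_estimate(_aln(seq1, seq2))
        # independent oracle: 1 synonymous transition, kappa = inf (no
        # transversions observed) so synonymous sites weight only transitions
        syn_ts, syn_tv, nonsyn_ts, nonsyn_tv = oracle_pair_differences("GGC", "GGT")
        assert (syn_ts, syn_tv, nonsyn_ts, nonsyn_tv) == (1, 0, 0, 0)
        # with kappa -> inf the per-codon synonymous site count tends to the
        # number of synonymous transitions / 1 = 1 site per GGC codon
        l_s = 100 * 1.0
        p_s = 1 / l_s
        expected_ds = -0.5 * np.log(1 - 2 * p_s)
        assert est.ds == pytest.approx(expected_ds, rel=1e-9)
        assert est.dn == 0.0

    def test_pathway_tables_match_oracle_for_all_three_diff_pairs(self, rng):
        """Spot-check pathway averaging against the independent enumerator."""
        from cgiscape.subst_rates import _PAIR

        picks = rng.integers(0, 64, size=(150, 2))
        for i, j in picks:
            c1, c2 = CODONS[i], CODONS[j]
            if "*" in (AMINO_ACIDS[i], AMINO_ACIDS[j]):
                continue
            k = 64 * i + j
            got = np.array(
                [_PAIR["syn_ts"][k], _PAIR["syn_tv"][k],
                 _PAIR["nonsyn_ts"][k], _PAIR["nonsyn_tv"][k]]
            )
            assert got == pytest.approx(oracle_pair_differences(c1, c2)), (c1, c2)

    def test_site_counts_match_oracle(self):
        from cgiscape.subst_rates import _SYN_TS, _SYN_TV

        for kappa in (0.5, 1.0, 3.0):
            for idx in range(0, 64, 7):
                if IS_STOP[idx]:
                    continue
                got = (kappa * _SYN_TS[idx] + _SYN_TV[idx]) / (kappa + 2.0)
                assert got == pytest.approx(oracle_syn_sites(CODONS[idx], kappa))

    def test_r_grows_with_transition_count(self):
        """With transversions held fixed, more transitions inflate kappa."""
        base = "GGC"
        kappas = []
        for n_ts in (2, 5, 9):
            codons1 = [base] * 100
            codons2 = ["GGT"] * n_ts + ["GGA"] * 2 + [base] * (100 - n_ts - 2)
            est = ina_estimate(_aln("".join(codons1), "".join(codons2)))
            kappas.append(est.kappa)
        assert kappas[0] < kappas[1] < kappas[2]

    def test_saturation_flagged_not_clipped(self):
        # maximal divergence at synonymous sites: every codon pair differs by
        # a synonymous transition -> P_S = 1/L_S saturates the correction
        seq1 = "GGC" * 30
        seq2 = "GGT" * 30
        est = ina_estimate(_aln(seq1, seq2))
        assert est.saturated
        assert np.isnan(est.ds)


class TestBootstrap:
    def test_zero_divergence_gives_degenerate_ci(self):
        aln = _aln("ATGGCTTTA" * 20, "ATGGCTTTA" * 20)
        ci_dn, ci_ds = bootstrap_ci(aln, b=100, seed=0)
        assert ci_ds == (0.0, 0.0) and ci_dn == (0.0, 0.0)

    def test_fixed_seed_reproducible(self):
        aln, _ = simulate_codon_alignment(
            SimulationConfig(seed=8), n_codons=500, branch_length=0.4
        )
        assert bootstrap_ci(aln, b=200, seed=3) == bootstrap_ci(aln, b=200, seed=3)

    def test_ci_covers_truth_in_repeated_neutral_simulations(self):
        """~95% CI covers the generating dS in >= 90% of repetitions."""
        reps, covered = 40, 0
        for r in range(reps):
            aln, truth = simulate_codon_alignment(
                SimulationConfig(seed=2000 + r),
                n_codons=2000,
                cpg_multiplier=1.0,
                omega=1.0,
                branch_length=0.5,
            )
            _, ci_ds = bootstrap_ci(aln, b=300, seed=r)
            if ci_ds[0] <= truth["branch_length"] <= ci_ds[1]:
                covered += 1
        assert covered >= 0.9 * reps


class TestFilters:
    def _rec(self, gene, iso, n, n_exons=4, idents=(0.9, 0.9, 0.9)):
        aln = _aln("GGC" * n, "GGC" * n)
        return AlignmentRecord(gene, iso, aln, n_exons, tuple(idents))

    def test_low_identity_exon_drops_gene(self):
        recs = [self._rec("a", "a1", 50, idents=(0.9, 0.65, 0.9))]
        assert filter_alignments(recs) == []

    def test_longest_isoform_kept(self):
        recs = [self._rec("a", "short", 40), self._rec("a", "long", 60)]
        kept = filter_alignments(recs)
        assert [r.isoform for r in kept] == ["long"]

    def test_mixed_fixture_counts(self):
        recs = [
            self._rec("a", "a1", 50),
            self._rec("b", "b1", 50, n_exons=2),       # too few exons
            self._rec("c", "c1", 50, idents=(0.6,)),   # low identity
            self._rec("d", "d1", 50),
            self._rec("d", "d2", 70),                  # same gene, longer
            self._rec("e", "e1", 50),
        ]
        kept = filter_alignments(recs)
        assert sorted(r.gene for r in kept) == ["a", "d", "e"]
        assert next(r for r in kept if r.gene == "d").isoform == "d2"


class TestReports:
    def test_ratio_and_reduction_arithmetic(self):
        assert dn_ds_ratio(0.100, 0.800) == 0.125
        assert ds_reduction_pct(0.910, 1.510) == 40
        assert ds_reduction_pct(0.800, 1.273) == 37

    def test_report_shape_and_na_rows(self):
        aln, _ = simulate_codon_alignment(
            SimulationConfig(seed=9), n_codons=3000, branch_length=0.4
        )
        df = rates_report(aln)
        assert len(df) == 5 * 3 * 2  # classes x positions x in/out
        assert set(df["codon_class"]) == {"CG", "GC", "AG", "GA", "all"}
        big = df[df["n_codons"] >= 10]
        assert (big["dn_ds"].dropna() >= 0).all()

    def test_null_protection_gives_similar_ds(self):
        """With no CpG protection, dS in and out of CGIs agree within CIs."""
        aln, _ = simulate_codon_alignment(
            SimulationConfig(seed=10),
            n_codons=8000,
            cpg_multiplier=1.0,
            omega=1.0,
            branch_length=0.5,
        )
        cg = select_codon_class(aln, "CG")
        inside = cg.subset(cg.in_cgi)
        outside = cg.subset(~cg.in_cgi)
        _, ci_in = bootstrap_ci(inside, b=300, seed=1)
        _, ci_out = bootstrap_ci(outside, b=300, seed=2)
        assert ci_in[0] <= ci_out[1] and ci_out[0] <= ci_in[1]  # CIs overlap
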