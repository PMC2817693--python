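"""PWM construction, calibrated scanning and exact occurrence P-values."""

import itertools

import numpy as np
import pytest

from cgiscape.sp1_motif import (
    PWM,
    _all_word_scores,
    _word_occurrence_weights,
    best_hit_score,
    build_pwm,
    calibrate_threshold,
    cumulative_curve,
    enrichment_curve,
    make_control,
    pvalue_at_least_k,
    scan,
    sequence_background,
)
from cgiscape.synthetic_data import (
    SimulationConfig,
    simulate_sp1_sequences,
    simulate_sp1_training_sites,
)


class TestBuildPwm:
    def test_closed_form_weight(self):
        pwm = build_pwm(["GGGGCGGGG"] * 4, pseudocount=1.0)
        # column of 4 G's, uniform background: ln((4 + 0.25) / (5 * 0.25))
        assert pwm.weights[0, 2] == pytest.approx(np.log(3.4))

    def test_balanced_column_weights_vanish_at_large_n(self):
        sites = ["A", "C", "G", "T"] * 100
        pwm = build_pwm(sites)
        assert np.allclose(pwm.weights, 0.0, atol=0.01)

    def test_matches_independent_formula_on_random_sites(self, rng):
        sites = ["".join(rng.choice(list("ACGT"), 7)) for _ in range(50)]
        bg = np.array([0.2, 0.3, 0.3, 0.2])
        pwm = build_pwm(sites, pseudocount=2.0, background=bg)
        # independent recomputation
        for i in range(7):
            for b, base in enumerate("ACGT"):
                n_ib = sum(1 for s in sites if s[i] == base)
                expected = np.log((n_ib + 2.0 * bg[b]) / ((50 + 2.0) * bg[b]))
                assert pwm.weights[i, b] == pytest.approx(expected)

    def test_unequal_lengths_and_empty_raise(self):
        with pytest.raises(ValueError):
            build_pwm(["ACG", "ACGT"])
        with pytest.raises(ValueError):
            build_pwm([])


class TestCalibrate:
    def test_percentile_example(self):
        # 10 sites with best scores 1..10 at sensitivity 0.9 -> T = 2
        weights = np.zeros((1, 4))
        weights[0] = [1.0, 2.0, 3.0, 4.0]
        pwm = PWM(weights, np.full(4, 0.25))
        sites = ["A", "C", "G", "T"]
        scores = sorted(
            best_hit_score(s, pwm, both_strands=False) for s in sites
        )
        assert scores == [1, 2, 3, 4]
        assert calibrate_threshold(pwm, sites, 0.75, both_strands=False) == 2
        assert calibrate_threshold(pwm, sites, 1.0, both_strands=False) == 1

    def test_invalid_sensitivity(self):
        pwm = build_pwm(["ACG"])
        with pytest.raises(ValueError):
            calibrate_threshold(pwm, ["ACG"], 0.0)

    def test_planted_sites_recovered_at_calibrated_threshold(self):
        cfg = SimulationConfig(seed=21)
        rng = cfg.rng("motif")
        sites = simulate_sp1_training_sites(rng, n=200)
        pwm = build_pwm(sites)
        t = calibrate_threshold(pwm, sites, 0.90)
        recovered = sum(best_hit_score(s, pwm) >= t for s in sites)
        assert recovered >= 0.90 * len(sites)


class TestScan:
    def test_consensus_hit_found(self):
        pwm = build_pwm(["GGGGCGGGG"] * 10)
        seq = "ATAT" + "GGGGCGGGG" + "TTTT"
        res = scan(seq, pwm, pwm.max_score - 1e-9)
        assert any(pos == 4 and strand == "+" for pos, strand, _ in res.hits)

    def test_poly_a_has_no_hits(self):
        pwm = build_pwm(["GGGGCGGGG"] * 10)
        assert scan("A" * 200, pwm, 0.0).k == 0

    def test_sequence_shorter_than_motif(self):
        pwm = build_pwm(["GGGGCGGGG"] * 10)
        assert scan("GGGG", pwm, -100.0).k == 0

    def test_hits_match_naive_rescoring_oracle(self, rng):
        sites = ["".join(rng.choice(list("ACGT"), 5)) for _ in range(30)]
        pwm = build_pwm(sites)
        seq = "".join(rng.choice(list("ACGT"), 2000, p=[0.2, 0.3, 0.3, 0.2]))
        t = np.percentile(_all_word_scores(pwm), 98)
        res = scan(seq, pwm, t)
        naive = []
        comp = str.maketrans("ACGT", "TGCA")
        for pos in range(len(seq) - 4):
            word = seq[pos : pos + 5]
            if pwm.score_word(word) >= t:
                naive.append((pos, "+"))
            if pwm.score_word(word.translate(comp)[::-1]) >= t:
                naive.append((pos, "-"))
        assert [(p, s) for p, s, _ in res.hits] == sorted(naive)
        # recomputing reported hit scores reproduces them exactly
        for pos, strand, score in res.hits:
            word = seq[pos : pos + 5]
            if strand == "-":
                word = word.translate(comp)[::-1]
            assert pwm.score_word(word) == score


def _enumerate_pvalues(pwm, threshold, L_seq, bg, k_max, both):
    """Vectorised exhaustive oracle over all 4^L_seq sequences."""
    occ = _word_occurrence_weights(pwm, threshold, both)
    L = pwm.length
    n_words = L_seq - L + 1
    digits = np.indices((4,) * L_seq).reshape(L_seq, -1)
    probs = np.prod(bg[digits], axis=0)
    counts = np.zeros(digits.shape[1], dtype=int)
    pows = 4 ** np.arange(L - 1, -1, -1)
    for off in range(n_words):
        word_idx = (digits[off : off + L] * pows[:, None]).sum(axis=0)
        counts += occ[word_idx]
    return [float(probs[counts >= k].sum()) for k in range(k_max + 1)]


class TestPValue:
    def test_trivial_bounds(self):
        pwm = build_pwm(["GGG"] * 5)
        bg = np.full(4, 0.25)
        assert pvalue_at_least_k(8, bg, pwm, 0.0, 0).p == 1.0
        assert pvalue_at_least_k(8, bg, pwm, pwm.max_score + 1, 1).p == 0.0

    @pytest.mark.parametrize("both", [False, True])
    def test_dp_equals_exhaustive_enumeration(self, rng, both):
        sites = ["".join(rng.choice(list("ACGT"), 3)) for _ in range(12)]
        sites += ["GCG"] * 6
        pwm = build_pwm(sites)
        bg = np.array([0.2, 0.3, 0.3, 0.2])
        t = float(np.percentile(_all_word_scores(pwm), 85))
        expected = _enumerate_pvalues(pwm, t, 8, bg, 3, both)
        for k in range(4):
            dp = pvalue_at_least_k(8, bg, pwm, t, k, both_strands=both).p
            assert abs(dp - expected[k]) <= 1e-12

    def test_order1_dp_equals_enumeration(self):
        rng = np.random.default_rng(5)
        sites = ["".join(rng.choice(list("ACGT"), 3)) for _ in range(10)] + ["GGC"] * 5
        pwm = build_pwm(sites)
        bg = np.array([0.3, 0.2, 0.3, 0.2])
        trans = np.array(
            [[0.4, 0.2, 0.2, 0.2], [0.1, 0.4, 0.1, 0.4],
             [0.25, 0.25, 0.25, 0.25], [0.2, 0.3, 0.3, 0.2]]
        )
        occ = _word_occurrence_weights(pwm, 1.0, False)
        L_seq = 6
        totals = np.zeros(4)
        for word in itertools.product(range(4), repeat=L_seq):
            p = bg[word[0]]
            for a, b in zip(word, word[1:]):
                p *= trans[a, b]
            k = sum(
                occ[16 * word[i] + 4 * word[i + 1] + word[i + 2]]
                for i in range(L_seq - 2)
            )
            totals[: min(int(k), 3) + 1] += p
        for k in range(4):
            dp = pvalue_at_least_k(
                L_seq, bg, pwm, 1.0, k, both_strands=False,
                background_order=1, transition=trans,
            ).p
            assert abs(dp - totals[k]) <= 1e-12

    def test_monotone_in_k_and_length(self, rng):
        sites = ["".join(rng.choice(list("ACGT"), 3)) for _ in range(8)] + ["GCG"] * 4
        pwm = build_pwm(sites)
        bg = np.full(4, 0.25)
        t = float(np.percentile(_all_word_scores(pwm), 80))
        ps = [pvalue_at_least_k(12, bg, pwm, t, k).p for k in range(5)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))
        ps_len = [pvalue_at_least_k(L, bg, pwm, t, 2).p for L in (6, 10, 14, 20)]
        assert all(a <= b + 1e-15 for a, b in zip(ps_len, ps_len[1:]))


class TestControls:
    def test_length_two_is_itself(self, rng):
        assert make_control("AC", rng) == "AC"

    def test_dinucleotide_counts_preserved_exactly(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 400, p=[0.17, 0.33, 0.33, 0.17]))
        from collections import Counter

        dinucs = Counter(seq[i : i + 2] for i in range(len(seq) - 1))
        for _ in range(10):
            ctrl = make_control(seq, rng)
            assert Counter(
                ctrl[i : i + 2] for i in range(len(ctrl) - 1)
            ) == dinucs

    def test_markov_control_matches_length_and_alphabet(self, rng):
        seq = "ACGTACGTCCGG" * 20
        ctrl = make_control(seq, rng, mode="markov1")
        assert len(ctrl) == len(seq)
        assert set(ctrl) <= set("ACGT")

    def test_mean_composition_of_shuffles_matches_input(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 300, p=[0.17, 0.33, 0.33, 0.17]))
        from collections import Counter

        base = Counter(seq)
        for _ in range(5):
            ctrl = make_control(seq, rng)
            assert Counter(ctrl) == base  # exact, not only in the mean


class TestEnrichmentCurve:
    def test_planted_class_dominates_shuffled_control(self):
        cfg = SimulationConfig(seed=31, n_motif_seqs=12, motif_seq_len=300)
        rng = cfg.rng("motif")
        sites = simulate_sp1_training_sites(rng)
        pwm = build_pwm(sites)
        t = calibrate_threshold(pwm, sites, 0.90)
        sets = simulate_sp1_sequences(pwm, cfg, rng)
        sub = {
            "five_prime": sets["five_prime"],
            "five_prime_control": sets["five_prime_control"],
        }
        df = enrichment_curve(sub, pwm, t)
        curve = cumulative_curve(df, np.array([1.0, 2.0, 3.0]))
        planted = curve[curve["set_name"] == "five_prime"]["fraction"].to_numpy()
        control = curve[curve["set_name"] == "five_prime_control"]["fraction"].to_numpy()
        assert (planted >= control).all()
        assert planted.sum() > control.sum()

    def test_identical_sequences_give_step_function(self):
        pwm = build_pwm(["GGGGCGGGG"] * 10)
        seq = "AT" * 100 + "GGGGCGGGG" + "AT" * 100
        df = enrichment_curve({"x": [seq] * 5}, pwm, pwm.max_score - 1e-9)
        assert df["p"].nunique() == 1
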