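"""ChIP-chip normalisation pipeline and rank tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cgiscape.cgi import CgiClass, CpGIsland
from cgiscape.chip import (
    average_replicates,
    chip_pipeline,
    class_tests,
    filter_pm,
    median_scale,
    pairwise_ratio_tests,
    partition_probes,
    quantile_normalize,
)
from cgiscape.core_io import GenomicInterval

GI = GenomicInterval


class TestMedianScale:
    def test_median_250_doubles(self):
        out = median_scale(np.array([100.0, 250.0, 400.0]))
        assert out.tolist() == [200.0, 500.0, 800.0]

    def test_constant_500_unchanged(self):
        out = median_scale(np.full(10, 500.0))
        assert (out == 500.0).all()

    def test_lognormal_chip_median_exact(self, rng):
        vals = rng.lognormal(6.0, 0.7, 1001)
        out = median_scale(vals)
        assert np.median(out) == pytest.approx(500.0, abs=1e-9)

    def test_zero_median_raises(self):
        with pytest.raises(ValueError):
            median_scale(np.zeros(3))


class TestQuantileNormalize:
    def test_identical_chips_unchanged(self):
        chips = np.tile(np.array([[3.0], [1.0], [2.0]]), (1, 4))
        assert np.allclose(quantile_normalize(chips), chips)

    def test_three_by_three_worked_example(self):
        chips = np.array([[1.0, 2, 3], [2, 4, 6], [3, 6, 9]]).T
        out = quantile_normalize(chips)
        assert np.allclose(out, np.array([[2.0, 2, 2], [4, 4, 4], [6, 6, 6]]))

    def test_identical_sorted_vectors_after(self, rng):
        chips = rng.lognormal(6, 0.5, (200, 5))
        out = quantile_normalize(chips)
        ref = np.sort(out[:, 0])
        for j in range(1, 5):
            assert np.allclose(np.sort(out[:, j]), ref)

    def test_rank_order_preserved(self, rng):
        chips = rng.lognormal(6, 0.5, (100, 3))
        out = quantile_normalize(chips)
        for j in range(3):
            assert (np.argsort(out[:, j]) == np.argsort(chips[:, j])).all()

    def test_ragged_input_raises(self):
        with pytest.raises(ValueError):
            quantile_normalize(np.array([1.0, 2.0, 3.0]))


def _probe_frame(n=6):
    return pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(n)],
            "chrom": "chr1",
            "pos": np.arange(n) * 100 + 50,
            "kind": "PM",
        }
    )


class TestAverageReplicates:
    def test_identical_replicates(self):
        df = _probe_frame(3)
        for col in ("treated.1.1", "treated.1.2"):
            df[col] = [10.0, 20.0, 30.0]
        out = average_replicates(df)
        assert out["treated"].tolist() == [10.0, 20.0, 30.0]

    def test_mean_of_two(self):
        df = _probe_frame(1)
        df["input.1.1"], df["input.1.2"] = [400.0], [600.0]
        assert average_replicates(df)["input"].tolist() == [500.0]

    def test_six_replicates_match_oracle_mean(self, rng):
        df = _probe_frame(20)
        cols = [f"treated.{s}.{r}" for s in (1, 2) for r in (1, 2, 3)]
        mat = rng.lognormal(6, 0.3, (20, 6))
        for j, c in enumerate(cols):
            df[c] = mat[:, j]
        out = average_replicates(df)
        assert np.allclose(out["treated"].to_numpy(), mat.mean(axis=1))

    def test_missing_replicate_warns_and_averages_present(self):
        df = _probe_frame(2)
        df["input.1.1"] = [400.0, 100.0]
        df["input.1.2"] = [600.0, np.nan]
        with pytest.warns(UserWarning, match="incomplete"):
            out = average_replicates(df)
        assert out["input"].tolist() == [500.0, 100.0]


def _islands():
    return [
        CpGIsland(GI("chr1", 1000, 2000), 0.66, 0.8, CgiClass.FIVE_PRIME),
        CpGIsland(GI("chr1", 5000, 5600), 0.66, 0.8, CgiClass.INTERGENIC),
    ]


class TestPartition:
    def test_midpoint_membership(self):
        df = _probe_frame(3)
        df["pos"] = [1500, 5100, 9000]
        out = partition_probes(df, _islands())
        assert out["region_class"].tolist() == [
            "five_prime", "intergenic", "non_cgi",
        ]

    def test_unknown_chrom_warns_non_cgi(self):
        df = _probe_frame(1)
        df["chrom"] = "chr9"
        with pytest.warns(UserWarning, match="chr9|without"):
            out = partition_probes(df, _islands())
        assert out["region_class"].tolist() == ["non_cgi"]

    def test_synthetic_plant_matches_oracle(self, rng):
        islands = [
            CpGIsland(GI("chr1", int(s), int(s) + 400), 0.66, 0.8,
                      list(CgiClass)[i % 4])
            for i, s in enumerate(range(0, 50_000, 2500))
        ]
        df = _probe_frame(500)
        df["pos"] = rng.integers(0, 60_000, 500)
        out = partition_probes(df, islands)
        for _, row in out.iterrows():
            expected = "non_cgi"
            for isl in islands:
                if isl.interval.start <= row["pos"] < isl.interval.end:
                    expected = isl.cgi_class.value
            assert row["region_class"] == expected


def _synthetic_partitioned(rng, effect=1.3, n=2000):
    rows = []
    for cls in ("five_prime", "intragenic", "three_prime", "intergenic",
                "non_cgi"):
        base = rng.lognormal(np.log(500), 0.5, n)
        mult = effect if cls != "non_cgi" else 1.0
        treated = base * mult * rng.lognormal(0, 0.15, n)
        inp = base * rng.lognormal(0, 0.15, n)
        rows.append(pd.DataFrame({
            "region_class": cls, "treated": treated, "input": inp,
        }))
    return pd.concat(rows, ignore_index=True)


class TestClassTests:
    def test_identical_conditions_non_significant_unit_ratio(self):
        df = pd.DataFrame({
            "region_class": "five_prime",
            "treated": np.linspace(100, 900, 50),
            "input": np.linspace(100, 900, 50),
        })
        out = class_tests(df)
        row = out.loc["five_prime"]
        assert row["ratio_median"] == 1.0
        assert row["p_value"] > 0.9

    def test_planted_effect_detected_only_in_cgi_classes(self):
        df = _synthetic_partitioned(np.random.default_rng(77))
        out = class_tests(df)
        for cls in ("five_prime", "intragenic", "three_prime", "intergenic"):
            assert out.loc[cls, "p_value"] < 0.05
        assert out.loc["non_cgi", "p_value"] > 0.05

    def test_rank_test_close_to_permutation_oracle(self, rng):
        x = rng.lognormal(6, 0.4, 20)
        y = rng.lognormal(6.2, 0.4, 20)
        df = pd.DataFrame({
            "region_class": ["five_prime"] * 20 + ["non_cgi"] * 20,
            "treated": np.concatenate([x, y]),
            "input": np.ones(40),
        })
        p_rank = pairwise_ratio_tests(df).loc["five_prime", "non_cgi"]
        # permutation oracle on the Mann-Whitney U statistic
        pooled = np.concatenate([x, y])
        u_obs = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
        count = 0
        n_perm = 3000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            u = stats.mannwhitneyu(
                perm[:20], perm[20:], alternative="two-sided"
            ).statistic
            if abs(u - 200) >= abs(u_obs - 200):  # 200 = n1*n2/2
                count += 1
        p_perm = count / n_perm
        assert abs(p_rank - p_perm) < 0.02

    def test_empty_class_yields_na(self):
        df = pd.DataFrame({
            "region_class": ["five_prime"] * 5,
            "treated": np.arange(5.0) + 1,
            "input": np.arange(5.0) + 1,
        })
        out = class_tests(df)
        assert np.isnan(out.loc["intragenic", "p_value"])


class TestPipeline:
    def test_mm_probes_filtered(self):
        df = _probe_frame(4)
        df.loc[1, "kind"] = "MM"
        assert len(filter_pm(df)) == 3

    def test_deterministic_rerun(self, sim_genome, sim_config):
        from cgiscape.synthetic_data import simulate_probes

        probes = simulate_probes(sim_genome.cgis, sim_genome.chrom_sizes,
                                 sim_config)
        s1, p1, _ = chip_pipeline(probes, sim_genome.cgis)
        s2, p2, _ = chip_pipeline(probes, sim_genome.cgis)
        assert s1.equals(s2) and p1.equals(p2)

    def test_cgi_classes_significant_on_simulated_probes(self, sim_genome,
                                                         sim_config):
        from cgiscape.synthetic_data import simulate_probes

        probes = simulate_probes(sim_genome.cgis, sim_genome.chrom_sizes,
                                 sim_config)
        out, pairwise, _ = chip_pipeline(probes, sim_genome.cgis)
        for cls in ("five_prime", "intragenic", "three_prime", "intergenic"):
            assert out.loc[cls, "p_value"] < 0.05
        # strongest effect at 5' islands
        assert out.loc["five_prime", "ratio_median"] == out["ratio_median"].max()
        # all CGI classes separate from non-CGI on ratios
        for cls in ("five_prime", "intragenic", "three_prime", "intergenic"):
            assert pairwise.loc[cls, "non_cgi"] < 0.05
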