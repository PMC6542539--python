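"""RPM normalization, coverage filtering, efficiency, correction, ranking."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ripscan.enrichment import (
    FilterParams,
    background_correct,
    enrichment_table,
    filter_transcripts,
    normalize_rpm,
    rank_genes,
    rip_efficiency,
)

from conftest import make_count_table


class TestNormalizeRpm:
    def test_single_gene_column_is_one_million(self):
        t = make_count_table({"s_TAP_Input": [50]})
        assert normalize_rpm(t).counts.iloc[0, 0] == 1_000_000

    def test_hand_arithmetic(self):
        t = make_count_table({"s_TAP_Input": [30, 99_970]})
        assert normalize_rpm(t).counts.iloc[0, 0] == pytest.approx(300.0)

    def test_all_zero_column_names_the_sample(self):
        t = make_count_table({"s_TAP_Input": [0, 0]})
        with pytest.raises(ValueError, match="s_TAP_Input"):
            normalize_rpm(t)

    def test_columns_sum_to_one_million(self, rng):
        counts = {
            f"x{i}_TAP_Input": rng.integers(0, 500, size=30).tolist() for i in range(3)
        }
        rpm = normalize_rpm(make_count_table(counts))
        assert np.allclose(rpm.counts.sum(axis=0), 1e6, rtol=1e-6)


class TestFilterTranscripts:
    def test_boundary_is_exclusive_below_threshold(self):
        # RPM 14.9 dropped, 15.0 retained: counts per million scale directly.
        t = make_count_table({"s_TAP_Input": [149, 150, 9_999_701]})
        rpm = normalize_rpm(t)
        kept = filter_transcripts(rpm, FilterParams(min_input_rpm=15.0))
        assert list(kept) == ["g1", "g2"]

    def test_zero_threshold_keeps_everything(self):
        t = make_count_table({"s_TAP_Input": [1, 2, 3]})
        kept = filter_transcripts(
            normalize_rpm(t), FilterParams(min_input_rpm=0.0)
        )
        assert len(kept) == 3

    def test_noncoding_dropped_even_at_high_coverage(self):
        t = make_count_table(
            {"s_TAP_Input": [500, 500]}, gene_types=["coding", "noncoding"]
        )
        kept = filter_transcripts(normalize_rpm(t), FilterParams(min_input_rpm=15))
        assert list(kept) == ["g0"]
        kept_all = filter_transcripts(
            normalize_rpm(t), FilterParams(min_input_rpm=15, drop_noncoding=False)
        )
        assert list(kept_all) == ["g0", "g1"]

    def test_filter_uses_only_requested_strain_input(self, paired_table):
        rpm = normalize_rpm(paired_table)
        kept = filter_transcripts(
            rpm, FilterParams(min_input_rpm=150_000), strains=["HTS1"], protocol="TAP"
        )
        assert list(kept) == ["g0", "g1", "g2"]


class TestRipEfficiency:
    def test_identical_columns_give_unity(self):
        t = make_count_table(
            {"s_TAP_Input": [10, 20, 30], "s_TAP_Bound": [10, 20, 30]}
        )
        e = rip_efficiency(normalize_rpm(t), "s", "TAP")
        assert np.allclose(e, 1.0)

    def test_hand_arithmetic(self, paired_table):
        rpm = normalize_rpm(paired_table)
        e = rip_efficiency(rpm, "HTS1", "TAP")
        assert e.loc["g0"] == pytest.approx(70 / 40)

    def test_zero_bound_count_gives_zero_efficiency(self):
        t = make_count_table({"s_TAP_Input": [10, 10], "s_TAP_Bound": [0, 20]})
        e = rip_efficiency(normalize_rpm(t), "s", "TAP")
        assert e.iloc[0] == 0.0

    def test_missing_pair_raises(self, paired_table):
        with pytest.raises(KeyError, match="no Bound sample"):
            rip_efficiency(normalize_rpm(paired_table), "HTS1", "GFP")


class TestBackgroundCorrect:
    def test_self_subtraction_is_zero(self):
        e = pd.Series([1.0, 2.0], index=["a", "b"])
        assert (background_correct(e, e) == 0).all()

    def test_hand_arithmetic(self):
        e_t = pd.Series([6.0], index=["a"])
        e_u = pd.Series([1.5], index=["a"])
        assert background_correct(e_t, e_u).loc["a"] == pytest.approx(4.5)

    def test_intersection_drops_one_sided_genes(self):
        e_t = pd.Series([6.0, 2.0], index=["a", "b"])
        e_u = pd.Series([1.0], index=["a"])
        c = background_correct(e_t, e_u)
        assert list(c.index) == ["a"]

    def test_fill_zero_mode_keeps_tagged_genes(self):
        e_t = pd.Series([6.0, 2.0], index=["a", "b"])
        e_u = pd.Series([1.0], index=["a"])
        c = background_correct(e_t, e_u, mode="fill_zero")
        assert c.loc["b"] == 2.0

    def test_negative_values_are_kept(self):
        c = background_correct(
            pd.Series([0.5], index=["a"]), pd.Series([2.0], index=["a"])
        )
        assert c.loc["a"] == pytest.approx(-1.5)


class TestRankGenes:
    def test_simple_ordering(self):
        c = pd.Series([0.1, 5.0, 2.0], index=["a", "b", "c"])
        assert rank_genes(c).tolist() == [3, 1, 2]

    def test_tie_break_matches_exhaustive_total_order(self, rng):
        # Brute-force oracle: sort tuples (-c, -rpm_bound, gene_id).
        for _ in range(20):
            n = int(rng.integers(2, 11))
            genes = [f"g{i}" for i in range(n)]
            c = pd.Series(rng.choice([0.0, 1.0, 2.5], size=n), index=genes)
            b = pd.Series(rng.choice([5.0, 9.0], size=n), index=genes)
            expected_order = sorted(
                genes, key=lambda g: (-c[g], -b[g], g)
            )
            ranks = rank_genes(c, rpm_bound=b)
            assert [g for g, _ in sorted(ranks.items(), key=lambda kv: kv[1])] == (
                expected_order
            )

    def test_equal_values_deterministic_lexicographic(self):
        c = pd.Series([1.0, 1.0], index=["zz", "aa"])
        ranks = rank_genes(c)
        assert ranks.loc["aa"] == 1 and ranks.loc["zz"] == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_genes(pd.Series(dtype=float))


class TestPipelineProperties:
    def test_scale_invariance(self, paired_table):
        base = enrichment_table(paired_table, "HTS1", "TAP", filter_params=FilterParams(0, False))
        scaled = paired_table
        scaled.counts["HTS1_TAP_Bound"] *= 17
        again = enrichment_table(scaled, "HTS1", "TAP", filter_params=FilterParams(0, False))
        assert (base["rank"] == again["rank"]).all()
        assert np.allclose(base["corrected"], again["corrected"])

    def test_bound_count_monotonicity(self, paired_table):
        fp = FilterParams(0, False)
        before = enrichment_table(paired_table, "HTS1", "TAP", filter_params=fp)
        bumped = paired_table
        bumped.counts.loc["g2", "HTS1_TAP_Bound"] += 40
        after = enrichment_table(bumped, "HTS1", "TAP", filter_params=fp)
        assert after.loc["g2", "rank"] <= before.loc["g2", "rank"]

    def test_full_table_shape_and_rank_permutation(self, paired_table):
        tab = enrichment_table(paired_table, "HTS1", "TAP", filter_params=FilterParams(0, False))
        assert sorted(tab["rank"]) == list(range(1, len(tab) + 1))
        assert {"rpm_input", "rpm_bound", "efficiency", "corrected", "rank"} <= set(
            tab.columns
        )
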