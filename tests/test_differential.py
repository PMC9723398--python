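"""Normalization, presence filtering and geometric-mean regulation calls."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phosphonet import (
    ComparisonDesign,
    ConfigError,
    Thresholds,
    call_regulation,
    call_sites_and_proteins,
    filter_by_presence,
    geometric_mean,
    normalize_ratios,
    summarize_sets,
)
from phosphonet.differential import call_sites

from conftest import make_table


class TestNormalization:
    def test_median_log2_centering_matches_direct_arithmetic(self):
        # log2 median of {2, 4, 8} is 2, so each value is divided by 4
        table = make_table([[2.0, 1, 1], [4.0, 1, 1], [8.0, 1, 1]])
        normalized = normalize_ratios(table)
        assert normalized["ratio_stim_rep1"].tolist() == [0.5, 1.0, 2.0]

    def test_already_centered_column_is_unchanged_and_idempotent(self):
        table = make_table([[0.5, 1, 1], [1.0, 1, 1], [2.0, 1, 1]])
        once = normalize_ratios(table)
        pd.testing.assert_frame_equal(once, table)
        pd.testing.assert_frame_equal(normalize_ratios(once), once)

    def test_single_value_columns_center_on_themselves(self):
        # one site: every column's sole value is its own median -> becomes 1.0
        table = make_table([[5.0, 2.0, 3.0]])
        normalized = normalize_ratios(table)
        assert np.allclose(normalized.filter(regex="^ratio_"), 1.0, atol=1e-12)

    def test_every_column_has_zero_median_log2_and_missing_untouched(self):
        rng = np.random.default_rng(0)
        ratios = rng.lognormal(0.3, 0.5, size=(40, 3)).tolist()
        ratios[5][1] = None
        table = make_table(ratios)
        normalized = normalize_ratios(table)
        for column in normalized.filter(regex="^ratio_").columns:
            present = normalized[column].dropna()
            assert abs(np.median(np.log2(present))) < 1e-12
        assert np.isnan(normalized["ratio_stim_rep2"].iloc[5])

    def test_scale_equivariance_per_column(self):
        rng = np.random.default_rng(1)
        table = make_table(rng.lognormal(0, 0.4, size=(20, 3)).tolist())
        scaled = table.copy()
        scaled["ratio_stim_rep2"] = scaled["ratio_stim_rep2"] * 7.3
        pd.testing.assert_frame_equal(normalize_ratios(table), normalize_ratios(scaled))

    def test_all_missing_column_names_the_column(self):
        table = make_table([[None, 1, 1], [None, 2, 1]])
        with pytest.raises(ConfigError, match="ratio_stim_rep1"):
            normalize_ratios(table)

    def test_nonpositive_ratio_names_the_record(self):
        table = make_table([[1.0, 1, 1], [-2.0, 1, 1]])
        with pytest.raises(ConfigError, match="S001"):
            normalize_ratios(table)


class TestGeometricMean:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([4.0, 1.0], 2.0),
            ([2.0, 2.0, 2.0], 2.0),
            ([1.2, 1.8, 1.5], 3.24 ** (1 / 3)),
        ],
    )
    def test_matches_direct_arithmetic(self, values, expected):
        assert geometric_mean(values) == pytest.approx(expected, rel=1e-12)

    def test_rejects_empty_and_nonpositive(self):
        with pytest.raises(ConfigError):
            geometric_mean([])
        with pytest.raises(ConfigError):
            geometric_mean([1.0, 0.0])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.01, 100.0), min_size=1, max_size=6), st.randoms())
    def test_commutative_in_input_order(self, values, rnd):
        shuffled = list(values)
        rnd.shuffle(shuffled)
        assert geometric_mean(values) == pytest.approx(geometric_mean(shuffled))


class TestRegulationCall:
    @pytest.mark.parametrize(
        "gm, label",
        [
            (1.6, "up"),
            (0.5, "down"),
            (1.5, "unchanged"),  # strict inequality at the boundary
            (0.67, "unchanged"),
            (1.0, "unchanged"),
        ],
    )
    def test_thresholds_are_strict(self, gm, label, thresholds):
        assert call_regulation(gm, thresholds) == label

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(1.01, 5.0), st.floats(0.001, 10.0))
    def test_raising_up_threshold_never_creates_up_calls(self, up, gm):
        loose = Thresholds(up_threshold=1.5)
        tight = Thresholds(up_threshold=1.5 + up)
        if call_regulation(gm, tight) == "up":
            assert call_regulation(gm, loose) == "up"


class TestPresenceFilter:
    def test_two_of_three_rule(self, thresholds, comparison):
        table = make_table(
            [
                [2.0, 2.0, 2.0],  # 3/3 -> retained
                [2.0, 2.0, None],  # 2/3 -> retained
                [2.0, None, None],  # 1/3 -> not quantified
            ]
        )
        kept, dropped = filter_by_presence(table, thresholds, comparison)
        assert kept["site_id"].tolist() == ["S000", "S001"]
        assert dropped["site_id"].tolist() == ["S002"]

    def test_absent_denominator_replicate_counts_as_missing(self, thresholds, comparison):
        table = make_table([[2.0, 2.0, 2.0]], ctrl_ratios=[[1.0, None, None]])
        kept, dropped = filter_by_presence(table, thresholds, comparison)
        assert len(kept) == 0 and len(dropped) == 1

    def test_unknown_condition_is_an_error(self, thresholds):
        table = make_table([[1.0, 1.0, 1.0]])
        with pytest.raises(ConfigError, match="missing_cond"):
            filter_by_presence(
                table, thresholds, ComparisonDesign("bad", "missing_cond", "ctrl")
            )


class TestSiteAndProteinCalls:
    def test_protein_direction_is_union_of_regulated_site_directions(
        self, thresholds, comparison
    ):
        table = make_table(
            [
                [2.0, 2.0, 2.0],  # up
                [1.0, 1.0, 1.0],  # unchanged
                [2.0, 2.0, 2.0],  # up
                [0.4, 0.4, 0.4],  # down
                [1.0, 1.0, 1.0],  # unchanged
            ],
            proteins=["PA", "PA", "PB", "PB", "PC"],
        )
        sites, proteins = call_sites_and_proteins(table, [comparison], thresholds)
        by_protein = proteins.set_index("protein_id")
        assert by_protein.loc["PA", "directions"] == "up"
        assert bool(by_protein.loc["PA", "regulated"])
        assert by_protein.loc["PB", "directions"] == "up|down"
        assert by_protein.loc["PC", "directions"] == ""
        assert not bool(by_protein.loc["PC", "regulated"])

    def test_gm_ratio_uses_only_present_replicates(self, thresholds, comparison):
        table = make_table([[4.0, 1.0, None]])
        sites = call_sites(table, comparison, thresholds)
        assert sites["gm_ratio"].iloc[0] == pytest.approx(2.0)
        assert sites["n_present"].iloc[0] == 2

    def test_duplicate_site_ids_rejected(self, thresholds, comparison):
        table = make_table([[1.0, 1, 1], [1.0, 1, 1]])
        table.loc[1, "site_id"] = "S000"
        with pytest.raises(ConfigError, match="duplicate"):
            call_sites(table, comparison, thresholds)

    def test_partition_up_down_unchanged_not_quantified(self, thresholds, comparison):
        rng = np.random.default_rng(7)
        ratios = rng.lognormal(0, 0.6, size=(60, 3))
        ratios[rng.random((60, 3)) < 0.3] = np.nan
        listed = [[None if np.isnan(v) else v for v in row] for row in ratios]
        table = make_table(listed)
        # guard against an all-NaN normalization column in this fixture
        sites = call_sites(table, comparison, thresholds)
        counts = sites["label"].value_counts()
        assert counts.sum() == len(table)
        assert set(counts.index) <= {"up", "down", "unchanged", "not_quantified"}


class TestSetSummaries:
    @staticmethod
    def _calls(entries, comparison="T3"):
        return pd.DataFrame(
            [
                {
                    "site_id": sid,
                    "protein_id": sid,
                    "comparison": comparison,
                    "n_present": 3,
                    "gm_ratio": 2.0 if label == "up" else 0.5,
                    "label": label,
                }
                for sid, label in entries
            ]
        )

    def test_unique_shared_coherent_discordant(self):
        a = self._calls([("p1", "up"), ("p2", "up")])
        b = self._calls([("p2", "up"), ("p3", "down")])
        overlap, kinetics = summarize_sets(a, b, "ACKR2", "CCR5")
        row = overlap.iloc[0]
        assert (
            row["unique_to_a"],
            row["unique_to_b"],
            row["shared_coherent"],
            row["shared_discordant"],
        ) == (1, 1, 1, 0)
        by = kinetics.set_index("receptor")
        assert by.loc["ACKR2", "n_up"] == 2 and by.loc["CCR5", "n_down"] == 1

    def test_identical_and_disjoint_call_sets(self):
        a = self._calls([("p1", "up"), ("p2", "down")])
        overlap, _ = summarize_sets(a, a.copy(), "A", "B")
        assert overlap.iloc[0]["unique_to_a"] == 0
        assert overlap.iloc[0]["shared_coherent"] == 2
        b = self._calls([("q1", "up")])
        overlap2, _ = summarize_sets(a, b, "A", "B")
        assert overlap2.iloc[0]["shared_coherent"] + overlap2.iloc[0]["shared_discordant"] == 0

    def test_opposite_directions_are_discordant(self):
        a = self._calls([("p1", "up")])
        b = self._calls([("p1", "down")])
        overlap, _ = summarize_sets(a, b)
        assert overlap.iloc[0]["shared_discordant"] == 1

    def test_mismatched_comparisons_rejected(self):
        a = self._calls([("p1", "up")], comparison="T3")
        b = self._calls([("p1", "up")], comparison="T30")
        with pytest.raises(ConfigError, match="mismatched"):
            summarize_sets(a, b)


class TestThresholdValidation:
    def test_up_threshold_must_exceed_one(self):
        with pytest.raises(ConfigError):
            Thresholds(up_threshold=0.9)

    def test_min_present_bounded_by_replicates(self):
        with pytest.raises(ConfigError):
            Thresholds(min_present=4, n_replicates=3)

    def test_same_condition_comparison_rejected(self):
        with pytest.raises(ConfigError):
            ComparisonDesign("bad", "stim", "stim")
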