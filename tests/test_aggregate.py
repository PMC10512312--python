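"""Binning, keyword categorization and section averaging rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bgcrank import aggregate
from bgcrank.aggregate import (
    BinScheme,
    Bin,
    default_amp_bin_scheme,
    default_keyword_scheme,
)
from bgcrank.errors import ConfigurationError


def _hits(values, species="s", annotation=""):
    return pd.DataFrame(
        {
            "species_id": [species] * len(values),
            "feature_name": [f"f{i}" for i in range(len(values))],
            "match_percent": pd.array(values, dtype="float64"),
            "annotation": [annotation] * len(values),
        }
    )


class TestThresholdSplit:
    def test_75_is_inclusive_high(self):
        high, low = aggregate.split_by_threshold(_hits([75.0, 74.9]))
        assert high["count"].sum() == 1 and low["count"].sum() == 1
        assert high.loc[0, "category"] == "f0"  # the 75.0 hit
        assert low.loc[0, "category"] == "f1"

    @given(st.lists(st.floats(0, 100, allow_nan=False), max_size=50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_conservation(self, values):
        high, low = aggregate.split_by_threshold(_hits(values))
        assert high["count"].sum() + low["count"].sum() == len(values)

    def test_counts_keyed_by_feature(self, hit_table):
        high, _ = aggregate.split_by_threshold(hit_table)
        row = high[(high["species_id"] == "h1") & (high["category"] == "clavaric acid")]
        assert row["count"].item() == 1


class TestAmpBinning:
    @pytest.mark.parametrize(
        "value,label",
        [
            (100.0, "100"),
            (99.9, "99.9–95.0"),
            (95.0, "99.9–95.0"),
            (94.9, "94.9–90.0"),
            (90.0, "94.9–90.0"),
            (89.95, "89.9–80.0"),
            (80.0, "89.9–80.0"),
            (70.0, "79.9–70.0"),
            (69.9, "69.9–51.0"),
            (51.0, "69.9–51.0"),
        ],
    )
    def test_bin_membership(self, value, label):
        assert default_amp_bin_scheme().assign(value) == label

    @pytest.mark.parametrize("value", [50.9, 50.0, 0.0])
    def test_exclusion_floor(self, value):
        assert default_amp_bin_scheme().assign(value) is None

    def test_partition_on_decigrid(self):
        """Every 0.1-grid value of [0,100] is excluded or in exactly one bin."""
        scheme = default_amp_bin_scheme()
        grid = np.round(np.arange(0.0, 100.05, 0.1), 1)
        for value in grid:
            memberships = sum(b.contains(float(value)) for b in scheme.bins)
            if value < scheme.exclusion_threshold:
                assert scheme.assign(float(value)) is None
            else:
                assert memberships == 1

    def test_binned_counts_and_exclusions(self):
        values = [100.0, 97.3, 92.0, 85.0, 73.0, 60.0, 50.9, 12.0]
        binned = aggregate.bin_amp_matches(_hits(values))
        assert binned.n_excluded == 2
        assert binned.n_retained == 6
        assert binned.counts["count"].sum() == 6
        assert len(binned.per_bin["100"]) == 1

    def test_overlapping_scheme_rejected(self):
        with pytest.raises(ConfigurationError, match="disjointly"):
            BinScheme(
                bins=(Bin("a", 80.0, 100.0, True, True), Bin("b", 50.0, 90.0)),
                exclusion_threshold=50.0,
            )

    def test_gapped_scheme_rejected(self):
        with pytest.raises(ConfigurationError, match="disjointly"):
            BinScheme(bins=(Bin("a", 80.0, 100.0, True, True),), exclusion_threshold=50.0)


class TestKeywords:
    def test_case_insensitive_substring(self):
        scheme = default_keyword_scheme()
        assert scheme.assign("Hypothetical Protein, partial") == "hypothetical protein"
        assert scheme.assign("Glycoside Hydrolase family 18") == "glycoside hydrolase family"

    def test_first_match_wins(self):
        scheme = aggregate.KeywordScheme(
            categories=(("first", ("protein",)), ("second", ("hypothetical",)))
        )
        assert scheme.assign("hypothetical protein") == "first"

    def test_empty_annotation_falls_back(self):
        assert default_keyword_scheme().assign("") == "unannotated"
        assert default_keyword_scheme().assign("novel widget") == "unannotated"

    def test_counts_conserved(self, hit_table):
        out = aggregate.bin_keywords(hit_table)
        assert out["count"].sum() == len(hit_table)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ConfigurationError, match="unique"):
            aggregate.KeywordScheme(categories=(("x", ("a",)), ("x", ("b",))))


class TestHypotheticalFraction:
    def _counts(self, mapping):
        rows = [
            {"species_id": sp, "category": cat, "count": n}
            for sp, cats in mapping.items()
            for cat, n in cats.items()
        ]
        return pd.DataFrame(rows)

    def test_ratio(self):
        counts = self._counts({"s": {"hypothetical protein": 7, "peptidase": 3}})
        frac = aggregate.hypothetical_fraction(counts)
        assert frac["s"] == pytest.approx(0.7)

    def test_zero_total_absent_not_zero(self):
        counts = self._counts({"a": {"peptidase": 0}, "b": {"hypothetical protein": 2}})
        frac = aggregate.hypothetical_fraction(counts)
        assert "a" not in frac.index
        assert frac["b"] == 1.0


class TestTopK:
    def test_lexicographic_tie_break(self):
        counts = pd.DataFrame(
            {"species_id": ["s"] * 3, "category": ["B", "A", "C"], "count": [3, 3, 1]}
        )
        assert aggregate.top_k_annotations(counts, k=2)["s"] == ["A", "B"]

    def test_truncation_and_exclusion(self):
        counts = pd.DataFrame(
            {
                "species_id": ["s"] * 3,
                "category": ["unannotated", "X", "Y"],
                "count": [9, 2, 1],
            }
        )
        assert aggregate.top_k_annotations(counts, k=5)["s"] == ["X", "Y"]
        assert aggregate.top_k_annotations(counts, k=5, exclude=())["s"] == [
            "unannotated", "X", "Y",
        ]

    def test_k_must_be_positive(self):
        with pytest.raises(ConfigurationError):
            aggregate.top_k_annotations(pd.DataFrame(columns=["species_id", "category", "count"]), k=0)


class TestGenomeTotals:
    def test_sum_and_implicit_zero(self, count_table, species_table):
        totals = aggregate.genome_totals(count_table, species_table)
        assert totals["h1"] == 6
        assert totals["t2"] == 0
        assert totals.sum() == count_table["count"].sum()


class TestSectionAverage:
    def test_implicit_zero_in_denominator(self, species_table):
        counts = pd.DataFrame(
            {"species_id": ["h1"], "category": ["c"], "count": [4]}
        )
        matrix = aggregate.section_average(counts, species_table)
        # h2 recorded nothing but still divides the Harzianum sum
        assert matrix.values.at["Harzianum", "c"] == pytest.approx(2.0)
        assert matrix.species_counts["Harzianum"] == 2

    def test_single_species_section_is_identity(self, species_table):
        counts = pd.DataFrame(
            {"species_id": ["l1", "l1"], "category": ["a", "b"], "count": [5, 7]}
        )
        matrix = aggregate.section_average(counts, species_table)
        assert matrix.values.at["Longibrachiatum", "a"] == 5.0
        assert matrix.values.at["Longibrachiatum", "b"] == 7.0

    def test_cells_times_n_equal_section_sums(self, count_table, species_table):
        matrix = aggregate.section_average(count_table, species_table)
        merged = count_table.merge(species_table, on="species_id")
        for section in matrix.values.index:
            for category in matrix.values.columns:
                direct = merged.loc[
                    (merged["section"] == section) & (merged["category"] == category),
                    "count",
                ].sum()
                cell = matrix.values.at[section, category]
                assert cell * matrix.species_counts[section] == pytest.approx(direct)

    @given(st.integers(2, 9))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_linearity(self, factor):
        species = pd.DataFrame(
            {"species_id": ["a", "b", "c"], "section": ["S1", "S1", "S2"], "strain": ""}
        )
        counts = pd.DataFrame(
            {"species_id": ["a", "b", "c"], "category": ["x", "x", "y"], "count": [1, 4, 2]}
        )
        base = aggregate.section_average(counts, species)
        scaled = counts.assign(count=counts["count"] * factor)
        out = aggregate.section_average(scaled, species)
        pd.testing.assert_frame_equal(out.values, base.values * factor)

    def test_unknown_species_rejected(self, species_table):
        counts = pd.DataFrame({"species_id": ["ghost"], "category": ["c"], "count": [1]})
        with pytest.raises(ConfigurationError, match="ghost"):
            aggregate.section_average(counts, species_table)
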