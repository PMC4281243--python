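"""Classifier unit and property tests, including the brute-force group oracle."""

import itertools

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tissuespec.errors import ConfigError, DataError
from tissuespec.expression_io import TissueProfile, average_by_tissue
from tissuespec.specificity_classifier import (
    Category,
    CategoryTally,
    Thresholds,
    classify_gene,
    classify_profile,
    find_enriched_group,
    is_detected,
    mrna_pool_fractions,
    tissue_specificity_score,
    top_expressed,
)

from conftest import make_profile


def brute_force_group(series: pd.Series, target: str, thresholds: Thresholds):
    """Exhaustive search over every tissue subset of the allowed sizes.

    Returns the smallest qualifying size (or None); independent of the
    sorted-prefix implementation.
    """
    others = [t for t in series.index if t != target]
    for size in range(thresholds.group_min_size, thresholds.group_max_size + 1):
        for combo in itertools.combinations(others, size - 1):
            group = set(combo) | {target}
            outside = [series[t] for t in series.index if t not in group]
            level = max(max(outside), thresholds.ts_denominator_floor)
            if series[list(group)].mean() >= thresholds.group_fold * level:
                return size
    return None


class TestIsDetected:
    @pytest.mark.parametrize(
        "fpkm, expected", [(0.99, False), (1.0, True), (1421.0, True), (0.0, False)]
    )
    def test_detection_boundary(self, fpkm, expected):
        assert is_detected(fpkm, 1.0) is expected

    def test_negative_rejected(self):
        from tissuespec.errors import NegativeValueError

        with pytest.raises(NegativeValueError):
            is_detected(-1.0)


class TestTissueSpecificityScore:
    def test_direct_ratio(self):
        profile = pd.Series({"kidney": 100.0, "liver": 4.0, "lung": 2.0})
        assert tissue_specificity_score(profile, "kidney") == pytest.approx(25.0)

    def test_denominator_floor_when_all_others_silent(self):
        profile = pd.Series({"kidney": 100.0, "liver": 0.0, "lung": 0.0})
        assert tissue_specificity_score(profile, "kidney") == pytest.approx(10_000.0)

    def test_max_of_others(self):
        profile = pd.Series({"kidney": 250.0, "liver": 50.0, "lung": 10.0, "skin": 0.5})
        assert tissue_specificity_score(profile, "kidney") == pytest.approx(5.0)

    def test_unknown_target(self):
        with pytest.raises(DataError):
            tissue_specificity_score(pd.Series({"liver": 1.0, "lung": 2.0}), "kidney")

    def test_scale_invariance(self):
        profile = pd.Series({"kidney": 30.0, "liver": 7.0, "lung": 2.0})
        a = tissue_specificity_score(profile, "kidney")
        b = tissue_specificity_score(profile * 13.7, "kidney")
        assert a == pytest.approx(b)


class TestFindEnrichedGroup:
    def test_pair_with_strong_partner(self):
        values = {"kidney": 50.0, "liver": 40.0}
        values.update({f"t{i}": 8.0 for i in range(8)})
        group = find_enriched_group(pd.Series(values), "kidney")
        assert group == {"kidney", "liver"}  # mean 45 >= 5 * 8

    def test_flat_competitors_yield_none(self):
        values = {"kidney": 50.0}
        values.update({f"t{i}": 49.0 for i in range(9)})
        assert find_enriched_group(pd.Series(values), "kidney") is None

    def test_group_max_size_must_leave_outside_tissues(self):
        values = {"kidney": 50.0, "liver": 40.0, "lung": 1.0}
        with pytest.raises(ConfigError):
            find_enriched_group(pd.Series(values), "kidney", Thresholds(group_max_size=7))

    def test_smallest_qualifying_group_returned(self):
        # both {kidney, a} and any larger prefix qualify; expect the pair
        values = {"kidney": 100.0, "a": 100.0}
        values.update({f"t{i}": 1.0 for i in range(8)})
        group = find_enriched_group(pd.Series(values), "kidney")
        assert group == {"kidney", "a"}

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_oracle(self, data):
        n_tissues = data.draw(st.integers(8, 10))
        values = data.draw(
            st.lists(
                st.floats(0.0, 1000.0, allow_nan=False, width=32),
                min_size=n_tissues,
                max_size=n_tissues,
            )
        )
        series = pd.Series(values, index=[f"t{i}" for i in range(n_tissues)])
        thresholds = Thresholds(group_max_size=min(7, n_tissues - 1))
        found = find_enriched_group(series, "t0", thresholds)
        oracle_size = brute_force_group(series, "t0", thresholds)
        if oracle_size is None:
            assert found is None
        else:
            assert found is not None and len(found) == oracle_size
            outside = [series[t] for t in series.index if t not in found]
            level = max(max(outside), thresholds.ts_denominator_floor)
            assert series[list(found)].mean() >= thresholds.group_fold * level


class TestClassifyGene:
    def test_highly_enriched(self):
        values = {"kidney": 100.0}
        values.update({f"t{i}": 1.9 for i in range(26)})
        c = classify_gene(pd.Series(values), "kidney")
        assert c.category is Category.HIGHLY_ENRICHED
        assert c.ts_score == pytest.approx(100 / 1.9)

    def test_expressed_in_all(self):
        values = {f"t{i}": 5.0 for i in range(26)}
        values["kidney"] = 5.0
        c = classify_gene(pd.Series(values), "kidney")
        assert c.category is Category.EXPRESSED_IN_ALL
        assert c.n_detected_tissues == 27

    def test_not_detected_takes_precedence(self):
        values = {"kidney": 0.5}
        values.update({f"t{i}": float(i) for i in range(26)})
        assert classify_gene(pd.Series(values), "kidney").category is Category.NOT_DETECTED

    def test_group_enriched_when_ts_too_low(self):
        values = {"kidney": 30.0, "liver": 10.0}
        values.update({f"t{i}": 0.2 for i in range(25)})
        c = classify_gene(pd.Series(values), "kidney")
        assert c.ts_score == pytest.approx(3.0)
        assert c.category is Category.GROUP_ENRICHED
        assert c.enriched_group == {"kidney", "liver"}

    def test_enhanced_denominator_includes_target(self):
        # target 30, seven tissues at 10, nineteen at 0.5: mean = 110.5/27
        values = {"kidney": 30.0}
        values.update({f"mid{i}": 10.0 for i in range(7)})
        values.update({f"low{i}": 0.5 for i in range(19)})
        c = classify_gene(pd.Series(values), "kidney")
        assert c.category is Category.ENHANCED
        assert 30.0 >= 5 * (110.5 / 27)

    def test_mixed_fallback(self):
        values = {"kidney": 5.0}
        values.update({f"mid{i}": 5.0 for i in range(10)})
        values.update({f"low{i}": 0.0 for i in range(16)})
        c = classify_gene(pd.Series(values), "kidney")
        assert c.category is Category.MIXED
        assert c.n_detected_tissues == 11

    def test_monotone_in_target_fpkm(self):
        base = {"kidney": 10.0, "liver": 8.0}
        base.update({f"t{i}": 2.0 for i in range(8)})
        order = [
            Category.NOT_DETECTED,
            Category.MIXED,
            Category.EXPRESSED_IN_ALL,
            Category.ENHANCED,
            Category.GROUP_ENRICHED,
            Category.MODERATELY_ENRICHED,
            Category.HIGHLY_ENRICHED,
        ]
        last_ts, last_rank = -1.0, -1
        ranks = []
        for target in [0.5, 5.0, 10.0, 50.0, 100.0, 1000.0]:
            values = dict(base, kidney=target)
            c = classify_gene(pd.Series(values), "kidney")
            assert c.ts_score >= last_ts
            last_ts = c.ts_score
            ranks.append(order.index(c.category))
        # never moves from a more specific category to a less specific one
        assert ranks == sorted(ranks)


class TestClassifyProfile:
    def test_empty_profile(self):
        profile = TissueProfile(pd.DataFrame(columns=["kidney", "liver"], dtype=float))
        classifications, tally = classify_profile(profile, "kidney")
        assert classifications == [] and tally.total == 0

    def test_partition_and_tally(self, planted_study):
        config, matrix, samples, truths = planted_study
        profile = average_by_tissue(matrix, samples)
        classifications, tally = classify_profile(profile, "kidney")
        assert tally.total == len(classifications) == matrix.n_genes
        assert sum(tally.counts.values()) == tally.total
        assert tally.elevated_count == sum(
            tally.counts[c]
            for c in (
                Category.HIGHLY_ENRICHED,
                Category.MODERATELY_ENRICHED,
                Category.GROUP_ENRICHED,
                Category.ENHANCED,
            )
        )

    def test_gene_order_invariance(self, planted_study):
        _, matrix, samples, _ = planted_study
        profile = average_by_tissue(matrix, samples)
        _, tally_a = classify_profile(profile, "kidney")
        permuted = TissueProfile(
            profile.mean_fpkm.sample(frac=1, random_state=0),
            n_samples_per_tissue=profile.n_samples_per_tissue,
        )
        _, tally_b = classify_profile(permuted, "kidney")
        assert tally_a.counts == tally_b.counts

    def test_scale_invariance_of_categories(self):
        profile = make_profile(
            {
                "g1": {"kidney": 100.0, "liver": 1.5, "lung": 1.5, "skin": 1.5},
                "g2": {"kidney": 8.0, "liver": 8.0, "lung": 8.0, "skin": 8.0},
            }
        )
        scaled = TissueProfile(profile.mean_fpkm * 3.0)
        thresholds = Thresholds(group_max_size=2)
        a, _ = classify_profile(profile, "kidney", thresholds)
        b, _ = classify_profile(scaled, "kidney", thresholds)
        # detection status unchanged for every tissue => same categories
        assert [c.category for c in a] == [c.category for c in b]
        assert [c.ts_score for c in a] == pytest.approx([c.ts_score for c in b])


class TestPoolFractions:
    def test_two_gene_split(self):
        profile = make_profile(
            {
                "hk": {"kidney": 80.0, "liver": 80.0, "lung": 80.0, "skin": 80.0},
                "enr": {"kidney": 20.0, "liver": 0.1, "lung": 0.1, "skin": 0.1},
            }
        )
        thresholds = Thresholds(group_max_size=2)
        classifications, _ = classify_profile(profile, "kidney", thresholds)
        pools = mrna_pool_fractions(profile, classifications, "kidney")
        assert pools.fractions["expressed_in_all"] == pytest.approx(0.8)
        assert pools.fractions["elevated"] == pytest.approx(0.2)
        assert sum(pools.fractions.values()) == pytest.approx(1.0)

    def test_all_one_category(self):
        profile = make_profile(
            {f"g{i}": {"kidney": 5.0, "liver": 5.0, "lung": 5.0, "skin": 5.0} for i in range(4)}
        )
        classifications, _ = classify_profile(profile, "kidney", Thresholds(group_max_size=2))
        pools = mrna_pool_fractions(profile, classifications, "kidney")
        assert pools.fractions["expressed_in_all"] == pytest.approx(1.0)

    def test_zero_total_rejected(self):
        profile = make_profile({"g": {"kidney": 0.0, "liver": 0.0, "lung": 0.0, "skin": 0.0}})
        classifications, _ = classify_profile(profile, "kidney", Thresholds(group_max_size=2))
        with pytest.raises(DataError):
            mrna_pool_fractions(profile, classifications, "kidney")


class TestTopExpressed:
    def test_ranking_and_tie_break(self):
        profile = make_profile(
            {
                "zz": {"kidney": 100.0, "liver": 1.0, "lung": 1.0, "skin": 1.0},
                "aa": {"kidney": 100.0, "liver": 1.0, "lung": 1.0, "skin": 1.0},
                "mid": {"kidney": 50.0, "liver": 1.0, "lung": 1.0, "skin": 1.0},
            }
        )
        classifications, _ = classify_profile(profile, "kidney", Thresholds(group_max_size=2))
        table = top_expressed(profile, "kidney", classifications, n=2)
        assert list(table["gene_id"]) == ["aa", "zz"]

    def test_n_larger_than_gene_count_returns_all(self):
        profile = make_profile({"g": {"kidney": 5.0, "liver": 1.0, "lung": 1.0, "skin": 1.0}})
        classifications, _ = classify_profile(profile, "kidney", Thresholds(group_max_size=2))
        assert len(top_expressed(profile, "kidney", classifications, n=30)) == 1

    def test_category_annotation_present(self):
        profile = make_profile(
            {"g": {"kidney": 500.0, "liver": 1.0, "lung": 1.0, "skin": 1.0}}
        )
        classifications, _ = classify_profile(profile, "kidney", Thresholds(group_max_size=2))
        table = top_expressed(profile, "kidney", classifications, n=1)
        assert table.loc[0, "category"] == "highly_enriched"


def test_category_tally_from_counts_matches_manual():
    tally = CategoryTally(
        {
            Category.HIGHLY_ENRICHED: 2,
            Category.MODERATELY_ENRICHED: 3,
            Category.GROUP_ENRICHED: 5,
            Category.ENHANCED: 7,
            Category.MIXED: 11,
        }
    )
    assert tally.elevated_count == 17
    assert tally.total == 28
    assert tally.top_level_counts["elevated"] == 17
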