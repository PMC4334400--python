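"""New-study ranking (scenario 1) and study-extension comparison (scenario 2)."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from assaydesign import (
    Assay,
    DiseaseModel,
    ExtensionScenario,
    InvalidParameterError,
    affordable_sample_size,
    equivalence_hit_ratio,
    evaluate_design,
    expected_complete_mechanisms,
    extension_sample_ratio,
    extension_yields,
    min_extra_hit_rate,
    partition_parameter_space,
    rank_assays,
    ranking_report,
    required_base_hit_rate,
)

prices = st.floats(min_value=0.01, max_value=100.0)
complexities = st.floats(min_value=1.0, max_value=12.0)


# ---------------------------------------------------------------- scenario 1

@pytest.mark.parametrize("budget, price, expected", [
    (16, 4, 4), (16, 1, 16), (3, 4, 0), (10, 3, 3),
])
def test_affordable_sample_size(budget, price, expected):
    assert affordable_sample_size(budget, price) == expected


def test_affordable_sample_size_rejects_free_assay():
    with pytest.raises(InvalidParameterError):
        affordable_sample_size(10, 0)


def test_evaluate_design_fills_all_fields(wes, two_mutation_disease):
    ev = evaluate_design(16, wes, two_mutation_disease)
    assert ev.n == 4
    assert round(ev.expected_yield, 2) == 0.29
    assert ev.discoverability == pytest.approx(0.0729)
    assert ev.utility == pytest.approx(0.0729 / 4)
    assert ev.budget_spent == 16 and ev.budget_left == 0


def test_evaluate_design_zero_budget(wes, two_mutation_disease):
    ev = evaluate_design(0, wes, two_mutation_disease)
    assert ev.n == 0 and ev.expected_yield == 0.0


def test_evaluate_design_reports_leftover(two_mutation_disease):
    ev = evaluate_design(10, Assay("x", 0.3, 3.0), two_mutation_disease)
    assert ev.n == 3 and ev.budget_left == pytest.approx(1.0)


class TestRanking:
    def test_wes_beats_chip_at_equal_budget(self, wes, chip,
                                            two_mutation_disease):
        report = ranking_report(16, [chip, wes], two_mutation_disease)
        assert report["utility_order"] == ["WES", "chip-CNV"]
        (ratio,) = report["pairwise_yield_ratios"]
        # 26% better when quoted from 2-dp yields, ~27% at full precision
        assert ratio["yield_ratio_display"] == pytest.approx(1.26)
        assert ratio["yield_ratio"] == pytest.approx(0.2916 / 0.2304,
                                                     rel=1e-12)

    def test_single_assay(self, wes, two_mutation_disease):
        assert rank_assays(16, [wes], two_mutation_disease)[0].assay == wes

    def test_tie_broken_by_name(self, two_mutation_disease):
        twins = [Assay("beta", 0.3, 2.0), Assay("alpha", 0.3, 2.0)]
        ranked = rank_assays(8, twins, two_mutation_disease)
        assert [e.assay.name for e in ranked] == ["alpha", "beta"]

    def test_empty_catalog_rejected(self, two_mutation_disease):
        with pytest.raises(InvalidParameterError):
            rank_assays(10, [], two_mutation_disease)

    def test_c1_ranking_reduces_to_hit_rate_per_price(self):
        catalog = [Assay("a", 0.4, 3.0), Assay("b", 0.3, 2.0),
                   Assay("c", 0.9, 10.0)]
        ranked = rank_assays(60, catalog, DiseaseModel(1))
        by_v_over_p = sorted(catalog, key=lambda a: -a.hit_rate / a.price)
        assert [e.assay.name for e in ranked] == [a.name for a in by_v_over_p]

    def test_doubling_budget_doubles_yield_for_divisible_prices(
            self, wes, chip, two_mutation_disease):
        for assay in (wes, chip):
            ev1 = evaluate_design(16, assay, two_mutation_disease)
            ev2 = evaluate_design(32, assay, two_mutation_disease)
            assert ev2.expected_yield == pytest.approx(2 * ev1.expected_yield)


# ---------------------------------------------------------------- scenario 2

class TestExtensionYields:
    def test_chip_genotyping_existing_trios_wins(self, crs_extension):
        verdict = extension_yields(crs_extension)
        assert verdict.n_A == 5
        assert verdict.yield_A == pytest.approx(0.3645, rel=1e-12)
        assert round(verdict.yield_B, 2) == 0.61
        assert verdict.favoured == "B"

    def test_uninformative_extra_assay_favours_new_cases(self):
        sc = ExtensionScenario(n=4, base_hit_rate=0.3, augmented_hit_rate=0.3,
                               complexity=2, price_A=2.0, price_B=1.0,
                               budget=4.0)
        verdict = extension_yields(sc)
        assert verdict.yield_B == pytest.approx(
            expected_complete_mechanisms(4, 0.3, 2))
        assert verdict.favoured == "A"

    def test_boundary_scenario_is_equivalent_with_continuous_n(self):
        # place v_B exactly on the equivalence locus and check the tie
        v, c, p_a, p_b, n = 0.27, 2.0, 4.0, 1.0, 4
        v_b = v * equivalence_hit_ratio(p_b, p_a, c)
        sc = ExtensionScenario(n=n, base_hit_rate=v, augmented_hit_rate=v_b,
                               complexity=c, price_A=p_a, price_B=p_b,
                               budget=n * p_b)
        verdict = extension_yields(sc, continuous_n=True)
        assert verdict.yield_A == pytest.approx(verdict.yield_B, rel=1e-12)
        assert verdict.favoured == "equivalent"

    def test_unaffordable_strategy_b_is_flagged(self):
        sc = ExtensionScenario(n=10, base_hit_rate=0.2,
                               augmented_hit_rate=0.5, complexity=2,
                               price_A=1.0, price_B=5.0, budget=3.0)
        verdict = extension_yields(sc)
        assert verdict.favoured == "infeasible"
        assert "infeasible" in verdict.feasibility_notes

    @given(n=st.integers(min_value=1, max_value=50),
           v=st.floats(min_value=0.05, max_value=0.5),
           c=complexities, p_a=prices, p_b=prices)
    @settings(max_examples=100)
    def test_verdict_independent_of_sample_size_on_boundary(self, n, v, c,
                                                            p_a, p_b):
        v_b = v * equivalence_hit_ratio(p_b, p_a, c)
        if v_b > 1.0:
            return  # infeasible corner: no assay can reach the tie
        sc = ExtensionScenario(n=n, base_hit_rate=v, augmented_hit_rate=v_b,
                               complexity=c, price_A=p_a, price_B=p_b,
                               budget=n * p_b)
        assert extension_yields(sc, continuous_n=True).favoured == "equivalent"


@pytest.mark.parametrize("v, v_b, c, expected", [
    (0.27, 0.27, 5, 1.0),
    (0.27, 0.39, 2, (0.39 / 0.27) ** 2),
    (0.2, 0.4, 3, 8.0),
])
def test_extension_sample_ratio(v, v_b, c, expected):
    assert extension_sample_ratio(v, v_b, c) == pytest.approx(expected)


class TestBreakeven:
    def test_equivalence_hit_ratio_values(self):
        assert equivalence_hit_ratio(1e-12, 1.0, 2) == pytest.approx(1.0)
        assert equivalence_hit_ratio(1.0, 4.0, 2) == pytest.approx(
            1.25 ** 0.5)
        assert equivalence_hit_ratio(1.0, 1.0, 1) == pytest.approx(2.0)

    def test_equivalence_ratio_decreasing_in_c_with_unit_limit(self):
        ratios = [equivalence_hit_ratio(1.0, 4.0, c)
                  for c in (1, 2, 4, 50, 1000)]
        assert ratios == sorted(ratios, reverse=True)
        assert ratios[-1] == pytest.approx(1.0, abs=1e-3)
        assert equivalence_hit_ratio(1.0, 4.0, math.inf) == 1.0

    def test_min_extra_hit_rate_example(self):
        bk = min_extra_hit_rate(0.27, 1.0, 4.0, 2)
        assert round(bk.value, 3) == 0.032
        assert bk.feasible

    def test_min_extra_hit_rate_free_assay_is_zero(self):
        assert min_extra_hit_rate(0.4, 1e-15, 1.0, 3).value == pytest.approx(
            0.0, abs=1e-12)

    def test_min_extra_hit_rate_flags_impossible_increment(self):
        bk = min_extra_hit_rate(0.5, 3.0, 1.0, 1)
        assert bk.value == pytest.approx(1.5)
        assert not bk.feasible

    def test_required_base_hit_rate_example_is_impossible(self):
        bk = required_base_hit_rate(0.12, 1.0, 4.0, 2)
        assert round(bk.value, 2) == 1.02
        assert not bk.feasible

    def test_required_base_hit_rate_zero_delta(self):
        bk = required_base_hit_rate(0.0, 2.0, 3.0, 2)
        assert bk.value == 0.0 and bk.feasible

    @given(v=st.floats(min_value=1e-3, max_value=1.0), p_a=prices,
           p_b=prices, c=complexities)
    @settings(max_examples=200)
    def test_breakeven_round_trip(self, v, p_a, p_b, c):
        delta = min_extra_hit_rate(v, p_b, p_a, c).value
        back = required_base_hit_rate(delta, p_b, p_a, c).value
        assert back == pytest.approx(v, rel=1e-12)


class TestPartition:
    def test_example_point_favours_reassaying(self):
        grid = partition_parameter_space((0.2, 0.3), (1.4, 1.5), [2],
                                         resolution=11)
        # P_B/P_A = 0.25, v_B/v = 0.39/0.27 ~ 1.444
        j = int(abs(grid.price_ratios - 0.25).argmin())
        i = int(abs(grid.hit_ratios - 0.39 / 0.27).argmin())
        assert grid.labels[2][i, j] == "B"

    def test_unit_hit_ratio_favours_new_cases(self):
        grid = partition_parameter_space((0.5, 2.0), (0.999999, 1.000001),
                                         [2], resolution=3)
        assert (grid.labels[2][1] == "A").all()

    def test_sub_unit_hit_ratio_is_infeasible(self):
        grid = partition_parameter_space((0.5, 2.0), (0.2, 0.8), [1, 2],
                                         resolution=4)
        for lab in grid.labels.values():
            assert (lab == "infeasible").all()

    def test_infinite_complexity_boundary_is_one(self):
        grid = partition_parameter_space((0.1, 3.0), (0.9, 2.0), [math.inf],
                                         resolution=9)
        assert grid.boundary_curves[math.inf] == pytest.approx(1.0)

    def test_labels_agree_with_direct_yield_comparison(self):
        """Brute-force oracle: at every cell, rebuild the equal-budget
        scenario from the ratios and compare the two yields directly."""
        grid = partition_parameter_space((0.05, 3.0), (1.0, 2.5), [1, 2, 4],
                                         resolution=17)
        n, v = 10, 0.3
        for c in (1, 2, 4):
            for i, r in enumerate(grid.hit_ratios):
                for j, p in enumerate(grid.price_ratios):
                    v_b = v * r
                    if v_b > 1.0:
                        continue
                    n_a = n * (1.0 + p)  # equal budget, continuous n_A
                    yield_a = n_a * v ** c
                    yield_b = n * v_b ** c
                    label = grid.labels[c][i, j]
                    if abs(yield_a - yield_b) <= 1e-9 * max(yield_a, yield_b):
                        assert label == "equivalent"
                    elif yield_a > yield_b:
                        assert label == "A", (c, r, p)
                    else:
                        assert label == "B", (c, r, p)

    def test_invalid_ranges_rejected(self):
        with pytest.raises(InvalidParameterError):
            partition_parameter_space((2.0, 1.0), (1.0, 2.0), [2])
        with pytest.raises(InvalidParameterError):
            partition_parameter_space((0.5, 2.0), (1.0, 2.0), [2],
                                      resolution=1)
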