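"""Support statistic and weighted-average aggregation."""

from __future__ import annotations

import itertools
import random

import pytest
from hypothesis import given, strategies as st

from tomspace import (
    AssociationKind,
    AssociationTable,
    ConfigurationError,
    ModuleDefinition,
    ModuleRole,
    TargetSpace,
    compare_formula_to_modules,
    round2,
    support,
    weighted_average,
)


def space(genes, owner="X", kind="drug_module"):
    return TargetSpace(owner_id=owner, owner_kind=kind, genes=frozenset(genes))


def brute_force_support(x: set, y: set) -> float:
    """Independent oracle: double loop over explicit membership tests."""
    overlap = 0
    for gx in x:
        for gy in y:
            if gx == gy:
                overlap += 1
                break
    return overlap / len(x)


class TestSupport:
    def test_half_overlap(self):
        r = support(space({"A", "B", "C", "D"}), space({"A", "B"}, "F1", "formula"))
        assert r.support == 0.5
        assert r.overlap_genes == ("A", "B")
        assert (r.drug_space_size, r.formula_space_size) == (4, 2)

    def test_identical_spaces(self):
        r = support(space({"A", "B"}), space({"A", "B"}, "F1", "formula"))
        assert r.support == 1.0

    def test_disjoint_spaces(self):
        r = support(space({"A"}), space({"B"}, "F1", "formula"))
        assert r.support == 0.0 and r.overlap_genes == ()

    def test_empty_drug_space_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            support(space(set()), space({"A"}, "F1", "formula"))

    def test_overlap_sorted_and_subset_of_both(self):
        x, y = {"C", "B", "A", "Z"}, {"B", "Z", "Q"}
        r = support(space(x), space(y, "F1", "formula"))
        assert list(r.overlap_genes) == sorted(r.overlap_genes)
        assert set(r.overlap_genes) <= x and set(r.overlap_genes) <= y

    def test_matches_brute_force_on_random_pairs(self):
        universe = [f"g{i}" for i in range(20)]
        rng = random.Random(42)
        for _ in range(200):
            x = set(rng.sample(universe, rng.randint(1, 20)))
            y = set(rng.sample(universe, rng.randint(0, 20)))
            r = support(space(x), space(y, "F", "formula"))
            assert r.support == brute_force_support(x, y)

    def test_adding_overlap_gene_strictly_increases_support(self):
        x = {"A", "B", "C", "D"}
        r1 = support(space(x), space({"A"}, "F", "formula"))
        r2 = support(space(x), space({"A", "B"}, "F", "formula"))
        assert r2.support > r1.support


class TestWeightedAverage:
    @pytest.mark.parametrize(
        "main,sides,expected",
        [
            (0.63, [0.44, 0.66, 0.5, 0.69], 0.60),   # printed Anxiety column F1
            (0.84, [0.44, 0.43, 0.70, 0.72, 0.69, 0.62], 0.72),  # Epilepsy F1 headline
            (0.32, [0.31, 0.22, 0.25, 0.13, 0.16, 0.17], 0.26),  # Epilepsy F6
        ],
    )
    def test_reproduces_printed_support_rows(self, main, sides, expected):
        ws = weighted_average(main, sides)
        assert round2(ws.weighted_average) == expected

    def test_weights_sum_to_one(self):
        ws = weighted_average(0.5, [0.1, 0.2, 0.3])
        assert abs(sum(ws.weights) - 1.0) < 1e-12
        assert ws.weights[0] == 0.5

    def test_no_side_modules_returns_main(self):
        ws = weighted_average(0.37, [])
        assert ws.weighted_average == 0.37 and ws.weights == [1.0]

    @given(st.floats(0, 1), st.lists(st.floats(0, 1), max_size=8),
           st.floats(0, 1))
    def test_convexity_bounds(self, main, sides, w):
        ws = weighted_average(main, sides, main_weight=w)
        lo, hi = min([main] + sides), max([main] + sides)
        assert lo - 1e-12 <= ws.weighted_average <= hi + 1e-12

    @given(st.floats(0, 1), st.lists(st.floats(0, 1), min_size=1, max_size=6), st.randoms())
    def test_permutation_invariance_of_sides(self, main, sides, rnd):
        shuffled = sides[:]
        rnd.shuffle(shuffled)
        assert weighted_average(main, shuffled).weighted_average == pytest.approx(
            weighted_average(main, sides).weighted_average, abs=1e-12
        )

    @given(st.floats(0, 1), st.integers(0, 6))
    def test_equal_supports_are_a_fixed_point(self, s, m):
        assert weighted_average(s, [s] * m).weighted_average == pytest.approx(s, abs=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=7))
    def test_equals_arithmetic_mean_at_uniform_weight(self, supports):
        main, sides = supports[0], supports[1:]
        ws = weighted_average(main, sides, main_weight=1 / len(supports))
        assert ws.weighted_average == pytest.approx(sum(supports) / len(supports), abs=1e-9)

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_out_of_range_support_rejected(self, bad):
        with pytest.raises(ValueError):
            weighted_average(bad, [0.5])
        with pytest.raises(ValueError):
            weighted_average(0.5, [bad])

    def test_out_of_range_main_weight_rejected(self):
        with pytest.raises(ValueError):
            weighted_average(0.5, [0.5], main_weight=1.5)


def _module_pair(mid, role, genes):
    mod = ModuleDefinition(mid, mid, role, [f"{mid}_d"])
    return mod, space(genes, owner=mid)


class TestCompareFormulaToModules:
    def test_single_main_module(self):
        formula = space({"A", "B"}, "F1", "formula")
        modules = [_module_pair("M1", ModuleRole.MAIN, {"A", "B", "C", "D"})]
        results, score = compare_formula_to_modules(formula, modules)
        assert len(results) == 1
        assert score.weighted_average == results[0].support == 0.5

    def test_exact_ratios_and_side_order(self):
        formula = space({f"g{i}" for i in range(10)}, "F1", "formula")
        modules = [
            _module_pair("M1", ModuleRole.MAIN, {"g0", "g1", "g2", "x1"}),
            _module_pair("S1", ModuleRole.SIDE_EFFECT, {"g0", "x1", "x2"}),
            _module_pair("S2", ModuleRole.SIDE_EFFECT, {"x1", "x2"}),
        ]
        results, score = compare_formula_to_modules(formula, modules)
        assert [r.support for r in results] == [3 / 4, 1 / 3, 0.0]
        assert score.side_supports == [("S1", 1 / 3), ("S2", 0.0)]
        assert score.weighted_average == pytest.approx(0.5 * 3 / 4 + 0.25 / 3, abs=1e-12)

    @pytest.mark.parametrize("roles", [[], [ModuleRole.MAIN, ModuleRole.MAIN]])
    def test_main_module_count_enforced(self, roles):
        formula = space({"A"}, "F1", "formula")
        modules = [_module_pair(f"M{i}", r, {"A"}) for i, r in enumerate(roles)]
        modules += [_module_pair("S9", ModuleRole.SIDE_EFFECT, {"A"})]
        with pytest.raises(ConfigurationError, match="role=main"):
            compare_formula_to_modules(formula, modules)
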