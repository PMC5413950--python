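"""Graft efficiencies, Fisher exact contrasts, and the additive synergy model."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from mrsynergy import (
    ContingencyTable,
    GraftGroup,
    contingency_vs_control,
    efficiency,
    fisher_exact_two_tailed,
    fit_additive_model,
    predict_additive,
    synergy_t_test,
    table1_fixture,
)
from conftest import oracle_fisher_two_tailed


class TestEfficiency:
    def test_published_percentages(self):
        naf = GraftGroup("NAF", 56, 46, 18)
        assert efficiency(naf) == pytest.approx(39.1, abs=0.05)
        iept = GraftGroup("iEpt", 22, 18, 1)
        assert efficiency(iept) == pytest.approx(5.6, abs=0.05)

    def test_zero_positive_gives_zero(self):
        assert efficiency(GraftGroup("g", 10, 5, 0)) == 0.0

    def test_denominator_choice_and_zero_denominator(self):
        g = GraftGroup("g", 10, 5, 2)
        assert efficiency(g, "performed") == pytest.approx(20.0)
        with pytest.raises(ValueError, match="zero"):
            efficiency(GraftGroup("none", 5, 0, 0))

    def test_count_invariants_enforced(self):
        with pytest.raises(ValueError, match="positive <= grown"):
            GraftGroup("bad", 5, 3, 4)


class TestFisherExact:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((4, 6, 1, 17), 0.041),   # pair-factor group vs control
            ((18, 28, 1, 17), 0.013), # triple-factor group vs control
            ((3, 6, 1, 17), 0.093),   # single-factor group vs control
            ((2, 1, 1, 2), 1.0),
        ],
    )
    def test_reference_tables(self, table, expected):
        assert fisher_exact_two_tailed(ContingencyTable(*table)) == pytest.approx(
            expected, abs=5e-4
        )

    def test_zero_row_gives_one(self):
        assert fisher_exact_two_tailed(ContingencyTable(0, 0, 3, 7)) == 1.0

    @given(
        st.tuples(st.integers(0, 25), st.integers(0, 25),
                  st.integers(0, 25), st.integers(0, 25)).filter(lambda t: sum(t) >= 1)
    )
    def test_matches_integer_enumeration_oracle(self, table):
        mine = fisher_exact_two_tailed(ContingencyTable(*table))
        assert mine == pytest.approx(oracle_fisher_two_tailed(*table), abs=1e-10)

    @given(
        st.tuples(st.integers(0, 20), st.integers(0, 20),
                  st.integers(0, 20), st.integers(0, 20)).filter(lambda t: sum(t) >= 1)
    )
    def test_matches_scipy(self, table):
        mine = fisher_exact_two_tailed(ContingencyTable(*table))
        assert mine == pytest.approx(stats.fisher_exact(np.array(table).reshape(2, 2))[1],
                                     rel=1e-9, abs=1e-12)

    def test_transpose_and_exchange_invariance(self):
        a, b, c, d = 5, 3, 2, 9
        p = fisher_exact_two_tailed(ContingencyTable(a, b, c, d))
        assert fisher_exact_two_tailed(ContingencyTable(a, c, b, d)) == pytest.approx(p, abs=1e-12)
        assert fisher_exact_two_tailed(ContingencyTable(d, c, b, a)) == pytest.approx(p, abs=1e-12)

    def test_contrast_builder_matches_published_table(self):
        groups = {g.label: g for g in table1_fixture()}
        t = contingency_vs_control(groups["iEpt+Nkx3.1+Foxa1"], groups["iEpt"])
        assert (t.a, t.b, t.c, t.d) == (4, 6, 1, 17)


class TestAdditiveModel:
    @pytest.fixture
    def toy_groups(self):
        # control 5%, factor A 20%, factor B 10% among 100 grown each
        return [
            GraftGroup("ctrl", 100, 100, 5),
            GraftGroup("ctrl+A", 100, 100, 20),
            GraftGroup("ctrl+B", 100, 100, 10),
            GraftGroup("ctrl+A+B", 100, 100, 80),
        ]

    @pytest.fixture
    def toy_factor_map(self):
        return {
            "ctrl": frozenset(),
            "ctrl+A": frozenset({"A"}),
            "ctrl+B": frozenset({"B"}),
            "ctrl+A+B": frozenset({"A", "B"}),
        }

    def test_slopes_and_additive_prediction(self, toy_groups, toy_factor_map):
        model = fit_additive_model(toy_groups, "ctrl", toy_factor_map)
        assert model.slopes["A"] == pytest.approx(math.log(4))
        assert model.slopes["B"] == pytest.approx(math.log(2))
        assert predict_additive(model, ["A", "B"]) == pytest.approx(40.0)

    def test_empty_factor_set_predicts_control(self, toy_groups, toy_factor_map):
        model = fit_additive_model(toy_groups, "ctrl", toy_factor_map)
        assert predict_additive(model, []) == pytest.approx(5.0)

    def test_factor_at_control_level_has_zero_slope(self):
        groups = [GraftGroup("c", 100, 100, 5), GraftGroup("c+F", 100, 100, 5)]
        model = fit_additive_model(groups, "c", {"c": frozenset(), "c+F": frozenset({"F"})})
        assert model.slopes["F"] == pytest.approx(0.0)
        assert predict_additive(model, ["F"]) == pytest.approx(5.0)

    def test_zero_efficiency_floored_with_flag(self):
        groups = [GraftGroup("c", 50, 50, 5), GraftGroup("c+F", 50, 40, 0)]
        model = fit_additive_model(groups, "c", {"c": frozenset(), "c+F": frozenset({"F"})})
        assert np.isfinite(model.slopes["F"]) and model.slopes["F"] < 0
        assert model.floor["c+F"] == pytest.approx(100 * 0.5 / 40)

    def test_pair_base_prediction_clause_ii(self, toy_groups, toy_factor_map):
        groups = toy_groups + [GraftGroup("ctrl+C", 100, 100, 10)]
        factor_map = {**toy_factor_map, "ctrl+C": frozenset({"C"})}
        model = fit_additive_model(groups, "ctrl", factor_map)
        pred = predict_additive(model, ["C"], base_group="ctrl+A+B")
        assert pred == pytest.approx(100.0)  # 80% * 2, capped at 100
        pred2 = predict_additive(model, ["B"], base_group="ctrl+A")
        assert pred2 == pytest.approx(40.0)

    def test_prediction_monotone_in_slopes(self, toy_groups, toy_factor_map):
        model = fit_additive_model(toy_groups, "ctrl", toy_factor_map)
        assert (
            predict_additive(model, [])
            < predict_additive(model, ["B"])
            < predict_additive(model, ["A"])
            < predict_additive(model, ["A", "B"])
        )

    def test_missing_slope_is_error(self, toy_groups, toy_factor_map):
        model = fit_additive_model(toy_groups, "ctrl", toy_factor_map)
        with pytest.raises(ValueError, match="no fitted slope"):
            predict_additive(model, ["Z"])

    def test_missing_control_is_error(self, toy_groups, toy_factor_map):
        with pytest.raises(ValueError, match="control"):
            fit_additive_model(toy_groups, "nope", toy_factor_map)


class TestSynergyTTest:
    def test_hand_computed_example(self):
        # log-excesses {1.0, 1.1, 0.9}: mean 1.0, sd 0.1, t = 1.0/(0.1/sqrt(3))
        observed = [100 * math.exp(e) for e in (1.0, 1.1, 0.9)]
        res = synergy_t_test(observed, predicted=100.0)
        assert res.t_stat == pytest.approx(17.32, abs=0.01)
        assert res.df == 2
        assert res.p_one_tailed == pytest.approx(0.0017, abs=2e-4)

    def test_observed_equal_to_predicted(self):
        res = synergy_t_test([40.0, 40.0, 40.0], predicted=40.0)
        assert res.t_stat == 0.0 and res.p_one_tailed == 0.5

    def test_observed_below_predicted_no_synergy(self):
        res = synergy_t_test([10.0, 12.0, 9.0], predicted=40.0)
        assert res.p_one_tailed > 0.5

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="replicate"):
            synergy_t_test([40.0], predicted=20.0)
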