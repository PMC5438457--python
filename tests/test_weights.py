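"""Weighting stack: poststratification, R and A factors, Kish diagnostics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mpssim.population import ReferenceDistribution
from mpssim.weights import (SelectionScenario, WeightSet, cv_of_weights,
                            design_effect, design_effect_sum_form,
                            effective_sample_size, multiphone_adjustment,
                            nonresponse_adjustment, poststratification_weights,
                            relative_probability, selection_probability,
                            trim_weights, weighted_estimate)

REF = ReferenceDistribution(("g",), {("A",): 0.6, ("B",): 0.4})

positive_weights = st.lists(
    st.floats(min_value=0.01, max_value=100.0, allow_nan=False), min_size=1,
    max_size=50)


class TestPoststratification:
    def test_ratio_formula(self):
        strata = [("A",)] * 50 + [("B",)] * 50
        ws = poststratification_weights(strata, REF)
        assert ws.weights[0] == pytest.approx(1.2)
        assert ws.weights[-1] == pytest.approx(0.8)

    def test_identity_when_sample_matches_reference(self):
        strata = [("A",)] * 60 + [("B",)] * 40
        ws = poststratification_weights(strata, REF)
        np.testing.assert_allclose(ws.weights, 1.0)

    def test_weighted_shares_equal_reference(self):
        strata = [("A",)] * 17 + [("B",)] * 83
        ws = poststratification_weights(strata, REF)
        w = ws.weights
        share_a = w[:17].sum() / w.sum()
        assert abs(share_a - 0.6) < 1e-12
        assert abs(w[17:].sum() / w.sum() - 0.4) < 1e-12

    def test_unknown_stratum_rejected(self):
        with pytest.raises(KeyError):
            poststratification_weights([("C",)], REF)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            poststratification_weights([], REF)


class TestNonresponse:
    def test_zero_rate_is_identity(self):
        ws = WeightSet.flat([("A",)] * 5)
        out = nonresponse_adjustment(ws, {("A",): 0.0})
        np.testing.assert_allclose(out.weights, 1.0)

    def test_closed_form_rates(self):
        ws = WeightSet.flat([("A",), ("B",)])
        out = nonresponse_adjustment(ws, {("A",): 0.5, ("B",): 0.9})
        assert out.weights[0] == pytest.approx(2.0)
        assert out.weights[1] == pytest.approx(10.0)

    def test_factor_matches_simulated_response_rate(self):
        # group of 200 responding with probability 0.5: R estimated as the
        # inverse realized response rate should land near 2
        rng = np.random.default_rng(12)
        responded = rng.random(200) < 0.5
        f_hat = 1.0 - responded.mean()
        ws = WeightSet.flat([("A",)])
        out = nonresponse_adjustment(ws, {("A",): f_hat})
        se_f = np.sqrt(0.25 / 200)
        upper = 1.0 / (1.0 - (0.5 + 3 * se_f))
        lower = 1.0 / (1.0 - (0.5 - 3 * se_f))
        assert lower <= out.weights[0] <= upper

    def test_full_nonresponse_rejected(self):
        ws = WeightSet.flat([("A",)])
        with pytest.raises(ValueError):
            nonresponse_adjustment(ws, {("A",): 1.0})


class TestMultiphone:
    def test_inverse_phone_count(self):
        ws = WeightSet.flat([("A",)] * 3)
        out = multiphone_adjustment(ws, [1, 2, 4])
        np.testing.assert_allclose(out.weights, [1.0, 0.5, 0.25])

    def test_zero_phones_rejected(self):
        with pytest.raises(ValueError):
            multiphone_adjustment(WeightSet.flat([("A",)]), [0])

    def test_equalizes_contact_advantage(self):
        # three-phone owners contacted three times as often; 1/T restores
        # equal per-person effective contribution
        rng = np.random.default_rng(3)
        t = np.where(rng.random(3000) < 0.1, 3, 1)
        contacts = rng.binomial(10_000, t / t.sum())
        contribution = contacts / t
        m3 = contribution[t == 3].mean()
        m1 = contribution[t == 1].mean()
        se = np.sqrt(contribution[t == 3].var(ddof=1) / (t == 3).sum()
                     + contribution[t == 1].var(ddof=1) / (t == 1).sum())
        assert abs(m3 - m1) <= 3 * se


class TestSelectionProbability:
    @pytest.mark.parametrize("np_, nt, expected", [
        (1, 100_000_000, 1.00e-8),
        (3, 120_000_000, 2.5e-8),
        (1, 200_000_000, 5e-9),
    ])
    def test_published_scenarios(self, np_, nt, expected):
        p = selection_probability(SelectionScenario(1, np_, nt))
        assert p == pytest.approx(expected)

    def test_scales_with_sample_size(self):
        s1 = selection_probability(SelectionScenario(1, 1, 10**6))
        s500 = selection_probability(SelectionScenario(500, 1, 10**6))
        assert s500 == pytest.approx(500 * s1)

    def test_relative_probability(self):
        nt = 120_000_000
        assert relative_probability(SelectionScenario(1, 3, nt),
                                    SelectionScenario(1, 1, nt)) == pytest.approx(3.0)
        assert relative_probability(SelectionScenario(1, 1, nt),
                                    SelectionScenario(1, 1, nt)) == 1.0
        assert relative_probability(SelectionScenario(1, 2, nt),
                                    SelectionScenario(1, 1, nt)) == pytest.approx(2.0)

    def test_mismatched_populations_rejected(self):
        with pytest.raises(ValueError):
            relative_probability(SelectionScenario(1, 1, 100),
                                 SelectionScenario(1, 1, 200))

    def test_invalid_scenarios_rejected(self):
        with pytest.raises(ValueError):
            SelectionScenario(0, 1, 100)
        with pytest.raises(ValueError):
            SelectionScenario(1, 3, 2)


class TestKishDiagnostics:
    def test_equal_weights_cv_zero_deff_one(self):
        w = np.full(10, 2.5)
        assert cv_of_weights(w) == 0.0
        assert design_effect(w) == 1.0
        assert effective_sample_size(w) == 10.0

    def test_hand_computed_cv(self):
        assert cv_of_weights(np.array([1.0, 3.0])) == pytest.approx(0.5)

    def test_hand_computed_deff_both_forms(self):
        w = np.array([1.0, 1.0, 1.0, 3.0])
        assert design_effect(w) == pytest.approx(4 / 3)
        assert design_effect_sum_form(w) == pytest.approx(4 / 3)
        assert effective_sample_size(w) == pytest.approx(3.0)

    @given(positive_weights)
    def test_kish_identity(self, ws):
        w = np.array(ws)
        assert abs(design_effect(w) - design_effect_sum_form(w)) < 1e-12

    @given(positive_weights, st.floats(min_value=0.01, max_value=100))
    def test_scale_invariance(self, ws, c):
        w = np.array(ws)
        assert cv_of_weights(c * w) == pytest.approx(cv_of_weights(w), abs=1e-10)

    @given(positive_weights)
    def test_deff_at_least_one(self, ws):
        assert design_effect(np.array(ws)) >= 1.0


class TestTrimming:
    def test_containing_bounds_change_nothing(self):
        ws = WeightSet.flat([("A",)] * 4)
        out = trim_weights(ws, 0.5, 2.0)
        np.testing.assert_allclose(out.weights, ws.weights)

    def test_hand_computed_trim(self):
        ws = nonresponse_adjustment(
            WeightSet.flat([("A",), ("A",), ("B",)]),
            {("A",): 0.0, ("B",): 0.9})
        # weights {1, 1, 10}: clip at 2 -> {1, 1, 2}, rescale by 12/4 = 3
        out = trim_weights(ws, 0.1, 2.0)
        np.testing.assert_allclose(out.weights, [3.0, 3.0, 6.0])
        assert out.weights.sum() == pytest.approx(ws.weights.sum())
        assert cv_of_weights(out) < cv_of_weights(ws)

    @given(positive_weights, st.floats(0.2, 1.0), st.floats(1.0, 5.0))
    def test_cv_never_increases(self, ws, lo, hi):
        ones = np.ones(len(ws))
        base = WeightSet(tuple([("A",)] * len(ws)), np.array(ws),
                         ones.copy(), ones.copy(), ones.copy(), ones.copy())
        out = trim_weights(base, lo, hi)
        assert cv_of_weights(out) <= cv_of_weights(base) + 1e-12
        assert out.weights.sum() == pytest.approx(base.weights.sum())

    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError):
            trim_weights(WeightSet.flat([("A",)]), 2.0, 1.0)


class TestWeightedEstimate:
    def test_equal_weights_is_plain_mean(self):
        ws = WeightSet.flat([("A",)] * 4)
        y = [1.0, 0.0, 1.0, 1.0]
        est = weighted_estimate(y, ws)
        assert est.estimate == pytest.approx(0.75)
        assert est.variance == pytest.approx(np.var(y) / 4)

    def test_poststratification_restores_population_mix(self):
        # stratum A all 1s, B all 0s: weighted mean must hit the reference
        # share of A regardless of the sample split
        strata = [("A",)] * 30 + [("B",)] * 70
        y = [1.0] * 30 + [0.0] * 70
        ws = poststratification_weights(strata, REF)
        assert weighted_estimate(y, ws).estimate == pytest.approx(0.6)

    def test_matches_statsmodels_weighted_mean(self):
        from statsmodels.stats.weightstats import DescrStatsW

        rng = np.random.default_rng(8)
        y = rng.random(40)
        ws = multiphone_adjustment(WeightSet.flat([("A",)] * 40),
                                   rng.integers(1, 4, size=40))
        ours = weighted_estimate(y, ws).estimate
        theirs = DescrStatsW(y, weights=ws.weights).mean
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_estimate([1.0], WeightSet.flat([("A",)] * 2))


class TestWeightSetContainer:
    def test_factors_compose_multiplicatively(self):
        ws = poststratification_weights([("A",), ("B",)], REF)
        ws = nonresponse_adjustment(ws, {("A",): 0.5, ("B",): 0.0})
        ws = multiphone_adjustment(ws, [2, 1])
        expected = np.array([1.2 * 2.0 * 0.5, 0.8 * 1.0 * 1.0])
        np.testing.assert_allclose(ws.weights, expected)

    def test_normalized_mean_one_same_diagnostics(self):
        ws = multiphone_adjustment(WeightSet.flat([("A",)] * 5), [1, 2, 3, 1, 2])
        norm = ws.normalized()
        assert norm.weights.mean() == pytest.approx(1.0)
        assert norm.deff == pytest.approx(ws.deff)

    def test_csv_export_columns(self, tmp_path):
        ws = WeightSet.flat([("A",), ("B",)])
        path = tmp_path / "w.csv"
        ws.to_csv(path)
        header = path.read_text().splitlines()[0].split(",")
        for col in ("respondent_id", "stratum", "poststrat", "nonresponse",
                    "multiphone", "final_weight"):
            assert col in header

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError):
            WeightSet(( ("A",), ), np.array([0.0]), np.ones(1), np.ones(1),
                      np.ones(1), np.ones(1))
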