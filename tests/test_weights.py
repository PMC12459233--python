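import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swtime import Design, TreatmentStructure
from swtime.weights import (
    WeightError,
    expected_estimate,
    numerical_weights,
    w1_closed_form,
    w2_closed_form,
    w3_small_design_closed_form,
    w4_small_design_closed_form,
    weight_table,
)

GAMMAS = [0.0, 0.2, 0.5, 0.69, 0.9]


def _standard(Q, per_seq=1):
    return Design(I=per_seq * Q, J=Q + 1, K=1)


class TestClosedForms:
    @pytest.mark.parametrize("Q", [2, 4, 7, 9])
    def test_w1_gamma_zero_reduction(self, Q):
        s = np.arange(1, Q + 1)
        reduced = 6 * (s - Q - 1) * (s - Q) / (Q * (Q + 1) * (2 * Q - 2))
        assert np.allclose(w1_closed_form(Q, 0.0, s), reduced, atol=1e-14)
        assert np.all(reduced >= 0)

    @pytest.mark.parametrize("Q", [2, 3, 5, 9, 11])
    @pytest.mark.parametrize("g", GAMMAS)
    def test_w1_sums_to_one(self, Q, g):
        assert np.sum(w1_closed_form(Q, g, np.arange(1, Q + 1))) == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("Q", [2, 3, 5, 9, 11])
    def test_w2_nonnegative_and_sums_to_one(self, Q):
        w = w2_closed_form(Q, np.arange(2, Q + 1))
        assert np.all(w >= 0)
        assert np.sum(w) == pytest.approx(1.0, abs=1e-12)

    def test_w2_three_sequence_design_is_uniform(self):
        """In the 3-sequence, 4-period trial both calendar weights equal 1/2."""
        assert w2_closed_form(3, 2) == pytest.approx(0.5, abs=1e-14)
        assert w2_closed_form(3, 3) == pytest.approx(0.5, abs=1e-14)

    @pytest.mark.parametrize("g", GAMMAS)
    def test_small_design_forms_sum_to_one(self, g):
        assert sum(w3_small_design_closed_form(g)) == pytest.approx(1.0, abs=1e-12)
        assert sum(w4_small_design_closed_form(g)) == pytest.approx(1.0, abs=1e-12)

    def test_small_design_gamma_zero_values(self):
        w3 = w3_small_design_closed_form(0.0)
        assert w3[0] == pytest.approx(6 / 13, abs=1e-14)
        assert w3[1] == pytest.approx(7 / 13, abs=1e-14)
        w4 = w4_small_design_closed_form(0.0)
        assert w4 == (pytest.approx(0.75, abs=1e-14), pytest.approx(0.25, abs=1e-14))

    def test_domain_errors(self):
        with pytest.raises(WeightError):
            w1_closed_form(1, 0.0, 1)
        with pytest.raises(WeightError):
            w1_closed_form(4, 0.0, 5)
        with pytest.raises(WeightError):
            w2_closed_form(4, 1)
        with pytest.raises(WeightError):
            w3_small_design_closed_form(1.0)


class TestNumericalEngine:
    @pytest.mark.parametrize("Q", [2, 3, 6, 9])
    @pytest.mark.parametrize("g", GAMMAS)
    def test_matches_w1(self, Q, g):
        ew = numerical_weights(_standard(Q), g, "IT", "ETI")
        assert np.allclose(ew.weights, w1_closed_form(Q, g, np.arange(1, Q + 1)), atol=1e-8)

    @pytest.mark.parametrize("Q", [3, 6, 9])
    def test_matches_w2_and_gamma_invariant(self, Q):
        base = numerical_weights(_standard(Q), 0.0, "IT", "CTI").weights
        assert np.allclose(base, w2_closed_form(Q, np.arange(2, Q + 1)), atol=1e-8)
        for g in (0.3, 0.69, 0.95):
            w = numerical_weights(_standard(Q), g, "IT", "CTI").weights
            assert np.allclose(w, base, atol=1e-8)

    @pytest.mark.parametrize("g", GAMMAS)
    def test_matches_w3_small_design(self, g):
        ew = numerical_weights(Design(I=3, J=4, K=1), g, "ETI", "CTI")
        assert np.allclose(ew.weights, w3_small_design_closed_form(g), atol=1e-8)

    @pytest.mark.parametrize("g", GAMMAS)
    def test_matches_w4_small_design(self, g):
        d = Design(I=3, J=3, K=1, Q=3, truncated=True)
        ew = numerical_weights(d, g, "CTI", "ETI")
        assert np.allclose(ew.weights, w4_small_design_closed_form(g), atol=1e-8)

    @pytest.mark.parametrize("kind, n", [("ETI", 9), ("CTI", 8)])
    def test_correct_specification_is_uniform(self, kind, n):
        ew = numerical_weights(_standard(9), 0.69, kind, kind)
        assert np.allclose(ew.weights, np.full(n, 1 / n), atol=1e-10)

    def test_cluster_and_sequence_level_agree(self):
        """Replicating clusters within sequences leaves the weights unchanged and
        splits each sequence's cell weight equally across its clusters."""
        for g in (0.0, 0.69):
            one = numerical_weights(_standard(5, per_seq=1), g, "ETI", "CTI")
            three = numerical_weights(_standard(5, per_seq=3), g, "ETI", "CTI")
            assert np.allclose(one.weights, three.weights, atol=1e-10)
            lam = three.lambda_cells.reshape(5, 3, 6)
            assert np.allclose(lam, lam[:, :1, :], atol=1e-10)
            assert np.allclose(three.lambda_sequence_cells, one.lambda_cells, atol=1e-10)

    @given(Q=st.integers(2, 8), g=st.floats(0.0, 0.95))
    @settings(deadline=None, max_examples=30)
    def test_all_weight_families_sum_to_one(self, Q, g):
        d = _standard(Q)
        for fitted in ("IT", "ETI", "CTI"):
            for true in ("ETI", "CTI"):
                ew = numerical_weights(d, g, fitted, true)
                assert np.sum(ew.weights) == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("fitted, true", [("IT", "ETI"), ("ETI", "CTI"), ("CTI", "ETI")])
    def test_gamma_dependence_of_misspecified_weights(self, fitted, true):
        """Away from the IT-under-CTI case, weights move with gamma (Q >= 3)."""
        d = _standard(5)
        w0 = numerical_weights(d, 0.0, fitted, true).weights
        w9 = numerical_weights(d, 0.9, fitted, true).weights
        assert np.max(np.abs(w0 - w9)) > 1e-3


class TestExpectedEstimate:
    def test_constant_curve_recovered(self):
        ew = numerical_weights(_standard(9), 0.69, "IT", "ETI")
        const = TreatmentStructure("ETI", np.full(9, 4.2))
        assert expected_estimate(ew, const) == pytest.approx(4.2, abs=1e-8)

    def test_delayed_effect_curve_turns_negative(self, eti_curve):
        """A nonnegative, delayed exposure-time effect curve drives the
        misspecified IT expectation below zero at high gamma."""
        ew = numerical_weights(_standard(9), 0.69, "IT", "ETI")
        value = expected_estimate(ew, eti_curve)
        assert value < 0
        # cross-check through the printed closed form
        closed = float(np.sum(w1_closed_form(9, 0.69, np.arange(1, 10)) * eti_curve.effects))
        assert value == pytest.approx(closed, abs=1e-8)

    def test_correct_specification_returns_truth(self, eti_curve):
        from swtime import estimand_truth

        d = Design(I=9, J=10, K=1)
        ew = numerical_weights(d, 0.69, "ETI", "ETI")
        assert expected_estimate(ew, eti_curve) == pytest.approx(
            estimand_truth(eti_curve, d), abs=1e-10
        )

    def test_mismatches_rejected(self, eti_curve):
        ew = numerical_weights(_standard(9), 0.69, "IT", "CTI")
        with pytest.raises(WeightError):
            expected_estimate(ew, eti_curve)
        with pytest.raises(WeightError):
            expected_estimate(
                numerical_weights(_standard(4), 0.0, "IT", "ETI"), eti_curve
            )


class TestWeightTable:
    def test_table_layout(self):
        t = weight_table(_standard(4), [0.0, 0.5], "IT", "ETI")
        assert len(t) == 8
        assert set(t.columns) == {"fitted_kind", "true_kind", "Q", "gamma", "index", "weight"}
        sums = t.groupby("gamma")["weight"].sum()
        assert np.allclose(sums, 1.0, atol=1e-8)
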