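"""Cost-benefit and metabolic forms: closed-form optima and perturbation costs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exprsel.core_forms import (
    CostBenefitParams,
    compare_forms,
    metabolic_form,
    metabolic_optimum,
    net_benefit,
    optimum_cost_benefit,
    reference_costs,
    selection_exact,
    selection_quadratic,
)


def log_uniform(lo, hi):
    return st.floats(math.log(lo), math.log(hi)).map(math.exp)


class TestNetBenefit:
    @pytest.mark.parametrize(
        "f,K,P,expected",
        [
            (1.0, 0.01, 0.0, 0.0),  # no expression, no benefit, no cost
            (1.0, 0.01, 0.09, 0.81),  # 0.09/0.1 - 0.09
            (0.5, 0.1, 0.2, 0.5 * 0.2 / 0.3 - 0.2),
        ],
    )
    def test_values(self, f, K, P, expected):
        assert net_benefit(P, CostBenefitParams(f=f, K=K)) == pytest.approx(expected)

    def test_at_optimum_matches_grid_maximum(self):
        # nonessential protein, f = 0.2, half-max cost K = 5e-4
        params = CostBenefitParams(f=0.2, K=5e-4)
        grid = np.linspace(1e-7, 0.1, 10**6)
        vals = params.f * grid / (params.K + grid) - grid
        P_opt, s_opt = optimum_cost_benefit(params)
        assert s_opt == pytest.approx(vals.max(), rel=1e-9)
        # (sqrt(f)-sqrt(K))^2 = f + K - 2*sqrt(f*K) = 0.2005 - 0.02 exactly
        assert s_opt == pytest.approx(0.1805, rel=1e-12)
        assert net_benefit(P_opt, params) == pytest.approx(s_opt, rel=1e-12)

    def test_rejects_invalid_expression(self):
        params = CostBenefitParams(f=1.0, K=0.01)
        for P in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError):
                net_benefit(P, params)


class TestOptimum:
    def test_essential_protein_one_copy_per_cell(self):
        # f=1 with K at the one-copy-per-cell floor puts the optimum at ~4.5e-4
        P_opt, _ = optimum_cost_benefit(CostBenefitParams(f=1.0, K=2e-7))
        assert P_opt == pytest.approx(4.5e-4, rel=0.01)

    def test_closed_form_hand_values(self):
        P_opt, s_opt = optimum_cost_benefit(CostBenefitParams(f=1.0, K=0.01))
        assert P_opt == pytest.approx(0.09, rel=1e-12)
        assert s_opt == pytest.approx(0.81, rel=1e-12)

    def test_degenerate_K_equals_f_rejected(self):
        with pytest.raises(ValueError):
            CostBenefitParams(f=0.1, K=0.1)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(f=log_uniform(1e-4, 1.0), K=log_uniform(1e-7, 1e-2))
    def test_agrees_with_brute_force_grid(self, f, K):
        if K >= f / 2:
            K = f / 2.001
        params = CostBenefitParams(f=f, K=K)
        P_opt, s_opt = optimum_cost_benefit(params)
        # dense grid around the predicted optimum scale
        grid = np.linspace(0.0, min(10 * P_opt + 1e-4, 0.999), 10**6)
        step = grid[1] - grid[0]
        vals = f * grid / (K + grid) - grid
        assert abs(P_opt - grid[np.argmax(vals)]) <= step
        assert s_opt >= vals.max() - 1e-12


class TestMetabolicForm:
    def test_essential_gene_K_001_is_nine_percent(self):
        P_opt, s_opt = metabolic_optimum(0.01)
        assert P_opt == pytest.approx(0.1 / 1.1, rel=1e-12)
        assert s_opt == pytest.approx(1 / 1.21, rel=1e-12)
        # the optimum maximizes the flux expression
        grid = np.linspace(1e-6, 0.9, 200001)
        vals = grid / (0.01 + grid / (1 - grid))
        assert s_opt == pytest.approx(vals.max(), rel=1e-8)

    def test_free_enzyme_limit(self):
        P_opt, s_opt = metabolic_optimum(1e-12)
        assert P_opt < 2e-6
        assert s_opt == pytest.approx(1.0, rel=1e-5)

    def test_rejects_P_one(self):
        with pytest.raises(ValueError):
            metabolic_form(1.0, 0.01)


class TestCompareForms:
    def test_small_K_differences(self):
        dP, ds = compare_forms(0.01)
        assert 0 <= dP <= 0.02 and 0 <= ds <= 0.02
        dP6, ds6 = compare_forms(1e-6)
        assert dP6 < 1e-3 and ds6 < 1e-3
        assert compare_forms(0.0) == (0.0, 0.0)

    def test_monotone_increasing_in_K(self):
        Ks = np.logspace(-6, -1, 40)
        diffs = np.array([compare_forms(float(K)) for K in Ks])
        assert np.all(np.diff(diffs[:, 0]) > 0)
        assert np.all(np.diff(diffs[:, 1]) > 0)


class TestSelectionExact:
    def test_no_perturbation_no_cost(self):
        assert selection_exact(CostBenefitParams(f=1.0, K=1e-4), 1.0).s == pytest.approx(0.0, abs=1e-15)

    def test_halving_costs_half_P_opt(self):
        res = selection_exact(CostBenefitParams(f=1.0, K=1e-6), 0.5)
        assert res.s_over_P_opt == pytest.approx(0.50, abs=0.005)

    def test_gene_loss_equals_optimum_net_benefit(self):
        res = selection_exact(CostBenefitParams(f=1.0, K=1e-4), 0.0)
        assert res.s == pytest.approx((1 - 0.01) ** 2, rel=1e-10)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        f=log_uniform(1e-4, 1.0),
        K=log_uniform(1e-7, 1e-2),
        factor=st.floats(0.0, 5.0),
    )
    def test_nonnegative_at_optimum(self, f, K, factor):
        if K >= f / 2:
            K = f / 2.001
        res = selection_exact(CostBenefitParams(f=f, K=K), factor)
        assert res.s >= -1e-14


class TestSelectionQuadratic:
    @pytest.mark.parametrize(
        "eps,coeff",
        [
            (0.0, 0.0),
            (0.01, 0.0001 / 1.01),
            (0.25, 0.05),  # redundancy arithmetic: 0.25**2/1.25
            (-0.5, 0.5),
            (1.0, 0.5),
        ],
    )
    def test_values(self, eps, coeff):
        assert selection_quadratic(eps, 1.0) == pytest.approx(coeff, rel=1e-12, abs=1e-15)

    def test_rejects_total_loss(self):
        with pytest.raises(ValueError):
            selection_quadratic(-1.0, 0.01)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(f=log_uniform(1e-3, 1.0), K_over_f=log_uniform(1e-5, 0.05))
    @pytest.mark.parametrize("factor", [0.5, 2.0, 0.99, 1.01])
    def test_within_twofold_of_exact_when_benefit_dominates(self, factor, f, K_over_f):
        # the approximation envelope for 2-fold and 1% changes, f > 10*K
        params = CostBenefitParams(f=f, K=f * K_over_f)
        exact = selection_exact(params, factor)
        approx = selection_quadratic(factor - 1.0, exact.P_opt)
        assert approx <= 2.0 * exact.s + 1e-15
        assert approx >= exact.s / 2.0 - 1e-15


class TestReferenceCosts:
    @pytest.mark.parametrize(
        "eps,P,expected",
        [
            (1.0, 1e-4, (1e-4, 1.0)),
            (-0.5, 0.3, (0.15, 0.5)),
            (0.0, 0.1, (0.0, 0.0)),
        ],
    )
    def test_values(self, eps, P, expected):
        lin, rate_lim = reference_costs(eps, P)
        assert lin == pytest.approx(expected[0])
        assert rate_lim == pytest.approx(expected[1])
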