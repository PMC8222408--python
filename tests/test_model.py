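"""Payoffs, equilibria, preference zones and inequality trajectories."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import minimize_scalar

from veilcare.model import (
    BenefitSpec,
    CostSpec,
    DisagreementError,
    DomainError,
    InformationState,
    Mode,
    ParameterError,
    care_weight,
    classify_preferences,
    eval_benefit,
    eval_cost,
    make_dyad,
    mother_fitness,
    optimal_investment,
    scan_zone_grid,
    solve_equilibrium,
    variance_trajectory,
)

VEIL0 = InformationState(Mode.VEIL, 0.0)
NOVEIL0 = InformationState(Mode.NO_VEIL, 0.0)


def numeric_optimum(x, k, w, benefit=None, cost=None):
    """Independent derivative-free maximiser of w*b(x+y) - c(k,y)."""
    benefit = benefit or BenefitSpec()
    cost = cost or CostSpec()
    res = minimize_scalar(
        lambda y: -(w * eval_benefit(benefit, x + y) - eval_cost(cost, k, y)),
        bounds=(0.0, benefit.domain_max - x),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x)


def best_response_iteration(dyad, assignment, info, iters=50):
    """Fixed point of alternating best responses (equilibrium oracle)."""
    by_id = {o.id: o for o in dyad.offspring}
    y = {m.id: 0.0 for m in dyad.mothers}
    for _ in range(iters):
        new = {}
        for m in dyad.mothers:
            off = by_id[assignment.offspring_of(m.id)]
            if info.mode is Mode.VEIL:
                w = (1 + info.r) / 2
            else:
                w = 1.0 if off.parent_id == m.id else info.r
            new[m.id] = optimal_investment(off.x, m.k, w)
        if max(abs(new[k] - y[k]) for k in y) < 1e-12:
            return new
        y = new
    return y


class TestPayoffPrimitives:
    @pytest.mark.parametrize(
        "t, expected", [(0.0, 0.0), (1.0, 0.5), (0.4, 0.32)]
    )
    def test_benefit_values(self, t, expected):
        assert eval_benefit(BenefitSpec(), t) == pytest.approx(expected)

    def test_benefit_domain_error_names_cap(self):
        with pytest.raises(DomainError, match="1"):
            eval_benefit(BenefitSpec(), 1.5)
        with pytest.raises(DomainError):
            eval_benefit(BenefitSpec(), -0.1)

    def test_benefit_shape(self):
        grid = np.linspace(0, 1, 1000)
        vals = np.array([eval_benefit(BenefitSpec(), t) for t in grid])
        assert vals[0] == 0.0
        assert np.all(np.diff(vals) > 0), "benefit must be strictly increasing"
        assert np.all(np.diff(vals, 2) < 1e-12), "benefit must be concave"

    @pytest.mark.parametrize(
        "k, y, expected",
        [(0.75, 0.0, 0.0), (0.75, 0.2, 0.03), (1.5, 0.4, 0.24)],
    )
    def test_cost_values(self, k, y, expected):
        assert eval_cost(CostSpec(), k, y) == pytest.approx(expected)

    def test_cost_domain_errors(self):
        with pytest.raises(DomainError):
            eval_cost(CostSpec(), 0.0, 0.1)
        with pytest.raises(DomainError):
            eval_cost(CostSpec(), 1.0, -0.1)

    def test_cost_shape(self):
        ys = np.linspace(0, 1, 1000)
        vals = np.array([eval_cost(CostSpec(), 0.7, y) for y in ys])
        assert np.all(np.diff(vals) > 0)
        assert np.all(np.diff(vals, 2) > -1e-12)
        # increasing in k
        assert eval_cost(CostSpec(), 2.0, 0.3) > eval_cost(CostSpec(), 1.0, 0.3)


class TestCareWeight:
    def test_veil_r0_halves_valuation(self):
        assert care_weight(InformationState(Mode.VEIL, 0.0)) == 0.5

    def test_veil_clonal_limit(self):
        assert care_weight(InformationState(Mode.VEIL, 1.0)) == 1.0

    def test_no_veil_weights(self):
        info = InformationState(Mode.NO_VEIL, 0.3)
        assert care_weight(info, "own") == 1.0
        assert care_weight(info, "other") == pytest.approx(0.3)


class TestOptimalInvestment:
    @pytest.mark.parametrize(
        "x, k, w, expected",
        [
            (0.15, 0.75, 1.0, 0.34),
            (0.25, 1.25, 0.5, 0.125),
            (0.5, 1.0, 0.0, 0.0),
        ],
    )
    def test_known_values(self, x, k, w, expected):
        assert optimal_investment(x, k, w) == pytest.approx(expected, abs=1e-9)

    def test_zero_marginal_benefit_at_cap(self):
        # x at the domain cap leaves no room (and no incentive) to invest
        assert optimal_investment(1.0, 1.0, 1.0) == 0.0

    @given(
        x=st.floats(0.05, 0.5),
        k=st.floats(0.2, 3.0),
        w=st.floats(0.01, 1.0),
    )
    def test_matches_numeric_oracle(self, x, k, w):
        closed = optimal_investment(x, k, w)
        assert closed == pytest.approx(numeric_optimum(x, k, w), abs=1e-6)

    @given(
        x=st.floats(0.05, 0.5),
        k=st.floats(0.2, 3.0),
        w=st.floats(0.1, 1.0),
        dx=st.floats(0.01, 0.3),
        dk=st.floats(0.01, 1.0),
    )
    def test_care_according_to_need(self, x, k, w, dx, dk):
        """Effort strictly decreases in initial size and in cost steepness."""
        assert optimal_investment(x + dx, k, w) < optimal_investment(x, k, w)
        assert optimal_investment(x, k + dk, w) < optimal_investment(x, k, w)

    def test_custom_family_uses_numeric_path(self):
        b = BenefitSpec(family="custom", func=lambda t: np.sqrt(t))
        y = optimal_investment(0.2, 1.0, 1.0, benefit=b)
        assert y == pytest.approx(numeric_optimum(0.2, 1.0, 1.0, benefit=b), abs=1e-6)


class TestEquilibrium:
    def test_point_b_outcome_b2(self, point_b, veil0):
        eq = solve_equilibrium(point_b, point_b.assignments()["s2"], veil0)
        assert eq.y["m1"] == pytest.approx(0.1, abs=1e-9)
        assert eq.y["m2"] == pytest.approx(0.3, abs=1e-9)
        assert eq.t["o_hi"] == pytest.approx(0.4, abs=1e-9)
        assert eq.t["o_lo"] == pytest.approx(0.4, abs=1e-9)
        assert mother_fitness(eq) == pytest.approx((0.305, 0.275), abs=1e-6)

    def test_point_b_outcome_b1(self, point_b, veil0):
        eq = solve_equilibrium(point_b, point_b.assignments()["s1"], veil0)
        assert mother_fitness(eq) == pytest.approx((0.27198, 0.26956), abs=1e-5)

    def test_point_a_outcome_a1(self, point_a, veil0):
        eq = solve_equilibrium(point_a, point_a.assignments()["s1"], veil0)
        assert eq.y["m1"] == pytest.approx(0.14167, abs=1e-5)
        assert eq.y["m2"] == pytest.approx(0.1875, abs=1e-9)
        assert eq.t["o_lo"] == pytest.approx(0.29167, abs=1e-5)
        assert eq.t["o_hi"] == pytest.approx(0.4375, abs=1e-9)

    def test_symmetric_dyad_symmetric_outcome(self, veil0):
        d = make_dyad(1.0, 1.0, 0.2, 0.2)
        eq = solve_equilibrium(d, d.assignments()["s1"], veil0)
        y1, y2 = eq.y.values()
        t1, t2 = eq.t.values()
        assert y1 == pytest.approx(y2)
        assert t1 == pytest.approx(t2)

    def test_exchange_at_zero_relatedness_means_no_care(self):
        """With known parentage and r=0, a swapped carer invests nothing,
        leaving each mother the bare survival of her own uncared-for pup."""
        d = make_dyad(1.0, 0.8, 0.3, 0.2, parented=True, mother1_owns="hi")
        exchange = d.assignments()["s1"]  # m1 tends lo = m2's pup
        eq = solve_equilibrium(d, exchange, NOVEIL0)
        assert all(y == 0.0 for y in eq.y.values())
        assert eq.fitness["m1"] == pytest.approx(eval_benefit(d.benefit, 0.3))
        assert eq.fitness["m2"] == pytest.approx(eval_benefit(d.benefit, 0.2))

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_best_response_oracle(self, seed, veil0):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            d = make_dyad(*rng.uniform(0.2, 3.0, 2), *sorted(rng.uniform(0.05, 0.5, 2))[::-1])
            a = d.assignments()["s1"]
            eq = solve_equilibrium(d, a, veil0)
            oracle = best_response_iteration(d, a, veil0)
            for mid in eq.y:
                assert eq.y[mid] == pytest.approx(oracle[mid], abs=1e-6)


class TestClassification:
    def test_point_a_is_disagreement(self, point_a, veil0):
        assert classify_preferences(point_a, veil0).label == "disagreement"

    def test_point_b_agreement_on_need_based_care(self, point_b, veil0):
        cls = classify_preferences(point_b, veil0)
        assert cls.label == "agreement_s2"
        # in s2 the better-condition mother (m2, k=0.5) tends the smaller pup
        eq = cls.equilibria["s2"]
        assert eq.assignment.offspring_of("m2") == "o_lo"

    def test_no_veil_always_own_care(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            k1, k2 = rng.uniform(0.2, 3.0, 2)
            x_hi, x_lo = sorted(rng.uniform(0.05, 0.5, 2))[::-1]
            d = make_dyad(k1, k2, x_hi, x_lo, parented=True,
                          mother1_owns=rng.choice(["hi", "lo"]))
            cls = classify_preferences(d, NOVEIL0)
            assert cls.label == f"agreement_{cls.own_care_assignment}"

    def test_equal_condition_veil_disagreement_over_larger(self, veil0):
        rng = np.random.default_rng(8)
        for _ in range(200):
            k = rng.uniform(0.2, 3.0)
            x_lo = rng.uniform(0.05, 0.4)
            x_hi = x_lo + rng.uniform(0.01, 0.1)
            cls = classify_preferences(make_dyad(k, k, x_hi, x_lo), veil0)
            assert cls.label == "disagreement"
            # each mother wants to tend the larger pup herself
            assert cls.preferred["m1"] == "s2"
            assert cls.preferred["m2"] == "s1"

    def test_agreement_implies_need_based_pairing(self, veil0):
        """Every mutually preferred outcome pairs the better-condition
        mother with the smaller pup, which then gains more care than the
        larger one; the variance drops unless the extra care overshoots
        and reverses the size ranking outright."""
        rng = np.random.default_rng(9)
        found = 0
        for _ in range(500):
            k1, k2 = sorted(rng.uniform(0.2, 3.0, 2))[::-1]  # m1 inferior
            x_hi, x_lo = sorted(rng.uniform(0.05, 0.5, 2))[::-1]
            d = make_dyad(k1, k2, x_hi, x_lo)
            cls = classify_preferences(d, veil0)
            if cls.agreed_assignment is None:
                continue
            found += 1
            eq = cls.equilibria[cls.agreed_assignment]
            low_k = min(d.mothers, key=lambda m: m.k)
            assert eq.assignment.offspring_of(low_k.id) == "o_lo"
            y_lo = eq.y[eq.assignment.carer_of("o_lo")]
            y_hi = eq.y[eq.assignment.carer_of("o_hi")]
            assert y_lo > y_hi
            pre, post = variance_trajectory(d, veil0, "mutually_preferred")
            if eq.t["o_lo"] <= eq.t["o_hi"]:
                assert post < pre
        assert found > 20, "random search should hit the agreement zone"


class TestZoneGrid:
    def test_reference_points_labelled(self, veil0):
        grid = scan_zone_grid(k_mean=1.0, x_mean=0.2, dk_max=1.5, dx_max=0.3,
                              resolution=31, info=veil0)
        assert grid.label_at(0.5, 0.1) == "disagreement"
        assert grid.label_at(1.0, 0.2) == "agreement_s2"
        assert grid.label_at(0.0, 0.0) == "boundary"

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ParameterError):
            scan_zone_grid(k_mean=0.5, dk_max=1.5)
        with pytest.raises(ParameterError):
            scan_zone_grid(x_mean=0.1, dx_max=0.5)

    def test_dataframe_export(self, veil0):
        grid = scan_zone_grid(resolution=5, info=veil0)
        df = grid.to_dataframe()
        assert len(df) == 25
        assert set(df.columns) == {"dk", "dx", "k1", "k2", "x_hi", "x_lo", "label"}
        assert set(df.label) <= {"agreement_s1", "agreement_s2",
                                 "disagreement", "boundary"}


class TestVarianceTrajectory:
    def test_point_b_mutual_outcome_equalises(self, point_b, veil0):
        pre, post = variance_trajectory(point_b, veil0, "mutually_preferred")
        assert pre == pytest.approx(0.01)
        assert post == pytest.approx(0.0, abs=1e-12)

    def test_point_a_forced_outcome_reinforces(self, point_a, veil0):
        pre, post = variance_trajectory(point_a, veil0, "forced_s1")
        assert pre == pytest.approx(0.0025)
        assert post == pytest.approx(0.005317, abs=1e-5)
        assert post > pre

    def test_point_a_mixture_roughly_preserves(self, point_a, veil0):
        pre, post = variance_trajectory(point_a, veil0, "equal_mixture")
        assert post == pytest.approx(pre, rel=0.25)

    def test_mutual_outcome_unavailable_in_disagreement(self, point_a, veil0):
        with pytest.raises(DisagreementError):
            variance_trajectory(point_a, veil0, "mutually_preferred")

    def test_unknown_policy_rejected(self, point_a, veil0):
        with pytest.raises(ParameterError):
            variance_trajectory(point_a, veil0, "whatever")


class TestDyadStructure:
    def test_offspring_sorted_by_size(self):
        d = make_dyad(1.0, 1.0, 0.1, 0.3)  # given in the "wrong" order
        assert d.x_hi.x == pytest.approx(0.3)
        assert d.x_lo.x == pytest.approx(0.1)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            make_dyad(-1.0, 1.0, 0.3, 0.1)
        with pytest.raises(ParameterError):
            make_dyad(1.0, 1.0, 1.3, 0.1)
        with pytest.raises(ParameterError):
            InformationState(Mode.VEIL, 1.5)
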