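"""Fill-up bounds: worked examples, exhaustive-enumeration and LP oracle
equivalence, monotonicity/Lipschitz properties, and the supporting
arithmetic (q rescaling, incidence ceilings, outward rounding)."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from _oracles import enumeration_bounds, lp_fillup_bounds
from overtreat.bounds import (
    BoundsInterval,
    age_standardize,
    bound_overtreatment,
    bounds_curve,
    q_max_from_incidence,
    rescale_q,
    round_outward,
)


# ---------------------------------------------------------------------------
# q rescaling
# ---------------------------------------------------------------------------


def test_rescale_q_worked_example():
    # 30% of the whole cohort overdiagnosed, 75% eligible -> 40% of eligible
    assert rescale_q(0.30, 1000, 750) == pytest.approx(0.40)


def test_rescale_q_zero_and_infeasible():
    assert rescale_q(0.0, 100, 75) == 0.0
    with pytest.raises(ValueError, match="inconsistent with rule-out"):
        rescale_q(0.80, 100, 75)


# ---------------------------------------------------------------------------
# fill-up bounds
# ---------------------------------------------------------------------------


def test_zero_overdiagnosis_gives_the_point_zero():
    iv = bound_overtreatment(np.array([0.3, 0.6]), 4, 0.0)
    assert (iv.lower, iv.upper) == (0.0, 0.0)


def test_integer_fillup_worked_example():
    # q=0.5 of n_total=4 means 2 of the 4 eligible cases are overdiagnosed:
    # extremes are the two smallest / two largest propensities
    iv = bound_overtreatment(np.array([0.1, 0.2, 0.7, 0.9]), 4, 0.5)
    assert iv.lower == pytest.approx(0.075)
    assert iv.upper == pytest.approx(0.4)


def test_fractional_fillup_worked_example():
    # m = 1.5: the marginal case enters with weight one half
    iv = bound_overtreatment(np.array([0.2, 0.4, 0.8]), 3, 0.5)
    assert iv.lower == pytest.approx((0.2 + 0.5 * 0.4) / 3)
    assert iv.upper == pytest.approx((0.8 + 0.5 * 0.4) / 3)


def test_fillup_equals_exhaustive_subset_enumeration():
    rng = np.random.default_rng(2024)
    for _ in range(25):
        n_elig = int(rng.integers(2, 13))
        n_total = n_elig + int(rng.integers(0, 5))
        p = rng.uniform(size=n_elig)
        m = int(rng.integers(0, n_elig + 1))
        lo_o, hi_o = enumeration_bounds(p, n_total, m)
        iv = bound_overtreatment(p, n_total, m / n_total)
        assert iv.lower == pytest.approx(lo_o, abs=1e-12)
        assert iv.upper == pytest.approx(hi_o, abs=1e-12)


def test_fillup_equals_lp_optimum_for_fractional_mass():
    rng = np.random.default_rng(7)
    for _ in range(25):
        n_elig = int(rng.integers(2, 40))
        n_total = n_elig + int(rng.integers(0, 10))
        p = rng.uniform(size=n_elig)
        m = float(rng.uniform(0, n_elig))
        lo_o, hi_o = lp_fillup_bounds(p, n_total, m)
        iv = bound_overtreatment(p, n_total, m / n_total)
        assert iv.lower == pytest.approx(lo_o, abs=1e-7)
        assert iv.upper == pytest.approx(hi_o, abs=1e-7)


@given(
    p=st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40),
    qs=st.tuples(st.floats(min_value=0, max_value=1),
                 st.floats(min_value=0, max_value=1)),
)
def test_endpoints_monotone_lipschitz_and_ordered(p, qs):
    p = np.asarray(p)
    n_total = len(p) + 3
    q_cap = len(p) / n_total
    q1, q2 = sorted(q * q_cap for q in qs)
    iv1 = bound_overtreatment(p, n_total, q1)
    iv2 = bound_overtreatment(p, n_total, q2)
    assert 0.0 <= iv1.lower <= iv1.upper <= iv1.q_total + 1e-9
    # both endpoints non-decreasing in q ...
    assert iv1.lower <= iv2.lower + 1e-9
    assert iv1.upper <= iv2.upper + 1e-9
    # ... and 1-Lipschitz (propensities are at most 1)
    assert iv2.lower - iv1.lower <= (q2 - q1) + 1e-9
    assert iv2.upper - iv1.upper <= (q2 - q1) + 1e-9


def test_curve_passes_through_origin_and_is_monotone(oracle4k, cohort4k):
    from overtreat.ruleout import apply_ruleout

    eligible, _, _ = apply_ruleout(cohort4k)
    p = oracle4k.align(eligible.case_ids)
    grid = np.linspace(0, 0.35, 15)
    curve = bounds_curve(p, len(cohort4k), grid)
    df = curve.to_frame()
    assert df.loc[0, "lower"] == 0.0 and df.loc[0, "upper"] == 0.0
    assert (np.diff(df["lower"]) >= -1e-12).all()
    assert (np.diff(df["upper"]) >= -1e-12).all()


def test_propensities_outside_unit_interval_rejected():
    with pytest.raises(ValueError):
        bound_overtreatment(np.array([0.2, 1.4]), 4, 0.2)


# ---------------------------------------------------------------------------
# incidence ceiling, age standardisation, outward rounding
# ---------------------------------------------------------------------------


def test_incidence_trend_ceiling_overall_and_dcis():
    # overall breast cancer, 1980 vs 2013 age-standardized incidence
    assert 100 * q_max_from_incidence(230.1, 364.6) == pytest.approx(36.9, abs=0.05)
    assert round(100 * q_max_from_incidence(230.1, 364.6)) == 37
    # DCIS-only incidence trend
    assert round(100 * q_max_from_incidence(6.5, 66.2)) == 90


def test_incidence_ceiling_edge_cases():
    assert q_max_from_incidence(200.0, 200.0) == 0.0
    with pytest.raises(ValueError):
        q_max_from_incidence(300.0, 200.0)


@pytest.mark.parametrize(
    "rates,weights,expected",
    [
        ([123.4], [7.0], 123.4),
        ([100.0, 300.0], [1.0, 1.0], 200.0),
        ([100.0, 300.0], [1.0, 3.0], 250.0),
    ],
)
def test_age_standardize_weighted_mean(rates, weights, expected):
    assert age_standardize(rates, weights) == pytest.approx(expected)


def test_age_standardize_rejects_zero_weights():
    with pytest.raises(ValueError):
        age_standardize([100.0, 200.0], [0.0, 0.0])


@pytest.mark.parametrize(
    "interval,expected",
    [((5.6, 12.4), (5, 13)), ((7.0, 7.0), (7, 7)), ((0.01, 0.99), (0, 1))],
)
def test_round_outward(interval, expected):
    assert round_outward(*interval) == expected


def test_interval_invariants_enforced():
    with pytest.raises(ValueError):
        BoundsInterval(q_total=0.2, q_eligible=0.25, lower=0.3, upper=0.1)
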