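"""Rule-out criteria: per-case logic, cohort partitioning, DCIS mode, and
the alternative-criteria sweep."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import make_case, make_cohort
from overtreat.bounds import bounds_curve
from overtreat.ruleout import (
    DCIS_HISTOLOGY_CODES,
    RuleOutCriteria,
    alternative_criteria_sweep,
    apply_ruleout,
    dcis_criteria,
    is_ruled_out,
    ruled_out_mask,
)


@pytest.mark.parametrize(
    "kw,expected",
    [
        # two invaded nodes alone suffice; one does not
        (dict(nodes_positive=2), True),
        (dict(nodes_positive=1, tumor_size_cm=3.9), False),
        # 4 cm is the size threshold; 3.9 cm tumors could still be overdiagnosed
        (dict(tumor_size_cm=4.0), True),
        (dict(tumor_size_cm=3.99), False),
        # unknown size/nodes must never exclude
        (dict(tumor_size_cm=None, nodes_positive=None), False),
        (dict(distant_metastasis=True), True),
        (dict(invades_fascia_muscle_chestwall=True), True),
        (dict(skin_ulceration_or_adjacent_skin=True), True),
        (dict(invades_fascia_muscle_chestwall=None,
              skin_ulceration_or_adjacent_skin=None,
              distant_metastasis=None), False),
    ],
)
def test_is_ruled_out_default_criteria(kw, expected):
    assert is_ruled_out(make_case("x", **kw)) is expected


def test_disabled_criteria_do_not_trigger():
    crit = RuleOutCriteria(use_distant_metastasis=False)
    assert is_ruled_out(make_case("x", distant_metastasis=True), crit) is False


def test_thresholds_must_be_positive():
    with pytest.raises(ValueError):
        RuleOutCriteria(min_nodes_ruleout=0)


def test_vectorised_mask_agrees_with_per_case_logic(cohort4k):
    for crit in (RuleOutCriteria(), RuleOutCriteria(min_nodes_ruleout=1,
                                                    min_size_cm_ruleout=3.0)):
        mask = ruled_out_mask(cohort4k, crit)
        for i in range(0, len(cohort4k), 173):
            assert mask[i] == is_ruled_out(cohort4k.record(i), crit)


def test_apply_ruleout_partitions_the_cohort(cohort4k):
    eligible, excluded, report = apply_ruleout(cohort4k)
    assert len(eligible) + len(excluded) == len(cohort4k)
    assert not set(eligible.case_ids) & set(excluded.case_ids)
    assert report.n_eligible == len(eligible)
    assert report.n_excluded == len(excluded)
    # a case may trip several criteria, so tallies bound the exclusions
    assert sum(report.triggers.values()) >= report.n_excluded


def test_all_benign_cohort_excludes_nobody():
    cohort = make_cohort([make_case(f"c{i}") for i in range(4)])
    eligible, excluded, _ = apply_ruleout(cohort)
    assert len(excluded) == 0 and len(eligible) == 4


def test_metastatic_case_is_excluded_via_its_flag_not_its_stage():
    cases = [make_case(f"c{i}") for i in range(3)]
    cases.append(make_case("m", stage="IV", distant_metastasis=True))
    cases.append(make_case("na", stage="NA"))  # unknown stage stays eligible
    eligible, excluded, _ = apply_ruleout(make_cohort(cases))
    assert len(eligible) == 4 and len(excluded) == 1
    assert excluded.record(0).case_id == "m"


def test_dcis_mode_keeps_only_dcis(cohort4k):
    eligible, _, _ = apply_ruleout(cohort4k, dcis_criteria())
    f = eligible.frame
    assert len(eligible) > 0
    assert (f["behavior"] == "in_situ").all()
    assert f["histology_icdo3"].isin(list(DCIS_HISTOLOGY_CODES)).all()
    assert {8201, 8230, 8523} <= DCIS_HISTOLOGY_CODES
    assert set(range(8500, 8508)) <= DCIS_HISTOLOGY_CODES


@given(
    nodes=st.integers(min_value=1, max_value=3),
    size=st.floats(min_value=1.0, max_value=4.0),
)
def test_tightening_thresholds_only_shrinks_the_eligible_set(
    cohort4k, nodes, size
):
    base_eligible = ~ruled_out_mask(cohort4k, RuleOutCriteria())
    tighter = RuleOutCriteria(min_nodes_ruleout=nodes, min_size_cm_ruleout=size)
    tight_eligible = ~ruled_out_mask(cohort4k, tighter)
    if nodes <= 2 and size <= 4.0:
        assert not (tight_eligible & ~base_eligible).any()


def test_sweep_identical_criteria_give_identical_curves(cohort4k, oracle4k):
    df = alternative_criteria_sweep(
        cohort4k, [RuleOutCriteria(), RuleOutCriteria()], oracle4k,
        [0.0, 0.1, 0.2],
    )
    a = df[df.criteria_index == 0].reset_index(drop=True)
    b = df[df.criteria_index == 1].reset_index(drop=True)
    assert (a[["q", "lower", "upper"]].values == b[["q", "lower", "upper"]].values).all()


def test_sweep_stricter_criteria_mostly_move_the_upper_bound(cohort4k, oracle4k):
    """The minimum plausible estimate is nearly criteria-independent; the
    maximum moves, because stricter criteria remove high-propensity cases."""
    strict = RuleOutCriteria(min_nodes_ruleout=1, min_size_cm_ruleout=3.0)
    df = alternative_criteria_sweep(
        cohort4k, [RuleOutCriteria(), strict], oracle4k, [0.1, 0.2]
    )
    base = df[df.criteria_index == 0].set_index("q")
    alt = df[df.criteria_index == 1].set_index("q")
    assert (alt["n_eligible"] < base["n_eligible"]).all()
    lower_spread = (base["lower"] - alt["lower"]).abs().max()
    upper_spread = (base["upper"] - alt["upper"]).abs().max()
    assert lower_spread < upper_spread
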