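"""Synthetic-cohort generator: determinism, calibration of the scenario
margins, latent-label masking, and the exchangeability guarantee."""

import numpy as np
import pytest

from conftest import make_case, make_cohort
from overtreat.cohort import CohortError
from overtreat.ruleout import ruled_out_mask
from overtreat.simulate import (
    LogisticSpec,
    SyntheticConfig,
    default_config,
    generate_cohort,
    load_scenario,
    true_overtreatment_rate,
    true_propensities,
)


def test_generation_is_deterministic_given_seed():
    a = generate_cohort(default_config(n_cases=1000, seed=7))
    b = generate_cohort(default_config(n_cases=1000, seed=7))
    assert a == b
    c = generate_cohort(default_config(n_cases=1000, seed=8))
    assert not (a == c)


def test_forcing_zero_overdiagnosis_probability():
    cfg = default_config(n_cases=800, seed=3)
    cfg.overdiagnosis_model = LogisticSpec(intercept=-50.0)
    cohort = generate_cohort(cfg)
    assert not cohort.frame["overdiagnosed"].any()


def test_marginal_mastectomy_rate_is_calibrated(cohort50k):
    """The scenario pins the marginal mastectomy rate at 33.8%; the
    observed fraction must sit within 3 binomial standard errors."""
    target = 0.338
    se = np.sqrt(target * (1 - target) / len(cohort50k))
    assert abs(cohort50k.mastectomy.mean() - target) < 3 * se


def test_overdiagnosed_cases_never_carry_ruleout_characteristics(cohort50k):
    v = cohort50k.frame["overdiagnosed"].to_numpy(bool)
    assert v.any()
    assert not (v & ruled_out_mask(cohort50k)).any()


def test_exchangeability_holds_within_strata_when_delta_zero(cohort50k):
    """With no exchangeability violation, overdiagnosed and
    non-overdiagnosed cases in the same covariate stratum have equal
    mastectomy rates up to binomial noise."""
    f = cohort50k.frame
    v = f["overdiagnosed"].to_numpy(bool)
    m = cohort50k.mastectomy
    strata = (
        f["behavior"].astype(str)
        + "|" + cohort50k.variable("size_group").astype(str)
        + "|" + cohort50k.variable("age_group").astype(str)
    )
    zs = []
    for _, idx in strata.groupby(strata).groups.items():
        sv, sm = v[idx], m[idx]
        n1, n0 = sv.sum(), (~sv).sum()
        if min(n1, n0) < 50:
            continue
        p1, p0 = sm[sv].mean(), sm[~sv].mean()
        pool = sm.mean()
        se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n0))
        zs.append((p1 - p0) / se)
    assert len(zs) >= 5
    assert max(abs(z) for z in zs) < 4.5


def test_delta_shifts_mastectomy_odds_of_overdiagnosed_cases():
    cfg = default_config(n_cases=30_000, seed=9,
                         exchangeability_violation_delta=1.5)
    cohort = generate_cohort(cfg)
    v = cohort.frame["overdiagnosed"].to_numpy(bool)
    m = cohort.mastectomy
    p_model = true_propensities(cohort, cfg).p_hat
    # overdiagnosed cases get mastectomy far more often than their delta=0
    # conditional probability predicts
    assert m[v].mean() > p_model[v].mean() + 0.10


def test_covariate_streams_are_independent_of_schema_extensions():
    """Adding an extra covariate must not perturb the draws of the others
    (documented per-covariate stream splitting)."""
    import copy

    cfg_a = default_config(n_cases=2000, seed=4)
    cfg_b = default_config(n_cases=2000, seed=4)
    cfg_b.covariate_params = copy.deepcopy(cfg_b.covariate_params)
    cfg_b.covariate_params["extras"]["screening_program"] = {"yes": 0.5, "no": 0.5}
    a, b = generate_cohort(cfg_a), generate_cohort(cfg_b)
    assert (a.frame["age_years"] == b.frame["age_years"]).all()
    assert (a.frame["tumor_size_cm"].fillna(-1) == b.frame["tumor_size_cm"].fillna(-1)).all()
    assert (a.frame["surgery_class"] == b.frame["surgery_class"]).all()
    assert "screening_program" in b.extra_names


@pytest.mark.parametrize(
    "n_mv,n_other,expected",
    [(0, 10, 0.0), (10, 0, 1.0), (2, 8, 0.2)],
)
def test_true_overtreatment_rate_counts_m_and_v(n_mv, n_other, expected):
    records = [
        make_case(f"mv{i}", surgery_class="mastectomy", overdiagnosed=True)
        for i in range(n_mv)
    ] + [
        make_case(f"o{i}", surgery_class="bcs", overdiagnosed=False)
        for i in range(n_other)
    ]
    assert true_overtreatment_rate(make_cohort(records)) == expected


def test_true_overtreatment_rate_requires_flags():
    cohort = make_cohort([make_case("a")])
    with pytest.raises(CohortError, match="no overdiagnosis flags"):
        true_overtreatment_rate(cohort)


def test_true_propensities_read_off_the_generating_model(cohort4k, default_cfg):
    tp = true_propensities(cohort4k, default_cfg)
    assert len(tp) == len(cohort4k)
    assert tp.p_hat.min() >= 0 and tp.p_hat.max() <= 1
    assert tp.tags[0] == "oracle"
    # calibration pins the mean of the model probabilities to the target
    assert abs(tp.p_hat.mean() - 0.338) < 1e-9


def test_scenario_presets_load():
    cfg = load_scenario("small", seed=42)
    assert cfg.n_cases == 1500 and cfg.seed == 42
    with pytest.raises(KeyError):
        load_scenario("no_such_scenario")


def test_invalid_config_rejected():
    with pytest.raises(CohortError):
        SyntheticConfig(n_cases=0)
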