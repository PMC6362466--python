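"""Propensity estimation: honesty (OOB / cross-fitting), determinism, and
the Brier / c-statistic / calibration diagnostics."""

import numpy as np
import pytest
from sklearn.model_selection import KFold

from overtreat.cohort import Cohort
from overtreat.propensity import (
    CategoricalEncoder,
    ModelSpec,
    PropensityEstimates,
    brier_score,
    c_statistic,
    calibration_curve,
    fit_and_predict,
)
from overtreat.simulate import LogisticSpec, default_config, generate_cohort


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "p,y,expected",
    [
        ([0.0, 1.0, 1.0], [0, 1, 1], 0.0),
        ([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1], 0.25),
        ([0.2, 0.8], [0, 1], 0.04),
    ],
)
def test_brier_score_closed_forms(p, y, expected):
    assert brier_score(np.array(p), np.array(y)) == pytest.approx(expected)


@pytest.mark.parametrize(
    "p,y,expected",
    [
        ([0.2, 0.8], [0, 1], 1.0),
        ([0.4, 0.4, 0.4, 0.4], [0, 1, 0, 1], 0.5),
        # 4 positive-negative pairs: 2 wins + 2 more wins, 1 tie counted half
        ([0.1, 0.4, 0.4, 0.9], [0, 1, 0, 1], 0.875),
    ],
)
def test_c_statistic_counts_ties_as_half(p, y, expected):
    assert c_statistic(np.array(p), np.array(y)) == pytest.approx(expected)


def test_c_statistic_requires_both_classes():
    with pytest.raises(ValueError):
        c_statistic(np.array([0.2, 0.8]), np.array([1, 1]))


def test_calibration_counts_partition_the_sample():
    rng = np.random.default_rng(0)
    p = rng.uniform(size=5000)
    y = rng.uniform(size=5000) < p
    tab = calibration_curve(p, y, n_bins=10)
    assert tab["count"].sum() == 5000
    # data generated from its own probabilities: every decile near identity
    se = np.sqrt(tab["mean_p_hat"] * (1 - tab["mean_p_hat"]) / tab["count"])
    assert (np.abs(tab["mean_p_hat"] - tab["observed_rate"]) < 3 * se + 1e-9).all()


def test_single_bin_is_the_overall_rate():
    p = np.array([0.2, 0.4, 0.9])
    y = np.array([0, 1, 1])
    tab = calibration_curve(p, y, n_bins=1)
    assert len(tab) == 1
    assert tab["observed_rate"].iloc[0] == pytest.approx(2 / 3)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def test_oracle_family_passes_through_the_generating_model(cohort4k, default_cfg):
    est = fit_and_predict(cohort4k, ModelSpec(model_family="oracle",
                                              oracle=default_cfg))
    from overtreat.simulate import true_propensities

    assert np.array_equal(est.p_hat, true_propensities(cohort4k, default_cfg).p_hat)


@pytest.mark.parametrize("family,kw", [
    ("random_forest", {"n_trees": 120}),
    ("logistic", {}),
])
def test_same_cohort_and_seed_give_identical_estimates(cohort4k, family, kw):
    spec = lambda: ModelSpec(model_family=family, seed=17, **kw)  # noqa: E731
    a = fit_and_predict(cohort4k, spec())
    b = fit_and_predict(cohort4k, spec())
    assert np.array_equal(a.p_hat, b.p_hat)
    assert a.tags == b.tags


def test_uninformative_covariates_recover_the_constant_rate():
    """When mastectomy is assigned at a flat 30% regardless of covariates,
    the fitted out-of-sample propensities must average to 30% within
    binomial error."""
    cfg = default_config(n_cases=6000, seed=31)
    cfg.mastectomy_model = LogisticSpec(terms={}, target_marginal=0.30)
    cohort = generate_cohort(cfg)
    est = fit_and_predict(cohort, ModelSpec(model_family="logistic", seed=2))
    se = np.sqrt(0.3 * 0.7 / len(cohort))
    assert abs(est.p_hat.mean() - 0.30) < 3 * se


def test_single_class_outcome_is_an_error(cohort4k):
    frame = cohort4k.frame.copy()
    frame["surgery_class"] = "bcs"
    degenerate = Cohort(frame, cohort4k.extra_names)
    with pytest.raises(ValueError, match="single-class"):
        fit_and_predict(degenerate, ModelSpec(model_family="logistic"))


def test_crossfit_never_uses_a_cases_own_outcome(cohort4k):
    """Data-leak canary: permuting the outcomes of one held-out fold must
    not change that fold's predictions, because they come from a model
    trained on the other folds only."""
    spec = ModelSpec(model_family="logistic", seed=13, n_folds=5)
    base = fit_and_predict(cohort4k, spec)
    fold0 = next(iter(
        KFold(n_splits=5, shuffle=True, random_state=13).split(np.zeros(len(cohort4k)))
    ))[1]
    frame = cohort4k.frame.copy()
    rng = np.random.default_rng(99)
    shuffled = frame.loc[fold0, "surgery_class"].to_numpy()
    rng.shuffle(shuffled)
    frame.loc[fold0, "surgery_class"] = shuffled
    tampered = Cohort(frame, cohort4k.extra_names)
    alt = fit_and_predict(tampered, spec)
    assert np.array_equal(base.p_hat[fold0], alt.p_hat[fold0])
    # and outside the tampered fold predictions generally do change
    rest = np.setdiff1d(np.arange(len(cohort4k)), fold0)
    assert not np.array_equal(base.p_hat[rest], alt.p_hat[rest])


def test_oob_predictions_differ_from_in_sample():
    """OOB forest probabilities are not the resubstitution probabilities —
    with deep trees resubstitution is near-perfect, OOB is honest."""
    cfg = default_config(n_cases=1200, seed=41)
    cohort = generate_cohort(cfg)
    est = fit_and_predict(cohort, ModelSpec(n_trees=150, seed=3))
    y = cohort.mastectomy
    assert set(est.tags) == {"oob"}
    assert brier_score(est.p_hat, y) > 0.05  # honest, not memorised


def test_estimates_align_by_case_id(cohort4k, logistic4k):
    sub = cohort4k.subset(np.arange(len(cohort4k)) % 7 == 0)
    p = logistic4k.align(sub.case_ids)
    assert len(p) == len(sub)
    idx = list(cohort4k.case_ids).index(sub.record(0).case_id)
    assert p[0] == logistic4k.p_hat[idx]
    with pytest.raises(KeyError):
        logistic4k.align(["not_a_case"])


def test_encoder_maps_unseen_levels_to_na():
    import pandas as pd

    enc = CategoricalEncoder()
    train = pd.DataFrame({"a": ["x", "y", "NA"]})
    enc.fit(train)
    unseen = enc.transform(pd.DataFrame({"a": ["z"]}))
    explicit_na = enc.transform(pd.DataFrame({"a": ["NA"]}))
    assert np.array_equal(unseen, explicit_na)


def test_p_hat_validated():
    with pytest.raises(ValueError):
        PropensityEstimates(["a"], np.array([1.2]), ["oob"])
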