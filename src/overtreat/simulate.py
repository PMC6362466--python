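"""Synthetic registry-cohort generator with known ground truth.

Real registry case listings carry no overdiagnosis labels — that is the
whole identification problem.  This module generates registry-*like*
cohorts in which the latent structure is known, so that every downstream
stage (rule-out, propensity estimation, fill-up bounds, sensitivity
analysis) can be validated end to end:

* covariates are drawn from categorical/parametric distributions loosely
  calibrated to published margins for US breast-cancer case listings
  (about 21% in situ disease, mastectomy more likely for larger tumors and
  younger women, an overall mastectomy rate near 33.8%);
* first-course surgery is assigned by a logistic model on the covariates,
  which defines the true propensity Pr(M | X);
* a latent overdiagnosis flag V is drawn from a second logistic model
  concentrated on early-stage patterns, and is *masked to zero* for any
  case showing a rule-out characteristic — by construction no generated
  overdiagnosis carries features that rule overdiagnosis out;
* conditional on the covariates, V and the mastectomy draw are independent
  (the exchangeability assumption holds exactly) unless
  ``exchangeability_violation_delta`` shifts the mastectomy log-odds of
  overdiagnosed cases, which lets tests probe what breaks when the key
  assumption fails;
* optionally, a latent binary covariate that is *not recorded* in the
  cohort can shift the mastectomy log-odds, emulating an omitted variable
  with a known conditional odds ratio for the sensitivity analysis.

All randomness hangs off a single integer seed; each covariate gets its own
deterministic substream (seeded by a CRC of its name) so adding a covariate
does not perturb the draws of the others.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import Cohort, CohortError, _coerce_types, CORE_COLUMNS
from .propensity import PropensityEstimates
from .ruleout import RuleOutCriteria, ruled_out_mask

__all__ = [
    "LogisticSpec",
    "OmittedCovariate",
    "SyntheticConfig",
    "default_config",
    "load_scenario",
    "generate_cohort",
    "true_propensities",
    "true_overtreatment_rate",
]

# ---------------------------------------------------------------------------
# Derived numeric features the generating models are written in.
# ---------------------------------------------------------------------------

_SIZE_CAP_CM = 6.0


def _size(f: pd.DataFrame) -> np.ndarray:
    s = f["tumor_size_cm"].to_numpy(float)
    return np.where(np.isnan(s), 0.0, np.minimum(s, _SIZE_CAP_CM))


def _nodes(f: pd.DataFrame) -> np.ndarray:
    return f["nodes_positive"].to_numpy(float)


FEATURES: dict[str, Callable[[pd.DataFrame], np.ndarray]] = {
    "in_situ": lambda f: (f["behavior"] == "in_situ").to_numpy(float),
    "size_cm": _size,
    "size_missing": lambda f: np.isnan(f["tumor_size_cm"].to_numpy(float)).astype(float),
    "age_per_decade": lambda f: (f["age_years"].to_numpy(float) - 60.0) / 10.0,
    "nodes_1": lambda f: (_nodes(f) == 1).astype(float),
    "nodes_2plus": lambda f: (_nodes(f) >= 2).astype(float),
    "nodes_any": lambda f: (_nodes(f) >= 1).astype(float),
    "nodes_missing": lambda f: np.isnan(_nodes(f)).astype(float),
    "grade_iii_iv": lambda f: f["grade"].isin(["III", "IV"]).to_numpy(float),
    "grade_missing": lambda f: (f["grade"] == "NA").to_numpy(float),
    "her2_pos": lambda f: (f["her2"] == "pos").to_numpy(float),
    "hr_neg": lambda f: (f["hr"] == "neg").to_numpy(float),
    "receptors_missing": lambda f: (f["her2"] == "NA").to_numpy(float),
    "fascia": lambda f: f["invades_fascia_muscle_chestwall"].fillna(False).to_numpy(float),
    "skin": lambda f: f["skin_ulceration_or_adjacent_skin"].fillna(False).to_numpy(float),
    "mets": lambda f: f["distant_metastasis"].fillna(False).to_numpy(float),
}


@dataclass
class LogisticSpec:
    """A logistic model: intercept + named derived-feature terms (log-odds
    per unit) + optional per-level effects of raw categorical columns.

    ``target_marginal`` requests calibration: the intercept is re-solved on
    each cohort so the mean probability hits the target exactly (used to
    pin the scenario's marginal mastectomy rate).
    """

    intercept: float = 0.0
    terms: dict[str, float] = field(default_factory=dict)
    level_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    target_marginal: float | None = None

    def linear_predictor(self, frame: pd.DataFrame) -> np.ndarray:
        """Covariate contribution to the log-odds, excluding the intercept."""
        lp = np.zeros(len(frame))
        for name, coef in self.terms.items():
            try:
                feat = FEATURES[name]
            except KeyError:
                raise CohortError(f"unknown model feature {name!r}") from None
            lp += coef * feat(frame)
        for col, effects in self.level_effects.items():
            lp += frame[col].map(effects).fillna(0.0).to_numpy(float)
        return lp

    def calibrated_intercept(self, lp: np.ndarray,
                             mix: tuple[float, float] | None = None) -> float:
        """Intercept, re-solved against ``target_marginal`` if one is set.

        ``mix = (prevalence, log_or)`` marginalises over an independent
        latent binary shifter when calibrating.
        """
        if self.target_marginal is None:
            return self.intercept

        def mean_p(b: float) -> float:
            if mix is None:
                return float(expit(b + lp).mean())
            prev, beta = mix
            return float(
                (prev * expit(b + lp + beta) + (1 - prev) * expit(b + lp)).mean()
            )

        lo, hi = -30.0, 30.0
        target = self.target_marginal
        return float(brentq(lambda b: mean_p(b) - target, lo, hi, xtol=1e-12))

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "terms": dict(self.terms),
            "level_effects": {k: dict(v) for k, v in self.level_effects.items()},
            "target_marginal": self.target_marginal,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LogisticSpec":
        return cls(**d)


@dataclass
class OmittedCovariate:
    """A latent binary covariate that shifts mastectomy log-odds but is not
    recorded in the generated cohort (drawn independently of X)."""

    prevalence: float = 0.4
    log_or: float = 0.0


def _default_mastectomy_model() -> LogisticSpec:
    return LogisticSpec(
        intercept=-1.0,
        terms={
            "size_cm": 0.33,
            "size_missing": -0.35,
            "age_per_decade": -0.25,
            "in_situ": -0.25,
            "nodes_1": 0.35,
            "nodes_2plus": 0.80,
            "nodes_missing": -0.90,
            "grade_iii_iv": 0.25,
            "her2_pos": 0.30,
            "hr_neg": 0.10,
            "mets": -1.00,
            "fascia": 0.30,
            "skin": 0.30,
        },
        level_effects={
            "region": {
                "Detroit": 0.20,
                "Hawaii": -0.20,
                "Utah": 0.10,
                "Connecticut": -0.10,
                "Seattle-Puget Sound": 0.05,
            },
            "race": {"Asian or Pacific Islander": 0.15, "Other": -0.20},
        },
        target_marginal=0.338,
    )


def _default_overdiagnosis_model() -> LogisticSpec:
    return LogisticSpec(
        intercept=-1.2,
        terms={
            "in_situ": 1.4,
            "size_cm": -0.45,
            "age_per_decade": 0.25,
            "nodes_any": -1.5,
            "grade_iii_iv": -0.6,
        },
    )


#: per-covariate distribution parameters of the default scenario; presets
#: may override individual entries.
DEFAULT_COVARIATE_PARAMS: dict = {
    "age_bins": {
        "bins": [(40, 49), (50, 64), (65, 84), (85, 94)],
        "probs": [0.169, 0.395, 0.387, 0.049],
    },
    "in_situ_fraction": 0.21,
    "histology_in_situ": {
        "codes": [8500, 8501, 8503, 8507, 8201, 8230, 8523, 8520],
        "probs": [0.62, 0.06, 0.05, 0.03, 0.04, 0.04, 0.02, 0.14],
    },
    "histology_invasive": {
        "codes": [8500, 8520, 8480, 8510, 8140],
        "probs": [0.75, 0.10, 0.05, 0.03, 0.07],
    },
    "size": {
        "na_prob": 0.12,
        "in_situ_mu": 0.20,
        "in_situ_sigma": 0.70,
        "invasive_mu": 0.50,
        "invasive_sigma": 0.75,
    },
    "nodes": {
        "in_situ": {"zero": 0.62, "na": 0.38},
        "invasive": {"zero": 0.52, "one": 0.09, "two_plus": 0.13, "na": 0.26},
        "two_plus_poisson_mean": 3.0,
    },
    "grade_probs": {"I": 0.21, "II": 0.41, "III": 0.30, "IV": 0.006, "NA": 0.074},
    "molecular_probs": {
        "HER2-/HR-": 0.079,
        "HER2-/HR+": 0.578,
        "HER2+/HR-": 0.033,
        "HER2+/HR+": 0.077,
        "NA": 0.233,
    },
    "regions": {
        "San Francisco-Oakland": 0.13,
        "Connecticut": 0.14,
        "Detroit": 0.15,
        "Hawaii": 0.04,
        "Iowa": 0.11,
        "New Mexico": 0.06,
        "Seattle-Puget Sound": 0.17,
        "Utah": 0.07,
        "Atlanta": 0.13,
    },
    "races": {
        "White": 0.770,
        "Black": 0.111,
        "Asian or Pacific Islander": 0.106,
        "American Indian or Alaska Native": 0.007,
        "Other": 0.006,
    },
    "extras": {
        "marital_status": {
            "married": 0.55, "single": 0.18, "widowed": 0.12,
            "divorced": 0.12, "NA": 0.03,
        },
        "insurance": {
            "private": 0.55, "medicare": 0.30, "medicaid": 0.10,
            "uninsured": 0.02, "NA": 0.03,
        },
        "diagnosis_quarter": {"Q1": 0.25, "Q2": 0.25, "Q3": 0.25, "Q4": 0.25},
    },
    "non_mastectomy_split": {"bcs": 0.852, "other": 0.020, "none": 0.128},
}


@dataclass
class SyntheticConfig:
    """Full specification of a synthetic scenario."""

    n_cases: int = 6000
    seed: int = 0
    mastectomy_model: LogisticSpec = field(default_factory=_default_mastectomy_model)
    overdiagnosis_model: LogisticSpec = field(
        default_factory=_default_overdiagnosis_model
    )
    exchangeability_violation_delta: float = 0.0
    omitted_covariate: OmittedCovariate | None = None
    covariate_params: dict = field(default_factory=lambda: DEFAULT_COVARIATE_PARAMS)

    def __post_init__(self):
        if self.n_cases <= 0:
            raise CohortError("n_cases must be positive")


def default_config(n_cases: int = 6000, seed: int = 0, **kw) -> SyntheticConfig:
    return SyntheticConfig(n_cases=n_cases, seed=seed, **kw)


def load_scenario(name_or_path: str, seed: int | None = None,
                  n_cases: int | None = None) -> SyntheticConfig:
    """Load a scenario preset by name (from the shipped YAML) or a YAML path."""
    path = Path(name_or_path)
    if path.suffix in (".yml", ".yaml") and path.exists():
        entry = yaml.safe_load(path.read_text())
    else:
        text = resources.files("overtreat.data").joinpath("scenarios.yaml").read_text()
        presets = yaml.safe_load(text)
        if name_or_path not in presets:
            raise KeyError(
                f"unknown scenario {name_or_path!r}; available: {sorted(presets)}"
            )
        entry = presets[name_or_path]
    cfg = SyntheticConfig()
    if "n_cases" in entry:
        cfg = replace(cfg, n_cases=int(entry["n_cases"]))
    if "seed" in entry:
        cfg = replace(cfg, seed=int(entry["seed"]))
    if "exchangeability_violation_delta" in entry:
        cfg = replace(
            cfg,
            exchangeability_violation_delta=float(
                entry["exchangeability_violation_delta"]
            ),
        )
    if "mastectomy_target_marginal" in entry:
        cfg.mastectomy_model.target_marginal = entry["mastectomy_target_marginal"]
    if "omitted_covariate" in entry and entry["omitted_covariate"]:
        oc = entry["omitted_covariate"]
        cfg = replace(
            cfg,
            omitted_covariate=OmittedCovariate(
                prevalence=float(oc.get("prevalence", 0.4)),
                log_or=float(oc.get("log_or", 0.0)),
            ),
        )
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    if n_cases is not None:
        cfg = replace(cfg, n_cases=n_cases)
    return cfg


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _stream(seed: int, name: str) -> np.random.Generator:
    """Independent deterministic substream for one covariate/stage."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])


def _choice(rng, items: dict, n: int) -> np.ndarray:
    keys = list(items.keys())
    probs = np.asarray(list(items.values()), float)
    probs = probs / probs.sum()
    return rng.choice(np.array(keys, dtype=object), size=n, p=probs)


def _draw_covariates(config: SyntheticConfig) -> pd.DataFrame:
    cp = config.covariate_params
    n, seed = config.n_cases, config.seed

    # age
    rng = _stream(seed, "age")
    bins = cp["age_bins"]["bins"]
    which = rng.choice(len(bins), size=n, p=np.asarray(cp["age_bins"]["probs"]) /
                       np.sum(cp["age_bins"]["probs"]))
    lo = np.array([b[0] for b in bins])[which]
    hi = np.array([b[1] for b in bins])[which]
    age = lo + np.floor(rng.random(n) * (hi - lo + 1)).astype(int)

    # behavior
    rng = _stream(seed, "behavior")
    in_situ = rng.random(n) < cp["in_situ_fraction"]
    behavior = np.where(in_situ, "in_situ", "invasive").astype(object)

    # histology
    rng = _stream(seed, "histology")
    hist = np.empty(n, dtype=np.int64)
    for flag, key in ((True, "histology_in_situ"), (False, "histology_invasive")):
        sel = in_situ == flag
        codes = np.asarray(cp[key]["codes"])
        probs = np.asarray(cp[key]["probs"], float)
        hist[sel] = rng.choice(codes, size=int(sel.sum()), p=probs / probs.sum())

    # tumor size (cm, one decimal, like registry coding)
    rng = _stream(seed, "size")
    sp = cp["size"]
    mu = np.where(in_situ, sp["in_situ_mu"], sp["invasive_mu"])
    sigma = np.where(in_situ, sp["in_situ_sigma"], sp["invasive_sigma"])
    size = np.round(np.exp(rng.normal(mu, sigma)), 1)
    size = np.minimum(size, 20.0)
    size[rng.random(n) < sp["na_prob"]] = np.nan

    # positive nodes
    rng = _stream(seed, "nodes")
    npar = cp["nodes"]
    nodes = np.zeros(n)
    u = rng.random(n)
    extra = 2.0 + rng.poisson(npar["two_plus_poisson_mean"], size=n)
    isp, ivp = npar["in_situ"], npar["invasive"]
    # in situ: zero or NA
    nodes[in_situ & (u >= isp["zero"])] = np.nan
    # invasive: zero / one / two-plus / NA
    inv = ~in_situ
    c1 = ivp["zero"]
    c2 = c1 + ivp["one"]
    c3 = c2 + ivp["two_plus"]
    nodes[inv & (u >= c1) & (u < c2)] = 1
    sel2 = inv & (u >= c2) & (u < c3)
    nodes[sel2] = extra[sel2]
    nodes[inv & (u >= c3)] = np.nan

    # grade
    rng = _stream(seed, "grade")
    grade = _choice(rng, cp["grade_probs"], n)

    # molecular status -> her2/hr
    rng = _stream(seed, "molecular")
    mol = _choice(rng, cp["molecular_probs"], n)
    her2 = np.where(np.char.startswith(mol.astype(str), "HER2+"), "pos", "neg").astype(object)
    hr = np.where(np.char.endswith(mol.astype(str), "HR+"), "pos", "neg").astype(object)
    her2[mol == "NA"] = "NA"
    hr[mol == "NA"] = "NA"

    # local invasion flags and distant metastasis
    rng = _stream(seed, "flags")
    big = (~np.isnan(size)) & (size >= 3.0)
    fascia = rng.random(n) < np.where(in_situ, 0.0, np.where(big, 0.06, 0.005))
    skin = rng.random(n) < np.where(in_situ, 0.0, np.where(big, 0.04, 0.003))
    heavy = (nodes >= 2) | ((~np.isnan(size)) & (size >= 4.0))
    mets = rng.random(n) < np.where(in_situ, 0.0, np.where(heavy, 0.15, 0.02))
    fascia = pd.array(fascia, dtype="boolean")
    skin = pd.array(skin, dtype="boolean")
    mets = pd.array(mets, dtype="boolean")
    na_flags = rng.random(n) < 0.02
    fascia[na_flags] = pd.NA
    na_flags = rng.random(n) < 0.02
    skin[na_flags] = pd.NA

    # AJCC stage, derived coarsely from the measurements
    rng = _stream(seed, "stage")
    stage = np.full(n, "NA", dtype=object)
    stage[in_situ] = "0"
    inv = ~in_situ
    size0 = np.where(np.isnan(size), 1.5, size)
    nodes0 = np.where(np.isnan(nodes), 0.0, nodes)
    stage[inv & (nodes0 == 0) & (size0 < 2.0)] = "I"
    stage[inv & (((nodes0 >= 1) & (nodes0 <= 3)) | ((nodes0 == 0) & (size0 >= 2.0)))] = "II"
    stage[inv & ((nodes0 >= 4) | fascia.fillna(False).to_numpy() |
                 skin.fillna(False).to_numpy())] = "III"
    stage[inv & mets.fillna(False).to_numpy()] = "IV"
    unknown = inv & np.isnan(size) & np.isnan(nodes) & (rng.random(n) < 0.6)
    stage[unknown & ~mets.fillna(False).to_numpy()] = "NA"

    # geography / demography / extras
    region = _choice(_stream(seed, "region"), cp["regions"], n)
    race = _choice(_stream(seed, "race"), cp["races"], n)
    extras = {
        name: _choice(_stream(seed, f"extra:{name}"), probs, n)
        for name, probs in cp["extras"].items()
    }

    frame = pd.DataFrame(
        {
            "case_id": [f"S{i:07d}" for i in range(n)],
            "age_years": age,
            "stage": stage,
            "tumor_size_cm": size,
            "nodes_positive": nodes,
            "grade": grade,
            "her2": her2,
            "hr": hr,
            "histology_icdo3": hist,
            "behavior": behavior,
            "invades_fascia_muscle_chestwall": fascia,
            "skin_ulceration_or_adjacent_skin": skin,
            "distant_metastasis": mets,
            "surgery_class": "none",  # placeholder until surgery is drawn
            "region": region,
            "race": race,
            **extras,
        }
    )
    return _coerce_types(frame)


def _mastectomy_lp_and_intercept(
    frame: pd.DataFrame, config: SyntheticConfig
) -> tuple[np.ndarray, float, tuple[float, float] | None]:
    model = config.mastectomy_model
    lp = model.linear_predictor(frame)
    mix = None
    oc = config.omitted_covariate
    if oc is not None and oc.log_or != 0.0:
        mix = (oc.prevalence, oc.log_or)
    b = model.calibrated_intercept(lp, mix=mix)
    return lp, b, mix


def generate_cohort(config: SyntheticConfig | None = None) -> Cohort:
    """Generate a cohort with populated latent ``overdiagnosed`` flags.

    Deterministic given ``config.seed``.  Overdiagnosis probabilities are
    masked to zero for cases showing any default rule-out characteristic,
    so generated overdiagnoses are always in the eligible set.
    """
    config = config if config is not None else SyntheticConfig()
    frame = _draw_covariates(config)
    extras = tuple(c for c in frame.columns if c not in CORE_COLUMNS)

    # latent overdiagnosis
    tmp = Cohort(frame, extras)
    excluded = ruled_out_mask(tmp, RuleOutCriteria())
    vm = config.overdiagnosis_model
    lp_v = vm.linear_predictor(frame)
    p_v = expit(vm.calibrated_intercept(lp_v) + lp_v)
    p_v = np.where(excluded, 0.0, p_v)
    v = _stream(config.seed, "overdiagnosis").random(config.n_cases) < p_v

    # surgery
    lp, b, mix = _mastectomy_lp_and_intercept(frame, config)
    lp_draw = b + lp + config.exchangeability_violation_delta * v
    if mix is not None:
        prev, beta = mix
        u = _stream(config.seed, "omitted_covariate").random(config.n_cases) < prev
        lp_draw = lp_draw + beta * u
    p_m = expit(lp_draw)
    rng = _stream(config.seed, "surgery")
    m = rng.random(config.n_cases) < p_m
    split = config.covariate_params["non_mastectomy_split"]
    alt = _choice(rng, split, config.n_cases)
    frame = frame.copy()
    frame["surgery_class"] = np.where(m, "mastectomy", alt)
    frame["overdiagnosed"] = v
    return Cohort(frame, extras)


def true_propensities(cohort: Cohort, config: SyntheticConfig) -> PropensityEstimates:
    """The generating model's Pr(M | X) for every case in ``cohort`` — an
    oracle for testing the estimation pipeline, not a fitted quantity.

    When the scenario includes an omitted covariate the returned value is
    the marginal over it (which is what Pr(M | X) means when X excludes the
    omitted variable).  Valid as the conditional mastectomy probability of
    both latent groups only when the exchangeability-violation delta is 0.
    """
    lp, b, mix = _mastectomy_lp_and_intercept(cohort.frame, config)
    if mix is None:
        p = expit(b + lp)
    else:
        prev, beta = mix
        p = prev * expit(b + lp + beta) + (1 - prev) * expit(b + lp)
    return PropensityEstimates(
        case_ids=list(cohort.case_ids),
        p_hat=np.asarray(p, float),
        tags=["oracle"] * len(cohort),
        model={"model_family": "oracle", "seed": config.seed},
    )


def true_overtreatment_rate(cohort: Cohort) -> float:
    """Realised Pr(M, V): the fraction of the cohort that is both
    overdiagnosed and treated by mastectomy.  Requires latent flags."""
    if not cohort.has_overdiagnosis_flags:
        raise CohortError("cohort has no overdiagnosis flags")
    if len(cohort) == 0:
        return 0.0
    v = cohort.frame["overdiagnosed"].to_numpy(bool)
    return float((cohort.mastectomy & v).mean())
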