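"""End-to-end orchestration: cohort -> descriptive tables -> rule-out ->
propensities -> bounds -> sensitivity, with all stage artifacts written to
an output directory and a deterministic machine-readable run report.

Every stage writes files sufficient to re-run any later stage in isolation
(the eligible-case propensity CSV plus the cohort size is all the bounding
step needs).  All randomness — simulation, forest bootstraps, cross-fitting
folds — derives from the single configured seed; derived per-stage seeds
are recorded in the report.  Running the same configuration twice produces
byte-identical reports.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .bounds import bounds_curve, q_max_from_incidence
from .cohort import Cohort, read_cohort, write_cohort
from .descriptive import summarize, trend_test
from .propensity import ModelSpec, diagnostics, fit_and_predict
from .ruleout import RuleOutCriteria, apply_ruleout, dcis_criteria
from .sensitivity import sensitivity_sweep
from .simulate import (
    SyntheticConfig,
    generate_cohort,
    load_scenario,
    true_propensities,
)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("overtreat")

_DESCRIBE_VARS = (
    ("stage", "0"),
    ("size_group", "0.0-0.9"),
    ("nodes_group", "0"),
    ("grade", "I"),
    ("molecular_status", "HER2-/HR+"),
    ("age_group", "40-49"),
    ("race", None),  # reference chosen as the modal level
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    cohort_csv: str | Path | None = None
    scenario: str | SyntheticConfig | None = "default"
    criteria: RuleOutCriteria = field(default_factory=RuleOutCriteria)
    model: ModelSpec = field(default_factory=ModelSpec)
    q_grid: list[float] | None = None
    q_max_rates: tuple[float, float] | None = (230.1, 364.6)
    q_grid_points: int = 38
    lambdas: list[float] = field(default_factory=lambda: [1.0, 5.0, 25.0])
    out_dir: str | Path = "overtreat_run"
    seed: int = 0
    dcis_mode: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key in ("cohort_csv", "scenario", "out_dir", "seed", "dcis_mode",
                    "q_grid", "lambdas", "q_grid_points"):
            if key in d:
                setattr(cfg, key, d[key])
        if "q_max_rates" in d:
            cfg.q_max_rates = tuple(d["q_max_rates"]) if d["q_max_rates"] else None
        if "criteria" in d:
            cfg.criteria = RuleOutCriteria.from_dict(d["criteria"])
        if "model" in d:
            cfg.model = ModelSpec(**d["model"])
        return cfg


def _derived_seed(seed: int, stage: str) -> int:
    return (int(seed) ^ zlib.crc32(stage.encode())) & 0x7FFFFFFF


def _round_floats(obj, ndigits: int = 12):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _load_or_simulate(config: RunConfig, out: Path, report: dict) -> Cohort:
    if config.cohort_csv is not None:
        cohort, excl = read_cohort(config.cohort_csv)
        report["input"] = {"source": str(config.cohort_csv),
                           "exclusions": excl.as_dict()}
        return cohort
    if isinstance(config.scenario, SyntheticConfig):
        sim = config.scenario
    else:
        sim = load_scenario(config.scenario or "default",
                            seed=_derived_seed(config.seed, "simulate"))
    cohort = generate_cohort(sim)
    write_cohort(cohort, out / "cohort.csv", include_latent=False)
    truth = true_propensities(cohort, sim)
    sidecar = truth.to_frame().rename(columns={"p_hat": "true_p"})
    sidecar["overdiagnosed"] = cohort.frame["overdiagnosed"].astype(int).to_numpy()
    sidecar[["case_id", "overdiagnosed", "true_p"]].to_csv(
        out / "cohort_truth.csv", index=False
    )
    report["input"] = {
        "source": "synthetic",
        "n_cases": len(cohort),
        "simulation_seed": sim.seed,
        "overdiagnosed_fraction": float(
            cohort.frame["overdiagnosed"].mean()
        ),
    }
    return cohort


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the (already written) report dict."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "derived_seeds": {
            s: _derived_seed(config.seed, s) for s in ("simulate", "model")
        },
        "dcis_mode": config.dcis_mode,
    }

    cohort = _load_or_simulate(config, out, report)
    n_total = len(cohort)
    log.info("stage cohort: n=%d (%.1fs)", n_total, time.time() - t0)

    # descriptive tables
    tables = []
    for var, ref in _DESCRIBE_VARS:
        values = cohort.variable(var)
        if values.nunique() < 2:
            continue
        if ref is None or ref not in set(values):
            ref = values.mode().iloc[0]
        tables.append(summarize(cohort, var, ref).to_frame())
    if tables:
        import pandas as pd

        pd.concat(tables, ignore_index=True).to_csv(
            out / "descriptive.csv", index=False
        )
    trend = {}
    for var in ("size_group", "age_group"):
        try:
            chi2, p = trend_test(cohort, var)
            trend[var] = {"chi2": chi2, "p": p}
        except ValueError:
            pass
    report["descriptive"] = {
        "n_total": n_total,
        "mastectomy_rate": float(cohort.mastectomy.mean()),
        "trend_tests": trend,
    }
    log.info("stage describe done (%.1fs)", time.time() - t0)

    # rule-out
    criteria = dcis_criteria(config.criteria) if config.dcis_mode else config.criteria
    eligible, excluded, ro_report = apply_ruleout(cohort, criteria)
    write_cohort(eligible, out / "eligible.csv")
    write_cohort(excluded, out / "excluded.csv")
    report["ruleout"] = {"criteria": criteria.to_dict(), **ro_report.as_dict()}
    report["ruleout"]["eligible_mastectomy_rate"] = (
        float(eligible.mastectomy.mean()) if len(eligible) else None
    )
    log.info("stage ruleout: %d eligible (%.1fs)", len(eligible), time.time() - t0)

    # propensities (fit on the full cohort; bounds use the eligible subset)
    model = config.model
    model.seed = _derived_seed(config.seed, "model")
    if model.model_family == "oracle" and model.oracle is None:
        raise ValueError("oracle model family needs an explicit SyntheticConfig")
    estimates = fit_and_predict(cohort, model)
    estimates.to_frame().to_csv(out / "propensities.csv", index=False)
    diag = diagnostics(estimates, cohort.mastectomy)
    report["propensity"] = {"model": estimates.model, **diag}
    log.info("stage propensity: brier=%.4f (%.1fs)", diag["brier"], time.time() - t0)

    # bounds
    p_elig = estimates.align(eligible.case_ids)
    q_cap = len(eligible) / n_total
    if config.q_grid is not None:
        q_grid = list(config.q_grid)
    else:
        if config.q_max_rates is not None:
            q_max = q_max_from_incidence(*config.q_max_rates)
        else:
            q_max = q_cap
        q_max = min(q_max, q_cap)
        q_grid = list(np.round(np.linspace(0.0, q_max, config.q_grid_points), 10))
    curve = bounds_curve(p_elig, n_total, q_grid)
    curve.to_frame().to_csv(out / "bounds_curve.csv", index=False)
    headline = curve[-1]
    lo_pct, hi_pct = headline.rounded_pct()
    report["bounds"] = {
        "q_grid": q_grid,
        "curve": [[iv.q_total, iv.lower, iv.upper] for iv in curve],
        "headline": {
            "q": headline.q_total,
            "lower": headline.lower,
            "upper": headline.upper,
            "lower_pct_rounded": lo_pct,
            "upper_pct_rounded": hi_pct,
        },
    }
    try:
        from .plotting import plot_bounds_curve

        ax = plot_bounds_curve(curve)
        ax.figure.savefig(out / "bounds_curve.png", dpi=150,
                          bbox_inches="tight")
    except Exception as e:  # plotting must never kill an analysis run
        log.warning("bounds plot skipped: %s", e)
    log.info("stage bounds done (%.1fs)", time.time() - t0)

    # sensitivity
    curves = sensitivity_sweep(p_elig, n_total, q_grid, config.lambdas)
    import pandas as pd

    long = pd.concat(
        [c.to_frame().assign(odds_ratio=lam)[
            ["odds_ratio", "q", "lower", "upper"]
        ] for lam, c in curves.items()],
        ignore_index=True,
    )
    long.to_csv(out / "sensitivity.csv", index=False)
    report["sensitivity"] = {
        str(lam): [[iv.q_total, iv.lower, iv.upper] for iv in c]
        for lam, c in curves.items()
    }
    try:
        from .plotting import plot_sensitivity_curves

        ax = plot_sensitivity_curves(curves)
        ax.figure.savefig(out / "sensitivity.png", dpi=150, bbox_inches="tight")
    except Exception as e:
        log.warning("sensitivity plot skipped: %s", e)
    log.info("pipeline complete (%.1fs)", time.time() - t0)

    report = _round_floats(report)
    (out / "report.json").write_text(
        json.dumps(report, sort_keys=True, indent=2) + "\n"
    )
    return report
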