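"""Descriptive tables: per-level mastectomy rates, univariate risk ratios
and chi-square trend tests, in the layout of a registry characteristics
table (one block per variable, an "NA" row where missingness occurs).

Risk ratios are unconditional maximum-likelihood estimates — the ratio of
the observed mastectomy proportions — with log-Wald 95% confidence
intervals:

    RR = (a / n1) / (b / n0),
    CI = exp( log RR ± 1.96 · sqrt(1/a − 1/n1 + 1/b − 1/n0) ),

where a of n1 level cases and b of n0 reference cases underwent mastectomy.
Trend across ordered levels uses the Cochran–Armitage chi-square test for
trend (1 df) with consecutive integer scores by default; "NA" levels are
excluded from trends but reported as their own risk-ratio rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .cohort import (
    AGE_GROUPS,
    Cohort,
    GRADES,
    MOLECULAR_GROUPS,
    NODES_GROUPS,
    SIZE_GROUPS,
    STAGES,
)

__all__ = [
    "LevelSummary",
    "CategorySummary",
    "risk_ratio",
    "summarize",
    "trend_test",
    "CANONICAL_LEVELS",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile

#: canonical display/order for the standard variables (others are sorted)
CANONICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "stage": STAGES,
    "grade": GRADES,
    "age_group": AGE_GROUPS,
    "size_group": SIZE_GROUPS,
    "nodes_group": NODES_GROUPS,
    "molecular_status": MOLECULAR_GROUPS,
    "behavior": ("in_situ", "invasive"),
}


@dataclass
class LevelSummary:
    level: str
    n: int
    n_mastectomy: int
    pct: float
    risk_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    is_reference: bool
    rr_defined: bool = True


@dataclass
class CategorySummary:
    variable: str
    reference_level: str
    levels: list[LevelSummary]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "variable": self.variable,
                    "level": l.level,
                    "n": l.n,
                    "n_mastectomy": l.n_mastectomy,
                    "pct": l.pct,
                    "risk_ratio": l.risk_ratio,
                    "ci_low": l.ci_low,
                    "ci_high": l.ci_high,
                    "reference": l.is_reference,
                }
                for l in self.levels
            ]
        )


def risk_ratio(a: int, n1: int, b: int, n0: int) -> tuple[float, float, float]:
    """Unconditional-ML risk ratio of level (a/n1) versus reference (b/n0)
    with a log-Wald 95% CI.  Requires events in both groups for the CI;
    zero events in the reference make the ratio undefined (ValueError)."""
    if min(n1, n0) <= 0:
        raise ValueError("both groups must be non-empty")
    if b == 0:
        raise ValueError("zero events in the reference level: RR undefined")
    rr = (a / n1) / (b / n0)
    if a == 0:
        return rr, float("nan"), float("nan")
    se = math.sqrt(1 / a - 1 / n1 + 1 / b - 1 / n0)
    return rr, rr * math.exp(-Z_95 * se), rr * math.exp(Z_95 * se)


def _level_order(variable: str, observed: Sequence[str]) -> list[str]:
    canon = CANONICAL_LEVELS.get(variable)
    if canon is None:
        ordered = sorted(set(observed))
        if "NA" in ordered:  # NA row last
            ordered.remove("NA")
            ordered.append("NA")
        return ordered
    return [l for l in canon if l in set(observed)]


def summarize(cohort: Cohort, variable: str, reference_level: str) -> CategorySummary:
    """Per-level counts, mastectomy percentages and risk ratios versus the
    reference level for one categorical variable."""
    values = cohort.variable(variable)
    m = cohort.mastectomy
    levels = _level_order(variable, values.unique())
    if reference_level not in levels:
        raise ValueError(
            f"reference level {reference_level!r} not observed for {variable!r}"
        )
    ref_mask = (values == reference_level).to_numpy()
    n0 = int(ref_mask.sum())
    b = int(m[ref_mask].sum())
    out: list[LevelSummary] = []
    for level in levels:
        mask = (values == level).to_numpy()
        n1 = int(mask.sum())
        a = int(m[mask].sum())
        pct = a / n1 if n1 else float("nan")
        if level == reference_level:
            out.append(LevelSummary(level, n1, a, pct, 1.0, None, None, True))
            continue
        try:
            rr, lo, hi = risk_ratio(a, n1, b, n0)
            defined = True
            lo = None if math.isnan(lo) else lo
            hi = None if math.isnan(hi) else hi
        except ValueError:
            rr = lo = hi = None
            defined = False
        out.append(LevelSummary(level, n1, a, pct, rr, lo, hi, False, defined))
    assert sum(l.n for l in out) == len(cohort)
    return CategorySummary(variable, reference_level, out)


def trend_test(
    cohort: Cohort,
    variable: str,
    levels: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> tuple[float, float]:
    """Cochran–Armitage chi-square test for trend in mastectomy proportions
    across ordered levels (1 df).

    ``levels`` defaults to the canonical order with "NA" excluded; ``scores``
    default to consecutive integers.  Returns ``(chi2, p)``.  With two
    levels the statistic reduces to the ordinary Pearson chi-square.
    """
    values = cohort.variable(variable)
    m = cohort.mastectomy
    if levels is None:
        levels = [l for l in _level_order(variable, values.unique()) if l != "NA"]
    levels = list(levels)
    if len(levels) < 2:
        raise ValueError("trend test needs at least two ordered levels")
    s = (
        np.asarray(scores, dtype=float)
        if scores is not None
        else np.arange(1.0, len(levels) + 1.0)
    )
    if len(s) != len(levels):
        raise ValueError("scores must align with levels")
    n_i = np.array([(values == l).sum() for l in levels], dtype=float)
    y_i = np.array([int(m[(values == l).to_numpy()].sum()) for l in levels], dtype=float)
    if (n_i == 0).any():
        raise ValueError("every trend level must be non-empty")
    n = n_i.sum()
    pbar = y_i.sum() / n
    if pbar in (0.0, 1.0):
        raise ValueError("degenerate table: all or no cases had mastectomy")
    t = float(np.sum(s * (y_i - n_i * pbar)))
    var = pbar * (1 - pbar) * (np.sum(n_i * s**2) - np.sum(n_i * s) ** 2 / n)
    if var <= 0:
        raise ValueError("degenerate scores: zero trend variance")
    chi2 = t * t / var
    p = float(chi2_dist.sf(chi2, df=1))
    return float(chi2), p
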