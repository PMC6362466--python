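"""Fill-up partial-identification bounds on the rate of mastectomy for
overdiagnosed breast cancer.

The estimand is Pr(M, V): the proportion of the full study population that
was both overdiagnosed (V) and treated by total mastectomy (M).  Under the
exchangeability assumption — conditional on observed characteristics X, the
probability of mastectomy is the same for overdiagnosed and
non-overdiagnosed cases — the estimand is

    Pr(M, V) = sum_i Pr(M | X = x_i) Pr(V | X = x_i) Pr(X = x_i),

where the sum runs over the cases not ruled out from being overdiagnoses,
Pr(M | X) comes from the propensity model and Pr(X = x_i) = 1/n_total for
each observed case.  Only Pr(V | X = x_i) is unknown.  Fixing the overall
overdiagnosis proportion q constrains the per-case Pr(V | X) weights to lie
in [0, 1] and sum to m = q * n_total; the extreme values of the linear
functional above are attained by "filling up" the overdiagnosed group with
the cases of smallest (lower bound) or largest (upper bound) propensity.

The implementation uses the fractional (linear-programming) form of the
fill-up: when m is not an integer the marginal case enters with fractional
weight, which makes the curve continuous in q, renders tie-breaking between
equal propensities irrelevant, and coincides with the integer assignment up
to O(1/n).  Everything here is a large-sample plug-in: with cohorts of tens
of thousands of cases the sampling error of the plug-in is negligible next
to the width of the identification interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BoundsInterval",
    "BoundsCurve",
    "rescale_q",
    "bound_overtreatment",
    "bounds_curve",
    "q_max_from_incidence",
    "age_standardize",
    "round_outward",
]

_EPS = 1e-9


@dataclass(frozen=True)
class BoundsInterval:
    """Lower/upper bound on Pr(M, V) at one assumed overdiagnosis proportion.

    ``q_total`` is the assumed fraction of the *full* study population that
    was overdiagnosed; ``q_eligible`` is the same quantity rescaled to the
    eligible (not-ruled-out) subset.  ``lower`` and ``upper`` are fractions
    of the full study population.
    """

    q_total: float
    q_eligible: float
    lower: float
    upper: float

    def __post_init__(self):
        if not (-_EPS <= self.lower <= self.upper + _EPS):
            raise ValueError(f"invalid interval [{self.lower}, {self.upper}]")

    def rounded_pct(self) -> tuple[int, int]:
        """Outward-rounded integer-percent version of the interval."""
        return round_outward(100.0 * self.lower, 100.0 * self.upper)


class BoundsCurve:
    """A grid of :class:`BoundsInterval` indexed by q_total."""

    def __init__(self, intervals: Sequence[BoundsInterval]):
        self.intervals = list(intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[BoundsInterval]:
        return iter(self.intervals)

    def __getitem__(self, i) -> BoundsInterval:
        return self.intervals[i]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for iv in self.intervals:
            lo_pct, hi_pct = iv.rounded_pct()
            rows.append(
                {
                    "q": iv.q_total,
                    "q_eligible": iv.q_eligible,
                    "lower": iv.lower,
                    "upper": iv.upper,
                    "lower_pct_rounded": lo_pct,
                    "upper_pct_rounded": hi_pct,
                }
            )
        return pd.DataFrame(rows)


def rescale_q(q_total: float, n_total: int, n_eligible: int) -> float:
    """Rescale an overdiagnosis proportion from the full study population to
    the eligible subset.

    If a fraction ``q_total`` of all cases are overdiagnosed and only
    ``n_eligible / n_total`` of cases remain after the rule-out step, then
    ``q_total * n_total / n_eligible`` of the remaining cases are
    overdiagnosed (e.g. 30% of the cohort with 75% eligible gives 40% of the
    eligible cases).

    Raises ``ValueError`` when the implied eligible-subset proportion
    exceeds 1, i.e. the assumed amount of overdiagnosis is inconsistent with
    the rule-out criteria.
    """
    if not 0.0 <= q_total <= 1.0:
        raise ValueError(f"q_total must be in [0, 1], got {q_total}")
    if n_eligible > n_total:
        raise ValueError("n_eligible cannot exceed n_total")
    if q_total == 0.0:
        return 0.0
    if n_eligible == 0:
        raise ValueError(
            "assumed overdiagnosis proportion inconsistent with rule-out "
            "criteria: no eligible cases remain"
        )
    q_eligible = q_total * n_total / n_eligible
    if q_eligible > 1.0 + _EPS:
        raise ValueError(
            f"assumed overdiagnosis proportion inconsistent with rule-out "
            f"criteria: q_total={q_total} implies {q_eligible:.4f} of the "
            f"eligible subset"
        )
    return min(q_eligible, 1.0)


def _fillup_sum(p_sorted: np.ndarray, m: float) -> float:
    """Sum of the first floor(m) entries plus a fractional share of the
    next; ``p_sorted`` may be in ascending (lower bound) or descending
    (upper bound) order."""
    n = len(p_sorted)
    k = int(math.floor(m + _EPS))
    k = min(k, n)
    frac = m - k
    total = float(p_sorted[:k].sum())
    if frac > _EPS and k < n:
        total += frac * float(p_sorted[k])
    return total


def bound_overtreatment(
    p: np.ndarray | Sequence[float], n_total: int, q_total: float
) -> BoundsInterval:
    """Fill-up bounds on Pr(M, V) at one overdiagnosis proportion.

    Parameters
    ----------
    p
        Propensities Pr(M | X = x_i) of the *eligible* cases (cases not
        ruled out from being overdiagnosed).
    n_total
        Size of the full study population (eligible + ruled-out).
    q_total
        Assumed proportion of the full study population overdiagnosed.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-d array of propensities")
    if len(p) and (p.min() < -_EPS or p.max() > 1 + _EPS):
        raise ValueError("propensities must lie in [0, 1]")
    if n_total < len(p):
        raise ValueError("n_total cannot be smaller than the eligible count")
    q_eligible = rescale_q(q_total, n_total, len(p))
    m = q_total * n_total  # == q_eligible * n_eligible
    m = min(m, float(len(p)))
    p_sorted = np.sort(p)
    lower = _fillup_sum(p_sorted, m) / n_total
    upper = _fillup_sum(p_sorted[::-1], m) / n_total
    return BoundsInterval(q_total=q_total, q_eligible=q_eligible,
                          lower=lower, upper=upper)


def bounds_curve(
    p: np.ndarray | Sequence[float], n_total: int, q_grid: Iterable[float]
) -> BoundsCurve:
    """Fill-up bounds over a grid of overdiagnosis proportions.

    Every grid point must be feasible (``q * n_total <= n_eligible``).  Both
    endpoints of the resulting curve are non-decreasing and 1-Lipschitz in
    q, and the curve passes through (0, 0).
    """
    return BoundsCurve([bound_overtreatment(p, n_total, q) for q in q_grid])


def q_max_from_incidence(rate_early: float, rate_late: float) -> float:
    """Ceiling on the overdiagnosis proportion from an incidence trend.

    If the incidence of non-overdiagnosed cancer has been constant or rising
    between a pre-screening era and the study year, and screening accounts
    for essentially all overdiagnosis, then the overdiagnosed share of
    current cases can be at most the relative increase in (age-standardized)
    incidence: ``1 - rate_early / rate_late``.
    """
    if rate_early <= 0 or rate_late <= 0:
        raise ValueError("incidence rates must be positive")
    if rate_late < rate_early:
        raise ValueError(
            "late-period incidence below early-period incidence implies a "
            "negative overdiagnosis ceiling"
        )
    return 1.0 - rate_early / rate_late


def age_standardize(
    age_specific_rates: Sequence[float], standard_weights: Sequence[float]
) -> float:
    """Directly age-standardized rate: weight-normalised mean of
    age-specific rates against a standard population."""
    rates = np.asarray(age_specific_rates, dtype=float)
    w = np.asarray(standard_weights, dtype=float)
    if rates.shape != w.shape:
        raise ValueError("rates and weights must align")
    if (w < 0).any():
        raise ValueError("standard-population weights must be non-negative")
    if w.sum() <= 0:
        raise ValueError("standard-population weights must not all be zero")
    return float(np.average(rates, weights=w))


def round_outward(lower_pct: float, upper_pct: float) -> tuple[int, int]:
    """Round a percentage interval outward to whole percents (floor the
    lower endpoint, ceil the upper), the conservative direction for
    reporting identification bounds.  E.g. (5.6, 12.4) -> (5, 13)."""
    if lower_pct > upper_pct + _EPS:
        raise ValueError("lower endpoint exceeds upper endpoint")
    # snap away float fuzz so that e.g. 7.000000001 still rounds to 7
    lo = math.floor(round(lower_pct, 9))
    hi = math.ceil(round(upper_pct, 9))
    return int(lo), int(hi)
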