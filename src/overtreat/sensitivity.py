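"""Omitted-variable sensitivity analysis for the fill-up bounds.

The main analysis trusts the fitted propensities Pr(M | X).  Variables the
registry does not record (symptoms, family history, screening history,
BRCA status) and informative missingness could make the *true* conditional
mastectomy probabilities more spread out than the fitted ones, even if the
fit is unbiased on average.  The sensitivity analysis widens the bounds
against the worst such distortion, governed by a single parameter: the
largest odds ratio Λ by which omitted information can shift any case's
mastectomy probability.

Adversary's move (a reconstruction of this class of analysis): replace each
propensity p_i by any p*_i with

    |logit p*_i − logit p_i| ≤ log Λ        (per-case odds-ratio cap)
    Σ p*_i = Σ p_i                          (calibration in the large)

and recompute the fill-up bound on the perturbed propensities; the upper
bound is maximised and the lower bound minimised over the adversary's
choices.  The calibration constraint encodes "predictions are not
systematically biased, but their variance may be understated"; the global
(rather than per-decile) reading of calibration is the weakest and hence
most conservative one.  Λ = 1 pins p* = p and reduces exactly to the main
analysis; intervals are nested and widen monotonically in Λ.

The optimum is computed by a water-filling argument.  Because all cases are
shifted on the logit scale by the same cap, the per-case feasible boxes
[lo_i, hi_i] are ordered the same way as the p_i themselves, and the
extremal perturbation has a simple structure: to inflate the upper bound
the adversary pushes the m highest-propensity cases up to their caps,
funding the increase by pushing low-propensity cases down (mass that the
fill-up never counts), with at most one case strictly between its bounds.
The test suite verifies the water-filling optimum against an exhaustive
linear-programming oracle on small instances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit, logit

from .bounds import BoundsCurve, BoundsInterval, rescale_q

__all__ = ["SensitivityParams", "sensitive_bounds", "sensitivity_sweep"]

_EPS = 1e-9


@dataclass(frozen=True)
class SensitivityParams:
    """Sensitivity-analysis configuration.

    ``odds_ratio`` is Λ, the largest factor by which omitted variables and
    missing data can change any case's odds of mastectomy; Λ = 1 recovers
    the main analysis.
    """

    odds_ratio: float = 1.0
    calibration_preserved: bool = True

    def __post_init__(self):
        if self.odds_ratio < 1.0:
            raise ValueError("sensitivity odds ratio must be >= 1")
        if not self.calibration_preserved:
            raise ValueError(
                "only the calibration-preserving analysis is defined; an "
                "uncalibrated adversary would make the bounds vacuous"
            )


def _logit_box(p: np.ndarray, log_or: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-case feasible interval under a log-odds shift of at most
    ``log_or`` in either direction.  Degenerate propensities 0 and 1 are
    fixed points of any odds-ratio shift."""
    with np.errstate(divide="ignore"):
        lg = logit(np.clip(p, 0.0, 1.0))
    lo = np.where(p <= 0.0, 0.0, np.where(p >= 1.0, 1.0, expit(lg - log_or)))
    hi = np.where(p <= 0.0, 0.0, np.where(p >= 1.0, 1.0, expit(lg + log_or)))
    return lo, hi


def _max_topm(start: np.ndarray, lo: np.ndarray, hi: np.ndarray, m: float) -> float:
    """Maximum of (sum of the largest floor(m) entries + frac * next) over
    vectors x with lo <= x <= hi and sum(x) = sum(start).

    Requires the boxes to be co-ordered with ``start`` (sorting by start
    also sorts lo and hi), which holds for a common logit shift.  Runs the
    water-filling scheme described in the module docstring.
    """
    n = len(start)
    if n == 0 or m <= _EPS:
        return 0.0
    order = np.argsort(-start, kind="stable")
    s, l, h = start[order], lo[order], hi[order]
    m = min(m, float(n))
    k = int(math.floor(m + _EPS))
    frac = m - k
    if frac <= _EPS:
        frac = 0.0
    base = float(s[:k].sum()) + (frac * float(s[k]) if frac and k < n else 0.0)
    if k == n:  # every case is counted: the calibration constraint fixes the sum
        return base

    frac_idx = k if frac else None
    zero_from = k + 1 if frac else k

    cap_up_full = float((h[:k] - s[:k]).sum())
    cap_dn_zero = float((s[zero_from:] - l[zero_from:]).sum())

    # 1) raise fully-counted cases, funded by uncounted cases (gain 1/unit)
    t1 = min(cap_up_full, cap_dn_zero)
    gain = t1
    rem_up = cap_up_full - t1
    rem_dn = cap_dn_zero - t1
    if frac_idx is not None:
        if rem_up > _EPS:
            # 2a) uncounted cases exhausted: fund remaining raises by
            # lowering the fractionally-counted case (gain 1 - frac)
            t2 = min(rem_up, float(s[frac_idx] - l[frac_idx]))
            gain += t2 * (1.0 - frac)
        elif rem_dn > _EPS:
            # 2b) counted cases capped: spend leftover uncounted mass on the
            # fractionally-counted case (gain frac)
            t3 = min(float(h[frac_idx] - s[frac_idx]), rem_dn)
            gain += t3 * frac
    return base + gain


def sensitive_bounds(
    p: np.ndarray | Sequence[float],
    n_total: int,
    q_total: float,
    params: SensitivityParams,
) -> BoundsInterval:
    """Fill-up bounds widened against the worst Λ-bounded omitted-variable
    distortion of the eligible propensities.

    Reduces exactly to :func:`overtreat.bounds.bound_overtreatment` at
    Λ = 1; the returned interval always nests the Λ = 1 interval and stays
    within [0, q_total].
    """
    p = np.asarray(p, dtype=float)
    if len(p) and (p.min() < -_EPS or p.max() > 1 + _EPS):
        raise ValueError("propensities must lie in [0, 1]")
    q_eligible = rescale_q(q_total, n_total, len(p))
    m = min(q_total * n_total, float(len(p)))
    log_or = math.log(params.odds_ratio)
    lo, hi = _logit_box(p, log_or)
    upper = _max_topm(p, lo, hi, m) / n_total
    # the minimised lower bound is the negated mirror problem
    lower = -_max_topm(-p, -hi, -lo, m) / n_total
    lower = max(lower, 0.0)
    return BoundsInterval(q_total=q_total, q_eligible=q_eligible,
                          lower=lower, upper=min(upper, q_total))


def sensitivity_sweep(
    p: np.ndarray | Sequence[float],
    n_total: int,
    q_grid: Iterable[float],
    lambdas: Iterable[float],
) -> dict[float, BoundsCurve]:
    """One bounds curve per sensitivity odds ratio Λ; curves are nested and
    widen monotonically in Λ."""
    q_grid = list(q_grid)
    out: dict[float, BoundsCurve] = {}
    for lam in lambdas:
        params = SensitivityParams(odds_ratio=lam)
        out[lam] = BoundsCurve(
            [sensitive_bounds(p, n_total, q, params) for q in q_grid]
        )
    return out
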