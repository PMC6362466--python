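"""Independent brute-force/LP oracles for the fill-up and sensitivity
bounds, kept deliberately naive (exhaustive enumeration and generic linear
programming) so they share no code path with the implementation."""

import itertools

import numpy as np
from scipy.optimize import linprog


def enumeration_bounds(p, n_total, m):
    """Min/max over all size-m subsets of sum(subset)/n_total (integer m)."""
    p = np.asarray(p, float)
    sums = [sum(c) for c in itertools.combinations(p, m)]
    return min(sums) / n_total, max(sums) / n_total


def lp_fillup_bounds(p, n_total, m):
    """Optimum of min/max sum(w_i p_i) with 0 <= w_i <= 1 and sum w = m."""
    p = np.asarray(p, float)
    n = len(p)
    a_eq, b_eq = [np.ones(n)], [m]
    bounds = [(0.0, 1.0)] * n
    lo = linprog(p, A_eq=a_eq, b_eq=b_eq, bounds=bounds, method="highs")
    hi = linprog(-p, A_eq=a_eq, b_eq=b_eq, bounds=bounds, method="highs")
    assert lo.status == 0 and hi.status == 0
    return lo.fun / n_total, -hi.fun / n_total


def lp_sensitivity_bounds(p, n_total, m, odds_ratio):
    """Joint adversary-plus-fill-up optimum by exhaustive enumeration of the
    fill-up weight supports and one LP per support.

    The adversary may move each propensity within its odds-ratio box while
    preserving the total; for each candidate set of counted cases the inner
    problem is linear in the perturbed propensities.
    """
    from scipy.special import expit, logit

    p = np.asarray(p, float)
    n = len(p)
    log_or = np.log(odds_ratio)
    lo_box = expit(logit(p) - log_or)
    hi_box = expit(logit(p) + log_or)
    c_sum = p.sum()
    k = int(np.floor(m + 1e-12))
    frac = m - k
    best_hi, best_lo = -np.inf, np.inf
    for s in itertools.combinations(range(n), k):
        rest = [j for j in range(n) if j not in s]
        marginals = rest if (frac > 1e-12 and k < n) else [None]
        for j in marginals:
            w = np.zeros(n)
            w[list(s)] = 1.0
            if j is not None:
                w[j] = frac
            box = list(zip(lo_box, hi_box))
            r = linprog(-w, A_eq=[np.ones(n)], b_eq=[c_sum], bounds=box,
                        method="highs")
            if r.status == 0:
                best_hi = max(best_hi, -r.fun)
            r = linprog(w, A_eq=[np.ones(n)], b_eq=[c_sum], bounds=box,
                        method="highs")
            if r.status == 0:
                best_lo = min(best_lo, r.fun)
    return best_lo / n_total, best_hi / n_total


def permutation_trend_pvalue(counts, events, scores, n_perm, rng):
    """Two-sided permutation p-value for the linear trend statistic
    sum(scores * events per level) under random relabelling of outcomes."""
    counts = np.asarray(counts, int)
    events = np.asarray(events, int)
    scores = np.asarray(scores, float)
    labels = np.repeat(scores, counts)
    y = np.concatenate([
        np.r_[np.ones(e), np.zeros(c - e)] for c, e in zip(counts, events)
    ])
    obs = abs(np.sum(labels * (y - y.mean())))
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(y)
        if abs(np.sum(labels * (perm - perm.mean()))) >= obs - 1e-12:
            hits += 1
    return hits / n_perm
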