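"""Out-of-sample propensity-of-mastectomy estimation and its diagnostics.

Each case needs an estimate of Pr(M | X = x_i), the probability of total
mastectomy given its observed characteristics.  With dozens of categorical
covariates a cross-table is hopelessly sparse, so the probabilities are
estimated by regression.  Two honesty mechanisms keep the estimate for case
i from using case i's own outcome:

* random forests use their out-of-bag (OOB) predictions — each case is
  scored only by the trees whose bootstrap sample did not contain it;
* other model families are cross-fitted: the cohort is split into K folds
  and each fold is predicted by a model trained on the other K-1.

Fold membership for cross-fitting is drawn independently of the outcomes
(plain shuffled K-fold, not stratified), so shuffling the outcomes of a
held-out fold provably cannot change its predictions — a property the test
suite exercises as a data-leak canary.

Categorical covariates are one-hot encoded with "NA" kept as a level of its
own; levels unseen at fit time are mapped to "NA" at predict time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold

from .cohort import Cohort

__all__ = [
    "ModelSpec",
    "PropensityEstimates",
    "CategoricalEncoder",
    "fit_and_predict",
    "brier_score",
    "c_statistic",
    "calibration_curve",
    "diagnostics",
]


@dataclass
class ModelSpec:
    """Propensity model configuration.

    The random-forest defaults are the untuned reference settings: 2500
    trees, sqrt(#variables) tried per split, Gini splitting, leaf size 1.
    ``max_random_splits`` records the companion cap on random splits for
    multi-level variables used by some forest implementations; the forest
    backend used here splits one-hot indicators exhaustively, so the cap is
    retained in the descriptor for provenance but has no effect.
    """

    model_family: str = "random_forest"  # random_forest | logistic | oracle
    n_trees: int = 2500
    mtry: str = "sqrt"
    min_leaf: int = 1
    max_random_splits: int = 25
    n_folds: int = 5
    seed: int = 0
    oracle: object | None = None  # SyntheticConfig, for model_family="oracle"

    def describe(self) -> dict:
        d = {
            "model_family": self.model_family,
            "seed": self.seed,
        }
        if self.model_family == "random_forest":
            d.update(
                n_trees=self.n_trees,
                mtry=self.mtry,
                min_leaf=self.min_leaf,
                split_rule="gini",
                max_random_splits=self.max_random_splits,
            )
        elif self.model_family == "logistic":
            d.update(n_folds=self.n_folds)
        return d


@dataclass
class PropensityEstimates:
    """Per-case out-of-sample estimates of Pr(M | X = x_i)."""

    case_ids: list[str]
    p_hat: np.ndarray
    tags: list[str]
    model: dict = field(default_factory=dict)

    def __post_init__(self):
        self.p_hat = np.asarray(self.p_hat, dtype=float)
        if not (len(self.case_ids) == len(self.p_hat) == len(self.tags)):
            raise ValueError("case_ids, p_hat and tags must align")
        if len(self.p_hat) and (self.p_hat.min() < 0 or self.p_hat.max() > 1):
            raise ValueError("p_hat must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.p_hat)

    def align(self, case_ids: Sequence[str]) -> np.ndarray:
        """Propensities for a subset of cases, in the subset's order."""
        index = pd.Index(self.case_ids)
        locs = index.get_indexer(list(case_ids))
        if (locs < 0).any():
            missing = [c for c, l in zip(case_ids, locs) if l < 0][:3]
            raise KeyError(f"no propensity estimate for case(s) {missing}")
        return self.p_hat[locs]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"case_id": self.case_ids, "p_hat": self.p_hat, "tag": self.tags}
        )


class CategoricalEncoder:
    """One-hot encoder with "NA" as an explicit level and unseen-level
    fallback to "NA"."""

    def __init__(self):
        self.levels_: dict[str, list[str]] = {}

    def fit(self, frame: pd.DataFrame) -> "CategoricalEncoder":
        self.levels_ = {}
        for col in frame.columns:
            levels = sorted(frame[col].astype(str).unique())
            if "NA" not in levels:
                levels.append("NA")
            self.levels_[col] = levels
        return self

    def transform(self, frame: pd.DataFrame) -> np.ndarray:
        if not self.levels_:
            raise RuntimeError("encoder not fitted")
        blocks = []
        for col, levels in self.levels_.items():
            s = frame[col].astype(str)
            s = s.where(s.isin(levels), "NA")
            cat = pd.Categorical(s, categories=levels)
            blocks.append(pd.get_dummies(cat, dtype=np.float64).to_numpy())
        return np.hstack(blocks)

    def fit_transform(self, frame: pd.DataFrame) -> np.ndarray:
        return self.fit(frame).transform(frame)

    @property
    def feature_names_(self) -> list[str]:
        return [f"{c}={l}" for c, ls in self.levels_.items() for l in ls]


def fit_and_predict(cohort: Cohort, spec: ModelSpec | None = None) -> PropensityEstimates:
    """Fit the propensity model and return honest per-case estimates.

    Deterministic given ``spec.seed``.  Raises ``ValueError`` when the
    cohort's outcome is single-class (no model can be fit).
    """
    spec = spec if spec is not None else ModelSpec()
    y = cohort.mastectomy
    ids = list(cohort.case_ids)

    if spec.model_family == "oracle":
        if spec.oracle is None:
            raise ValueError("oracle family requires spec.oracle (a SyntheticConfig)")
        from .simulate import true_propensities

        return true_propensities(cohort, spec.oracle)

    if len(np.unique(y)) < 2:
        raise ValueError("cohort outcome is single-class; cannot fit a model")

    X = CategoricalEncoder().fit_transform(cohort.covariate_frame())

    if spec.model_family == "random_forest":
        clf = RandomForestClassifier(
            n_estimators=spec.n_trees,
            criterion="gini",
            max_features="sqrt" if spec.mtry == "sqrt" else spec.mtry,
            min_samples_leaf=spec.min_leaf,
            bootstrap=True,
            oob_score=True,
            random_state=spec.seed,
            n_jobs=1,
        )
        clf.fit(X, y)
        pos = list(clf.classes_).index(True)
        p = clf.oob_decision_function_[:, pos]
        # a case never out of bag has no OOB score; fall back to the full
        # forest for those (vanishingly rare beyond a few dozen trees)
        bad = ~np.isfinite(p)
        if bad.any():
            p[bad] = clf.predict_proba(X[bad])[:, pos]
        tags = ["oob"] * len(p)
    elif spec.model_family == "logistic":
        p = np.full(len(y), np.nan)
        tags = [""] * len(y)
        kf = KFold(n_splits=spec.n_folds, shuffle=True, random_state=spec.seed)
        for k, (train, test) in enumerate(kf.split(X)):
            if len(np.unique(y[train])) < 2:
                raise ValueError(f"fold {k}: training outcome single-class")
            clf = LogisticRegression(max_iter=2000)
            clf.fit(X[train], y[train])
            pos = list(clf.classes_).index(True)
            p[test] = clf.predict_proba(X[test])[:, pos]
            for i in test:
                tags[i] = f"crossfit fold {k}"
        assert np.isfinite(p).all()
    else:
        raise ValueError(f"unknown model family {spec.model_family!r}")

    return PropensityEstimates(
        case_ids=ids, p_hat=np.clip(p, 0.0, 1.0), tags=tags, model=spec.describe()
    )


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def _align(estimates, outcomes) -> tuple[np.ndarray, np.ndarray]:
    p = estimates.p_hat if isinstance(estimates, PropensityEstimates) else np.asarray(
        estimates, dtype=float
    )
    y = np.asarray(outcomes, dtype=float)
    if p.shape != y.shape:
        raise ValueError("estimates and outcomes must have equal length")
    return p, y


def brier_score(estimates, outcomes) -> float:
    """Mean squared error of the predicted probabilities against the 0/1
    outcomes; 0 is perfect, 0.25 is the score of a constant 0.5."""
    p, y = _align(estimates, outcomes)
    return float(np.mean((p - y) ** 2))


def c_statistic(estimates, outcomes) -> float:
    """Area under the ROC curve: the probability that a randomly chosen
    mastectomy case is ranked above a randomly chosen non-mastectomy case,
    ties counted one half."""
    p, y = _align(estimates, outcomes)
    if len(np.unique(y)) < 2:
        raise ValueError("c-statistic requires both outcome classes")
    return float(roc_auc_score(y, p))


def calibration_curve(estimates, outcomes, n_bins: int = 10) -> pd.DataFrame:
    """Reliability table over predicted-probability quantile bins.

    Returns one row per non-empty bin with the mean prediction, the
    observed outcome rate and the case count; counts sum to n.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    p, y = _align(estimates, outcomes)
    edges = np.quantile(p, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 2:  # constant predictions: one bin
        idx = np.zeros(len(p), dtype=int)
    else:
        idx = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, len(edges) - 2)
    rows = []
    for b in range(idx.max() + 1 if len(p) else 0):
        sel = idx == b
        if not sel.any():
            continue
        rows.append(
            {
                "bin": b,
                "mean_p_hat": float(p[sel].mean()),
                "observed_rate": float(y[sel].mean()),
                "count": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)


def diagnostics(estimates, outcomes, n_bins: int = 10) -> dict:
    """Brier score, c-statistic and calibration table in one report."""
    p, y = _align(estimates, outcomes)
    return {
        "n": int(len(p)),
        "outcome_rate": float(y.mean()) if len(y) else float("nan"),
        "mean_p_hat": float(p.mean()) if len(p) else float("nan"),
        "brier": brier_score(p, y),
        "c_statistic": c_statistic(p, y) if len(np.unique(y)) > 1 else None,
        "calibration": calibration_curve(p, y, n_bins).to_dict("records"),
    }
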