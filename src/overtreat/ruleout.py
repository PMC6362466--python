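"""Rule-out criteria: partition a cohort into cases that cannot have been
overdiagnosed and the remaining eligible set.

A case is ruled out from being overdiagnosed if it shows any characteristic
that marks aggressive or advanced disease which would quickly become
clinically evident without screening: two or more invaded lymph nodes, a
tumor of at least 4 cm diameter, invasion of the pectoral fascia, muscle or
chest wall, skin invasion with ulceration (or invasion of adjacent skin), or
distant metastasis.  The criteria are deliberately conservative in the other
direction: a case with one positive node or a 2.0-3.9 cm tumor could still
(rarely) be an overdiagnosis, so it stays eligible, and an *unknown* size or
node count never rules a case out — misclassifying an overdiagnosis as a
non-overdiagnosis would invalidate the downstream bounds, whereas keeping a
non-overdiagnosis eligible merely widens them.

Stage is never tested directly: the rule-out operates on the underlying
measurements, so stage-IV disease is excluded through its distant-metastasis
flag and stage-NA cases remain eligible.

A histology restriction turns the criteria into "keep only DCIS" mode for
the ductal-carcinoma-in-situ sub-analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import CaseRecord, Cohort

__all__ = [
    "RuleOutCriteria",
    "RuleOutReport",
    "DCIS_HISTOLOGY_CODES",
    "dcis_criteria",
    "is_ruled_out",
    "ruled_out_mask",
    "apply_ruleout",
    "alternative_criteria_sweep",
]

#: ICD-O-3 histology codes defining ductal carcinoma in situ (together with
#: in situ behavior).
DCIS_HISTOLOGY_CODES = frozenset({8201, 8230, 8523} | set(range(8500, 8508)))


@dataclass(frozen=True)
class RuleOutCriteria:
    """Parameterised rule-out criteria.

    The defaults reproduce the standard criteria set; thresholds can be
    tightened for sensitivity sweeps (e.g. ``min_nodes_ruleout=1`` and/or
    ``min_size_cm_ruleout=3.0``).
    """

    min_nodes_ruleout: int = 2
    min_size_cm_ruleout: float = 4.0
    use_fascia_invasion: bool = True
    use_skin_ulceration: bool = True
    use_distant_metastasis: bool = True
    restrict_to_histologies: frozenset[int] | None = None
    restrict_behavior: str | None = None

    def __post_init__(self):
        if self.min_nodes_ruleout <= 0:
            raise ValueError("min_nodes_ruleout must be positive")
        if self.min_size_cm_ruleout <= 0:
            raise ValueError("min_size_cm_ruleout must be positive")

    def to_dict(self) -> dict:
        d = {
            "min_nodes_ruleout": self.min_nodes_ruleout,
            "min_size_cm_ruleout": self.min_size_cm_ruleout,
            "use_fascia_invasion": self.use_fascia_invasion,
            "use_skin_ulceration": self.use_skin_ulceration,
            "use_distant_metastasis": self.use_distant_metastasis,
        }
        if self.restrict_to_histologies is not None:
            d["restrict_to_histologies"] = sorted(self.restrict_to_histologies)
        if self.restrict_behavior is not None:
            d["restrict_behavior"] = self.restrict_behavior
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RuleOutCriteria":
        d = dict(d)
        if "restrict_to_histologies" in d and d["restrict_to_histologies"] is not None:
            d["restrict_to_histologies"] = frozenset(
                int(c) for c in d["restrict_to_histologies"]
            )
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RuleOutCriteria":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def dcis_criteria(base: RuleOutCriteria | None = None) -> RuleOutCriteria:
    """Criteria for the DCIS sub-analysis: rule out everything that is not
    ductal carcinoma in situ, on top of the base criteria."""
    base = base if base is not None else RuleOutCriteria()
    return replace(
        base,
        restrict_to_histologies=DCIS_HISTOLOGY_CODES,
        restrict_behavior="in_situ",
    )


def is_ruled_out(case: CaseRecord, criteria: RuleOutCriteria | None = None) -> bool:
    """True iff any enabled criterion is met.  ``None`` (unknown) field
    values never trigger the criterion that reads them."""
    c = criteria if criteria is not None else RuleOutCriteria()
    if case.nodes_positive is not None and case.nodes_positive >= c.min_nodes_ruleout:
        return True
    if case.tumor_size_cm is not None and case.tumor_size_cm >= c.min_size_cm_ruleout:
        return True
    if c.use_fascia_invasion and case.invades_fascia_muscle_chestwall is True:
        return True
    if c.use_skin_ulceration and case.skin_ulceration_or_adjacent_skin is True:
        return True
    if c.use_distant_metastasis and case.distant_metastasis is True:
        return True
    if c.restrict_to_histologies is not None:
        if case.histology_icdo3 not in c.restrict_to_histologies:
            return True
        if c.restrict_behavior is not None and case.behavior != c.restrict_behavior:
            return True
    return False


def _criterion_masks(cohort: Cohort, c: RuleOutCriteria) -> dict[str, np.ndarray]:
    f = cohort.frame
    nodes = f["nodes_positive"].to_numpy(float)
    size = f["tumor_size_cm"].to_numpy(float)
    masks = {
        "nodes": (~np.isnan(nodes)) & (nodes >= c.min_nodes_ruleout),
        "size": (~np.isnan(size)) & (size >= c.min_size_cm_ruleout),
    }
    if c.use_fascia_invasion:
        masks["fascia_invasion"] = (
            f["invades_fascia_muscle_chestwall"].fillna(False).to_numpy(bool)
        )
    if c.use_skin_ulceration:
        masks["skin_ulceration"] = (
            f["skin_ulceration_or_adjacent_skin"].fillna(False).to_numpy(bool)
        )
    if c.use_distant_metastasis:
        masks["distant_metastasis"] = f["distant_metastasis"].fillna(False).to_numpy(bool)
    if c.restrict_to_histologies is not None:
        bad = ~f["histology_icdo3"].isin(list(c.restrict_to_histologies)).to_numpy()
        if c.restrict_behavior is not None:
            bad |= (f["behavior"] != c.restrict_behavior).to_numpy()
        masks["histology_restriction"] = bad
    return masks


def ruled_out_mask(cohort: Cohort, criteria: RuleOutCriteria | None = None) -> np.ndarray:
    """Vectorised counterpart of :func:`is_ruled_out` over a whole cohort."""
    c = criteria if criteria is not None else RuleOutCriteria()
    masks = _criterion_masks(cohort, c)
    out = np.zeros(len(cohort), dtype=bool)
    for m in masks.values():
        out |= m
    return out


@dataclass
class RuleOutReport:
    n_input: int
    n_eligible: int
    n_excluded: int
    triggers: dict[str, int]

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_eligible": self.n_eligible,
            "n_excluded": self.n_excluded,
            "triggers": dict(self.triggers),
        }


def apply_ruleout(
    cohort: Cohort, criteria: RuleOutCriteria | None = None
) -> tuple[Cohort, Cohort, RuleOutReport]:
    """Split ``cohort`` into (eligible, excluded) under ``criteria``.

    The two parts are disjoint and their union is the input.  The report
    tallies, per criterion, how many cases triggered it (a case can trigger
    several).
    """
    c = criteria if criteria is not None else RuleOutCriteria()
    masks = _criterion_masks(cohort, c)
    out = np.zeros(len(cohort), dtype=bool)
    for m in masks.values():
        out |= m
    report = RuleOutReport(
        n_input=len(cohort),
        n_eligible=int((~out).sum()),
        n_excluded=int(out.sum()),
        triggers={k: int(m.sum()) for k, m in masks.items()},
    )
    return cohort.subset(~out), cohort.subset(out), report


def alternative_criteria_sweep(
    cohort: Cohort,
    criteria_list: Sequence[RuleOutCriteria],
    estimates,
    q_grid: Iterable[float],
) -> pd.DataFrame:
    """Recompute the bounds curve under each rule-out criteria set.

    ``estimates`` are propensity estimates for the *full* cohort (the fitted
    model does not change with the criteria); for each criteria set the
    eligible subset is re-derived and the fill-up bounds recomputed on its
    propensities.  Returns a long-format frame with columns
    ``criteria_index, n_eligible, q, lower, upper``.
    """
    from .bounds import bounds_curve  # local import to avoid a cycle

    if not criteria_list:
        raise ValueError("need at least one criteria set")
    q_grid = list(q_grid)
    n_total = len(cohort)
    rows = []
    for j, crit in enumerate(criteria_list):
        eligible, _, rep = apply_ruleout(cohort, crit)
        p = estimates.align(eligible.case_ids)
        curve = bounds_curve(p, n_total, q_grid)
        for iv in curve:
            rows.append(
                {
                    "criteria_index": j,
                    "n_eligible": rep.n_eligible,
                    "q": iv.q_total,
                    "lower": iv.lower,
                    "upper": iv.upper,
                }
            )
    return pd.DataFrame(rows)
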