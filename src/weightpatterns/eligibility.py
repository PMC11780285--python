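"""Cohort eligibility cascade and analysis-sample definitions.

The exclusion cascade removes, in order: platform testers and affiliated
staff (pseudo-members), employer-paid memberships, members living
overseas, members aged under 18, members with a starting BMI in the
underweight range (<18.5 kg/m^2), members with no recorded starting
weight, and members whose starting weight fails the validity cutoffs
(strictly below 13 kg or above 250 kg).  Each step's removal count is
logged in a :class:`FilterReport`.

Two nested analysis samples follow: *longer-term members* (baseline and
~12-week weigh-ins present, paid membership of at least a year) and the
*complete-case* subsample (weigh-ins present at every grid point).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._grid import TIME_POINTS, WEIGHT_VALID_MAX_KG, WEIGHT_VALID_MIN_KG
from .cohort import Cohort

__all__ = ["FilterReport", "apply_exclusions", "select_longer_term",
           "select_complete_case"]


@dataclass
class FilterReport:
    """Ordered log of (filter name, n removed, n remaining) steps."""

    steps: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, name: str, n_removed: int, n_remaining: int) -> None:
        if self.steps and n_remaining > self.steps[-1][2]:
            raise ValueError("n_remaining must be nonincreasing")
        self.steps.append((name, int(n_removed), int(n_remaining)))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([{"filter": n, "n_removed": r, "n_remaining": k}
                       for n, r, k in self.steps], fh, indent=2)

    def __iter__(self):
        return iter(self.steps)


def _exclusion_predicates(members: pd.DataFrame, baseline: pd.Series):
    """Each predicate marks the members a step removes."""
    start = members["start_weight_kg"]
    return [
        ("pseudo_member", members["pseudo_member"].to_numpy(bool)),
        ("employer_paid", members["employer_paid"].to_numpy(bool)),
        ("overseas", members["overseas"].to_numpy(bool)),
        ("underage", (members["age_years"] < 18).to_numpy()),
        ("underweight_bmi", (members["start_bmi"] < 18.5).fillna(False).to_numpy()),
        ("missing_start_weight", (start.isna() | baseline.isna()).to_numpy()),
        ("invalid_start_weight",
         ((start < WEIGHT_VALID_MIN_KG) | (start > WEIGHT_VALID_MAX_KG))
         .fillna(False).to_numpy()),
    ]


def apply_exclusions(cohort: Cohort) -> tuple[Cohort, FilterReport]:
    """Run the exclusion cascade; returns the filtered cohort and the log.

    The steps are independent predicates, so the final sample does not
    depend on their order; the per-step removal counts do.
    """
    members = cohort.members.reset_index(drop=True)
    baseline = (cohort.weights["baseline"]
                .reindex(members["member_id"].to_numpy())
                .reset_index(drop=True))
    keep = np.ones(len(members), dtype=bool)
    report = FilterReport()
    for name, removes in _exclusion_predicates(members, baseline):
        hit = keep & removes
        keep &= ~removes
        report.add(name, int(hit.sum()), int(keep.sum()))
    return cohort.subset(members.loc[keep, "member_id"]), report


def select_longer_term(cohort: Cohort, min_membership_days: int = 365,
                       w12_inclusion: pd.Series | None = None) -> Cohort:
    """Keep members with baseline and ~12-week weights and >=1 year paid.

    ``w12_inclusion`` optionally supplies a separate boolean flag (indexed
    by member_id) marking who met the 12-week inclusion weigh-in, allowing
    the 12-week *analysis* value to be treated as missing independently of
    inclusion; by default the analysis value itself must be present.
    """
    members = cohort.members
    w = cohort.weights.reindex(members["member_id"].to_numpy())
    has_w12 = (w12_inclusion.reindex(members["member_id"].to_numpy()).fillna(False)
               .to_numpy(bool)
               if w12_inclusion is not None else w["w12"].notna().to_numpy())
    keep = (w["baseline"].notna().to_numpy()
            & has_w12
            & (members["membership_days"] >= min_membership_days).to_numpy())
    return cohort.subset(members.loc[keep, "member_id"])


def select_complete_case(cohort: Cohort) -> Cohort:
    """Keep members observed at every one of the five grid points."""
    w = cohort.weights
    keep = w[list(TIME_POINTS)].notna().all(axis=1)
    return cohort.subset(w.index[keep])
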