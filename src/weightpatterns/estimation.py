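"""Three-way estimation comparison and engagement-outcome association.

The same outcome summaries (mean loss kg, mean %TBW loss, proportions
reaching 5% and 10% loss) are computed three ways: on multiply-imputed
data (via :mod:`weightpatterns.mi`), on whatever weigh-ins are available
at each time point, and on the complete-case subsample.  On a cohort with
no missing weigh-ins the three coincide.

Engagement is summarized as average weekly platform use (total activity
divided by weeks of paid membership) and related to 12-month loss with a
Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._grid import POST_BASELINE
from .cohort import Cohort
from .eligibility import select_complete_case
from .outcomes import weekly_use

__all__ = ["AssociationResult", "available_case_table", "complete_case_table",
           "subgroup_summaries", "engagement_association",
           "MEMBERSHIP_DURATION_BINS"]

#: default bins (days) for the duration-of-paid-membership subgrouping
MEMBERSHIP_DURATION_BINS = ((365, 547), (548, 730), (731, None))


@dataclass(frozen=True)
class AssociationResult:
    """Pearson association between weekly platform use and 12-month loss."""

    r: float
    n: int
    p_value: float
    threshold_groups: pd.DataFrame  # summary at the 30-uses/week cutpoint

    def __post_init__(self):
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("correlation must lie in [-1, 1]")


def _rows_for(weights: pd.DataFrame, members: pd.DataFrame, approach: str,
              stratum: str) -> list[dict]:
    rows = []
    for tp in POST_BASELINE:
        obs = weights[tp].notna() & weights["baseline"].notna()
        loss = (weights.loc[obs, "baseline"] - weights.loc[obs, tp]).to_numpy(float)
        base = weights.loc[obs, "baseline"].to_numpy(float)
        pct = 100.0 * loss / base
        n = int(obs.sum())
        row = {"approach": approach, "stratum": stratum, "time_point": tp, "n": n}
        if n:
            row.update({
                "mean_loss_kg": loss.mean(),
                "se_loss_kg": loss.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "mean_loss_pct": pct.mean(),
                "se_loss_pct": pct.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "prop_ge5": float(np.mean(pct >= 5.0)),
                "prop_ge10": float(np.mean(pct >= 10.0)),
            })
        else:
            row.update({k: np.nan for k in
                        ("mean_loss_kg", "se_loss_kg", "mean_loss_pct",
                         "se_loss_pct", "prop_ge5", "prop_ge10")})
        rows.append(row)
    return rows


def available_case_table(cohort: Cohort) -> pd.DataFrame:
    """Summaries over members observed at each time point."""
    return pd.DataFrame(_rows_for(cohort.weights, cohort.members,
                                  "available", "total"))


def complete_case_table(cohort: Cohort) -> pd.DataFrame:
    """Summaries over the subsample observed at every grid point."""
    cc = select_complete_case(cohort)
    return pd.DataFrame(_rows_for(cc.weights, cc.members, "complete", "total"))


def _membership_bin(days: pd.Series) -> pd.Series:
    def lab(d):
        for lo, hi in MEMBERSHIP_DURATION_BINS:
            if d >= lo and (hi is None or d <= hi):
                return f"{lo}-{hi}" if hi is not None else f">{lo - 1}"
        return "<365"
    return days.map(lab)


def _grouping(cohort: Cohort, group_by: str) -> pd.Series:
    members = cohort.members.set_index("member_id")
    if group_by == "membership_duration":
        return _membership_bin(members["membership_days"])
    if group_by == "weight_status":
        from .outcomes import bmi_class
        return pd.Series(bmi_class(members["start_bmi"].to_numpy(float)),
                         index=members.index)
    if group_by not in members.columns:
        raise KeyError(f"unknown grouping variable {group_by!r}")
    return members[group_by]


def subgroup_summaries(cohort: Cohort, group_by: str,
                       approaches: tuple[str, ...] = ("available", "complete"),
                       ) -> pd.DataFrame:
    """Per-stratum available/complete-case tables for a grouping variable.

    ``group_by`` is any member column plus the derived groupings
    ``weight_status`` (BMI class at start) and ``membership_duration``
    (binned days of paid membership).
    """
    groups = _grouping(cohort, group_by)
    rows = []
    for value in pd.unique(groups.dropna()):
        ids = groups.index[groups == value]
        sub = cohort.subset(ids)
        if "available" in approaches:
            rows += _rows_for(sub.weights, sub.members, "available", str(value))
        if "complete" in approaches:
            cc = select_complete_case(sub)
            rows += _rows_for(cc.weights, cc.members, "complete", str(value))
    out = pd.DataFrame(rows)
    out.insert(1, "group_by", group_by)
    return out


def engagement_association(cohort: Cohort, use_complete_case: bool = True,
                           threshold_per_week: float = 30.0) -> AssociationResult:
    """Pearson r between average weekly platform use and 12-month loss.

    By default computed on the complete-case subsample (the sample the
    pattern analyses use); with ``use_complete_case=False`` it uses every
    member with an available 12-month weigh-in.  Also summarizes the
    cohort split at the 30-uses-per-week cutpoint: group sizes, mean use,
    mean 12-month loss, and the share who lost weight in both of the
    first two 3-month blocks.
    """
    sub = select_complete_case(cohort) if use_complete_case else cohort
    w = sub.weights
    obs = w["m12"].notna() & w["baseline"].notna()
    ids = w.index[obs]
    loss12 = (w.loc[ids, "baseline"] - w.loc[ids, "m12"]).to_numpy(float)
    members = sub.members.set_index("member_id").loc[ids]
    total_act = sub.activity.groupby("member_id", observed=True)["total_activity"].sum()
    use = weekly_use(total_act.reindex(ids).fillna(0).to_numpy(float),
                     members["membership_days"].to_numpy(float))
    if np.std(use) == 0 or np.std(loss12) == 0:
        raise ValueError("zero variance in use or loss; correlation undefined")
    r, p = stats.pearsonr(use, loss12)

    hi = use >= threshold_per_week
    # losing in each of the first two blocks means both changes < -1.4 kg
    from ._grid import MAINTENANCE_BAND_KG
    b1 = (w.loc[ids, "w12"] - w.loc[ids, "baseline"]).to_numpy(float)
    b2 = (w.loc[ids, "m6"] - w.loc[ids, "w12"]).to_numpy(float)
    lost_first6 = (b1 < -MAINTENANCE_BAND_KG) & (b2 < -MAINTENANCE_BAND_KG)
    groups = []
    for name, mask in ((f">={threshold_per_week:g}/week", hi),
                       (f"<{threshold_per_week:g}/week", ~hi)):
        groups.append({
            "group": name, "n": int(mask.sum()),
            "mean_weekly_use": float(use[mask].mean()) if mask.any() else np.nan,
            "mean_loss_kg_m12": float(loss12[mask].mean()) if mask.any() else np.nan,
            "share_loss_first_6mo": float(lost_first6[mask].mean()) if mask.any() else np.nan,
        })
    return AssociationResult(r=float(r), n=int(len(ids)), p_value=float(p),
                             threshold_groups=pd.DataFrame(groups))
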